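"""ROI extraction, fiducial detection, histogram thresholding, depot
segmentation and tissue-boundary surface extraction.

The segmentation strategy mirrors grayscale "surface determination":
the injected saline depot is brighter than SC fat in the T2-FSE-like
contrast, so a single per-ROI histogram threshold separates it; the
ID/SC and SC/IM interfaces are recovered column-by-column along the
depth axis as class transitions, with sub-voxel edge interpolation
(the rendered surfaces are single-valued height fields over the skin
plane, which keeps thickness mapping well-posed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from scipy.interpolate import NearestNDInterpolator, RegularGridInterpolator
from scipy.signal import find_peaks

from . import _mesh
from .volio import VoxelVolume, get_logger

__all__ = [
    "FiducialSet",
    "Capsule",
    "DepotSegmentation",
    "BoundarySurface",
    "extract_roi",
    "detect_fiducials",
    "select_threshold",
    "segment_depot",
    "extract_boundaries",
    "estimate_class_levels",
    "sc_band_mask",
]

log = get_logger(__name__)


@dataclass
class Capsule:
    oil_centroid_mm: np.ndarray
    oil_lower_surface_y_mm: float
    approx_radius_mm: float
    voxel_count: int = 0


@dataclass
class FiducialSet:
    capsules: list[Capsule]

    def __post_init__(self):
        # deterministic ordering for cross-stage correspondence
        self.capsules.sort(key=lambda c: (round(c.oil_centroid_mm[2], 1),
                                          round(c.oil_centroid_mm[0], 1)))

    @property
    def centroids(self) -> np.ndarray:
        return np.array([c.oil_centroid_mm for c in self.capsules])

    def __len__(self):
        return len(self.capsules)


@dataclass
class DepotSegmentation:
    """Binary depot mask plus its closed surface mesh."""

    mask: np.ndarray
    threshold_used: float
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]
    component_id: int = 0
    backfilled: bool = False
    void_filled_voxels: int = 0
    mesh: trimesh.Trimesh | None = None

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz

    @property
    def volume_mL(self) -> float:
        return float(self.mask.sum()) * self.voxel_volume_mm3 / 1000.0

    def rebuild_mesh(self) -> None:
        self.mesh = _mesh.mask_to_mesh(self.mask, self.spacing_mm, self.origin_mm)


@dataclass
class BoundarySurface:
    """Tissue interface as a height field y(x, z) plus an open sheet mesh."""

    kind: str  # "ID_SC" | "SC_IM"
    height_field: np.ndarray       # (nx, nz), mm, complete (inpainted)
    valid_mask: np.ndarray         # (nx, nz), True where measured directly
    x_mm: np.ndarray
    z_mm: np.ndarray
    mesh: trimesh.Trimesh = None

    def __post_init__(self):
        if self.mesh is None:
            self.mesh = _mesh.heightfield_mesh(self.x_mm, self.z_mm, self.height_field)

    def smoothed(self, median_size: tuple[int, int] = (3, 3),
                 gaussian_sigma: tuple[float, float] = (2.0, 0.8)) -> "BoundarySurface":
        """Median + Gaussian smoothed copy (use only after slice
        realignment, when neighbouring slices are mutually consistent).

        Tissue interfaces are smooth at the millimetre scale, so the
        low-pass mainly suppresses extraction noise -- important because
        minimum-distance measurements against a noisy sheet are biased
        low.  ``gaussian_sigma`` is in grid units (x, z)."""
        fieldv = ndimage.median_filter(self.height_field, size=median_size, mode="nearest")
        if gaussian_sigma is not None:
            fieldv = ndimage.gaussian_filter(fieldv, sigma=gaussian_sigma, mode="nearest")
        return BoundarySurface(self.kind, fieldv, self.valid_mask.copy(),
                               self.x_mm, self.z_mm)

    def height_at(self, x, z) -> np.ndarray:
        interp = RegularGridInterpolator(
            (self.x_mm, self.z_mm), self.height_field,
            bounds_error=False, fill_value=None)
        pts = np.column_stack([np.atleast_1d(x), np.atleast_1d(z)])
        return interp(pts)

    def shifted(self, shifts_xy: np.ndarray) -> "BoundarySurface":
        """Apply per-slice in-plane (x, y) corrections to the sheet."""
        nz = len(self.z_mm)
        out = np.empty_like(self.height_field)
        for k in range(nz):
            sx, sy = shifts_xy[k]
            out[:, k] = np.interp(self.x_mm - sx, self.x_mm, self.height_field[:, k]) + sy
        return BoundarySurface(self.kind, out, self.valid_mask.copy(),
                               self.x_mm, self.z_mm, mesh=None)


# ---------------------------------------------------------------------------
# ROI
# ---------------------------------------------------------------------------

def extract_roi(volume: VoxelVolume, fiducials: FiducialSet, half_extent_mm) -> VoxelVolume:
    """Lateral sub-volume centred between the fiducial capsules.

    ``half_extent_mm`` applies to the lateral axes (x and z); the full
    depth is retained.  Physical coordinates are preserved via origin
    update; a warning is emitted when the ROI is clipped by the volume
    edge, an error when it would be empty or the fiducials lie outside
    the volume.
    """
    if np.isscalar(half_extent_mm):
        hx = hz = float(half_extent_mm)
    else:
        hx, hz = (float(v) for v in half_extent_mm)
    cents = fiducials.centroids
    xs = volume.axis_coords(0)
    zs = volume.axis_coords(2)
    for c in cents:
        if not (xs[0] - 1 <= c[0] <= xs[-1] + 1 and zs[0] - 1 <= c[2] <= zs[-1] + 1):
            raise ValueError(f"fiducial at {c} lies outside the volume")
    cx, cz = cents[:, 0].mean(), cents[:, 2].mean()
    i0 = int(np.searchsorted(xs, cx - hx))
    i1 = int(np.searchsorted(xs, cx + hx, side="right"))
    k0 = int(np.searchsorted(zs, cz - hz))
    k1 = int(np.searchsorted(zs, cz + hz, side="right"))
    clipped = (cx - hx < xs[0] - 1e-9) or (cx + hx > xs[-1] + 1e-9) \
        or (cz - hz < zs[0] - 1e-9) or (cz + hz > zs[-1] + 1e-9)
    i0, k0 = max(i0, 0), max(k0, 0)
    i1, k1 = min(i1, len(xs)), min(k1, len(zs))
    if i1 <= i0 or k1 <= k0:
        raise ValueError("empty ROI")
    if clipped:
        warnings.warn("ROI clipped by volume edge", stacklevel=2)
    sub = volume.intensities[i0:i1, :, k0:k1]
    origin = (float(xs[i0]), volume.origin_mm[1], float(zs[k0]))
    return VoxelVolume(sub.copy(), volume.spacing_mm, origin,
                       stage=volume.stage, site=volume.site)


# ---------------------------------------------------------------------------
# Intensity classes
# ---------------------------------------------------------------------------

def estimate_class_levels(intensities: np.ndarray) -> dict:
    """Estimate background / muscle / SC-fat intensity modes from the
    histogram.  Relies only on the contrast ordering muscle < SC fat and
    a dominant near-zero background."""
    v = intensities.ravel()
    hi = np.percentile(v, 99.9)
    if hi <= 0:
        raise ValueError("volume appears empty")
    bins = np.linspace(0, hi * 1.02, 256)
    hist, edges = np.histogram(v, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = ndimage.gaussian_filter1d(hist.astype(float), 2.5)
    peaks, props = find_peaks(smooth, prominence=smooth.max() * 0.02)
    if len(peaks) < 2:
        raise ValueError("histogram has fewer than 2 modes; cannot separate tissue classes")
    lv_bg = centers[peaks[0]] if centers[peaks[0]] < 0.2 * hi else 0.0
    tissue_peaks = [p for p in peaks if centers[p] > max(3 * lv_bg, 0.12 * hi)]
    if len(tissue_peaks) < 2:
        raise ValueError("could not find distinct muscle and SC-fat modes")
    masses = smooth[tissue_peaks]
    top2 = sorted(np.argsort(masses)[-2:])
    lv_mus = centers[tissue_peaks[top2[0]]]
    lv_sc = centers[tissue_peaks[top2[1]]]
    if lv_mus > lv_sc:
        lv_mus, lv_sc = lv_sc, lv_mus
    return {"background": float(lv_bg), "muscle": float(lv_mus), "sc_fat": float(lv_sc)}


# ---------------------------------------------------------------------------
# Threshold selection
# ---------------------------------------------------------------------------

def select_threshold(roi, method: str = "otsu", fixed_value: float | None = None,
                     mask: np.ndarray | None = None) -> float:
    """Grayscale threshold separating SC fat from the brighter depot.

    ``method``:
      * ``"otsu"``  -- exhaustive between-class-variance maximisation over
        the integer-rounded histogram;
      * ``"valley"`` -- minimum between the two brightest prominent modes;
      * ``"fixed"`` -- returns ``fixed_value`` unchanged.
    """
    values = roi.intensities if isinstance(roi, VoxelVolume) else np.asarray(roi, float)
    if mask is not None:
        values = values[mask]
    values = values.ravel()
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("fixed method requires fixed_value")
        return float(fixed_value)
    if method == "otsu":
        return otsu_threshold(values)
    if method == "valley":
        return valley_threshold(values)
    raise ValueError(f"unknown threshold method {method!r}")


def otsu_threshold(values: np.ndarray) -> float:
    """Exhaustive Otsu on the integer-rounded histogram.

    Candidate cuts are every integer level t; classes are v <= t versus
    v > t; the returned threshold is t* + 0.5 for the maximising t (ties
    broken toward the smallest t).
    """
    v = np.round(np.asarray(values, float)).astype(np.int64)
    v = v - v.min()
    offset = np.round(np.asarray(values, float)).min()
    hist = np.bincount(v)
    if len(hist) < 2:
        raise ValueError("constant image: Otsu threshold undefined")
    p = hist.astype(float) / hist.sum()
    levels = np.arange(len(hist), dtype=float)
    w0 = np.cumsum(p)[:-1]
    w1 = 1.0 - w0
    mu0 = np.cumsum(p * levels)[:-1]
    mu_t = (p * levels).sum()
    valid = (w0 > 0) & (w1 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        m0 = mu0 / w0
        m1 = (mu_t - mu0) / w1
        between = w0 * w1 * (m0 - m1) ** 2
    between[~valid] = -np.inf
    t = int(np.argmax(between))
    return float(t + offset) + 0.5


def valley_threshold(values: np.ndarray) -> float:
    """Histogram minimum between the SC-fat mode and the depot mode."""
    v = np.asarray(values, float)
    if np.ptp(v) < 1e-9:
        raise ValueError("constant image has a unimodal histogram; no depot present")
    hist, edges = np.histogram(v, bins=128)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = ndimage.gaussian_filter1d(hist.astype(float), 2.0)
    peaks, _ = find_peaks(smooth, prominence=smooth.max() * 0.05)
    if len(peaks) < 2:
        raise ValueError("unimodal histogram: no depot mode found (no depot present?)")
    p_sc, p_dep = peaks[-2], peaks[-1]  # the two brightest modes
    valley = p_sc + int(np.argmin(smooth[p_sc:p_dep + 1]))
    return float(centers[valley])


# ---------------------------------------------------------------------------
# Fiducial detection
# ---------------------------------------------------------------------------

def detect_fiducials(volume: VoxelVolume, min_volume_mL: float = 0.05,
                     max_volume_mL: float = 1.5) -> FiducialSet:
    """Detect fish-oil capsules floating above the skin.

    Bright connected components are filtered by a capsule-plausible
    volume range and by being fully surrounded by background (capsules
    sit above the invisible dermis gap, unlike the depot which touches
    SC fat).  The oil body is modelled as a sphere: the centroid gives
    the centre, the component volume the radius, and centre + radius
    the imaged lower oil surface used for the dermal-gap estimate.
    """
    lv = estimate_class_levels(volume.intensities)
    thr = lv["sc_fat"] + 0.5 * (lv["sc_fat"] - lv["muscle"])
    bright = volume.intensities > thr
    labels, n = ndimage.label(bright, structure=np.ones((3, 3, 3)))
    if n == 0:
        raise ValueError("no fiducial capsules found")
    dx, dy, dz = volume.spacing_mm
    voxvol = dx * dy * dz
    dark = volume.intensities < 0.5 * (lv["background"] + lv["muscle"])
    capsules = []
    for lab in range(1, n + 1):
        comp = labels == lab
        count = int(comp.sum())
        vol_mL = count * voxvol / 1000.0
        if not (min_volume_mL <= vol_mL <= max_volume_mL):
            continue
        shell = ndimage.binary_dilation(comp, iterations=2) & ~comp
        if shell.sum() == 0 or dark[shell].mean() < 0.8:
            continue  # touches tissue: not a capsule
        idx = np.argwhere(comp)
        cent = idx.mean(axis=0) * np.array(volume.spacing_mm) + np.array(volume.origin_mm)
        r = (3 * count * voxvol / (4 * np.pi)) ** (1 / 3)
        # flag merged/overlapping capsules by elongation
        extent = (idx.max(axis=0) - idx.min(axis=0) + 1) * np.array(volume.spacing_mm)
        if extent.max() > 3.2 * r:
            warnings.warn("merged/overlapping fiducial capsules reported as one blob",
                          stacklevel=2)
        capsules.append(Capsule(cent, float(cent[1] + r), float(r), count))
    if not capsules:
        raise ValueError("no fiducial capsules found")
    return FiducialSet(capsules)


# ---------------------------------------------------------------------------
# Depot segmentation
# ---------------------------------------------------------------------------

def segment_depot(roi: VoxelVolume, threshold: float,
                  cannula_axis_xz: tuple[float, float] = (0.0, 0.0),
                  id_sc: "BoundarySurface | None" = None,
                  cylinder_radius_mm: float = 8.0,
                  opening_radius_mm: float | None = None) -> DepotSegmentation:
    """Threshold + clean + pick the connected component at the cannula.

    Voxels above threshold are opened with a ~1-voxel-radius structuring
    element (specified in mm, converted per axis), labelled with
    26-connectivity, and the component intersecting a cylinder around
    the cannula axis is returned (largest wins ties; nearest if none
    intersects).  Anything above the ID/SC surface (fiducial oil) is
    excluded when the surface is available.
    """
    dx, dy, dz = roi.spacing_mm
    mask = roi.intensities > threshold
    if id_sc is not None:
        ys = roi.axis_coords(1)
        xs = roi.axis_coords(0)
        zs = roi.axis_coords(2)
        interp = RegularGridInterpolator((id_sc.x_mm, id_sc.z_mm), id_sc.height_field,
                                         bounds_error=False, fill_value=None)
        X, Z = np.meshgrid(xs, zs, indexing="ij")
        idh = interp(np.column_stack([X.ravel(), Z.ravel()])).reshape(X.shape)
        below = ys[None, :, None] >= idh[:, None, :]
        mask &= below
    r = opening_radius_mm if opening_radius_mm is not None else dx
    radii = [max(int(round(r / s)), 0) for s in roi.spacing_mm]
    if any(radii):
        g = np.ogrid[tuple(slice(-v, v + 1) for v in radii)]
        dist2 = sum((gi / max(ri, 1)) ** 2 for gi, ri in zip(g, radii))
        struct = dist2 <= 1.0 + 1e-9
        # opening by reconstruction: the erosion kills speckle smaller than
        # the element, propagation restores the surviving components to
        # their exact thresholded extent (a plain opening would shave ~one
        # voxel off the whole depot surface and bias small volumes low)
        seeds = ndimage.binary_erosion(mask, structure=struct)
        mask = ndimage.binary_propagation(seeds, mask=mask)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
    if n == 0:
        log.warning("no bright component found: empty depot mask")
        return DepotSegmentation(np.zeros_like(mask), threshold, roi.spacing_mm, roi.origin_mm)
    xs = roi.axis_coords(0)
    zs = roi.axis_coords(2)
    cx, cz = cannula_axis_xz
    d2 = (xs[:, None] - cx) ** 2 + (zs[None, :] - cz) ** 2  # lateral distance to axis
    counts = np.bincount(labels.ravel())[1:]
    min_d = np.full(n, np.inf)
    for lab in range(1, n + 1):
        comp_lateral = (labels == lab).any(axis=1)
        if comp_lateral.any():
            min_d[lab - 1] = np.sqrt(d2[comp_lateral].min())
    touching = np.flatnonzero(min_d <= cylinder_radius_mm)
    if touching.size:
        best = touching[np.argmax(counts[touching])] + 1
    else:
        log.warning("no component near cannula axis: empty depot mask")
        return DepotSegmentation(np.zeros_like(mask), threshold, roi.spacing_mm, roi.origin_mm)
    out = labels == best
    seg = DepotSegmentation(out, threshold, roi.spacing_mm, roi.origin_mm,
                            component_id=int(best))
    seg.rebuild_mesh()
    return seg


# ---------------------------------------------------------------------------
# Boundary extraction
# ---------------------------------------------------------------------------

def sc_band_mask(roi: VoxelVolume, id_sc: "BoundarySurface", sc_im: "BoundarySurface") -> np.ndarray:
    """Voxels between the two boundary surfaces (the SC layer + depot)."""
    ys = roi.axis_coords(1)
    band = (ys[None, :, None] > id_sc.height_field[:, None, :]) \
        & (ys[None, :, None] < sc_im.height_field[:, None, :])
    return band


def _inpaint(fieldv: np.ndarray, valid: np.ndarray, xs, zs) -> np.ndarray:
    """Fill invalid height-field columns by harmonic (Laplace)
    interpolation from the valid rim.

    Harmonic filling is an averaging operator: rim extraction noise is
    attenuated into the hole rather than amplified (an exact polynomial
    interpolant would overshoot), and smooth surfaces are recovered to
    second order.  Grid anisotropy is respected through 1/spacing^2
    neighbour weights; array edges act as Neumann boundaries."""
    if valid.all():
        return fieldv
    X, Z = np.meshgrid(xs, zs, indexing="ij")
    pts = np.column_stack([X[valid], Z[valid]])
    near = NearestNDInterpolator(pts, fieldv[valid])
    out = fieldv.copy()
    hole = ~valid
    out[hole] = near(np.column_stack([X[hole], Z[hole]]))  # initial guess
    dx = float(xs[1] - xs[0]) if len(xs) > 1 else 1.0
    dz = float(zs[1] - zs[0]) if len(zs) > 1 else 1.0
    wx, wz = 1.0 / dx ** 2, 1.0 / dz ** 2
    for _ in range(800):
        pad = np.pad(out, 1, mode="edge")
        nbr = (wx * (pad[:-2, 1:-1] + pad[2:, 1:-1])
               + wz * (pad[1:-1, :-2] + pad[1:-1, 2:])) / (2 * wx + 2 * wz)
        delta = np.abs(nbr[hole] - out[hole]).max()
        out[hole] = nbr[hole]
        if delta < 1e-4:
            break
    return out


def reinpaint(surface: "BoundarySurface") -> "BoundarySurface":
    """Re-fill the invalid columns of a boundary surface from its valid
    neighbours (used after slice realignment, when the valid columns are
    mutually consistent again)."""
    fieldv = _inpaint(surface.height_field.copy(), surface.valid_mask,
                      surface.x_mm, surface.z_mm)
    return BoundarySurface(surface.kind, fieldv, surface.valid_mask.copy(),
                           surface.x_mm, surface.z_mm)


def extract_boundaries(roi: VoxelVolume, levels: dict | None = None,
                       invalid_disk: tuple[float, float, float] | None = None,
                       median_size: tuple[int, int] = (5, 1),
                       ) -> tuple[BoundarySurface, BoundarySurface]:
    """Extract ID/SC and SC/IM interfaces as height fields + sheet meshes.

    Per lateral column the deepest contiguous muscle run anchors the
    SC/IM interface; walking up through the contiguous tissue run (SC
    fat, through-depot columns included) until the signal drops into the
    invisible-dermis gap gives the ID/SC interface.  Both positions are
    refined to sub-voxel precision by linear interpolation of the class
    mid-level crossing.  Columns without a resolvable run (e.g. through
    the cannula void, which ``invalid_disk=(x, z, radius)`` can mark
    explicitly) are flagged invalid and inpainted from their neighbours;
    fields are median-filtered.
    """
    dx, dy, dz = roi.spacing_mm
    v = ndimage.median_filter(roi.intensities, size=(1, 3, 1))
    nx, ny, nz = v.shape
    lv = levels or estimate_class_levels(v)
    bg, mus, sc = lv["background"], lv["muscle"], lv["sc_fat"]
    t_id = 0.5 * (bg + sc)
    t_im = 0.5 * (mus + sc)
    cut_bg = 0.5 * (bg + mus)
    cut_bright = sc + 0.5 * (sc - mus)

    cols = v.transpose(0, 2, 1).reshape(-1, ny)  # (N, ny) top -> bottom
    cls = np.zeros(cols.shape, dtype=np.int8)
    cls[cols >= cut_bg] = 1          # muscle
    cls[cols >= t_im] = 2            # sc fat
    cls[cols >= cut_bright] = 3      # depot / oil

    muscle = cls == 1
    suffix = np.cumprod(muscle[:, ::-1], axis=1)[:, ::-1].astype(bool)
    mlen = suffix.sum(axis=1)
    sc_im_idx = ny - mlen
    valid = (mlen >= 3) & (sc_im_idx >= 3)
    above = np.clip(sc_im_idx - 1, 0, ny - 1)
    rows = np.arange(cols.shape[0])
    valid &= np.isin(cls[rows, above], (2, 3))

    tissue = cls >= 1
    jidx = np.arange(ny)[None, :]
    last_gap = np.maximum.accumulate(np.where(~tissue, jidx, -1), axis=1)
    id_idx = last_gap[rows, above] + 1
    valid &= (id_idx >= 2) & (above - id_idx >= 2)

    def edge_position(idx, lo, hi, upper_is_lo):
        """Sub-voxel interface depth by partial-volume integration.

        Over a 4-voxel window straddling the transition the occupancy of
        the brighter class in each voxel is (v - lo)/(hi - lo); summing
        occupancies locates the edge without the phase-bistability of
        single-pair interpolation (unbiased for any edge position
        relative to the grid, linear in the noise).  Values are clipped
        at +-0.5 occupancy beyond the classes so a stray bright (depot)
        voxel inside the window cannot dominate.
        """
        offs = np.arange(-2, 2)
        js = np.clip(idx[:, None] + offs[None, :], 0, ny - 1)
        vals = cols[rows[:, None], js]
        u = np.clip((vals - lo) / (hi - lo), -0.5, 1.5)  # occupancy of hi class
        window_top = (idx - 2) * dy - dy / 2
        if upper_is_lo:
            return window_top + (1.0 - u).sum(axis=1) * dy
        return window_top + u.sum(axis=1) * dy

    # ID/SC: invisible dermis (background level) above, SC fat below
    y_id = edge_position(id_idx, bg, sc, upper_is_lo=True)
    # SC/IM: SC fat above, darker muscle below
    y_im = edge_position(sc_im_idx, mus, sc, upper_is_lo=False)

    y_id = y_id.reshape(nx, nz) + roi.origin_mm[1]
    y_im = y_im.reshape(nx, nz) + roi.origin_mm[1]
    valid = valid.reshape(nx, nz)
    valid &= y_id < y_im

    xs = roi.axis_coords(0)
    zs = roi.axis_coords(2)
    if invalid_disk is not None:
        cx, cz, r = invalid_disk
        X, Z = np.meshgrid(xs, zs, indexing="ij")
        valid &= ((X - cx) ** 2 + (Z - cz) ** 2) > r ** 2
    if not valid.any():
        raise ValueError("no column with a resolvable SC layer")

    y_id = _inpaint(y_id, valid, xs, zs)
    y_im = _inpaint(y_im, valid, xs, zs)
    if median_size is not None:
        y_id = ndimage.median_filter(y_id, size=median_size, mode="nearest")
        y_im = ndimage.median_filter(y_im, size=median_size, mode="nearest")
    np.minimum(y_id, y_im - 1e-6, out=y_id)

    id_sc = BoundarySurface("ID_SC", y_id, valid.copy(), xs, zs)
    sc_im = BoundarySurface("SC_IM", y_im, valid.copy(), xs, zs)
    return id_sc, sc_im
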