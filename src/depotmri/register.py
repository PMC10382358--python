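"""Artifact corrections and inter-scan rigid alignment.

Implements the four corrections applied to the scans -- dermal-gap
arithmetic under the fiducial capsules, metal-void backfill from the
post-removal scan, low-order polynomial attenuation (bias) correction,
breathing slice-to-slice realignment -- plus least-squares rigid series
alignment (closed-form orthogonal Procrustes on fiducial
correspondences, refined by iterative closest point on ID-surface
samples).

The canonical per-scan ordering is: bias correction, boundary
extraction + segmentation, void backfill, slice realignment, metrics --
threshold stability requires a flat field first, and realignment
operates on the extracted boundary sheets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import _mesh
from .segment import BoundarySurface, DepotSegmentation, FiducialSet
from .volio import VoxelVolume, get_logger

__all__ = [
    "RigidTransform",
    "SliceShiftSchedule",
    "estimate_dermal_thickness",
    "backfill_void",
    "bias_correct",
    "realign_slices",
    "align_series",
    "kabsch",
]

log = get_logger(__name__)


@dataclass
class RigidTransform:
    """p_ref = rotation @ p_moving + translation (mm)."""

    rotation: np.ndarray
    translation_mm: np.ndarray
    rms_residual_mm: float = 0.0

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation_mm = np.asarray(self.translation_mm, dtype=float)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det=+1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.rotation.T + self.translation_mm

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation_mm, self.rms_residual_mm)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self ∘ other)(p) = self(other(p))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation_mm + self.translation_mm)

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(),
                "translation_mm": self.translation_mm.tolist(),
                "rms_residual_mm": float(self.rms_residual_mm)}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["rotation"]), np.array(d["translation_mm"]),
                   float(d.get("rms_residual_mm", 0.0)))


@dataclass
class SliceShiftSchedule:
    """Per-slice in-plane correction vectors (mm); near-zero mean."""

    shifts_mm: np.ndarray  # (nz, 2)

    def __post_init__(self):
        self.shifts_mm = np.asarray(self.shifts_mm, dtype=float)
        if self.shifts_mm.ndim != 2 or self.shifts_mm.shape[1] != 2:
            raise ValueError("shifts must be (nz, 2)")
        if not np.all(np.isfinite(self.shifts_mm)):
            raise ValueError("shifts must be finite")


# ---------------------------------------------------------------------------
# Dermal thickness (invisible-dermis correction)
# ---------------------------------------------------------------------------

def estimate_dermal_thickness(fiducials: FiducialSet, id_sc: BoundarySurface,
                              capsule_wall_mm: float) -> float:
    """Dermis thickness from the capsule-to-tissue gap.

    The dermis is invisible, so per capsule the vertical gap between the
    imaged oil lower surface and the ID/SC interface equals dermis +
    capsule wall; subtracting the (caliper-measured) wall thickness and
    averaging over capsules gives the dermis estimate, clamped at zero.
    """
    if capsule_wall_mm < 0:
        raise ValueError("capsule wall thickness must be non-negative")
    gaps = []
    x_lo, x_hi = id_sc.x_mm[0], id_sc.x_mm[-1]
    z_lo, z_hi = id_sc.z_mm[0], id_sc.z_mm[-1]
    for cap in fiducials.capsules:
        cx, _, cz = cap.oil_centroid_mm
        if not (x_lo <= cx <= x_hi and z_lo <= cz <= z_hi):
            continue
        boundary_y = float(id_sc.height_at(cx, cz)[0])
        gaps.append(boundary_y - cap.oil_lower_surface_y_mm)
    if not gaps:
        raise ValueError("no fiducial capsule lies above a valid boundary column")
    thickness = float(np.mean(gaps)) - capsule_wall_mm
    if thickness <= 0:
        warnings.warn(f"dermal gap does not exceed capsule wall ({thickness:.2f} mm); "
                      "clamping to 0", stacklevel=2)
        thickness = max(thickness, 0.0)
    return thickness


# ---------------------------------------------------------------------------
# Void backfill
# ---------------------------------------------------------------------------

def backfill_void(seg: DepotSegmentation, void_mask: np.ndarray,
                  reference: DepotSegmentation,
                  transform: RigidTransform | None = None) -> DepotSegmentation:
    """Backfill the cannula imaging void from the post-removal depot.

    Only voxels inside ``void_mask`` may change; they adopt the aligned
    reference depot's occupancy (nearest-neighbour transfer on the
    target grid).  ``transform`` maps reference-frame points into the
    target frame (identity when omitted).
    """
    void_mask = np.asarray(void_mask, dtype=bool)
    if void_mask.shape != seg.mask.shape:
        raise ValueError("void mask shape mismatch")
    out = seg.mask.copy()
    n_filled = 0
    if not void_mask.any():
        new = DepotSegmentation(out, seg.threshold_used, seg.spacing_mm, seg.origin_mm,
                                component_id=seg.component_id, backfilled=True,
                                void_filled_voxels=0)
        new.mesh = seg.mesh
        return new
    if not reference.mask.any():
        warnings.warn("reference (post-removal) depot empty: void left unfilled", stacklevel=2)
    else:
        t = transform or RigidTransform.identity()
        inv = t.inverse()
        idx = np.argwhere(void_mask)
        pts = idx * np.array(seg.spacing_mm) + np.array(seg.origin_mm)
        ref_pts = inv.apply(pts)
        ref_idx = np.round((ref_pts - np.array(reference.origin_mm))
                           / np.array(reference.spacing_mm)).astype(int)
        inside = np.all((ref_idx >= 0) & (ref_idx < reference.mask.shape), axis=1)
        occ = np.zeros(len(idx), dtype=bool)
        occ[inside] = reference.mask[tuple(ref_idx[inside].T)]
        before = out[tuple(idx.T)]
        out[tuple(idx.T)] = occ
        n_filled = int((occ & ~before).sum())
    new = DepotSegmentation(out, seg.threshold_used, seg.spacing_mm, seg.origin_mm,
                            component_id=seg.component_id, backfilled=True,
                            void_filled_voxels=n_filled)
    new.rebuild_mesh()
    return new


# ---------------------------------------------------------------------------
# Bias (attenuation) correction
# ---------------------------------------------------------------------------

def _poly_terms(coords: np.ndarray, order: int) -> np.ndarray:
    """Polynomial design matrix, total degree <= order, coords in [-1, 1]."""
    x, z = coords.T
    cols = []
    for i in range(order + 1):
        for k in range(order + 1 - i):
            cols.append(x ** i * z ** k)
    return np.column_stack(cols)


def bias_correct(roi: VoxelVolume, order: int = 2) -> VoxelVolume:
    """Divide out a fitted low-order polynomial attenuation field.

    The field is fitted to voxels of the dominant tissue mode (so the
    anatomy's own class structure does not masquerade as shading) and
    normalised to mean 1; the division preserves local intensity
    ordering.  A constant image is returned unchanged with a notice.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    v = roi.intensities
    if np.ptp(v) < 1e-9:
        log.info("bias_correct: constant image, returning input unchanged")
        return roi.copy()
    from .segment import estimate_class_levels

    try:
        lv = estimate_class_levels(v)
        sc, mus = lv["sc_fat"], lv["muscle"]
        # SC-fat voxels only: above the muscle/SC midpoint, below the
        # SC/bright midpoint, with headroom for the shading itself
        sel = (v > 0.5 * (sc + mus)) & (v < sc + 0.6 * (sc - mus))
    except ValueError:
        mode = float(np.median(v[v > 0.25 * v.max()]))
        sel = np.abs(v - mode) < 0.35 * mode
    if sel.sum() < 100:
        log.info("bias_correct: too few dominant-mode voxels, returning input")
        return roi.copy()
    nx, ny, nz = v.shape
    # the fit region (dominant tissue class) occupies a thin depth slab, so
    # the shading field is modelled over the lateral (x, z) plane only
    gx, _, gz = np.meshgrid(np.linspace(-1, 1, nx), np.zeros(ny),
                            np.linspace(-1, 1, nz), indexing="ij")
    grids = (gx, gz)
    coords = np.stack([g[sel] for g in grids], axis=1)
    vals = v[sel]
    if len(vals) > 200_000:  # subsample deterministically for the fit
        step = len(vals) // 200_000 + 1
        coords, vals = coords[::step], vals[::step]
    A = _poly_terms(coords, order)
    coef, *_ = np.linalg.lstsq(A, vals, rcond=None)
    full_coords = np.stack([g.ravel() for g in grids], axis=1)
    fieldv = (_poly_terms(full_coords, order) @ coef).reshape(v.shape)
    fieldv /= fieldv.mean()
    fieldv = np.clip(fieldv, 0.2, None)
    return roi.copy(intensities=v / fieldv)


# ---------------------------------------------------------------------------
# Breathing slice realignment
# ---------------------------------------------------------------------------

def _slice_misfit_shift(x_mm, contours_k, contours_ref, valid_k, valid_ref,
                        search_mm=4.0, step=0.1):
    """Best (dx, dy) aligning one slice's boundary contours to a reference.

    For a candidate lateral shift dx the optimal dy is the mean residual;
    dx is found by grid search + parabolic refinement.
    """
    ok = valid_k & valid_ref
    if ok.sum() < 8:
        return None
    dxs = np.arange(-search_mm, search_mm + step / 2, step)
    errs = np.empty(len(dxs))
    dys = np.empty(len(dxs))
    for i, dx in enumerate(dxs):
        res = []
        for ck, cr in zip(contours_k, contours_ref):
            shifted = np.interp(x_mm - dx, x_mm, ck)
            res.append((cr - shifted)[ok])
        res = np.concatenate(res)
        dy = res.mean()
        dys[i] = dy
        errs[i] = np.mean((res - dy) ** 2)
    i = int(np.argmin(errs))
    dx = dxs[i]
    if 0 < i < len(dxs) - 1:  # parabolic sub-step refinement
        e0, e1, e2 = errs[i - 1], errs[i], errs[i + 1]
        denom = e0 - 2 * e1 + e2
        if denom > 0:
            dx += step * 0.5 * (e0 - e2) / denom
    return float(dx), float(dys[i])


def realign_slices(id_sc: BoundarySurface, sc_im: BoundarySurface,
                   volume: VoxelVolume | None = None,
                   apply_to_volume: bool = False,
                   max_iter: int = 30, damping: float = 0.5,
                   ) -> tuple[SliceShiftSchedule, BoundarySurface, BoundarySurface,
                              VoxelVolume | None]:
    """Slice-to-slice realignment of the boundary sheets (stair-step fix).

    Each axial slice's in-plane (x, y) shift is chosen to minimise the
    squared mismatch of its ID/SC + SC/IM contours against the average
    contour of its two neighbouring slices; updates are damped and
    iterated to convergence, under a zero-net-mean-shift constraint so
    the series does not drift.  Slices with no valid columns inherit the
    shift of the nearest valid slice.  Returns the correction schedule
    and the corrected surfaces (and intensity volume when requested).
    """
    nz = len(id_sc.z_mm)
    x_mm = id_sc.x_mm
    total = np.zeros((nz, 2))
    cur_id = id_sc.height_field.copy()
    cur_im = sc_im.height_field.copy()
    valid = id_sc.valid_mask & sc_im.valid_mask

    for _ in range(max_iter):
        deltas = np.zeros((nz, 2))
        found = np.zeros(nz, dtype=bool)
        for k in range(nz):
            nbrs = [j for j in (k - 1, k + 1) if 0 <= j < nz]
            ref_id = np.mean([cur_id[:, j] for j in nbrs], axis=0)
            ref_im = np.mean([cur_im[:, j] for j in nbrs], axis=0)
            vref = np.logical_and.reduce([valid[:, j] for j in nbrs])
            res = _slice_misfit_shift(x_mm, (cur_id[:, k], cur_im[:, k]),
                                      (ref_id, ref_im), valid[:, k], vref)
            if res is not None:
                deltas[k] = res
                found[k] = True
        if not found.any():
            break
        if not found.all():  # copy from nearest valid slice
            good = np.flatnonzero(found)
            for k in np.flatnonzero(~found):
                deltas[k] = deltas[good[np.argmin(np.abs(good - k))]]
        deltas *= damping
        total += deltas
        for k in range(nz):
            dxk, dyk = deltas[k]
            cur_id[:, k] = np.interp(x_mm - dxk, x_mm, cur_id[:, k]) + dyk
            cur_im[:, k] = np.interp(x_mm - dxk, x_mm, cur_im[:, k]) + dyk
        if np.abs(deltas).max() < 0.02:
            break

    # Breathing motion is slice-to-slice (high-frequency along z); genuine
    # anatomy varies smoothly across slices.  Keep only the high-frequency
    # component of the estimated schedule so real structure (e.g. the
    # expansion bump's z-profile) is not smeared, and enforce zero net
    # mean shift so the series does not drift.
    if nz >= 3:
        # binomial [1,2,1]/4 smoother: zero response to slice-to-slice
        # alternation (the breathing signature), unity to smooth trends
        kern = np.array([0.25, 0.5, 0.25])
        smooth = np.column_stack([
            ndimage.correlate1d(total[:, 0], kern, mode="mirror"),
            ndimage.correlate1d(total[:, 1], kern, mode="mirror")])
        total = total - smooth
    total -= total.mean(axis=0)
    # detection deadband: a genuine stair-step is of order the breathing
    # excursion (mm); sub-0.2 mm estimates are boundary-extraction noise
    # and correcting them would only roughen clean scans
    if np.sqrt((total ** 2).mean()) < 0.2:
        total = np.zeros_like(total)
    out_id = id_sc.shifted(total)
    out_im = sc_im.shifted(total)
    out_vol = None
    if apply_to_volume and volume is not None:
        dx, dy, _ = volume.spacing_mm
        arr = volume.intensities.copy()
        for k in range(nz):
            sx, sy = total[k]
            if sx or sy:
                arr[:, :, k] = ndimage.shift(arr[:, :, k], (sx / dx, sy / dy),
                                             order=1, mode="nearest")
        out_vol = volume.copy(intensities=arr)
    return SliceShiftSchedule(total), out_id, out_im, out_vol


# ---------------------------------------------------------------------------
# Rigid series alignment
# ---------------------------------------------------------------------------

def kabsch(moving: np.ndarray, reference: np.ndarray,
           weights: np.ndarray | None = None) -> RigidTransform:
    """Closed-form least-squares rigid fit (orthogonal Procrustes)."""
    moving = np.asarray(moving, float)
    reference = np.asarray(reference, float)
    if moving.shape != reference.shape or len(moving) < 3:
        raise ValueError("need >= 3 paired points")
    w = np.ones(len(moving)) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    mu_m = (w[:, None] * moving).sum(axis=0)
    mu_r = (w[:, None] * reference).sum(axis=0)
    H = (w[:, None] * (moving - mu_m)).T @ (reference - mu_r)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = mu_r - R @ mu_m
    res = reference - (moving @ R.T + t)
    rms = float(np.sqrt((w * (res ** 2).sum(axis=1)).sum()))
    return RigidTransform(R, t, rms)


def align_series(moving_fiducials: FiducialSet, reference_fiducials: FiducialSet,
                 moving_id_sc: BoundarySurface | None = None,
                 reference_id_sc: BoundarySurface | None = None,
                 icp_iterations: int = 10, surface_samples: int = 600,
                 residual_ceiling_mm: float = 2.0) -> RigidTransform:
    """Least-squares rigid alignment of one stage onto the reference stage.

    Fiducial centroids give a closed-form Procrustes initialisation
    (correspondence by sorted order, stable for the small repositioning
    offsets involved); when ID/SC surfaces are supplied, the fit is
    refined by ICP on surface samples with the fiducials kept in the
    correspondence set.  The RMS residual decreases monotonically over
    ICP iterations (fixed correspondences are re-estimated each step).
    """
    m_pts = moving_fiducials.centroids
    r_pts = reference_fiducials.centroids
    n = min(len(m_pts), len(r_pts))
    if n < 3:
        raise ValueError("need at least 3 fiducial correspondences for rigid alignment")
    m_pts, r_pts = m_pts[:n], r_pts[:n]
    # correspondence by exhaustive permutation (capsule sets are small and
    # unlabelled; sorted order alone can swap nearly-tied capsules)
    if n <= 6:
        from itertools import permutations

        best = None
        for perm in permutations(range(n)):
            cand = kabsch(m_pts, r_pts[list(perm)])
            # repositioning between scans is small: reject implausibly
            # large candidate transforms (e.g. symmetry flips)
            angle = np.degrees(np.arccos(np.clip((np.trace(cand.rotation) - 1) / 2, -1, 1)))
            if angle > 20 or np.linalg.norm(cand.translation_mm) > 15:
                continue
            if best is None or cand.rms_residual_mm < best[0].rms_residual_mm:
                best = (cand, perm)
        if best is None:
            t = kabsch(m_pts, r_pts)
        else:
            t, perm = best
            r_pts = r_pts[list(perm)]
    else:
        t = kabsch(m_pts, r_pts)
    if moving_id_sc is None or reference_id_sc is None:
        if t.rms_residual_mm > residual_ceiling_mm:
            warnings.warn(f"alignment residual {t.rms_residual_mm:.2f} mm exceeds ceiling",
                          stacklevel=2)
        return t

    valid = moving_id_sc.valid_mask
    verts = moving_id_sc.mesh.vertices[valid.ravel()]
    step = max(len(verts) // surface_samples, 1)
    samples = verts[::step]
    prox = _mesh._MeshProximity(reference_id_sc.mesh.vertices, reference_id_sc.mesh.faces)
    # fiducials weighted up: they carry the lateral information
    fid_w = np.full(len(m_pts), float(len(samples)) / max(len(m_pts), 1) * 0.5)
    last_rms = np.inf
    for _ in range(icp_iterations):
        moved = t.apply(samples)
        _, closest = prox.query(moved)
        src = np.vstack([m_pts, samples])
        dst = np.vstack([r_pts, closest])
        w = np.concatenate([fid_w, np.ones(len(samples))])
        t_new = kabsch(src, dst, weights=w)
        if t_new.rms_residual_mm > last_rms - 1e-5:
            break
        t = t_new
        last_rms = t.rms_residual_mm
    if t.rms_residual_mm > residual_ceiling_mm:
        warnings.warn(f"alignment residual {t.rms_residual_mm:.2f} mm exceeds ceiling",
                      stacklevel=2)
    return t
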