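"""Synthetic injection-series phantom with exact ground truth.

Emulates T2-FSE-like axial MRI stacks of a large-volume subcutaneous
(LVSC) saline injection series: bright fluid depot inside the SC fat
layer, darker muscle below, an invisible dermis gap under fish-oil
fiducial capsules, 3 mm slices on a 4 mm pitch, sub-millimetre in-plane
resolution, and the four documented acquisition artifacts (invisible
dermis, metal-cannula void, grayscale attenuation gradient, breathing
stair-step).  Every stage comes with exact truth: depot mask, boundary
height fields, thickness maps, applied slice shifts and rigid offsets.

Geometry model
--------------
All anatomy lives in a fixed "anatomy frame" centred on the cannula
(x = z = 0), with y the depth axis (skin at small y).  Tissue interfaces
are single-valued height fields:

* skin surface  ``y_skin(x, z)`` -- gentle lateral curvature;
* ID/SC boundary ``y_skin + dermis`` (dermis itself is invisible);
* SC/IM boundary ``y_skin + dermis + T(x, z)`` where ``T`` is the
  pre-injection SC thickness profile.

Injection thickens the SC layer *in place* (tissue conforms): the skin
and ID/SC surfaces are lifted by a flat-top (super-Gaussian) bump whose
amplitude at the cannula equals the prescribed per-stage expansion
percentage of the baseline thickness, and whose width is solved so that
the integrated SC volume increase equals the injected volume.  The
depot is a dominant oblate spheroid with seeded angular lobes
(star-shaped implicit field), clipped inside the SC layer and trimmed
to the exact target voxel count.

Stage frames: the pre-cannulation (naive) and post-removal scans carry
small rigid offsets (subject repositioning); in-series stages share one
frame because a single infusion set stays in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volio import ScanSeries, VoxelVolume, stage_sort_key, write_truth_sidecar, write_volume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "StageTruth",
    "InfeasibleGeometryError",
    "SITE_PRESETS",
    "generate_stage",
    "apply_artifacts",
    "add_noise",
    "generate_series",
    "write_series",
    "breathing_schedule",
]

DEFAULT_LEVELS = {
    "background": 0.0,
    "dermis": 0.0,  # invisible in the sequence
    "muscle": 60.0,
    "sc_fat": 100.0,
    "depot": 200.0,
    "oil": 255.0,
}

# Study conditions per injection site: baseline SC thickness at cannula
# placement (mm), mean percent expansion per cumulative stage, protocol
# cumulative volumes (mL), and whether breathing motion affects scans
# (observed in all abdominal series).
SITE_PRESETS = {
    "abdomen": dict(
        sc_baseline_thickness_mm=19.0,
        stage_expansion_pct=(0.7, 4.5, 5.2),
        depot_volumes_mL=(2.0, 5.0, 10.0),
        breathing_shift_mm=1.0,
        fov_lateral_mm=168.0,
        depth_extent_mm=64.0,
    ),
    "thigh": dict(
        sc_baseline_thickness_mm=10.2,
        stage_expansion_pct=(11.2, 21.3, 28.5),
        depot_volumes_mL=(2.0, 5.0, 10.0),
        breathing_shift_mm=None,
        fov_lateral_mm=128.0,
        depth_extent_mm=56.0,
    ),
    "arm": dict(
        sc_baseline_thickness_mm=8.8,
        stage_expansion_pct=(5.9, 12.2),
        depot_volumes_mL=(2.0, 5.0),
        breathing_shift_mm=None,
        fov_lateral_mm=128.0,
        depth_extent_mm=48.0,
    ),
}


class InfeasibleGeometryError(ValueError):
    """Requested depot volume cannot be accommodated by the site geometry."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic injection series.

    Defaults reproduce the imaging protocol: 0.6 mm in-plane resolution,
    3 mm slices with 1 mm skip (4 mm pitch), ~10.8 cm stack extent, and
    the per-site baseline thickness / expansion presets.
    """

    site_label: str = "thigh"
    in_plane_res_mm: float = 0.6
    slice_pitch_mm: float = 4.0
    slice_thickness_mm: float = 3.0
    stack_extent_mm: float = 108.0
    # in-plane field of view (not printed in the protocol; exposed as a
    # parameter); depth extent likewise.
    fov_lateral_mm: float = 128.0
    depth_extent_mm: float = 56.0

    dermis_thickness_mm: float = 1.5
    skin_depth_mm: float = 14.0
    skin_curvature_mm: float = 6.0
    sc_baseline_thickness_mm: float = 10.2
    sc_modulation_frac: float = 0.05
    sc_modulation_wavelength_mm: tuple[float, float] = (64.0, 108.0)
    muscle_undulation_mm: float = 0.0
    muscle_undulation_wavelength_mm: tuple[float, float] = (48.0, 80.0)

    depot_volumes_mL: tuple[float, ...] = (2.0, 5.0, 10.0)
    stage_expansion_pct: tuple[float, ...] = (11.2, 21.3, 28.5)
    depot_eccentricity: float = 0.35  # depth semi-axis as fraction of final thickness
    depot_lobes: int = 4
    depot_lobe_scale: float = 0.45  # lobe radius in normalised spheroid units
    depot_margin_mm: float = 1.5

    fiducial_positions: tuple[tuple[float, float], ...] | None = None  # (x, z) on skin
    capsule_radius_mm: float = 5.0
    capsule_wall_mm: float = 0.5

    intensity_levels: dict = field(default_factory=lambda: dict(DEFAULT_LEVELS))
    noise_sigma: float = 5.0
    noise_model: str = "gaussian"  # or "rician"
    bias_field_amplitude: float = 0.15
    breathing_shift_mm: object = None  # None | amplitude | (nz, 2) array
    void_radius_mm: float = 3.0
    cannula_insertion_angle_deg: float = 0.0

    # (tx, ty, tz, rotation about depth axis in degrees)
    naive_offset: tuple[float, float, float, float] = (0.6, -0.4, 0.8, 0.5)
    post_removal_offset: tuple[float, float, float, float] = (1.2, -0.9, 0.6, -0.8)

    partial_volume: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lv = self.intensity_levels
        if lv["depot"] <= lv["sc_fat"]:
            raise ValueError("depot intensity must be strictly greater than SC fat")
        if self.slice_pitch_mm < self.slice_thickness_mm:
            raise ValueError("slice pitch must be >= slice thickness")
        for name in ("in_plane_res_mm", "slice_pitch_mm", "stack_extent_mm",
                     "dermis_thickness_mm", "sc_baseline_thickness_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.noise_sigma < 0 or self.bias_field_amplitude < 0 or self.void_radius_mm < 0:
            raise ValueError("noise/bias/void amplitudes must be non-negative")
        vols = tuple(float(v) for v in self.depot_volumes_mL)
        if any(b <= a for a, b in zip(vols, vols[1:])):
            raise ValueError("depot volumes must be strictly increasing")
        if len(self.stage_expansion_pct) != len(vols):
            raise ValueError("stage_expansion_pct must align with depot_volumes_mL")
        if any(p <= 0 for p in self.stage_expansion_pct):
            raise ValueError("stage expansion percentages must be strictly positive")
        pct = tuple(float(p) for p in self.stage_expansion_pct)
        if any(b < a for a, b in zip(pct, pct[1:])):
            raise ValueError("stage expansion percentages must be non-decreasing")

    @classmethod
    def for_site(cls, site: str, **overrides) -> "PhantomSpec":
        """Spec pre-filled with the study conditions of one site."""
        if site not in SITE_PRESETS:
            raise ValueError(f"unknown site {site!r}; expected one of {sorted(SITE_PRESETS)}")
        kw = dict(SITE_PRESETS[site])
        kw.update(overrides)
        return cls(site_label=site, **kw)

    # -- derived grid -----------------------------------------------------
    @property
    def grid_shape(self) -> tuple[int, int, int]:
        nx = int(round(self.fov_lateral_mm / self.in_plane_res_mm))
        ny = int(round(self.depth_extent_mm / self.in_plane_res_mm))
        nz = int(round(self.stack_extent_mm / self.slice_pitch_mm))
        return nx, ny, nz

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.in_plane_res_mm, self.in_plane_res_mm, self.slice_pitch_mm)

    @property
    def origin(self) -> tuple[float, float, float]:
        nx, _, nz = self.grid_shape
        return (-(nx - 1) / 2 * self.in_plane_res_mm, 0.0, -(nz - 1) / 2 * self.slice_pitch_mm)

    def stage_names(self) -> list[str]:
        return (["naive", "insertion"]
                + [f"v{v:g}" for v in self.depot_volumes_mL]
                + ["post_removal"])

    def capsule_xz(self) -> np.ndarray:
        if self.fiducial_positions is not None:
            return np.asarray(self.fiducial_positions, dtype=float)
        hx = 0.35 * self.fov_lateral_mm / 2
        hz = 0.52 * self.stack_extent_mm / 2
        # deliberately irregular placement (hand-taped capsules are never
        # symmetric); an exactly symmetric layout would make fiducial
        # correspondence ambiguous under half-turn flips
        return np.array([[-hx - 2.5, -hz + 2.0], [hx + 1.5, -hz - 2.5],
                         [-hx + 3.0, hz + 2.0], [hx - 1.0, hz - 3.0]])


@dataclass
class StageTruth:
    """Exact ground truth for one generated stage (in that stage's frame)."""

    stage: str
    depot_mask: np.ndarray
    void_mask: np.ndarray
    id_sc_height_mm: np.ndarray
    sc_im_height_mm: np.ndarray
    thickness_map_mm: np.ndarray
    true_depot_volume_mL: float
    reference_thickness_mm: float
    rotation: np.ndarray
    translation_mm: np.ndarray
    slice_shifts_mm: np.ndarray
    capsule_centers_mm: np.ndarray  # oil centres, stage frame
    oil_radius_mm: float
    cannula_xz_mm: tuple[float, float]


@dataclass
class PhantomTruth:
    site: str
    dermis_thickness_mm: float
    stages: dict[str, StageTruth] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Anatomy fields
# ---------------------------------------------------------------------------

def _skin_base(spec: PhantomSpec, x):
    half = spec.fov_lateral_mm / 2
    return spec.skin_depth_mm + spec.skin_curvature_mm * (np.asarray(x) / half) ** 2


def _thickness_base(spec: PhantomSpec, x, z):
    b = spec.sc_baseline_thickness_mm
    lx, lz = spec.sc_modulation_wavelength_mm
    t = b * (1.0 + spec.sc_modulation_frac
             * np.sin(2 * np.pi * np.asarray(x) / lx)
             * np.sin(2 * np.pi * np.asarray(z) / lz))
    if spec.muscle_undulation_mm:
        mx, mz = spec.muscle_undulation_wavelength_mm
        t = t + spec.muscle_undulation_mm * np.sin(2 * np.pi * np.asarray(x) / mx) \
                                          * np.sin(2 * np.pi * np.asarray(z) / mz)
    return t


def _bump_profile(amp_mm: float, sigma_mm: float, r2):
    """Flat-top (super-Gaussian) expansion bump.

    The plateau makes the reference-point thickness well-defined: the
    prescribed apex value holds over the depot footprint rather than at
    a single knife-edge peak, so the deepest-depot reference point (which
    is only defined up to a few mm on near-parallel surfaces) still sees
    the calibrated thickness."""
    if amp_mm == 0:
        return np.zeros_like(np.asarray(r2, dtype=float))
    return amp_mm * np.exp(-((np.asarray(r2) / (2 * sigma_mm ** 2)) ** 2))


def _solve_bump_sigma(spec: PhantomSpec, amp_mm: float, volume_mm3: float) -> float:
    """Width of the SC-expansion bump such that the discrete integral of
    the bump over the lateral grid equals the injected volume."""
    nx, _, nz = spec.grid_shape
    dx, _, dz = spec.spacing
    xs = np.arange(nx) * dx + spec.origin[0]
    zs = np.arange(nz) * dz + spec.origin[2]
    r2 = xs[:, None] ** 2 + zs[None, :] ** 2

    def integral(sigma):
        return _bump_profile(amp_mm, sigma, r2).sum() * dx * dz

    lo, hi = 1.0, 1000.0
    if integral(hi) < volume_mm3 * 0.999:
        raise InfeasibleGeometryError(
            f"expansion of {amp_mm:.3f} mm cannot accommodate {volume_mm3 / 1000:.1f} mL "
            "within the field of view; increase fov_lateral_mm or the expansion percentage"
        )
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if integral(mid) < volume_mm3:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class _StageGeom:
    stage: str
    pct: float
    volume_mm3: float
    bump_amp: float
    bump_sigma: float
    cannula: bool
    rotation: np.ndarray
    translation: np.ndarray


def _offset_to_transform(offset) -> tuple[np.ndarray, np.ndarray]:
    tx, ty, tz, deg = offset
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    # rotation about the depth (y) axis: keeps tissue boundaries height fields
    rot = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    return rot, np.array([tx, ty, tz], dtype=float)


def _series_geometry(spec: PhantomSpec) -> dict[str, _StageGeom]:
    ident = (np.eye(3), np.zeros(3))
    geoms: dict[str, _StageGeom] = {}
    b = spec.sc_baseline_thickness_mm
    geoms["naive"] = _StageGeom("naive", 0.0, 0.0, 0.0, 1.0, False,
                                *_offset_to_transform(spec.naive_offset))
    geoms["insertion"] = _StageGeom("insertion", 0.0, 0.0, 0.0, 1.0, True,
                                    ident[0].copy(), ident[1].copy())
    for v, pct in zip(spec.depot_volumes_mL, spec.stage_expansion_pct):
        amp = b * pct / 100.0
        sigma = _solve_bump_sigma(spec, amp, v * 1000.0)
        geoms[f"v{v:g}"] = _StageGeom(f"v{v:g}", pct, v * 1000.0, amp, sigma, True,
                                      ident[0].copy(), ident[1].copy())
    pct_last = spec.stage_expansion_pct[-1]
    v_last = spec.depot_volumes_mL[-1]
    amp = b * pct_last / 100.0
    geoms["post_removal"] = _StageGeom(
        "post_removal", pct_last, v_last * 1000.0, amp,
        _solve_bump_sigma(spec, amp, v_last * 1000.0), False,
        *_offset_to_transform(spec.post_removal_offset))
    return geoms


def _depot_shape(spec: PhantomSpec):
    """Series-level depot shape in normalised spheroid coordinates.

    A dominant oblate spheroid with a direction-dependent radius
    modulation (seeded angular lobes): the implicit field is star-shaped,
    so its level sets are nested and *connected* at every injected volume
    (a union of separate lobe spheroids would shed disconnected blobs at
    small volumes).  Lobes avoid the straight-down direction so the main
    bolus bottom remains the deepest depot point -- the reference for the
    thickness track."""
    t_final = spec.sc_baseline_thickness_mm * (1 + spec.stage_expansion_pct[-1] / 100.0)
    c_ax = spec.depot_eccentricity * t_final
    v_final = spec.depot_volumes_mL[-1] * 1000.0
    a_ax = np.sqrt(3 * v_final / (4 * np.pi * c_ax))
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF, 101]))
    dirs, amps = [], []
    for _ in range(spec.depot_lobes):
        phi = rng.uniform(0, 2 * np.pi)
        # y points down (depth): keep lobes lateral/up
        uy = rng.uniform(-0.5, 0.2)
        sl = np.sqrt(max(1 - uy ** 2, 0.0))
        dirs.append([np.cos(phi) * sl, uy, np.sin(phi) * sl])
        amps.append(rng.uniform(0.4, 1.0) * spec.depot_lobe_scale)
    return a_ax, c_ax, np.array(dirs).reshape(-1, 3), np.array(amps)


def _lateral_anatomy(spec, geom, x_grid, z_vals, shift_x=None):
    """Anatomy-frame lateral coordinates for scanner-frame grid points.

    ``shift_x`` is an optional per-slice breathing displacement (mm):
    the anatomy seen by slice k is shifted, so the inverse is applied
    during rasterisation (acquisition-like, no resampling blur)."""
    rot, t = geom.rotation, geom.translation
    xp = x_grid[:, None] - t[0]
    if shift_x is not None:
        xp = xp - np.asarray(shift_x)[None, :]
    zp = np.asarray(z_vals)[None, :] - t[2]
    # inverse of the y-axis rotation
    xa = rot[0, 0] * xp + rot[2, 0] * zp
    za = rot[0, 2] * xp + rot[2, 2] * zp
    return xa, za


def _stage_fields(spec, geom, x_grid, z_vals, shift=None):
    """Scanner-frame ID/SC and SC/IM height fields on a lateral grid;
    ``shift`` is the per-slice breathing (x, y) schedule or None."""
    sx = shift[:, 0] if shift is not None else None
    xa, za = _lateral_anatomy(spec, geom, x_grid, z_vals, shift_x=sx)
    skin = _skin_base(spec, xa)
    bump = _bump_profile(geom.bump_amp, geom.bump_sigma, xa ** 2 + za ** 2)
    ty = geom.translation[1]
    if shift is not None:
        ty = ty + shift[:, 1][None, :]
    id_sc = skin - bump + spec.dermis_thickness_mm + ty
    sc_im = skin + spec.dermis_thickness_mm + _thickness_base(spec, xa, za) + ty
    skin_y = skin - bump + ty
    return skin_y, id_sc, sc_im


def _capsule_centres(spec, geom) -> np.ndarray:
    """Oil centres in the stage (scanner) frame; capsules ride on the skin."""
    rot, t = geom.rotation, geom.translation
    out = []
    for cx, cz in spec.capsule_xz():
        bump = float(_bump_profile(geom.bump_amp, geom.bump_sigma,
                                   np.array(cx ** 2 + cz ** 2)))
        cy = float(_skin_base(spec, cx)) - bump - spec.capsule_radius_mm
        p = rot @ np.array([cx, cy, cz]) + t
        out.append(p)
    return np.array(out)


def _depot_mask_for_stage(spec, geom, shape_params, x_grid, y_grid, z_grid,
                          id_field, sc_im_field, shift=None) -> tuple[np.ndarray, float]:
    """Exact-count depot mask in the stage frame.

    The implicit spheroid+lobes field is thresholded at the level that
    yields exactly ``round(V / voxel_volume)`` voxels inside the clipped
    SC layer, so the truth volume matches the target within half a voxel.
    """
    a_ax, c_ax, lobe_dirs, lobe_amps = shape_params
    sx = shift[:, 0] if shift is not None else None
    xa, za = _lateral_anatomy(spec, geom, x_grid, z_grid, shift_x=sx)
    t_stage = spec.sc_baseline_thickness_mm * (1 + geom.pct / 100.0)
    yc = float(_skin_base(spec, 0.0)) - geom.bump_amp + spec.dermis_thickness_mm \
        + t_stage / 2.0 + geom.translation[1]
    yc = yc + (shift[:, 1] if shift is not None else np.zeros(len(z_grid)))  # (nz,)
    ux = xa / a_ax                      # (nx, nz)
    uz = za / a_ax
    uy = (y_grid[:, None] - yc[None, :]) / c_ax   # (ny, nz)
    r2 = ux[:, None, :] ** 2 + uy[None, :, :] ** 2 + uz[:, None, :] ** 2
    r = np.sqrt(np.maximum(r2, 1e-12))
    radius_mod = np.ones_like(r)
    ang_w2 = 0.15  # angular width of a lobe (1 - cos similarity)
    for d, amp in zip(lobe_dirs, lobe_amps):
        cos = (ux[:, None, :] * d[0] + uy[None, :, :] * d[1]
               + uz[:, None, :] * d[2]) / r
        radius_mod += amp * np.exp(-(1.0 - cos) / ang_w2)
    f = (r / radius_mod) ** 2
    margin = spec.depot_margin_mm
    clip = ((y_grid[None, :, None] >= id_field[:, None, :] + margin)
            & (y_grid[None, :, None] <= sc_im_field[:, None, :] - margin))
    voxvol = spec.in_plane_res_mm ** 2 * spec.slice_pitch_mm
    n_target = int(round(geom.volume_mm3 / voxvol))
    vals = f[clip]
    if vals.size < n_target:
        raise InfeasibleGeometryError(
            f"stage {geom.stage}: SC layer cannot hold {geom.volume_mm3 / 1000:.1f} mL")
    thr = np.partition(vals, n_target - 1)[n_target - 1]
    if thr > 1.3 ** 2:
        raise InfeasibleGeometryError(
            f"stage {geom.stage}: depot of {geom.volume_mm3 / 1000:.1f} mL does not fit "
            "the SC layer at this site without deforming beyond its intended shape")
    mask = clip & (f <= thr)
    excess = int(mask.sum()) - n_target
    if excess > 0:  # trim ties deterministically
        tie = np.argwhere(mask & (f == thr))
        for i in range(excess):
            mask[tuple(tie[i])] = False
    return mask, n_target * voxvol / 1000.0


def generate_stage(spec: PhantomSpec, stage: str, rng=None) -> tuple[VoxelVolume, StageTruth]:
    """Generate one clean (artifact- and noise-free) stage volume + truth.

    Labelled regions match the truth masks exactly before noise; with
    ``partial_volume=True`` (default) the tissue interfaces and capsules
    are rendered with analytic sub-voxel occupancy so boundary positions
    are defined to better than the voxel size.
    """
    stage_sort_key(stage)
    geoms = _series_geometry(spec)
    if stage not in geoms:
        raise ValueError(f"stage {stage!r} not part of this series ({list(geoms)})")
    geom = geoms[stage]
    lv = spec.intensity_levels
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.spacing
    xs = np.arange(nx) * dx + spec.origin[0]
    ys = np.arange(ny) * dy  # origin y = 0
    zs = np.arange(nz) * dz + spec.origin[2]
    capsules = _capsule_centres(spec, geom)
    r_oil = spec.capsule_radius_mm - spec.capsule_wall_mm
    sched = breathing_schedule(spec, stage)

    if spec.partial_volume:
        offsets = (np.arange(5) + 0.5) / 5 * spec.slice_thickness_mm - spec.slice_thickness_mm / 2
    else:
        offsets = np.array([0.0])
    ye0 = (ys - dy / 2)[None, :, None]
    ye1 = (ys + dy / 2)[None, :, None]
    intens = np.zeros((nx, ny, nz))
    y_bottom = spec.depth_extent_mm
    for off in offsets:
        _, id_f, im_f = _stage_fields(spec, geom, xs, zs + off, shift=sched)
        idb = id_f[:, None, :]
        imb = im_f[:, None, :]
        if spec.partial_volume:
            sc_frac = np.clip(np.minimum(ye1, imb) - np.maximum(ye0, idb), 0.0, None) / dy
            mus_frac = np.clip(np.minimum(ye1, y_bottom) - np.maximum(ye0, imb), 0.0, None) / dy
        else:
            yc = ys[None, :, None]
            sc_frac = ((yc >= idb) & (yc < imb)).astype(float)
            mus_frac = (yc >= imb).astype(float)
        layer = lv["sc_fat"] * sc_frac + lv["muscle"] * mus_frac
        for cap in capsules:
            d2 = (xs[:, None] - sched[:, 0][None, :] - cap[0]) ** 2 \
                + (zs[None, :] + off - cap[2]) ** 2
            h = np.sqrt(np.clip(r_oil ** 2 - d2, 0.0, None))
            has = h > 0
            if not has.any():
                continue
            cap_y = cap[1] + sched[:, 1][None, :]
            top = (cap_y - h)[:, None, :]
            bot = (cap_y + h)[:, None, :]
            if spec.partial_volume:
                oil_frac = np.clip(np.minimum(ye1, bot) - np.maximum(ye0, top), 0.0, None) / dy
            else:
                yc = ys[None, :, None]
                oil_frac = ((yc >= top) & (yc < bot)).astype(float)
            oil_frac *= has[:, None, :]
            layer += lv["oil"] * oil_frac
        intens += layer
    intens /= len(offsets)

    _, id0, im0 = _stage_fields(spec, geom, xs, zs)  # anatomy-frame truth fields
    if geom.volume_mm3 > 0:
        shape_params = _depot_shape(spec)
        _, id_obs, im_obs = _stage_fields(spec, geom, xs, zs, shift=sched)
        mask, true_vol = _depot_mask_for_stage(
            spec, geom, shape_params, xs, ys, zs, id_obs, im_obs, shift=sched)
        intens[mask] = lv["depot"]
    else:
        mask = np.zeros((nx, ny, nz), dtype=bool)
        true_vol = 0.0

    cannula_xz = (float(geom.translation[0]), float(geom.translation[2])) if geom.cannula else (0.0, 0.0)
    truth = StageTruth(
        stage=stage,
        depot_mask=mask,
        void_mask=np.zeros_like(mask),
        id_sc_height_mm=id0,
        sc_im_height_mm=im0,
        thickness_map_mm=im0 - id0,
        true_depot_volume_mL=true_vol,
        reference_thickness_mm=spec.sc_baseline_thickness_mm * (1 + geom.pct / 100.0),
        rotation=geom.rotation,
        translation_mm=geom.translation,
        slice_shifts_mm=sched.copy(),
        capsule_centers_mm=capsules,
        oil_radius_mm=r_oil,
        cannula_xz_mm=cannula_xz,
    )
    vol = VoxelVolume(intens, spec.spacing, spec.origin, stage=stage, site=spec.site_label)
    return vol, truth


# ---------------------------------------------------------------------------
# Artifacts and noise
# ---------------------------------------------------------------------------

def breathing_schedule(spec: PhantomSpec, stage: str) -> np.ndarray:
    """Per-slice in-plane (x, y) shift schedule in mm; zero-ish mean."""
    nz = spec.grid_shape[2]
    b = spec.breathing_shift_mm
    if b is None:
        return np.zeros((nz, 2))
    b_arr = np.asarray(b, dtype=float)
    if b_arr.ndim == 0:
        amp = float(b_arr)
        signs = np.where(np.arange(nz) % 2 == 0, 1.0, -1.0)
        return np.column_stack([amp * signs, amp * signs])
    if b_arr.shape != (nz, 2):
        raise ValueError(f"breathing schedule must have shape ({nz}, 2)")
    return b_arr


def apply_artifacts(volume: VoxelVolume, spec: PhantomSpec, stage: str,
                    truth: StageTruth | None = None,
                    slice_shifts: np.ndarray | None = None) -> VoxelVolume:
    """Apply metal-cannula void and attenuation bias (and, for externally
    supplied schedules, breathing slice translation).

    Generated stages already carry the breathing stair-step: it is
    rendered analytically per acquired slice (the anatomy moves between
    slice acquisitions, so each slice is a crisp shifted view -- resampling
    a finished volume would instead blur it).  Pass ``slice_shifts`` to
    translate the slices of an arbitrary volume.  The void is applied
    only while the cannula is in situ (insertion and injected stages,
    never post-removal) and follows the tissue's per-slice displacement;
    the void mask is recorded into ``truth`` when given.
    """
    geom = _series_geometry(spec)[stage]
    nx, ny, nz = volume.shape
    dx, dy, dz = volume.spacing_mm
    out = volume.intensities.copy()

    if slice_shifts is not None:
        for k in range(nz):
            sx, sy = np.asarray(slice_shifts)[k]
            if sx or sy:
                out[:, :, k] = ndimage.shift(
                    out[:, :, k], (sx / dx, sy / dy), order=1, mode="nearest")
        if truth is not None:
            truth.slice_shifts_mm = truth.slice_shifts_mm + np.asarray(slice_shifts)

    void = np.zeros((nx, ny, nz), dtype=bool)
    if geom.cannula and spec.void_radius_mm > 0:
        sched = truth.slice_shifts_mm if truth is not None \
            else breathing_schedule(spec, stage)
        xs = np.arange(nx) * dx + volume.origin_mm[0]
        ys = np.arange(ny) * dy + volume.origin_mm[1]
        zs = np.arange(nz) * dz + volume.origin_mm[2]
        skin_c = float(_skin_base(spec, 0.0)) - geom.bump_amp
        t_stage = spec.sc_baseline_thickness_mm * (1 + geom.pct / 100.0)
        y_top = skin_c - 1.0
        y_bot = skin_c + spec.dermis_thickness_mm + 0.75 * t_stage
        tilt = np.tan(np.deg2rad(spec.cannula_insertion_angle_deg))
        x_axis = tilt * (ys - y_top)  # cannula enters at the origin
        d2 = ((xs[:, None, None] - x_axis[None, :, None]
               - sched[:, 0][None, None, :]) ** 2
              + (zs[None, None, :]) ** 2)
        in_y = (ys[None, :, None] >= y_top + sched[:, 1][None, None, :]) \
            & (ys[None, :, None] <= y_bot + sched[:, 1][None, None, :])
        void = (d2 < spec.void_radius_mm ** 2) & in_y
        out[void] = spec.intensity_levels["background"]
    if truth is not None:
        truth.void_mask = void

    if spec.bias_field_amplitude > 0:
        xs = np.arange(nx) * dx + volume.origin_mm[0]
        half = spec.fov_lateral_mm / 2
        fieldv = np.clip(1.0 + spec.bias_field_amplitude * xs / half, 0.05, None)
        out *= fieldv[:, None, None]

    return volume.copy(intensities=out)


def add_noise(volume: VoxelVolume, spec: PhantomSpec, rng: np.random.Generator) -> VoxelVolume:
    if spec.noise_sigma <= 0:
        return volume
    s = spec.noise_sigma
    v = volume.intensities
    if spec.noise_model == "rician":
        out = np.sqrt((v + rng.normal(0, s, v.shape)) ** 2 + rng.normal(0, s, v.shape) ** 2)
    else:
        out = np.clip(v + rng.normal(0, s, v.shape), 0.0, None)
    return volume.copy(intensities=out)


# ---------------------------------------------------------------------------
# Series
# ---------------------------------------------------------------------------

def generate_series(spec: PhantomSpec) -> tuple[ScanSeries, PhantomTruth]:
    """Generate the full stage sequence (naive ... post_removal) + truth.

    Deterministic: identical spec (including seed) yields bit-identical
    volumes.  Small rigid offsets separate the naive and post-removal
    frames from the in-series frame (subject repositioning).
    """
    truth = PhantomTruth(site=spec.site_label, dermis_thickness_mm=spec.dermis_thickness_mm)
    volumes = {}
    for idx, stage in enumerate(spec.stage_names()):
        vol, st = generate_stage(spec, stage)
        vol = apply_artifacts(vol, spec, stage, truth=st)
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF, idx]))
        vol = add_noise(vol, spec, rng)
        volumes[stage] = vol
        truth.stages[stage] = st
    return ScanSeries(site=spec.site_label, volumes=volumes), truth


def write_series(series: ScanSeries, truth: PhantomTruth | None, out_dir: str | Path) -> Path:
    """Write one NIfTI per stage plus the JSON truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for stage, vol in series.volumes.items():
        write_volume(vol, out_dir / f"{stage}.nii.gz")
    if truth is not None:
        write_truth_sidecar(truth, out_dir / "truth.json")
    return out_dir
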