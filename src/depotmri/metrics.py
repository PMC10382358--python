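"""Depot and tissue morphometrics.

Quantities reported per scan: depot volume (mL), minimum 3-D distances
from the depot surface to the ID/SC and SC/IM boundary sheets, depth
from the skin surface (ID/SC distance plus mean dermal thickness),
orthographic projected area parallel to the skin with principal-axis
dimensions, SC thickness maps (minimum 3-D distance between the two
boundary sheets, column-wise), the fixed-reference-point thickness
track across an injection series, and skin-surface heat maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from . import _mesh
from .register import RigidTransform
from .segment import BoundarySurface, DepotSegmentation
from .volio import get_logger, stage_sort_key

__all__ = [
    "DepotMetrics",
    "ThicknessMap",
    "SeriesThicknessTrack",
    "depot_volume",
    "min_distance",
    "depth_from_skin",
    "project_and_axes",
    "ProjectionResult",
    "thickness_map",
    "track_reference_thickness",
    "render_heatmap",
]

log = get_logger(__name__)


@dataclass
class DepotMetrics:
    volume_mL: float
    min_dist_to_id_sc_mm: float
    min_dist_to_sc_im_mm: float
    depth_from_skin_mm: float
    projected_area_cm2: float
    principal_x_mm: float
    principal_y_mm: float
    z_extent_mm: float

    def __post_init__(self):
        if self.principal_x_mm < self.principal_y_mm:  # ordering convention
            self.principal_x_mm, self.principal_y_mm = self.principal_y_mm, self.principal_x_mm


@dataclass
class ThicknessMap:
    values_mm: np.ndarray      # (nx, nz)
    valid_mask: np.ndarray
    x_mm: np.ndarray
    z_mm: np.ndarray
    stats: dict = field(default_factory=dict)
    hist_edges_mm: np.ndarray | None = None
    hist_pct: np.ndarray | None = None


@dataclass
class SeriesThicknessTrack:
    reference_point_mm: np.ndarray
    thickness_mm: dict[str, float]
    percent_change: dict[str, float]  # vs. cannula placement; empty w/o insertion


# ---------------------------------------------------------------------------

def depot_volume(seg: DepotSegmentation, spacing_mm=None) -> float:
    """Mask voxel count x voxel volume, in mL."""
    dx, dy, dz = spacing_mm if spacing_mm is not None else seg.spacing_mm
    return float(seg.mask.sum()) * dx * dy * dz / 1000.0


def min_distance(depot_mesh: trimesh.Trimesh, boundary: BoundarySurface) -> float:
    """Minimum Euclidean point-to-triangle distance from the depot surface
    vertices to the boundary sheet; 0 when the depot crosses the sheet."""
    if depot_mesh is None or len(depot_mesh.vertices) == 0:
        raise ValueError("empty depot mesh")
    verts = depot_mesh.vertices
    d, _ = _mesh.closest_on_mesh(verts, boundary.mesh)
    heights = boundary.height_at(verts[:, 0], verts[:, 2])
    side = verts[:, 1] - heights
    if np.nanmin(side) < 0 < np.nanmax(side):  # crosses the sheet
        return 0.0
    return float(d.min())


def depth_from_skin(min_dist_to_id_sc_mm: float, dermal_thickness_mm: float) -> float:
    """Depot depth from the skin surface: ID/SC offset + mean dermis."""
    if min_dist_to_id_sc_mm < 0 or dermal_thickness_mm < 0:
        raise ValueError("distances must be non-negative")
    return float(min_dist_to_id_sc_mm + dermal_thickness_mm)


@dataclass
class ProjectionResult:
    projected_area_cm2: float
    principal_x_mm: float
    principal_y_mm: float
    z_extent_mm: float


def project_and_axes(depot_mesh: trimesh.Trimesh,
                     id_sc: BoundarySurface | None = None,
                     pixel_mm: float = 0.25) -> ProjectionResult:
    """Orthographic depot footprint parallel to the skin surface.

    The local skin plane is the least-squares plane through the ID/SC
    surface over the depot's lateral footprint (identity orientation
    when no surface is given).  The depot is rotated so that plane maps
    to X-Y, its triangles are rasterised at ``pixel_mm``, and the
    principal axes are the maximal caliper extent along the footprint's
    first principal direction and the orthogonal extent.
    """
    from skimage.draw import polygon as sk_polygon

    if depot_mesh is None or len(depot_mesh.faces) == 0:
        raise ValueError("empty depot mesh")
    verts = depot_mesh.vertices
    if id_sc is not None:
        pad = 5.0
        sel_x = (id_sc.x_mm >= verts[:, 0].min() - pad) & (id_sc.x_mm <= verts[:, 0].max() + pad)
        sel_z = (id_sc.z_mm >= verts[:, 2].min() - pad) & (id_sc.z_mm <= verts[:, 2].max() + pad)
        X, Z = np.meshgrid(id_sc.x_mm[sel_x], id_sc.z_mm[sel_z], indexing="ij")
        Y = id_sc.height_field[np.ix_(sel_x, sel_z)]
        A = np.column_stack([X.ravel(), Z.ravel(), np.ones(X.size)])
        coef, *_ = np.linalg.lstsq(A, Y.ravel(), rcond=None)
        normal = np.array([-coef[0], 1.0, -coef[1]])
        normal /= np.linalg.norm(normal)
    else:
        normal = np.array([0.0, 1.0, 0.0])
    e1 = np.array([1.0, 0.0, 0.0])
    e1 = e1 - e1.dot(normal) * normal
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    basis = np.column_stack([e1, e2])  # in-plane coordinates
    uv = verts @ basis
    depth = verts @ normal
    z_extent = float(depth.max() - depth.min())

    lo = uv.min(axis=0) - 2 * pixel_mm
    hi = uv.max(axis=0) + 2 * pixel_mm
    shape = np.ceil((hi - lo) / pixel_mm).astype(int) + 1
    grid = np.zeros(shape, dtype=bool)
    tri_uv = (uv[depot_mesh.faces] - lo) / pixel_mm  # (nf, 3, 2)
    for tri in tri_uv:
        rr, cc = sk_polygon(tri[:, 0], tri[:, 1], shape=grid.shape)
        grid[rr, cc] = True
    n_px = int(grid.sum())
    area_cm2 = n_px * pixel_mm ** 2 / 100.0
    if n_px == 0:
        warnings.warn("degenerate (flat) depot footprint", stacklevel=2)
        return ProjectionResult(0.0, 0.0, 0.0, z_extent)
    px_uv = np.argwhere(grid) * pixel_mm + lo
    centered = px_uv - px_uv.mean(axis=0)
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evecs = evecs[:, order]
    # tie-break toward the x-grid direction
    if abs(evals[order[0]] - evals[order[1]]) < 1e-9:
        evecs = np.eye(2)
    proj1 = centered @ evecs[:, 0]
    proj2 = centered @ evecs[:, 1]
    p1 = float(proj1.max() - proj1.min()) + pixel_mm
    p2 = float(proj2.max() - proj2.min()) + pixel_mm
    if p2 > p1:
        p1, p2 = p2, p1
    return ProjectionResult(area_cm2, p1, p2, z_extent)


# ---------------------------------------------------------------------------
# Thickness mapping
# ---------------------------------------------------------------------------

def thickness_map(id_sc: BoundarySurface, sc_im: BoundarySurface,
                  mode: str = "min3d", hist_bin_mm: float = 1.0) -> ThicknessMap:
    """SC thickness over the skin-plane grid.

    Per column the thickness is the minimum 3-D distance from the SC/IM
    surface point to the ID/SC sheet (``mode="min3d"``, the default) or
    the plain vertical gap (``mode="vertical"``, for sensitivity
    analysis).  Includes summary statistics and a percent-frequency
    histogram (frequencies sum to 100).
    """
    if not np.array_equal(id_sc.x_mm, sc_im.x_mm) or not np.array_equal(id_sc.z_mm, sc_im.z_mm):
        raise ValueError("boundary surfaces must share the same lateral grid")
    valid = id_sc.valid_mask & sc_im.valid_mask
    if not valid.any():
        raise ValueError("boundary surfaces have disjoint valid regions")
    X, Z = np.meshgrid(id_sc.x_mm, id_sc.z_mm, indexing="ij")
    if mode == "vertical":
        vals = sc_im.height_field - id_sc.height_field
    elif mode == "min3d":
        pts = np.column_stack([X.ravel(), sc_im.height_field.ravel(), Z.ravel()])
        d, _ = _mesh.closest_on_mesh(pts, id_sc.mesh)
        vals = d.reshape(X.shape)
    else:
        raise ValueError(f"unknown thickness mode {mode!r}")
    vals = np.clip(vals, 0.0, None)
    sel = vals[valid]
    stats = {
        "mean": float(sel.mean()), "median": float(np.median(sel)),
        "sd": float(sel.std(ddof=1)) if sel.size > 1 else 0.0,
        "min": float(sel.min()), "max": float(sel.max()), "n": int(sel.size),
    }
    top = max(np.ceil(sel.max() / hist_bin_mm), 1) * hist_bin_mm
    edges = np.arange(0.0, top + hist_bin_mm / 2, hist_bin_mm)
    hist, edges = np.histogram(sel, bins=edges)
    pct = hist / hist.sum() * 100.0
    return ThicknessMap(vals, valid, id_sc.x_mm, id_sc.z_mm, stats, edges, pct)


def track_reference_thickness(id_sc_by_stage: dict[str, BoundarySurface],
                              sc_im_by_stage: dict[str, BoundarySurface],
                              depot_mesh_largest: trimesh.Trimesh,
                              largest_stage: str,
                              transforms: dict[str, RigidTransform] | None = None,
                              insertion_stage: str = "insertion",
                              ) -> SeriesThicknessTrack:
    """SC thickness at the fixed deepest-depot reference point.

    The reference is the SC/IM surface point closest to the depot at the
    largest injected stage.  It is carried to every other stage through
    the per-stage rigid alignment transforms (stage frame -> common
    frame) and re-interpolated onto that stage's SC/IM surface -- the
    muscle interface is the stable anchor, and snapping removes the
    depth component of any residual rigid-alignment error (tissue
    expansion is not rigid).  The thickness at each stage is then the
    minimum 3-D distance from the snapped point to the stage's ID/SC
    sheet.  Percent change is relative to the cannula-placement
    (insertion) scan; when that scan is missing the absolute values are
    still reported.
    """
    transforms = transforms or {}
    if largest_stage not in id_sc_by_stage or largest_stage not in sc_im_by_stage:
        raise ValueError("largest stage surfaces missing")
    if depot_mesh_largest is None or len(depot_mesh_largest.vertices) == 0:
        raise ValueError("empty depot mesh at the largest stage")
    sc_im_largest = sc_im_by_stage[largest_stage]
    valid = sc_im_largest.valid_mask.ravel()
    pts = sc_im_largest.mesh.vertices
    d, _ = _mesh.closest_on_mesh(pts, depot_mesh_largest)
    d = np.where(valid, d, np.inf)
    ref_stage_point = pts[int(np.argmin(d))]

    t_largest = transforms.get(largest_stage, RigidTransform.identity())
    ref_common = t_largest.apply(ref_stage_point)

    thick: dict[str, float] = {}
    for stage, surf in sorted(id_sc_by_stage.items(), key=lambda kv: stage_sort_key(kv[0])):
        t = transforms.get(stage, RigidTransform.identity())
        p_stage = t.inverse().apply(ref_common)
        if stage in sc_im_by_stage:  # interpolate onto this stage's IM surface
            _, snapped = _mesh.closest_on_mesh(p_stage[None, :], sc_im_by_stage[stage].mesh)
            p_stage = snapped[0]
        dist, _ = _mesh.closest_on_mesh(p_stage[None, :], surf.mesh)
        thick[stage] = float(dist[0])

    pct: dict[str, float] = {}
    if insertion_stage in thick:
        base = thick[insertion_stage]
        for stage, val in thick.items():
            pct[stage] = (val - base) / base * 100.0
    else:
        log.warning("insertion stage missing: percent change undefined")
    return SeriesThicknessTrack(np.asarray(ref_common), thick, pct)


# ---------------------------------------------------------------------------
# Heat maps
# ---------------------------------------------------------------------------

def render_heatmap(tmap: ThicknessMap, out_path, vmin: float | None = None,
                   vmax: float | None = None, title: str | None = None):
    """Top-down SC-thickness heat map PNG (shallow blue -> thick dark red).

    Pass the same ``vmin``/``vmax`` for every stage of a site so the
    colour scale is comparable across the series.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmin = float(tmap.values_mm[tmap.valid_mask].min()) if vmin is None else vmin
    vmax = float(tmap.values_mm[tmap.valid_mask].max()) if vmax is None else vmax
    if vmax <= vmin:
        vmax = vmin + 1e-6
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(tmap.values_mm.T, origin="lower", cmap="turbo",
                   vmin=vmin, vmax=vmax, aspect="auto",
                   extent=(tmap.x_mm[0], tmap.x_mm[-1], tmap.z_mm[0], tmap.z_mm[-1]))
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("z (mm)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="SC thickness (mm)")
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return out_path
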