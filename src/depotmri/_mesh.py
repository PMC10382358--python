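"""Shared triangle-mesh geometry: exact point-to-triangle distances with a
k-d-tree prefilter, height-field triangulation, and mask iso-surfacing.

The point-to-triangle primitive is written out in full (vectorised
Ericson closest-point-on-triangle) because minimum 3-D depot-to-boundary
distances are a core measurement of the pipeline and must be testable
against a brute-force oracle.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "closest_point_on_triangles",
    "closest_on_mesh",
    "heightfield_mesh",
    "mask_to_mesh",
]


def closest_point_on_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Closest point on each triangle ``(a, b, c)`` to each point ``p``.

    All inputs broadcast to a common leading shape with trailing dim 3.
    Returns ``(closest, dist2)``.
    """
    p, a, b, c = np.broadcast_arrays(p, a, b, c)
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("...i,...i", ab, ap)
    d2 = np.einsum("...i,...i", ac, ap)
    bp = p - b
    d3 = np.einsum("...i,...i", ab, bp)
    d4 = np.einsum("...i,...i", ac, bp)
    cp = p - c
    d5 = np.einsum("...i,...i", ab, cp)
    d6 = np.einsum("...i,...i", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    denom_ab = d1 - d3
    v_ab = np.where(denom_ab != 0, d1 / np.where(denom_ab == 0, 1.0, denom_ab), 0.0)
    denom_ac = d2 - d6
    w_ac = np.where(denom_ac != 0, d2 / np.where(denom_ac == 0, 1.0, denom_ac), 0.0)
    denom_bc = (d4 - d3) + (d5 - d6)
    w_bc = np.where(denom_bc != 0, (d4 - d3) / np.where(denom_bc == 0, 1.0, denom_bc), 0.0)

    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v_in = vb / denom
    w_in = vc / denom

    closest = a + v_in[..., None] * ab + w_in[..., None] * ac  # interior default

    # edge BC region
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    wbc = np.clip(w_bc, 0.0, 1.0)
    closest = np.where(on_bc[..., None], b + wbc[..., None] * (c - b), closest)
    # edge AC region
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    wac = np.clip(w_ac, 0.0, 1.0)
    closest = np.where(on_ac[..., None], a + wac[..., None] * ac, closest)
    # edge AB region
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    vab = np.clip(v_ab, 0.0, 1.0)
    closest = np.where(on_ab[..., None], a + vab[..., None] * ab, closest)
    # vertex regions
    closest = np.where(((d6 >= 0) & (d5 - d6 <= 0))[..., None], c, closest)
    closest = np.where(((d3 >= 0) & (d4 - d3 <= 0))[..., None], b, closest)
    closest = np.where(((d1 <= 0) & (d2 <= 0))[..., None], a, closest)

    diff = p - closest
    return closest, np.einsum("...i,...i", diff, diff)


class _MeshProximity:
    """k-d-tree accelerated closest-point queries against one mesh."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, k: int = 8):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        self.k = int(min(k, len(self.vertices)))
        self.tree = cKDTree(self.vertices)
        # vertex -> incident faces, padded with -1
        counts = np.zeros(len(self.vertices), dtype=np.int64)
        np.add.at(counts, self.faces.ravel(), 1)
        max_deg = max(int(counts.max()), 1)
        incident = np.full((len(self.vertices), max_deg), -1, dtype=np.int64)
        cursor = np.zeros(len(self.vertices), dtype=np.int64)
        for fi, tri in enumerate(self.faces):
            for v in tri:
                incident[v, cursor[v]] = fi
                cursor[v] += 1
        self.incident = incident

    def query(self, points: np.ndarray, chunk: int = 4096):
        """Return (distances, closest_points) from each point to the mesh."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        out_d = np.empty(n)
        out_p = np.empty((n, 3))
        for lo in range(0, n, chunk):
            pts = points[lo: lo + chunk]
            _, vidx = self.tree.query(pts, k=self.k)
            vidx = np.atleast_2d(vidx)
            cand = self.incident[vidx].reshape(len(pts), -1)  # (m, k*max_deg)
            bad = cand < 0
            cand = np.where(bad, 0, cand)
            tri = self.faces[cand]  # (m, c, 3)
            a = self.vertices[tri[..., 0]]
            b = self.vertices[tri[..., 1]]
            c = self.vertices[tri[..., 2]]
            cp, d2 = closest_point_on_triangles(pts[:, None, :], a, b, c)
            d2 = np.where(bad, np.inf, d2)
            best = np.argmin(d2, axis=1)
            rows = np.arange(len(pts))
            out_d[lo: lo + chunk] = np.sqrt(d2[rows, best])
            out_p[lo: lo + chunk] = cp[rows, best]
        return out_d, out_p


def closest_on_mesh(points: np.ndarray, mesh: trimesh.Trimesh, k: int = 8):
    """Distances and closest points from ``points`` to a triangle mesh."""
    prox = _MeshProximity(mesh.vertices, mesh.faces, k=k)
    return prox.query(points)


def heightfield_mesh(x_mm: np.ndarray, z_mm: np.ndarray, height_y_mm: np.ndarray) -> trimesh.Trimesh:
    """Triangulate a single-valued surface y(x, z) into an open sheet.

    ``height_y_mm`` has shape ``(len(x_mm), len(z_mm))``.
    """
    nx, nz = height_y_mm.shape
    if nx != len(x_mm) or nz != len(z_mm):
        raise ValueError("height field shape does not match grid")
    X, Z = np.meshgrid(np.asarray(x_mm, float), np.asarray(z_mm, float), indexing="ij")
    verts = np.column_stack([X.ravel(), np.asarray(height_y_mm, float).ravel(), Z.ravel()])
    idx = np.arange(nx * nz).reshape(nx, nz)
    v00 = idx[:-1, :-1].ravel()
    v10 = idx[1:, :-1].ravel()
    v01 = idx[:-1, 1:].ravel()
    v11 = idx[1:, 1:].ravel()
    faces = np.concatenate(
        [np.column_stack([v00, v10, v11]), np.column_stack([v00, v11, v01])], axis=0
    )
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def mask_to_mesh(mask: np.ndarray, spacing_mm, origin_mm=(0.0, 0.0, 0.0)) -> trimesh.Trimesh | None:
    """Closed iso-surface mesh of a binary voxel mask (marching cubes).

    Returns ``None`` for an empty mask.  The mask is zero-padded so the
    surface closes at the array edge; vertices are in physical mm.
    """
    from skimage.measure import marching_cubes

    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return None
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(spacing_mm))
    verts = verts - np.asarray(spacing_mm, dtype=float) + np.asarray(origin_mm, dtype=float)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:  # enforce outward orientation
        mesh = trimesh.Trimesh(vertices=verts, faces=faces[:, ::-1], process=False)
    return mesh
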