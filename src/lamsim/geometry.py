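"""Rigid transforms and triangle-mesh utilities.

Everything operates in the global Cartesian frame of the model:
x = left lateral, y = anterior, z = cranial, millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import GeometryError, InvalidInputError

__all__ = ["RigidTransform", "closest_point_on_triangles", "surface_point_query",
           "triangle_areas_normals"]

_ORTHO_TOL = 1e-10


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> R x + t (R proper orthogonal, t in mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-8:
            raise InvalidInputError("rotation is not orthogonal")
        if np.linalg.det(R) < 0:
            raise InvalidInputError("rotation is improper (det R = -1)")
        # re-orthonormalize to machine precision so long compositions stay clean
        u, _, vt = np.linalg.svd(R)
        R = u @ vt
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls):
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points):
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform"):
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self):
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def triangle_areas_normals(vertices, faces):
    """Per-triangle areas (mm^2) and unit normals; raises on degenerate faces."""
    v = np.asarray(vertices, float)
    f = np.asarray(faces, int)
    e1 = v[f[:, 1]] - v[f[:, 0]]
    e2 = v[f[:, 2]] - v[f[:, 0]]
    cr = np.cross(e1, e2)
    nrm = np.linalg.norm(cr, axis=1)
    if np.any(nrm <= 1e-12):
        raise GeometryError(f"{int((nrm <= 1e-12).sum())} degenerate triangle(s)")
    return 0.5 * nrm, cr / nrm[:, None]


def closest_point_on_triangles(points, tri_vertices):
    """Closest point on each triangle for each point (paired, vectorized).

    ``points``: (n, 3); ``tri_vertices``: (n, 3, 3).  Returns (closest, dist2).
    Standard region-classification algorithm on the barycentric plane.
    """
    p = np.asarray(points, float)
    a, b, c = tri_vertices[:, 0], tri_vertices[:, 1], tri_vertices[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def setwhere(mask, value):
        m = mask & ~done
        out[m] = value[m]
        done[m] = True

    setwhere((d1 <= 0) & (d2 <= 0), a)                               # vertex A
    setwhere((d3 >= 0) & (d4 <= d3), b)                              # vertex B
    setwhere((d6 >= 0) & (d5 <= d6), c)                              # vertex C
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    setwhere((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)   # edge AB
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    setwhere((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)   # edge AC
    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = np.where((d4 - d3) + (d5 - d6) != 0,
                        (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
    setwhere((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
             b + w_bc[:, None] * (c - b))                                  # edge BC
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v_in = np.where(denom != 0, vb / denom, 0.0)
        w_in = np.where(denom != 0, vc / denom, 0.0)
    inner = a + v_in[:, None] * ab + w_in[:, None] * ac                    # interior
    out[~done] = inner[~done]
    d = p - out
    return out, np.einsum("ij,ij->i", d, d)


class SurfaceProximity:
    """Accelerated closest-point queries against a fixed triangle surface.

    A k-d tree on triangle centroids prunes to ``k`` candidate triangles per
    query point; the exact point-triangle projection picks the winner.  For
    smooth, reasonably uniform meshes this matches the exhaustive search.
    """

    def __init__(self, vertices, faces, k=16):
        self.vertices = np.asarray(vertices, float)
        self.faces = np.asarray(faces, int)
        _, self.face_normals = triangle_areas_normals(self.vertices, self.faces)
        self.tri = self.vertices[self.faces]           # (m, 3, 3)
        self.centroids = self.tri.mean(axis=1)
        self.k = min(k, len(self.faces))
        self.tree = cKDTree(self.centroids)

    def query(self, points):
        """Return (closest_points, distances, face_indices) for each point."""
        p = np.asarray(points, float)
        _, cand = self.tree.query(p, k=self.k)
        cand = np.atleast_2d(cand)
        n, k = cand.shape
        flat_pts = np.repeat(p, k, axis=0)
        flat_tris = self.tri[cand.ravel()]
        cp, d2 = closest_point_on_triangles(flat_pts, flat_tris)
        d2 = d2.reshape(n, k)
        best = np.argmin(d2, axis=1)
        rows = np.arange(n)
        face_idx = cand[rows, best]
        closest = cp.reshape(n, k, 3)[rows, best]
        return closest, np.sqrt(d2[rows, best]), face_idx


def surface_point_query(vertices, faces, points, k=16):
    """One-shot convenience wrapper around :class:`SurfaceProximity`."""
    return SurfaceProximity(vertices, faces, k=k).query(points)
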