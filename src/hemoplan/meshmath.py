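"""Exact triangle-mesh geometry primitives used by the planners.

All queries are brute-force vectorised over faces with numpy — the meshes
involved (lesion surfaces, skull tables) have at most a few hundred
thousand triangles and each planning run needs only a handful of queries,
so no spatial index is required.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ray_triangle_hits", "closest_point_on_mesh", "point_in_mesh"]

_EPS = 1e-12


def ray_triangle_hits(origin, direction, vertices, faces) -> np.ndarray:
    """Sorted positive ray parameters t of all intersections of the ray
    ``origin + t * direction`` with the mesh (Moller-Trumbore, inclusive
    of triangle edges)."""
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    v0 = vertices[faces[:, 0]]
    e1 = vertices[faces[:, 1]] - v0
    e2 = vertices[faces[:, 2]] - v0
    pvec = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > _EPS
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = origin - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
    qvec = np.cross(tvec, e1)
    v = np.einsum("j,ij->i", direction, qvec) * inv_det
    t = np.einsum("ij,ij->i", e2, qvec) * inv_det
    hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t > 1e-9)
    return np.sort(t[hit])


def _closest_points_on_triangles(p, v0, v1, v2):
    """Closest point to ``p`` on each triangle (Ericson's region method)."""
    ab = v1 - v0
    ac = v2 - v0
    ap = p - v0
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - v1
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - v2
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    result = np.empty_like(v0)
    done = np.zeros(len(v0), dtype=bool)

    def assign(cond, value):
        sel = cond & ~done
        result[sel] = value[sel] if value.ndim == 2 else value
        done[sel] = True

    assign((d1 <= 0) & (d2 <= 0), v0)  # vertex A
    assign((d3 >= 0) & (d4 <= d3), v1)  # vertex B
    assign((d6 >= 0) & (d5 <= d6), v2)  # vertex C

    vc = d1 * d4 - d3 * d2
    t = np.divide(d1, d1 - d3, out=np.zeros_like(d1), where=np.abs(d1 - d3) > _EPS)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), v0 + t[:, None] * ab)  # edge AB

    vb = d5 * d2 - d1 * d6
    t = np.divide(d2, d2 - d6, out=np.zeros_like(d2), where=np.abs(d2 - d6) > _EPS)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), v0 + t[:, None] * ac)  # edge AC

    va = d3 * d6 - d5 * d4
    denom = (d4 - d3) + (d6 - d5)
    t = np.divide(d4 - d3, denom, out=np.zeros_like(d4), where=np.abs(denom) > _EPS)
    assign((va <= 0) & (d4 - d3 >= 0) & (d6 - d5 <= 0), v1 + t[:, None] * (v2 - v1))  # edge BC

    # interior
    denom = va + vb + vc
    denom = np.where(np.abs(denom) > _EPS, denom, 1.0)
    u = vb / denom
    w = vc / denom
    assign(np.ones(len(v0), dtype=bool), v0 + u[:, None] * ab + w[:, None] * ac)
    return result


def closest_point_on_mesh(point, vertices, faces) -> tuple[np.ndarray, float]:
    """Globally closest surface point on the mesh and its distance."""
    p = np.asarray(point, dtype=float)
    cand = _closest_points_on_triangles(p, vertices[faces[:, 0]], vertices[faces[:, 1]], vertices[faces[:, 2]])
    d2 = ((cand - p) ** 2).sum(axis=1)
    k = int(np.argmin(d2))
    return cand[k], float(np.sqrt(d2[k]))


def point_in_mesh(point, vertices, faces) -> bool:
    """Ray-parity containment test for a closed mesh.

    An odd number of crossings along a probe ray means inside.  The probe
    direction is fixed but irrational-ish so it avoids axis-aligned
    edge/vertex grazing on marching-cubes meshes."""
    direction = np.array([0.57735026, 0.51449575, 0.63245553])
    t = ray_triangle_hits(point, direction, vertices, faces)
    # collapse duplicate hits from shared edges
    if len(t) > 1:
        t = t[np.concatenate([[True], np.diff(t) > 1e-9])]
    return len(t) % 2 == 1
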