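"""Low-level triangle-mesh geometry kernels.

Exact closest-point queries against a triangle soup, vertex adjacency and
normals.  Queries are brute force over all triangles, chunked over query
points so peak memory stays bounded; phantom and ROI-scale meshes (a few
thousand triangles) are well within budget.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "vertex_adjacency",
    "triangle_normals",
    "vertex_normals",
    "closest_point_on_mesh",
    "barycentric_coordinates",
]


def vertex_adjacency(triangles: np.ndarray, n_vertices: int) -> list[np.ndarray]:
    """1-ring neighbour indices for every vertex (excluding the vertex itself)."""
    tri = np.asarray(triangles, dtype=np.int64)
    edges = np.vstack(
        [tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]]
    )
    edges = np.vstack([edges, edges[:, ::-1]])
    edges = np.unique(edges, axis=0)
    neigh: list[np.ndarray] = []
    # edges sorted by the first column: slice per vertex
    starts = np.searchsorted(edges[:, 0], np.arange(n_vertices + 1))
    for v in range(n_vertices):
        neigh.append(edges[starts[v]:starts[v + 1], 1])
    return neigh


def triangle_normals(vertices: np.ndarray, triangles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit normals and areas of every triangle."""
    a = vertices[triangles[:, 0]]
    b = vertices[triangles[:, 1]]
    c = vertices[triangles[:, 2]]
    cr = np.cross(b - a, c - a)
    norm = np.linalg.norm(cr, axis=1)
    areas = 0.5 * norm
    with np.errstate(invalid="ignore", divide="ignore"):
        normals = np.where(norm[:, None] > 0, cr / np.where(norm == 0, 1, norm)[:, None], 0.0)
    return normals, areas


def vertex_normals(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Area-weighted unit vertex normals."""
    normals, areas = triangle_normals(vertices, triangles)
    vn = np.zeros_like(vertices, dtype=float)
    w = normals * areas[:, None]
    for k in range(3):
        np.add.at(vn, triangles[:, k], w)
    norm = np.linalg.norm(vn, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return vn / norm


def _closest_on_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Closest point to ``p`` on each triangle (a, b, c); all broadcastable (..., 3).

    Standard region decomposition (vertex / edge / face regions of the
    triangle's plane projection), fully vectorised.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.sum(ab * ap, axis=-1)
    d2 = np.sum(ac * ap, axis=-1)

    bp = p - b
    d3 = np.sum(ab * bp, axis=-1)
    d4 = np.sum(ac * bp, axis=-1)

    cp = p - c
    d5 = np.sum(ab * cp, axis=-1)
    d6 = np.sum(ac * cp, axis=-1)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    with np.errstate(invalid="ignore", divide="ignore"):
        v_ab = d1 / (d1 - d3)
        w_ac = d2 / (d2 - d6)
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        denom = va + vb + vc
        v_in = vb / denom
        w_in = vc / denom
    v_ab = np.nan_to_num(v_ab)
    w_ac = np.nan_to_num(w_ac)
    w_bc = np.nan_to_num(w_bc)
    v_in = np.nan_to_num(v_in)
    w_in = np.nan_to_num(w_in)

    out = a + v_in[..., None] * ab + w_in[..., None] * ac  # face region default

    m_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    out = np.where(m_bc[..., None], b + w_bc[..., None] * (c - b), out)
    m_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(m_ac[..., None], a + w_ac[..., None] * ac, out)
    m_c = (d6 >= 0) & (d5 <= d6)
    out = np.where(m_c[..., None], c, out)
    m_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(m_ab[..., None], a + v_ab[..., None] * ab, out)
    m_b = (d3 >= 0) & (d4 <= d3)
    out = np.where(m_b[..., None], b, out)
    m_a = (d1 <= 0) & (d2 <= 0)
    out = np.where(m_a[..., None], a, out)
    return out


def closest_point_on_mesh(
    vertices: np.ndarray,
    triangles: np.ndarray,
    points: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact closest point on a triangle mesh for every query point.

    Returns ``(closest, triangle_index, distance)``.  Candidate triangles
    are pruned with a KD-tree over triangle centroids: the nearest centroid
    distance d0 bounds the true distance from above, so only triangles whose
    centroid lies within d0 + (largest centroid-to-vertex radius) can carry
    the closest point.  The final comparison over candidates is exact.
    """
    from scipy.spatial import cKDTree

    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = np.asarray(triangles, dtype=np.int64)
    A = vertices[tri[:, 0]]
    B = vertices[tri[:, 1]]
    C = vertices[tri[:, 2]]
    cent = (A + B + C) / 3.0
    r_max = float(
        np.sqrt(
            np.max(
                np.maximum.reduce(
                    [
                        np.sum((A - cent) ** 2, axis=1),
                        np.sum((B - cent) ** 2, axis=1),
                        np.sum((C - cent) ** 2, axis=1),
                    ]
                )
            )
        )
    )
    tree = cKDTree(cent)

    n = len(points)
    closest = np.empty_like(points)
    tri_idx = np.empty(n, dtype=np.int64)
    dist = np.empty(n, dtype=float)
    chunk = 8192
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        pts = points[lo:hi]
        d0, _ = tree.query(pts)
        cand_lists = tree.query_ball_point(pts, d0 + r_max + 1e-9)
        counts = np.fromiter((len(c) for c in cand_lists), dtype=np.int64, count=hi - lo)
        pt_rep = np.repeat(np.arange(hi - lo), counts)
        cand = np.concatenate(cand_lists).astype(np.int64)
        cp = _closest_on_triangles(pts[pt_rep], A[cand], B[cand], C[cand])
        d2 = np.sum((cp - pts[pt_rep]) ** 2, axis=-1)
        bounds = np.concatenate([[0], np.cumsum(counts)])
        for k in range(hi - lo):
            a_, b_ = bounds[k], bounds[k + 1]
            best = a_ + int(np.argmin(d2[a_:b_]))
            closest[lo + k] = cp[best]
            tri_idx[lo + k] = cand[best]
            dist[lo + k] = np.sqrt(d2[best])
    return closest, tri_idx, dist


def barycentric_coordinates(
    points: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> np.ndarray:
    """Barycentric coordinates (u, v, w) of points known to lie on triangles."""
    v0 = b - a
    v1 = c - a
    v2 = points - a
    d00 = np.sum(v0 * v0, axis=-1)
    d01 = np.sum(v0 * v1, axis=-1)
    d11 = np.sum(v1 * v1, axis=-1)
    d20 = np.sum(v2 * v0, axis=-1)
    d21 = np.sum(v2 * v1, axis=-1)
    denom = d00 * d11 - d01 * d01
    denom = np.where(denom == 0, 1.0, denom)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    u = 1.0 - v - w
    bary = np.stack([u, v, w], axis=-1)
    bary = np.clip(bary, 0.0, 1.0)
    return bary / bary.sum(axis=-1, keepdims=True)
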