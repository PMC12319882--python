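"""Projecting retinotopy onto streamlines and quantifying topographic order.

Each streamline endpoint is anchored to the white surface by the three
vertices of its closest triangle ("the three vertices surrounding the
endpoint"); the mean of their eccentricity and polar-angle values (circular
for polar angle) gives four retinotopy values per streamline (2 ends x 2
maps).  The V1-end means are propagated along the whole streamline as its
carried retinotopy.  Streamlines are then clustered into contiguous bands
drawn below the V1 border in the eccentricity (6 bands) and polar-angle
(15 bands) directions, and topographic order is summarised by a Spearman
rank correlation between carried values and positions along a reference
axis.
"""

from __future__ import annotations

import colorsys
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from ._mesh import barycentric_coordinates, closest_point_on_mesh
from .io_formats import (
    ConfigurationError,
    CorticalLabel,
    SurfaceMesh,
    Tractogram,
    ValidationError,
    VertexScalarMap,
)
from .retinotopy import circular_mean_deg

logger = logging.getLogger(__name__)

__all__ = [
    "ProjectionParams",
    "EndpointAssignment",
    "TopographicClustering",
    "endpoint_vertices",
    "project_retinotopy",
    "band_labels",
    "cluster_by_band",
    "topographic_order_index",
]


@dataclass
class ProjectionParams:
    """Projection controls: off-surface tolerance and the intracortical cap."""

    tolerance: float = 2.0
    intracortical_max_fraction: float = 0.8
    barycentric_weighted: bool = False
    strict: bool = False

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be > 0")
        if not 0 < self.intracortical_max_fraction <= 1:
            raise ValidationError("intracortical_max_fraction must be in (0, 1]")


@dataclass
class EndpointAssignment:
    """One endpoint anchored to three surface vertices with its mean maps."""

    streamline: int
    end: str  # "V1" | "V2"
    vertices: np.ndarray  # 3 vertex indices
    weights: np.ndarray  # barycentric weights
    eccentricity: float
    polar_angle: float
    valued: bool = True

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.int64).ravel()
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.vertices.shape != (3,) or self.weights.shape != (3,):
            raise ValidationError("an endpoint needs exactly 3 vertices + weights")


class OffSurfaceError(ValidationError):
    """Endpoint farther from the mesh than the allowed tolerance."""


def endpoint_vertices(
    point: np.ndarray, mesh: SurfaceMesh, tolerance: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Three vertices of the triangle containing the closest surface point.

    Returns ``(vertex_indices, barycentric_weights)``; raises
    :class:`OffSurfaceError` when the endpoint is farther than ``tolerance``
    mm from the mesh.
    """
    p = np.asarray(point, dtype=float).reshape(1, 3)
    closest, tri_idx, dist = closest_point_on_mesh(mesh.vertices, mesh.triangles, p)
    if dist[0] > tolerance:
        raise OffSurfaceError(
            f"endpoint {np.round(p[0], 3).tolist()} is {dist[0]:.2f} mm off-surface"
        )
    tri = mesh.triangles[tri_idx[0]]
    bary = barycentric_coordinates(
        closest[0], mesh.vertices[tri[0]], mesh.vertices[tri[1]], mesh.vertices[tri[2]]
    )
    return tri.copy(), bary


def _triangle_in_label(tri: np.ndarray, label_vertices: set[int]) -> bool:
    """Majority rule: a triangle lies in a surface label if >= 2 vertices do."""
    return sum(int(v) in label_vertices for v in tri) >= 2


def _endpoint_means(
    tri: np.ndarray,
    bary: np.ndarray,
    ecc: VertexScalarMap,
    pol: VertexScalarMap,
    weighted: bool,
) -> tuple[float, float, bool]:
    valued = bool(ecc.valid[tri].all() and pol.valid[tri].all())
    w = bary if weighted else np.full(3, 1.0 / 3.0)
    e = float(np.sum(w * ecc.values[tri]))
    rad = np.deg2rad(pol.values[tri])
    p = np.mod(
        np.rad2deg(np.arctan2(np.sum(w * np.sin(rad)), np.sum(w * np.cos(rad)))),
        360.0,
    )
    return e, float(p * (p != 360.0)), valued


def project_retinotopy(
    t: Tractogram,
    mesh: SurfaceMesh,
    ecc: VertexScalarMap,
    pol: VertexScalarMap,
    v1: CorticalLabel,
    v2: CorticalLabel,
    params: ProjectionParams | None = None,
    intracortical_fractions: np.ndarray | None = None,
) -> tuple[list[EndpointAssignment], "np.recarray"]:
    """Assign endpoint retinotopy to streamlines and carry the V1-end values.

    ``intracortical_fractions``, when given, is used to drop streamlines
    exceeding the intracortical cap *before* projection.  Returns the
    endpoint assignments (two per projected streamline) and a record array
    with one row per input streamline: carried eccentricity/polar angle and
    status flags (``projected``, ``valued``, reason codes).
    """
    params = params or ProjectionParams()
    if len(ecc) != mesh.n_vertices or len(pol) != mesh.n_vertices:
        raise ValidationError("maps not bound to this mesh")
    if v1.vertex_indices is None or v2.vertex_indices is None:
        raise ValidationError("projection needs surface-based V1/V2 labels")
    set1 = set(v1.vertex_indices.tolist())
    set2 = set(v2.vertex_indices.tolist())

    n = len(t)
    rec = np.recarray(
        n,
        dtype=[
            ("index", np.int64),
            ("projected", np.bool_),
            ("valued", np.bool_),
            ("ecc_v1", np.float64),
            ("pol_v1", np.float64),
            ("ecc_v2", np.float64),
            ("pol_v2", np.float64),
            ("v1_end", np.int64),  # 0 = first point, 1 = last point, -1 n/a
            ("reason", "U24"),
        ],
    )
    rec.index = np.arange(n)
    rec.projected = False
    rec.valued = False
    rec.ecc_v1 = rec.pol_v1 = rec.ecc_v2 = rec.pol_v2 = np.nan
    rec.v1_end = -1
    rec.reason = ""

    assignments: list[EndpointAssignment] = []
    for i, s in enumerate(t):
        if intracortical_fractions is not None and (
            intracortical_fractions[i] > params.intracortical_max_fraction
        ):
            rec.reason[i] = "intracortical"
            continue
        try:
            tri0, bary0 = endpoint_vertices(s[0], mesh, params.tolerance)
            tri1, bary1 = endpoint_vertices(s[-1], mesh, params.tolerance)
        except OffSurfaceError as exc:
            rec.reason[i] = "off_surface"
            logger.info("streamline %d dropped from projection: %s", i, exc)
            continue
        in1 = (_triangle_in_label(tri0, set1), _triangle_in_label(tri1, set1))
        in2 = (_triangle_in_label(tri0, set2), _triangle_in_label(tri1, set2))
        if in1[0] and not in1[1] and in2[1]:
            v1_end = 0
        elif in1[1] and not in1[0] and in2[0]:
            v1_end = 1
        else:
            rec.reason[i] = "ambiguous_v1_end"
            if params.strict:
                raise ValidationError(f"streamline {i} has no unique V1-side endpoint")
            continue

        tris = (tri0, tri1)
        barys = (bary0, bary1)
        ends = {}
        valued = True
        for tag, end_idx in (("V1", v1_end), ("V2", 1 - v1_end)):
            e, p, ok = _endpoint_means(
                tris[end_idx], barys[end_idx], ecc, pol, params.barycentric_weighted
            )
            valued &= ok
            ends[tag] = (e, p)
            assignments.append(
                EndpointAssignment(i, tag, tris[end_idx], barys[end_idx], e, p, ok)
            )
        rec.projected[i] = True
        rec.valued[i] = valued
        if not valued:
            rec.reason[i] = "unvalued_vertex"
        rec.ecc_v1[i], rec.pol_v1[i] = ends["V1"]
        rec.ecc_v2[i], rec.pol_v2[i] = ends["V2"]
        rec.v1_end[i] = v1_end
    return assignments, rec


def band_labels(
    mesh: SurfaceMesh,
    vertex_indices: np.ndarray,
    axis: np.ndarray,
    n_bands: int,
    direction: str,
) -> list[CorticalLabel]:
    """Partition labelled vertices into contiguous equal-extent bands.

    Vertices are binned by their coordinate along ``axis`` into ``n_bands``
    equal intervals spanning the occupied range; every vertex lands in
    exactly one band.  ``direction`` tags the bands ("eccentricity" or
    "polar_angle").
    """
    if n_bands < 2:
        raise ConfigurationError("need at least 2 bands")
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ConfigurationError("degenerate (zero) band direction")
    axis = axis / norm
    idx = np.asarray(vertex_indices, dtype=np.int64)
    coord = mesh.vertices[idx] @ axis
    lo, hi = float(coord.min()), float(coord.max())
    if hi - lo <= 0:
        raise ConfigurationError("band direction degenerate over these vertices")
    width = (hi - lo) / n_bands
    which = np.clip(((coord - lo) / width).astype(int), 0, n_bands - 1)
    return [
        CorticalLabel(name=f"{direction}_band_{b:02d}", vertex_indices=idx[which == b])
        for b in range(n_bands)
    ]


def band_colour(cluster_id: int, n_bands: int) -> tuple[float, float, float]:
    """Deterministic RGB colour for a cluster id (evenly spaced hues)."""
    hue = cluster_id / max(1, n_bands)
    return colorsys.hsv_to_rgb(0.85 * hue, 0.9, 0.95)


@dataclass
class TopographicClustering:
    """Band assignment of streamlines by their V1-end termination."""

    direction: str
    band_names: list[str]
    cluster_id: np.ndarray  # per streamline, -1 = unassigned
    colours: np.ndarray = field(default=None)  # (n_bands, 3) RGB
    order_index: float | None = None

    def __post_init__(self) -> None:
        self.cluster_id = np.asarray(self.cluster_id, dtype=np.int64)
        if self.colours is None:
            n = len(self.band_names)
            self.colours = np.array([band_colour(b, n) for b in range(n)])

    def occupancy(self) -> np.ndarray:
        n = len(self.band_names)
        return np.bincount(self.cluster_id[self.cluster_id >= 0], minlength=n)


def cluster_by_band(
    t: Tractogram,
    bands: list[CorticalLabel],
    mesh: SurfaceMesh,
    v1_end_points: np.ndarray,
    direction: str = "eccentricity",
    max_distance: float = np.inf,
) -> TopographicClustering:
    """Assign each streamline the band holding its nearest band vertex.

    ``v1_end_points`` are the V1-side endpoint positions, one per streamline
    (NaN rows are left unassigned).  Endpoints farther than ``max_distance``
    from every band vertex are unassigned and logged.
    """
    pts = np.atleast_2d(np.asarray(v1_end_points, dtype=float))
    if len(pts) != len(t):
        raise ValidationError("one V1 endpoint per streamline required")
    all_verts, owner = [], []
    for b, lab in enumerate(bands):
        if lab.vertex_indices is None or len(lab.vertex_indices) == 0:
            continue
        all_verts.append(mesh.vertices[lab.vertex_indices])
        owner.append(np.full(len(lab.vertex_indices), b))
    if not all_verts:
        raise ValidationError("all bands are empty")
    tree = cKDTree(np.vstack(all_verts))
    owner = np.concatenate(owner)

    cluster = np.full(len(t), -1, dtype=np.int64)
    ok = np.isfinite(pts).all(axis=1)
    if ok.any():
        d, j = tree.query(pts[ok])
        assigned = np.where(d <= max_distance, owner[j], -1)
        cluster[np.flatnonzero(ok)] = assigned
        n_out = int(np.sum(assigned < 0))
        if n_out:
            logger.info("%d endpoints beyond max_distance: unassigned", n_out)
    return TopographicClustering(
        direction=direction,
        band_names=[lab.name for lab in bands],
        cluster_id=cluster,
    )


def topographic_order_index(
    values: np.ndarray,
    positions: np.ndarray,
    circular: bool = False,
) -> float:
    """Spearman rank correlation between carried retinotopy and position.

    Circular values (polar angle, degrees) are first unwrapped by centring
    on their circular mean, ranking the signed deviations in (-180, 180].
    Constant values make the index undefined; it is reported as 0 and
    logged.
    """
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=float)
    ok = np.isfinite(values) & np.isfinite(positions)
    values, positions = values[ok], positions[ok]
    if len(values) < 3:
        raise ValidationError("order index needs >= 3 streamlines")
    if circular:
        centre = circular_mean_deg(values)
        values = np.mod(values - centre + 180.0, 360.0) - 180.0
    if np.ptp(values) == 0 or np.ptp(positions) == 0:
        logger.warning("order index undefined for constant input; reporting 0")
        return 0.0
    rho, _ = spearmanr(values, positions)
    return float(rho)
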