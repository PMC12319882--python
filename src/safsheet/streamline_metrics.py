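"""Per-streamline geometry for short association fibres.

The central descriptors are the arc length and the bending angle: the angle
subtended at the streamline's apex (its point of highest curvature, taken to
sit near the sulcal fundus) by the two vectors joining the apex to the
endpoints.  Smaller bending angles mean more U-shaped fibres, larger angles
more V-shaped, with a straight line assigned 180 deg by convention.

Selection filters reproduce the standard SAF post-processing chain: keep
streamlines that traverse both the V1 and V2 labels, restrict lengths to a
band (3-120 mm in vivo, 3-30 mm post mortem), drop streamlines that dive
deeper than ~2 mm below the white surface (long-range contamination), and
drop streamlines that run mostly (> 80 %) inside the cortical ribbon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from ._mesh import barycentric_coordinates, closest_point_on_mesh
from .io_formats import (
    CorticalLabel,
    SurfaceMesh,
    Tractogram,
    ValidationError,
    validate_streamline,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionParams",
    "StreamlineGeometry",
    "resample_streamline",
    "arc_length",
    "apex_and_bending_angle",
    "connects_labels",
    "length_filter",
    "intracortical_fraction",
    "deep_wm_exclusion",
    "signed_distance_to_surface",
    "compute_geometry",
]

# curvature below this (1/mm, i.e. radius > 1000 mm) counts as straight
STRAIGHT_CURVATURE_EPS = 1e-3


@dataclass
class SelectionParams:
    """Streamline selection and resampling parameters.

    Defaults follow the in vivo protocol; ``preset("postmortem")`` switches
    to the 3-30 mm length band and the finer 0.1 mm step.
    """

    min_length: float = 3.0
    max_length: float = 120.0
    intracortical_max_fraction: float = 0.8
    deep_exclusion_depth: float = 2.0
    resample_step: float = 0.2
    smooth_before_curvature: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_length < self.max_length:
            raise ValidationError("need 0 < min_length < max_length")
        if not 0 < self.intracortical_max_fraction <= 1:
            raise ValidationError("intracortical_max_fraction must be in (0, 1]")
        if self.deep_exclusion_depth <= 0:
            raise ValidationError("deep_exclusion_depth must be > 0")
        if self.resample_step <= 0:
            raise ValidationError("resample_step must be > 0")

    @classmethod
    def preset(cls, name: str) -> "SelectionParams":
        if name == "invivo":
            return cls()
        if name == "postmortem":
            return cls(max_length=30.0, resample_step=0.1)
        raise ValidationError(f"unknown preset {name!r}")


@dataclass
class StreamlineGeometry:
    """Derived geometry record for one streamline."""

    index: int
    length: float
    bending_angle: float
    apex_index: int
    apex_position: np.ndarray
    intracortical_fraction: float | None = None
    passed_filters: dict = field(default_factory=dict)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError("length must be > 0")
        if not self.degenerate and not (0.0 <= self.bending_angle <= 180.0):
            raise ValidationError("bending angle outside [0, 180]")


def arc_length(s: np.ndarray) -> float:
    """Total arc length: sum of consecutive point distances (mm)."""
    pts = validate_streamline(s)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _cumulative_arc(pts: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_streamline(s: np.ndarray, step: float) -> np.ndarray:
    """Resample to (nearly) equal arc-length spacing, endpoints preserved.

    Sample stations sit at 0, step, 2*step, ... plus the exact final point,
    so the last segment may be shorter than ``step``.  A step at or beyond
    the total length collapses to the two endpoints.
    """
    if step <= 0:
        raise ValidationError("step must be > 0")
    pts = validate_streamline(s)
    cum = _cumulative_arc(pts)
    total = cum[-1]
    if step >= total:
        return np.vstack([pts[0], pts[-1]])
    stations = np.arange(0.0, total, step)
    if total - stations[-1] < 1e-9 * max(1.0, total):
        stations = stations[:-1]
    stations = np.concatenate([stations, [total]])
    out = np.column_stack([np.interp(stations, cum, pts[:, k]) for k in range(3)])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return float("nan")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def apex_and_bending_angle(
    s: np.ndarray, params: SelectionParams | None = None
) -> tuple[int, float, np.ndarray]:
    """Apex (highest-curvature resampled point) and bending angle in degrees.

    The streamline is resampled to uniform arc-length spacing; discrete
    curvature is the second central difference of the (optionally 3-point
    smoothed) coordinates.  Ties in the curvature maximum break toward the
    arc-length midpoint; a near-straight streamline (max curvature below
    1e-3 / mm) takes the midpoint as apex and reports 180 deg.

    Returns ``(apex_index, angle_deg, apex_position)`` where the index is
    into the resampled polyline.
    """
    params = params or SelectionParams()
    pts = validate_streamline(s)
    total = arc_length(pts)
    # exactly uniform spacing (h <= resample_step) so the second difference
    # is a consistent curvature estimate at every interior point
    n = int(np.ceil(total / params.resample_step)) + 1
    if n < 3:
        raise ValidationError("bending angle undefined for < 3 resampled points")
    cum = _cumulative_arc(pts)
    stations = np.linspace(0.0, total, n)
    r = np.column_stack([np.interp(stations, cum, pts[:, k]) for k in range(3)])
    r[0], r[-1] = pts[0], pts[-1]
    h = total / (n - 1)

    work = r
    if params.smooth_before_curvature and len(r) >= 3:
        work = r.copy()
        work[1:-1] = (r[:-2] + r[1:-1] + r[2:]) / 3.0

    second = (work[:-2] - 2 * work[1:-1] + work[2:]) / h**2
    curvature = np.linalg.norm(second, axis=1)  # interior points 1..n-2

    mid = (len(r) - 1) / 2.0
    kmax = float(curvature.max())
    if kmax < STRAIGHT_CURVATURE_EPS:
        apex = int(round(mid))
    else:
        ties = np.flatnonzero(curvature >= kmax * (1.0 - 1e-3)) + 1
        apex = int(ties[np.argmin(np.abs(ties - mid))])
    apex_pos = r[apex]
    if apex == 0 or apex == len(r) - 1:  # safeguard; curvature is interior-only
        apex = int(round(mid))
        apex_pos = r[apex]
    angle = _angle_deg(apex_pos - r[0], apex_pos - r[-1])
    if np.isnan(angle):
        angle = 180.0
    return apex, angle, apex_pos


def compute_geometry(
    t: Tractogram, params: SelectionParams | None = None
) -> list[StreamlineGeometry]:
    """Length, apex and bending angle for every streamline of a tractogram."""
    params = params or SelectionParams()
    out = []
    for i, s in enumerate(t):
        length = arc_length(s)
        try:
            apex, angle, pos = apex_and_bending_angle(s, params)
            out.append(StreamlineGeometry(i, length, angle, apex, pos))
        except ValidationError:
            logger.warning("streamline %d: bending angle undefined, flagged", i)
            out.append(
                StreamlineGeometry(
                    i, length, float("nan"), -1, s[0] * np.nan, degenerate=True
                )
            )
    return out


def connects_labels(
    s: np.ndarray,
    v1: CorticalLabel,
    v2: CorticalLabel,
    mesh: SurfaceMesh | None = None,
    tolerance: float = 1.0,
) -> bool:
    """True iff the streamline has at least one point in V1 and one in V2."""
    pts = validate_streamline(s)
    in1 = v1.contains_world(pts, mesh=mesh, tolerance=tolerance)
    in2 = v2.contains_world(pts, mesh=mesh, tolerance=tolerance)
    return bool(in1.any() and in2.any())


def length_filter(
    t: Tractogram, params: SelectionParams | None = None
) -> tuple[Tractogram, np.ndarray]:
    """Keep streamlines with min_length <= arc length <= max_length."""
    params = params or SelectionParams()
    lengths = np.array([arc_length(s) for s in t])
    keep = (lengths >= params.min_length) & (lengths <= params.max_length)
    logger.info("length filter: kept %d / %d", int(keep.sum()), len(t))
    return t.subset(keep), keep


def signed_distance_to_surface(points: np.ndarray, mesh: SurfaceMesh) -> np.ndarray:
    """Signed distance of world points to a surface: positive on the side the
    vertex normals point to (outward, i.e. above the white surface)."""
    points = np.atleast_2d(points)
    closest, tri_idx, dist = closest_point_on_mesh(mesh.vertices, mesh.triangles, points)
    vn = mesh.vertex_normals()
    tris = mesh.triangles[tri_idx]
    bary = barycentric_coordinates(
        closest,
        mesh.vertices[tris[:, 0]],
        mesh.vertices[tris[:, 1]],
        mesh.vertices[tris[:, 2]],
    )
    normal = np.einsum("ij,ijk->ik", bary, vn[tris])
    side = np.sign(np.einsum("ij,ij->i", points - closest, normal))
    side[side == 0] = 1.0
    return side * dist


def _check_ribbon(white: SurfaceMesh, pial: SurfaceMesh) -> None:
    """Sanity check that pial lies outside white (sampled at pial vertices)."""
    sample = pial.vertices[:: max(1, len(pial.vertices) // 64)]
    sd = signed_distance_to_surface(sample, white)
    if np.median(sd) <= 0:
        raise ValidationError("pial surface lies inside white: not a cortical ribbon")


def intracortical_fraction(
    s: np.ndarray,
    white: SurfaceMesh,
    pial: SurfaceMesh,
    params: SelectionParams | None = None,
) -> float:
    """Fraction of arc length inside the cortical ribbon (white < p < pial).

    Estimated as the fraction of uniformly resampled points whose signed
    distance is positive to the white surface and negative to the pial one.
    """
    params = params or SelectionParams()
    _check_ribbon(white, pial)
    r = resample_streamline(s, params.resample_step)
    above_white = signed_distance_to_surface(r, white) > 0
    below_pial = signed_distance_to_surface(r, pial) < 0
    return float(np.mean(above_white & below_pial))


def intracortical_fractions(
    t: Tractogram,
    white: SurfaceMesh,
    pial: SurfaceMesh,
    params: SelectionParams | None = None,
) -> np.ndarray:
    """Intracortical fraction of every streamline (batched mesh queries)."""
    params = params or SelectionParams()
    if len(t) == 0:
        return np.zeros(0)
    _check_ribbon(white, pial)
    resampled = [resample_streamline(s, params.resample_step) for s in t]
    counts = np.array([len(r) for r in resampled])
    pts = np.vstack(resampled)
    inside = (signed_distance_to_surface(pts, white) > 0) & (
        signed_distance_to_surface(pts, pial) < 0
    )
    bounds = np.concatenate([[0], np.cumsum(counts)])
    return np.array(
        [inside[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
    )


def intracortical_filter(
    t: Tractogram,
    white: SurfaceMesh,
    pial: SurfaceMesh,
    params: SelectionParams | None = None,
) -> tuple[Tractogram, np.ndarray, np.ndarray]:
    """Remove streamlines with more than the allowed intracortical fraction."""
    params = params or SelectionParams()
    fracs = intracortical_fractions(t, white, pial, params)
    keep = fracs <= params.intracortical_max_fraction
    logger.info("intracortical filter: kept %d / %d", int(keep.sum()), len(t))
    return t.subset(keep), keep, fracs


def deep_wm_exclusion(
    t: Tractogram,
    white: SurfaceMesh,
    depth: float | None = None,
    params: SelectionParams | None = None,
) -> tuple[Tractogram, np.ndarray]:
    """Remove streamlines with any point deeper than ``depth`` below white.

    Depth is the unsigned distance to the white surface for points on its
    inner (negative normal) side.  ``depth=inf`` is the identity.
    """
    params = params or SelectionParams()
    if depth is None:
        depth = params.deep_exclusion_depth
    keep = np.ones(len(t), dtype=bool)
    if not np.isinf(depth) and len(t):
        counts = np.array([len(s) for s in t])
        sd = signed_distance_to_surface(np.vstack(list(t)), white)
        bounds = np.concatenate([[0], np.cumsum(counts)])
        keep = np.array(
            [not np.any(sd[a:b] < -depth) for a, b in zip(bounds[:-1], bounds[1:])]
        )
    logger.info("deep WM exclusion: kept %d / %d", int(keep.sum()), len(t))
    return t.subset(keep), keep


def select_connecting(
    t: Tractogram,
    v1: CorticalLabel,
    v2: CorticalLabel,
    mesh: SurfaceMesh | None = None,
    tolerance: float = 1.0,
) -> tuple[Tractogram, np.ndarray]:
    """Keep streamlines traversing both V1 and V2."""
    if len(t) == 0:
        return t, np.zeros(0, dtype=bool)
    counts = np.array([len(s) for s in t])
    pts = np.vstack(list(t))
    in1 = v1.contains_world(pts, mesh=mesh, tolerance=tolerance)
    in2 = v2.contains_world(pts, mesh=mesh, tolerance=tolerance)
    bounds = np.concatenate([[0], np.cumsum(counts)])
    keep = np.array(
        [in1[a:b].any() and in2[a:b].any() for a, b in zip(bounds[:-1], bounds[1:])]
    )
    logger.info("V1-V2 selection: kept %d / %d", int(keep.sum()), len(t))
    return t.subset(keep), keep
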