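"""Conditioning of per-vertex retinotopic maps.

Phase-encoded retinotopy assigns each surface vertex an eccentricity and a
polar angle, but raw maps are noisy.  Here we (i) score each vertex by the
SNR of its fMRI response at the stimulus frequency, (ii) mask vertices whose
SNR falls below a reliability threshold, (iii) smooth the surviving values
over 1-ring mesh neighbourhoods for a fixed number of iterations, and (iv)
resolve V1/V2 voxel-label overlaps created by volume resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import (
    ConfigurationError,
    CorticalLabel,
    SurfaceMesh,
    ValidationError,
    VertexScalarMap,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FMRITimeSeries",
    "ReliabilityParams",
    "circular_mean_deg",
    "compute_snr",
    "reliable_mask",
    "smooth_vertex_map",
    "resolve_label_overlap",
]


@dataclass
class FMRITimeSeries:
    """Per-vertex fMRI time series from a phase-encoded run.

    ``samples`` is (V, T); ``stimulus_frequency`` is in cycles per run, so the
    response of interest sits in DFT bin ``stimulus_frequency``.
    """

    samples: np.ndarray
    stimulus_frequency: int
    tr: float = 2.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("non-finite fMRI sample")
        if self.stimulus_frequency < 1:
            raise ValidationError("stimulus frequency must be >= 1 cycle/run")
        if self.samples.shape[1] < 4 * self.stimulus_frequency:
            raise ValidationError(
                "need at least 4 samples per stimulus cycle "
                f"(T={self.samples.shape[1]}, f={self.stimulus_frequency})"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class ReliabilityParams:
    """Reliability threshold on SNR and the smoothing iteration count."""

    snr_threshold: float = 5.0
    smoothing_iterations: int = 4

    def __post_init__(self) -> None:
        if self.snr_threshold <= 0:
            raise ValidationError("snr_threshold must be > 0")
        if self.smoothing_iterations < 0:
            raise ValidationError("smoothing_iterations must be >= 0")


def circular_mean_deg(values: np.ndarray, axis=None) -> np.ndarray | float:
    """Mean direction of angles in degrees, on [0, 360)."""
    rad = np.deg2rad(np.asarray(values, dtype=float))
    s = np.mean(np.sin(rad), axis=axis)
    c = np.mean(np.cos(rad), axis=axis)
    out = np.mod(np.rad2deg(np.arctan2(s, c)), 360.0)
    # a tiny negative angle can round the modulus up to exactly 360.0
    return out * (out != 360.0)


def compute_snr(ts: FMRITimeSeries) -> VertexScalarMap:
    """Per-vertex response SNR at the stimulus frequency.

    SNR = |spectrum at the stimulus bin| / std of |spectrum| over all
    non-DC bins (one-sided spectrum, stimulus bin included in the std).
    A vanishing denominator (e.g. an all-zero series) yields SNR 0.
    """
    T = ts.n_samples
    if ts.stimulus_frequency >= (T // 2 + 1):
        raise ConfigurationError(
            f"stimulus bin {ts.stimulus_frequency} at or above Nyquist for T={T}"
        )
    spectrum = np.abs(np.fft.rfft(ts.samples, axis=1))
    signal = spectrum[:, ts.stimulus_frequency]
    noise = np.std(spectrum[:, 1:], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        snr = np.where(noise > np.finfo(float).eps, signal / noise, 0.0)
    return VertexScalarMap(snr, kind="snr")


def reliable_mask(snr: VertexScalarMap, params: ReliabilityParams | None = None) -> np.ndarray:
    """Vertices whose SNR reaches the threshold; strictly-below is unreliable."""
    params = params or ReliabilityParams()
    if snr.kind != "snr":
        raise ConfigurationError(f"expected an snr map, got {snr.kind}")
    return snr.values >= params.snr_threshold


def smooth_vertex_map(
    vmap: VertexScalarMap,
    mesh: SurfaceMesh,
    mask: np.ndarray | None = None,
    params: ReliabilityParams | None = None,
) -> VertexScalarMap:
    """Iterative neighbourhood-mean smoothing restricted to reliable vertices.

    Per iteration, each reliable vertex is replaced by the mean of its
    reliable 1-ring neighbours and itself; unreliable vertices contribute to
    no mean and keep their (unvalued) entry.  Polar-angle maps use the
    circular mean.  Runs exactly ``params.smoothing_iterations`` passes.
    """
    params = params or ReliabilityParams()
    if len(vmap) != mesh.n_vertices:
        raise ValidationError("map not bound to this mesh (vertex count differs)")
    if mask is None:
        mask = vmap.valid.copy()
    else:
        mask = np.asarray(mask, dtype=bool)
        if len(mask) != len(vmap):
            raise ValidationError("mask length differs from map")
        mask = mask & vmap.valid

    from scipy import sparse

    n = mesh.n_vertices
    tri = mesh.triangles
    edges = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
    edges = np.unique(np.vstack([edges, edges[:, ::-1]]), axis=0)
    loops = np.arange(n)
    rows = np.concatenate([edges[:, 0], loops])
    cols = np.concatenate([edges[:, 1], loops])
    A = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )  # 1-ring adjacency + self

    m = mask.astype(float)
    pool_size = A @ m
    isolated = mask & (pool_size <= 1) & (np.asarray(A.sum(axis=1)).ravel() > 1)
    if isolated.any():
        logger.info(
            "%d reliable vertices have no reliable neighbours; values kept",
            int(isolated.sum()),
        )

    values = vmap.values.copy()
    circular = vmap.kind == "polar_angle"
    safe = np.where(pool_size > 0, pool_size, 1.0)
    for _ in range(params.smoothing_iterations):
        if circular:
            rad = np.deg2rad(values)
            s = (A @ (np.sin(rad) * m)) / safe
            c = (A @ (np.cos(rad) * m)) / safe
            smoothed = np.mod(np.rad2deg(np.arctan2(s, c)), 360.0)
            smoothed = smoothed * (smoothed != 360.0)
        else:
            smoothed = (A @ (values * m)) / safe
        values = np.where(mask, smoothed, values)
    return VertexScalarMap(values, vmap.kind, valid=mask)


def resolve_label_overlap(
    v1: CorticalLabel,
    v2: CorticalLabel,
    prob_v1: dict[tuple[int, int, int], float] | np.ndarray,
) -> tuple[CorticalLabel, CorticalLabel]:
    """Make voxel labels disjoint using a V1 probability map on overlap voxels.

    Each overlap voxel goes to V1 iff P(V1) >= 0.5 (ties to V1, logged).
    The union of the outputs equals the union of the inputs.

    ``prob_v1`` is either a dense 3D array indexed by voxel, or a mapping
    from voxel index triples to probabilities (only overlap voxels needed).
    """
    if v1.voxels is None or v2.voxels is None:
        raise ValidationError("overlap resolution needs voxel-based labels")
    if v1.affine is None or v2.affine is None or not np.allclose(v1.affine, v2.affine):
        raise ValidationError("labels must share a common voxel grid")

    set1, set2 = v1.voxel_set(), v2.voxel_set()
    overlap = sorted(set1 & set2)
    if not overlap:
        return v1, v2

    def lookup(vox: tuple[int, int, int]) -> float:
        if isinstance(prob_v1, dict):
            if vox not in prob_v1:
                raise ValidationError(f"no V1 probability for overlap voxel {vox}")
            return float(prob_v1[vox])
        try:
            return float(prob_v1[vox])
        except IndexError as exc:
            raise ValidationError(f"no V1 probability for overlap voxel {vox}") from exc

    missing = []
    to_v1, to_v2 = [], []
    for vox in overlap:
        try:
            p = lookup(vox)
        except ValidationError:
            missing.append(vox)
            continue
        if p == 0.5:
            logger.info("overlap voxel %s tied at p=0.5 -> V1", vox)
        (to_v1 if p >= 0.5 else to_v2).append(vox)
    if missing:
        raise ValidationError(f"undefined probability at overlap voxels {missing}")

    new1 = (set1 - set(overlap)) | set(to_v1)
    new2 = (set2 - set(overlap)) | set(to_v2)

    def as_array(vox_set: set) -> np.ndarray:
        return np.array(sorted(vox_set), dtype=np.int64).reshape(-1, 3)

    out1 = CorticalLabel(v1.name, vertex_indices=v1.vertex_indices,
                         voxels=as_array(new1), affine=v1.affine)
    out2 = CorticalLabel(v2.name, vertex_indices=v2.vertex_indices,
                         voxels=as_array(new2), affine=v2.affine)
    assert not (out1.voxel_set() & out2.voxel_set())
    return out1, out2
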