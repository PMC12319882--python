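"""SNR statistic, reliability masking, surface smoothing, overlap resolution."""

import numpy as np
import pytest

from safsheet.io_formats import ConfigurationError, CorticalLabel, ValidationError, VertexScalarMap
from safsheet.retinotopy import (
    FMRITimeSeries,
    ReliabilityParams,
    circular_mean_deg,
    compute_snr,
    reliable_mask,
    resolve_label_overlap,
    smooth_vertex_map,
)

from conftest import grid_mesh


def dft_snr_oracle(x: np.ndarray, f: int) -> float:
    """Brute-force DFT implementation of the spectral SNR statistic."""
    T = len(x)
    t = np.arange(T)
    mags = np.array(
        [abs(np.sum(x * np.exp(-2j * np.pi * k * t / T))) for k in range(T // 2 + 1)]
    )
    denom = np.std(mags[1:])
    return 0.0 if denom < np.finfo(float).eps else mags[f] / denom


class TestComputeSNR:
    def test_all_zero_series_is_zero(self):
        ts = FMRITimeSeries(np.zeros((3, 64)), stimulus_frequency=8)
        assert compute_snr(ts).values.tolist() == [0.0, 0.0, 0.0]

    def test_pure_sinusoid_matches_oracle(self):
        T, f = 128, 8
        x = np.sin(2 * np.pi * f * np.arange(T) / T)
        snr = compute_snr(FMRITimeSeries(x[None, :], stimulus_frequency=f)).values[0]
        assert snr == pytest.approx(dft_snr_oracle(x, f), rel=1e-10)
        # only the stimulus bin is non-zero: SNR = nb/sqrt(nb-1), nb = T/2
        assert snr == pytest.approx(64 / np.sqrt(63), rel=1e-9)

    def test_matches_oracle_on_random_series(self):
        rng = np.random.default_rng(42)
        T, f = 96, 6
        X = rng.normal(size=(100, T)) + np.sin(2 * np.pi * f * np.arange(T) / T)
        snr = compute_snr(FMRITimeSeries(X, stimulus_frequency=f)).values
        oracle = np.array([dft_snr_oracle(x, f) for x in X])
        assert np.max(np.abs(snr - oracle) / oracle) < 1e-8

    @pytest.mark.parametrize("seed", range(10))
    def test_noise_monotonicity_same_pattern(self, seed):
        # doubling the sd of the same noise pattern strictly lowers SNR
        rng = np.random.default_rng(seed)
        T, f = 128, 8
        sig = np.sin(2 * np.pi * f * np.arange(T) / T)
        noise = rng.normal(size=T)
        snrs = [
            compute_snr(
                FMRITimeSeries((sig + sd * noise)[None], stimulus_frequency=f)
            ).values[0]
            for sd in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a > b for a, b in zip(snrs, snrs[1:]))

    def test_scaling_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(5, 64)) + 2.0
        a = compute_snr(FMRITimeSeries(x, stimulus_frequency=4)).values
        b = compute_snr(FMRITimeSeries(17.3 * x, stimulus_frequency=4)).values
        assert np.allclose(a, b, rtol=1e-12)

    def test_stimulus_bin_beyond_nyquist_rejected(self):
        with pytest.raises((ConfigurationError, ValidationError)):
            compute_snr(FMRITimeSeries(np.zeros((1, 64)), stimulus_frequency=33))


class TestReliableMask:
    def test_threshold_boundary_inclusive(self):
        snr = VertexScalarMap(np.array([4.9, 5.0, 5.1]), kind="snr")
        mask = reliable_mask(snr, ReliabilityParams(snr_threshold=5.0))
        assert mask.tolist() == [False, True, True]

    def test_tiny_threshold_keeps_all_positive(self):
        snr = VertexScalarMap(np.array([0.1, 3.0, 9.0]), kind="snr")
        assert reliable_mask(snr, ReliabilityParams(snr_threshold=1e-9)).all()

    def test_all_zero_snr_empty_mask(self):
        snr = VertexScalarMap(np.zeros(5), kind="snr")
        assert not reliable_mask(snr).any()


def smoothing_oracle(mesh, values, mask, iterations, circular=False):
    """Independent loop implementation of masked 1-ring mean smoothing."""
    neigh = {v: set() for v in range(mesh.n_vertices)}
    for a, b, c in mesh.triangles:
        for u, w in ((a, b), (b, c), (c, a)):
            neigh[int(u)].add(int(w))
            neigh[int(w)].add(int(u))
    vals = np.array(values, dtype=float)
    for _ in range(iterations):
        new = vals.copy()
        for v in range(mesh.n_vertices):
            if not mask[v]:
                continue
            pool = [v] + [w for w in sorted(neigh[v]) if mask[w]]
            if circular:
                rad = np.deg2rad(vals[pool])
                new[v] = np.degrees(
                    np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad)))
                ) % 360.0
            else:
                new[v] = np.mean(vals[pool])
        vals = new
    return vals


class TestSmoothing:
    def test_constant_map_identity(self):
        mesh = grid_mesh(6, 6)
        vmap = VertexScalarMap(np.full(mesh.n_vertices, 4.2), kind="eccentricity")
        out = smooth_vertex_map(vmap, mesh, params=ReliabilityParams(smoothing_iterations=4))
        assert np.allclose(out.values, 4.2, atol=1e-12)

    def test_matches_brute_force_oracle_on_grid(self):
        mesh = grid_mesh(5, 5)
        rng = np.random.default_rng(11)
        values = mesh.vertices[:, 0] * 0.5 + rng.normal(0, 0.2, mesh.n_vertices)
        mask = rng.random(mesh.n_vertices) > 0.2
        vmap = VertexScalarMap(np.abs(values), kind="eccentricity", valid=mask)
        out = smooth_vertex_map(
            vmap, mesh, mask, ReliabilityParams(smoothing_iterations=3)
        )
        oracle = smoothing_oracle(mesh, np.abs(values), mask, 3)
        assert np.allclose(out.values[mask], oracle[mask], atol=1e-10)
        assert np.allclose(out.values[~mask], np.abs(values)[~mask])  # untouched

    def test_linear_gradient_interior_unchanged(self):
        mesh = grid_mesh(5, 5)
        values = mesh.vertices[:, 0].copy()  # linear in x
        vmap = VertexScalarMap(values, kind="eccentricity")
        out = smooth_vertex_map(vmap, mesh, params=ReliabilityParams(smoothing_iterations=1))
        centre = 2 * 5 + 2  # interior vertex with symmetric 1-ring
        assert out.values[centre] == pytest.approx(values[centre], abs=1e-12)
        # boundary shrinks toward the interior
        assert out.values[0] > values[0]
        assert out.values[4] < values[4]

    def test_circular_mean_across_wrap(self):
        mesh = grid_mesh(2, 2)  # 4 vertices, all mutually connected enough
        vals = np.array([359.0, 1.0, 359.0, 1.0])
        vmap = VertexScalarMap(vals, kind="polar_angle")
        out = smooth_vertex_map(vmap, mesh, params=ReliabilityParams(smoothing_iterations=1))
        # every pool mixes 359 and 1 -> circular mean near 0, never near 180
        dev = np.minimum(out.values, 360 - out.values)
        assert np.all(dev < 2.0)

    def test_range_contraction_property(self):
        mesh = grid_mesh(7, 7)
        rng = np.random.default_rng(0)
        for trial in range(5):
            values = rng.uniform(0, 10, mesh.n_vertices)
            vmap = VertexScalarMap(values, kind="eccentricity")
            prev = values
            for _ in range(3):
                out = smooth_vertex_map(
                    VertexScalarMap(prev, kind="eccentricity"),
                    mesh,
                    params=ReliabilityParams(smoothing_iterations=1),
                )
                assert np.ptp(out.values) <= np.ptp(prev) + 1e-12
                prev = out.values

    def test_exact_iteration_count(self):
        mesh = grid_mesh(5, 5)
        values = mesh.vertices[:, 0] ** 2
        one = smooth_vertex_map(
            VertexScalarMap(values, "eccentricity"), mesh,
            params=ReliabilityParams(smoothing_iterations=1),
        ).values
        four = smooth_vertex_map(
            VertexScalarMap(values, "eccentricity"), mesh,
            params=ReliabilityParams(smoothing_iterations=4),
        ).values
        manual = values
        for _ in range(4):
            manual = smooth_vertex_map(
                VertexScalarMap(manual, "eccentricity"), mesh,
                params=ReliabilityParams(smoothing_iterations=1),
            ).values
        assert not np.allclose(one, four)
        assert np.allclose(manual, four, atol=1e-10)


class TestCircularMean:
    def test_wraparound(self):
        assert circular_mean_deg(np.array([359.0, 1.0])) == pytest.approx(0.0, abs=1e-9)

    def test_plain_mean_when_clustered(self):
        assert circular_mean_deg(np.array([10.0, 20.0, 30.0])) == pytest.approx(20.0)


class TestOverlapResolution:
    def _labels(self, vox1, vox2):
        affine = np.eye(4)
        return (
            CorticalLabel("V1", voxels=np.array(vox1), affine=affine),
            CorticalLabel("V2", voxels=np.array(vox2), affine=affine),
        )

    def test_probability_rule(self):
        v1, v2 = self._labels([[0, 0, 0], [1, 0, 0]], [[1, 0, 0], [2, 0, 0]])
        out1, out2 = resolve_label_overlap(v1, v2, {(1, 0, 0): 0.7})
        assert (1, 0, 0) in out1.voxel_set()
        assert (1, 0, 0) not in out2.voxel_set()

    def test_disjoint_inputs_unchanged(self):
        v1, v2 = self._labels([[0, 0, 0]], [[5, 5, 5]])
        out1, out2 = resolve_label_overlap(v1, v2, {})
        assert out1.voxel_set() == v1.voxel_set()
        assert out2.voxel_set() == v2.voxel_set()

    def test_exhaustive_overlap_counts(self):
        overlap = [[i, 0, 0] for i in range(10)]
        v1, v2 = self._labels(overlap + [[20, 0, 0]], overlap + [[30, 0, 0]])
        prob = {(i, 0, 0): (0.6 if i < 4 else 0.4) for i in range(10)}
        out1, out2 = resolve_label_overlap(v1, v2, prob)
        assert len(out1.voxel_set()) == 4 + 1
        assert len(out2.voxel_set()) == 6 + 1
        assert not (out1.voxel_set() & out2.voxel_set())

    def test_conservation_and_disjointness_random(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            vox1 = rng.integers(0, 6, size=(rng.integers(3, 20), 3))
            vox2 = rng.integers(0, 6, size=(rng.integers(3, 20), 3))
            v1, v2 = self._labels(vox1, vox2)
            union = v1.voxel_set() | v2.voxel_set()
            prob = {v: rng.random() for v in (v1.voxel_set() & v2.voxel_set())}
            out1, out2 = resolve_label_overlap(v1, v2, prob)
            assert not (out1.voxel_set() & out2.voxel_set())
            assert out1.voxel_set() | out2.voxel_set() == union

    def test_tie_goes_to_v1(self):
        v1, v2 = self._labels([[1, 1, 1]], [[1, 1, 1]])
        out1, out2 = resolve_label_overlap(v1, v2, {(1, 1, 1): 0.5})
        assert (1, 1, 1) in out1.voxel_set()

    def test_missing_probability_reports_voxels(self):
        v1, v2 = self._labels([[1, 1, 1]], [[1, 1, 1]])
        with pytest.raises(ValidationError, match=r"\(1, 1, 1\)"):
            resolve_label_overlap(v1, v2, {})
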