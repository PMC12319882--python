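"""Endpoint anchoring, retinotopy projection, banding, order quantification."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from safsheet.io_formats import CorticalLabel, Tractogram, ValidationError, VertexScalarMap
from safsheet.projection_topography import (
    OffSurfaceError,
    ProjectionParams,
    band_labels,
    cluster_by_band,
    endpoint_vertices,
    project_retinotopy,
    topographic_order_index,
)
from safsheet.synthetic_data import SceneConfig, make_scene

from conftest import grid_mesh


class TestEndpointVertices:
    def test_endpoint_on_vertex(self):
        mesh = grid_mesh(4, 4)
        tri, w = endpoint_vertices(mesh.vertices[5] + [0, 0, 0.3], mesh)
        assert 5 in tri
        assert w[list(tri).index(5)] == pytest.approx(1.0, abs=1e-9)
        assert w.sum() == pytest.approx(1.0)

    def test_endpoint_at_triangle_centroid(self):
        mesh = grid_mesh(3, 3)
        tri = mesh.triangles[0]
        centroid = mesh.vertices[tri].mean(axis=0)
        got, w = endpoint_vertices(centroid, mesh)
        assert set(got) == set(tri)
        assert np.allclose(np.sort(w), [1 / 3] * 3, atol=1e-9)

    def test_matches_exhaustive_closest_triangle_search(self, quiet_scene):
        # oracle: trimesh's naive closest-point search over all triangles
        import trimesh
        import trimesh.proximity as prox

        mesh = quiet_scene.white
        tm = trimesh.Trimesh(mesh.vertices, mesh.triangles, process=False)
        rng = np.random.default_rng(4)
        normals = mesh.vertex_normals()
        idx = rng.integers(0, mesh.n_vertices, 20)
        pts = mesh.vertices[idx] + 0.5 * normals[idx] + rng.normal(0, 0.1, (20, 3))
        closest_o, dist_o, _ = prox.closest_point_naive(tm, pts)
        for p, co, do in zip(pts, closest_o, dist_o):
            tri, w = endpoint_vertices(p, mesh, tolerance=2.0)
            ours = w @ mesh.vertices[tri]
            assert np.linalg.norm(p - ours) == pytest.approx(do, abs=1e-9)

    def test_off_surface_rejected(self):
        mesh = grid_mesh(3, 3)
        with pytest.raises(OffSurfaceError):
            endpoint_vertices(np.array([1.0, 1.0, 5.0]), mesh, tolerance=2.0)


def _straight_tract(mesh, x_pairs, z=0.2):
    """Streamlines running across the mesh from x0 to x1 at fixed y."""
    sls = []
    for (x0, y0), (x1, y1) in x_pairs:
        n = 30
        sls.append(
            np.column_stack(
                [np.linspace(x0, x1, n), np.linspace(y0, y1, n), np.full(n, z)]
            )
        )
    return Tractogram(sls)


class TestProjectRetinotopy:
    def _setup(self):
        mesh = grid_mesh(11, 11)  # 10x10 mm
        ecc = VertexScalarMap(3.0 + 0.39 * mesh.vertices[:, 1], "eccentricity")
        pol = VertexScalarMap(180.0 + 9.0 * mesh.vertices[:, 0], "polar_angle")
        x = mesh.vertices[:, 0]
        v1 = CorticalLabel("V1", vertex_indices=np.flatnonzero(x < 5))
        v2 = CorticalLabel("V2", vertex_indices=np.flatnonzero(x >= 5))
        t = _straight_tract(mesh, [((0.0, 2.0), (10.0, 2.0)), ((10.0, 7.0), (0.0, 7.0))])
        return mesh, ecc, pol, v1, v2, t

    def test_four_values_and_v1_end_detection(self):
        mesh, ecc, pol, v1, v2, t = self._setup()
        assignments, rec = project_retinotopy(t, mesh, ecc, pol, v1, v2)
        assert rec.projected.all()
        assert len(assignments) == 2 * len(t)
        for row in rec:
            assert np.isfinite([row.ecc_v1, row.pol_v1, row.ecc_v2, row.pol_v2]).all()
        # first streamline starts on the V1 side, second ends there
        assert rec.v1_end[0] == 0 and rec.v1_end[1] == 1
        # carried V1 polar angle is near the V1-side field values
        assert rec.pol_v1[0] < rec.pol_v2[0]

    def test_intracortical_filter_applied_before_projection(self):
        mesh, ecc, pol, v1, v2, t = self._setup()
        icf = np.array([0.85, 0.5])
        _, rec = project_retinotopy(
            t, mesh, ecc, pol, v1, v2, intracortical_fractions=icf
        )
        assert not rec.projected[0] and rec.reason[0] == "intracortical"
        assert rec.projected[1]

    def test_circular_mean_at_endpoint(self):
        mesh = grid_mesh(3, 3)
        ecc = VertexScalarMap(np.full(9, 4.0), "eccentricity")
        vals = np.zeros(9)
        vals[[0, 1, 3]] = [350.0, 10.0, 0.0]  # triangle 0 vertices
        pol = VertexScalarMap(vals, "polar_angle")
        v1 = CorticalLabel("V1", vertex_indices=np.array([0, 1, 3]))
        v2 = CorticalLabel("V2", vertex_indices=np.array([2, 5, 8]))
        tri = np.array([0, 1, 3])
        start = mesh.vertices[tri].mean(axis=0)
        t = Tractogram([np.vstack([start, mesh.vertices[8] + [0, 0, 0.1]])])
        _, rec = project_retinotopy(t, mesh, ecc, pol, v1, v2)
        dev = min(rec.pol_v1[0], 360 - rec.pol_v1[0])
        assert dev < 1e-6  # circular mean of {350, 10, 0} is 0, not 120

    def test_phantom_eccentricity_rank_correlation(self, quiet_scene):
        s = quiet_scene
        _, rec = project_retinotopy(
            s.tractogram, s.white, s.eccentricity, s.polar_angle, s.v1, s.v2
        )
        assert rec.projected.all()
        rho, _ = spearmanr(rec.ecc_v1, s.manifest["seed_eccentricity"])
        assert rho >= 0.99

    def test_stability_under_mesh_refinement(self, quiet_scene):
        import trimesh

        s = quiet_scene
        _, rec = project_retinotopy(
            s.tractogram, s.white, s.eccentricity, s.polar_angle, s.v1, s.v2
        )
        tm = trimesh.Trimesh(s.white.vertices, s.white.triangles, process=False)
        sub_v, sub_f = trimesh.remesh.subdivide(tm.vertices, tm.faces)
        from safsheet.io_formats import SurfaceMesh

        fine = SurfaceMesh(sub_v, sub_f, role="white")
        e0, e1 = s.config.retinotopy.ecc_range
        ecc_f = VertexScalarMap(
            e0 + (e1 - e0) * fine.vertices[:, 1] / s.config.fold.extent_ap,
            "eccentricity",
        )
        pol_f = VertexScalarMap(np.zeros(fine.n_vertices), "polar_angle")
        x = fine.vertices[:, 0]
        v1f = CorticalLabel("V1", vertex_indices=np.flatnonzero(x < 0))
        v2f = CorticalLabel("V2", vertex_indices=np.flatnonzero(x >= 0))
        _, rec_f = project_retinotopy(
            s.tractogram, fine, ecc_f, pol_f, v1f, v2f
        )
        both = rec.projected & rec_f.projected
        assert np.abs(rec.ecc_v1[both] - rec_f.ecc_v1[both]).max() < 0.1


class TestBandLabels:
    def test_equal_partition_along_axis(self):
        mesh = grid_mesh(4, 31)  # 30 mm in y
        idx = np.arange(mesh.n_vertices)
        bands = band_labels(mesh, idx, np.array([0.0, 1.0, 0.0]), 6, "eccentricity")
        assert len(bands) == 6
        seen = np.concatenate([b.vertex_indices for b in bands])
        assert sorted(seen) == sorted(idx)  # exact partition
        for b in bands:  # each band spans 5 mm of y
            ys = mesh.vertices[b.vertex_indices, 1]
            assert ys.max() - ys.min() <= 5.0 + 1e-9

    def test_fifteen_bands_pairwise_disjoint(self):
        mesh = grid_mesh(4, 31)
        idx = np.arange(mesh.n_vertices)
        bands = band_labels(mesh, idx, np.array([0.0, 1.0, 0.0]), 15, "polar_angle")
        assert len(bands) == 15
        sets = [set(b.vertex_indices.tolist()) for b in bands]
        for i in range(15):
            for j in range(i + 1, 15):
                assert not (sets[i] & sets[j])

    def test_two_vertex_path_two_singletons(self):
        mesh = grid_mesh(2, 2)
        bands = band_labels(
            mesh, np.array([0, 1]), np.array([1.0, 0.0, 0.0]), 2, "eccentricity"
        )
        assert [len(b.vertex_indices) for b in bands] == [1, 1]

    def test_degenerate_direction_rejected(self):
        mesh = grid_mesh(3, 3)
        with pytest.raises(Exception):
            band_labels(mesh, np.arange(9), np.zeros(3), 4, "eccentricity")


class TestClusterByBand:
    def test_phantom_occupancy_matches_manifest(self, scene):
        s = scene
        bands = band_labels(
            s.white, s.v1.vertex_indices, np.array([0.0, 1.0, 0.0]),
            s.config.n_ecc_bands, "eccentricity",
        )
        v1_ends = np.array(
            [
                sl[0] if not rev else sl[-1]
                for sl, rev in zip(s.tractogram, s.manifest["reversed"])
            ]
        )
        clustering = cluster_by_band(s.tractogram, bands, s.white, v1_ends)
        expected = np.bincount(s.manifest["ecc_band"], minlength=s.config.n_ecc_bands)
        assert clustering.occupancy().tolist() == expected.tolist()

    def test_polar_band_occupancy_matches_manifest(self, scene):
        s = scene
        bands = band_labels(
            s.white, s.v1.vertex_indices, np.array([1.0, 0.0, 0.0]),
            s.config.n_polar_bands, "polar_angle",
        )
        v1_ends = np.array(
            [
                sl[0] if not rev else sl[-1]
                for sl, rev in zip(s.tractogram, s.manifest["reversed"])
            ]
        )
        clustering = cluster_by_band(s.tractogram, bands, s.white, v1_ends)
        expected = np.bincount(
            s.manifest["polar_band"], minlength=s.config.n_polar_bands
        )
        assert clustering.occupancy().tolist() == expected.tolist()

    def test_single_occupied_cluster(self):
        mesh = grid_mesh(4, 11)
        bands = band_labels(
            mesh, np.arange(mesh.n_vertices), np.array([0.0, 1.0, 0.0]), 5, "ecc"
        )
        t = Tractogram([np.array([[1.0, 0.5, 0.0], [1.0, 0.5, 3.0]]) for _ in range(4)])
        ends = np.array([[1.0, 0.5, 0.0]] * 4)
        clustering = cluster_by_band(t, bands, mesh, ends)
        occ = clustering.occupancy()
        assert occ[0] == 4 and occ[1:].sum() == 0

    def test_cluster_id_monotone_in_eccentricity(self, quiet_scene):
        s = quiet_scene
        bands = band_labels(
            s.white, s.v1.vertex_indices, np.array([0.0, 1.0, 0.0]), 6, "ecc"
        )
        v1_ends = np.array(
            [
                sl[0] if not rev else sl[-1]
                for sl, rev in zip(s.tractogram, s.manifest["reversed"])
            ]
        )
        clustering = cluster_by_band(s.tractogram, bands, s.white, v1_ends)
        order = np.argsort(s.manifest["seed_eccentricity"].to_numpy())
        ids = clustering.cluster_id[order]
        assert np.all(np.diff(ids) >= 0)  # non-decreasing band with eccentricity

    def test_colours_deterministic(self):
        mesh = grid_mesh(3, 6)
        bands = band_labels(
            mesh, np.arange(mesh.n_vertices), np.array([0.0, 1.0, 0.0]), 3, "ecc"
        )
        t = Tractogram([np.array([[0.0, 0, 0], [0, 5, 0]])])
        c1 = cluster_by_band(t, bands, mesh, np.array([[0.0, 0, 0]]))
        c2 = cluster_by_band(t, bands, mesh, np.array([[0.0, 0, 0]]))
        assert np.array_equal(c1.colours, c2.colours)
        assert len(np.unique(c1.colours, axis=0)) == 3


class TestOrderIndex:
    def test_perfect_order(self):
        v = np.linspace(3, 6.9, 50)
        assert topographic_order_index(v, np.arange(50)) == pytest.approx(1.0)

    def test_reversed_order(self):
        v = np.linspace(3, 6.9, 50)
        assert topographic_order_index(v, -np.arange(50.0)) == pytest.approx(-1.0)

    def test_random_permutations_near_zero(self):
        rng = np.random.default_rng(0)
        vals = []
        base = np.linspace(0, 1, 100)
        for _ in range(20):
            vals.append(abs(topographic_order_index(rng.permutation(base), base)))
        assert np.mean(vals) < 0.2

    def test_circular_unwrapping_across_zero(self):
        # angles descending through the wrap: 20 -> 350 as position grows
        pos = np.arange(8.0)
        ang = np.mod(20.0 - 7.0 * pos, 360.0)
        rho = topographic_order_index(ang, pos, circular=True)
        assert rho == pytest.approx(-1.0)

    def test_constant_values_reported_zero(self):
        assert topographic_order_index(np.full(5, 2.0), np.arange(5.0)) == 0.0

    def test_too_few_rejected(self):
        with pytest.raises(ValidationError):
            topographic_order_index(np.array([1.0, 2.0]), np.array([0.0, 1.0]))
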