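"""Mesh statistics: projection, geodesic smoothing, random-effects maps,
cluster calibration and conjunction codes."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import sparse

from semint.surface import (
    ClusterThreshold,
    MemaMap,
    SubjectNodeMap,
    SurfaceMesh,
    conjunction,
    estimate_cluster_threshold,
    geodesic_smooth,
    max_cluster_size,
    mema,
    project_electrodes,
    smoothing_kernel,
    threshold_map,
)
from semint.synthetic import make_mesh


def path_mesh(n=3):
    """Degenerate 'mesh' that is a path graph with unit edges.

    Faces are padded with a far-away vertex so the edge set of interest is
    the path 0-1-...-(n-1).
    """
    verts = np.zeros((n, 3))
    verts[:, 0] = np.arange(n, dtype=float)
    faces = np.array([[i, i + 1, i] for i in range(n - 1)])
    return SurfaceMesh(verts, faces)


class TestProjectElectrodes:
    def test_exact_vertex_hit(self, small_mesh):
        k = 17
        assert project_electrodes(small_mesh, small_mesh.vertices[k])[0] == k

    def test_equidistant_tie_lowest_index(self):
        mesh = path_mesh(3)
        # halfway between vertices 0 and 1
        assert project_electrodes(mesh, np.array([[0.5, 0.0, 0.0]]))[0] == 0

    def test_brute_force_nearest_neighbor(self, small_mesh, rng):
        coords = rng.uniform(-60, 60, size=(40, 3))
        got = project_electrodes(small_mesh, coords)
        d = np.linalg.norm(
            coords[:, None, :] - small_mesh.vertices[None, :, :], axis=-1
        )
        assert np.all(d[np.arange(40), got] <= d.min(axis=1) + 1e-12)

    def test_empty_mesh_rejected(self):
        mesh = SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(ValueError, match="empty"):
            project_electrodes(mesh, np.zeros((1, 3)))

    def test_nonfinite_coords_rejected(self, small_mesh):
        with pytest.raises(ValueError, match="finite"):
            project_electrodes(small_mesh, np.array([[np.nan, 0, 0]]))


class TestGeodesicSmoothing:
    def test_constant_preserved(self, small_mesh):
        out = geodesic_smooth(small_mesh, np.full(small_mesh.n_vertices, 3.3), 10.0)
        np.testing.assert_allclose(out, 3.3, atol=1e-10)

    def test_path_graph_hand_weights(self):
        """Row-normalized Gaussian kernel on a 3-vertex unit path.

        With sigma = 1 the raw kernel row from the end vertex is
        (1, e^-0.5, e^-2); the smoothed value at each vertex i is
        sum_j K(i,j) v_j / sum_j K(i,j).
        """
        mesh = path_mesh(3)
        fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0))  # sigma exactly 1
        delta = np.array([1.0, 0.0, 0.0])
        out = geodesic_smooth(mesh, delta, fwhm)
        k01, k02, k12 = np.exp(-0.5), np.exp(-2.0), np.exp(-0.5)
        expected = np.array(
            [
                1.0 / (1.0 + k01 + k02),
                k01 / (k01 + 1.0 + k12),
                k02 / (k02 + k12 + 1.0),
            ]
        )
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_kernel_rows_normalized(self, small_mesh):
        k = smoothing_kernel(small_mesh, 10.0)
        np.testing.assert_allclose(
            np.asarray(k.sum(axis=1)).ravel(), 1.0, atol=1e-9
        )

    def test_vertex_relabeling_equivariance(self, small_mesh, rng):
        v = rng.standard_normal(small_mesh.n_vertices)
        perm = rng.permutation(small_mesh.n_vertices)
        inv = np.argsort(perm)
        mesh_p = SurfaceMesh(small_mesh.vertices[perm], inv[small_mesh.faces])
        out = geodesic_smooth(small_mesh, v, 10.0)
        out_p = geodesic_smooth(mesh_p, v[perm], 10.0)
        np.testing.assert_allclose(out_p, out[perm], atol=1e-9)

    def test_coverage_weights_ignore_uncovered(self, small_mesh):
        v = np.full(small_mesh.n_vertices, 5.0)
        w = np.ones(small_mesh.n_vertices)
        v[0] = 1e6  # uncovered junk value must not leak
        w[0] = 0.0
        out = geodesic_smooth(small_mesh, v, 10.0, weights=w)
        np.testing.assert_allclose(out[1:], 5.0, atol=1e-9)


class TestMema:
    def test_dersimonian_laird_hand_example(self):
        maps = [
            SubjectNodeMap("a", np.array([1.0]), np.array([1.0]), np.array([True])),
            SubjectNodeMap("b", np.array([3.0]), np.array([1.0]), np.array([True])),
        ]
        res = mema(maps, min_coverage=2)
        # Q = 2, tau2 = 1, weights 1/2 -> pooled 2, se 1, t 2
        assert res.effect[0] == pytest.approx(2.0)
        assert res.tau2[0] == pytest.approx(1.0)
        assert res.t_stat[0] == pytest.approx(2.0)
        assert res.df[0] == 1

    def test_identical_zero_effects(self):
        maps = [
            SubjectNodeMap(s, np.zeros(4), np.ones(4), np.ones(4, bool))
            for s in "abc"
        ]
        res = mema(maps, min_coverage=3)
        np.testing.assert_allclose(res.effect, 0.0)
        np.testing.assert_allclose(res.t_stat, 0.0)

    def test_homogeneous_reduces_to_mean(self, rng):
        beta = rng.standard_normal(3) * 0.01  # tiny spread -> tau2 = 0
        maps = [
            SubjectNodeMap(str(i), np.array([beta[i]]), np.array([4.0]),
                           np.array([True]))
            for i in range(3)
        ]
        res = mema(maps, min_coverage=3)
        assert res.tau2[0] == 0.0
        assert res.effect[0] == pytest.approx(beta.mean())
        assert res.t_stat[0] == pytest.approx(beta.mean() / np.sqrt(4.0 / 3.0))

    def test_matches_statsmodels_combine_effects(self, rng):
        """Independent DL oracle on heterogeneous inputs.

        statsmodels does not truncate tau^2 at zero, so the comparison is
        restricted to cases where the moment estimate is positive (our
        truncation is then inactive).
        """
        from statsmodels.stats.meta_analysis import combine_effects

        checked = 0
        for _ in range(30):
            k = int(rng.integers(2, 6))
            eff = rng.standard_normal(k) * 5.0  # large spread -> heterogeneity
            var = rng.uniform(0.1, 0.5, k)
            cmb = combine_effects(eff, var, method_re="dl")
            if cmb.tau2 <= 0:
                continue
            maps = [
                SubjectNodeMap(str(i), np.array([eff[i]]), np.array([var[i]]),
                               np.array([True]))
                for i in range(k)
            ]
            res = mema(maps, min_coverage=2)
            assert res.tau2[0] == pytest.approx(cmb.tau2, rel=1e-8)
            assert res.effect[0] == pytest.approx(
                cmb.summary_frame().loc["random effect", "eff"], rel=1e-8
            )
            checked += 1
        assert checked >= 10

    def test_coverage_masking(self):
        covered = np.array([True, False])
        maps = [
            SubjectNodeMap(s, np.array([1.0, 9.0]), np.array([1.0, 1.0]), covered)
            for s in "abc"
        ]
        res = mema(maps, min_coverage=3)
        assert res.coverage[0] == 3 and res.coverage[1] == 0
        assert np.isnan(res.t_stat[1])


class TestClusterThreshold:
    def test_alpha_near_one_min_size_small(self, small_mesh):
        ct = estimate_cluster_threshold(
            small_mesh, 10.0, 2.0, alpha=0.999, n_iter=100, seed=0
        )
        # the 0.001 quantile of max cluster sizes is (almost surely) 0 -> +1
        assert ct.min_cluster_size <= 2

    def test_monotone_in_alpha(self, small_mesh):
        sizes = [
            estimate_cluster_threshold(
                small_mesh, 10.0, 2.0, alpha=a, n_iter=200, seed=3
            ).min_cluster_size
            for a in (0.2, 0.05, 0.01)
        ]
        assert sizes[0] <= sizes[1] <= sizes[2]

    def test_monotone_in_fwhm(self, small_mesh):
        small = estimate_cluster_threshold(
            small_mesh, 5.0, 2.0, alpha=0.05, n_iter=200, seed=3
        ).min_cluster_size
        large = estimate_cluster_threshold(
            small_mesh, 20.0, 2.0, alpha=0.05, n_iter=200, seed=3
        ).min_cluster_size
        assert small <= large

    def test_bad_alpha_rejected(self, small_mesh):
        with pytest.raises(ValueError, match="alpha"):
            estimate_cluster_threshold(small_mesh, 5.0, 2.0, alpha=1.5, n_iter=100)

    def test_max_cluster_size_matches_enumeration(self):
        """All 64 patterns on a 6-vertex mesh vs a networkx oracle."""
        mesh = make_mesh(12, 10.0, seed=5)
        adj = mesh.adjacency(weighted=False)[:6, :6]
        g = nx.from_scipy_sparse_array(adj)
        for bits in itertools.product([False, True], repeat=6):
            mask = np.array(bits)
            sub = g.subgraph(np.flatnonzero(mask))
            oracle = max((len(c) for c in nx.connected_components(sub)), default=0)
            assert max_cluster_size(adj.tocsr(), mask) == oracle


def simple_mema_map(t, pct, cov):
    n = len(t)
    return MemaMap(
        effect=np.asarray(pct, float),
        t_stat=np.asarray(t, float),
        df=np.full(n, 5.0),
        coverage=np.asarray(cov),
        percent_bga=np.asarray(pct, float),
        tau2=np.zeros(n),
        min_coverage=3,
    )


class TestThresholdMap:
    def test_rule_application(self):
        m = simple_mema_map([3.0, 3.0, 1.0], [6.0, 4.0, 6.0], [4, 4, 4])
        mask = threshold_map(m, t_min=1.96, pct_min=5.0, min_coverage=3)
        np.testing.assert_array_equal(mask, [True, False, False])

    def test_low_coverage_fails_regardless_of_t(self):
        m = simple_mema_map([10.0], [50.0], [2])
        assert not threshold_map(m, 1.96, 5.0, min_coverage=3)[0]

    def test_isolated_vertex_fails_cluster_rule(self, small_mesh):
        n = small_mesh.n_vertices
        t = np.zeros(n)
        t[5] = 10.0
        m = simple_mema_map(t, t * 10, np.full(n, 4))
        ct = ClusterThreshold(2.0, 0.01, min_cluster_size=10, n_iterations=100, seed=0)
        mask = threshold_map(m, 1.96, 0.0, 3, cluster=ct, mesh=small_mesh)
        assert not mask.any()


class TestConjunction:
    def test_single_contrast_codes(self):
        maps = {
            "reference": np.array([True, False, True]),
            "coherence": np.array([False, False, True]),
            "narrowing": np.array([False, False, True]),
        }
        cmap = conjunction(maps)
        labels = cmap.labels()
        assert labels[0] == "R"
        assert labels[1] == ""
        assert labels[2] == "R+C+N"

    def test_codes_match_boolean_oracle(self, rng):
        maps = {k: rng.random(50) < 0.4 for k in ("reference", "coherence", "narrowing")}
        cmap = conjunction(maps)
        for i in range(50):
            expected = (
                int(maps["reference"][i])
                | (int(maps["coherence"][i]) << 1)
                | (int(maps["narrowing"][i]) << 2)
            )
            assert cmap.code[i] == expected

    def test_mesh_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mesh"):
            conjunction({"a": np.zeros(3, bool), "b": np.zeros(4, bool)})
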