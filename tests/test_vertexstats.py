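import numpy as np
import pytest
from scipy import stats

import oracles
import taumap as tm
from taumap.thickness import SkeletonField
from taumap.vertexstats import (
    ClusterResult,
    DesignMatrix,
    VertexStatMap,
    _vertex_pvalues,
)


def hex_fan_mesh():
    """Center vertex with six ring neighbors (center degree 6)."""
    faces = np.array([[0, i, i % 6 + 1] for i in range(1, 7)])
    return faces, 7


@pytest.fixture(scope="module")
def small_adjacency(small_template):
    return tm.mesh_adjacency(small_template.skeleton_faces,
                             small_template.n_vertices)


class TestDiffuseSmooth:
    def test_constant_field_is_fixed_point(self, small_template,
                                           small_adjacency):
        n = small_template.n_vertices
        fld = SkeletonField(np.full(n, 2.5), np.ones(n, dtype=bool))
        for T in (0.5, 4.0, 10.0):
            out = tm.diffuse_smooth(fld, small_adjacency, T)
            np.testing.assert_allclose(out.thickness, 2.5, atol=1e-12)

    def test_constant_field_with_missingness_preserved(self, small_template,
                                                       small_adjacency):
        n = small_template.n_vertices
        rng = np.random.default_rng(0)
        valid = rng.random(n) > 0.3
        fld = SkeletonField(np.full(n, 2.5), valid)
        out = tm.diffuse_smooth(fld, small_adjacency, 4.0)
        np.testing.assert_allclose(out.thickness[out.valid], 2.5, atol=1e-12)

    def test_zero_time_returns_input(self, small_template, small_adjacency):
        n = small_template.n_vertices
        rng = np.random.default_rng(1)
        fld = SkeletonField(rng.random(n), rng.random(n) > 0.2)
        out = tm.diffuse_smooth(fld, small_adjacency, 0.0)
        np.testing.assert_array_equal(out.thickness, fld.thickness)

    def test_single_spike_one_step_matches_hand_computation(self):
        faces, n = hex_fan_mesh()
        A = tm.mesh_adjacency(faces, n)
        f = np.zeros(n)
        f[0] = 1.0
        fld = SkeletonField(f, np.ones(n, dtype=bool))
        out = tm.diffuse_smooth(fld, A, T=0.25, step=0.25)
        # center: 1 + 0.25*(0 - 1) = 0.75; ring vertex (degree 3, one active
        # neighbor): 0 + 0.25*(1/3 - 0) = 1/12
        assert out.thickness[0] == pytest.approx(0.75)
        np.testing.assert_allclose(out.thickness[1:], 1.0 / 12.0)

    def test_discrete_maximum_principle(self, small_template, small_adjacency):
        n = small_template.n_vertices
        rng = np.random.default_rng(2)
        for _ in range(20):
            vals = rng.normal(size=n)
            valid = rng.random(n) > 0.25
            fld = SkeletonField(vals.copy(), valid)
            out = tm.diffuse_smooth(fld, small_adjacency, 4.0)
            lo, hi = vals[valid].min(), vals[valid].max()
            assert (out.thickness[out.valid] >= lo - 1e-10).all()
            assert (out.thickness[out.valid] <= hi + 1e-10).all()


class TestVertexGlm:
    def test_exact_linear_data_recovered_to_machine_precision(self):
        rng = np.random.default_rng(3)
        n, V = 12, 6
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        slopes = rng.normal(size=V)
        Y = 1.5 + np.outer(x, slopes)
        d = DesignMatrix(X, np.array([0.0, 1.0]))
        sm = tm.vertex_glm(Y, np.ones((n, V), dtype=bool), d, 0.25)
        assert sm.analyzed.all()
        # residuals are exactly zero so |t| is huge wherever slope != 0
        assert (np.abs(sm.t) > 1e6).all()
        assert (sm.df == n - 2).all()

    def test_vertex_below_validity_fraction_unanalyzed(self):
        n = 10
        X = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
        d = DesignMatrix(X, np.array([0.0, 1.0]))
        Y = np.random.default_rng(0).normal(size=(n, 2))
        valid = np.ones((n, 2), dtype=bool)
        valid[2:, 0] = False  # 20% valid < 25%
        sm = tm.vertex_glm(Y, valid, d, min_valid_fraction=0.25)
        assert not sm.analyzed[0]
        assert sm.analyzed[1]

    def test_constant_variable_of_interest_unanalyzed_not_exception(self):
        n = 8
        X = np.column_stack([np.ones(n), np.ones(n)])
        d = DesignMatrix(X, np.array([0.0, 1.0]))
        Y = np.random.default_rng(1).normal(size=(n, 3))
        sm = tm.vertex_glm(Y, np.ones((n, 3), dtype=bool), d, 0.25)
        assert not sm.analyzed.any()

    def test_matches_per_vertex_regression_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n, V = 8, 5
            X = np.column_stack([np.ones(n), rng.normal(size=n),
                                 rng.normal(size=n)])
            Y = rng.normal(size=(n, V))
            valid = rng.random((n, V)) > 0.2
            d = DesignMatrix(X, np.array([0.0, 1.0, 0.0]))
            sm = tm.vertex_glm(Y, valid, d, 0.25)
            for j in range(V):
                m = valid[:, j]
                if m.sum() < 4 or np.linalg.matrix_rank(X[m]) < 3:
                    assert not sm.analyzed[j]
                    continue
                beta, *_ = np.linalg.lstsq(X[m], Y[m, j], rcond=None)
                resid = Y[m, j] - X[m] @ beta
                s2 = resid @ resid / (m.sum() - 3)
                se = np.sqrt(s2 * np.linalg.inv(X[m].T @ X[m])[1, 1])
                assert sm.t[j] == pytest.approx(beta[1] / se, abs=1e-10)
                assert sm.df[j] == m.sum() - 3


class TestClusterExtract:
    def test_null_map_yields_no_clusters(self, small_template,
                                         small_adjacency):
        n = small_template.n_vertices
        sm = VertexStatMap(t=np.zeros(n), df=np.full(n, 10),
                           analyzed=np.ones(n, dtype=bool))
        assert tm.cluster_extract(sm, small_adjacency, 0.01, "negative") == []

    def test_single_suprathreshold_vertex_is_extent_one(self, small_template,
                                                        small_adjacency):
        n = small_template.n_vertices
        t = np.zeros(n)
        t[5] = -10.0
        sm = VertexStatMap(t=t, df=np.full(n, 10),
                           analyzed=np.ones(n, dtype=bool))
        clusters = tm.cluster_extract(sm, small_adjacency, 0.01, "negative")
        assert len(clusters) == 1
        assert clusters[0].extent == 1
        assert clusters[0].vertices.tolist() == [5]

    def test_components_match_flood_fill_oracle(self, small_template,
                                                small_adjacency):
        rng = np.random.default_rng(5)
        n = small_template.n_vertices
        adj_lists = [small_adjacency[i].indices.tolist() for i in range(n)]
        for _ in range(10):
            t = rng.normal(size=n) * 3
            sm = VertexStatMap(t=t, df=np.full(n, 12),
                               analyzed=np.ones(n, dtype=bool))
            clusters = tm.cluster_extract(sm, small_adjacency, 0.05,
                                          "negative")
            # independent flood fill over suprathreshold vertices
            supra = set(np.where(stats.t.cdf(t, 12) < 0.05)[0].tolist())
            seen, comps = set(), []
            for v in sorted(supra):
                if v in seen:
                    continue
                stack, comp = [v], set()
                while stack:
                    u = stack.pop()
                    if u in comp:
                        continue
                    comp.add(u)
                    stack.extend(w for w in adj_lists[u]
                                 if w in supra and w not in comp)
                seen |= comp
                comps.append(frozenset(comp))
            got = {frozenset(c.vertices.tolist()) for c in clusters}
            assert got == set(comps)


class TestFreedmanLane:
    def _toy_problem(self, seed=6, n=5, strong=False):
        tpl = tm.make_template((32, 24, 24), (0.5, 0.5, 0.5), seed=0,
                               skeleton_shape=(8, 6))
        A = tm.mesh_adjacency(tpl.skeleton_faces, tpl.n_vertices)
        rng = np.random.default_rng(seed)
        V = tpl.n_vertices
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, rng.normal(size=n)])
        Y = rng.normal(size=(n, V))
        if strong:
            Y[:, :10] -= 40.0 * np.outer(x, np.ones(10))
        valid = rng.random((n, V)) > 0.15
        d = DesignMatrix(X, np.array([0.0, 1.0, 0.0]))
        return tpl, A, Y, valid, d

    def test_minimum_corrected_p_is_the_formula_floor(self):
        """An observed cluster larger than every permutation maximum over
        999 permutations receives corrected p = 1/1000."""
        tpl = tm.make_template((32, 24, 24), (0.5, 0.5, 0.5), seed=0,
                               skeleton_shape=(8, 6))
        A = tm.mesh_adjacency(tpl.skeleton_faces, tpl.n_vertices)
        rng = np.random.default_rng(1)
        n, V = 12, tpl.n_vertices
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, rng.normal(size=n)])
        Y = rng.normal(size=(n, V))
        Y[:, :12] -= 3.0 * np.outer(x, np.ones(12))
        Y[:, :12] += 0.5 * rng.normal(size=(n, 12))
        d = DesignMatrix(X, np.array([0.0, 1.0, 0.0]))
        stat, clusters, maxima = tm.freedman_lane_fwe(
            Y, np.ones((n, V), dtype=bool), d, A,
            cluster_p=0.01, n_permutations=999, seed=0,
        )
        assert clusters
        big = max(clusters, key=lambda c: c.extent)
        assert big.extent > maxima.max()
        assert min(c.corrected_p for c in clusters) == pytest.approx(1 / 1000)
        # general formula consistency on every cluster
        for c in clusters:
            expected = (1 + (maxima >= c.extent).sum()) / 1000
            assert c.corrected_p == pytest.approx(expected)

    def test_exhaustive_mode_matches_independent_enumeration(self,
                                                             small_template):
        tpl, A, Y, valid, d = self._toy_problem(n=5, strong=True)
        n = 5
        stat, clusters, maxima = tm.freedman_lane_fwe(
            Y, valid, d, A, cluster_p=0.05, exhaustive=True
        )
        adj_lists = [A[i].indices.tolist() for i in range(tpl.n_vertices)]
        comps, pvals, _ = oracles.freedman_lane_exhaustive(
            Y, valid, d.X, d.contrast, adj_lists, 0.05, 0.25
        )
        assert len(maxima) == 120
        got = sorted(
            (frozenset(c.vertices.tolist()), c.corrected_p) for c in clusters
        )
        want = sorted(
            (frozenset(c), p) for c, p in zip(comps, pvals)
        )
        assert [g[0] for g in got] == [w[0] for w in want]
        np.testing.assert_allclose([g[1] for g in got], [w[1] for w in want])

    def test_monte_carlo_converges_to_exhaustive(self):
        tpl, A, Y, valid, d = self._toy_problem(n=5, strong=True)
        _, cl_ex, _ = tm.freedman_lane_fwe(Y, valid, d, A, cluster_p=0.05,
                                           exhaustive=True)
        _, cl_mc, _ = tm.freedman_lane_fwe(Y, valid, d, A, cluster_p=0.05,
                                           n_permutations=2000, seed=3)
        ex = {frozenset(c.vertices.tolist()): c.corrected_p for c in cl_ex}
        for c in cl_mc:
            key = frozenset(c.vertices.tolist())
            assert abs(c.corrected_p - ex[key]) <= 2 / np.sqrt(2000)

    def test_results_reproducible_for_fixed_seed(self):
        tpl, A, Y, valid, d = self._toy_problem(n=8)
        r1 = tm.freedman_lane_fwe(Y, valid, d, A, n_permutations=50, seed=11)
        r2 = tm.freedman_lane_fwe(Y, valid, d, A, n_permutations=50, seed=11)
        np.testing.assert_array_equal(r1[2], r2[2])
        assert [c.corrected_p for c in r1[1]] == [c.corrected_p for c in r2[1]]

    def test_no_analyzed_vertices_is_an_error(self):
        tpl, A, Y, valid, d = self._toy_problem(n=5)
        with pytest.raises(ValueError):
            tm.freedman_lane_fwe(Y, np.zeros_like(valid), d, A,
                                 n_permutations=10, seed=0)
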