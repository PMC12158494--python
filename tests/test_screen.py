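"""Moran's I screen, BH adjustment, natural splines and the monotone filter."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from quiestem.bulk import BulkPair
from quiestem.preprocess import Embedding
from quiestem.screen import (
    bh_adjust,
    build_knn_graph,
    fit_spline,
    intersect_datasets,
    monotone_decreasing,
    moran_screen,
    morans_i,
    morans_test,
    rank_candidates,
    select_trajectory_genes,
)


def _emb(points, ids=None):
    points = np.asarray(points, dtype=float)
    ids = ids or [f"c{i}" for i in range(points.shape[0])]
    cols = [f"d{i+1}" for i in range(points.shape[1])]
    return Embedding(pd.DataFrame(points, index=ids, columns=cols), "test")


def _path_adj(n):
    g = nx.path_graph(n)
    for u, v in g.edges:
        g[u][v]["weight"] = 1.0
    return nx.to_scipy_sparse_array(g, format="csr")


class TestKnnGraph:
    def test_equidistant_triangle_symmetrized(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        A = build_knn_graph(_emb(pts), k=1).toarray()
        # each point's single neighbour (tie-broken by id) unioned symmetric
        assert (A == A.T).all()
        assert A.diagonal().sum() == 0
        assert A.sum() >= 4  # at least two undirected edges survive

    def test_k_equals_n_minus_one_complete(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 2))
        A = build_knn_graph(_emb(pts), k=5).toarray()
        assert (A + np.eye(6) == 1).all()

    def test_no_self_loops(self):
        rng = np.random.default_rng(1)
        A = build_knn_graph(_emb(rng.normal(size=(30, 3))), k=4)
        assert A.diagonal().sum() == 0

    def test_invalid_k(self):
        emb = _emb(np.random.default_rng(2).normal(size=(5, 2)))
        with pytest.raises(ValueError):
            build_knn_graph(emb, k=0)
        with pytest.raises(ValueError):
            build_knn_graph(emb, k=5)


def brute_force_moran(x, W):
    """Literal double-sum evaluation of Moran's I."""
    x = np.asarray(x, float)
    n = len(x)
    xbar = x.mean()
    num = sum(
        W[i, j] * (x[i] - xbar) * (x[j] - xbar) for i in range(n) for j in range(n)
    )
    den = sum((xi - xbar) ** 2 for xi in x)
    Wsum = W.sum()
    return (n / Wsum) * num / den


class TestMoransI:
    def test_path4_blocked_signal(self):
        assert morans_i(np.array([1, 1, -1, -1]), _path_adj(4)) == pytest.approx(1 / 3)

    def test_path4_alternating_signal(self):
        assert morans_i(np.array([1, -1, 1, -1]), _path_adj(4)) == pytest.approx(-1.0)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(4), _path_adj(4))

    def test_matches_brute_force_on_small_graphs(self):
        """Random graphs on <= 6 nodes, random values, exact to 1e-12."""
        rng = np.random.default_rng(7)
        for n in range(3, 7):
            for _ in range(20):
                W = (rng.random((n, n)) < 0.5).astype(float)
                np.fill_diagonal(W, 0)
                if W.sum() == 0:
                    continue
                x = rng.normal(size=n)
                from scipy import sparse

                got = morans_i(x, sparse.csr_matrix(W))
                assert got == pytest.approx(brute_force_moran(x, W), abs=1e-12)


class TestMoransTest:
    def test_exhaustive_enumeration_path4(self):
        p = morans_test(np.array([1, 1, -1, -1]), _path_adj(4), mode="exhaustive")
        assert p == pytest.approx(1 / 3)

    def test_permutation_seed_reproducible(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        A = _path_adj(12)
        p1 = morans_test(x, A, mode="permutation", n_perm=199, seed=9)
        p2 = morans_test(x, A, mode="permutation", n_perm=199, seed=9)
        assert p1 == p2

    def test_permutation_matches_exhaustive_at_small_n(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=6)
        A = _path_adj(6)
        p_ex = morans_test(x, A, mode="exhaustive")
        p_mc = morans_test(x, A, mode="permutation", n_perm=4999, seed=0)
        # add-one MC estimate within 3 binomial SEs of the exact proportion
        se = np.sqrt(p_ex * (1 - p_ex) / 4999)
        assert abs(p_mc - p_ex) < 3 * se + 1 / 5000

    def test_smooth_gradient_minimal_p(self):
        """A smooth gradient on a 200-cell line maximizes I; the sampled
        permutation p hits the add-one lower bound and the normal p underflows."""
        xs = np.linspace(0, 1, 200)
        emb = _emb(np.column_stack([xs, np.zeros_like(xs)]))
        A = build_knn_graph(emb, k=10)
        signal = 3 - 2 * xs
        p_perm = morans_test(signal, A, mode="permutation", n_perm=1000, seed=0)
        assert p_perm == pytest.approx(1 / 1001)
        p_norm = morans_test(signal, A, mode="normal")
        assert p_norm < 1e-30

    def test_normal_mode_agrees_with_permutation_moderate_signal(self):
        rng = np.random.default_rng(5)
        xs = np.linspace(0, 1, 120)
        emb = _emb(np.column_stack([xs, np.zeros_like(xs)]))
        A = build_knn_graph(emb, k=8)
        x = xs + rng.normal(scale=1.2, size=120)  # weak-to-moderate signal
        p_norm = morans_test(x, A, mode="normal")
        p_perm = morans_test(x, A, mode="permutation", n_perm=9999, seed=1)
        assert p_perm == pytest.approx(p_norm, abs=0.02)


def reference_bh(p):
    """Textbook step-up: q_(i) = min over j >= i of m p_(j) / j, capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, m * p[i] / rank)
        q[i] = prev
    return q


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_identity(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust(np.ones(5)), 1.0)

    def test_matches_reference_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.uniform(size=20)
            np.testing.assert_allclose(bh_adjust(p), reference_bh(p), atol=1e-12)
        p = rng.uniform(size=1000)
        np.testing.assert_allclose(bh_adjust(p), reference_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestSelectTrajectoryGenes:
    def _res(self, qs):
        return pd.DataFrame(
            {"morans_i": 0.5, "p_value": qs, "q_value": qs},
            index=[f"g{i}" for i in range(len(qs))],
        )

    def test_exact_zero_selected(self):
        assert select_trajectory_genes(self._res([0.0, 0.5])) == ["g0"]

    def test_tiny_but_nonzero_not_selected(self):
        with pytest.warns(UserWarning):
            assert select_trajectory_genes(self._res([1e-250])) == []

    def test_permutation_floor_warns(self):
        res = self._res([1 / 1001, 0.3])
        with pytest.warns(UserWarning, match="normal"):
            assert select_trajectory_genes(res) == []


class TestIntersect:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"A", "B", "C"}, {"B", "C", "D"}, ["B", "C"]),
            ({"A"}, {"B"}, []),
            ({"A", "B"}, {"A", "B"}, ["A", "B"]),
        ],
    )
    def test_examples(self, a, b, expected):
        assert intersect_datasets(a, b) == expected


class TestFitSpline:
    def test_linear_function_reproduced_exactly(self):
        t = np.linspace(0, 1, 20)
        fit = fit_spline(t, 3 - 2 * t, df=3)
        grid = np.linspace(0, 1, 50)
        np.testing.assert_allclose(fit.derivative(grid), -2.0, atol=1e-8)
        np.testing.assert_allclose(fit.predict(grid), 3 - 2 * grid, atol=1e-8)

    def test_constant_has_zero_derivative(self):
        t = np.linspace(0, 2, 25)
        fit = fit_spline(t, np.full(25, 1.7), df=3)
        np.testing.assert_allclose(fit.derivative(np.linspace(0, 2, 40)), 0.0, atol=1e-8)

    def test_parabola_derivative_changes_sign(self):
        t = np.linspace(0, 1, 60)
        fit = fit_spline(t, (t - 0.5) ** 2, df=3)
        d = fit.derivative(np.linspace(0, 1, 60))
        assert (d[:10] < 0).all()
        assert (d[-10:] > 0).all()

    def test_normal_equations_satisfied(self):
        rng = np.random.default_rng(2)
        t = rng.uniform(0, 3, 80)
        y = np.sin(t) + rng.normal(scale=0.2, size=80)
        fit = fit_spline(t, y, df=4)
        from quiestem.screen import _ns_basis

        B = np.column_stack([np.ones_like(t), _ns_basis(t, fit.knots)])
        resid = y - (fit.coef[0] + B[:, 1:] @ fit.coef[1:])
        np.testing.assert_allclose(B.T @ resid, 0.0, atol=1e-8)

    def test_linear_tails_outside_boundary(self):
        rng = np.random.default_rng(4)
        t = rng.uniform(0, 1, 50)
        y = np.cos(2 * t) + rng.normal(scale=0.1, size=50)
        fit = fit_spline(t, y, df=3)
        # beyond the boundary knot the derivative is constant (natural tails)
        left = fit.derivative(np.array([t.min() - 0.5, t.min() - 0.1, t.min()]))
        np.testing.assert_allclose(left, left[0], atol=1e-9)

    def test_insufficient_distinct_t_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_spline(np.array([0.0, 0.0, 1.0, 1.0]), np.arange(4.0), df=3)


class TestMonotoneDecreasing:
    def test_decreasing_line_true(self):
        t = np.linspace(0, 1, 30)
        fit = fit_spline(t, 3 - 2 * t, df=3)
        assert monotone_decreasing(fit, np.linspace(0, 1, 100)) is True

    def test_constant_false_under_strict_inequality(self):
        t = np.linspace(0, 1, 30)
        fit = fit_spline(t, np.ones(30), df=3)
        assert monotone_decreasing(fit, np.linspace(0, 1, 100)) is False

    def test_parabola_false(self):
        t = np.linspace(0, 1, 60)
        fit = fit_spline(t, (t - 0.5) ** 2, df=3)
        assert monotone_decreasing(fit, np.linspace(0, 1, 100)) is False

    def test_empty_grid_rejected(self):
        t = np.linspace(0, 1, 30)
        fit = fit_spline(t, 3 - 2 * t, df=3)
        with pytest.raises(ValueError):
            monotone_decreasing(fit, np.array([]))


class TestRankCandidates:
    def _pair(self):
        df = pd.DataFrame(
            {
                "tpm_retained": [100.0, 10.0, 1.0],
                "tpm_reduced": [10.0, 10.0, 10.0],
            },
            index=pd.Index(["a", "b", "c"], name="gene_id"),
        )
        return BulkPair(df)

    def test_sorted_by_retained_tpm(self):
        out = rank_candidates(["b", "c", "a"], self._pair())
        assert out.index.tolist() == ["a", "b", "c"]
        assert out["rank"].tolist() == [1, 2, 3]

    def test_single_gene_rank_one(self):
        out = rank_candidates(["b"], self._pair())
        assert out["rank"].tolist() == [1]

    def test_missing_gene_ranked_last(self):
        out = rank_candidates(["zz", "a"], self._pair())
        assert out.index.tolist() == ["a", "zz"]
        assert np.isnan(out.loc["zz", "tpm_retained"])
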