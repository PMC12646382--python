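"""Standardization and the linear-Gaussian BIC: formula fidelity,
decomposability, delta scoring, cache transparency."""

import math

import numpy as np
import pytest

from dagclimb.dag import DirectedGraph, EdgeMove, legal_moves
from dagclimb.scoring import (
    ScoreCache,
    StandardizedDataset,
    fit_local,
    graph_score,
    local_bic,
    score_delta,
    standardize,
)
from conftest import all_dags, random_dag, random_dataset


# -------------------------------------------------------------- standardization

class TestStandardize:
    def test_simple_column(self):
        ds = standardize(np.array([[1.0], [2.0], [3.0]]), ["x"])
        assert np.allclose(ds.column("x"), [-1.0, 0.0, 1.0])

    def test_idempotent(self, rng):
        ds = standardize(rng.normal(size=(50, 3)), list("abc"))
        again = standardize(ds.values, ds.columns)
        assert np.allclose(again.values, ds.values, atol=1e-12)

    def test_hand_computed_column(self):
        # mean 20, sample sd sqrt(200/3)
        ds = standardize(np.array([[10.0], [20.0], [20.0], [30.0]]), ["x"])
        sd = math.sqrt(200.0 / 3.0)
        assert np.allclose(ds.column("x"), [(v - 20.0) / sd for v in (10, 20, 20, 30)])

    def test_constant_column_rejected_by_name(self):
        with pytest.raises(ValueError, match="const_col"):
            standardize(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]), ["x", "const_col"])

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="3 rows"):
            standardize(np.array([[1.0], [2.0]]), ["x"])

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="listwise"):
            standardize(np.array([[1.0], [np.nan], [3.0]]), ["x"])

    def test_validate_flags_nonstandard_columns(self, rng):
        ds = standardize(rng.normal(size=(30, 2)), ["a", "b"])
        ds.validate()
        bad = StandardizedDataset(ds.values * 2.0, ds.columns)
        with pytest.raises(ValueError):
            bad.validate()


# ------------------------------------------------------------------- local BIC

def bic_formula(n, k, rss):
    """Independent one-line evaluation of the printed score formula."""
    return -(n / 2) * (math.log(2 * math.pi) + 1 + math.log(rss / n)) - ((k + 2) / 2) * math.log(n)


class TestLocalBic:
    def test_reference_value_rss_over_n_one(self):
        # constructed column with RSS exactly n: score collapses to
        # -(n/2)(ln 2pi + 1) - ln n for k=0
        n = 100
        x = np.arange(n, dtype=float)
        x = x - x.mean()
        x *= math.sqrt(n / (x @ x))
        ds = StandardizedDataset(x[:, None], ["x"])
        expected = -(n / 2) * (math.log(2 * math.pi) + 1) - math.log(n)
        assert local_bic(ds, "x") == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(-146.4990, abs=5e-5)

    def test_parent_free_rss_is_n_minus_one(self, rng):
        ds = standardize(rng.normal(size=(200, 1)), ["x"])
        fit = fit_local(ds, "x", [])
        assert fit.rss == pytest.approx(ds.n - 1, abs=1e-6)

    def test_matches_independent_formula_on_simulated_regression(self, rng):
        n = 500
        parent = rng.normal(size=n)
        child = 0.6 * parent + rng.normal(size=n)
        ds = standardize(np.column_stack([parent, child]), ["p", "c"])
        # separately coded least squares for the oracle RSS
        X = np.column_stack([np.ones(n), ds.column("p")])
        beta = np.linalg.solve(X.T @ X, X.T @ ds.column("c"))
        rss = float(((ds.column("c") - X @ beta) ** 2).sum())
        assert local_bic(ds, "c", ["p"]) == pytest.approx(bic_formula(n, 1, rss), abs=1e-9)

    def test_deterministic_and_parent_order_invariant(self, rng):
        ds = random_dataset(rng, list("abcd"), n=150)
        s1 = local_bic(ds, "a", ["b", "c"])
        assert s1 == local_bic(ds, "a", ["b", "c"])
        assert s1 == pytest.approx(local_bic(ds, "a", ["c", "b"]), abs=1e-9)

    def test_row_order_invariance(self, rng):
        ds = random_dataset(rng, list("abc"), n=100)
        perm = rng.permutation(ds.n)
        shuffled = StandardizedDataset(ds.values[perm], ds.columns)
        assert local_bic(shuffled, "a", ["b"]) == pytest.approx(
            local_bic(ds, "a", ["b"]), abs=1e-9
        )

    def test_child_in_parents_rejected(self, rng):
        ds = random_dataset(rng, list("ab"), n=50)
        with pytest.raises(ValueError):
            local_bic(ds, "a", ["a", "b"])

    def test_collinear_child_score_finite_via_rss_floor(self, rng):
        x = rng.normal(size=80)
        ds = standardize(np.column_stack([x, x * 2.0]), ["a", "b"])
        score = local_bic(ds, "b", ["a"])
        assert np.isfinite(score)

    def test_singular_design_warns_but_scores(self, rng):
        x = rng.normal(size=80)
        y = rng.normal(size=80)
        ds = standardize(np.column_stack([x, x * 3.0, y]), ["a", "a2", "y"])
        with pytest.warns(UserWarning, match="singular"):
            assert np.isfinite(local_bic(ds, "y", ["a", "a2"]))

    def test_pure_noise_parent_lowers_score_on_average(self, rng):
        # the (k+2)/2 ln n penalty dominates the chance RSS reduction
        n = 400
        deltas = []
        for _ in range(120):
            ds = standardize(rng.normal(size=(n, 2)), ["x", "z"])
            deltas.append(local_bic(ds, "x", ["z"]) - local_bic(ds, "x"))
        assert np.mean(deltas) < 0
        assert np.mean(np.array(deltas) < 0) > 0.9


# ------------------------------------------------------- graph score and cache

def brute_graph_score(ds, g):
    """Independent graph scorer: per-node OLS via solve + printed formula."""
    total = 0.0
    for v in g.nodes:
        parents = g.parents(v)
        y = ds.column(v)
        X = np.column_stack([np.ones(ds.n)] + [ds.column(p) for p in parents])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        total += bic_formula(ds.n, len(parents), rss)
    return total


class TestGraphScore:
    def test_empty_graph_is_sum_of_parent_free_scores(self, rng):
        ds = random_dataset(rng, list("abcd"), n=120)
        g = DirectedGraph(ds.columns)
        expected = sum(local_bic(ds, v) for v in ds.columns)
        assert graph_score(ds, g) == pytest.approx(expected, abs=1e-9)

    def test_cache_transparent(self, rng):
        ds = random_dataset(rng, list("abcd"), n=120)
        g = random_dag(rng, ds.columns, p_edge=0.5)
        cache = ScoreCache()
        s1 = graph_score(ds, g, cache)
        s2 = graph_score(ds, g, cache)  # second pass fully cached
        assert s1 == s2 == pytest.approx(graph_score(ds, g), abs=0)
        assert cache.hits >= len(g.nodes)

    def test_all_three_node_dags_match_brute_force_oracle(self, rng):
        ds = random_dataset(rng, list("abc"), n=100)
        count = 0
        for g in all_dags(list("abc")):
            assert graph_score(ds, g) == pytest.approx(brute_graph_score(ds, g), abs=1e-9)
            count += 1
        assert count == 25  # 25 DAGs on 3 labelled nodes


class TestScoreDelta:
    def test_matches_full_rescore_for_all_legal_moves(self, rng):
        for _ in range(15):
            ds = random_dataset(rng, list("abcdef"), n=100)
            g = random_dag(rng, ds.columns, p_edge=0.4)
            base = graph_score(ds, g)
            cache = ScoreCache()
            for move in legal_moves(g):
                h = g.copy()
                from dagclimb.dag import apply_move

                apply_move(h, move)
                assert score_delta(ds, g, move, cache) == pytest.approx(
                    graph_score(ds, h) - base, abs=1e-9
                )

    def test_remove_then_add_deltas_cancel(self, rng):
        ds = random_dataset(rng, list("abc"), n=100)
        g = DirectedGraph(ds.columns, [("a", "b")])
        d_rm = score_delta(ds, g, EdgeMove("remove", ("a", "b")))
        g2 = DirectedGraph(ds.columns)
        d_add = score_delta(ds, g2, EdgeMove("add", ("a", "b")))
        assert d_rm + d_add == pytest.approx(0.0, abs=1e-9)

    def test_illegal_move_rejected(self, rng):
        ds = random_dataset(rng, list("abc"), n=100)
        g = DirectedGraph(ds.columns, [("a", "b"), ("b", "c")])
        with pytest.raises(ValueError):
            score_delta(ds, g, EdgeMove("add", ("c", "a")))
        with pytest.raises(ValueError):
            score_delta(ds, g, EdgeMove("remove", ("c", "a")))
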