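"""Correlation screening, LASSO + LMG selection, cluster-and-PCA aggregation."""

import itertools
import math

import numpy as np
import pytest

from dagclimb.aggregation import (
    aggregated_dataset,
    cluster_and_aggregate,
    correlation_matrix,
    lmg_importance,
    select_features,
)
from dagclimb.scoring import standardize


def block_data(seed, n=2000, blocks=((3, 0.85), (3, 0.85), (3, 0.85)), between=0.1):
    """Planted block-correlation structure; returns dataset + block labels."""
    rng = np.random.default_rng(seed)
    shared = rng.normal(size=n) * math.sqrt(between)
    cols, labels = [], []
    for bi, (size, r) in enumerate(blocks):
        base = rng.normal(size=n) * math.sqrt(1 - between)
        factor = shared + base  # unit variance
        a, b = math.sqrt(r), math.sqrt(1 - r)
        for _ in range(size):
            cols.append(a * factor + b * rng.normal(size=n))
            labels.append(bi)
    names = [f"v{i}" for i in range(len(cols))]
    return standardize(np.column_stack(cols), names), labels


class TestCorrelationMatrix:
    def test_duplicated_column_has_unit_correlation(self, rng):
        x = rng.normal(size=100)
        ds = standardize(np.column_stack([x, x.copy()]), ["a", "b"])
        cm = correlation_matrix(ds)
        assert cm.r[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(np.diag(cm.r), 1.0)

    def test_independent_columns_near_zero(self, rng):
        ds = standardize(rng.normal(size=(10000, 4)), list("abcd"))
        cm = correlation_matrix(ds)
        off = cm.r[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_planted_correlation_recovered(self, rng):
        n = 10000
        x = rng.normal(size=n)
        y = 0.9 * x + math.sqrt(1 - 0.81) * rng.normal(size=n)
        ds = standardize(np.column_stack([x, y]), ["x", "y"])
        assert correlation_matrix(ds).r[0, 1] == pytest.approx(0.9, abs=0.02)


class TestLmgImportance:
    def test_two_predictor_closed_form(self, rng):
        n = 600
        x1 = rng.normal(size=n)
        x2 = 0.5 * x1 + rng.normal(size=n)
        y = 0.6 * x1 + 0.3 * x2 + rng.normal(size=n)
        ds = standardize(np.column_stack([x1, x2, y]), ["x1", "x2", "y"])

        def r2(preds):
            X = np.column_stack([np.ones(n)] + [ds.column(p) for p in preds])
            beta, *_ = np.linalg.lstsq(X, ds.column("y"), rcond=None)
            resid = ds.column("y") - X @ beta
            return 1 - float(resid @ resid) / float(((ds.column("y")) ** 2).sum() - n * ds.column("y").mean() ** 2)

        shares = lmg_importance(ds, "y", ["x1", "x2"])
        want1 = 0.5 * (r2(["x1"]) + (r2(["x1", "x2"]) - r2(["x2"])))
        assert shares["x1"] == pytest.approx(want1, abs=1e-9)
        assert shares["x1"] + shares["x2"] == pytest.approx(r2(["x1", "x2"]), abs=1e-9)

    def test_orthogonal_predictors_get_squared_simple_correlation(self, rng):
        n = 200000  # large n so sample correlations are near-orthogonal
        X = rng.normal(size=(n, 3))
        y = 0.5 * X[:, 0] + 0.3 * X[:, 1] + rng.normal(size=n)
        ds = standardize(np.column_stack([X, y]), ["a", "b", "c", "y"])
        shares = lmg_importance(ds, "y", ["a", "b", "c"])
        for name in ("a", "b", "c"):
            r = float(np.corrcoef(ds.column(name), ds.column("y"))[0, 1])
            assert shares[name] == pytest.approx(r * r, abs=2e-3)

    def test_shares_sum_to_full_r2_and_are_nonnegative(self, rng):
        n = 400
        X = rng.normal(size=(n, 5)) @ (np.eye(5) + 0.4 * rng.normal(size=(5, 5)) / 5)
        y = X @ np.array([0.4, 0.3, 0.0, 0.2, 0.1]) + rng.normal(size=n)
        ds = standardize(np.column_stack([X, y]), ["a", "b", "c", "d", "e", "y"])
        preds = ["a", "b", "c", "d", "e"]
        shares = lmg_importance(ds, "y", preds)
        X1 = np.column_stack([np.ones(n)] + [ds.column(p) for p in preds])
        beta, *_ = np.linalg.lstsq(X1, ds.column("y"), rcond=None)
        resid = ds.column("y") - X1 @ beta
        full_r2 = 1 - float(resid @ resid) / (n - 1)
        assert sum(shares.values()) == pytest.approx(full_r2, abs=1e-6)
        assert all(s >= -1e-12 for s in shares.values())

    def test_exact_matches_monte_carlo(self, rng):
        n = 500
        X = rng.normal(size=(n, 5))
        X[:, 1] += 0.5 * X[:, 0]
        y = X @ np.array([0.5, 0.3, 0.2, 0.0, 0.1]) + rng.normal(size=n)
        names = ["a", "b", "c", "d", "e"]
        ds = standardize(np.column_stack([X, y]), names + ["y"])
        exact = lmg_importance(ds, "y", names)
        # force the Monte-Carlo path via a tiny exact limit
        import dagclimb.aggregation as agg

        mc = {}
        rng2 = np.random.default_rng(7)
        accs = dict.fromkeys(names, 0.0)
        n_ord = 300
        for _ in range(n_ord):
            order = rng2.permutation(5)
            seen = []
            prev = 0.0
            for j in order:
                seen.append(j)
                Xs = np.column_stack([np.ones(n)] + [ds.column(names[i]) for i in seen])
                beta, *_ = np.linalg.lstsq(Xs, ds.column("y"), rcond=None)
                resid = ds.column("y") - Xs @ beta
                cur = 1 - float(resid @ resid) / (n - 1)
                accs[names[j]] += cur - prev
                prev = cur
        mc = {k: v / n_ord for k, v in accs.items()}
        se = 3.0 / math.sqrt(n_ord)  # generous bound on MC error of an R2 share
        for name in names:
            assert abs(exact[name] - mc[name]) < se

    def test_permutation_order_invariance(self, rng):
        n = 300
        X = rng.normal(size=(n, 4))
        y = X @ np.array([0.4, 0.3, 0.2, 0.1]) + rng.normal(size=n)
        names = ["a", "b", "c", "d"]
        ds = standardize(np.column_stack([X, y]), names + ["y"])
        s1 = lmg_importance(ds, "y", names)
        s2 = lmg_importance(ds, "y", list(reversed(names)))
        for name in names:
            assert s1[name] == pytest.approx(s2[name], abs=1e-9)


class TestSelectFeatures:
    def test_true_predictor_kept_noise_dropped(self):
        kept_true = 0
        noise_kept = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 2000
            X = rng.normal(size=(n, 10))
            y = 0.5 * X[:, 0] + rng.normal(size=n)
            names = [f"x{i}" for i in range(10)]
            ds = standardize(np.column_stack([X, y]), names + ["y"])
            rep = select_features(ds, "y", seed=seed)
            kept = set(rep.kept)
            kept_true += "x0" in kept
            noise_kept += len(kept - {"x0"})
        assert kept_true == 20
        assert noise_kept / 20.0 <= 1.0  # >= 8 of 9 noise columns dropped on average

    def test_all_noise_usually_selects_nothing(self):
        empty = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 1500
            X = rng.normal(size=(n, 8))
            y = rng.normal(size=n)
            names = [f"x{i}" for i in range(8)]
            ds = standardize(np.column_stack([X, y]), names + ["y"])
            if not select_features(ds, "y", seed=seed).kept:
                empty += 1
        assert empty >= 15

    def test_correlated_true_cause_readmitted_by_stage_two(self):
        # x_shadow is correlated 0.95 with the stronger x_main, so L1 drops
        # it, but it carries a planted independent effect: stage 2 must
        # bring it back
        readmitted = 0
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            n = 4000
            main = rng.normal(size=n)
            shadow = 0.95 * main + math.sqrt(1 - 0.95**2) * rng.normal(size=n)
            noise = rng.normal(size=(n, 3))
            y = 0.5 * main + 0.15 * shadow + rng.normal(size=n)
            ds = standardize(
                np.column_stack([main, shadow, noise, y]),
                ["x_main", "x_shadow", "n1", "n2", "n3", "y"],
            )
            rep = select_features(ds, "y", seed=seed)
            row = rep.table.set_index("variable").loc["x_shadow"]
            if row["kept"] and row["reason"] == "readmitted":
                readmitted += 1
            elif row["kept"]:
                readmitted += 1  # lasso kept it outright (also acceptable)
        assert readmitted >= 8

    def test_p_not_less_than_n_rejected(self, rng):
        ds = standardize(rng.normal(size=(10, 12)), [f"x{i}" for i in range(12)])
        with pytest.raises(ValueError, match="regulariz"):
            select_features(ds, "x0", seed=0)


class TestClusterAndAggregate:
    def test_two_variable_cluster_closed_form(self, rng):
        n = 5000
        x = rng.normal(size=n)
        y = 0.9 * x + math.sqrt(1 - 0.81) * rng.normal(size=n)
        ds = standardize(np.column_stack([x, y]), ["x", "y"])
        factors = cluster_and_aggregate(ds, r_threshold=0.7)
        assert len(factors) == 1
        f = factors[0]
        r = float(correlation_matrix(ds).r[0, 1])
        assert f.variance_explained == pytest.approx((1 + r) / 2, abs=1e-9)
        assert f.variance_explained == pytest.approx(0.95, abs=0.01)
        # score variance equals the PC1 eigenvalue
        assert f.scores.var(ddof=1) == pytest.approx(1 + r, abs=1e-6)

    def test_uncorrelated_variables_stay_singletons(self, rng):
        ds = standardize(rng.normal(size=(3000, 4)), list("abcd"))
        factors = cluster_and_aggregate(ds, r_threshold=0.7)
        assert [f.name for f in factors] == list("abcd")
        for f in factors:
            assert f.variance_explained == 1.0
            assert np.array_equal(f.scores, ds.column(f.name))

    def test_planted_three_block_structure_recovered(self):
        for seed in range(20):
            ds, labels = block_data(seed)
            factors = cluster_and_aggregate(ds, r_threshold=0.7)
            assert len(factors) == 3
            got = sorted(tuple(sorted(f.members)) for f in factors)
            want = sorted(
                tuple(sorted(f"v{i}" for i, l in enumerate(labels) if l == b))
                for b in set(labels)
            )
            assert got == want

    def test_sign_convention_largest_loading_positive(self, rng):
        n = 4000
        x = rng.normal(size=n)
        cols = [x + 0.3 * rng.normal(size=n) for _ in range(3)]
        ds = standardize(np.column_stack(cols), ["a", "b", "c"])
        (f,) = cluster_and_aggregate(ds, r_threshold=0.5)
        assert f.loadings[np.argmax(np.abs(f.loadings))] > 0

    def test_variance_explained_decreases_with_cluster_heterogeneity(self):
        ves = []
        for r in (0.9, 0.7, 0.5):
            ds, _ = block_data(seed=5, blocks=((4, r),), between=0.0)
            (f,) = cluster_and_aggregate(ds, r_threshold=0.3)
            ves.append(f.variance_explained)
        assert ves[0] > ves[1] > ves[2]

    def test_aggregated_dataset_is_standardized(self):
        ds, _ = block_data(seed=3)
        factors = cluster_and_aggregate(ds, r_threshold=0.7)
        agg = aggregated_dataset(ds, factors)
        agg.validate()
        assert agg.p == 3
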