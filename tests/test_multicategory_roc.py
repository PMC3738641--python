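import itertools
import math

import numpy as np
import pytest

import synoclass as sc
from synoclass.multicategory_roc import posterior_severity_scores


def enumeration_hum(values_by_class, class_order):
    """Tuple-enumeration oracle with explicit tie-credit counting.

    For each cross-class tuple: zero credit unless non-decreasing in class
    order; otherwise 1/K where K is the number of position permutations
    that sort the tuple (counted by brute force over all M! permutations).
    """
    arrays = [list(values_by_class[c]) for c in class_order]
    m = len(arrays)
    total = 0.0
    count = 0
    for tup in itertools.product(*arrays):
        count += 1
        if any(tup[i + 1] < tup[i] for i in range(m - 1)):
            continue
        k = sum(
            1
            for perm in itertools.permutations(range(m))
            if all(tup[perm[i]] <= tup[perm[i + 1]] for i in range(m - 1))
        )
        total += 1.0 / k
    return total / count


def random_small_instance(rng):
    n_classes = int(rng.integers(3, 5))
    order = [f"c{i}" for i in range(n_classes)]
    vbc = {}
    while True:
        sizes = rng.integers(1, 6, n_classes)
        if np.prod(sizes) <= 500:
            break
    for c, n in zip(order, sizes):
        if rng.random() < 0.5:
            vbc[c] = rng.integers(0, 4, n).astype(float)  # force ties
        else:
            vbc[c] = rng.normal(0, 1, n)
    return vbc, order


class TestHumNull:
    @pytest.mark.parametrize("m, expected", [(2, 0.5), (3, 1 / 6), (6, 1 / 720)])
    def test_one_over_m_factorial(self, m, expected):
        assert sc.hum_null(m) == pytest.approx(expected)

    def test_six_class_null_prints_as_0014(self):
        assert round(sc.hum_null(6), 4) == 0.0014

    def test_fewer_than_two_classes_rejected(self):
        with pytest.raises(ValueError):
            sc.hum_null(1)


class TestHumSingle:
    def test_two_classes_reduce_to_auc(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            lo = rng.integers(0, 5, rng.integers(2, 8)).astype(float)
            hi = rng.integers(0, 5, rng.integers(2, 8)).astype(float)
            res = sc.hum_single({"lo": lo, "hi": hi}, ["lo", "hi"])
            assert res.hum == pytest.approx(sc.auc(hi, lo), abs=1e-12)

    def test_three_class_toy(self):
        res = sc.hum_single({"A": [1, 2], "B": [3], "C": [2.5, 5]}, ["A", "B", "C"])
        assert res.hum == 0.5
        assert res.estimator == "exhaustive"
        assert res.tuples == 4

    def test_constant_marker_scores_exactly_the_null(self):
        vbc = {g: [7.0, 7.0] for g in sc.GROUPS}
        res = sc.hum_single(vbc)
        assert res.hum == pytest.approx(1 / 720, abs=1e-15)
        assert res.null_hum == pytest.approx(1 / 720)

    @pytest.mark.parametrize("seed", range(15))
    def test_exhaustive_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vbc, order = random_small_instance(rng)
        res = sc.hum_single(vbc, order)
        assert res.estimator == "exhaustive"
        assert res.hum == pytest.approx(enumeration_hum(vbc, order), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        vbc = {g: rng.lognormal(sc.SEVERITY_RANK[g] * 0.3, 1, 5) for g in sc.GROUPS}
        base = sc.hum_single(vbc).hum
        for f in (np.log, np.sqrt, lambda x: 3 * x + 2):
            transformed = {g: f(np.asarray(v)) for g, v in vbc.items()}
            assert sc.hum_single(transformed).hum == pytest.approx(base, abs=1e-12)

    def test_monte_carlo_agrees_with_exhaustive(self):
        rng = np.random.default_rng(6)
        vbc = {g: rng.normal(sc.SEVERITY_RANK[g], 2, 10) for g in sc.GROUPS}
        exact = sc.hum_single(vbc)
        mc = sc.hum_single(vbc, max_tuples=10, seed=17, mc_tuples=200_000)
        assert mc.estimator == "monte_carlo"
        se = math.sqrt(max(exact.hum * (1 - exact.hum), 1e-12) / mc.tuples)
        assert abs(mc.hum - exact.hum) < 3 * se + 1e-9

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            sc.hum_single({"a": [1.0], "b": []}, ["a", "b"])

    def test_default_class_order_is_severity(self):
        vbc = {g: [float(sc.SEVERITY_RANK[g])] for g in sc.GROUPS}
        res = sc.hum_single(vbc)
        assert res.class_order == sc.GROUPS
        assert res.hum == 1.0  # perfectly ordered singleton classes


class TestHumCombined:
    def test_perfect_separation_on_tic_alone(self):
        order = ["a", "b", "c"]
        marker = {c: [1.0, 1.0, 1.0, 1.0] for c in order}  # uninformative
        tic = {c: [10.0 * (i + 1) + j for j in range(4)]
               for i, c in enumerate(order)}
        res = sc.hum_combined(marker, tic, order)
        assert res.hum == 1.0

    def test_duplicated_tic_matches_single_tic(self):
        """A duplicated feature adds no information: with a monotone
        reduction rule the combined HUM equals the single-feature HUM
        exactly, and the default posterior reduction is symmetric in the
        two (identical) columns."""
        rng = np.random.default_rng(7)
        order = list(sc.GROUPS)
        tic = {g: rng.normal(sc.SEVERITY_RANK[g] * 2.0, 1.0, 6) for g in order}
        single = sc.hum_single(tic, order).hum
        monotone = sc.hum_combined(
            tic, tic, order, reducer=lambda X, y, co: X[:, 0]
        ).hum
        assert monotone == pytest.approx(single, abs=1e-12)
        # default posterior reduction: invariant under swapping the columns
        a = sc.hum_combined(tic, tic, order).hum
        swapped = sc.hum_combined(
            tic, tic, order,
            reducer=lambda X, y, co: posterior_severity_scores(
                X[:, ::-1], y, co
            ),
        ).hum
        assert a == pytest.approx(swapped, abs=1e-12)

    def test_scores_match_brute_force_posterior_oracle(self):
        """LOO Gaussian posterior scoring recomputed with explicit loops."""
        rng = np.random.default_rng(8)
        order = ["a", "b", "c"]
        X, y = [], []
        for i, c in enumerate(order):
            for _ in range(4):
                X.append([rng.normal(i, 1), rng.normal(2 * i, 1)])
                y.append(c)
        X = np.array(X)
        y = np.array(y)
        got = posterior_severity_scores(X, y, order)
        for i in range(len(y)):
            Xt = np.delete(X, i, axis=0)
            yt = np.delete(y, i)
            span = Xt.max(axis=0) - Xt.min(axis=0)
            floor = 1e-9 * span**2 + 1e-12
            logps = []
            for c in order:
                sel = yt == c
                mu = Xt[sel].mean(axis=0)
                var = np.maximum(Xt[sel].var(axis=0), floor)
                ll = math.log(sel.sum() / len(yt))
                for j in range(2):
                    ll += -0.5 * (
                        math.log(2 * math.pi * var[j])
                        + (X[i, j] - mu[j]) ** 2 / var[j]
                    )
                logps.append(ll)
            w = np.exp(np.array(logps) - max(logps))
            w /= w.sum()
            expected = sum((k + 1) * w[k] for k in range(3))
            assert got[i] == pytest.approx(expected, rel=1e-9)

    def test_mismatched_classes_rejected(self):
        with pytest.raises(ValueError):
            sc.hum_combined({"a": [1.0]}, {"b": [1.0]}, ["a"])


class TestRanking:
    def test_descending_with_null_row_last(self):
        results = [
            sc.HumResult(("CD68",), sc.GROUPS, 0.1, 1 / 720, "exhaustive", 10),
            sc.HumResult(("TIC",), sc.GROUPS, 0.2, 1 / 720, "exhaustive", 10),
        ]
        table = sc.rank_features(results)
        assert list(table["feature"]) == ["TIC", "CD68", "null hypothesis"]
        assert table["hum"].iloc[-1] == pytest.approx(1 / 720)

    def test_equal_hums_break_lexicographically(self):
        results = [
            sc.HumResult(("CD68",), sc.GROUPS, 0.1, 1 / 720, "exhaustive", 10),
            sc.HumResult(("CD15",), sc.GROUPS, 0.1, 1 / 720, "exhaustive", 10),
        ]
        table = sc.rank_features(results)
        assert list(table["feature"])[:2] == ["CD15", "CD68"]

    def test_tic_ranks_first_on_default_cohort(self, small_profiles):
        """TIC dominates every single marker in simultaneous six-class
        discrimination under the default simulation regime."""
        table = sc.rank_features(sc.run_hum(small_profiles, "singles", seed=3))
        assert table["feature"].iloc[0] == "TIC"
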