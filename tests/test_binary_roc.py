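import numpy as np
import pandas as pd
import pytest

import synoclass as sc
from synoclass.binary_roc import OUTLIER_THRESHOLD, delong_variance, reversal_cluster


def brute_force_auc(pos, neg):
    """Pair-counting oracle: wins + half-ties over all pairs."""
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def random_instance(rng):
    n1, n2 = rng.integers(1, 21, size=2)
    if rng.random() < 0.5:  # discretise to force ties
        pos = rng.integers(0, 6, n1).astype(float)
        neg = rng.integers(0, 6, n2).astype(float)
    else:
        pos = rng.normal(1, 1, n1)
        neg = rng.normal(0, 1, n2)
    return pos, neg


class TestAuc:
    def test_fully_separated(self):
        assert sc.auc([5, 6, 7], [1, 2]) == 1.0

    def test_small_example(self):
        assert sc.auc([3, 5], [1, 4]) == 0.75

    def test_all_tied(self):
        assert sc.auc([2, 2], [2, 2, 2]) == 0.5

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pos, neg = random_instance(rng)
        assert sc.auc(pos, neg) == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_complement_identity(self, seed):
        rng = np.random.default_rng(seed)
        pos, neg = random_instance(rng)
        assert sc.auc(pos, neg) + sc.auc(neg, pos) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_consistent_with_u_statistic(self, seed):
        rng = np.random.default_rng(100 + seed)
        pos, neg = random_instance(rng)
        u, _ = sc.mann_whitney_u(pos, neg)
        assert sc.auc(pos, neg) == pytest.approx(u / (len(pos) * len(neg)))

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            sc.auc([], [1.0])


class TestCorrectAuc:
    @pytest.mark.parametrize(
        "raw, corrected, reversed_", [(0.30, 0.70, True), (0.50, 0.50, False),
                                      (0.01, 0.99, True), (0.75, 0.75, False)]
    )
    def test_correction_rule(self, raw, corrected, reversed_):
        got, rev = sc.correct_auc(raw)
        assert got == pytest.approx(corrected)
        assert rev is reversed_

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sc.correct_auc(1.2)


class TestInference:
    def test_delong_matches_structural_component_oracle(self):
        rng = np.random.default_rng(8)
        pos = rng.normal(1, 1, 12)
        neg = rng.normal(0, 1, 9)
        # explicit double-loop structural components
        m, n = len(pos), len(neg)
        psi = np.array(
            [[1.0 if p > q else (0.5 if p == q else 0.0) for q in neg] for p in pos]
        )
        v10 = psi.mean(axis=1)
        v01 = psi.mean(axis=0)
        expected = v10.var(ddof=1) / m + v01.var(ddof=1) / n
        assert delong_variance(pos, neg) == pytest.approx(expected, rel=1e-12)

    def test_identical_distributions_ci_straddles_half(self):
        rng = np.random.default_rng(9)
        inf = sc.auc_inference(rng.normal(size=100), rng.normal(size=100))
        assert inf.ci[0] < 0.5 < inf.ci[1]
        assert inf.p > 0.05
        assert inf.method == "delong"

    def test_perfect_separation_uses_bootstrap_and_rejects(self):
        pos = np.arange(10) + 100.0
        neg = np.arange(10) * 1.0
        inf = sc.auc_inference(pos, neg, seed=3)
        assert inf.method == "bootstrap"
        assert inf.ci[0] > 0.5
        assert inf.p < 0.01

    def test_bootstrap_deterministic_under_seed(self):
        pos = np.arange(10) + 100.0
        neg = np.arange(10) * 1.0
        a = sc.auc_inference(pos, neg, seed=3)
        b = sc.auc_inference(pos, neg, seed=3)
        assert a == b

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            sc.auc_inference([1.0], [2.0, 3.0])


@pytest.fixture(scope="module")
def fixture():
    return sc.load_table2_fixture()


@pytest.fixture(scope="module")
def tables():
    fx = sc.load_table2_fixture()
    return (fx[fx["method"] == "absolute"].copy(),
            fx[fx["method"] == "relative"].copy())


@pytest.fixture(scope="module")
def roc_tables(small_profiles):
    return {
        m: sc.run_binary_roc(small_profiles, m, seed=7)
        for m in ("absolute", "relative", "tic")
    }


class TestPublishedAucGrid:

    def test_grid_shape_and_significance_tallies(self, fixture):
        assert len(fixture) == 165  # 15 pairs x (5x2 markers + TIC)
        sig = fixture.groupby("method")["significant"].sum()
        assert sig["absolute"] == 50
        assert sig["relative"] == 29

    @pytest.mark.parametrize(
        "scope, method, expected",
        [("CD15", "absolute", 0.96), ("CD68", "absolute", 0.97),
         ("CD3", "absolute", 0.93), ("CD20", "absolute", 0.77),
         ("CD38", "absolute", 0.90), ("CD15", "relative", 0.74),
         ("CD68", "relative", 0.82), ("CD3", "relative", 0.63),
         ("CD20", "relative", 0.69), ("CD38", "relative", 0.82),
         ("TIC", "tic", 0.99), ("all", "absolute", 0.90),
         ("all", "relative", 0.72)],
    )
    def test_median_corrected_auc_reproduces_summary_table(
        self, fixture, scope, method, expected
    ):
        sub = fixture[fixture["method"] == method]
        assert sc.median_corrected_auc(sub, scope) == pytest.approx(expected)

    def test_single_result_median_is_itself(self):
        df = pd.DataFrame({"marker": ["CD15"], "corrected_auc": [0.87]})
        assert sc.median_corrected_auc(df, "all") == 0.87


class TestDifferenceAnalysis:

    def test_known_outlier_from_published_grid(self, tables):
        """CD15 at RA vs Orth.A: 0.98 - 0.58 = 0.40, above the 0.17
        threshold."""
        diffs, summary = sc.auc_difference_analysis(*tables)
        row = diffs[(diffs["marker"] == "CD15") & (diffs["pair"] == "RA:Orth.A")]
        assert row["difference"].iloc[0] == pytest.approx(0.40)
        assert bool(row["outlier"].iloc[0])
        assert summary["n"] == 75
        below_band = int((diffs["difference"] < -0.07 - 1e-9).sum())
        assert summary["n_outliers"] == summary["n"] - summary["n_in_band"] - below_band

    def test_equal_aucs_not_outlier(self):
        a = pd.DataFrame({"marker": ["CD15"], "pair": ["RA:OA"],
                          "corrected_auc": [0.8]})
        diffs, _ = sc.auc_difference_analysis(a, a.copy())
        assert diffs["difference"].iloc[0] == 0.0
        assert not diffs["outlier"].iloc[0]

    def test_threshold_is_strict(self):
        a = pd.DataFrame({"marker": ["CD15"], "pair": ["RA:OA"],
                          "corrected_auc": [0.87]})
        b = a.assign(corrected_auc=[0.87 - OUTLIER_THRESHOLD])
        diffs, _ = sc.auc_difference_analysis(a, b)
        assert diffs["difference"].iloc[0] == pytest.approx(0.17)
        assert not diffs["outlier"].iloc[0]
        assert diffs["in_band"].iloc[0]

    def test_key_mismatch_rejected(self, tables):
        a, r = tables
        with pytest.raises(ValueError, match="keys"):
            sc.auc_difference_analysis(a, r.iloc[:-1])


class TestCohortRoc:

    def test_family_sizes(self, roc_tables):
        assert len(roc_tables["absolute"]) == 75
        assert len(roc_tables["relative"]) == 75
        assert len(roc_tables["tic"]) == 15

    def test_corrected_auc_consistent_with_raw(self, roc_tables):
        for df in roc_tables.values():
            for row in df.itertuples():
                corr, rev = sc.correct_auc(row.raw_auc)
                assert row.corrected_auc == pytest.approx(corr)
                assert row.reversed == rev
                assert 0.5 <= row.corrected_auc <= 1.0

    def test_significance_requires_ci_and_fdr(self, roc_tables):
        for df in roc_tables.values():
            sig = df[df["significant"]]
            assert ((sig["ci_lo"] > 0.5) | (sig["ci_hi"] < 0.5)).all()
            assert (sig["p_fdr"] < 0.05).all()

    def test_reversal_cluster_subset_of_reversed(self, roc_tables):
        cluster = reversal_cluster(roc_tables["relative"])
        assert cluster["reversed"].all()
        assert cluster["significant"].all()

    def test_missing_group_skips_its_pairs(self, small_cohort):
        frame = small_cohort.frame
        partial = sc.Cohort(frame[frame["group"] != "EA"].copy())
        profiles = sc.profile_cohort(partial)
        out = sc.run_binary_roc(profiles, "absolute", seed=1)
        assert len(out) == 5 * 10  # 5 groups -> 10 ordered pairs
        assert not out["pair"].str.contains("EA").any()
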