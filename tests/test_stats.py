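"""Statistical primitives against hand-derived and brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from udrpanel import (
    cohort_summary,
    estimate_dispersion,
    exact_nb_test,
    mann_whitney,
    qpcr_fold_change,
    roc_auc,
)
from udrpanel.samples import SampleMeta


# ---------------------------------------------------------------------------
# rank-sum
# ---------------------------------------------------------------------------

def ranksum_enumeration_p(x, y) -> tuple[float, float]:
    """Brute-force two-sided exact rank-sum p: enumerate every assignment of
    the pooled (untied) values to groups and double the extreme-tail mass."""
    pooled = sorted(list(x) + list(y))
    n1 = len(x)

    def u_stat(group1):
        return sum(1 for a in group1 for b in pooled if b not in group1 and a > b)

    # multiset-free because values are untied
    u_obs = sum(1 for a in x for b in y if a > b)
    u_max = max(u_obs, n1 * (len(pooled) - n1) - u_obs)
    dist = [u_stat(list(c)) for c in itertools.combinations(pooled, n1)]
    p = 2.0 * sum(1 for u in dist if u >= u_max) / len(dist)
    return float(u_obs), min(1.0, p)


class TestMannWhitney:
    @pytest.mark.parametrize(
        "x, y, u_expected, p_expected",
        [
            ([1, 2], [3, 4], 0.0, 1 / 3),   # most extreme of C(4,2)=6 splits
            ([1, 3], [2, 4], 1.0, 2 / 3),
        ],
    )
    def test_small_sample_exact_enumeration(self, x, y, u_expected, p_expected):
        u, p = mann_whitney(x, y)
        assert u == u_expected
        assert p == pytest.approx(p_expected, abs=1e-12)

    def test_identical_groups_are_symmetric(self):
        x = [1.0, 2.0, 5.0, 9.0]
        u, p = mann_whitney(x, x)
        assert u == len(x) ** 2 / 2
        assert p == pytest.approx(1.0, abs=0.05)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])
        with pytest.raises(ValueError):
            mann_whitney([np.nan], [1.0])

    @given(
        st.lists(st.integers(0, 10_000), min_size=2, max_size=4, unique=True),
        st.lists(st.integers(10_001, 20_000), min_size=2, max_size=4, unique=True),
        st.randoms(use_true_random=False),
    )
    def test_exact_branch_matches_full_enumeration(self, lo, hi, rnd):
        # interleave the two untied value pools randomly across groups
        pooled = [float(v) for v in lo + hi]
        rnd.shuffle(pooled)
        x, y = pooled[: len(lo)], pooled[len(lo):]
        u, p = mann_whitney(x, y)
        u_ref, p_ref = ranksum_enumeration_p(x, y)
        assert u == u_ref
        assert p == pytest.approx(p_ref, abs=1e-9)


# ---------------------------------------------------------------------------
# exact conditional NB test
# ---------------------------------------------------------------------------

class TestExactNb:
    def test_one_sided_extreme_is_doubled_binomial_tail(self):
        # 5 vs 0 counts, equal libsizes, Poisson limit: p = 2 * (1/2)**5
        res = exact_nb_test([5], [0], [100], [100], dispersion=0.0)
        assert res.p_value == pytest.approx(0.0625, abs=1e-12)
        assert not res.flat

    @pytest.mark.parametrize("dispersion", [0.0, 0.3])
    def test_identical_groups_give_p_one(self, dispersion):
        res = exact_nb_test([3, 3], [3, 3], [100, 100], [100, 100], dispersion)
        assert res.p_value == 1.0

    def test_equal_proportions_with_unequal_libsizes(self):
        res = exact_nb_test([3, 3], [3, 3], [50, 150], [150, 50], dispersion=0.0)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_feature_flags_flat(self):
        res = exact_nb_test([0, 0], [0, 0], [10, 10], [10, 10], 0.1)
        assert res.flat and res.p_value == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            exact_nb_test([-1], [0], [10], [10])

    def test_large_totals_match_enumeration_through_normal_limit(self):
        # same data evaluated exactly and via the large-total approximation
        from udrpanel import stats as statsmod

        counts1, counts2 = [5200, 4900], [5050, 5020]
        libs = [100_000, 100_000]
        exact = exact_nb_test(counts1, counts2, libs, libs, dispersion=0.05)
        original = statsmod.EXACT_NB_MAX_TOTAL
        statsmod.EXACT_NB_MAX_TOTAL = 10
        try:
            approx = exact_nb_test(counts1, counts2, libs, libs, dispersion=0.05)
        finally:
            statsmod.EXACT_NB_MAX_TOTAL = original
        assert approx.p_value == pytest.approx(exact.p_value, rel=0.05)


class TestDispersionEstimation:
    def test_poisson_data_yields_near_zero_common_dispersion(self):
        rng = np.random.default_rng(7)
        libs = np.full(20, 1.0)
        counts = rng.poisson(50.0, size=(2000, 20))
        _, common = estimate_dispersion(counts, libs)
        assert common <= 0.05

    def test_constant_feature_has_zero_dispersion(self):
        phi, _ = estimate_dispersion(np.full((1, 10), 7.0), np.full(10, 1.0))
        assert phi[0] == 0.0

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(11)
        phi_true, mean = 0.4, 100.0
        r = 1 / phi_true
        counts = rng.negative_binomial(r, r / (r + mean), size=(2000, 30))
        _, common = estimate_dispersion(counts, np.full(30, 1.0))
        assert common == pytest.approx(phi_true, abs=0.1)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            estimate_dispersion(np.ones((3, 1)), np.ones(1))


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

class TestRocAuc:
    @pytest.mark.parametrize(
        "case, control, expected",
        [
            ([3, 4], [1, 2], 1.0),      # perfect separation
            ([3, 1], [2, 0], 0.75),     # 3 concordant of 4 pairs
            ([1, 1], [1, 1], 0.5),      # ties only
        ],
    )
    def test_pairwise_concordance_values(self, case, control, expected):
        scores = np.array(case + control, dtype=float)
        labels = np.array([True] * len(case) + [False] * len(control))
        res = roc_auc(scores, labels, n_boot=0)
        assert res.auc == pytest.approx(expected)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        labels[0], labels[1] = True, False  # both classes present
        res = roc_auc(scores, labels, n_boot=0)
        assert tuple(res.points[0]) == (0.0, 0.0)
        assert tuple(res.points[-1]) == (1.0, 1.0)
        assert np.all(np.diff(res.points[:, 0]) >= 0)
        assert np.all(np.diff(res.points[:, 1]) >= 0)

    def test_bootstrap_ci_brackets_auc(self):
        rng = np.random.default_rng(1)
        scores = np.concatenate([rng.normal(1, 1, 30), rng.normal(0, 1, 30)])
        labels = np.array([True] * 30 + [False] * 30)
        res = roc_auc(scores, labels, n_boot=500, seed=5)
        assert 0.0 <= res.ci_low <= res.auc <= res.ci_high <= 1.0

    def test_one_class_missing_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [True, True])

    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=20), st.integers(1, 3))
    def test_score_reversal_flips_auc(self, scores, n_case):
        n_case = min(n_case, len(scores) - 1)
        labels = np.array([True] * n_case + [False] * (len(scores) - n_case))
        fwd = roc_auc(scores, labels, n_boot=0).auc
        rev = roc_auc(-np.asarray(scores), labels, n_boot=0).auc
        assert fwd + rev == pytest.approx(1.0)

    @given(
        st.lists(st.integers(0, 100_000), min_size=5, max_size=30, unique=True),
        st.integers(1, 4),
    )
    def test_auc_equals_normalized_u_without_ties(self, values, n_case):
        n_case = min(n_case, len(values) - 1)
        scores = np.array(values, dtype=float)
        labels = np.array([True] * n_case + [False] * (len(values) - n_case))
        auc = roc_auc(scores, labels, n_boot=0).auc
        u, _ = mann_whitney(scores[labels], scores[~labels])
        assert auc == pytest.approx(u / (n_case * (len(values) - n_case)))


# ---------------------------------------------------------------------------
# qPCR fold change
# ---------------------------------------------------------------------------

class TestQpcrFoldChange:
    def test_upregulated_example(self):
        r = qpcr_fold_change([-2.678], [-4.0])
        assert r.log2_fc == pytest.approx(1.322)
        assert r.fc_linear == pytest.approx(2.5, abs=0.001)
        assert r.direction == "up"

    def test_equal_means_are_flat(self):
        r = qpcr_fold_change([1.0, 3.0], [2.0, 2.0])
        assert r.fc_linear == 1.0 and r.direction == "flat"

    def test_sign_symmetry(self):
        r = qpcr_fold_change([1.0], [2.0])
        assert r.log2_fc == -1.0 and r.fc_linear == 2.0 and r.direction == "down"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            qpcr_fold_change([], [1.0])


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

class TestCohortSummary:
    def test_categorical_percentages_sum_to_100(self, discovery_demographics):
        table = cohort_summary(discovery_demographics)
        for var in ("sex", "smoking", "comorbidity"):
            sub = table[table["variable"] == var]
            for col in ("whole_pct", "benign_pct", "nsclc_pct"):
                assert sub[col].sum() == pytest.approx(100.0, abs=0.1)
        stage = table[table["variable"] == "stage"]
        assert stage["nsclc_pct"].sum() == pytest.approx(100.0, abs=0.1)

    def test_single_benign_sample_degenerates_gracefully(self):
        cohort = [SampleMeta("S1", "benign", "none", 67.0, "male", "yes")]
        table = cohort_summary(cohort)
        male = table[(table["variable"] == "sex") & (table["level"] == "male")].iloc[0]
        assert male["whole_pct"] == 100.0
        assert table["p_value"].dropna().empty

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary([])

    def test_age_p_value_present_for_two_groups(self, validation_demographics):
        table = cohort_summary(validation_demographics)
        age = table[(table["variable"] == "age") & (table["level"] == "mean")].iloc[0]
        assert 0.0 <= age["p_value"] <= 1.0
        assert age["test"] == "mann_whitney"
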