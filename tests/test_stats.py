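"""Spearman correlation, diagnostics, odds ratios, medians."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from memrisk import median_range, sens_spec, spearman, univariate_logistic_or


class TestSpearman:
    def test_identity_is_one(self):
        r = spearman([1, 2, 5, 9], [1, 2, 5, 9])
        assert r.r == pytest.approx(1.0)

    def test_matches_scipy_with_ties(self):
        """Mid-rank Pearson agrees with scipy's tie-corrected rho."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(5, 30)
            x = rng.integers(0, 6, n).astype(float)   # heavy ties
            y = rng.normal(size=n) + x
            if np.ptp(sps.rankdata(x)) == 0:
                continue
            ours = spearman(x, y).r
            ref = sps.spearmanr(x, y).statistic
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_exact_p_matches_enumeration_oracle(self):
        """At n=5 the p-value is the share of the 120 permutations with
        |rho| at least as extreme (oracle recomputed with scipy)."""
        x = [0.3, -1.2, 2.0, 0.7, 1.1]
        y = [10.0, 2.0, 31.0, 14.0, 9.0]
        res = spearman(x, y)
        count = 0
        for perm in itertools.permutations(y):
            r = sps.spearmanr(x, perm).statistic
            if abs(r) >= abs(res.r) - 1e-12:
                count += 1
        assert res.method == "exact"
        assert res.p == pytest.approx(count / 120.0)

    def test_t_approximation_for_larger_n(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=13)
        y = x + rng.normal(size=13)
        res = spearman(x, y)
        assert res.method == "t-approx"
        ref = sps.spearmanr(x, y)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_pairwise_deletion(self):
        x = [1.0, 2.0, None, 4.0, 5.0]
        y = [1.5, 2.5, 3.0, None, 5.5]
        assert spearman(x, y).n == 3

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3 complete pairs"):
            spearman([1, 2, None], [1, 2, 3])

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    @given(
        data=st.lists(
            st.tuples(st.integers(-1000, 1000), st.integers(-1000, 1000)),
            min_size=4,
            max_size=9,
            unique_by=(lambda t: t[0], lambda t: t[1]),
        ),
        scale=st.integers(1, 7),
    )
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_invariant_under_monotone_transform(self, data, scale):
        """r and p depend only on the rank orders, so strictly increasing
        transforms of either variable leave them unchanged."""
        x = [float(d[0]) for d in data]
        y = [float(d[1]) for d in data]
        base = spearman(x, y)
        trans = spearman([scale * v + 2.0 for v in x], [v**3 for v in y])
        assert trans.r == pytest.approx(base.r, abs=1e-12)
        assert trans.p == pytest.approx(base.p, abs=1e-12)


class TestSensSpec:
    def test_confusion_arithmetic(self):
        pred = [True] * 6 + [False] * 2 + [False] * 4 + [True] * 2
        cond = [True] * 6 + [True] * 2 + [False] * 4 + [False] * 2
        d = sens_spec(pred, cond)
        assert (d.tp, d.fn, d.tn, d.fp) == (6, 2, 4, 2)
        assert d.rounded() == (75, 67)
        assert d.n == 14

    def test_perfect_predictor(self):
        d = sens_spec([True, False, True], [True, False, True])
        assert d.sensitivity == 100.0
        assert d.specificity == 100.0

    def test_undefined_metric_marker(self):
        d = sens_spec([True, False], [True, True])   # no condition-negatives
        assert d.specificity is None
        assert d.sensitivity == 50.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        pred = rng.uniform(size=40) < 0.5
        cond = rng.uniform(size=40) < 0.4
        d1 = sens_spec(pred, cond)
        perm = rng.permutation(40)
        d2 = sens_spec(pred[perm], cond[perm])
        assert (d1.tp, d1.fp, d1.tn, d1.fn) == (d2.tp, d2.fp, d2.tn, d2.fn)


class TestLogisticOr:
    def test_binary_predictor_matches_closed_form(self):
        # 2x2 table a=8, b=6, c=5, d=11 -> OR = ad/bc
        x = [1.0] * 14 + [0.0] * 16
        y = [True] * 8 + [False] * 6 + [True] * 5 + [False] * 11
        res = univariate_logistic_or(x, y)
        assert res.estimable
        assert res.odds_ratio == pytest.approx(8 * 11 / (6 * 5), rel=1e-6)
        assert res.ci_low < res.odds_ratio < res.ci_high

    def test_constant_predictor_not_estimable(self):
        res = univariate_logistic_or([2.0] * 10, [True] * 5 + [False] * 5)
        assert not res.estimable
        assert res.odds_ratio is None

    def test_complete_separation_not_estimable(self):
        x = list(range(10))
        y = [v >= 5 for v in x]
        res = univariate_logistic_or(x, y)
        assert not res.estimable

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            univariate_logistic_or([1.0, 2.0, 3.0], [True, True, True])

    def test_study_predictors_all_non_significant(self, study_result):
        ors = study_result["odds_ratios"]
        assert len(ors) >= 6
        for name, res in ors.items():
            if res["estimable"]:
                assert res["p"] >= 0.05, name


class TestMedianRange:
    def test_study_resected_volumes(self, cohort):
        med, lo, hi = median_range([r.resected_volume for r in cohort])
        assert (lo, hi) == (8.0, 47.0)
        assert med == pytest.approx(24.5)  # average-of-middle-two over 14

    def test_study_remaining_hc_volumes(self, cohort):
        med, lo, hi = median_range([r.remaining_hc_volume for r in cohort])
        assert med == pytest.approx(0.2)   # 13 values: one patient missing
        assert (lo, hi) == (0.0, 2.4)

    def test_single_value(self):
        assert median_range([5.0]) == (5.0, 5.0, 5.0)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            median_range([None, None])
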