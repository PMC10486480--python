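import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from nphct import diagnostics, phantom
from nphct.errors import DegenerateInputError, ParameterError


@pytest.fixture(scope="module")
def reference():
    return phantom.reference_score_table()


def brute_force_pair_auc(table, tie_credit):
    """O(n^2) pair-counting oracle over the expanded per-subject scores."""
    scores, labels = table.expand()
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = conc = ties = 0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                conc += 1
            elif p == q:
                ties += 1
    return (conc + (0.5 * ties if tie_credit else 0.0)) / total


class TestConfusionFromGrouped:
    def test_reference_at_cutoff_5(self, reference):
        cm = diagnostics.confusion_from_grouped(reference, cutoff=5)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (81, 2, 110, 24)

    def test_cutoff_zero_calls_everything_positive(self, reference):
        cm = diagnostics.confusion_from_grouped(reference, cutoff=0)
        assert cm.fn == 0 and cm.tn == 0

    def test_cutoff_above_max_calls_everything_negative(self, reference):
        cm = diagnostics.confusion_from_grouped(reference, cutoff=13)
        assert cm.tp == 0 and cm.fp == 0


class TestMetrics:
    def test_reference_radiologist_column(self, reference):
        cm = diagnostics.confusion_from_grouped(reference, cutoff=5)
        pct = diagnostics.metrics(cm).as_percentages()
        assert pct == {
            "sensitivity": 77.14,
            "specificity": 98.21,
            "ppv": 97.59,
            "npv": 82.09,
            "accuracy": 88.02,
        }

    def test_perfect_test(self):
        m = diagnostics.metrics(diagnostics.ConfusionMatrix(1, 0, 1, 0))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.accuracy) == (1, 1, 1, 1, 1)

    def test_undefined_metric_flagged_not_zeroed(self):
        m = diagnostics.metrics(diagnostics.ConfusionMatrix(tp=0, fp=0, tn=5, fn=5))
        assert m.sensitivity == 0.0
        assert m.ppv is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            diagnostics.ConfusionMatrix(-1, 0, 0, 0)


class TestConfusionFromRates:
    def test_reconstructed_comparator_matrix(self):
        cm = diagnostics.confusion_from_rates(0.9905, 0.5714, n_pos=105, n_neg=112)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (104, 48, 64, 1)
        pct = diagnostics.metrics(cm).as_percentages()
        assert pct["ppv"] == 68.42 and pct["npv"] == 98.46 and pct["accuracy"] == 77.42

    def test_perfect_rates(self):
        cm = diagnostics.confusion_from_rates(1.0, 1.0, 10, 10)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (10, 0, 10, 0)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ParameterError):
            diagnostics.confusion_from_rates(1.2, 0.5, 10, 10)


class TestAuc:
    def test_strict_concordance_matches_pair_oracle(self, reference):
        assert diagnostics.auc_strict(reference) == pytest.approx(11215 / 11760)
        assert diagnostics.auc_strict(reference) == pytest.approx(
            brute_force_pair_auc(reference, tie_credit=False)
        )
        assert round(diagnostics.auc_strict(reference), 3) == 0.954

    def test_tie_credit_matches_pair_oracle(self, reference):
        assert diagnostics.auc_tie_credit(reference) == pytest.approx(11366 / 11760)
        assert diagnostics.auc_tie_credit(reference) == pytest.approx(
            brute_force_pair_auc(reference, tie_credit=True)
        )

    def test_fully_separated_groups(self):
        t = phantom.GroupedScoreTable([0, 1, 5, 6], [10, 5, 0, 0], [0, 0, 4, 6])
        assert diagnostics.auc_strict(t) == 1.0
        assert diagnostics.auc_tie_credit(t) == 1.0

    def test_identical_distributions(self):
        t = phantom.GroupedScoreTable([0, 1, 2], [5, 5, 5], [5, 5, 5])
        assert diagnostics.auc_tie_credit(t) == pytest.approx(0.5)
        assert diagnostics.auc_strict(t) < 0.5

    def test_tie_credit_never_below_strict(self, reference):
        assert diagnostics.auc_tie_credit(reference) >= diagnostics.auc_strict(reference)

    def test_empty_group_rejected(self):
        t = phantom.GroupedScoreTable([0, 1], [3, 2], [0, 0])
        with pytest.raises(DegenerateInputError):
            diagnostics.auc_strict(t)


class TestRocPoints:
    def test_endpoints_and_cutoff5(self, reference):
        pts = diagnostics.roc_points(reference)
        assert pts[0] == (1.0, 1.0)
        assert pts[-1] == (0.0, 0.0)
        assert (2 / 112, 81 / 105) in pts

    def test_monotone_staircase(self, reference):
        pts = diagnostics.roc_points(reference)
        fpr = [p[0] for p in pts]
        tpr = [p[1] for p in pts]
        assert fpr == sorted(fpr, reverse=True)
        assert tpr == sorted(tpr, reverse=True)

    def test_trapezoid_equals_tie_credit_auc(self, reference):
        pts = diagnostics.roc_points(reference)
        assert abs(
            diagnostics.trapezoidal_auc(pts) - diagnostics.auc_tie_credit(reference)
        ) < 1e-12


class TestOddsRatio:
    def test_no_association(self):
        or_, lo, hi = diagnostics.odds_ratio(10, 10, 10, 10)
        assert or_ == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_closed_form_oracle(self):
        or_, lo, hi = diagnostics.odds_ratio(20, 5, 5, 20)
        assert or_ == pytest.approx(16.0)
        se = math.sqrt(1 / 20 + 1 / 5 + 1 / 5 + 1 / 20)
        assert lo == pytest.approx(math.exp(math.log(16) - 1.96 * se))
        assert hi == pytest.approx(math.exp(math.log(16) + 1.96 * se))

    def test_zero_cell_yields_finite_estimate(self):
        or_, lo, hi = diagnostics.odds_ratio(5, 0, 3, 7)
        assert np.isfinite([or_, lo, hi]).all() and or_ > 0

    @given(
        a=st.integers(1, 40), b=st.integers(1, 40),
        c=st.integers(1, 40), d=st.integers(1, 40),
    )
    def test_symmetry_properties(self, a, b, c, d):
        or1, _, _ = diagnostics.odds_ratio(a, b, c, d)
        or2, _, _ = diagnostics.odds_ratio(d, c, b, a)  # swap rows and columns
        or3, _, _ = diagnostics.odds_ratio(b, a, d, c)  # swap one margin
        assert or1 == pytest.approx(or2)
        assert or3 == pytest.approx(1 / or1)


class TestChisqTest:
    def test_observed_equal_expected_gives_zero(self):
        stat, df = diagnostics.chisq_test([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0) and df == 1

    def test_diagonal_table_hand_oracle(self):
        # margins 10/10 each way -> every E = 5, sum (O-E)^2/E = 4*25/5 = 20
        stat, df = diagnostics.chisq_test([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0) and df == 1

    def test_degrees_of_freedom_2x3(self):
        _, df = diagnostics.chisq_test([[5, 6, 7], [8, 9, 10]])
        assert df == 2

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateInputError):
            diagnostics.chisq_test([[0, 0], [5, 5]])


class TestDeriveCutoffs:
    def test_reference_cohort_recovers_published_bands(self, reference):
        scores, labels = reference.expand()
        neg, border, pos = diagnostics.derive_cutoffs(scores, labels)
        assert neg == [0, 1, 2]
        assert border == [3, 4]
        assert pos == [5, 6, 7, 8, 9, 10, 11]

    def test_perfectly_separated_scores_monotone(self):
        scores = np.array([0] * 10 + [12] * 10)
        labels = np.array([0] * 10 + [1] * 10)
        neg, border, pos = diagnostics.derive_cutoffs(scores, labels)
        assert 0 in neg and 12 in pos

    def test_probability_nondecreasing_in_score(self, reference):
        scores, labels = reference.expand()
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1e6, max_iter=10_000)
        clf.fit(scores.reshape(-1, 1), labels)
        assert clf.coef_[0][0] >= 0

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            diagnostics.derive_cutoffs(np.array([1, 2, 3]), np.array([1, 1, 1]))
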