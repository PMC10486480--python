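"""Diagnostic-accuracy statistics over grouped ordinal score tables.

Everything here operates on a :class:`~nphct.phantom.GroupedScoreTable`
(counts of normal and diseased subjects per total score) or on explicit 2×2
counts: confusion matrices at a score cut-off, sensitivity/specificity/
PPV/NPV/accuracy, ROC points and AUC, odds ratios and Pearson chi-squared
tests.

Two AUC readings are provided because they genuinely differ on heavily tied
ordinal scores. ``auc_strict`` counts only strictly concordant cross-group
pairs; ``auc_tie_credit`` is the conventional Mann–Whitney statistic giving
half credit to ties and equals the trapezoidal area under the empirical ROC.
On the shipped reference cohort table the two are 0.954 and 0.966
respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InconsistencyError, ParameterError
from .phantom import GroupedScoreTable


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ParameterError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Fractions in [0, 1]; a metric with a zero denominator is None."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float

    def as_percentages(self, ndigits: int = 2) -> dict[str, float | None]:
        """All metrics as percentages rounded to ``ndigits`` decimals."""
        return {
            name: (None if v is None else round(100 * v, ndigits))
            for name, v in vars(self).items()
        }


def confusion_from_grouped(table: GroupedScoreTable, cutoff: int = 5) -> ConfusionMatrix:
    """Confusion matrix calling a subject positive iff total score >= cutoff.

    Subjects below the cutoff (including any borderline band) count as
    test-negative.
    """
    pos = table.scores >= cutoff
    return ConfusionMatrix(
        tp=int(table.n_nph[pos].sum()),
        fn=int(table.n_nph[~pos].sum()),
        fp=int(table.n_normal[pos].sum()),
        tn=int(table.n_normal[~pos].sum()),
    )


def metrics(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy from a 2×2 matrix."""
    if cm.total == 0:
        raise DegenerateInputError("empty confusion matrix")

    def frac(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return DiagnosticMetrics(
        sensitivity=frac(cm.tp, cm.tp + cm.fn),
        specificity=frac(cm.tn, cm.tn + cm.fp),
        ppv=frac(cm.tp, cm.tp + cm.fp),
        npv=frac(cm.tn, cm.tn + cm.fn),
        accuracy=(cm.tp + cm.tn) / cm.total,
    )


def confusion_from_rates(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> ConfusionMatrix:
    """Reconstruct integer confusion counts from rounded published rates.

    tp = round(sens·n_pos) and tn = round(spec·n_neg) with half-away-from-zero
    rounding; the remaining cells follow from the group sizes. Useful for
    recovering the implied 2×2 table of a published operating point.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ParameterError("rates must be fractions in [0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise ParameterError("group sizes must be > 0")

    def round_half_away(x: float) -> int:
        return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))

    tp = round_half_away(sensitivity * n_pos)
    tn = round_half_away(specificity * n_neg)
    fn, fp = n_pos - tp, n_neg - tn
    if min(tp, tn, fn, fp) < 0:
        raise InconsistencyError("rates and group sizes imply negative counts")
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def _pair_counts(table: GroupedScoreTable) -> tuple[int, int, int]:
    """(strictly concordant, tied, total) cross-group pair counts."""
    n0, n1 = table.total_normal, table.total_nph
    if n0 == 0 or n1 == 0:
        raise DegenerateInputError("both groups must be nonempty")
    cum_normal_below = np.concatenate([[0], np.cumsum(table.n_normal)[:-1]])
    concordant = int((table.n_nph * cum_normal_below).sum())
    tied = int((table.n_nph * table.n_normal).sum())
    return concordant, tied, n0 * n1


def auc_strict(table: GroupedScoreTable) -> float:
    """Fraction of cross-group pairs where the NPH score strictly exceeds the
    normal score — concordance with no credit for ties."""
    concordant, _, total = _pair_counts(table)
    return concordant / total


def auc_tie_credit(table: GroupedScoreTable) -> float:
    """Mann–Whitney AUC with half credit for tied pairs; equals the
    trapezoidal area under the empirical ROC."""
    concordant, tied, total = _pair_counts(table)
    return (concordant + 0.5 * tied) / total


def roc_points(table: GroupedScoreTable) -> list[tuple[float, float]]:
    """(1 − specificity, sensitivity) at every integer cutoff.

    Cutoffs run 0 .. max_score + 1, tracing the monotone staircase from
    (1, 1) down to (0, 0); its trapezoidal integral equals
    :func:`auc_tie_credit`.
    """
    n0, n1 = table.total_normal, table.total_nph
    if n0 == 0 or n1 == 0:
        raise DegenerateInputError("both groups must be nonempty")
    pts = []
    for cutoff in range(int(table.scores.min()), int(table.scores.max()) + 2):
        cm = confusion_from_grouped(table, cutoff=cutoff)
        pts.append((cm.fp / n0, cm.tp / n1))
    return pts


def trapezoidal_auc(points: list[tuple[float, float]]) -> float:
    """Trapezoidal integral of an ROC point list (any monotone order)."""
    pts = sorted(points)
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    return float(np.trapezoid(tpr, fpr))


def odds_ratio(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """Odds ratio (a·d)/(b·c) with a Woolf 95% CI for a 2×2 table
    ``[[a, b], [c, d]]``.

    When any cell is zero, the Haldane–Anscombe correction (+0.5 to every
    cell) is applied, so the estimate and CI are always finite.
    """
    if min(a, b, c, d) < 0:
        raise ParameterError("cell counts must be >= 0")
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    se = np.sqrt((1 / cells).sum())
    lo, hi = np.exp(np.log(or_) + np.array([-1.96, 1.96]) * se)
    return float(or_), float(lo), float(hi)


def chisq_test(table: np.ndarray) -> tuple[float, int]:
    """Pearson chi-squared statistic and df for an r×c count table.

    Expected counts come from the margins; zero margins are degenerate.
    """
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateInputError("table has a zero margin")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof)


def derive_cutoffs(
    scores: np.ndarray,
    labels: np.ndarray,
    p_lo: float = 0.25,
    p_hi: float = 0.75,
) -> tuple[list[int], list[int], list[int]]:
    """Derive Negative/Borderline/Positive score bands from a logistic fit.

    Fits a single-predictor logistic regression of disease status on the
    total score, maps every observed integer score to its fitted probability,
    and bands: p < ``p_lo`` → Negative, p > ``p_hi`` → Positive, else
    Borderline. Uses a negligible ridge penalty so perfectly separated inputs
    still yield a (monotone) fit.
    """
    from sklearn.linear_model import LogisticRegression

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise DegenerateInputError("both classes must be present")
    if not 0 < p_lo <= p_hi < 1:
        raise ParameterError("require 0 < p_lo <= p_hi < 1")
    clf = LogisticRegression(C=1e6, solver="lbfgs", tol=1e-8, max_iter=10_000)
    clf.fit(scores.reshape(-1, 1), labels)
    uniq = np.unique(scores).astype(int)
    p = clf.predict_proba(uniq.reshape(-1, 1))[:, 1]
    negative = [int(s) for s, pi in zip(uniq, p) if pi < p_lo]
    positive = [int(s) for s, pi in zip(uniq, p) if pi > p_hi]
    borderline = [int(s) for s in uniq if s not in negative and s not in positive]
    return negative, borderline, positive
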