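"""Feature selection, logistic classification and exact linear attribution.

The classification stage mirrors a standard medical-imaging tabular pipeline:
min–max scaling to [0, 1], chi-squared filter selection of the k strongest
features, and an L2-penalized logistic regression (inverse regularization
strength ``c``) evaluated by stratified k-fold cross-validation with scaling
and selection re-fit inside every training fold (no leakage). For a linear
model the Shapley attribution of a prediction has a closed form,
``w_j * (x_j - mean_j(reference))`` on the scaled logit scale, which is
implemented exactly rather than sampled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .errors import DegenerateInputError, ParameterError


def minmax_scale(
    X: pd.DataFrame, params: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map each column to [0, 1] by (x - min) / (max - min).

    Constant columns map to 0. When ``params`` (a min/max frame from a
    previous call) is given, those bounds are applied instead of refitting,
    so held-out data is scaled with training statistics.
    """
    if not np.isfinite(X.to_numpy(dtype=float)).all():
        raise ParameterError("feature matrix contains non-finite values")
    if params is None:
        params = pd.DataFrame({"min": X.min(axis=0), "max": X.max(axis=0)})
    params = params.loc[X.columns]
    span = (params["max"] - params["min"]).to_numpy()
    safe = np.where(span == 0, 1.0, span)
    scaled = (X.to_numpy(dtype=float) - params["min"].to_numpy()) / safe
    return pd.DataFrame(scaled, index=X.index, columns=X.columns), params


def chi2_scores(X: pd.DataFrame, y: np.ndarray) -> pd.Series:
    """Chi-squared filter score per feature on non-negative inputs.

    For feature j with class-wise sums O_cj and expected sums
    E_cj = (Σ_i x_ij)·(n_c/n), the score is Σ_c (O_cj − E_cj)² / E_cj;
    features whose total sum is zero score 0.
    """
    Xv = X.to_numpy(dtype=float)
    if (Xv < 0).any():
        raise ParameterError("chi2 requires non-negative feature values")
    y = np.asarray(y)
    classes = np.unique(y)
    n = len(y)
    observed = np.vstack([Xv[y == c].sum(axis=0) for c in classes])
    total = Xv.sum(axis=0)
    expected = np.outer([(y == c).sum() / n for c in classes], total)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    return pd.Series(terms.sum(axis=0), index=X.columns)


def select_top_k(scores: pd.Series, k: int = 10) -> list[str]:
    """Names of the k highest-scoring features, descending; ties by name."""
    if k > len(scores):
        raise ParameterError(f"k={k} exceeds the {len(scores)} available features")
    order = sorted(scores.index, key=lambda name: (-scores[name], name))
    return list(order[:k])


@dataclass
class FittedModel:
    """A fitted scaling + selection + logistic pipeline."""

    selected_features: list[str]
    weights: np.ndarray
    intercept: float
    scaling_params: pd.DataFrame  # min/max per *input* feature column
    regularization_c: float = 10.0
    chi2_scores_: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.selected_features):
            raise ParameterError("one weight per selected feature required")
        if self.regularization_c <= 0:
            raise ParameterError("regularization_c must be > 0")

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Scale with the stored training bounds and keep selected columns."""
        scaled, _ = minmax_scale(
            X[self.scaling_params.index], params=self.scaling_params
        )
        return scaled[self.selected_features]

    def decision_logit(self, X: pd.DataFrame) -> np.ndarray:
        Z = self.transform(X).to_numpy()
        return Z @ self.weights + self.intercept

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_logit(X)))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "selected_features": self.selected_features,
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "regularization_c": self.regularization_c,
            "scaling_params": {
                "features": list(self.scaling_params.index),
                "min": self.scaling_params["min"].tolist(),
                "max": self.scaling_params["max"].tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FittedModel":
        payload = json.loads(Path(path).read_text())
        sp = payload["scaling_params"]
        scaling = pd.DataFrame(
            {"min": sp["min"], "max": sp["max"]}, index=sp["features"]
        )
        return cls(
            selected_features=payload["selected_features"],
            weights=np.asarray(payload["weights"]),
            intercept=float(payload["intercept"]),
            scaling_params=scaling,
            regularization_c=float(payload["regularization_c"]),
        )


def fit_logistic(
    X: pd.DataFrame, y: np.ndarray, c: float = 10.0
) -> tuple[np.ndarray, float]:
    """L2-penalized logistic fit (penalty 1/c on the coefficients, not the
    intercept); deterministic because the objective is convex.

    Returns (weights, intercept) for the already scaled and selected matrix.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("both classes must be present to fit")
    if c <= 0:
        raise ParameterError("regularization c must be > 0")
    clf = LogisticRegression(C=c, solver="lbfgs", tol=1e-6, max_iter=10_000)
    clf.fit(X.to_numpy(dtype=float), y)
    return clf.coef_.ravel(), float(clf.intercept_[0])


def fit_pipeline(
    X: pd.DataFrame, y: np.ndarray, c: float = 10.0, k: int = 10
) -> FittedModel:
    """Scale → chi2-select top k → fit logistic, all on the given data."""
    scaled, params = minmax_scale(X)
    scores = chi2_scores(scaled, y)
    selected = select_top_k(scores, k=k)
    weights, intercept = fit_logistic(scaled[selected], y, c=c)
    return FittedModel(
        selected_features=selected,
        weights=weights,
        intercept=intercept,
        scaling_params=params,
        regularization_c=c,
        chi2_scores_=scores,
    )


@dataclass
class CVResult:
    """Out-of-fold predictions and metrics from stratified cross-validation."""

    oof_probability: np.ndarray
    fold_id: np.ndarray
    per_fold: list[dict]
    pooled: dict
    fold_selected: list[list[str]]


def cross_validate(
    X: pd.DataFrame,
    y: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    c: float = 10.0,
    k: int = 10,
    threshold: float = 0.5,
) -> CVResult:
    """Stratified k-fold CV of the full pipeline with no information leakage.

    Scaling and chi2 selection are re-fit on every training fold; each subject
    is predicted exactly once out-of-fold. Pooled metrics are computed from
    the out-of-fold probabilities (AUC, plus confusion metrics at the given
    probability threshold).
    """
    from . import diagnostics

    y = np.asarray(y)
    counts = pd.Series(y).value_counts()
    if len(counts) < 2 or counts.min() < folds:
        raise ParameterError(
            f"each class needs at least {folds} subjects for {folds}-fold CV"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    fold_id = np.full(len(y), -1, dtype=int)
    per_fold: list[dict] = []
    fold_selected: list[list[str]] = []
    for f, (train, test) in enumerate(skf.split(np.zeros(len(y)), y)):
        model = fit_pipeline(X.iloc[train], y[train], c=c, k=k)
        p = model.predict_proba(X.iloc[test])
        oof[test] = p
        fold_id[test] = f
        fold_selected.append(model.selected_features)
        per_fold.append(
            {
                "fold": f,
                "n_test": len(test),
                "auc": float(roc_auc_score(y[test], p)),
                "accuracy": float(np.mean((p >= threshold).astype(int) == y[test])),
            }
        )
    pred = (oof >= threshold).astype(int)
    cm = diagnostics.ConfusionMatrix(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
    )
    m = diagnostics.metrics(cm)
    pooled = {
        "auc": float(roc_auc_score(y, oof)),
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
        "ppv": m.ppv,
        "npv": m.npv,
        "accuracy": m.accuracy,
    }
    return CVResult(
        oof_probability=oof,
        fold_id=fold_id,
        per_fold=per_fold,
        pooled=pooled,
        fold_selected=fold_selected,
    )


@dataclass
class AttributionResult:
    """Exact additive attribution of one prediction on the logit scale."""

    contributions: pd.Series
    base_value: float

    @property
    def logit(self) -> float:
        return float(self.base_value + self.contributions.sum())


def linear_attribution(
    model: FittedModel, x: pd.Series | pd.DataFrame, reference: pd.DataFrame
) -> AttributionResult:
    """Per-feature contribution w_j·(x_j − mean_j(reference)) on the logit scale.

    Exact for a linear model: base value plus contributions reproduces the
    instance's logit to numerical precision.
    """
    if reference.empty:
        raise DegenerateInputError("reference set must be nonempty")
    if isinstance(x, pd.Series):
        x = x.to_frame().T
    missing = [f for f in model.scaling_params.index if f not in x.columns]
    if missing:
        raise ParameterError(f"instance is missing features: {missing[:3]}...")
    zx = model.transform(x).to_numpy().ravel()
    zref = model.transform(reference).to_numpy().mean(axis=0)
    contrib = model.weights * (zx - zref)
    base = float(model.intercept + model.weights @ zref)
    return AttributionResult(
        contributions=pd.Series(contrib, index=model.selected_features), base_value=base
    )


def mean_absolute_attribution(model: FittedModel, X: pd.DataFrame) -> pd.Series:
    """Mean |contribution| per selected feature over a cohort (reference = X).

    The cohort-level importance ranking analogous to a SHAP summary plot.
    """
    Z = model.transform(X).to_numpy()
    centered = Z - Z.mean(axis=0)
    mean_abs = np.abs(centered * model.weights).mean(axis=0)
    return pd.Series(mean_abs, index=model.selected_features).sort_values(ascending=False)
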