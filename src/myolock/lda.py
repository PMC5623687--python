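"""Linear discriminant analysis over window features.

A shared-covariance Gaussian classifier: per-class means, one pooled
within-class covariance, empirical priors. The discriminant score of class
``c`` for a feature row ``x`` is

    delta_c(x) = x' S^-1 mu_c - mu_c' S^-1 mu_c / 2 + log pi_c

and the prediction is the arg-max, with deterministic ties broken by the
canonical class order. A small diagonal shrinkage
``lambda = 1e-6 * trace(S) / p`` keeps the pooled covariance invertible on
degenerate training sets.

Fivefold stratified cross-validation with an aggregated 7x7 confusion
matrix quantifies offline performance; the error rate is the fraction of
misclassified held-out windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import (
    DegenerateTrainingError,
    InvalidConfigurationError,
    InvalidInputError,
)
from .features import FeatureMatrix
from .motions import CLASS_ORDER


@dataclass
class LDAModel:
    """Fitted shared-covariance Gaussian discriminant."""

    class_means: np.ndarray  # (k, p)
    pooled_covariance: np.ndarray  # (p, p)
    priors: np.ndarray  # (k,)
    class_order: tuple[str, ...]
    shrinkage: float = 1e-6
    # cached discriminant coefficients
    _coef: np.ndarray | None = field(default=None, repr=False)
    _intercept: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]

    def _discriminants(self) -> tuple[np.ndarray, np.ndarray]:
        if self._coef is None:
            p = self.n_features
            cov = self.pooled_covariance.copy()
            lam = self.shrinkage * np.trace(cov) / p
            cov[np.diag_indices_from(cov)] += lam
            inv_mu = np.linalg.solve(cov, self.class_means.T)  # (p, k)
            self._coef = inv_mu
            self._intercept = (
                -0.5 * np.einsum("ij,ji->i", self.class_means, inv_mu)
                + np.log(self.priors)
            )
        return self._coef, self._intercept

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Discriminant scores, rows x classes (in ``class_order``)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise InvalidInputError(
                f"expected {self.n_features} feature columns, got {X.shape}"
            )
        coef, intercept = self._discriminants()
        return X @ coef + intercept


def fit_lda(features: FeatureMatrix, shrinkage: float = 1e-6) -> LDAModel:
    """Fit the classifier on a labeled feature matrix.

    Requires at least two classes with at least two rows each. The pooled
    covariance is the within-class scatter divided by ``N - k``.
    """
    X, y = features.values, features.labels
    present = [c for c in CLASS_ORDER if c in y]
    if len(present) < 2:
        raise DegenerateTrainingError("need at least two motion classes to train")
    n, p = X.shape
    k = len(present)
    means = np.empty((k, p))
    priors = np.empty(k)
    scatter = np.zeros((p, p))
    for i, cls in enumerate(present):
        rows = X[y == cls]
        if rows.shape[0] < 2:
            raise DegenerateTrainingError(f"class {cls} has fewer than 2 rows")
        means[i] = rows.mean(axis=0)
        priors[i] = rows.shape[0] / n
        centered = rows - means[i]
        scatter += centered.T @ centered
    cov = scatter / (n - k)
    return LDAModel(
        class_means=means, pooled_covariance=cov, priors=priors,
        class_order=tuple(present), shrinkage=shrinkage,
    )


def predict_lda(model: LDAModel, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Per-row arg-max class; ties break toward the earlier class in order."""
    X = features.values if isinstance(features, FeatureMatrix) else features
    scores = model.scores(X)
    # np.argmax returns the first maximum, i.e. the earliest class in order
    idx = np.argmax(scores, axis=1)
    return np.array(model.class_order, dtype="<U2")[idx]


@dataclass
class ConfusionMatrix:
    """Actual-by-predicted window counts in the canonical 7-class order."""

    counts: np.ndarray
    class_order: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise InvalidInputError("confusion matrix shape mismatch")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def row_percent(self) -> np.ndarray:
        """Row-normalized percentages (per-class accuracy on the diagonal)."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, 100.0 * self.counts / sums, np.nan)

    def to_text(self) -> str:
        head = "actual\\pred " + " ".join(f"{c:>6}" for c in self.class_order)
        rows = [head]
        pct = self.row_percent()
        for i, c in enumerate(self.class_order):
            cells = " ".join(
                f"{v:6.1f}" if np.isfinite(v) else "     -" for v in pct[i]
            )
            rows.append(f"{c:>11} {cells}")
        return "\n".join(rows)


def confusion_from_sequences(actual, predicted) -> ConfusionMatrix:
    actual = np.asarray(actual, dtype="<U2")
    predicted = np.asarray(predicted, dtype="<U2")
    if actual.shape != predicted.shape:
        raise InvalidInputError("sequence length mismatch")
    index = {c: i for i, c in enumerate(CLASS_ORDER)}
    counts = np.zeros((len(CLASS_ORDER), len(CLASS_ORDER)), dtype=int)
    for a, p in zip(actual, predicted):
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(counts)


def crossval(
    features: FeatureMatrix,
    folds: int = 5,
    seed: int = 0,
    shrinkage: float = 1e-6,
) -> tuple[float, ConfusionMatrix]:
    """Stratified k-fold cross-validation.

    Returns the aggregate held-out error rate (misclassified / total) and
    the aggregated confusion matrix over all held-out windows.
    """
    if folds < 2:
        raise InvalidConfigurationError("folds must be >= 2")
    y = features.labels
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise InvalidConfigurationError(
            "every class needs at least as many rows as folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    actual_all, pred_all = [], []
    for train_idx, test_idx in skf.split(features.values, y):
        sub = FeatureMatrix(
            values=features.values[train_idx], labels=y[train_idx],
            columns=features.columns,
        )
        model = fit_lda(sub, shrinkage=shrinkage)
        pred = predict_lda(model, features.values[test_idx])
        actual_all.append(y[test_idx])
        pred_all.append(pred)
    actual = np.concatenate(actual_all)
    pred = np.concatenate(pred_all)
    confusion = confusion_from_sequences(actual, pred)
    error = float(np.mean(actual != pred))
    return error, confusion
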