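"""Confusion-matrix metrics, imbalance-preserving k-fold CV, and a
Gaussian naive-Bayes baseline.

Cross-validated results are *pooled*: the k held-out confusion matrices are
summed, so the pooled matrix totals equal the full table's row and class
counts and the derived metrics describe one classifier-worth of held-out
predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError, EmptySelectionError
from .preprocess import round_half_up
from .rules import AttributeAssociation, RuleSystem, build_rule, select_attributes


@dataclass(frozen=True)
class ConfusionMatrix:
    """Standard 2x2 cross-tabulation of predicted vs actual labels."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValidationError("confusion-matrix counts must be >= 0")

    @property
    def actual_positive(self) -> int:
        return self.tp + self.fn

    @property
    def actual_negative(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fn + other.fn,
            self.fp + other.fp,
            self.tn + other.tn,
        )

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn}


@dataclass(frozen=True)
class Metrics:
    """Sensitivity, specificity and accuracy in percent (one decimal)."""

    sensitivity: float
    specificity: float
    accuracy: float

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def confusion(predicted, actual) -> ConfusionMatrix:
    """Cross-tabulate 0/1 prediction and truth vectors."""
    p = np.asarray(predicted).astype(int)
    a = np.asarray(actual).astype(int)
    if p.shape != a.shape:
        raise ValidationError("predicted and actual must have equal length")
    return ConfusionMatrix(
        tp=int(np.sum((p == 1) & (a == 1))),
        fn=int(np.sum((p == 0) & (a == 1))),
        fp=int(np.sum((p == 1) & (a == 0))),
        tn=int(np.sum((p == 0) & (a == 0))),
    )


def metrics(cm: ConfusionMatrix) -> Metrics:
    """Percent sensitivity/specificity/accuracy, rounded half-up to 1 decimal."""
    if cm.actual_positive == 0 or cm.actual_negative == 0:
        raise ValidationError("metrics undefined: one class is empty")
    return Metrics(
        sensitivity=round_half_up(100.0 * cm.tp / cm.actual_positive, 1),
        specificity=round_half_up(100.0 * cm.tn / cm.actual_negative, 1),
        accuracy=round_half_up(100.0 * (cm.tp + cm.tn) / cm.total, 1),
    )


# ---------------------------------------------------------------------------
# stratified folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    """Assignment of each row to one of ``k`` folds, stratified by class."""

    k: int
    assignments: np.ndarray
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def stratified_kfold(labels, k: int = 10, seed: int = 0) -> FoldPlan:
    """Deal shuffled rows per class round-robin so every fold keeps the
    cohort's imbalance (per-fold positive counts and sizes differ by <= 1).

    A single fold pointer runs on across classes, which keeps total fold
    sizes within one row of each other as well.
    """
    y = np.asarray(labels).astype(int)
    n = len(y)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > n:
        raise ValidationError(f"k={k} exceeds number of rows ({n})")
    n_pos = int(y.sum())
    if 0 < n_pos < k:
        warnings.warn(
            f"only {n_pos} positives for k={k}: some folds will lack positives",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    assignments = np.empty(n, dtype=int)
    pointer = 0
    for cls in (1, 0):  # minority class dealt first
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i in idx:
            assignments[i] = pointer % k
            pointer += 1
    return FoldPlan(k=k, assignments=assignments, seed=seed)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    pooled: ConfusionMatrix
    fold_rules: list[RuleSystem]
    full_rule: RuleSystem
    plan: FoldPlan

    def to_dict(self) -> dict:
        return {
            "pooled_confusion": self.pooled.to_dict(),
            "pooled_metrics": metrics(self.pooled).to_dict(),
            "fold_rules": [r.to_string() for r in self.fold_rules],
            "full_rule": self.full_rule.to_dict(),
        }


def _fit_fold(
    features: pd.DataFrame,
    y: np.ndarray,
    alpha: float,
    joint: bool,
    epsilon: float,
    force_attrs: tuple[str, ...],
    mode: str,
) -> RuleSystem:
    assoc = select_attributes(features, y, alpha=alpha)
    by_name = {a.attribute: a for a in assoc}
    chosen: list[AttributeAssociation] = [a for a in assoc if a.selected]
    for name in force_attrs:
        if name in by_name and not by_name[name].selected:
            forced = by_name[name]
            chosen.append(
                AttributeAssociation(
                    forced.attribute,
                    forced.coefficient,
                    forced.odds_ratio,
                    forced.p_value,
                    forced.direction,
                    selected=True,
                    converged=forced.converged,
                )
            )
    if not chosen:
        if not assoc:
            raise EmptySelectionError("no screenable attribute")
        # fall back to the single most associated attribute so every fold
        # yields a rule; callers see the warning
        warnings.warn("no attribute passed the screen; using the lowest-p one",
                      stacklevel=2)
        a = assoc[0]
        chosen = [
            AttributeAssociation(
                a.attribute, a.coefficient, a.odds_ratio, a.p_value,
                a.direction, selected=True, converged=a.converged,
            )
        ]
    return build_rule(features, y, chosen, joint=joint, epsilon=epsilon, mode=mode)


def cross_validate(
    features: pd.DataFrame,
    labels,
    k: int = 10,
    seed: int = 0,
    alpha: float = 0.01,
    joint: bool = True,
    epsilon: float = 0.01,
    force_attrs: tuple[str, ...] = (),
    mode: str = "greedy",
) -> CVResult:
    """k-fold CV of the rule inducer with pooled held-out confusion matrix.

    Each fold's rule is fit on the other k-1 folds (screening included) and
    scored on the held-out fold; the k held-out matrices are summed.  The
    rule refit on all rows is reported alongside.
    """
    y = np.asarray(labels).astype(int)
    plan = stratified_kfold(y, k=k, seed=seed)
    pooled = ConfusionMatrix(0, 0, 0, 0)
    fold_rules = []
    for fold in range(k):
        tr = plan.train_indices(fold)
        te = plan.test_indices(fold)
        if y[te].sum() == 0:
            warnings.warn(f"fold {fold} has no positives; scoring anyway",
                          stacklevel=2)
        rule = _fit_fold(
            features.iloc[tr], y[tr], alpha, joint, epsilon, force_attrs, mode
        )
        fold_rules.append(rule)
        pooled = pooled + confusion(rule.predict(features.iloc[te]), y[te])
    full_rule = _fit_fold(features, y, alpha, joint, epsilon, force_attrs, mode)
    return CVResult(pooled=pooled, fold_rules=fold_rules, full_rule=full_rule, plan=plan)


# ---------------------------------------------------------------------------
# Gaussian naive-Bayes baseline
# ---------------------------------------------------------------------------

class GaussianNB:
    """Minimal Gaussian class-conditional naive Bayes (maximum posterior).

    Implemented directly (~30 lines of math) so the comparison stays
    fold-paired and dependency-light.  Per-class feature variances are
    floored at 1e-9 to survive degenerate columns.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GaussianNB":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        self.theta_, self.var_, self.prior_ = [], [], []
        for c in self.classes_:
            Xc = X[y == c]
            self.theta_.append(Xc.mean(axis=0))
            v = Xc.var(axis=0)
            if np.any(v < 1e-9):
                warnings.warn("zero-variance feature in a class; flooring variance",
                              stacklevel=2)
                v = np.maximum(v, 1e-9)
            self.var_.append(v)
            self.prior_.append(len(Xc) / len(X))
        return self

    def log_posterior(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        scores = []
        for mu, var, prior in zip(self.theta_, self.var_, self.prior_):
            ll = -0.5 * np.sum(
                np.log(2.0 * np.pi * var) + (X - mu) ** 2 / var, axis=1
            )
            scores.append(ll + np.log(prior))
        return np.column_stack(scores)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.log_posterior(X), axis=1)]


def naive_bayes_baseline(
    features: pd.DataFrame,
    labels,
    k: int = 10,
    seed: int = 0,
) -> ConfusionMatrix:
    """Pooled k-fold confusion matrix of the Gaussian NB baseline.

    Uses the identical fold plan as :func:`cross_validate` for the same
    (labels, k, seed), so rule-vs-baseline comparisons are paired.
    """
    y = np.asarray(labels).astype(int)
    X = features.to_numpy(float)
    plan = stratified_kfold(y, k=k, seed=seed)
    pooled = ConfusionMatrix(0, 0, 0, 0)
    for fold in range(k):
        tr = plan.train_indices(fold)
        te = plan.test_indices(fold)
        clf = GaussianNB().fit(X[tr], y[tr])
        pooled = pooled + confusion(clf.predict(X[te]), y[te])
    return pooled
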