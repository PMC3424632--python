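"""Conjunctive threshold-rule induction on imbalanced binary outcomes.

The pipeline has three stages:

1. **Screening** — each continuous attribute is tested for association with
   the positive class by univariate logistic regression (IRLS maximum
   likelihood, two-sided Wald test on the slope, likelihood-ratio fallback
   under separation).  Attributes with ``p < alpha`` are selected; the sign
   of the slope fixes the relation (``>=`` for positive association,
   ``<=`` for negative).

2. **Partition search** — for each selected attribute a decision threshold
   is initialised at the positive-class mean and then moved stepwise through
   candidate cut-points (midpoints of consecutive distinct values) in the
   sensitivity-increasing direction.  A step to a cut-point that strictly
   improves overall accuracy is accepted (the threshold moves there); the
   walk keeps exploring past non-improving cut-points while accuracy stays
   within ``epsilon`` of the best seen, and stops at the first cut-point
   falling further than ``epsilon`` below it.  The last accepted cut-point
   is returned, so the search is biased toward sensitivity (it only ever
   moves in the sensitivity-increasing direction, and ``epsilon`` lets it
   cross accuracy dips) while accuracy is maintained.

3. **Rule construction** — one condition per selected attribute is conjoined
   into a single ``If ... then 1 Else 0`` rule.  With ``joint=True`` a
   greedy coordinate pass re-runs the partition search for each threshold
   against the *conjunction's* confusion matrix, iterating until no
   threshold moves.

Thresholds are applied unrounded; printed rule strings round to one
decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .exceptions import (
    DegenerateAttributeError,
    EmptySelectionError,
    ValidationError,
)
from .preprocess import round_half_up

RELATIONS = (">=", "<=")
_GLYPH = {">=": "≥", "<=": "≤"}


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AttributeAssociation:
    """Result of screening one attribute against the outcome."""

    attribute: str
    coefficient: float  # log-odds per unit
    odds_ratio: float
    p_value: float
    direction: str  # ">=" when positively associated, "<=" otherwise
    selected: bool
    converged: bool = True

    def __post_init__(self) -> None:
        if self.direction not in RELATIONS:
            raise ValidationError(f"direction must be one of {RELATIONS}")


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable: log(1+exp(eta)) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_univariate_logistic(
    values,
    labels,
    alpha: float = 0.01,
    attribute: str = "x",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> AttributeAssociation:
    """Maximum-likelihood fit of ``logit P(y=1) = b0 + b1 x`` by IRLS.

    The reported p-value is the two-sided Wald test on ``b1``.  Under
    non-convergence or (quasi-)complete separation the Wald statistic is
    unreliable, so the p-value falls back to the likelihood-ratio test
    against the intercept-only model and ``converged`` is flagged False.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("values and labels must be 1-D and equal length")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValidationError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValidationError("both classes must be present")
    if np.ptp(x) == 0:
        raise DegenerateAttributeError(f"attribute {attribute!r} has zero variance")

    # standardize for conditioning; slope is rescaled back afterwards
    mu, sd = x.mean(), x.std()
    z = (x - mu) / sd
    X = np.column_stack([np.ones_like(z), z])

    pbar = y.mean()
    beta = np.array([np.log(pbar / (1.0 - pbar)), 0.0])
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = np.clip(p * (1.0 - p), 1e-10, None)
        XtW = X.T * w
        try:
            step = np.linalg.solve(XtW @ X, X.T @ (y - p))
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    eta = X @ beta
    p = expit(eta)
    w = np.clip(p * (1.0 - p), 1e-10, None)
    fisher = (X.T * w) @ X
    cov = np.linalg.inv(fisher)
    se_z = np.sqrt(cov[1, 1])

    coef = beta[1] / sd
    separated = not converged or np.abs(beta[1]) > 30.0 or se_z > 1e3

    if separated:
        ll_full = _log_likelihood(y, eta)
        ll_null = _log_likelihood(y, np.full_like(eta, np.log(pbar / (1 - pbar))))
        lr = max(0.0, 2.0 * (ll_full - ll_null))
        p_value = float(stats.chi2.sf(lr, df=1))
    else:
        zstat = beta[1] / se_z
        p_value = float(2.0 * stats.norm.sf(abs(zstat)))

    return AttributeAssociation(
        attribute=attribute,
        coefficient=float(coef),
        odds_ratio=float(np.exp(np.clip(coef, -700, 700))),
        p_value=p_value,
        direction=">=" if coef > 0 else "<=",
        selected=bool(p_value < alpha),
        converged=bool(not separated),
    )


def select_attributes(
    features: pd.DataFrame,
    labels,
    alpha: float = 0.01,
) -> list[AttributeAssociation]:
    """Screen every column of ``features`` independently.

    Returns associations in ascending p-value order with ``selected`` set
    for ``p < alpha``.  Zero-variance columns are skipped.  An empty
    selected set is not an error here: callers may force attributes in.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome is constant; nothing to screen")
    out = []
    for col in features.columns:
        try:
            out.append(
                fit_univariate_logistic(
                    features[col].to_numpy(float), y, alpha=alpha, attribute=str(col)
                )
            )
        except DegenerateAttributeError:
            continue
    out.sort(key=lambda a: (a.p_value, a.attribute))
    return out


# ---------------------------------------------------------------------------
# rule data model
# ---------------------------------------------------------------------------

def _format_threshold(threshold: float) -> str:
    r = round_half_up(threshold, 1)
    return str(int(r)) if r == int(r) else f"{r:.1f}"


@dataclass(frozen=True)
class RuleCondition:
    """A single inclusive threshold condition on one attribute."""

    attribute: str
    relation: str  # ">=" or "<="
    threshold: float

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValidationError(f"relation must be one of {RELATIONS}")
        if not np.isfinite(self.threshold):
            raise ValidationError("threshold must be finite")

    def holds(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return v >= self.threshold if self.relation == ">=" else v <= self.threshold

    def __str__(self) -> str:
        return f"{self.attribute} {_GLYPH[self.relation]} {_format_threshold(self.threshold)}"


@dataclass(frozen=True)
class RuleSystem:
    """Conjunction of one threshold condition per attribute."""

    conditions: tuple[RuleCondition, ...]

    def __post_init__(self) -> None:
        if len(self.conditions) < 1:
            raise ValidationError("a rule needs at least one condition")
        attrs = [c.attribute for c in self.conditions]
        if len(set(attrs)) != len(attrs):
            raise ValidationError("one condition per attribute")

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(c.attribute for c in self.conditions)

    def predict(self, features) -> np.ndarray:
        """1 iff every condition holds (inclusive relations), else 0."""
        if isinstance(features, pd.DataFrame):
            getter = lambda a: features[a].to_numpy(float)  # noqa: E731
            n = len(features)
        else:
            getter = lambda a: np.atleast_1d(np.asarray(features[a], dtype=float))  # noqa: E731
            n = None
        out = None
        for cond in self.conditions:
            try:
                col = getter(cond.attribute)
            except KeyError as exc:
                raise ValidationError(f"missing attribute {cond.attribute!r}") from exc
            mask = cond.holds(col)
            out = mask if out is None else (out & mask)
        if n is not None and len(out) != n:
            raise ValidationError("attribute columns have inconsistent length")
        return out.astype(int)

    def to_string(self) -> str:
        body = " and ".join(str(c) for c in self.conditions)
        return f"If {body} then 1 Else 0"

    def to_dict(self) -> dict:
        return {
            "conditions": [
                {"attribute": c.attribute, "relation": c.relation, "threshold": c.threshold}
                for c in self.conditions
            ],
            "string": self.to_string(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RuleSystem":
        return cls(
            tuple(
                RuleCondition(c["attribute"], c["relation"], float(c["threshold"]))
                for c in d["conditions"]
            )
        )


def predict(rule: RuleSystem, row) -> np.ndarray:
    """Apply ``rule`` to a row or table of feature values."""
    return rule.predict(row)


# ---------------------------------------------------------------------------
# partition search
# ---------------------------------------------------------------------------

def initial_partition(values, labels, direction: str = ">=") -> float:
    """Starting threshold: the attribute mean over positive-class rows.

    With no positive rows the overall mean is used (degenerate but defined).
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    pos = x[y == 1]
    return float(pos.mean()) if len(pos) else float(x.mean())


def _threshold_stats(x_sorted, pos_before, neg_before, threshold, relation):
    """(tp, fp, fn, tn) over the sorted active rows at an inclusive threshold."""
    n_pos = pos_before[-1]
    n_neg = neg_before[-1]
    if relation == ">=":
        i = np.searchsorted(x_sorted, threshold, side="left")
        tp = n_pos - pos_before[i]
        fp = n_neg - neg_before[i]
    else:
        i = np.searchsorted(x_sorted, threshold, side="right")
        tp = pos_before[i]
        fp = neg_before[i]
    return tp, fp, n_pos - tp, n_neg - fp


def _candidate_path(x_sorted: np.ndarray, start: float, relation: str) -> np.ndarray:
    """Cut-points beyond ``start`` in the sensitivity-increasing direction.

    Candidates are midpoints between consecutive distinct values — the
    partition is then exclusionary and exhaustive with no ties on observed
    data — plus the extreme observed value itself as terminal candidate so
    the all-rows-predicted-positive partition is reachable.
    """
    uniq = np.unique(x_sorted)
    mids = (uniq[1:] + uniq[:-1]) / 2.0
    if relation == ">=":
        path = np.concatenate([mids[::-1], uniq[:1]])
        return path[path < start]
    path = np.concatenate([mids, uniq[-1:]])
    return path[path > start]


def refine_partition(
    values,
    labels,
    direction: str = ">=",
    start: float | None = None,
    epsilon: float = 0.01,
    mode: str = "greedy",
    _extra_tn: int = 0,
    _extra_fn: int = 0,
    _total: int | None = None,
) -> float:
    """Move a threshold toward higher sensitivity under an accuracy budget.

    Starting from ``start`` (default: the positive-class mean), candidate
    cut-points are visited nearest-first in the direction that can only
    increase sensitivity (downward for ``>=``, upward for ``<=``).  A
    cut-point strictly improving overall accuracy is accepted and becomes
    the new threshold; non-improving cut-points are explored but not
    accepted (ties stay at the candidate nearest the start) while their
    accuracy remains within ``epsilon`` of the best seen, and the walk
    stops at the first cut-point falling below best-minus-``epsilon``.
    The last accepted threshold is returned.

    ``mode="exhaustive"`` instead scores every candidate on the path
    (ignoring ``epsilon``) and returns the global accuracy maximiser,
    breaking ties toward the candidate nearest the start; it is the
    brute-force alternative when accuracy dips larger than ``epsilon``
    must be crossed.

    The underscore parameters let :func:`build_rule` score a threshold
    against a conjunction: rows outside the active subset are predicted
    negative and contribute fixed true-negative / false-negative counts.
    """
    if direction not in RELATIONS:
        raise ValidationError(f"direction must be one of {RELATIONS}")
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    if start is None:
        start = initial_partition(x, y, direction)
    start = float(start)

    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y[order]
    pos_before = np.concatenate([[0], np.cumsum(ys)])
    neg_before = np.concatenate([[0], np.cumsum(1 - ys)])
    total = _total if _total is not None else len(x) + _extra_tn + _extra_fn
    if total == 0:
        raise ValidationError("cannot refine on an empty table")

    def accuracy(t: float) -> float:
        tp, fp, fn, tn = _threshold_stats(xs, pos_before, neg_before, t, direction)
        return (tp + tn + _extra_tn) / total

    path = _candidate_path(xs, start, direction)
    if len(path) == 0:
        return start

    if mode == "exhaustive":
        cand = np.concatenate([[start], path])
        stats_ = [
            _threshold_stats(xs, pos_before, neg_before, t, direction) for t in cand
        ]
        accs = np.array([(tp + tn + _extra_tn) / total for tp, _, _, tn in stats_])
        dist = np.abs(cand - start)
        best = max(range(len(cand)), key=lambda i: (accs[i], -dist[i]))
        return float(cand[best])
    if mode != "greedy":
        raise ValueError(f"unknown search mode {mode!r}")

    best_acc = accuracy(start)
    accepted = start
    tol = 1e-12
    for t in path:
        a = accuracy(t)
        if a < best_acc - epsilon - tol:
            break
        if a > best_acc + tol:
            best_acc = a
            accepted = float(t)
    return accepted


def build_rule(
    features: pd.DataFrame,
    labels,
    associations: list[AttributeAssociation],
    joint: bool = False,
    epsilon: float = 0.01,
    mode: str = "greedy",
    max_joint_sweeps: int = 50,
) -> RuleSystem:
    """Construct the conjunctive rule, one condition per selected attribute.

    ``associations`` supplies attribute order and relation direction; only
    entries with ``selected=True`` are used (pass pre-filtered or forced
    associations to override).  With ``joint=True`` a greedy coordinate
    pass re-refines each threshold against the conjunction's confusion
    matrix under the same accept rule, sweeping until stable.
    """
    chosen = [a for a in associations if a.selected]
    if not chosen:
        raise EmptySelectionError("no attribute selected; force attributes to proceed")
    y = np.asarray(labels).astype(int)
    n = len(y)

    conditions = []
    for assoc in chosen:
        x = features[assoc.attribute].to_numpy(float)
        thr = refine_partition(
            x,
            y,
            direction=assoc.direction,
            start=initial_partition(x, y, assoc.direction),
            epsilon=epsilon,
            mode=mode,
        )
        conditions.append(RuleCondition(assoc.attribute, assoc.direction, thr))

    if joint and len(conditions) > 1:
        cols = {c.attribute: features[c.attribute].to_numpy(float) for c in conditions}
        for _ in range(max_joint_sweeps):
            changed = False
            for j, cond in enumerate(conditions):
                others = [c for i, c in enumerate(conditions) if i != j]
                active = np.ones(n, dtype=bool)
                for oc in others:
                    active &= oc.holds(cols[oc.attribute])
                if not active.any():
                    continue
                inactive_y = y[~active]
                thr = refine_partition(
                    cols[cond.attribute][active],
                    y[active],
                    direction=cond.relation,
                    start=cond.threshold,
                    epsilon=epsilon,
                    mode=mode,
                    _extra_tn=int((inactive_y == 0).sum()),
                    _extra_fn=int((inactive_y == 1).sum()),
                    _total=n,
                )
                if thr != cond.threshold:
                    conditions[j] = replace(cond, threshold=thr)
                    changed = True
            if not changed:
                break

    return RuleSystem(tuple(conditions))
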