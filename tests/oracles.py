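"""Independent reference implementations used to cross-check the package.

Everything here is written as plain, slow Python loops (or delegated to
statsmodels) on purpose: these oracles share no code with the vectorised
implementations they verify.
"""

from __future__ import annotations

import math


def arv_oracle(values, times):
    num = 0.0
    den = 0.0
    for k in range(1, len(values)):
        w = times[k] - times[k - 1]
        num += w * abs(values[k] - values[k - 1])
        den += w
    return num / den


def wbp_oracle(values, times):
    num = 0.0
    den = 0.0
    for k in range(1, len(values)):
        w = times[k] - times[k - 1]
        num += w * (values[k] + values[k - 1]) / 2.0
        den += w
    return num / den


def condition_counts(values, labels, relation, threshold, extra_tn=0, extra_fn=0):
    """(tp, fp, fn, tn) for an inclusive single-threshold condition."""
    tp = fp = fn = tn = 0
    for x, y in zip(values, labels):
        pred = x >= threshold if relation == ">=" else x <= threshold
        if pred and y == 1:
            tp += 1
        elif pred and y == 0:
            fp += 1
        elif not pred and y == 1:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn + extra_fn, tn + extra_tn


def refine_oracle(values, labels, relation, start, epsilon=0.01,
                  extra_tn=0, extra_fn=0, total=None):
    """Naive re-derivation of the sensitivity-first threshold walk.

    Candidates are midpoints of consecutive distinct sorted values plus the
    extreme value in the walk direction; a candidate strictly improving
    accuracy is accepted, exploration continues while accuracy stays within
    epsilon of the best seen, and the last accepted candidate is returned.
    """
    if total is None:
        total = len(values) + extra_tn + extra_fn
    uniq = sorted(set(values))
    mids = [(a + b) / 2.0 for a, b in zip(uniq, uniq[1:])]
    if relation == ">=":
        path = [m for m in reversed(mids) if m < start] + (
            [uniq[0]] if uniq[0] < start else []
        )
    else:
        path = [m for m in mids if m > start] + ([uniq[-1]] if uniq[-1] > start else [])

    def acc(t):
        tp, fp, fn, tn = condition_counts(values, labels, relation, t, extra_tn, extra_fn)
        return (tp + tn) / total

    best = acc(start)
    accepted = start
    for t in path:
        a = acc(t)
        if a < best - epsilon - 1e-12:
            break
        if a > best + 1e-12:
            best = a
            accepted = t
    return accepted


def logistic_oracle(x, y):
    """Slope, Wald p-value from statsmodels (reference MLE)."""
    import numpy as np
    import statsmodels.api as sm

    X = sm.add_constant(np.asarray(x, float))
    fit = sm.Logit(np.asarray(y, float), X).fit(disp=0)
    return float(fit.params[1]), float(fit.pvalues[1])


def gaussian_log_posterior(x, mean, var, prior):
    return math.log(prior) - 0.5 * (
        math.log(2 * math.pi * var) + (x - mean) ** 2 / var
    )
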