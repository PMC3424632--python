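import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from abpmine import (
    AttributeAssociation,
    RuleCondition,
    RuleSystem,
    SimConfig,
    build_rule,
    fit_univariate_logistic,
    initial_partition,
    predict,
    refine_partition,
    select_attributes,
    simulate_cohort,
)
from abpmine.exceptions import (
    DegenerateAttributeError,
    EmptySelectionError,
    ValidationError,
)
from conftest import truth_features
from oracles import condition_counts, logistic_oracle, refine_oracle


class TestLogisticScreen:
    def test_matches_statsmodels(self):
        rng = np.random.default_rng(42)
        x = np.concatenate([rng.normal(0, 1, 120), rng.normal(1.2, 1, 60)])
        y = np.concatenate([np.zeros(120), np.ones(60)])
        a = fit_univariate_logistic(x, y)
        coef_ref, p_ref = logistic_oracle(x, y)
        assert a.coefficient == pytest.approx(coef_ref, rel=1e-5)
        assert a.p_value == pytest.approx(p_ref, rel=1e-4)
        assert a.odds_ratio == pytest.approx(np.exp(coef_ref), rel=1e-5)

    def test_separated_classes_selected(self):
        # seeded well-separated draw: must be selected at alpha 0.01
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0, 1, 100), rng.normal(2, 1, 100)])
        y = np.repeat([0, 1], 100)
        a = fit_univariate_logistic(x, y)
        assert a.selected
        assert a.direction == ">="

    def test_permuted_labels_p_uniform(self):
        # under the null the Wald p-value should be ~Uniform(0,1)
        rng = np.random.default_rng(123)
        n = 40
        x = rng.normal(size=n)
        pvals = []
        for _ in range(1000):
            y = np.zeros(n)
            y[rng.choice(n, size=n // 2, replace=False)] = 1
            pvals.append(fit_univariate_logistic(x, y).p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_constant_attribute_skipped(self):
        with pytest.raises(DegenerateAttributeError):
            fit_univariate_logistic(np.ones(20), np.repeat([0, 1], 10))

    def test_complete_separation_flagged(self):
        x = np.concatenate([np.arange(10), np.arange(20, 30)]).astype(float)
        y = np.repeat([0, 1], 10)
        a = fit_univariate_logistic(x, y)
        assert not a.converged
        assert a.p_value < 0.01  # likelihood-ratio fallback is decisive

    def test_direction_follows_sign(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(2, 1, 100), rng.normal(0, 1, 100)])
        y = np.repeat([0, 1], 100)
        assert fit_univariate_logistic(x, y).direction == "<="


class TestSelectAttributes:
    def test_two_driver_recovery(self):
        # outcome driven by exactly two of seven attributes (planted
        # log-odds 1.0 each); screening should recover exactly those two
        rng = np.random.default_rng(123)
        n = 2000
        hits = 0
        for _ in range(50):
            X = pd.DataFrame(
                rng.normal(size=(n, 7)), columns=[f"a{i}" for i in range(7)]
            )
            eta = -2.5 + 1.0 * X["a0"] + 1.0 * X["a1"]
            y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
            assoc = select_attributes(X, y, alpha=0.01)
            selected = {a.attribute for a in assoc if a.selected}
            hits += selected == {"a0", "a1"}
        assert hits >= 48  # >= 95% exact recovery

    def test_alpha_one_selects_everything(self, truth_cohort):
        feats, y = truth_features(truth_cohort)
        assoc = select_attributes(feats, y, alpha=1.0)
        assert all(a.selected for a in assoc)
        assert len(assoc) == 7

    def test_constant_labels_error(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValidationError):
            select_attributes(X, np.zeros(3))

    def test_sorted_by_p(self, truth_cohort):
        feats, y = truth_features(truth_cohort)
        assoc = select_attributes(feats, y)
        ps = [a.p_value for a in assoc]
        assert ps == sorted(ps)


class TestInitialPartition:
    def test_positive_mean(self):
        assert initial_partition([1, 4, 2, 5, 3, 6], [0, 1, 0, 1, 0, 1]) == 5.0

    def test_single_positive(self):
        assert initial_partition([1.0, 9.6], [0, 1]) == 9.6

    def test_all_positive_overall_mean(self):
        assert initial_partition([2.0, 4.0], [1, 1]) == 3.0


class TestRefinePartition:
    def test_separable_example(self):
        t = refine_partition([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1], ">=", start=5.0)
        assert t == 3.5
        tp, fp, fn, tn = condition_counts([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1], ">=", t)
        assert (tp, fp, fn, tn) == (3, 0, 0, 3)

    def test_all_positive_goes_to_min(self):
        t = refine_partition([1.0, 2.0, 5.0], [1, 1, 1], ">=", start=3.0)
        assert t == 1.0

    def test_le_direction(self):
        t = refine_partition([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 0, 0], "<=", start=2.0)
        assert t == 3.5

    def test_perfect_separation_matches_exhaustive(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n_pos = rng.integers(1, 6)
            n_neg = rng.integers(1, 6)
            neg = rng.uniform(0, 10, n_neg)
            pos = rng.uniform(11, 20, n_pos)
            x = np.concatenate([neg, pos])
            y = np.concatenate([np.zeros(n_neg), np.ones(n_pos)])
            t = refine_partition(x, y, ">=", start=initial_partition(x, y))
            t_ex = refine_partition(
                x, y, ">=", start=initial_partition(x, y), mode="exhaustive"
            )
            assert condition_counts(x, y, ">=", t) == condition_counts(x, y, ">=", t_ex)
            assert condition_counts(x, y, ">=", t)[:2] == (n_pos, 0)

    def test_matches_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            x = np.round(rng.uniform(0, 10, n), 1)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            for direction in (">=", "<="):
                start = initial_partition(x, y, direction)
                got = refine_partition(x, y, direction, start=start)
                want = refine_oracle(list(x), list(y), direction, start)
                assert got == pytest.approx(want)

    def test_empty_table_errors(self):
        with pytest.raises(ValidationError):
            refine_partition([], [], ">=", start=0.0)


@settings(max_examples=100, deadline=None)
@given(
    st.lists(
        st.tuples(st.floats(min_value=0, max_value=10), st.integers(0, 1)),
        min_size=3,
        max_size=40,
    ),
    st.floats(min_value=0, max_value=10),
    st.floats(min_value=0, max_value=10),
)
def test_threshold_monotonicity(rows, t_lo, t_hi):
    """Raising a >=-threshold never increases sensitivity nor decreases
    specificity (and symmetrically for <=)."""
    t_lo, t_hi = min(t_lo, t_hi), max(t_lo, t_hi)
    x = [r[0] for r in rows]
    y = [r[1] for r in rows]
    lo = condition_counts(x, y, ">=", t_lo)
    hi = condition_counts(x, y, ">=", t_hi)
    assert hi[0] <= lo[0]  # tp (sensitivity numerator) falls
    assert hi[3] >= lo[3]  # tn (specificity numerator) rises
    lo_le = condition_counts(x, y, "<=", t_lo)
    hi_le = condition_counts(x, y, "<=", t_hi)
    assert lo_le[0] <= hi_le[0]
    assert lo_le[3] >= hi_le[3]


def _assoc(attr, direction=">="):
    return AttributeAssociation(attr, 1.0 if direction == ">=" else -1.0,
                                2.7, 0.001, direction, selected=True)


class TestRuleSystem:
    def test_published_style_rule_representable(self):
        rule = RuleSystem(
            (
                RuleCondition("systolic ARV", ">=", 9.6),
                RuleCondition("systolic WBP", ">=", 137.0),
            )
        )
        assert rule.to_string() == "If systolic ARV ≥ 9.6 and systolic WBP ≥ 137 then 1 Else 0"

    def test_round_trip_dict(self):
        rule = RuleSystem((RuleCondition("a", "<=", 5.52),))
        assert RuleSystem.from_dict(rule.to_dict()) == rule

    def test_duplicate_attribute_rejected(self):
        with pytest.raises(ValidationError):
            RuleSystem(
                (RuleCondition("a", ">=", 1.0), RuleCondition("a", ">=", 2.0))
            )

    def test_predict_conjunction(self):
        rule = RuleSystem(
            (RuleCondition("arv", ">=", 9.6), RuleCondition("wbp", ">=", 137.0))
        )
        assert predict(rule, {"arv": 10.0, "wbp": 140.0})[0] == 1
        # inclusive relations: exactly at both thresholds is positive
        assert predict(rule, {"arv": 9.6, "wbp": 137.0})[0] == 1
        assert predict(rule, {"arv": 9.5, "wbp": 200.0})[0] == 0

    def test_predict_missing_attribute(self):
        rule = RuleSystem((RuleCondition("arv", ">=", 9.6),))
        with pytest.raises(ValidationError):
            predict(rule, {"wbp": 140.0})


class TestBuildRule:
    def test_single_attribute_equals_refine(self):
        x = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1])
        df = pd.DataFrame({"a": x})
        rule = build_rule(df, y, [_assoc("a")])
        t = refine_partition(x, y, ">=", start=initial_partition(x, y))
        assert rule.conditions[0].threshold == t

    def test_empty_selection_errors(self):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(EmptySelectionError):
            build_rule(df, [0, 1], [])

    def test_joint_never_decreases_sensitivity(self):
        rng = np.random.default_rng(23)
        for _ in range(40):
            n = int(rng.integers(4, 13))
            df = pd.DataFrame(
                {"a": np.round(rng.uniform(0, 10, n), 1),
                 "b": np.round(rng.uniform(0, 10, n), 1)}
            )
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            assoc = [_assoc("a"), _assoc("b")]
            marginal = build_rule(df, y, assoc, joint=False)
            joint = build_rule(df, y, assoc, joint=True)
            sens_marginal = (marginal.predict(df) & (y == 1)).sum()
            sens_joint = (joint.predict(df) & (y == 1)).sum()
            assert sens_joint >= sens_marginal

    def test_joint_matches_naive_coordinate_oracle(self):
        # same greedy accept rule, re-derived with O(n^2) loops
        rng = np.random.default_rng(31)
        for _ in range(60):
            n = int(rng.integers(4, 13))
            a = np.round(rng.uniform(0, 10, n), 1)
            b = np.round(rng.uniform(0, 10, n), 1)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            df = pd.DataFrame({"a": a, "b": b})
            got = build_rule(df, y, [_assoc("a"), _assoc("b")], joint=True)

            # oracle: marginal refine then alternating conjunction refine
            ta = refine_oracle(list(a), list(y), ">=", initial_partition(a, y))
            tb = refine_oracle(list(b), list(y), ">=", initial_partition(b, y))
            for _sweep in range(50):
                changed = False
                for which in (0, 1):
                    vals = a if which == 0 else b
                    other_vals, other_t = (b, tb) if which == 0 else (a, ta)
                    active = other_vals >= other_t
                    inactive_y = np.asarray(y)[~active]
                    if not active.any():
                        continue
                    new_t = refine_oracle(
                        list(vals[active]),
                        list(np.asarray(y)[active]),
                        ">=",
                        ta if which == 0 else tb,
                        extra_tn=int((inactive_y == 0).sum()),
                        extra_fn=int((inactive_y == 1).sum()),
                        total=n,
                    )
                    if which == 0 and new_t != ta:
                        ta, changed = new_t, True
                    elif which == 1 and new_t != tb:
                        tb, changed = new_t, True
                if not changed:
                    break
            thr = {c.attribute: c.threshold for c in got.conditions}
            assert thr["a"] == pytest.approx(ta)
            assert thr["b"] == pytest.approx(tb)

    def test_determinism(self, truth_cohort):
        feats, y = truth_features(truth_cohort)
        assoc = [a for a in select_attributes(feats, y) if a.selected]
        r1 = build_rule(feats, y, assoc, joint=True)
        r2 = build_rule(feats, y, assoc, joint=True)
        assert r1 == r2


class TestPlantedRecovery:
    def test_thresholds_recovered(self):
        hits = 0
        for seed in range(10):
            cfg = SimConfig(
                n_subjects=2000, label_noise=0.05, seed=seed, generate_recordings=False
            )
            cohort = simulate_cohort(cfg)
            feats, y = truth_features(cohort)
            assoc = [a for a in select_attributes(feats, y) if a.selected]
            rule = build_rule(feats, y, assoc, joint=True)
            thr = {c.attribute: c.threshold for c in rule.conditions}
            if (
                "sbp_arv" in thr
                and "sbp_wbp" in thr
                and abs(thr["sbp_arv"] - 9.6) <= 0.5
                and abs(thr["sbp_wbp"] - 137.0) <= 0.5
            ):
                hits += 1
        assert hits >= 9
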