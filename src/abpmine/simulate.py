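"""Synthetic ABP cohort generator.

Produces reading-level recordings and subject-level covariates with the
statistical structure the downstream analysis assumes: a minority positive
class planted exactly by a threshold rule on true subject-level features,
label noise on top, and within-subject AR(1) blood-pressure dynamics whose
increment scale is calibrated so the realized ARV of each recording matches
the subject's true ARV in expectation.

Layout of the truth table (one row per subject): the seven minable
attributes (``bmi, cholesterol, heart_rate, sbp_wbp, dbp_wbp, sbp_arv,
dbp_arv``), the noiseless ``true_label`` (the planted rule applied to the
true features) and the observed ``outcome`` (true label XOR a Bernoulli
flip).  Covariates outside the planted rule are drawn independently of the
outcome, so attribute screening should reject them — a built-in negative
control.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .exceptions import ValidationError
from .io import ABPRecording
from .rules import RuleCondition, RuleSystem

FEATURE_COLUMNS = (
    "bmi",
    "cholesterol",
    "heart_rate",
    "sbp_wbp",
    "dbp_wbp",
    "sbp_arv",
    "dbp_arv",
)

#: marginal (mean, sd) of outcome-independent attributes
_BASE_MARGINALS = {
    "bmi": (27.1, 5.6),
    "cholesterol": (5.5, 1.3),
    "heart_rate": (73.7, 9.8),
    "sbp_wbp": (133.8, 10.0),
    "dbp_wbp": (76.1, 10.0),
    "sbp_arv": (9.0, 2.5),
    "dbp_arv": (7.5, 1.8),
}

_CLIPS = {
    "bmi": (15.0, 55.0),
    "cholesterol": (2.5, 12.0),
    "heart_rate": (45.0, 120.0),
    "sbp_wbp": (85.0, 225.0),
    "dbp_wbp": (50.0, 110.0),
    "sbp_arv": (1.0, 30.0),
    "dbp_arv": (1.0, 25.0),
}

#: exponential scales for how far beyond a rule threshold satisfying /
#: violating draws land (attribute units); chosen so the planted boundary
#: is densely flanked on both sides
_SATISFY_SCALE = {"sbp_arv": 1.2, "sbp_wbp": 5.0, "dbp_wbp": 4.0, "dbp_arv": 1.0}
_VIOLATE_SCALE = {"sbp_arv": 1.8, "sbp_wbp": 5.0, "dbp_wbp": 4.0, "dbp_arv": 1.0}
#: zero-density half-width around each planted threshold: noiseless data
#: are then strictly separated, so fold-trained thresholds generalise
#: exactly, while recovered thresholds stay well within +-0.5 of truth
_MARGIN = {"sbp_arv": 0.12, "sbp_wbp": 0.3, "dbp_wbp": 0.25, "dbp_arv": 0.1}

DEFAULT_RULE = RuleSystem(
    (
        RuleCondition("sbp_arv", ">=", 9.6),
        RuleCondition("sbp_wbp", ">=", 137.0),
    )
)


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the cohort generator (defaults emulate a ~551-subject
    cohort with 1:9 imbalance and ~65 readings per 24 h)."""

    n_subjects: int = 551
    prevalence: float = 61.0 / 551.0
    readings_mean: int = 65
    readings_jitter: int = 8
    sampling_interval_min: float = 22.0
    true_rule: RuleSystem = field(default_factory=lambda: DEFAULT_RULE)
    label_noise: float = 0.05
    between_subject_sd: float = 10.0
    within_subject_sd: float = 2.0
    seed: int = 0
    #: lag-1 autocorrelation of the within-subject systolic walk
    ar_coef: float = 0.4
    #: skip reading-level generation when only the truth table is needed
    generate_recordings: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValidationError("prevalence must be in [0, 1]")
        if not 0.0 <= self.label_noise <= 0.5:
            raise ValidationError("label_noise must be in [0, 0.5]")
        if self.readings_mean < 2:
            raise ValidationError("readings_mean must be >= 2")


@dataclass
class SyntheticCohort:
    """Generated cohort plus ground truth for every planted quantity."""

    recordings: list[ABPRecording] | None
    subjects: pd.DataFrame
    truth: pd.DataFrame
    corrupted_readings: list[tuple[str, float]] = field(default_factory=list)
    missing_cholesterol: list[str] = field(default_factory=list)


def _max_attainable_arv(mean, lo: float, hi: float, rho: float) -> np.ndarray:
    """Largest ARV target whose AR(1) walk stays within (lo, hi) around mean.

    Conservative closed form: the stationary sd is capped at a third of the
    distance to the nearer bound, ignoring the white-noise share.
    """
    d = np.minimum(np.asarray(mean) - lo, hi - np.asarray(mean))
    v_diff = 2.0 * (1.0 - rho) * (d / 3.0) ** 2
    return 0.98 * np.sqrt(2.0 * v_diff / np.pi)


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    # stable per-subject substream: reproducible under subject reordering
    return np.random.default_rng([seed, zlib.crc32(subject_id.encode())])


def _trunc_exp(rng, scale: float, cap: float, size: int) -> np.ndarray:
    return np.minimum(rng.exponential(scale, size=size), cap)


def simulate_recording(
    subject_mean_sbp: float,
    subject_arv_target: float,
    cfg: SimConfig,
    rng: np.random.Generator,
    subject_id: str = "S0",
    dbp_mean: float | None = None,
    dbp_arv_target: float | None = None,
    hr_mean: float | None = None,
) -> ABPRecording:
    """One 24-h recording whose expected realized ARV matches the target.

    Times are a jittered grid over 24 h.  Systolic values follow an AR(1)
    walk around ``subject_mean_sbp`` plus white measurement noise of sd
    ``cfg.within_subject_sd``; the AR increment scale is solved in closed
    form so that the expected mean absolute successive difference equals
    ``subject_arv_target``.  Diastolic defaults to a fixed physiologic
    offset below systolic with its own calibrated walk.  Setting
    ``within_subject_sd = 0`` (with ``readings_jitter = 0``) yields a
    constant, evenly sampled series with realized ARV 0.
    """
    if subject_mean_sbp <= 0 or subject_arv_target < 0:
        raise ValidationError("targets must be positive")
    if dbp_mean is None:
        dbp_mean = subject_mean_sbp - 57.7
    if dbp_arv_target is None:
        dbp_arv_target = 0.75 * subject_arv_target
    if hr_mean is None:
        hr_mean = 73.7

    if cfg.readings_jitter > 0:
        n = int(np.clip(round(rng.normal(cfg.readings_mean, cfg.readings_jitter)),
                        max(2, cfg.readings_mean - 3 * cfg.readings_jitter),
                        cfg.readings_mean + 3 * cfg.readings_jitter))
        n = max(n, 2)
        spacing = 1440.0 / n
        times = spacing * (np.arange(n) + 0.5 + rng.uniform(-0.3, 0.3, size=n))
    else:
        n = cfg.readings_mean
        spacing = 1440.0 / n
        times = spacing * (np.arange(n) + 0.5)

    def channel(mean: float, arv: float, lo: float, hi: float) -> np.ndarray:
        if cfg.within_subject_sd == 0 or arv == 0:
            return np.full(n, mean)
        # E|diff| = arv  =>  Var(diff) = pi/2 * arv^2, split between white
        # measurement noise (contributes 2*ws^2) and the AR(1) walk
        v_diff = np.pi / 2.0 * arv**2
        ws2 = min(cfg.within_subject_sd**2, v_diff / 4.0)
        v_ar_diff = v_diff - 2.0 * ws2
        rho = cfg.ar_coef
        var_stat = v_ar_diff / (2.0 * (1.0 - rho))
        if mean - 3.0 * np.sqrt(var_stat) < lo or mean + 3.0 * np.sqrt(var_stat) > hi:
            raise ValidationError(
                f"ARV target {arv} unattainable within ({lo}, {hi}) around {mean}"
            )
        innov = rng.normal(0.0, np.sqrt(var_stat * (1.0 - rho**2)), size=n)
        innov[0] = rng.normal(0.0, np.sqrt(var_stat))
        walk = lfilter([1.0], [1.0, -rho], innov)
        white = rng.normal(0.0, np.sqrt(ws2), size=n)
        return np.clip(mean + walk + white, lo, hi)

    sbp = channel(subject_mean_sbp, subject_arv_target, 70.6, 259.4)
    dbp = channel(dbp_mean, dbp_arv_target, 40.6, 149.4)
    dbp = np.minimum(dbp, sbp - 3.0)
    hr = (
        np.full(n, hr_mean)
        if cfg.within_subject_sd == 0
        else np.clip(hr_mean + rng.normal(0.0, 4.0, size=n), 40.0, 150.0)
    )
    return ABPRecording.from_arrays(subject_id, times, sbp, dbp, hr)


def _draw_features(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """True subject-level features with the planted class structure."""
    n = cfg.n_subjects
    is_pos = rng.random(n) < cfg.prevalence

    feats = {}
    for col in FEATURE_COLUMNS:
        mu, sd = _BASE_MARGINALS[col]
        if col == "sbp_wbp":
            sd = cfg.between_subject_sd
        lo, hi = _CLIPS[col]
        feats[col] = np.clip(rng.normal(mu, sd, size=n), lo, hi)

    conds = cfg.true_rule.conditions
    m = len(conds)
    # negatives violate a nonempty subset of conditions: each single
    # condition with weight 0.6/m, all conditions jointly with weight 0.4
    fail_choice = rng.random(n)
    fail_all = fail_choice < 0.4
    single = np.clip(((fail_choice - 0.4) / 0.6 * m).astype(int), 0, m - 1)

    for j, cond in enumerate(conds):
        lo, hi = _CLIPS[cond.attribute]
        sat_scale = _SATISFY_SCALE.get(cond.attribute, 1.0)
        vio_scale = _VIOLATE_SCALE.get(cond.attribute, 1.0)
        margin = _MARGIN.get(cond.attribute, 0.05 * sat_scale)
        sign = 1.0 if cond.relation == ">=" else -1.0
        t = cond.threshold
        sat_cap = ((hi - t) if sign > 0 else (t - lo)) - margin
        vio_cap = ((t - lo) if sign > 0 else (hi - t)) - margin
        sat = t + sign * (margin + _trunc_exp(rng, sat_scale, max(sat_cap, 1e-6), n))
        vio = t - sign * (margin + _trunc_exp(rng, vio_scale, max(vio_cap, 1e-6), n))
        col = feats[cond.attribute]
        violate_here = ~is_pos & (fail_all | (single == j))
        satisfy_here = is_pos | (~is_pos & ~fail_all & (single != j))
        col[violate_here] = vio[violate_here]
        col[satisfy_here] = sat[satisfy_here]

    # keep ARV targets reachable by the recording generator; for rules of
    # the default shape this can only push negatives further negative
    feats["sbp_arv"] = np.minimum(
        feats["sbp_arv"], _max_attainable_arv(feats["sbp_wbp"], 70.6, 259.4, cfg.ar_coef)
    )
    feats["dbp_arv"] = np.minimum(
        feats["dbp_arv"], _max_attainable_arv(feats["dbp_wbp"], 40.6, 149.4, cfg.ar_coef)
    )

    df = pd.DataFrame(feats)
    truth_label = cfg.true_rule.predict(df)
    if not np.array_equal(truth_label.astype(bool), is_pos):
        raise ValidationError(
            "planted rule is unattainable within physiologic ranges; "
            "adjust true_rule or the generator clips"
        )
    df["true_label"] = truth_label
    return df


def simulate_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Full cohort: truth table, subjects table and (optionally) recordings."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    if cfg.prevalence * n < 1:
        import warnings

        warnings.warn("expected fewer than one positive subject", stacklevel=2)

    ids = [f"S{i:05d}" for i in range(n)]
    truth = _draw_features(cfg, rng)
    truth.insert(0, "id", ids)

    flips = rng.random(n) < cfg.label_noise
    truth["outcome"] = (truth["true_label"].to_numpy().astype(bool) ^ flips).astype(int)

    subjects = pd.DataFrame(
        {
            "id": ids,
            "sex": (rng.random(n) < 0.321).astype(int),
            "age": np.clip(rng.normal(67.1, 8.0, size=n), 56.0, 95.0),
            "bmi": truth["bmi"].to_numpy(),
            "cholesterol": truth["cholesterol"].to_numpy(),
            "outcome": truth["outcome"].to_numpy(),
        }
    )

    recordings = None
    if cfg.generate_recordings:
        recordings = []
        for i, sid in enumerate(ids):
            srng = _subject_rng(cfg.seed, sid)
            recordings.append(
                simulate_recording(
                    float(truth["sbp_wbp"].iat[i]),
                    float(truth["sbp_arv"].iat[i]),
                    cfg,
                    srng,
                    subject_id=sid,
                    dbp_mean=float(truth["dbp_wbp"].iat[i]),
                    dbp_arv_target=float(truth["dbp_arv"].iat[i]),
                    hr_mean=float(truth["heart_rate"].iat[i]),
                )
            )

    return SyntheticCohort(recordings=recordings, subjects=subjects, truth=truth)


def inject_artifacts(
    cohort: SyntheticCohort,
    outlier_rate: float = 0.02,
    missing_chol_rate: float = 0.011,
    rng: np.random.Generator | None = None,
) -> SyntheticCohort:
    """Corrupt a random fraction of readings and blank cholesterol cells.

    Corrupted readings receive a physiologically impossible value on one
    channel (systolic 300 or diastolic 25 mmHg), so the quality filter
    should remove exactly them.  Ground-truth lists of corrupted readings
    and blanked subjects are recorded on the returned cohort.
    """
    if not 0.0 <= outlier_rate <= 1.0 or not 0.0 <= missing_chol_rate <= 1.0:
        raise ValidationError("rates must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(0)

    corrupted: list[tuple[str, float]] = []
    new_recordings = None
    if cohort.recordings is not None:
        new_recordings = []
        for rec in cohort.recordings:
            if outlier_rate == 0:
                new_recordings.append(rec)
                continue
            times = rec.times
            sbp = rec.systolic.copy()
            dbp = rec.diastolic.copy()
            hr = rec.heart_rate
            mask = rng.random(len(rec)) < outlier_rate
            for i in np.flatnonzero(mask):
                if rng.random() < 0.5:
                    sbp[i] = 300.0
                else:
                    dbp[i] = 25.0
                corrupted.append((rec.subject_id, float(times[i])))
            new_recordings.append(
                ABPRecording.from_arrays(
                    rec.subject_id, times, sbp, dbp, hr, rec.max_duration_min
                )
            )

    subjects = cohort.subjects.copy()
    blank = rng.random(len(subjects)) < missing_chol_rate
    subjects.loc[blank, "cholesterol"] = np.nan
    missing_ids = subjects.loc[blank, "id"].tolist()

    return SyntheticCohort(
        recordings=new_recordings,
        subjects=subjects,
        truth=cohort.truth,
        corrupted_readings=corrupted,
        missing_cholesterol=missing_ids,
    )


def feature_table(subjects: pd.DataFrame, indices: pd.DataFrame) -> pd.DataFrame:
    """Merge subject covariates with per-recording indices into the minable
    table: seven attribute columns plus ``outcome``, indexed by subject id."""
    merged = subjects.merge(indices, on="id", how="inner")
    out = pd.DataFrame(
        {
            "id": merged["id"],
            "bmi": merged["bmi"],
            "cholesterol": merged["cholesterol"],
            "heart_rate": merged["hr_mean"],
            "sbp_wbp": merged["sbp_wbp"],
            "dbp_wbp": merged["dbp_wbp"],
            "sbp_arv": merged["sbp_arv"],
            "dbp_arv": merged["dbp_arv"],
            "outcome": merged["outcome"],
        }
    )
    return out
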