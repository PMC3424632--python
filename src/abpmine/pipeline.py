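"""End-to-end orchestration: simulate/load -> preprocess -> indices -> fit ->
evaluate, emitting one machine-readable JSON report."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, indices, io, preprocess, rules, simulate
from .config import RunConfig
from .exceptions import ABPMineError

log = logging.getLogger("abpmine")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ABPMineError as exc:
                raise ABPMineError(f"stage {name!r}: {exc}") from exc

        return wrapper

    return deco


def simulate_stage(cfg: RunConfig) -> simulate.SyntheticCohort:
    sim = cfg.simulate
    sim_cfg = simulate.SimConfig(
        n_subjects=sim.n_subjects,
        prevalence=sim.prevalence,
        readings_mean=sim.readings_mean,
        readings_jitter=sim.readings_jitter,
        label_noise=sim.label_noise,
        between_subject_sd=sim.between_subject_sd,
        within_subject_sd=sim.within_subject_sd,
        seed=cfg.seed,
    )
    cohort = simulate.simulate_cohort(sim_cfg)
    if sim.outlier_rate > 0 or sim.missing_chol_rate > 0:
        cohort = simulate.inject_artifacts(
            cohort,
            outlier_rate=sim.outlier_rate,
            missing_chol_rate=sim.missing_chol_rate,
            rng=np.random.default_rng([cfg.seed, 1]),
        )
    return cohort


@_stage("preprocess")
def preprocess_stage(cfg: RunConfig, recordings, subjects):
    pp = cfg.preprocess
    report = preprocess.QCReport()
    clean = preprocess.preprocess_recordings(
        recordings,
        min_readings=pp.min_readings,
        sbp_range=(pp.sbp_low, pp.sbp_high),
        dbp_range=(pp.dbp_low, pp.dbp_high),
        report=report,
    )
    kept_ids = {rec.subject_id for rec in clean}
    subjects = subjects[subjects["id"].isin(kept_ids)].reset_index(drop=True)
    subjects = preprocess.impute_missing(subjects, pp.impute_attribute, report=report)
    log.info(
        "preprocess: %d/%d subjects kept, %d readings discarded, %d cells imputed",
        report.subjects_out,
        report.subjects_in,
        report.readings_discarded_outlier,
        report.missing_imputed,
    )
    return clean, subjects, report


@_stage("indices")
def indices_stage(cfg: RunConfig, recordings) -> pd.DataFrame:
    return indices.indices_table(recordings, convention=cfg.indices.wbp_convention)


@_stage("fit")
def fit_stage(cfg: RunConfig, features: pd.DataFrame, labels):
    assoc = rules.select_attributes(features, labels, alpha=cfg.fit.alpha)
    chosen = [a for a in assoc if a.selected or a.attribute in cfg.fit.force_attrs]
    chosen = [
        a if a.selected else rules.AttributeAssociation(
            a.attribute, a.coefficient, a.odds_ratio, a.p_value, a.direction,
            selected=True, converged=a.converged)
        for a in chosen
    ]
    rule = rules.build_rule(
        features,
        labels,
        chosen,
        joint=cfg.fit.joint,
        epsilon=cfg.fit.epsilon,
        mode=cfg.fit.mode,
    )
    return assoc, rule


@_stage("evaluate")
def evaluate_stage(cfg: RunConfig, features: pd.DataFrame, labels):
    cv = evaluation.cross_validate(
        features,
        labels,
        k=cfg.evaluate.k,
        seed=cfg.seed,
        alpha=cfg.fit.alpha,
        joint=cfg.fit.joint,
        epsilon=cfg.fit.epsilon,
        force_attrs=tuple(cfg.fit.force_attrs),
        mode=cfg.fit.mode,
    )
    nb = None
    if cfg.evaluate.baseline == "nb":
        nb = evaluation.naive_bayes_baseline(
            features, labels, k=cfg.evaluate.k, seed=cfg.seed
        )
    return cv, nb


def run_pipeline(
    cfg: RunConfig,
    readings_path: str | None = None,
    subjects_path: str | None = None,
) -> dict:
    """Execute all stages and return the JSON-ready report.

    Without input paths a synthetic cohort is generated under ``cfg.seed``;
    with paths the on-disk tables are used instead.
    """
    if readings_path is None:
        cohort = simulate_stage(cfg)
        recordings, subjects = cohort.recordings, cohort.subjects
    else:
        recordings = io.read_readings(readings_path)
        subjects = io.read_subjects(subjects_path)

    recordings, subjects, qc = preprocess_stage(cfg, recordings, subjects)
    idx = indices_stage(cfg, recordings)
    table = simulate.feature_table(subjects, idx)
    features = table[list(simulate.FEATURE_COLUMNS)]
    labels = table["outcome"].to_numpy()

    assoc, rule = fit_stage(cfg, features, labels)
    cv, nb = evaluate_stage(cfg, features, labels)

    report = {
        "config": cfg.to_dict(),
        "qc": qc.to_dict(),
        "associations": [
            {
                "attribute": a.attribute,
                "coefficient": a.coefficient,
                "odds_ratio": a.odds_ratio,
                "p_value": a.p_value,
                "direction": a.direction,
                "selected": a.selected,
            }
            for a in assoc
        ],
        "rule": rule.to_dict(),
        "cross_validation": cv.to_dict(),
    }
    if nb is not None:
        report["naive_bayes"] = {
            "pooled_confusion": nb.to_dict(),
            "pooled_metrics": evaluation.metrics(nb).to_dict(),
        }
    return report


def write_report(report: dict, cfg: RunConfig, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
    cfg.save(out / "effective_config.yaml")
    return path
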