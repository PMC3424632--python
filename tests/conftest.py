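import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from abpmine import ABPRecording, SimConfig, simulate_cohort


def make_recording(subject_id="S1", times=None, sbp=None, dbp=None, hr=None):
    if times is None:
        times = [0.0, 30.0, 60.0]
    if sbp is None:
        sbp = [120.0, 130.0, 110.0]
    if dbp is None:
        dbp = [80.0, 85.0, 75.0]
    return ABPRecording.from_arrays(subject_id, times, sbp, dbp, hr)


@pytest.fixture
def recording():
    return make_recording()


@pytest.fixture
def readings_csv(tmp_path):
    path = tmp_path / "readings.csv"
    path.write_text(
        "subject_id,time_min,sbp,dbp,hr\n"
        "S1,0,120,80,70\n"
        "S1,30,130,85,72\n"
        "S1,60,110,75,68\n"
    )
    return path


@pytest.fixture
def subjects_csv(tmp_path):
    path = tmp_path / "subjects.csv"
    path.write_text(
        "id,sex,age,bmi,cholesterol,outcome\n"
        "S1,0,67,27.1,5.5,0\n"
        "S2,1,70,30.2,,1\n"
    )
    return path


@pytest.fixture(scope="session")
def truth_cohort():
    """Mid-size noisy cohort, truth features only (fast)."""
    cfg = SimConfig(n_subjects=800, label_noise=0.05, seed=11, generate_recordings=False)
    return simulate_cohort(cfg)


def truth_features(cohort):
    feats = cohort.truth[
        ["bmi", "cholesterol", "heart_rate", "sbp_wbp", "dbp_wbp", "sbp_arv", "dbp_arv"]
    ]
    return feats, cohort.truth["outcome"].to_numpy()


@pytest.fixture(scope="session")
def noiseless_cohort():
    cfg = SimConfig(n_subjects=1200, label_noise=0.0, seed=5, generate_recordings=False)
    return simulate_cohort(cfg)
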