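"""Run configuration: YAML-backed, strictly validated.

Every default matches the printed analysis constants where one exists
(40-reading floor, 70-260 / 40-150 mmHg validity ranges, alpha 0.01,
10 folds).  Unknown keys are rejected so typos fail loudly, and the
effective merged config can be serialised next to each report for
provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import yaml

from .exceptions import ValidationError


def _from_dict(cls, data: dict):
    if data is None:
        return cls()
    if not isinstance(data, dict):
        raise ValidationError(f"{cls.__name__}: expected a mapping, got {type(data).__name__}")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"{cls.__name__}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        sub = _SECTION_TYPES.get(name)
        if sub is not None:
            value = _from_dict(sub, value)
        if name == "force_attrs" and isinstance(value, (list, tuple)):
            value = tuple(value)
        kwargs[name] = value
    return cls(**kwargs)


@dataclass
class PreprocessConfig:
    min_readings: int = 40
    sbp_low: float = 70.0
    sbp_high: float = 260.0
    dbp_low: float = 40.0
    dbp_high: float = 150.0
    impute_attribute: str = "cholesterol"


@dataclass
class IndicesConfig:
    wbp_convention: str = "trapezoid"


@dataclass
class FitConfig:
    alpha: float = 0.01
    epsilon: float = 0.01
    joint: bool = True
    force_attrs: tuple = ()
    mode: str = "greedy"


@dataclass
class EvaluateConfig:
    k: int = 10
    baseline: str = "nb"


@dataclass
class SimulateConfig:
    n_subjects: int = 551
    prevalence: float = 61.0 / 551.0
    readings_mean: int = 65
    readings_jitter: int = 8
    label_noise: float = 0.05
    between_subject_sd: float = 10.0
    within_subject_sd: float = 2.0
    outlier_rate: float = 0.0
    missing_chol_rate: float = 0.0


_SECTION_TYPES = {
    "preprocess": PreprocessConfig,
    "indices": IndicesConfig,
    "fit": FitConfig,
    "evaluate": EvaluateConfig,
    "simulate": SimulateConfig,
}


@dataclass
class RunConfig:
    seed: int = 42
    out_dir: str = "out"
    verbosity: int = 1
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    indices: IndicesConfig = field(default_factory=IndicesConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _from_dict(cls, data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fit"]["force_attrs"] = list(d["fit"]["force_attrs"])
        return d

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
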