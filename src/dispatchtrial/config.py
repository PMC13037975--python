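"""Generator / pipeline configuration.

One :class:`GeneratorConfig` drives every stage of the synthetic pipeline.
Defaults are the package's calibrated study conditions: a low-acuity adult
dispatch cohort (median age 77, 45 % female, mean NEWS ~ 3), resource-
constrained situations (RCS) of 2–4 patients with mean size ~ 2.2,
ambulance-stage vital-sign missingness of 11–14 % per component falling to
3.7–4.8 % after hospital supplementation, a dispatch nurse whose pairwise
accuracy against subsequent NEWS is ~ 63 %, a risk model at ~ 70 %, and an
intervention-arm rate of following the model calibrated so that observed
model agreement lands near 81 %.

The single global ``seed`` is expanded into independent per-stage streams
(:meth:`GeneratorConfig.rng`), so any one stage can be reproduced without
re-running the others.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml


class ConfigError(ValueError):
    """Invalid configuration value."""


# stage names -> fixed offsets for per-stage independent RNG streams
_STAGES = (
    "cohort",
    "vitals",
    "predictions",
    "randomize",
    "decisions",
    "missingness",
    "optout",
    "impute",
    "analysis",
)

#: ambulance-stage per-component missingness (the two printed extremes are
#: pulse 11.0 % and temperature 14.2 %; the rest interpolate between them)
DEFAULT_MISS_AMBULANCE = {
    "respiratory_rate": 0.120,
    "spo2": 0.125,
    "on_oxygen": 0.118,
    "systolic_bp": 0.115,
    "pulse": 0.110,
    "consciousness": 0.112,
    "temperature": 0.142,
}

#: final rates after hospital supplementation (extremes: consciousness
#: 3.7 %, temperature 4.8 %)
DEFAULT_MISS_FINAL = {
    "respiratory_rate": 0.042,
    "spo2": 0.044,
    "on_oxygen": 0.043,
    "systolic_bp": 0.040,
    "pulse": 0.039,
    "consciousness": 0.037,
    "temperature": 0.048,
}


@dataclass
class GeneratorConfig:
    """Study conditions for one simulated trial."""

    # cohort structure
    n_rcs: int = 1570  # base RCS; with repeat re-rolls ~1,845 randomizations
    rcs_size_dist: dict = field(default_factory=lambda: {2: 0.82, 3: 0.14, 4: 0.04})
    n_months: int = 46
    model_update_months: tuple = (10, 40)
    site2_start_month: int = 40
    site2_prob: float = 0.8  # P(site 2 | month >= site2_start_month)

    # latent severity and perception
    acuity_sd: float = 1.0
    nurse_noise_sd: float = 5.0
    nurse_vitals_weight: float = 0.8
    model_noise_sd: float = 1.7
    band_slope: float = 0.8
    baseline_news: float = 3.0

    # behavior
    compliance_prob: float = 0.615  # P(defer to model | intervention); see risk.calibrate_compliance
    optout_prob_per_patient: float = 0.08
    repeat_randomization_prob: float = 0.20  # control-arm re-roll probability
    repeat_intervention_factor: float = 0.75  # intervention re-roll = prob * factor
    repeat_grow_prob: float = 0.40  # P(a re-roll adds a late-arriving patient)

    # demographics
    female_prob: float = 0.45
    age_median: float = 77.0

    # missingness
    miss_rate_ambulance: dict = field(default_factory=lambda: dict(DEFAULT_MISS_AMBULANCE))
    miss_rate_final: dict = field(default_factory=lambda: dict(DEFAULT_MISS_FINAL))
    miss_acuity_beta: float = 0.3  # MAR tilt: sicker patients slightly more complete
    mcar: bool = False

    # imputation
    m_imputations: int = 10
    mice_iterations: int = 10
    mice_engine: str = "rf"  # "rf" (random-forest conditional draws) or "pmm"

    seed: int = 0

    def __post_init__(self):
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for name in (
            "compliance_prob",
            "optout_prob_per_patient",
            "repeat_randomization_prob",
            "repeat_grow_prob",
            "female_prob",
            "site2_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} must lie in [0, 1]")
        if self.n_rcs <= 0:
            raise ConfigError("n_rcs must be positive")
        if not self.rcs_size_dist:
            raise ConfigError("rcs_size_dist must be non-empty")
        if any(int(s) < 2 for s in self.rcs_size_dist):
            raise ConfigError("RCS sizes must be >= 2 (a comparison needs two patients)")
        if any(p < 0 for p in self.rcs_size_dist.values()):
            raise ConfigError("rcs_size_dist probabilities must be non-negative")
        tot = float(sum(self.rcs_size_dist.values()))
        if abs(tot - 1.0) > 1e-8:
            raise ConfigError(f"rcs_size_dist must sum to 1 (got {tot})")
        for mapname in ("miss_rate_ambulance", "miss_rate_final"):
            rates = getattr(self, mapname)
            for comp, r in rates.items():
                if not (0.0 <= r <= 1.0):
                    raise ConfigError(f"{mapname}[{comp}]={r} must lie in [0, 1]")
        for comp, r in self.miss_rate_final.items():
            amb = self.miss_rate_ambulance.get(comp, 0.0)
            if r > amb + 1e-12:
                raise ConfigError(
                    f"final missingness for {comp} ({r}) exceeds ambulance-stage rate ({amb})"
                )
        if self.m_imputations < 1:
            raise ConfigError("m_imputations must be >= 1")
        if self.mice_engine not in ("rf", "pmm"):
            raise ConfigError(f"unknown mice_engine {self.mice_engine!r}")
        if self.acuity_sd <= 0:
            raise ConfigError("acuity_sd must be positive")

    # -- RNG streams -----------------------------------------------------
    def rng(self, stage: str) -> np.random.Generator:
        """Independent, reproducible generator for one pipeline stage."""
        if stage not in _STAGES:
            raise ConfigError(f"unknown stage {stage!r}; expected one of {_STAGES}")
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STAGES.index(stage),))
        return np.random.default_rng(ss)

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["model_update_months"] = list(self.model_update_months)
        d["rcs_size_dist"] = {int(k): float(v) for k, v in self.rcs_size_dist.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "rcs_size_dist" in d:
            d["rcs_size_dist"] = {int(k): float(v) for k, v in d["rcs_size_dist"].items()}
        if "model_update_months" in d:
            d["model_update_months"] = tuple(d["model_update_months"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
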