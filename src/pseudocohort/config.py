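"""Simulation and run configuration objects (YAML round-trippable)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from ._time import as_date


class ConfigurationError(ValueError):
    """Raised for invalid simulation or run configuration."""


def _default_covariates() -> dict:
    # Marginal laws for the family-level covariate set plus optional
    # log-hazard-ratio effects of covariates on the abuse hazard
    # (all zero by default: no confounding unless asked for).
    return {
        "income_mean": 120.0,
        "income_sd": 80.0,
        "neighborhood_mean": 105.0,
        "neighborhood_sd": 35.0,
        "p_tertiary_education": 0.35,
        "p_psychiatric": 0.04,
        "p_interparental_violence": 0.003,
        "p_substance_abuse": 0.01,
        "p_parental_maltreatment": 0.06,
        "p_immigrant": 0.25,
        "p_refugee": 0.03,
        "reconstituted_probs": [0.9, 0.06, 0.04],  # biological / step / adopted-foster
        "abuse_log_hr": {},  # e.g. {"education": -0.2, "income": -0.001}
        "missing_rates": {
            "neighborhood_resources": 0.0,
            "reconstituted_family": 0.0,
            "education": 0.0,
            "income": 0.0,
            "immigration_background": 0.0,
        },
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic registry generator.

    Rates are per person-year (diagnoses/prescriptions: per parent-year;
    hazards: per child-year).  ``true_log_rr`` maps category name to the
    log relative risk of abuse while the family is exposed in it.
    """

    n_families: int = 500
    study_start: str = "1997-01-01"
    study_end: str = "2018-12-31"
    burn_in_years: int = 3
    category_diagnosis_rates: dict = field(default_factory=dict)
    prescription_rates: dict = field(default_factory=dict)
    true_log_rr: dict = field(default_factory=dict)
    baseline_abuse_hazard: float = 0.003
    death_hazard: float = 0.0005
    censoring_hazards_by_period: list = field(default_factory=lambda: [0.005, 0.01, 0.02])
    covariate_distributions: dict = field(default_factory=_default_covariates)
    p_two_parents: float = 0.85
    # P(1, 2, 3-5, 6+ children); counts inside 3-5 / 6+ drawn uniformly
    family_size_probs: list = field(default_factory=lambda: [0.46, 0.37, 0.164, 0.006])
    family_frailty_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_families < 0:
            raise ConfigurationError("n_families must be >= 0")
        if as_date(self.study_end) <= as_date(self.study_start):
            raise ConfigurationError("study_end must be after study_start")
        if self.burn_in_years < 0:
            raise ConfigurationError("burn_in_years must be >= 0")
        for name, rates in (
            ("category_diagnosis_rates", self.category_diagnosis_rates),
            ("prescription_rates", self.prescription_rates),
        ):
            for key, r in rates.items():
                if r < 0:
                    raise ConfigurationError(f"{name}[{key!r}] must be >= 0")
        for key, b in self.true_log_rr.items():
            if not np.isfinite(b):
                raise ConfigurationError(f"true_log_rr[{key!r}] must be finite")
        for r in [self.baseline_abuse_hazard, self.death_hazard, *self.censoring_hazards_by_period]:
            if r < 0:
                raise ConfigurationError("hazards must be >= 0")
        if abs(sum(self.family_size_probs) - 1.0) > 1e-9:
            raise ConfigurationError("family_size_probs must sum to 1")

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
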