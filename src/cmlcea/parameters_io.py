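"""Model configuration: loading, validation, provenance and life tables.

The configuration collects every scalar input of the model: the cohort
definition (start age, sex mix, first-line treatment distribution), the
clinical transition parameters that are plain probabilities (DMR
maintenance, line sequencing), utilities per health state and arm,
resource-use frequencies with unit costs, drug prices, monitoring
schedules, discount rates and the time horizon.  Survival-curve inputs are
referenced by role/treatment and handled by :mod:`cmlcea.survival`.

Validation is strict: probability distributions that do not sum to one are
rejected, never silently renormalized, and out-of-range utilities or
negative costs are errors naming the offending field.  Every parameter can
carry a provenance tag (literature table, assumption, or synthetic) in
``config.provenance``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

#: The fixed health-state set of the model.
STATES = ("CML-CP", "DMR", "TFR", "AP/BC", "Death")

#: Treatment lines; BSC (best supportive care) is imatinib + interferon.
TKI_LINES = ("imatinib", "nilotinib", "dasatinib")
LINES = TKI_LINES + ("BSC",)

SCHEMA_VERSION = "1.0"


class ConfigValidationError(Exception):
    """A configuration value violates a domain constraint."""


class NormalizationError(ConfigValidationError):
    """A probability distribution does not sum to one."""


def _check_distribution(name: str, dist: Dict[str, float], tol: float = 1e-9) -> None:
    total = sum(dist.values())
    if abs(total - 1.0) > tol:
        raise NormalizationError(
            f"{name} must sum to 1 (got {total:.12g}); refusing to renormalize"
        )
    for key, value in dist.items():
        if not 0.0 <= value <= 1.0:
            raise ConfigValidationError(f"{name}[{key}] = {value} outside [0, 1]")


class ModelConfig(BaseModel):
    """Full parameter set for one model run (both arms share it).

    Monetary amounts are 2020 Chinese Yuan (CNY); durations are years.
    """

    model_config = ConfigDict(validate_assignment=False)

    schema_version: str = SCHEMA_VERSION

    # Horizon and discounting
    time_horizon_years: int = 50
    cycle_length_years: float = 1.0
    discount_rate_costs: float = 0.03
    discount_rate_benefits: float = 0.03

    # Cohort
    male_fraction: float = 0.62
    start_age_years: float = 41.0

    # Clinical transition inputs
    first_line_distribution: Dict[str, float]
    dmr_maintain_prob: Dict[str, float]
    dmr_achievement_multiplier: Dict[str, float] = {
        "imatinib": 1.0, "nilotinib": 1.0, "dasatinib": 1.0,
    }
    apbc_treatment_mix: Dict[str, float]
    line_sequencing: Dict[str, Dict[str, float]]

    # Utilities per state, by arm
    utilities_monitored: Dict[str, float]
    utilities_unmonitored: Dict[str, float]

    # Monitoring schedules: name -> {band -> tests/year}; bands are
    # "CML-CP", "DMR", "TFR:year1", "TFR:later".
    monitoring_schedules: Dict[str, Dict[str, float]]
    monitoring_schedule: str = "base"
    monitoring_test_cost: float = 250.0

    # Follow-up resource use and unit costs
    resource_use: Dict[str, Dict[str, float]]
    unit_costs: Dict[str, float]

    # Drugs: list prices per cost period (default monthly)
    drug_costs: Dict[str, float]
    drug_cost_period_multiplier: float = 12.0
    interferon_admin_cost: float = 0.0

    # Progressed disease and end of life
    hospital_days_apbc: float = 36.0
    hospital_day_cost: float = 300.0
    terminal_care_cost: float = 0.0
    terminal_care_trigger: Literal["all", "apbc"] = "all"

    # Survival-curve references: "ROLE/label" -> file path or identifier
    curve_refs: Dict[str, str] = {}

    # Provenance tags: field path -> citation / "assumption" / "synthetic"
    provenance: Dict[str, str] = {}

    @model_validator(mode="after")
    def _domain_checks(self) -> "ModelConfig":
        _check_distribution("first_line_distribution", self.first_line_distribution)
        _check_distribution("apbc_treatment_mix", self.apbc_treatment_mix)
        for line, row in self.line_sequencing.items():
            _check_distribution(f"line_sequencing[{line}]", row)
        for name, probs in (
            ("dmr_maintain_prob", self.dmr_maintain_prob),
            ("first_line_distribution", self.first_line_distribution),
        ):
            for key, value in probs.items():
                if not 0.0 <= value <= 1.0:
                    raise ConfigValidationError(
                        f"{name}[{key}] = {value} outside [0, 1]"
                    )
        for arm, utils in (
            ("utilities_monitored", self.utilities_monitored),
            ("utilities_unmonitored", self.utilities_unmonitored),
        ):
            for state, value in utils.items():
                if state not in STATES:
                    raise ConfigValidationError(
                        f"{arm} names unknown health state {state!r}"
                    )
                if not 0.0 <= value <= 1.0:
                    raise ConfigValidationError(
                        f"{arm}[{state}] = {value} outside [0, 1]"
                    )
        for state in self.resource_use:
            if state not in STATES:
                raise ConfigValidationError(
                    f"resource_use names unknown health state {state!r}"
                )
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ConfigValidationError("male_fraction outside [0, 1]")
        for name, value in (
            ("start_age_years", self.start_age_years),
            ("time_horizon_years", self.time_horizon_years),
            ("discount_rate_costs", self.discount_rate_costs),
            ("discount_rate_benefits", self.discount_rate_benefits),
            ("monitoring_test_cost", self.monitoring_test_cost),
            ("hospital_days_apbc", self.hospital_days_apbc),
            ("hospital_day_cost", self.hospital_day_cost),
            ("terminal_care_cost", self.terminal_care_cost),
            ("interferon_admin_cost", self.interferon_admin_cost),
            ("drug_cost_period_multiplier", self.drug_cost_period_multiplier),
        ):
            if value < 0:
                raise ConfigValidationError(f"{name} = {value} must be >= 0")
        for table_name, table in (
            ("unit_costs", self.unit_costs),
            ("drug_costs", self.drug_costs),
        ):
            for key, value in table.items():
                if value < 0:
                    raise ConfigValidationError(
                        f"{table_name}[{key}] = {value} must be >= 0"
                    )
        for state, profile in self.resource_use.items():
            for res, freq in profile.items():
                if freq < 0:
                    raise ConfigValidationError(
                        f"resource_use[{state}][{res}] = {freq} must be >= 0"
                    )
        if self.monitoring_schedule not in self.monitoring_schedules:
            raise ConfigValidationError(
                f"monitoring_schedule {self.monitoring_schedule!r} not among "
                f"defined schedules {sorted(self.monitoring_schedules)}"
            )
        return self

    @property
    def monitoring_frequency(self) -> Dict[str, float]:
        """Tests/year per band under the active monitoring schedule."""
        return self.monitoring_schedules[self.monitoring_schedule]


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML/JSON model configuration.

    Raises :class:`NormalizationError` when a probability distribution does
    not sum to one and :class:`ConfigValidationError` for any other domain
    violation; schema/type problems surface as pydantic ``ValidationError``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ModelConfig.model_validate(raw)


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Serialize a configuration to YAML; round-trips through load_config."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)


@dataclass
class LifeTable:
    """Age-by-sex annual all-cause death probabilities.

    Lookup clamps beyond the last tabulated age, so the oldest qx applies
    to every later age.
    """

    ages: np.ndarray
    q_male: np.ndarray
    q_female: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.q_male = np.asarray(self.q_male, dtype=float)
        self.q_female = np.asarray(self.q_female, dtype=float)
        if not (len(self.ages) == len(self.q_male) == len(self.q_female)):
            raise ConfigValidationError("life table columns have unequal length")
        if np.any(np.diff(self.ages) != 1):
            raise ConfigValidationError("life table ages must be contiguous")
        for name, q in (("q_male", self.q_male), ("q_female", self.q_female)):
            if np.any((q < 0) | (q > 1)):
                raise ConfigValidationError(f"{name} has values outside [0, 1]")

    def lookup(self, age: float, sex: str) -> float:
        if age < 0:
            raise ValueError(f"age must be >= 0, got {age}")
        idx = int(np.clip(math.floor(age) - self.ages[0], 0, len(self.ages) - 1))
        return float(self.q_male[idx] if sex == "male" else self.q_female[idx])

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        """Read a headered CSV with columns age, sex, qx."""
        df = pd.read_csv(path)
        males = df[df["sex"] == "male"].sort_values("age")
        females = df[df["sex"] == "female"].sort_values("age")
        if not np.array_equal(males["age"].values, females["age"].values):
            raise ConfigValidationError("male and female age ranges differ")
        return cls(males["age"].values, males["qx"].values, females["qx"].values)

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for sex, q in (("male", self.q_male), ("female", self.q_female)):
            for age, qx in zip(self.ages, q):
                rows.append({"age": int(age), "sex": sex, "qx": qx})
        pd.DataFrame(rows).to_csv(path, index=False)


def blended_mortality(life_table: LifeTable, age: float, male_fraction: float) -> float:
    """Sex-averaged annual death probability at a given attained age.

    Returns ``male_fraction * q_male(age) + (1 - male_fraction) * q_female(age)``.
    The sex mix is held fixed over the horizon (a simplification: the model
    does not track differential male/female survivorship within the cohort).
    """
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    if not 0.0 <= male_fraction <= 1.0:
        raise ValueError("male_fraction outside [0, 1]")
    qm = life_table.lookup(age, "male")
    qf = life_table.lookup(age, "female")
    return male_fraction * qm + (1.0 - male_fraction) * qf
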