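"""Synthetic stand-ins for every model input that is not a printed value.

The real analysis digitized Kaplan-Meier figures from the literature for
time to treatment discontinuation (TTD), progression-free survival (PFS),
MR4.5 achievement, TFR relapse-free survival and AP/BC overall survival,
and used a national all-cause life table.  None of those coordinates are
published, so this module generates them: survival curves sampled from
known parametric families with small Gaussian "digitization" noise
(ground truth retained for recovery tests), and a Gompertz-Makeham life
table.  All printed scalar inputs (treatment mix, maintenance
probabilities, utilities, monitoring frequencies, resource use, unit
costs, drug prices) are embedded verbatim in the base-case fixture.

All randomness flows through an explicit seeded generator; the same seed
always yields the same fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import numpy as np

from .parameters_io import LifeTable, ModelConfig, save_config
from .survival import (
    DigitizedCurve,
    ParametricSurvival,
    isotonic_decreasing,
    survival_at,
    curve_to_csv,
)

__all__ = [
    "CurveGenerator", "generate_km_curve", "generate_life_table",
    "make_base_fixture", "FixtureBundle", "write_fixture_files",
    "CURVE_TRUTH",
]


@dataclass(frozen=True)
class CurveGenerator:
    """Specification of one synthetic digitized curve."""

    truth: ParametricSurvival
    n_points: int = 40
    noise_sd: float = 0.005    # survival-probability units (digitization error)
    censor_time: float = 10.0  # years of figure follow-up
    seed: int = 0


def generate_km_curve(
    gen: CurveGenerator, role: str = "", treatment: str = ""
) -> DigitizedCurve:
    """Emit noisy coordinates on the true S(t), clipped and isotonic-repaired.

    Points sit at evenly spaced times over (0, censor_time].  Deterministic
    for a fixed seed; with ``noise_sd = 0`` the points lie exactly on the
    generating survival function.
    """
    if gen.censor_time <= 0:
        raise ValueError("censor_time must be > 0")
    if gen.n_points < 3:
        raise ValueError("n_points must be >= 3")
    if gen.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(gen.seed)
    times = np.linspace(gen.censor_time / gen.n_points, gen.censor_time, gen.n_points)
    s_true = np.asarray(survival_at(gen.truth, times))
    s = s_true + rng.normal(0.0, gen.noise_sd, size=gen.n_points)
    s = np.clip(s, 0.0, 1.0)
    s = np.clip(isotonic_decreasing(s), 0.0, 1.0)
    return DigitizedCurve(tuple(times), tuple(s), role=role, treatment=treatment)


def generate_life_table(
    makeham_male: Tuple[float, float, float],
    makeham_female: Tuple[float, float, float],
    max_age: int = 100,
) -> LifeTable:
    """Gompertz-Makeham life table: qx = 1 - exp(-(A + B e^{C age})).

    A is the age-independent background hazard, B the senescent hazard at
    age 0 and C its exponential age slope.  Raises if any qx leaves [0, 1].
    """
    ages = np.arange(0, max_age + 1, dtype=float)

    def q(coefs):
        a, b, c = coefs
        hazard = a + b * np.exp(c * ages)
        qx = -np.expm1(-hazard)
        if np.any((qx < 0) | (qx > 1)):
            raise ValueError("Makeham coefficients give qx outside [0, 1]")
        return qx

    return LifeTable(ages, q(makeham_male), q(makeham_female))


# Ground-truth families behind the synthetic digitized curves.  Chosen for
# clinical plausibility: TTD medians of roughly 8-12 years on first-line
# TKIs, slow progression from CML-CP (~2%/yr on TKIs, faster on BSC),
# MR4.5 achievement reaching ~45-60% by five years (slower with imatinib
# than second-generation TKIs), molecular relapse after TKI stop
# front-loaded in the first year with roughly half relapse-free
# afterwards, and a median AP/BC survival near one year.
CURVE_TRUTH: Dict[Tuple[str, str], ParametricSurvival] = {
    ("TTD", "imatinib"): ParametricSurvival("weibull", (0.9, 12.0)),
    ("TTD", "nilotinib"): ParametricSurvival("weibull", (1.0, 10.0)),
    ("TTD", "dasatinib"): ParametricSurvival("weibull", (1.0, 9.0)),
    ("PFS", "imatinib"): ParametricSurvival("exponential", (0.020,)),
    ("PFS", "nilotinib"): ParametricSurvival("exponential", (0.015,)),
    ("PFS", "dasatinib"): ParametricSurvival("exponential", (0.015,)),
    # hydroxyurea + interferon PFS stands in for BSC, as the model assigns
    ("PFS", "BSC"): ParametricSurvival("exponential", (0.080,)),
    ("MR45", "imatinib"): ParametricSurvival("log-normal", (1.80, 1.20)),
    ("MR45", "nilotinib"): ParametricSurvival("log-normal", (1.40, 1.10)),
    ("MR45", "dasatinib"): ParametricSurvival("log-normal", (1.45, 1.10)),
    ("TFR", ""): ParametricSurvival("log-logistic", (0.40, 1.65)),
    ("OS", ""): ParametricSurvival("weibull", (1.2, 1.5)),
}

_CENSOR_TIMES = {"TTD": 10.0, "PFS": 10.0, "MR45": 10.0, "TFR": 6.0, "OS": 6.0}

# Synthetic all-cause mortality (Gompertz-Makeham), male hazard above female.
MAKEHAM_MALE = (6.0e-4, 2.5e-5, 0.095)
MAKEHAM_FEMALE = (4.0e-4, 1.2e-5, 0.098)

_RESOURCES = (
    "Nurse-led visit", "Haematologist-led visit", "X-rays/radiography",
    "CT scans", "Full blood count", "Cytogenetic analysis",
    "Bone marrow aspiration", "FISH test", "Blood film exam",
    "Blood chemistry", "Blood transfusion", "Platelet transfusion",
    "Cytochemistry analysis",
)

_UNIT_COSTS = dict(zip(_RESOURCES, (
    30.0, 40.0, 70.0, 170.0, 20.0, 490.0, 100.0, 800.0, 100.0, 350.0,
    450.0, 1420.0, 100.0,
)))

_FREQ = {
    "CML-CP": (1.52, 6.88, 0.0, 0.0, 7.88, 2.96, 1.20, 2.24, 4.36, 7.52,
               0.04, 0.0, 0.20),
    "DMR": (1.16, 3.72, 0.0, 0.0, 4.52, 2.32, 0.12, 0.88, 2.00, 4.52,
            0.04, 0.0, 0.0),
    "TFR": (1.16, 3.72, 0.0, 0.0, 4.52, 2.32, 0.12, 0.88, 2.00, 4.52,
            0.04, 0.0, 0.0),
    "AP/BC": (2.04, 14.52, 3.96, 0.96, 17.52, 3.60, 3.60, 0.52, 8.76,
              12.60, 7.92, 1.20, 0.48),
}


@dataclass
class FixtureBundle:
    """A complete self-contained model input set."""

    config: ModelConfig
    curves: Dict[Tuple[str, str], DigitizedCurve]
    curve_truth: Dict[Tuple[str, str], ParametricSurvival]
    life_table: LifeTable
    seed: int


def base_case_config() -> ModelConfig:
    """The base-case configuration with every printed input embedded."""
    lit = "literature table"
    return ModelConfig(
        time_horizon_years=50,
        cycle_length_years=1.0,
        discount_rate_costs=0.03,
        discount_rate_benefits=0.03,
        male_fraction=0.62,
        start_age_years=41.0,
        first_line_distribution={"imatinib": 0.75, "nilotinib": 0.13,
                                 "dasatinib": 0.12},
        dmr_maintain_prob={"imatinib": 0.57, "nilotinib": 0.77,
                           "dasatinib": 0.72},
        apbc_treatment_mix={"imatinib": 0.5, "dasatinib": 0.5},
        line_sequencing={
            "imatinib": {"nilotinib": 0.5, "dasatinib": 0.5},
            "nilotinib": {"dasatinib": 1.0},
            "dasatinib": {"BSC": 1.0},
        },
        utilities_monitored={"CML-CP": 0.854, "DMR": 0.940, "TFR": 1.000,
                             "AP/BC": 0.595},
        utilities_unmonitored={"CML-CP": 0.854, "AP/BC": 0.595},
        monitoring_schedules={
            "base": {"CML-CP": 2.87, "DMR": 2.5, "TFR:year1": 9.0,
                     "TFR:later": 2.0},
            # ELN guideline schedule: monthly for the first 6 months of
            # TFR, 8-weekly for months 6-12, 12-weekly thereafter
            "eln": {"CML-CP": 2.87, "DMR": 2.5, "TFR:year1": 9.25,
                    "TFR:later": 52.0 / 12.0},
        },
        monitoring_schedule="base",
        monitoring_test_cost=250.0,
        resource_use={
            state: dict(zip(_RESOURCES, freqs)) for state, freqs in _FREQ.items()
        },
        unit_costs=dict(_UNIT_COSTS),
        drug_costs={"imatinib": 586.0, "nilotinib": 11364.0,
                    "dasatinib": 7500.0, "interferon": 912.88},
        drug_cost_period_multiplier=12.0,
        interferon_admin_cost=1095.75,
        hospital_days_apbc=36.0,
        hospital_day_cost=300.0,
        terminal_care_cost=30000.0,
        terminal_care_trigger="all",
        curve_refs={f"{role}/{label}": f"curve_{role.lower()}_{label or 'all'}.csv"
                    for role, label in CURVE_TRUTH},
        provenance={
            "first_line_distribution": lit,
            "dmr_maintain_prob": lit,
            "apbc_treatment_mix": "assumption (clinician input)",
            "line_sequencing": "assumption (clinician input)",
            "utilities_monitored": lit,
            "utilities_unmonitored": "assumption: same as monitored",
            "monitoring_schedules.base": "key-opinion-leader input",
            "monitoring_schedules.eln": "guideline schedule, annualized",
            "resource_use": "NICE technology appraisal",
            "unit_costs": lit,
            "drug_costs": lit,
            "interferon_admin_cost": lit,
            "hospital_days_apbc": lit,
            "hospital_day_cost": lit,
            "monitoring_test_cost": lit,
            "terminal_care_cost": "assumption",
            "drug_cost_period_multiplier": "assumption (monthly list price)",
            "curve_refs": "synthetic",
        },
    )


def make_base_fixture(seed: int = 20210) -> FixtureBundle:
    """Generate the full base-case fixture: config, curves and life table.

    Curve noise and point counts emulate figure digitization (40 points,
    survival-probability noise sd 0.005).  The ground-truth families are
    kept alongside the noisy curves for parameter-recovery tests.
    """
    seq = np.random.SeedSequence(seed)
    child_seeds = seq.generate_state(len(CURVE_TRUTH))
    curves = {}
    for ((role, label), truth), s in zip(sorted(CURVE_TRUTH.items()), child_seeds):
        gen = CurveGenerator(
            truth=truth, n_points=40, noise_sd=0.005,
            censor_time=_CENSOR_TIMES[role], seed=int(s) % (2**31),
        )
        curves[(role, label)] = generate_km_curve(gen, role=role, treatment=label)
    life_table = generate_life_table(MAKEHAM_MALE, MAKEHAM_FEMALE)
    return FixtureBundle(
        config=base_case_config(),
        curves=curves,
        curve_truth=dict(CURVE_TRUTH),
        life_table=life_table,
        seed=seed,
    )


def write_fixture_files(bundle: FixtureBundle, outdir: str | Path) -> Path:
    """Write config YAML, curve CSVs and life-table CSV to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (role, label), curve in bundle.curves.items():
        curve_to_csv(curve, outdir / bundle.config.curve_refs[f"{role}/{label}"])
    bundle.life_table.to_csv(outdir / "life_table.csv")
    save_config(bundle.config, outdir / "base_case.yaml")
    return outdir
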