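"""Scenario analyses and one-way deterministic sensitivity analysis.

The packaged scenario library covers the standard robustness checks for
this model class: cohort
composition (all male), discount rates (0%, 5%), alternative first-line
treatment mix, alternative line-sequencing splits, multiplicative
reductions in DMR achievement and maintenance, a uniform utility
reduction, the ELN guideline monitoring schedule, and drug-price
discounts.  One-way sensitivity varies single numeric parameters by
+/-25% of their base value (probabilities and utilities clamp to [0, 1]
with a logged clamp) and reports tornado entries sorted by bar width.

Scenario overrides are applied to a deep copy of the configuration and
re-validated before any simulation runs; the base configuration is never
mutated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .cohort_engine import CurveSet
from .comparator import Comparison, compare
from .parameters_io import LifeTable, ModelConfig
from .pipeline import run_strategy

__all__ = [
    "Override", "ScenarioSpec", "TornadoEntry", "apply_overrides",
    "run_scenario", "run_owsa", "scenario_library", "DEFAULT_OWSA_PARAMETERS",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Override:
    """One parameter override: set a value or scale it multiplicatively.

    ``path`` is dotted (attribute, then dict keys), e.g.
    ``"utilities_monitored.CML-CP"``.  With ``mode="mul"`` on a mapping,
    every numeric leaf is scaled.
    """

    path: str
    value: float | dict | str
    mode: str = "set"  # "set" | "mul"

    def __post_init__(self):
        if self.mode not in ("set", "mul"):
            raise ValueError(f"unknown override mode {self.mode!r}")


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    overrides: Tuple[Override, ...] = ()


@dataclass
class TornadoEntry:
    """One bar of the tornado diagram."""

    parameter: str
    low_result: float    # outcome at -25%
    high_result: float   # outcome at +25%
    base_result: float
    bar_width: float     # |high - low|


class OverrideError(ValueError):
    """An override path does not resolve or has the wrong type."""


def _resolve(container, parts: Sequence[str], path: str):
    for part in parts:
        if isinstance(container, dict):
            if part not in container:
                raise OverrideError(f"override path {path!r}: no key {part!r}")
            container = container[part]
        else:
            raise OverrideError(f"override path {path!r}: {part!r} not reachable")
    return container


def _scale_leaves(obj, factor: float):
    if isinstance(obj, dict):
        return {k: _scale_leaves(v, factor) for k, v in obj.items()}
    if isinstance(obj, (int, float)) and not isinstance(obj, bool):
        return obj * factor
    raise OverrideError(f"cannot scale non-numeric value {obj!r}")


def get_parameter(config: ModelConfig, path: str):
    parts = path.split(".")
    if not hasattr(config, parts[0]):
        raise OverrideError(f"override path {path!r}: no field {parts[0]!r}")
    return _resolve(getattr(config, parts[0]), parts[1:], path)


def apply_overrides(config: ModelConfig, overrides: Sequence[Override]) -> ModelConfig:
    """Return a new validated configuration with the overrides applied."""
    data = config.model_dump()
    for ov in overrides:
        parts = ov.path.split(".")
        if parts[0] not in data:
            raise OverrideError(f"override path {ov.path!r}: no field {parts[0]!r}")
        parent = _resolve(data, parts[:-1], ov.path) if len(parts) > 1 else data
        key = parts[-1]
        if isinstance(parent, dict) and key not in parent:
            raise OverrideError(f"override path {ov.path!r}: no key {key!r}")
        current = parent[key]
        if ov.mode == "mul":
            if isinstance(current, dict):
                parent[key] = _scale_leaves(current, float(ov.value))
            elif isinstance(current, (int, float)):
                parent[key] = current * float(ov.value)
            else:
                raise OverrideError(f"cannot scale {ov.path!r} of type "
                                    f"{type(current).__name__}")
        else:
            parent[key] = ov.value
    return ModelConfig.model_validate(data)


def run_scenario(
    base: ModelConfig,
    spec: ScenarioSpec,
    curves: CurveSet,
    life_table: LifeTable,
) -> Comparison:
    """Re-run the full two-arm pipeline under a scenario's overrides.

    Overrides are validated (and the config rebuilt) before any cohort is
    simulated; the base configuration is left untouched.
    """
    config = apply_overrides(base, spec.overrides)
    mon = run_strategy("monitored", config, curves, life_table)
    unm = run_strategy("unmonitored", config, curves, life_table)
    return compare(mon, unm)


def scenario_library() -> List[ScenarioSpec]:
    """The packaged 20-scenario library.

    Note: "imatinib->nilotinib 50%" equals the base case (the base routing
    is already 50/50); it is kept as an explicit identity scenario so the
    routing sweep is complete.
    """
    scen: List[ScenarioSpec] = [
        ScenarioSpec("All males", (Override("male_fraction", 1.0),)),
        ScenarioSpec("No discounting", (
            Override("discount_rate_costs", 0.0),
            Override("discount_rate_benefits", 0.0),
        )),
        ScenarioSpec("5% discount", (
            Override("discount_rate_costs", 0.05),
            Override("discount_rate_benefits", 0.05),
        )),
        ScenarioSpec("First-line imatinib 30%, nilotinib 40%, rest dasatinib", (
            Override("first_line_distribution",
                     {"imatinib": 0.30, "nilotinib": 0.40, "dasatinib": 0.30}),
        )),
    ]
    for pct in (40, 50, 30):
        scen.append(ScenarioSpec(
            f"Movement from imatinib to nilotinib {pct}%",
            (Override("line_sequencing.imatinib",
                      {"nilotinib": pct / 100, "dasatinib": 1 - pct / 100}),),
        ))
    scen.append(ScenarioSpec(
        "Movement from nilotinib to dasatinib 90%",
        (Override("line_sequencing.nilotinib", {"dasatinib": 0.9, "BSC": 0.1}),),
    ))
    for pct in (10, 20, 30):
        scen.append(ScenarioSpec(
            f"{pct}% reduction in achieving DMR",
            (Override("dmr_achievement_multiplier", 1 - pct / 100, mode="mul"),),
        ))
    for pct in (-10, -20, -30, 10):
        label = f"{abs(pct)}% {'less' if pct < 0 else 'higher'} DMR maintenance"
        scen.append(ScenarioSpec(
            label,
            (Override("dmr_maintain_prob", 1 + pct / 100, mode="mul"),),
        ))
    scen.append(ScenarioSpec(
        "10% less utility", (
            Override("utilities_monitored", 0.9, mode="mul"),
            Override("utilities_unmonitored", 0.9, mode="mul"),
        ),
    ))
    scen.append(ScenarioSpec(
        "ELN guideline monitoring frequency",
        (Override("monitoring_schedule", "eln"),),
    ))
    for pct in (10, 20, 30):
        scen.append(ScenarioSpec(
            f"{pct}% discount on drug costs",
            (Override("drug_costs", 1 - pct / 100, mode="mul"),),
        ))
    return scen


#: Parameter paths varied by default in the one-way sensitivity analysis.
DEFAULT_OWSA_PARAMETERS: Tuple[str, ...] = (
    "utilities_monitored.CML-CP",
    "utilities_unmonitored.CML-CP",
    "utilities_monitored.AP/BC",
    "utilities_unmonitored.AP/BC",
    "utilities_monitored.TFR",
    "utilities_monitored.DMR",
    "dmr_maintain_prob.nilotinib",
    "dmr_maintain_prob.dasatinib",
    "dmr_achievement_multiplier.imatinib",
    "drug_costs.nilotinib",
    "start_age_years",
    "discount_rate_benefits",
)

_CLAMPED_PREFIXES = (
    "utilities_monitored", "utilities_unmonitored", "dmr_maintain_prob",
    "male_fraction", "first_line_distribution",
)


def _owsa_value(path: str, base_value: float, factor: float) -> float:
    value = base_value * factor
    if path.split(".")[0] in _CLAMPED_PREFIXES and not 0.0 <= value <= 1.0:
        clamped = min(1.0, max(0.0, value))
        logger.info("OWSA clamp: %s %.6g -> %.6g", path, value, clamped)
        value = clamped
    return value


def run_owsa(
    base: ModelConfig,
    parameters: Sequence[str],
    curves: CurveSet,
    life_table: LifeTable,
    outcome: str = "delta_qaly",
    variation: float = 0.25,
) -> List[TornadoEntry]:
    """One-way +/-25% sensitivity analysis over the given parameter paths.

    ``outcome`` selects the tornado axis: any numeric attribute of
    :class:`Comparison` (``delta_qaly``, ``delta_cost``, ...).  Entries
    are sorted by descending bar width.
    """
    base_cmp = run_scenario(base, ScenarioSpec("base"), curves, life_table)
    base_result = getattr(base_cmp, outcome)
    entries: List[TornadoEntry] = []
    for path in parameters:
        base_value = get_parameter(base, path)
        if not isinstance(base_value, (int, float)) or isinstance(base_value, bool):
            raise OverrideError(f"OWSA parameter {path!r} is not numeric")
        results = {}
        for sign, factor in (("low", 1 - variation), ("high", 1 + variation)):
            value = _owsa_value(path, float(base_value), factor)
            cmp_ = run_scenario(
                base, ScenarioSpec(f"{path} {sign}", (Override(path, value),)),
                curves, life_table,
            )
            results[sign] = getattr(cmp_, outcome)
        entries.append(TornadoEntry(
            parameter=path,
            low_result=results["low"],
            high_result=results["high"],
            base_result=base_result,
            bar_width=abs(results["high"] - results["low"]),
        ))
    entries.sort(key=lambda e: -e.bar_width)
    return entries
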