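"""Valuation of a cohort trace: life-years, QALYs and costs.

Recurring quantities (occupancy-weighted LY, QALY and annual costs) are
half-cycle corrected by the trapezoid of consecutive cycle occupancies;
one-off terminal-care costs attach to incident deaths without correction.
Discounting divides the cycle-k trapezoid (spanning cycles k -> k+1) by
(1 + r)^(k+1), i.e. an end-of-cycle convention.

Cost categories follow the per-state decomposition of the model's results
tables: per-state "core" costs (drug acquisition and administration, plus
the AP/BC hospital stay), pooled follow-up resource-use costs, pooled
molecular-monitoring costs, and terminal care.  TFR accrues no drug cost;
BSC is costed as imatinib + interferon (drug + administration); the AP/BC
drug cost is the configured imatinib/dasatinib mix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

from .cohort_engine import Compartment, CohortTrace
from .parameters_io import ModelConfig, TKI_LINES

__all__ = [
    "CostBreakdown", "StrategyResult", "followup_cost_per_year",
    "annual_state_cost", "annual_cost_components", "accumulate",
]

HEALTH_STATES = ("CML-CP", "DMR", "TFR", "AP/BC")
COST_CATEGORIES = HEALTH_STATES + ("terminal care", "follow-up", "molecular monitoring")


class CostingError(KeyError):
    """A resource or utility needed for valuation is missing."""


def followup_cost_per_year(
    resource_profile: Dict[str, float], unit_costs: Dict[str, float]
) -> float:
    """Annual follow-up cost: dot product of use frequencies and unit costs.

    Hospital stay and molecular monitoring are costed separately and must
    not appear in the profile.  A resource without a unit cost is an error.
    """
    total = 0.0
    for resource, freq in resource_profile.items():
        if resource not in unit_costs:
            raise CostingError(f"no unit cost for resource {resource!r}")
        total += freq * unit_costs[resource]
    return total


def _annual_drug_cost(compartment: Compartment, config: ModelConfig) -> float:
    mult = config.drug_cost_period_multiplier
    state, line = compartment.state, compartment.line
    if state == "TFR":
        return 0.0
    if state == "AP/BC":
        return mult * sum(
            frac * config.drug_costs[drug]
            for drug, frac in config.apbc_treatment_mix.items()
        )
    # CML-CP or DMR (patients in DMR remain on the same therapy)
    if line in TKI_LINES:
        return mult * config.drug_costs[line]
    if line == "BSC":
        return mult * (
            config.drug_costs["imatinib"]
            + config.drug_costs["interferon"]
            + config.interferon_admin_cost
        )
    raise CostingError(f"unknown treatment line {line!r}")


def _monitoring_band(compartment: Compartment) -> str | None:
    state = compartment.state
    if state in ("CML-CP", "DMR"):
        return state
    if state == "TFR":
        return "TFR:year1" if compartment.state_time == 0 else "TFR:later"
    return None  # AP/BC and Death: no scheduled molecular testing


def annual_cost_components(
    compartment: Compartment, config: ModelConfig, monitored: bool
) -> Dict[str, float]:
    """Annual cost of a compartment split into core / follow-up / monitoring.

    "core" is drug acquisition (+ administration, + AP/BC hospital stay),
    attributed to the compartment's health state in the decomposition.
    """
    state = compartment.state
    if state == "Death":
        return {"core": 0.0, "follow-up": 0.0, "monitoring": 0.0}
    core = _annual_drug_cost(compartment, config)
    if state == "AP/BC":
        core += config.hospital_days_apbc * config.hospital_day_cost
    followup = followup_cost_per_year(
        config.resource_use.get(state, {}), config.unit_costs
    )
    monitoring = 0.0
    if monitored:
        band = _monitoring_band(compartment)
        if band is not None:
            freq = config.monitoring_frequency.get(band, 0.0)
            monitoring = freq * config.monitoring_test_cost
    return {"core": core, "follow-up": followup, "monitoring": monitoring}


def annual_state_cost(
    compartment: Compartment, config: ModelConfig, monitored: bool = True
) -> float:
    """Total annual cost of occupying a compartment (all categories)."""
    return sum(annual_cost_components(compartment, config, monitored).values())


@dataclass
class CostBreakdown:
    """Costs per category, discounted and undiscounted (CNY)."""

    undiscounted: Dict[str, float] = field(default_factory=dict)
    discounted: Dict[str, float] = field(default_factory=dict)

    def total(self, discounted: bool = True) -> float:
        table = self.discounted if discounted else self.undiscounted
        return sum(table.values())


@dataclass
class StrategyResult:
    """Lifetime outcomes of one strategy arm."""

    arm: str
    ly_undiscounted: Dict[str, float]
    ly_discounted: Dict[str, float]
    qaly_undiscounted: Dict[str, float]
    qaly_discounted: Dict[str, float]
    costs: CostBreakdown
    trace: CohortTrace

    def total_ly(self, discounted: bool = True) -> float:
        return sum((self.ly_discounted if discounted else self.ly_undiscounted).values())

    def total_qaly(self, discounted: bool = True) -> float:
        return sum(
            (self.qaly_discounted if discounted else self.qaly_undiscounted).values()
        )

    def total_cost(self, discounted: bool = True) -> float:
        return self.costs.total(discounted)


def accumulate(trace: CohortTrace, config: ModelConfig, arm: str) -> StrategyResult:
    """Value a trace: half-cycle-corrected LY/QALY and cost accounting.

    ``arm`` ("monitored"/"unmonitored") selects the utility set and whether
    monitoring costs accrue.  Raises if an occupied health state has no
    utility in the arm's utility table.
    """
    if arm not in ("monitored", "unmonitored"):
        raise ValueError(f"unknown arm {arm!r}")
    monitored = arm == "monitored"
    utilities = (
        config.utilities_monitored if monitored else config.utilities_unmonitored
    )
    rb, rc = config.discount_rate_benefits, config.discount_rate_costs

    ly_u = {s: 0.0 for s in HEALTH_STATES}
    ly_d = {s: 0.0 for s in HEALTH_STATES}
    q_u = {s: 0.0 for s in HEALTH_STATES}
    q_d = {s: 0.0 for s in HEALTH_STATES}
    cost_u = {c: 0.0 for c in COST_CATEGORIES}
    cost_d = {c: 0.0 for c in COST_CATEGORIES}

    # per-cycle flow rates (per year of occupancy) at each trace row
    n = trace.n_cycles
    state_occ = [
        {s: trace.state_occupancy(k, s) for s in HEALTH_STATES} for k in range(n + 1)
    ]
    flow_rows = []
    for k in range(n + 1):
        flows = {c: 0.0 for c in COST_CATEGORIES}
        for comp, occ in trace.rows[k].items():
            if comp.state == "Death" or occ == 0.0:
                continue
            parts = annual_cost_components(comp, config, monitored)
            flows[comp.state] += occ * parts["core"]
            flows["follow-up"] += occ * parts["follow-up"]
            flows["molecular monitoring"] += occ * parts["monitoring"]
        flow_rows.append(flows)

    for state in HEALTH_STATES:
        occupied = any(row[state] > 0 for row in state_occ)
        if occupied and state not in utilities:
            raise CostingError(f"no {arm} utility for occupied state {state!r}")

    dt = config.cycle_length_years
    for k in range(n):
        df_b = (1.0 + rb) ** -(k + 1)
        df_c = (1.0 + rc) ** -(k + 1)
        for state in HEALTH_STATES:
            trap = 0.5 * (state_occ[k][state] + state_occ[k + 1][state]) * dt
            ly_u[state] += trap
            ly_d[state] += trap * df_b
            u = utilities.get(state, 0.0)
            q_u[state] += trap * u
            q_d[state] += trap * u * df_b
        for cat in COST_CATEGORIES:
            if cat == "terminal care":
                continue
            trap = 0.5 * (flow_rows[k][cat] + flow_rows[k + 1][cat]) * dt
            cost_u[cat] += trap
            cost_d[cat] += trap * df_c
        # one-off terminal care on incident deaths, no half-cycle correction
        deaths = trace.deaths_by_source[k]
        if config.terminal_care_trigger == "apbc":
            dying = deaths.get("AP/BC", 0.0)
        else:
            dying = sum(deaths.values())
        tc = dying * config.terminal_care_cost
        cost_u["terminal care"] += tc
        cost_d["terminal care"] += tc * df_c

    return StrategyResult(
        arm=arm,
        ly_undiscounted=ly_u, ly_discounted=ly_d,
        qaly_undiscounted=q_u, qaly_discounted=q_d,
        costs=CostBreakdown(undiscounted=cost_u, discounted=cost_d),
        trace=trace,
    )
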