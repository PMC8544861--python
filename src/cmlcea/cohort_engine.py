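"""Discrete-time semi-Markov cohort simulation.

The cohort is partitioned into compartments keyed by (health state,
treatment line, state-time).  State-time is the semi-Markov clock: cycles
on the current treatment line for CML-CP and DMR, cycles since TFR entry
for TFR, cycles since progression for AP/BC.  Background mortality is
indexed by attained cohort age.

Within a cycle, the competing events from a CML-CP compartment are applied
as a conditional cascade in a fixed order -- background death, progression
to AP/BC (PFS curve), DMR achievement (MR4.5 curve, monitored TKI lines
only), treatment discontinuation (TTD curve, routed by the line-sequencing
matrix) -- each acting on the survivors of the previous event.  This
guarantees probabilities in [0, 1] and exact conservation of the cohort.

Arm differences: under molecular monitoring CML-CP patients on a TKI can
achieve DMR (a one-cycle tunnel that resolves to TFR with the line's
maintenance probability, otherwise back to CML-CP on the same line); TFR
patients relapse back to CML-CP restarting the same line.  Without
monitoring DMR and TFR are unreachable; the same TTD and PFS curves drive
line switching and progression.  AP/BC is absorbing until death, with its
overall-survival hazard floored at background mortality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Tuple

import numpy as np
import pandas as pd

from .parameters_io import LifeTable, ModelConfig, blended_mortality, TKI_LINES
from .survival import ParametricSurvival, cycle_probability

__all__ = [
    "Compartment", "CohortTrace", "CurveSet", "compartment_transitions",
    "step_monitored", "step_unmonitored", "run_cohort",
]

DEATH = "Death"
APBC = "AP/BC"


class Compartment(NamedTuple):
    """One (state, line, state_time) cell of the cohort partition."""

    state: str       # CML-CP, DMR, TFR, AP/BC, Death
    line: str        # imatinib / nilotinib / dasatinib / BSC / none
    state_time: int  # semi-Markov clock, cycles


DEATH_COMP = Compartment(DEATH, "none", 0)

Occupancy = Dict[Compartment, float]


class EngineError(RuntimeError):
    """A pathological transition probability was encountered."""


@dataclass
class CurveSet:
    """Fitted survival models keyed by role.

    ``ttd``, ``pfs``, ``mr45`` map treatment-line labels to models; ``tfr``
    and ``apbc_os`` are single curves.  Per-cycle probabilities are
    precomputed and cached up to the horizon.
    """

    ttd: Dict[str, ParametricSurvival]
    pfs: Dict[str, ParametricSurvival]
    mr45: Dict[str, ParametricSurvival]
    tfr: ParametricSurvival
    apbc_os: ParametricSurvival
    _cache: Dict[Tuple[str, str], np.ndarray] = field(default_factory=dict, repr=False)

    def probs(self, role: str, label: str, horizon: int, dt: float = 1.0) -> np.ndarray:
        key = (role, label)
        cached = self._cache.get(key)
        if cached is not None and len(cached) >= horizon + 1:
            return cached
        model = {
            "TTD": lambda: self.ttd[label],
            "PFS": lambda: self.pfs[label],
            "MR45": lambda: self.mr45[label],
            "TFR": lambda: self.tfr,
            "OS": lambda: self.apbc_os,
        }[role]()
        p = np.array(
            [cycle_probability(model, k, dt) for k in range(horizon + 1)]
        )
        self._cache[key] = p
        return p


@dataclass
class CohortTrace:
    """Per-cycle compartment occupancy for one strategy arm."""

    rows: List[Occupancy]                 # length horizon + 1
    ages: List[float]                     # attained age at each cycle index
    deaths_by_source: List[Dict[str, float]]  # per cycle: source state -> dying fraction
    arm: str

    @property
    def n_cycles(self) -> int:
        return len(self.rows) - 1

    def state_occupancy(self, cycle: int, state: str) -> float:
        return sum(v for c, v in self.rows[cycle].items() if c.state == state)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: cycle, state, line, state_time, occupancy, age."""
        records = []
        for k, row in enumerate(self.rows):
            for comp, occ in sorted(row.items()):
                records.append(
                    {"cycle": k, "state": comp.state, "line": comp.line,
                     "state_time": comp.state_time, "occupancy": occ,
                     "age": self.ages[k]}
                )
        return pd.DataFrame(records)


def _check_prob(p: float, what: str, comp: Compartment) -> float:
    if not (0.0 - 1e-12 <= p <= 1.0 + 1e-12):
        raise EngineError(f"{what} probability {p} outside [0,1] for {comp}")
    return min(1.0, max(0.0, p))


def compartment_transitions(
    comp: Compartment,
    age: float,
    config: ModelConfig,
    curves: CurveSet,
    life_table: LifeTable,
    monitored: bool,
) -> Dict[Compartment, float]:
    """Destination distribution for one compartment over one cycle.

    The returned probabilities sum to 1 exactly (the residual stays in the
    aged copy of the compartment).  This single function defines the
    transition rules for both the deterministic cohort step and the
    microsimulation oracle.
    """
    horizon = config.time_horizon_years
    q_bg = blended_mortality(life_table, age, config.male_fraction)
    t = comp.state_time
    out: Dict[Compartment, float] = {}

    if comp.state == DEATH:
        return {DEATH_COMP: 1.0}

    if comp.state == APBC:
        p_os = _check_prob(curves.probs("OS", "", horizon)[min(t, horizon)],
                           "AP/BC OS", comp)
        p_death = max(p_os, q_bg)  # cannot out-survive the general population
        out[DEATH_COMP] = p_death
        out[Compartment(APBC, "none", t + 1)] = 1.0 - p_death
        return out

    if comp.state == "DMR":
        m = config.dmr_maintain_prob[comp.line]
        out[DEATH_COMP] = q_bg
        alive = 1.0 - q_bg
        out[Compartment("TFR", comp.line, 0)] = alive * m
        out[Compartment("CML-CP", comp.line, t + 1)] = alive * (1.0 - m)
        return out

    if comp.state == "TFR":
        p_rel = _check_prob(curves.probs("TFR", "", horizon)[min(t, horizon)],
                            "TFR relapse", comp)
        out[DEATH_COMP] = q_bg
        alive = 1.0 - q_bg
        # molecular relapse: restart the same TKI line immediately
        out[Compartment("CML-CP", comp.line, 0)] = alive * p_rel
        out[Compartment("TFR", comp.line, t + 1)] = alive * (1.0 - p_rel)
        return out

    if comp.state != "CML-CP":
        raise EngineError(f"unknown state in {comp}")

    line = comp.line
    k = min(t, horizon)
    out[DEATH_COMP] = q_bg
    remaining = 1.0 - q_bg

    # progression to AP/BC
    p_prog = _check_prob(curves.probs("PFS", line, horizon)[k], "PFS", comp)
    out[Compartment(APBC, "none", 0)] = remaining * p_prog
    remaining *= 1.0 - p_prog

    # DMR achievement (monitored TKI lines only; never from BSC)
    if monitored and line in TKI_LINES:
        mult = config.dmr_achievement_multiplier.get(line, 1.0)
        p_dmr = _check_prob(
            min(1.0, curves.probs("MR45", line, horizon)[k] * mult), "MR4.5", comp
        )
        if p_dmr > 0:
            out[Compartment("DMR", line, t + 1)] = remaining * p_dmr
            remaining *= 1.0 - p_dmr

    # treatment discontinuation, routed to the next line (BSC is last line)
    if line in TKI_LINES:
        p_disc = _check_prob(curves.probs("TTD", line, horizon)[k], "TTD", comp)
        if p_disc > 0:
            routing = config.line_sequencing[line]
            for nxt, frac in routing.items():
                if frac > 0:
                    dest = Compartment("CML-CP", nxt, 0)
                    out[dest] = out.get(dest, 0.0) + remaining * p_disc * frac
            remaining *= 1.0 - p_disc

    stay = Compartment("CML-CP", line, t + 1)
    out[stay] = out.get(stay, 0.0) + remaining
    return out


def _step(
    occupancy: Occupancy,
    age: float,
    config: ModelConfig,
    curves: CurveSet,
    life_table: LifeTable,
    monitored: bool,
) -> Tuple[Occupancy, Dict[str, float]]:
    total = sum(occupancy.values())
    if abs(total - 1.0) > 1e-9:
        raise EngineError(f"occupancy sums to {total}, expected 1")
    nxt: Occupancy = {}
    deaths: Dict[str, float] = {}
    for comp, occ in occupancy.items():
        if occ == 0.0:
            continue
        for dest, p in compartment_transitions(
            comp, age, config, curves, life_table, monitored
        ).items():
            if p == 0.0:
                continue
            nxt[dest] = nxt.get(dest, 0.0) + occ * p
            if dest.state == DEATH and comp.state != DEATH:
                deaths[comp.state] = deaths.get(comp.state, 0.0) + occ * p
    return nxt, deaths


def step_monitored(
    occupancy: Occupancy, age: float, config: ModelConfig,
    curves: CurveSet, life_table: LifeTable,
) -> Tuple[Occupancy, Dict[str, float]]:
    """Advance the monitored-arm cohort one cycle.

    Returns the next-cycle occupancy and the incident deaths of the cycle
    broken down by source health state (for terminal-care costing).
    """
    return _step(occupancy, age, config, curves, life_table, monitored=True)


def step_unmonitored(
    occupancy: Occupancy, age: float, config: ModelConfig,
    curves: CurveSet, life_table: LifeTable,
) -> Tuple[Occupancy, Dict[str, float]]:
    """Advance the unmonitored-arm cohort one cycle (DMR/TFR unreachable)."""
    return _step(occupancy, age, config, curves, life_table, monitored=False)


def initial_occupancy(config: ModelConfig) -> Occupancy:
    """Whole cohort in CML-CP at state-time 0, split over first-line TKIs."""
    return {
        Compartment("CML-CP", line, 0): frac
        for line, frac in config.first_line_distribution.items()
        if frac > 0
    }


def run_cohort(
    strategy: str,
    config: ModelConfig,
    curves: CurveSet,
    life_table: LifeTable,
) -> CohortTrace:
    """Run the cohort over the configured horizon for one strategy.

    ``strategy`` is ``"monitored"`` or ``"unmonitored"``.  The trace holds
    ``time_horizon_years + 1`` occupancy rows (including the initial one);
    cohort age advances one year per cycle from ``start_age_years``.
    """
    if strategy not in ("monitored", "unmonitored"):
        raise ValueError(f"unknown strategy {strategy!r}")
    monitored = strategy == "monitored"
    occ = initial_occupancy(config)
    rows = [occ]
    ages = [config.start_age_years]
    deaths: List[Dict[str, float]] = []
    for k in range(config.time_horizon_years):
        age = config.start_age_years + k
        occ, dk = _step(occ, age, config, curves, life_table, monitored)
        rows.append(occ)
        ages.append(config.start_age_years + k + 1)
        deaths.append(dk)
    return CohortTrace(rows=rows, ages=ages, deaths_by_source=deaths, arm=strategy)
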