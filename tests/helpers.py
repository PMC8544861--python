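"""Independent oracles for the cohort engine.

``TreeOracle`` re-implements the within-cycle event cascade as a recursive
enumeration over individual patient paths, with its own closed-form
survival arithmetic -- it never calls the cohort engine, so agreement with
the engine's occupancy is a genuine cross-check of the flow bookkeeping
and the semi-Markov clocks.

``microsimulate`` draws a finite cohort of individual walkers through the
engine's own per-compartment transition distributions (aggregated as
multinomial draws, which is distributionally identical to independent
walkers), providing a Monte-Carlo check of the deterministic aggregation.
"""

import math
from typing import Callable, Dict, Tuple

import numpy as np

from cmlcea.cohort_engine import Compartment, CurveSet, compartment_transitions
from cmlcea.parameters_io import LifeTable, ModelConfig
from cmlcea.synthetic_data import base_case_config

Comp = Tuple[str, str, int]  # (state, line, state_time)

TKIS = ("imatinib", "nilotinib", "dasatinib")


# --- independent closed-form per-cycle probabilities -----------------------

def p_exponential(rate: float) -> float:
    return 1.0 - math.exp(-rate)


def p_weibull(shape: float, scale: float, k: int) -> float:
    h = ((k + 1) / scale) ** shape - (k / scale) ** shape
    return 1.0 - math.exp(-h)


class TreeOracle:
    """Exhaustive path enumeration of the semi-Markov dynamics.

    ``hazards`` maps (role, line) -> callable(k) giving the per-cycle event
    probability at state-time k; roles: TTD, PFS, MR45, TFR, OS.
    """

    def __init__(
        self,
        hazards: Dict[Tuple[str, str], Callable[[int], float]],
        q_background: float,
        maintain: Dict[str, float],
        sequencing: Dict[str, Dict[str, float]],
        monitored: bool,
    ):
        self.h = hazards
        self.q = q_background
        self.maintain = maintain
        self.seq = sequencing
        self.monitored = monitored

    def _branches(self, comp: Comp):
        state, line, t = comp
        q = self.q
        if state == "Death":
            return [(("Death", "none", 0), 1.0)]
        if state == "AP/BC":
            p = max(self.h[("OS", "")](t), q)
            return [(("Death", "none", 0), p), (("AP/BC", "none", t + 1), 1.0 - p)]
        if state == "DMR":
            m = self.maintain[line]
            return [
                (("Death", "none", 0), q),
                (("TFR", line, 0), (1 - q) * m),
                (("CML-CP", line, t + 1), (1 - q) * (1 - m)),
            ]
        if state == "TFR":
            p = self.h[("TFR", "")](t)
            return [
                (("Death", "none", 0), q),
                (("CML-CP", line, 0), (1 - q) * p),
                (("TFR", line, t + 1), (1 - q) * (1 - p)),
            ]
        # CML-CP cascade: death -> progression -> DMR achievement -> TTD
        out = [(("Death", "none", 0), q)]
        alive = 1.0 - q
        p_prog = self.h[("PFS", line)](t)
        out.append((("AP/BC", "none", 0), alive * p_prog))
        alive *= 1.0 - p_prog
        if self.monitored and line in TKIS:
            p_dmr = self.h[("MR45", line)](t)
            out.append((("DMR", line, t + 1), alive * p_dmr))
            alive *= 1.0 - p_dmr
        if line in TKIS:
            p_disc = self.h[("TTD", line)](t)
            for nxt, frac in self.seq[line].items():
                out.append((("CML-CP", nxt, 0), alive * p_disc * frac))
            alive *= 1.0 - p_disc
        out.append((("CML-CP", line, t + 1), alive))
        return out

    def occupancy(self, initial: Dict[Comp, float], n_cycles: int):
        """List of occupancy dicts, cycle 0 .. n_cycles."""
        rows = [dict(initial)]

        def walk(comp: Comp, mass: float, cycle: int, acc):
            if cycle == n_cycles:
                return
            for dest, p in self._branches(comp):
                m = mass * p
                if m == 0.0:
                    continue
                acc[cycle + 1][dest] = acc[cycle + 1].get(dest, 0.0) + m
                walk(dest, m, cycle + 1, acc)

        acc = [dict() for _ in range(n_cycles + 1)]
        for comp, mass in initial.items():
            walk(comp, mass, 0, acc)
        for k in range(1, n_cycles + 1):
            rows.append(acc[k])
        return rows


# --- microsimulation via the engine's transition distributions -------------

def microsimulate(
    config: ModelConfig,
    curves: CurveSet,
    life_table: LifeTable,
    monitored: bool,
    n_walkers: int,
    n_cycles: int,
    seed: int,
):
    """Empirical state occupancy of ``n_walkers`` individual random walks.

    Walkers in the same compartment are exchangeable, so their joint next
    step is drawn as a single multinomial per compartment.  Returns a list
    (cycle 0..n_cycles) of {state: fraction}.
    """
    rng = np.random.default_rng(seed)
    counts: Dict[Compartment, int] = {}
    # initial cohort split over first-line TKIs (largest remainder rounding)
    items = sorted(config.first_line_distribution.items())
    alloc = [int(n_walkers * frac) for _, frac in items]
    while sum(alloc) < n_walkers:
        alloc[int(np.argmax([f for _, f in items]))] += 1
    for (line, _), n in zip(items, alloc):
        if n:
            counts[Compartment("CML-CP", line, 0)] = n

    def state_fracs(c: Dict[Compartment, int]):
        out: Dict[str, float] = {}
        for comp, n in c.items():
            out[comp.state] = out.get(comp.state, 0.0) + n / n_walkers
        return out

    history = [state_fracs(counts)]
    for k in range(n_cycles):
        age = config.start_age_years + k
        nxt: Dict[Compartment, int] = {}
        for comp, n in counts.items():
            dests = compartment_transitions(
                comp, age, config, curves, life_table, monitored
            )
            labels = list(dests)
            draw = rng.multinomial(n, np.array([dests[d] for d in labels]))
            for dest, m in zip(labels, draw):
                if m:
                    nxt[dest] = nxt.get(dest, 0) + int(m)
        counts = nxt
        history.append(state_fracs(counts))
    return history


# --- shared toy model -------------------------------------------------------

TOY_RATES = {
    ("TTD", "imatinib"): 0.25, ("TTD", "nilotinib"): 0.20, ("TTD", "dasatinib"): 0.30,
    ("PFS", "imatinib"): 0.05, ("PFS", "nilotinib"): 0.04, ("PFS", "dasatinib"): 0.06,
    ("PFS", "BSC"): 0.30,
    ("MR45", "imatinib"): 0.15, ("MR45", "nilotinib"): 0.20, ("MR45", "dasatinib"): 0.18,
}
TOY_TFR_WEIBULL = (1.6, 3.0)   # shape, scale: clock-dependent relapse
TOY_OS_WEIBULL = (1.3, 1.2)    # clock-dependent AP/BC mortality
TOY_Q = 0.02                   # flat background annual death probability


def toy_config(horizon: int = 5) -> ModelConfig:
    cfg = base_case_config()
    data = cfg.model_dump()
    data["time_horizon_years"] = horizon
    data["first_line_distribution"] = {
        "imatinib": 0.5, "nilotinib": 0.3, "dasatinib": 0.2,
    }
    return ModelConfig.model_validate(data)


def toy_curveset() -> CurveSet:
    from cmlcea.survival import ParametricSurvival

    exp = lambda r: ParametricSurvival("exponential", (r,))
    return CurveSet(
        ttd={l: exp(TOY_RATES[("TTD", l)]) for l in TKIS},
        pfs={l: exp(TOY_RATES[("PFS", l)]) for l in TKIS + ("BSC",)},
        mr45={l: exp(TOY_RATES[("MR45", l)]) for l in TKIS},
        tfr=ParametricSurvival("weibull", TOY_TFR_WEIBULL),
        apbc_os=ParametricSurvival("weibull", TOY_OS_WEIBULL),
    )


def toy_oracle(monitored: bool) -> TreeOracle:
    hazards: Dict[Tuple[str, str], Callable[[int], float]] = {
        key: (lambda r: (lambda k: p_exponential(r)))(rate)
        for key, rate in TOY_RATES.items()
    }
    hazards[("TFR", "")] = lambda k: p_weibull(*TOY_TFR_WEIBULL, k)
    hazards[("OS", "")] = lambda k: p_weibull(*TOY_OS_WEIBULL, k)
    cfg = toy_config()
    return TreeOracle(
        hazards=hazards,
        q_background=TOY_Q,
        maintain=cfg.dmr_maintain_prob,
        sequencing=cfg.line_sequencing,
        monitored=monitored,
    )
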