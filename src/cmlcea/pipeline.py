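"""Convenience wiring: fit all curves, run both arms, compare."""

from __future__ import annotations

from typing import Dict, Tuple

from .cohort_engine import CurveSet, run_cohort
from .comparator import Comparison, compare
from .economics import StrategyResult, accumulate
from .parameters_io import LifeTable, ModelConfig
from .survival import DigitizedCurve, ParametricSurvival, fit_all_families, select_best
from .synthetic_data import FixtureBundle

__all__ = ["fit_curve_set", "run_strategy", "run_base_case"]


def fit_curve_set(
    curves: Dict[Tuple[str, str], DigitizedCurve]
) -> CurveSet:
    """Fit all families per digitized curve and keep the AIC-best model."""
    best: Dict[Tuple[str, str], ParametricSurvival] = {
        key: select_best(fit_all_families(curve)) for key, curve in curves.items()
    }
    return CurveSet(
        ttd={label: m for (role, label), m in best.items() if role == "TTD"},
        pfs={label: m for (role, label), m in best.items() if role == "PFS"},
        mr45={label: m for (role, label), m in best.items() if role == "MR45"},
        tfr=best[("TFR", "")],
        apbc_os=best[("OS", "")],
    )


def run_strategy(
    arm: str, config: ModelConfig, curves: CurveSet, life_table: LifeTable
) -> StrategyResult:
    """Run the cohort for one arm and value the trace."""
    trace = run_cohort(arm, config, curves, life_table)
    return accumulate(trace, config, arm)


def run_base_case(
    bundle: FixtureBundle, curves: CurveSet | None = None
) -> Tuple[StrategyResult, StrategyResult, Comparison]:
    """Full two-arm pipeline on a fixture bundle.

    Returns (monitored, unmonitored, comparison); the comparison treats
    the monitored arm as the intervention.
    """
    if curves is None:
        curves = fit_curve_set(bundle.curves)
    mon = run_strategy("monitored", bundle.config, curves, bundle.life_table)
    unm = run_strategy("unmonitored", bundle.config, curves, bundle.life_table)
    return mon, unm, compare(mon, unm)
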