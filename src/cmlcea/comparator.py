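"""Two-strategy comparison: incremental outcomes, ICER and dominance.

Dominance follows the usual cost-effectiveness quadrant rules on the
discounted totals of the intervention minus the comparator: more QALYs at
lower cost is *dominant* (no ICER reported), fewer QALYs at higher cost is
*dominated*; in the remaining quadrants the ICER (CNY per LY / per QALY)
is reported.  Zero-benefit denominators yield an undefined ICER with a
flag rather than an infinity, keeping tabular output parseable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .economics import StrategyResult

__all__ = ["Comparison", "compare", "ComparisonError"]


class ComparisonError(ValueError):
    """The two results do not come from comparable configurations."""


@dataclass
class Comparison:
    """Incremental result of intervention vs comparator (discounted scale)."""

    delta_ly: float
    delta_qaly: float
    delta_cost: float
    delta_ly_undiscounted: float
    delta_qaly_undiscounted: float
    delta_cost_undiscounted: float
    classification: str                       # dominant / dominated / ICER-reported
    icer_per_ly: Optional[float] = None
    icer_per_qaly: Optional[float] = None
    icer_undefined_reason: Optional[str] = None
    intervention: Optional[StrategyResult] = None
    comparator: Optional[StrategyResult] = None


def compare(
    intervention: StrategyResult, comparator: StrategyResult
) -> Comparison:
    """Compare two strategy results run under the same configuration.

    The two arms must differ only in the monitoring strategy; passing two
    results from the same arm is rejected.
    """
    if intervention.arm == comparator.arm:
        raise ComparisonError(
            f"both results are from the {intervention.arm!r} arm"
        )
    if intervention.trace.n_cycles != comparator.trace.n_cycles:
        raise ComparisonError("results were run over different horizons")

    d_ly = intervention.total_ly() - comparator.total_ly()
    d_qaly = intervention.total_qaly() - comparator.total_qaly()
    d_cost = intervention.total_cost() - comparator.total_cost()

    if d_qaly > 0 and d_cost < 0:
        classification = "dominant"
    elif d_qaly < 0 and d_cost > 0:
        classification = "dominated"
    else:
        classification = "ICER-reported"

    icer_ly = icer_qaly = None
    reason = None
    if classification == "ICER-reported":
        if d_qaly == 0 or d_ly == 0:
            reason = (
                "zero incremental benefit"
                + ("; incremental cost "
                   + ("positive" if d_cost > 0 else "negative" if d_cost < 0 else "zero"))
            )
        if d_ly != 0:
            icer_ly = d_cost / d_ly
        if d_qaly != 0:
            icer_qaly = d_cost / d_qaly

    return Comparison(
        delta_ly=d_ly,
        delta_qaly=d_qaly,
        delta_cost=d_cost,
        delta_ly_undiscounted=(
            intervention.total_ly(False) - comparator.total_ly(False)
        ),
        delta_qaly_undiscounted=(
            intervention.total_qaly(False) - comparator.total_qaly(False)
        ),
        delta_cost_undiscounted=(
            intervention.total_cost(False) - comparator.total_cost(False)
        ),
        classification=classification,
        icer_per_ly=icer_ly,
        icer_per_qaly=icer_qaly,
        icer_undefined_reason=reason,
        intervention=intervention,
        comparator=comparator,
    )
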