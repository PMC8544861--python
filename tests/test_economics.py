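"""Costing, utilities, half-cycle correction and discounting."""

import numpy as np
import pytest

from cmlcea.cohort_engine import Compartment, run_cohort
from cmlcea.economics import (
    CostingError,
    accumulate,
    annual_cost_components,
    annual_state_cost,
    followup_cost_per_year,
)
from cmlcea.parameters_io import ModelConfig
from cmlcea.synthetic_data import base_case_config

from conftest import constant_life_table, flat_curveset
from helpers import toy_config


# Per-state follow-up totals implied by the resource-use frequencies and
# unit costs (the dot products behind the published per-state totals).
FOLLOWUP_TOTALS = {"CML-CP": 6946.80, "DMR": 3926.80, "TFR": 3926.80,
                   "AP/BC": 14574.80}


@pytest.mark.parametrize("state,expected", sorted(FOLLOWUP_TOTALS.items()))
def test_followup_cost_dot_product(state, expected):
    cfg = base_case_config()
    cost = followup_cost_per_year(cfg.resource_use[state], cfg.unit_costs)
    assert cost == pytest.approx(expected, abs=1e-9)


def test_followup_cost_empty_profile():
    assert followup_cost_per_year({}, {"Nurse-led visit": 30.0}) == 0.0


def test_followup_cost_missing_unit_cost_names_resource():
    with pytest.raises(CostingError, match="MRI"):
        followup_cost_per_year({"MRI": 1.0}, {})


class TestAnnualStateCost:
    def setup_method(self):
        self.cfg = base_case_config()

    def test_tfr_year_one(self):
        comp = Compartment("TFR", "imatinib", 0)
        parts = annual_cost_components(comp, self.cfg, monitored=True)
        assert parts["core"] == 0.0                      # no drug cost in TFR
        assert parts["monitoring"] == pytest.approx(9 * 250.0)
        assert parts["follow-up"] == pytest.approx(3926.80)

    def test_tfr_later_years_monitoring_band(self):
        comp = Compartment("TFR", "imatinib", 3)
        parts = annual_cost_components(comp, self.cfg, monitored=True)
        assert parts["monitoring"] == pytest.approx(2 * 250.0)

    def test_cmlcp_monitoring_component(self):
        comp = Compartment("CML-CP", "imatinib", 0)
        parts = annual_cost_components(comp, self.cfg, monitored=True)
        assert parts["monitoring"] == pytest.approx(2.87 * 250.0)  # = 717.50

    def test_unmonitored_arm_has_no_monitoring_cost(self):
        for state, line in (("CML-CP", "imatinib"), ("AP/BC", "none")):
            comp = Compartment(state, line, 0)
            parts = annual_cost_components(comp, self.cfg, monitored=False)
            assert parts["monitoring"] == 0.0

    def test_tki_drug_cost_is_monthly_price_annualized(self):
        comp = Compartment("CML-CP", "nilotinib", 2)
        parts = annual_cost_components(comp, self.cfg, monitored=True)
        assert parts["core"] == pytest.approx(11364.0 * 12)

    def test_bsc_cost_is_imatinib_plus_interferon_with_administration(self):
        comp = Compartment("CML-CP", "BSC", 0)
        parts = annual_cost_components(comp, self.cfg, monitored=True)
        assert parts["core"] == pytest.approx((586.0 + 912.88 + 1095.75) * 12)

    def test_apbc_core_cost_mix_plus_hospital(self):
        comp = Compartment("AP/BC", "none", 0)
        parts = annual_cost_components(comp, self.cfg, monitored=True)
        expected_drug = 12 * (0.5 * 586.0 + 0.5 * 7500.0)
        assert parts["core"] == pytest.approx(expected_drug + 36 * 300.0)

    def test_unknown_line_rejected(self):
        with pytest.raises(CostingError):
            annual_state_cost(Compartment("CML-CP", "bosutinib", 0), self.cfg)


def _run_toy(discount_costs=0.03, discount_benefits=0.03, horizon=30, q=0.05,
             utilities=None, arm="monitored"):
    cfg = toy_config(horizon)
    data = cfg.model_dump()
    data["discount_rate_costs"] = discount_costs
    data["discount_rate_benefits"] = discount_benefits
    if utilities is not None:
        data["utilities_monitored"] = utilities
        data["utilities_unmonitored"] = utilities
    cfg = ModelConfig.model_validate(data)
    trace = run_cohort(arm, cfg, flat_curveset(), constant_life_table(q))
    return accumulate(trace, cfg, arm)


def test_zero_discount_equals_undiscounted():
    res = _run_toy(discount_costs=0.0, discount_benefits=0.0)
    assert res.total_ly(True) == pytest.approx(res.total_ly(False), rel=1e-12)
    assert res.total_qaly(True) == pytest.approx(res.total_qaly(False), rel=1e-12)
    assert res.total_cost(True) == pytest.approx(res.total_cost(False), rel=1e-12)


def test_unit_utilities_make_qaly_equal_ly():
    res = _run_toy(utilities={"CML-CP": 1.0, "DMR": 1.0, "TFR": 1.0, "AP/BC": 1.0})
    for state in ("CML-CP",):
        assert res.qaly_undiscounted[state] == pytest.approx(
            res.ly_undiscounted[state], rel=1e-12)
    assert res.total_qaly(False) == pytest.approx(res.total_ly(False), rel=1e-12)


def test_exponential_life_expectancy_closed_form():
    """Single-state cohort with constant death rate lambda: trapezoid LY at a
    long horizon matches 1/lambda within the O(dt^2) trapezoid bound."""
    lam = 0.2
    q = 1.0 - np.exp(-lam)
    res = _run_toy(q=q, horizon=200, discount_benefits=0.0, discount_costs=0.0)
    assert res.total_ly(False) == pytest.approx(1.0 / lam, abs=lam / 12 + 1e-6)


def test_discount_monotonicity(bundle, fitted_curves):
    """Totals strictly decrease as the discount rate rises (0% -> 3% -> 5%)."""
    totals = []
    for r in (0.0, 0.03, 0.05):
        data = bundle.config.model_dump()
        data["discount_rate_costs"] = r
        data["discount_rate_benefits"] = r
        cfg = ModelConfig.model_validate(data)
        trace = run_cohort("monitored", cfg, fitted_curves, bundle.life_table)
        res = accumulate(trace, cfg, "monitored")
        totals.append((res.total_ly(), res.total_qaly(), res.total_cost()))
    for a, b in zip(totals, totals[1:]):
        assert all(x > y for x, y in zip(a, b))


def test_half_cycle_correction_is_trapezoid(base_results):
    """Accumulated LY equals the trapezoid of the state-occupancy curve."""
    mon = base_results[0]
    trace = mon.trace
    for state in ("CML-CP", "TFR", "AP/BC"):
        occ = np.array([trace.state_occupancy(k, state)
                        for k in range(trace.n_cycles + 1)])
        assert mon.ly_undiscounted[state] == pytest.approx(np.trapezoid(occ),
                                                           rel=1e-12)


def test_category_closure(base_results):
    """Total cost equals the sum over all categories, both discount regimes."""
    for res in base_results[:2]:
        for discounted in (True, False):
            table = res.costs.discounted if discounted else res.costs.undiscounted
            assert res.total_cost(discounted) == pytest.approx(
                sum(table.values()), abs=1e-6)


def test_structural_inequalities(base_results):
    for res in base_results[:2]:
        assert res.total_qaly(False) <= res.total_ly(False)   # utilities <= 1
        assert res.total_ly(True) <= res.total_ly(False)      # discounting
        assert res.total_cost(True) <= res.total_cost(False)
        for table in (res.costs.discounted, res.costs.undiscounted):
            assert all(v >= -1e-9 for v in table.values())


def test_monitoring_cost_zero_in_unmonitored_arm(base_results):
    _, unm, _ = base_results
    assert unm.costs.undiscounted["molecular monitoring"] == 0.0
    assert unm.costs.undiscounted["DMR"] == 0.0
    assert unm.costs.undiscounted["TFR"] == 0.0


def test_terminal_care_scales_with_total_deaths(bundle, fitted_curves):
    data = bundle.config.model_dump()
    data["discount_rate_costs"] = 0.0
    cfg = ModelConfig.model_validate(data)
    trace = run_cohort("monitored", cfg, fitted_curves, bundle.life_table)
    res = accumulate(trace, cfg, "monitored")
    total_deaths = trace.state_occupancy(trace.n_cycles, "Death")
    assert res.costs.undiscounted["terminal care"] == pytest.approx(
        total_deaths * cfg.terminal_care_cost, rel=1e-9)


def test_missing_utility_for_occupied_state_raises(bundle, fitted_curves):
    data = bundle.config.model_dump()
    del data["utilities_monitored"]["TFR"]
    cfg = ModelConfig.model_validate(data)
    trace = run_cohort("monitored", cfg, fitted_curves, bundle.life_table)
    with pytest.raises(CostingError, match="TFR"):
        accumulate(trace, cfg, "monitored")
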