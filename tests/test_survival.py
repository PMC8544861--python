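"""Parametric survival families, fitting and AIC model selection."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cmlcea.survival import (
    FAMILIES,
    DepletionWarning,
    DigitizedCurve,
    FitResult,
    ParametricSurvival,
    cycle_probability,
    fit_all_families,
    fit_curve,
    isotonic_decreasing,
    select_best,
    survival_at,
)
from cmlcea.synthetic_data import CurveGenerator, generate_km_curve

# one representative parameter set per family (RCS knots on ln t over [0.25, 10])
_KNOTS = (math.log(0.25), math.log(1.5), math.log(4.0), math.log(10.0))
EXAMPLE_MODELS = [
    ParametricSurvival("exponential", (0.1,)),
    ParametricSurvival("gamma", (1.8, 0.3)),
    ParametricSurvival("generalized-gamma", (1.2, 0.9, 5.0)),
    ParametricSurvival("log-normal", (1.5, 0.8)),
    ParametricSurvival("log-logistic", (1.4, 6.0)),
    ParametricSurvival("gompertz", (0.2, 0.05)),
    ParametricSurvival("gompertz", (-0.15, 0.1)),
    ParametricSurvival("weibull", (1.5, 8.0)),
    ParametricSurvival("rcs-weibull", (-2.0, 1.2, 0.1, -0.05), _KNOTS),
    ParametricSurvival("rcs-log-logistic", (-1.5, 1.1, 0.2, -0.1), _KNOTS),
]
_IDS = [f"{m.family}{i}" for i, m in enumerate(EXAMPLE_MODELS)]


@pytest.mark.parametrize("model", EXAMPLE_MODELS, ids=_IDS)
def test_survival_starts_at_one_and_stays_in_unit_interval(model):
    assert survival_at(model, 0.0) == 1.0
    grid = np.linspace(0, 60, 1000)
    s = survival_at(model, grid)
    assert np.all((s >= 0) & (s <= 1))
    assert np.all(np.diff(s) <= 1e-9)  # non-increasing


def test_exponential_closed_form():
    m = ParametricSurvival("exponential", (0.1,))
    assert survival_at(m, 10.0) == pytest.approx(math.exp(-1.0), rel=1e-12)


def test_weibull_shape_one_equals_exponential():
    lam = 0.23
    w = ParametricSurvival("weibull", (1.0, 1.0 / lam))
    e = ParametricSurvival("exponential", (lam,))
    t = np.linspace(0, 20, 50)
    assert survival_at(w, t) == pytest.approx(survival_at(e, t), rel=1e-10)


def test_gompertz_small_shape_approaches_exponential():
    g = ParametricSurvival("gompertz", (1e-13, 0.1))
    e = ParametricSurvival("exponential", (0.1,))
    assert survival_at(g, 7.0) == pytest.approx(survival_at(e, 7.0), rel=1e-9)


def test_negative_time_rejected():
    with pytest.raises(ValueError):
        survival_at(EXAMPLE_MODELS[0], -0.5)


@pytest.mark.parametrize("family,params", [
    ("exponential", (-0.1,)),
    ("weibull", (0.0, 5.0)),
    ("weibull", (1.0, -5.0)),
    ("log-normal", (1.0, 0.0)),
    ("gompertz", (0.1, 0.0)),
    ("generalized-gamma", (1.0, -1.0, 2.0)),
])
def test_invalid_params_rejected(family, params):
    with pytest.raises(ValueError):
        ParametricSurvival(family, params)


class TestCycleProbability:
    def test_exponential_memoryless(self):
        lam = 0.3
        m = ParametricSurvival("exponential", (lam,))
        expected = 1.0 - math.exp(-lam)
        for k in range(20):
            assert cycle_probability(m, k) == pytest.approx(expected, rel=1e-12)

    def test_short_cycle_limit_vanishes(self):
        m = ParametricSurvival("weibull", (1.5, 8.0))
        assert cycle_probability(m, 3, 1e-9) < 1e-8

    def test_increasing_hazard_weibull(self):
        m = ParametricSurvival("weibull", (2.0, 10.0))
        probs = [cycle_probability(m, k) for k in range(21)]
        assert all(b > a for a, b in zip(probs, probs[1:]))

    def test_depleted_curve_warns_and_returns_one(self):
        m = ParametricSurvival("weibull", (3.0, 0.5))  # S(5) is ~0
        with pytest.warns(DepletionWarning):
            assert cycle_probability(m, 5) == 1.0

    def test_cohort_survival_identity_exponential(self):
        # surviving k cycles via per-cycle probabilities equals S(k)
        m = ParametricSurvival("exponential", (0.17,))
        alive = 1.0
        for k in range(30):
            alive *= 1.0 - cycle_probability(m, k)
            assert alive == pytest.approx(survival_at(m, k + 1.0), abs=1e-12)


def _noiseless_curve(model, n=40, tmax=15.0):
    t = np.linspace(tmax / n, tmax, n)
    return DigitizedCurve(tuple(t), tuple(survival_at(model, t)))


class TestFitCurve:
    def test_exponential_recovery_noiseless(self):
        fit = fit_curve(_noiseless_curve(ParametricSurvival("exponential", (0.2,))),
                        "exponential")
        assert fit.converged
        assert fit.model.params[0] == pytest.approx(0.2, rel=0.01)

    def test_weibull_recovery_with_noise(self):
        truth = ParametricSurvival("weibull", (1.5, 8.0))
        curve = generate_km_curve(CurveGenerator(
            truth=truth, n_points=50, noise_sd=0.005, censor_time=10.0, seed=7))
        fit = fit_curve(curve, "weibull")
        assert fit.converged
        shape, scale = fit.model.params
        assert shape == pytest.approx(1.5, rel=0.05)
        assert scale == pytest.approx(8.0, rel=0.05)

    def test_constant_curve_is_degenerate_for_all_families(self):
        t = np.linspace(0.5, 10, 20)
        curve = DigitizedCurve(tuple(t), tuple(np.ones(20)))
        for family in FAMILIES:
            assert not fit_curve(curve, family).converged

    def test_too_few_points_rejected(self):
        curve = DigitizedCurve((1.0, 2.0, 3.0), (0.9, 0.8, 0.7))
        with pytest.raises(ValueError):
            fit_curve(curve, "rcs-weibull")  # 4 params need >= 5 points

    def test_fit_is_deterministic(self):
        curve = generate_km_curve(CurveGenerator(
            truth=ParametricSurvival("weibull", (1.5, 8.0)),
            n_points=40, noise_sd=0.01, censor_time=10.0, seed=3))
        a = fit_curve(curve, "gamma")
        b = fit_curve(curve, "gamma")
        assert a.model.params == b.model.params and a.aic == b.aic


class TestSelectBest:
    def _fr(self, family, params, aic, converged=True):
        return FitResult(model=ParametricSurvival(family, params),
                         aic=aic, rss=1.0, converged=converged, family=family)

    def test_minimal_aic_wins(self):
        fits = [self._fr("exponential", (0.1,), 12.1),
                self._fr("weibull", (1.2, 5.0), 9.8),
                self._fr("gamma", (1.1, 0.2), 15.0)]
        assert select_best(fits).family == "weibull"

    def test_tie_prefers_fewer_parameters(self):
        fits = [self._fr("weibull", (1.2, 5.0), 10.0),
                self._fr("exponential", (0.1,), 10.0)]
        assert select_best(fits).family == "exponential"

    def test_unconverged_excluded(self):
        fits = [FitResult(model=None, aic=math.inf, rss=math.inf,
                          converged=False, family="gamma"),
                self._fr("exponential", (0.1,), 50.0)]
        assert select_best(fits).family == "exponential"

    def test_no_converged_fit_is_error(self):
        with pytest.raises(ValueError):
            select_best([FitResult(model=None, aic=math.inf, rss=math.inf,
                                   converged=False, family="gamma")])


def test_gompertz_generator_recovered_across_seeds():
    """Simulation study: with a clearly age-accelerating hazard, AIC picks
    the Gompertz family in >= 90% of 20 seeded replicates."""
    truth = ParametricSurvival("gompertz", (0.35, 0.03))
    hits = 0
    for seed in range(20):
        curve = generate_km_curve(CurveGenerator(
            truth=truth, n_points=50, noise_sd=0.005, censor_time=10.0, seed=seed))
        if select_best(fit_all_families(curve)).family == "gompertz":
            hits += 1
    assert hits >= 18  # 90% of 20


def test_selected_family_invariant_to_time_unit_rescaling(bundle):
    """Refitting with time in months instead of years must not change the
    AIC-selected family (scale parameters absorb the unit change)."""
    keys = [("TTD", "imatinib"), ("PFS", "BSC"), ("MR45", "nilotinib"),
            ("TFR", ""), ("OS", "")]
    for key in keys:
        curve = bundle.curves[key]
        fam_years = select_best(fit_all_families(curve)).family
        rescaled = DigitizedCurve(tuple(12.0 * t for t in curve.times),
                                  curve.survival)
        fam_months = select_best(fit_all_families(rescaled)).family
        assert fam_months == fam_years, key


def test_fitted_base_case_models_are_proper_survival_curves(fitted_curves):
    models = (list(fitted_curves.ttd.values()) + list(fitted_curves.pfs.values())
              + list(fitted_curves.mr45.values())
              + [fitted_curves.tfr, fitted_curves.apbc_os])
    grid = np.linspace(0, 50, 1000)
    for m in models:
        s = survival_at(m, grid)
        assert np.all((s >= 0) & (s <= 1))
        assert np.all(np.diff(s) <= 1e-9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DepletionWarning)
            for k in range(50):
                assert 0.0 <= cycle_probability(m, k) <= 1.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
def test_isotonic_projection_properties(values):
    y = np.array(values)
    out = isotonic_decreasing(y)
    assert np.all(np.diff(out) <= 1e-12)                    # non-increasing
    assert np.allclose(isotonic_decreasing(out), out)       # idempotent
    assert np.sum(out) == pytest.approx(np.sum(y), abs=1e-9)  # mean-preserving


def test_digitized_curve_invariants_enforced():
    with pytest.raises(ValueError):
        DigitizedCurve((1.0, 1.0), (0.9, 0.8))       # times not increasing
    with pytest.raises(ValueError):
        DigitizedCurve((1.0, 2.0), (0.5, 0.9))       # survival increasing
    with pytest.raises(ValueError):
        DigitizedCurve((1.0, 2.0), (1.1, 0.9))       # out of [0,1]
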