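"""Shared fixtures: the synthetic base-case bundle, fitted curves and
both strategy arms, computed once per session (curve fitting is the
expensive step)."""

import pytest

from cmlcea import (
    fit_curve_set,
    make_base_fixture,
    run_strategy,
    compare,
)
from cmlcea.cohort_engine import CurveSet
from cmlcea.parameters_io import LifeTable
from cmlcea.survival import ParametricSurvival

import numpy as np

BASE_SEED = 20210


@pytest.fixture(scope="session")
def bundle():
    return make_base_fixture(BASE_SEED)


@pytest.fixture(scope="session")
def fitted_curves(bundle):
    return fit_curve_set(bundle.curves)


@pytest.fixture(scope="session")
def base_results(bundle, fitted_curves):
    mon = run_strategy("monitored", bundle.config, fitted_curves, bundle.life_table)
    unm = run_strategy("unmonitored", bundle.config, fitted_curves, bundle.life_table)
    return mon, unm, compare(mon, unm)


def flat_curveset():
    """All event curves inert (S == 1 everywhere)."""
    none = ParametricSurvival("exponential", (0.0,))
    lines = ("imatinib", "nilotinib", "dasatinib")
    return CurveSet(
        ttd={l: none for l in lines},
        pfs={l: none for l in lines + ("BSC",)},
        mr45={l: none for l in lines},
        tfr=none,
        apbc_os=none,
    )


def constant_life_table(q: float = 0.0) -> LifeTable:
    ages = np.arange(0, 121)
    return LifeTable(ages, np.full(len(ages), q), np.full(len(ages), q))
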