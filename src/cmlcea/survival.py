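"""Parametric survival families, curve fitting and cycle probabilities.

Digitized Kaplan-Meier coordinates (time, survival) extracted from
published figures are the only time-to-event input available to the model,
so fitting uses nonlinear least squares on S(t) rather than a censored
likelihood, with a Gaussian pseudo-likelihood AIC

    AIC = n * ln(RSS / n) + 2 p

for family selection (lower is better).  Nine families are supported:
exponential, gamma, generalized gamma, log-normal, log-logistic, Gompertz,
Weibull, and Royston-Parmar restricted-cubic-spline (RCS) models on the
Weibull (proportional-hazards) and log-logistic (proportional-odds) link
scales with two interior knots.

Family parameterizations (all scales/rates > 0, t >= 0):

==================  =========================  ===============================
family              params                     S(t)
==================  =========================  ===============================
exponential         (rate,)                    exp(-rate * t)
gamma               (shape, rate)              1 - GammaCDF(t; shape, rate)
generalized-gamma   (shape_a, shape_c, scale)  scipy gengamma.sf (Stacy form)
log-normal          (mu, sigma)                1 - Phi((ln t - mu)/sigma)
log-logistic        (shape, scale)             1 / (1 + (t/scale)**shape)
gompertz            (shape, rate)              exp(-rate/shape*(e**(shape t)-1))
weibull             (shape, scale)             exp(-(t/scale)**shape)
rcs-weibull         4 spline coefs             exp(-exp(s(ln t)))
rcs-log-logistic    4 spline coefs             1 / (1 + exp(s(ln t)))
==================  =========================  ===============================

The Gompertz shape may be any real number (negative shape gives a
decreasing hazard with a survival plateau); its shape -> 0 limit is the
exponential.  The exponential rate may be 0 (S == 1, no events), which the
cohort engine uses for inert curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "FAMILIES", "ParametricSurvival", "DigitizedCurve", "FitResult",
    "survival_at", "cycle_probability", "fit_curve", "fit_all_families",
    "select_best", "rcs_basis", "isotonic_decreasing",
]

#: Family -> number of free parameters, in the canonical listing order
#: (used as the final tie-break in model selection).
FAMILIES: Dict[str, int] = {
    "exponential": 1,
    "gamma": 2,
    "generalized-gamma": 3,
    "log-normal": 2,
    "log-logistic": 2,
    "gompertz": 2,
    "weibull": 2,
    "rcs-weibull": 4,
    "rcs-log-logistic": 4,
}

_FAMILY_ORDER = {name: i for i, name in enumerate(FAMILIES)}

_DEPLETION_EPS = 1e-12


class DepletionWarning(UserWarning):
    """A survival curve reached zero within the modelled horizon."""


@dataclass(frozen=True)
class ParametricSurvival:
    """A fitted (or specified) parametric survival-time distribution."""

    family: str
    params: Tuple[float, ...]
    knots: Tuple[float, ...] = ()  # RCS families: [min, k1, k2, max] on ln t

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        object.__setattr__(self, "knots", tuple(float(k) for k in self.knots))
        if len(self.params) != FAMILIES[self.family]:
            raise ValueError(
                f"{self.family} expects {FAMILIES[self.family]} params, "
                f"got {len(self.params)}"
            )
        _validate_params(self.family, self.params)
        if self.family.startswith("rcs") and len(self.knots) != 4:
            raise ValueError("RCS families need 4 knots [min, k1, k2, max]")

    def survival(self, t):
        """Vectorized S(t); see :func:`survival_at`."""
        return survival_at(self, t)


@dataclass(frozen=True)
class DigitizedCurve:
    """Ordered (time, survival) coordinates standing in for a digitized KM figure."""

    times: Tuple[float, ...]
    survival: Tuple[float, ...]
    role: str = ""        # TTD, PFS, MR4.5, TFR, OS
    treatment: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if t.ndim != 1 or t.shape != s.shape or len(t) < 2:
            raise ValueError("curve needs matching 1-D times/survival, n >= 2")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(t < 0):
            raise ValueError("times must be >= 0")
        if np.any((s < 0) | (s > 1)):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError(
                "survival must be non-increasing; apply isotonic repair first"
            )
        object.__setattr__(self, "times", tuple(t))
        object.__setattr__(self, "survival", tuple(s))


@dataclass(frozen=True)
class FitResult:
    """One family fitted to one digitized curve."""

    model: Optional[ParametricSurvival]
    aic: float
    rss: float
    converged: bool
    family: str = ""

    def __post_init__(self):
        if self.converged and not math.isfinite(self.aic):
            raise ValueError("converged fit must have finite AIC")


# ---------------------------------------------------------------------------
# Survival evaluation


def _validate_params(family: str, p: Sequence[float]) -> None:
    if any(not math.isfinite(v) for v in p):
        raise ValueError(f"{family} params must be finite: {p}")
    if family == "exponential":
        if p[0] < 0:
            raise ValueError("exponential rate must be >= 0")
    elif family in ("gamma", "weibull", "log-logistic"):
        if p[0] <= 0 or p[1] <= 0:
            raise ValueError(f"{family} shape and scale/rate must be > 0")
    elif family == "generalized-gamma":
        if p[0] <= 0 or p[1] <= 0 or p[2] <= 0:
            raise ValueError("generalized-gamma params must be > 0")
    elif family == "log-normal":
        if p[1] <= 0:
            raise ValueError("log-normal sigma must be > 0")
    elif family == "gompertz":
        if p[1] <= 0:
            raise ValueError("gompertz rate must be > 0")
    # rcs-*: coefficients unconstrained; monotonicity is checked at fit time


def rcs_basis(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Restricted cubic spline design matrix [1, x, v1(x), v2(x)].

    ``knots`` is [k_min, k1, k2, k_max] on the log-time axis.  The basis is
    linear beyond the boundary knots, which keeps tail extrapolation of the
    log-cumulative-hazard (or log-odds) linear.
    """
    x = np.asarray(x, dtype=float)
    kmin, *interior, kmax = knots
    span = kmax - kmin
    cols = [np.ones_like(x), x]
    for kj in interior:
        lam = (kmax - kj) / span
        vj = (
            np.maximum(x - kj, 0.0) ** 3
            - lam * np.maximum(x - kmin, 0.0) ** 3
            - (1.0 - lam) * np.maximum(x - kmax, 0.0) ** 3
        ) / span**2  # scaled for conditioning
        cols.append(vj)
    return np.column_stack(cols)


def _rcs_linear_predictor(model: ParametricSurvival, t: np.ndarray) -> np.ndarray:
    x = np.log(t)
    basis = rcs_basis(x, model.knots)
    return basis @ np.asarray(model.params)


def survival_at(model: ParametricSurvival, t) -> np.ndarray | float:
    """Evaluate S(t) for t >= 0 (scalar or array); S(0) is exactly 1."""
    scalar = np.isscalar(t)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    p = model.params
    fam = model.family
    with np.errstate(over="ignore", under="ignore"):
        if fam == "exponential":
            s = np.exp(-p[0] * t)
        elif fam == "weibull":
            s = np.exp(-np.power(t / p[1], p[0]))
        elif fam == "gamma":
            s = stats.gamma.sf(t, p[0], scale=1.0 / p[1])
        elif fam == "generalized-gamma":
            s = stats.gengamma.sf(t, p[0], p[1], scale=p[2])
        elif fam == "log-normal":
            s = stats.lognorm.sf(t, p[1], scale=math.exp(p[0]))
        elif fam == "log-logistic":
            s = stats.fisk.sf(t, p[0], scale=p[1])
        elif fam == "gompertz":
            a, b = p
            if abs(a) < 1e-12:
                s = np.exp(-b * t)
            else:
                s = np.exp(-(b / a) * np.expm1(a * t))
        elif fam == "rcs-weibull":
            s = np.ones_like(t)
            pos = t > 0
            eta = _rcs_linear_predictor(model, t[pos])
            s[pos] = np.exp(-np.exp(eta))
        elif fam == "rcs-log-logistic":
            s = np.ones_like(t)
            pos = t > 0
            eta = _rcs_linear_predictor(model, t[pos])
            s[pos] = special.expit(-eta)
        else:  # pragma: no cover
            raise ValueError(fam)
    s = np.clip(s, 0.0, 1.0)
    s[t == 0] = 1.0
    return float(s[0]) if scalar else s


def cycle_probability(
    model: ParametricSurvival, cycle_index: int, cycle_length: float = 1.0
) -> float:
    """Per-cycle event probability 1 - S((k+1)D)/S(kD).

    When the curve is already depleted at the cycle start (S(kD) = 0 to
    numerical precision) the conditional probability is returned as 1 with
    a :class:`DepletionWarning`.
    """
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    if cycle_length <= 0:
        raise ValueError("cycle_length must be > 0")
    k = cycle_index
    s0 = survival_at(model, k * cycle_length)
    s1 = survival_at(model, (k + 1) * cycle_length)
    if s0 <= _DEPLETION_EPS:
        warnings.warn(
            f"{model.family} survival depleted at cycle {k}", DepletionWarning
        )
        return 1.0
    return float(min(1.0, max(0.0, 1.0 - s1 / s0)))


# ---------------------------------------------------------------------------
# Fitting


def isotonic_decreasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators projection onto non-increasing sequences."""
    y = np.asarray(y, dtype=float)
    levels = []  # (value_sum, count) blocks
    for v in y:
        levels.append([v, 1])
        # merge while the non-increasing constraint is violated
        while len(levels) > 1 and levels[-2][0] / levels[-2][1] < levels[-1][0] / levels[-1][1]:
            s, c = levels.pop()
            levels[-1][0] += s
            levels[-1][1] += c
    out = np.empty_like(y)
    i = 0
    for s, c in levels:
        out[i:i + c] = s / c
        i += c
    return out


def _transform(family: str, params: np.ndarray) -> np.ndarray:
    """Natural params -> unconstrained optimizer space."""
    p = np.asarray(params, dtype=float).copy()
    if family.startswith("rcs"):
        return p
    if family == "log-normal":
        p[1] = np.log(p[1])
        return p
    if family == "gompertz":
        p[1] = np.log(p[1])
        return p
    return np.log(p)


def _untransform(family: str, theta: np.ndarray) -> np.ndarray:
    p = np.asarray(theta, dtype=float).copy()
    if family.startswith("rcs"):
        return p
    if family == "log-normal":
        p[1] = np.exp(p[1])
        return p
    if family == "gompertz":
        p[1] = np.exp(p[1])
        return p
    return np.exp(p)


def _crude_rate(t: np.ndarray, s: np.ndarray) -> float:
    """Rough exponential rate from the last informative point."""
    s_end = max(float(s[-1]), 1e-3)
    t_end = float(t[-1])
    rate = -math.log(s_end) / t_end if t_end > 0 else 1.0
    return max(rate, 1e-6)


def _starting_points(
    family: str, t: np.ndarray, s: np.ndarray, knots: Sequence[float]
) -> List[np.ndarray]:
    """Five deterministic starts per family (natural parameter space)."""
    lam = _crude_rate(t, s)
    scale = 1.0 / lam
    mults = (0.25, 0.5, 1.0, 2.0, 4.0)
    shapes = (0.6, 0.8, 1.0, 1.4, 2.2)
    if family == "exponential":
        return [np.array([lam * m]) for m in mults]
    if family == "weibull":
        return [np.array([sh, scale]) for sh in shapes]
    if family == "gamma":
        return [np.array([sh, lam * max(sh, 0.5)]) for sh in shapes]
    if family == "generalized-gamma":
        return [np.array([a, c, scale]) for a, c in
                ((1.0, 1.0), (0.7, 1.3), (1.5, 0.8), (2.0, 1.0), (1.0, 0.6))]
    if family == "log-normal":
        mu = math.log(max(scale, 1e-6))
        return [np.array([mu + dm, sg]) for dm, sg in
                ((0.0, 1.0), (-0.5, 0.7), (0.5, 1.5), (0.0, 0.5), (0.0, 2.0))]
    if family == "log-logistic":
        return [np.array([sh, scale]) for sh in (0.5, 0.9, 1.3, 2.0, 3.0)]
    if family == "gompertz":
        return [np.array([a, lam]) for a in (-0.2, -0.05, 0.0 + 1e-3, 0.1, 0.3)]
    if family.startswith("rcs"):
        # linear least squares in the link space as the primary start
        eps = 1e-6
        pos = (t > 0) & (s > eps) & (s < 1 - eps)
        if pos.sum() >= 4:
            x = np.log(t[pos])
            y = s[pos]
            if family == "rcs-weibull":
                g = np.log(-np.log(y))
            else:
                g = np.log((1.0 - y) / y)
            basis = rcs_basis(x, knots)
            beta, *_ = np.linalg.lstsq(basis, g, rcond=None)
        else:
            beta = np.array([math.log(lam), 1.0, 0.0, 0.0])
        starts = [beta]
        for scale_f in (0.5, 1.5):
            starts.append(beta * scale_f)
        starts.append(beta + np.array([0.0, 0.5, 0.0, 0.0]))
        starts.append(np.array([math.log(lam), 1.0, 0.0, 0.0]))
        return starts
    raise ValueError(family)


def _default_knots(t: np.ndarray) -> Tuple[float, ...]:
    """Boundary knots at min/max observed positive time, interior at the
    33rd/67th percentiles of log-time."""
    x = np.log(t[t > 0])
    kmin, kmax = float(x.min()), float(x.max())
    k1, k2 = np.percentile(x, [33.0, 67.0])
    return (kmin, float(k1), float(k2), kmax)


def _check_shape(model: ParametricSurvival, t_max: float) -> bool:
    """S must be in [0,1] and non-increasing over a dense grid."""
    grid = np.linspace(0.0, max(t_max, 1e-6) * 1.5, 1000)
    s = survival_at(model, grid)
    if np.any(~np.isfinite(s)):
        return False
    return bool(np.all(np.diff(s) <= 1e-9))


def fit_curve(curve: DigitizedCurve, family: str) -> FitResult:
    """Fit one parametric family to a digitized curve by least squares.

    Deterministic: five fixed starting points per family, no randomness.
    Degenerate inputs (no events: all survival ~ 1) and fits whose survival
    function is non-monotone are returned with ``converged=False`` so that
    model selection skips them.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    t = np.asarray(curve.times, dtype=float)
    y = np.asarray(curve.survival, dtype=float)
    n_par = FAMILIES[family]
    if len(t) < max(3, n_par + 1):
        raise ValueError(
            f"need at least {max(3, n_par + 1)} points to fit {family}, got {len(t)}"
        )
    if np.all(y > 1.0 - 1e-9):  # no events digitized: positive-hazard fit is degenerate
        return FitResult(model=None, aic=math.inf, rss=math.inf,
                         converged=False, family=family)

    knots = _default_knots(t) if family.startswith("rcs") else ()

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = _untransform(family, theta)
        try:
            model = ParametricSurvival(family, tuple(p), knots)
        except ValueError:
            return np.full_like(y, 1e3)
        s = survival_at(model, t)
        return s - y

    best: Optional[Tuple[float, np.ndarray]] = None
    for start in _starting_points(family, t, y, knots):
        theta0 = _transform(family, start)
        if not np.all(np.isfinite(theta0)):
            continue
        try:
            sol = optimize.least_squares(
                residuals, theta0, method="lm" if len(theta0) <= len(y) else "trf",
                max_nfev=2000,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0] - 1e-15:
            best = (rss, sol.x)
    if best is None:
        return FitResult(model=None, aic=math.inf, rss=math.inf,
                         converged=False, family=family)
    rss, theta = best
    params = tuple(_untransform(family, theta))
    try:
        model = ParametricSurvival(family, params, knots)
    except ValueError:
        return FitResult(model=None, aic=math.inf, rss=rss,
                         converged=False, family=family)
    if not _check_shape(model, float(t[-1])):
        return FitResult(model=model, aic=math.inf, rss=rss,
                         converged=False, family=family)
    n = len(t)
    aic = n * math.log(max(rss, 1e-300) / n) + 2 * n_par
    return FitResult(model=model, aic=aic, rss=rss, converged=True, family=family)


def fit_all_families(
    curve: DigitizedCurve, families: Sequence[str] | None = None
) -> List[FitResult]:
    """Fit every candidate family (skipping those with too few points)."""
    results = []
    for fam in (families or FAMILIES):
        try:
            results.append(fit_curve(curve, fam))
        except ValueError:
            continue
    return results


def select_best(fits: Sequence[FitResult]) -> ParametricSurvival:
    """Minimum-AIC converged fit; ties broken by fewer parameters, then by
    the canonical family listing order."""
    converged = [f for f in fits if f.converged and f.model is not None]
    if not converged:
        raise ValueError("no converged fit to select from")
    converged.sort(
        key=lambda f: (f.aic, FAMILIES[f.model.family], _FAMILY_ORDER[f.model.family])
    )
    return converged[0].model


# ---------------------------------------------------------------------------
# Serialization


def model_to_dict(model: ParametricSurvival) -> dict:
    return {"family": model.family, "params": list(model.params),
            "knots": list(model.knots)}


def model_from_dict(d: dict) -> ParametricSurvival:
    return ParametricSurvival(d["family"], tuple(d["params"]),
                              tuple(d.get("knots", ())))


def curve_to_csv(curve: DigitizedCurve, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"time_years": curve.times, "survival_probability": curve.survival}
    ).to_csv(path, index=False)


def curve_from_csv(path, role: str = "", treatment: str = "") -> DigitizedCurve:
    import pandas as pd

    df = pd.read_csv(path)
    s = isotonic_decreasing(df["survival_probability"].values)
    return DigitizedCurve(tuple(df["time_years"].values), tuple(np.clip(s, 0, 1)),
                          role=role, treatment=treatment)
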