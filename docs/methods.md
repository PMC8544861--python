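# Methods

## Model structure

The model is a discrete-time semi-Markov cohort simulation with annual
cycles. The cohort is partitioned into compartments `(state, treatment
line, state-time)`; state-time is the clock the survival curves are read
on:

| state  | clock meaning            | curves read on it                  |
|--------|--------------------------|------------------------------------|
| CML-CP | years on current line    | TTD, PFS, MR4.5 (per line)         |
| DMR    | years on current line    | none (tunnel; maintenance scalar)  |
| TFR    | years since TFR entry    | relapse-free survival              |
| AP/BC  | years since progression  | overall survival                   |
| all    | attained cohort age      | background (life-table) mortality  |

The cohort starts at age 41, 62% male, all in CML-CP at clock 0, split
75 / 13 / 12% over first-line imatinib / nilotinib / dasatinib
(flumatinib is merged into dasatinib, and dasatinib's list price is used
for the merged line, as the costlier of the two). Discontinuation routes
imatinib → nilotinib or dasatinib (50/50), nilotinib → dasatinib,
dasatinib → best supportive care (BSC = imatinib + interferon). BSC is
the last line: it has no TTD, and DMR cannot be achieved on it.

**DMR as a one-cycle tunnel.** A single "probability of maintaining DMR
for one year" (0.57 / 0.77 / 0.72 by line) is the only maintenance
parameter, so DMR resolves after exactly one cycle: maintainers enter
TFR, the rest return to CML-CP on the same line. The line clock keeps
running through the DMR cycle because patients in DMR remain on the same
therapy (and keep accruing its drug cost). Guideline eligibility gates
for a TFR attempt (≥5 years on TKI, ≥2 years in DMR) are deliberately
*not* enforced: the parameter set contains no such gate, and adding one
would change the model class. This is a known divergence from clinical
practice guidelines.

**TFR relapse destination.** Patients losing molecular response in TFR
restart the TKI they discontinued, at line clock 0. Restarting at clock 0
is optimistic for increasing-hazard TTD curves; the alternative (resuming
the old clock) is not exposed because the tunnel bookkeeping would need
to carry two clocks for a second-order effect.

**AP/BC.** Absorbing until death. Its per-cycle death probability is the
OS-curve probability floored at the age-specific background probability —
a progressed patient cannot out-survive the general population.

**Competing events within a cycle** are applied as a conditional cascade
in the fixed order *background death → progression → DMR achievement →
discontinuation*, each acting on the survivors of the previous event.
This keeps every branch probability in [0, 1], conserves the cohort
exactly, and lets the most severe event dominate. The true within-cycle
ordering is unidentifiable from annual-cycle inputs; the cascade is this
package's resolution and the tree-enumeration oracle in the test suite
pins it down exactly.

Second-line DMR achievement reuses the line's own MR4.5 curve (i.e. the
curve is keyed by line label, not by line position); no data distinguish
first- from later-line achievement here.

## Survival curves and fitting

Input curves are digitized Kaplan-Meier coordinates: ordered
`(time, survival)` pairs, monotonicity-repaired by a non-increasing
pool-adjacent-violators projection before use (the repair magnitude is
small for realistic digitization noise; the projection was verified
against scikit-learn's isotonic regression during development).

Because coordinates are not individual-level data, a censored likelihood
is unavailable. Fitting minimizes the residual sum of squares of S(t) at
the digitized points, and families are compared by the Gaussian
pseudo-likelihood criterion

    AIC = n ln(RSS/n) + 2p,

lower is better; ties break toward fewer parameters, then canonical
family order. Nine families are supported (see the `survival` module
docstring for parameterizations). The two Royston-Parmar spline families
model the log cumulative hazard (Weibull scale) or log odds of failure
(log-logistic scale) as a restricted cubic spline in log time with two
interior knots at the 33rd/67th percentiles of observed log-time and
boundary knots at the observed extremes; extrapolation beyond the data is
therefore linear on the link scale. Optimization uses
`scipy.optimize.least_squares` from five deterministic data-derived
starting points per family (no randomness: fits are exactly
reproducible). A fit is flagged non-converged — and excluded from
selection — if the optimizer fails, parameters are invalid, the input has
no events (all survival ≈ 1), or the fitted survival function is not
non-increasing on a dense grid (this is how badly-behaved spline
coefficients are screened out).

The generalized-gamma family uses the scipy (Stacy) parameterization with
both shape parameters positive; it nests the Weibull (a = 1), gamma
(c = 1) and exponential families, which is what the nesting-aware
selection tests rely on. The negative-Q Prentice extension is not
included.

Per-cycle transition probabilities are `1 − S((k+1)Δ)/S(kΔ)`. A curve
depleted at the cycle start (S ≤ 1e−12) yields probability 1 with a
`DepletionWarning` rather than a division error.

## Economics

**Half-cycle correction** is the trapezoid of consecutive cycle
occupancies, applied to life-years, QALYs and all recurring costs.
One-off terminal-care costs attach to incident deaths without correction.
**Discounting** divides the cycle-k trapezoid (spanning cycles k → k+1)
by (1 + r)^(k+1) — an end-of-cycle convention, stated here because the
alternative (mid-cycle) conventions differ by a factor (1+r)^0.5 ≈ 1.5%
at 3%.

**Costs.** Drug list prices (¥586 imatinib, ¥11,364 nilotinib, ¥7,500
dasatinib, ¥912.88 interferon) are interpreted as *per month*
(`drug_cost_period_multiplier = 12`); the pricing period is genuinely
ambiguous in the source tables, so the multiplier is a single explicit
config knob rather than a buried constant. Interferon's administration
cost (¥1,095.75) is treated the same way and added to the BSC line.
Follow-up costs are the dot product of per-state resource-use
frequencies and unit costs over 13 resource categories — ¥6,946.80 /
¥3,926.80 / ¥3,926.80 / ¥14,574.80 per year for CML-CP / DMR / TFR /
AP-BC — with AP/BC hospital stays (36 days × ¥300) and molecular
monitoring costed separately on top. Monitoring costs ¥250 per test at
2.87 / 2.5 / 9 / 2 tests per year in CML-CP / DMR / TFR-year-1 /
TFR-later (monitored arm only). Terminal care (fixture default ¥30,000,
an assumption — no unit cost is published for it) applies to every death
by default; a config switch restricts it to AP/BC deaths, since the
evidence does not settle the trigger.

In the per-state cost decomposition, a state's row carries its drug
(+ administration, + hospital) costs, while follow-up, monitoring and
terminal care are pooled rows — which is why the TFR row is ¥0 even
though TFR occupancy does generate monitoring and follow-up spending.

## Scenario and sensitivity machinery

Scenario overrides are applied to a deep copy of the configuration and
fully re-validated *before* any simulation runs; a distribution knocked
off the simplex by an override is an error, never silently renormalized.
The packaged 20-scenario library covers: all-male cohort; 0% and 5%
discounting; first-line mix 30/40/30; imatinib→nilotinib routing at
40/50/30% (the 50% entry is an explicit identity scenario — it equals the
base case's 50/50 routing and is kept so the routing sweep is complete);
nilotinib→dasatinib 90% (remainder to BSC); DMR
achievement ×0.9/0.8/0.7 (multiplicative on the per-cycle achievement
probabilities — the multiplicative reading of "X% reduction" was chosen
over an absolute one); DMR maintenance ×0.9/0.8/0.7/1.1; all utilities
×0.9; the ELN-guideline monitoring schedule; and drug prices
×0.9/0.8/0.7.

The ELN schedule is encoded as a named monitoring schedule: monthly tests
during the first 6 months of TFR plus 8-weekly tests in months 6–12 give
≈ 9.25 tests in TFR year 1, and 12-weekly testing thereafter gives
52/12 ≈ 4.33 tests per year.

One-way sensitivity varies single numeric parameters by ±25% of the base
value. Probabilities and utilities clamp to [0, 1] (the clamp is logged;
e.g. CML-CP utility 0.854 × 1.25 clamps at 1.0, so that bar is
asymmetric). Tornado entries are sorted by descending spread of the
chosen outcome axis (ΔQALY or Δcost).

## Synthetic data

The generator emits survival points at 40 evenly spaced times over the
figure's follow-up window, adds Gaussian noise (sd 0.005 survival units,
emulating plot-digitization error), clips to [0, 1] and applies the
isotonic repair. Ground-truth families and parameters (chosen once, for
clinical plausibility):

| curve | family | params | rationale |
|---|---|---|---|
| TTD imatinib | Weibull | (0.9, 12) | ~63% still on drug at 5 y |
| TTD nilotinib / dasatinib | Weibull | (1.0, 10) / (1.0, 9) | slightly shorter persistence |
| PFS imatinib | exponential | rate 0.020 | ≈ 90% progression-free at 5 y |
| PFS nilotinib / dasatinib | exponential | rate 0.015 | 2G-TKIs marginally better |
| PFS BSC (hydroxyurea+IFN stand-in) | exponential | rate 0.080 | markedly worse post-TKI |
| MR4.5 imatinib | log-normal | (1.80, 1.20) | ~45% achieve by 5 y |
| MR4.5 nilotinib / dasatinib | log-normal | (1.40, 1.10) / (1.45, 1.10) | faster deep response |
| TFR relapse-free | log-logistic | (0.40, 1.65) | ~45% relapse in year 1, then plateau (front-loaded, matching intensified year-1 monitoring) |
| AP/BC OS | Weibull | (1.2, 1.5) | median ≈ 1.1 y |

The life table is Gompertz-Makeham, `qx = 1 − exp(−(A + B e^{C·age}))`,
with male coefficients (6e−4, 2.5e−5, 0.095) and female
(4e−4, 1.2e−5, 0.098), giving q(41) ≈ 0.002/0.001 and q(80) ≈ 0.05/0.03
— a plausible national-population shape, explicitly synthetic.

This calibration makes the monitored arm dominant in the base case and
across the scenario library, the qualitative headline the model class is
known for. The *yuan amounts and LY/QALY totals it produces are
calibration artifacts*: real digitized curves would shift them
substantially (our synthetic TTD curves, for instance, keep patients on
first-line therapy longer than the published cohorts suggest, inflating
undiscounted life-years). What passing tests demonstrate is the
machinery — conservation, clock handling, costing identities, dominance
logic, fitting recovery — not real-world point estimates. The
generator also does not emulate: digitization-time correlation of errors
along a curve, the step structure of true KM curves (points are sampled
on the smooth truth), informative censoring, or sex-specific disease
dynamics (only background mortality is sex-mixed).

## Verification design

Two independent oracles back the engine. A recursive path-enumeration
oracle re-implements the cascade with closed-form per-cycle
probabilities and must agree to 1e−12 over 5 cycles on a toy model with
clock-dependent (Weibull) TFR and OS hazards — this pins the semi-Markov
clock indexing exactly. A 200,000-walker microsimulation draws individual
trajectories through the engine's own per-compartment transition
distributions (aggregated as per-compartment multinomial draws, which is
distributionally identical) and must reproduce deterministic occupancies
within 3 Monte-Carlo standard errors at cycles 1, 5, 10 and 25; its
random stream is spawned from the fixture seed via `SeedSequence` so it
is independent of the curve-generation stream. Fitting is verified by
parameter recovery on synthetic curves (Weibull shape/scale within 5% at
n = 50, noise sd 0.005) and by family-selection simulation studies
(generating-or-nesting family selected in ≥ 90% of 20 replicates;
Gompertz identified when its hazard acceleration is clearly expressed in
the observation window — with weak curvature the 4-parameter spline
families can legitimately win the pseudo-AIC).

## Numerical choices and degenerate inputs

- Conservation tolerance 1e−9 per trace row; the cascade conserves to
  float rounding (~1e−15).
- Exponential rate 0 is allowed (S ≡ 1), used for inert curves; all
  other scale/rate parameters must be strictly positive.
- `S(0) = 1` exactly for every family (the spline families approach it in
  the limit; t = 0 is special-cased).
- A curve with no events (all survival ≈ 1) is degenerate for every
  positive-hazard family and yields `converged = False` rather than a
  boundary fit.
- Life-table lookups clamp beyond the last tabulated age; blended
  mortality is a fixed male/female mix (the mix does not age-drift).
- Problem sizes used throughout the tests and the acceptance script: the
  50-cycle horizon, 12 fitted curves × 9 families × 5 starts, 21 scenario
  runs × 2 arms, and one 200k-walker microsimulation — the full suite is
  a couple of minutes of compute, chosen to keep verification cheap
  enough to run on every change.

## Known limitations

- No probabilistic sensitivity analysis (one-way and scenario only).
- No adverse-event costs or disutilities; no T315I/mutation dynamics;
  no currency conversion or inflation adjustment.
- Monitoring frequency does not feed back into curve shapes (the same
  TTD/PFS curves serve both arms, a conservative assumption).
- Absolute cost and QALY totals for this comparison cannot be derived
  from tabulated scalar inputs alone — they depend on the survival
  curves, which are synthetic here. The package therefore asserts the
  qualitative result (dominance and its robustness) and every identity
  that *is* implied by the tabulated inputs, and never tunes the
  synthetic curves toward any particular totals.
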