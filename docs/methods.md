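# Methods

## Model structure

The model is a discrete-time Markov cohort state-transition model with
annual cycles. One arm is a mixture of three activity strata fixed at
baseline — cyclists, active non-cyclists and inactive non-cyclists —
because individuals are assumed to settle into an activity pattern once
the network is (or is not) built; there are no transitions between
strata. Cyclists and active non-cyclists share the "active" risk
profile. Within a stratum the states are Well, first-year CHD, post-CHD,
first-year stroke, post-stroke, type-2 diabetes, cancer, and Dead
(absorbing). There are no transitions between disease states and no
recovery to Well, so Well occupancy is non-increasing and Dead occupancy
non-decreasing by construction.

Transitions out of Well in each cycle: incident CHD and stroke events
are split by the age-band case-fatality rate between the first-year
disease state and Dead; T2D and cancer are entered whole; background
other-cause mortality applies. First-year CHD/stroke states last exactly
one cycle (carrying the first-event cost and utility), then feed the
post-event state. Chronic states persist until death.

### Activity stratification of incidence

Age-band population incidence `inc` is split by activity status via the
population-attributable fraction (PAF) of inactivity and the protective
relative risk RR (active vs inactive, < 1):

    inc_active   = inc · (1 − PAF)
    inc_inactive = inc_active / RR

`inc·(1−PAF)` is the standard counterfactual all-active incidence, so
the split reduces to the identity when PAF = 0. The printed PAFs (CHD
6%, T2D 7%, cancer 10%) are not exactly consistent with the inactive
prevalence and RRs used here, so the mixture of the two strata does not
reproduce the population incidence exactly; `mixture_consistency_gap`
reports the signed discrepancy for audit. No PAF is published for
stroke; the default 0.06 (the CHD value — both are CVD outcomes) is a
configurable choice. A single aggregate cancer state uses the printed
breast/colon figure of 0.10.

### Mortality

Mortality in the CHD, stroke and T2D states applies the published
mortality relative risk to the age band's CVD mortality, plus background
other-cause mortality; the cancer state applies its RR to all-cause
mortality directly. Other-cause mortality is computed as all-cause minus
CVD mortality — the only computable choice from the packaged tables,
which print no cancer- or diabetes-specific background rates; this
slightly double-counts cancer deaths in the background stream and is a
documented calibration approximation. Disease-state mortality is
independent of activity status; an optional per-cycle multiplicative
decline of the T2D mortality RR for the active strata exists
(`t2d_mortality_decline_active`, default 1.0 = off) because a faster
decline for active diabetics is qualitatively plausible but has no
published functional form.

### Rewards, discounting and conventions

Costs and QALYs accrue on start-of-cycle occupancy, discounted by
(1+r)^−t with the first cycle at t = 0 (undiscounted), r = 0.04/year.
With unit utility and no events this makes the 25-cycle QALY total
Σ_{t=0..24} 1.04^−t = 16.2470, a frozen analytic check. A half-cycle
correction (averaging start- and end-of-cycle occupancy) is available
but off by default. The wellbeing gain of being physically active
(0.05 QALY/year, the published conversion of 150 min/week at
2.22×10⁻⁴ QALY per 30 min ≈ 0.058) applies to active strata in the Well
state only by default (`wellbeing_scope="well"`), since the disease-state
utilities were measured without it; `"alive"` extends it to all alive
states.

The intervention arm pays a one-time investment of
`invest_per_capita × km` ($4.5/person/km × 100 km = $450) at t = 0 and
`maint_per_capita × km` ($6.6/person/year) every cycle. The per-capita
figures are per km of network: the printed investment total matches the
stated $3M/km construction cost, so only the per-km reading produces an
incremental cost of the observed order.

Age bands are looked up by current integer age each cycle; ages beyond
the last band's lower bound use the open 70+ band, which the 35- and
40-year horizon scenarios require.

### Validation oracle

`micro_simulate` walks individuals through the identical per-cycle
transition matrices with a seeded generator. Cohort occupancy and
discounted rewards must agree within 3 binomial standard errors per
(cycle, stratum, state) cell, with a 3/n additive allowance because
cells whose expected count is below a few individuals have Poisson
tails wider than the normal approximation. This is the package's main
correctness argument for the engine.

## Decision analysis

The ICER is ΔCost/ΔQALY; it is reported as undefined (None, with
dominant/dominated labels) when ΔQALY ≤ 0 rather than ±∞. Scenario runs
vary the intervention arm's cycling share (11.5/15/20/25%) holding the
status quo fixed, and the horizon (20/30/35/40 years) re-running both
arms. The tornado analysis varies one parameter at a time: relative
risks over their printed 95% CIs; costs and utilities over mean ±
1.96·sd truncated to their legal ranges; the intervention cycling share
over {0.07, 0.115}. Bars are sorted by ICER range width. Under this
bounds rule the cycling share is by far the widest bar; the per-capita
investment cost (whose printed sd is 38% of its mean) and the wellbeing
gain compete for second place.

## Probabilistic sensitivity analysis

Costs are sampled from gamma and utilities from beta distributions via
method-of-moments (gamma: shape = mean²/sd², scale = sd²/mean; beta:
ν = mean(1−mean)/sd² − 1, α = mean·ν, β = (1−mean)·ν); relative risks
from lognormal with μ = ln(base) and σ = (ln upper − ln lower)/(2·1.96).
All parameters are sampled independently from a single seeded generator
in a documented order (the relative-risk table in file order, then the
cost/utility table in file order), so runs are reproducible at the
contract level. Both arms share each iteration's draw and differ only in
cycling share and intervention cost — necessary for meaningful
increments. Protective disease RRs drawn at or above 1 (≈0.3% of draws,
driven by the wide cancer CI) are clipped just below 1 and counted. The
age-band incidence, mortality and case-fatality probabilities are fixed
in PSA because no dispersion is published for them; a caller can widen
the uncertain set with user-supplied sds. The cohort trace is linear in
its initial stratum mix, so each draw runs one active and one inactive
unit cohort and forms both arms as mixtures; this path is verified
bit-equal to the full two-arm engine on degenerate (sd = 0) draws.
Default: 10,000 iterations (~10 s on one CPU), CEAC grid $0–150,000 in
$1,000 steps.

Because the mean net monetary benefit of the base case is large relative
to the spread induced by the published dispersions, the probability of
cost-effectiveness at $72,550/QALY computes to ≈0.99. A materially lower
probability would require either treating the achieved cycling share
itself as uncertain (no distribution is published for it) or sampling
the arms independently; neither is adopted.

## Synthetic data

The city generator draws populations log-uniform on [10⁵, 3×10⁶],
network densities x lognormal (median 20 km per 100k, σ = 0.8), and mode
share s_max·(1 − e^(−kx)) + ε with s_max = 30%, k = 0.012,
ε ~ N(0, 3²), truncated to [0, 100]. The saturating-exponential gives
the concave, diminishing-returns shape real mode-share data exhibit
while keeping the true curve and its mean derivative
s_max·k·E[e^(−kx)] analytic, so marginal-effect recovery is testable
against ground truth. What it does not emulate: country-level
clustering, measurement error in network lengths, or any confounding
between city size and cycling culture — so passing recovery tests show
estimator correctness, not causal validity on real data. The
parameter-fixture generator applies multiplicative lognormal jitter to
every packaged table value, clipped into legal ranges (probabilities and
utilities to [0,1], CVD ≤ all-cause mortality, protective RRs < 1) with
the clip count reported; sd = 0 reproduces the packaged tables exactly.

## Regression stage

The estimator is local-linear kernel regression with a Gaussian kernel —
the standard assumption-free smoother with good boundary behaviour —
with bandwidth chosen by leave-one-out cross-validation (coarse log-grid
then bounded refinement). Local-linear fits reproduce affine data to
machine precision and converge to the global OLS line as the bandwidth
grows, both asserted in tests; predictions are clipped to [0, 100] and a
statsmodels local-linear fit serves as an independent cross-check. The
average marginal effect uses a central finite difference with step
0.05 × bandwidth — small against the smoothing scale, stable in floating
point. Predictions requested outside the observed support are clamped to
the boundary with a warning rather than extrapolated. The mode-share
response is regressed on density (km per 100k), the direction the
scatter analysis supports. Note that with a cross-validated bandwidth
the marginal-effect estimate carries a smoothing bias of a few
hundredths (on a mean derivative of ≈0.27 under generator defaults)
that does not vanish with repeated seeds; recovery is therefore judged
against the seed-to-seed spread, not the standard error of the mean.

The base-case 9% intervention share is a fixed scenario input (the 6%
baseline plus the ~3-point predicted change for Oslo's phase-I
expansion), keeping the Markov model decoupled from the regression
stage; the regression path remains available for reproduction runs on a
user-supplied city file.

## Problem sizes and determinism

Default runs: 25 annual cycles per arm (milliseconds), 10,000 PSA
iterations (~10 s), 50,000 micro-simulation individuals (~1 s), 20
generator seeds for regression-recovery checks. All stochastic
components take explicit integer seeds and are bit-reproducible given
seed and configuration.

## Known limitations

- Comorbidity is absent: disease states are mutually exclusive.
- Background mortality double-counts some cancer/T2D deaths (see above).
- The activity mix is frozen at baseline; behaviour change over 25–40
  years is not modelled.
- Injury and air-pollution effects of cycling are out of scope.
- The regression is a bivariate curve with no causal adjustment; its
  outputs are descriptive.
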