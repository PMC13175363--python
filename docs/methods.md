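# Methods

## Model structure

The engine is a three-state partitioned survival model (PSM):
progression-free (PFS), progressed disease (PD), and dead.  Occupancy is
derived directly from the two marginal survival curves — PFS share
`min(S_PFS, S_OS)`, death share `1 − S_OS`, PD share the remainder — so
the model never estimates transition probabilities and cannot represent
tunnel states or re-entry; that is the standard PSM trade-off against a
Markov cohort model.

Because the per-arm PFS and OS curves are fitted independently, their
extrapolated tails can cross.  The PFS curve is clamped below the OS
curve at every cycle boundary; the number of clamped cycles is recorded
on the trace and logged (one boundary is clamped for each arm of the
packaged case study, far in the tail).

### Time conventions

The canonical time unit is the **month** (365.25/12 days).  The packaged
lognormal parameters are month-scale fits: `exp(meanlog)` of the two OS
curves gives medians of 21.97 and 13.66 months, matching the source
trial's published 22.1- and 14.2-month median OS.  Cycles are 21 days
(one dosing interval), i.e. ≈0.690 months; a horizon of H years spans
`floor(H·365.25/21)` whole cycles and the residual partial cycle is
dropped (<0.06% of a 10-year horizon).

### Half-cycle correction and discounting

Per-cycle occupancy is the mean of the cycle-start and cycle-end values,
and discount factors `(1+r)^(−t)` are evaluated at cycle midpoints; with
the correction off (a config flag), cycle-end values and cycle-end
discounting are used.  The correction is on by default: the convention
of the original GUI implementation of the case study is not published,
so both are available.  Discounted cycle sums agree with a fine-grid
quadrature (step = cycle/10) of the continuous accrual integral within
2% (tested).

## Survival fitting and selection

Five families are supported (exponential, Weibull, Gompertz,
log-logistic, lognormal), parameterised as in the module docstring.
Fitting maximises the right-censored log-likelihood
`Σ_events ln f + Σ_censored ln S` with L-BFGS-B on the log scale for
positivity-constrained parameters, from three deterministic moment-style
starts (the exponential rate is closed-form).  Event times are clipped
to 1e-10 months before taking logs so zero times cannot produce infinite
event densities.  Model choice is lowest AIC; ties break by lowest BIC,
then fewest parameters, then input order.  BIC uses n = number of
subjects, not events.  Negative Gompertz shapes (survival plateaus) are
valid; extrapolation is always truncated at the model horizon, so
improper distributions cannot contribute infinite person-time, and the
median is reported as NaN when the plateau sits above 0.5.

A censored lognormal fit is cross-checked against an independent
survival library in the test suite; the in-package implementation is
used throughout because the five-family surface (including Gompertz)
must be uniform.

## Pseudo-IPD reconstruction

Digitized curve coordinates are first monotonized: survival increases up
to 0.005 (plot-reading jitter) are clamped, larger increases are
rejected as malformed.  Without an at-risk table — the packaged study
publishes none — all censoring is administrative at the last digitized
time, so the Kaplan–Meier estimator equals empirical survival and event
counts are recovered by rounding `n·(1−S)`.  This is the key divergence
from the interval-wise published-at-risk reconstruction algorithm; both
paths are implemented, and with an at-risk table censoring is spread
uniformly within each interval with event counts corrected iteratively
against the published counts.  Reconstruction reproduces input
probabilities within ~1/(2·n at risk), comfortably inside 0.02 absolute
for trial-sized cohorts (tested).

## Costs and calibration

All costs are CNY, mg-exact (the study prices per mg; no vial wastage).
Components: drug acquisition over the on-treatment share; disease
management over all alive states (labs/imaging; a PFS-only variant is a
config alternative); best supportive care over the PD share; a flat
per-cycle **subsequent-treatment residual** over the PD share; terminal
care weighted by incident deaths; and one-time adverse-event management
at model entry, undiscounted (Grade ≥3 events only, incidence × unit
cost).

The published analysis does not print its subsequent-treatment cost
composition or its drug-cost accrual rule, so two quantities are
**calibrated** by exact linear solves rather than asserted:

1. the reference arm's discounted drug budget, back-solved from the
   published price-sweep rows (incremental cost is linear in the
   retained price fraction with slope −budget; the three rows agree
   within 0.06%), then converted into a fixed treatment duration
   (≈7.6 cycles for the packaged study — far below mean time to
   progression, consistent with the source's "duration observed in the
   trial" costing);
2. a per-arm residual PD cost per cycle that reconciles each arm's total
   with the published base case (¥19,714/cycle dual, ¥12,956/cycle
   sorafenib).

Negative durations or residuals abort calibration with a report rather
than being clamped.  A consequence of spreading the residual over PD
person-time: incremental costs keep growing at long horizons, so the
ICER is not monotone in the horizon here even though the published
front-loaded costs made it so; the incremental QALY ordering and the
cost-effectiveness conclusion at every horizon are unaffected.

## Sensitivity analysis

One-way analysis re-runs the comparison at each parameter's published
range limits (±20% where no range is published) and ranks by ICER
spread; ties keep configuration order — relevant because body weight and
the bevacizumab price scale the same mg/kg cost term and therefore tie
exactly.  Parameter sets that break the utility ordering at a range edge
(u_PD = 0.816 > u_PFS = 0.76) are clamped and logged.

PSA distributions are moment-matched with mean = baseline and
SD = (max − min)/(2·1.96), reading the published range as an approximate
95% interval: Gamma for costs, Beta for utilities and adverse-event
incidences, Normal for weight, and a Beta rescaled to [0, 0.05] for the
discount rate (which is sampled, since the study lists a distribution
for it).  Infeasible Beta moments fall back to uniform(min, max) with a
logged warning.  Parameters are shared across arms within a draw; draws
violating the utility ordering are rejected and redrawn (~25% of draws,
counted and logged).  CEACs use incremental net monetary benefit with
exact ties split evenly; the crossover WTP is the linearly interpolated
smallest threshold reaching probability 0.5, with an out-of-range signal
otherwise.

## Synthetic trial generator

The generator emulates a 2:1 randomized trial (230 vs 116 subjects)
whose event times follow the packaged lognormal curves.  Per subject,
the recorded PFS time is `min(progression draw, OS draw)`: independent
marginal curves would let individuals progress after dying, which breaks
IPD-level checks, at the cost of a slightly heavier-than-lognormal PFS
tail.  Censoring combines uniform accrual over 12 months with an
administrative cutoff at 36 months (a plausible follow-up convention,
not an estimate of the source trial's) plus exponential dropout at
0.002/month.  Where tests need a bare "fraction censored" condition
(e.g. model-selection recovery at 20% censoring), censoring is modelled
as random loss to follow-up — the affected subjects are censored
uniformly before their event — because single-point administrative
censoring at the 20% quantile truncates the tail hard enough that the
lognormal/log-logistic distinction is genuinely undecidable at n = 230.

What the generator does **not** emulate: treatment switching,
adverse-event time series, covariate structure, informative censoring.
Passing tests therefore demonstrate the pipeline's statistical
correctness under the stated data-generating process, not robustness to
real-world messiness.

## Problem sizes and determinism

Default analyses run in seconds on one core: 174 cycles at the 10-year
horizon, 1000 PSA iterations, 20-replicate selection studies, n = 5000
recovery checks.  All randomness flows from a single top-level seed
through named per-stage substreams (CRC-keyed `SeedSequence`), and every
stochastic stage is bit-reproducible under a fixed seed.

## Known limitations

* The published dual-arm QALYs are not exactly recoverable from the
  published inputs: this engine yields 1.81 discounted QALYs at 10 years
  versus the published 1.71 (+6%), with the sorafenib arm within 2%.
  Rounded survival parameters, digitization error, and the original
  software's internal conventions are indistinguishable causes; the
  packaged tolerances reflect this.
* Absolute cost totals are calibration constraints, not predictions —
  the subsequent-treatment mix behind them is unpublished.
* No spline or mixture-cure extrapolation, no generalized-gamma family,
  no covariate-adjusted survival, no EVPI.
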