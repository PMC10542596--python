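# Methods

## Dose grid and dose-response curves

All designs operate on 25 physical doses, indexed 1..25 and equally spaced
in volume. Each curve maps a (possibly fractional) dose index to a success
probability through an affine latent mapping `latent = scale·dose + shift`:

| curve | family            | parameters                  | latent map     | ED90     | ED95     |
|-------|-------------------|-----------------------------|----------------|----------|----------|
| 1     | logistic-offset   | offset 13.5                 | x = d − 13.5   | 15.69722 | 16.44444 |
| 2     | log-logistic 4PL  | a=20, b=0.1,  c=100, d=0    | t = 4·d        | 12.98239 | 14.85043 |
| 3     | log-logistic 4PL  | a=20, b=0.075, c=100, d=0   | t = 4·d        | 17.30986 | 19.80057 |

Curve 1 is `p = 1/(1+e^{−x})`; curves 2–3 are `p = (c/100)/(1+a·e^{−bt})`,
with the lower-asymptote parameter `d` carried but inert at 0. ED levels
are obtained by closed-form inversion on the dose scale rather than by grid
search; the analytic values agree with a 1e-4-step grid search to well
under 1e-5 relative, so the discretisation is immaterial. True EDs are
fractional doses; trials assign integer doses only.

Virtual doses arise only in CRM working models: a dose below 1 responds
with certain failure and a dose above 25 with certain success, which allows
doses 1 and 25 themselves to be candidate EDs. Plain curve evaluation never
clamps.

## Centred isotonic regression (UDM/BCD estimator)

Per-dose success rates are fitted by weighted isotonic regression (weights
= trials per level; the pool-adjacent-violators step is delegated to
scikit-learn's `IsotonicRegression`). Each maximal flat stretch of the
monotone fit is then collapsed to a single point at the trial-weighted mean
of its dose indices, producing a strictly increasing curve; the ED estimate
is the linear interpolation of its inverse at the target level.

No extrapolation is performed: a target level outside the fitted
probability range yields "no estimate". An ED95 extrapolated from data
concentrated near the ED50 would be unbounded, and for the BCD an
un-reachable target level signals a monotonicity violation in the observed
rates; both situations are reported as no-estimate outcomes rather than
numbers. A single-point fit (all levels pooled) estimates only if it hits
the target exactly.

## UDM

90 patients per trial: a 40-patient walk (the classic ED50 stage) and 50
further patients. By default the second stage simply continues the same
walk — the alternative of restarting the walk at the stage-1 CIR estimate
of the ED50 is available (`phase2: restart_ed50`) and keeps n = 90 either
way. The final CIR fit pools all 90 observations. The walk truncates at
doses 1 and 25. A one-sample proportion test (95% Wilson score interval)
on the outcomes at the dose level nearest the estimate is attached to each
estimable trial for reporting; it plays no role in estimation.

## BCD

Trial sizes are fixed by the target: 100 observations (ED95) or 60 (ED90).
The default coin follows the design description literally — after a success
the dose is repeated with probability Γ and lowered with probability 1−Γ.
Its walk balances where downward moves `p·(1−Γ)` equal upward moves `1−p`,
i.e. at p\* = 1/(2−Γ) ≈ 0.952 for Γ = 0.95 — indistinguishable in practice
from the Durham–Flournoy construction (stay with (2Γ−1)/Γ, de-escalate
with (1−Γ)/Γ, balancing exactly at Γ), which is available as
`coin_rule: classic`.

## CRM

**Working model.** Six consecutive doses with the starting dose at
position 4, whose skeleton prior equals the target: (0.50, 0.60, 0.75,
0.90, 0.95, 0.98) for the ED90 and (0.50, 0.75, 0.90, 0.95, 0.98, 0.99)
for the ED95. The one-parameter power model `p_i(θ) = s_i^{exp(θ)}` with
θ ~ N(0, σ), σ = 1.34 by default (config key `sigma`), preserves the
skeleton's ordering for every θ.

**Posterior.** Posterior means of the six success probabilities are
computed by deterministic trapezoid quadrature: 2001 nodes over ±8σ, with
the likelihood evaluated in log space (`log(1−p)` via `expm1` so that
near-certain successes stay accurate). The quadrature agrees with a
1e-4-step brute-force integration over θ ∈ [−10, 10] to better than 1e-6,
and identical inputs always reproduce identical posteriors. Only the
current CRM segment's data enter the likelihood; a restarted CRM begins
from its priors.

**Allocation.** The next cohort receives the lowest window dose whose
posterior success probability is at or above the target (the qualifying
dose closest to the target, since posteriors are increasing). If no dose
qualifies the cohort receives the highest window dose.

**Stopping.** A segment ends on the 8+1 plateau rule — the last eight
patients at one dose and the recommendation for a further patient
unchanged — or at 36 patients. Cohort sizes of 2 or 4 are supported (both
divide 36).

**Restart random walk.** After every cohort the segment is checked against
three abandonment rules: (a) a *first* CRM that ends — by plateau or by the
36-patient cap — without a single failure restarts on a lower window: an
all-success CRM cannot localise a high quantile and its plateau dose is
not trusted as an estimate; (b) a segment failure fraction above 25%
restarts higher; (c) all six posteriors above 0.925 (ED95; 0.875 for ED90)
restart lower, all below 0.75 (0.70) restart higher. Rules (b) and (c) are
evaluated only once a segment holds at least 8 patients, so one early
failure cannot abort it, and a firing rule takes precedence over a
would-be plateau stop. Each restart shifts the window by 3 doses (half a
window; config `window_shift`) and at most 5 segments are run (config
`max_segments`); at the cap the trial terminates with its current
recommendation. The estimate is always the dose that would be allocated
to a hypothetical next cohort, so a CRM trial never returns "no estimate".
Patients and failures accumulate across segments, including patients
treated at virtual doses, whose deterministic outcomes enter the
likelihood.

## Monte Carlo harness

Every replicate draws from its own `numpy` `SeedSequence` keyed on
(master seed, design, curve, target, cohort, start, replicate), so batches
are reproducible bit for bit, cells can run in any order, and no two
replicates share a stream. Batch summaries report, per starting dose: the
no-estimate count, mean/SD of the estimate **over estimable replicates
only** (the study reports the no-estimate count separately, so the mean
must condition on estimability), and mean/SD of patients and failures over
all replicates (SDs use the n−1 denominator). Grand means across curves
and starting doses are unweighted means of per-cell means. Summary CSVs
are written with a fixed column order, rows sorted by starting dose and
floats at 6 significant digits, so identical runs produce identical bytes.

## Problem sizes

The bundled operating-characteristic checks and the acceptance script use
500 replicates per (design, curve, target, start) cell — the full grid of
25 starting doses and all three curves for the CRM sweep — which puts the
Monte Carlo standard error of the reported grand means well below the
tolerances applied to them; tolerance bands on stochastic checks are the
stated study band plus two Monte Carlo standard errors. The harness
default of 5000 replicates reproduces the full-scale study when desired.

## What the simulations do and do not show

The generator *is* the study design: outcomes are exact Bernoulli draws
from fully known, strictly monotone dose-response curves. Real dose-finding
data bring covariate heterogeneity, drifting baselines, misclassified
outcomes and possibly non-monotone response — none of which are modelled,
so passing checks here validate the designs' behaviour under their own
assumptions, not robustness to violations of them.

Known limitations:

- The published comparison's CRM model form and prior are not stated; the
  power model with N(0, 1.34) prior is this package's documented default,
  and operating characteristics that depend strongly on trial length (the
  cohort-4 failure load in particular) are sensitive to that choice and to
  the plateau rule's interaction with cohort size.
- With `max_segments = 5` and `window_shift = 3` a trial started at dose 1
  cannot push its window far enough to reach an ED above ~dose 18; from
  very high starting doses the first-CRM-only scope of restart rule (a)
  leaves a mild overestimation ramp for starts more than ~4 doses above
  the target. Both parameters are config keys.
- The BCD no-estimate proportion at high starting doses depends on the
  exact no-extrapolation semantics of the CIR inverse; on the flattest
  curve it approaches but does not exceed one half at the top starting
  dose under these semantics.
- The ED90 machinery (skeleton, cut-offs, 60-observation BCD) is exercised
  by the test suite but the headline Monte Carlo summaries here focus on
  the ED95 comparison.
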