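# Methods

## The problem

Two-cue integration experiments ask whether observers combine sensory
estimates the way a minimum-variance unbiased estimator (MVUE) would.
Because the competing accounts — MVUE, minimum-sigma cue selection (MS),
and probabilistic cue switching (PCS) — make highly correlated
predictions, a study can easily be incapable in principle of telling
them apart. `cuesim` simulates entire experiments end to end (observer
behaviour, psychophysical measurement, model prediction, group
statistics) so that the probability of distinguishing candidate models
under a given design can be quantified before any data are collected.

## Observer models

Each cue is a Gaussian estimator of a world property (sizes in mm
throughout): cue A has mean `S_A` and spread `sigma_A`, cue B likewise.
Reliability is inverse variance, `r = 1/sigma^2`, and the reliability
weights are `w_A = r_A / (r_A + r_B)`, `w_B = 1 - w_A`.

* **MVUE**: percept mean `w_A S_A + w_B S_B`; spread
  `sqrt(sigma_A^2 sigma_B^2 / (sigma_A^2 + sigma_B^2))`, never above the
  better single cue.
* **MS**: use the cue with the smaller sigma. Exact ties select cue A —
  a deterministic, documented convention; ties have measure zero under
  the continuous fitted sigmas produced by simulation.
* **PCS**: use cue A with probability `p_A`, cue B with `p_B`. The
  response distribution is a two-component Gaussian mixture with mean
  `p_A S_A + p_B S_B` and variance
  `p_A sigma_A^2 + p_B sigma_B^2 + p_A p_B (S_A - S_B)^2`. With equal
  cue means and `p = w` this collapses to
  `sqrt(2 sigma_A^2 sigma_B^2 / (sigma_A^2 + sigma_B^2))`, i.e. exactly
  `sqrt(2)` times the MVUE spread. Switching probabilities default to
  the reliability weights, the convention used when PCS predictions are
  derived from measured single-cue functions; an override is exposed.

The perturbation-analysis algebra quantifies how fragile weight
estimation is: if a conflict `delta` is added to cue B, a bias
`beta = -delta sigma_A^2 / sigma_B^2` in cue A restores the integrated
percept to its unperturbed value, erasing all evidence of
reliability-weighted integration. JNDs follow the
`sigma * sqrt(2)` convention. No `sqrt(2)` division of fitted sigmas is
applied anywhere: functions are parametrically simulated, so the fitted
spread *is* the estimator spread.

## Measurement pipeline

Responses follow a lapse-free cumulative Gaussian: P("larger") at
comparison level `x` is `Phi((x - mu)/sigma)`. Sampling uses the method
of constant stimuli — nine levels linearly spaced over a 20 mm span
centred on the true mean of each function (a best-case scenario for the
experimenter) — at 10, 25, 40 or 55 trials per level (90–495 trials per
function).

Fitting maximises the binomial log-likelihood over `(mu, log sigma)`
with a bounded quasi-Newton optimizer and two starts: probit-regression
initial values and the design centre. The log parameterisation enforces
`sigma > 0`; the surface of this 2-parameter lapse-free model is well
behaved, and the fit is checked against a brute-force likelihood lattice
in the tests. Standard errors come from the observed information
(finite differences of the analytic score), with a delta-method
transform from `log sigma` to `sigma`. The lapse rate is fixed at zero
because the simulated observers never lapse.

### Fit rejection

Real pipelines discard functions that cannot be fit. Two degeneracies
are flagged:

* `rejected_step` — perfectly separated data; the fitted sigma collapses
  below 1/100 of the inter-level spacing.
* `rejected_flat` — data at or around chance across all levels. The
  operational criterion is that the ML fit degenerates toward the
  constant-probability boundary, detected as a fitted sigma above 100
  times the sampling span (the optimizer's sigma bound sits another
  order of magnitude higher, so genuine degeneracy always crosses the
  threshold). This is the ML solution exactly when the sampled
  proportions carry a non-positive slope, so its probability falls
  steeply with trials per function, matching the observed decline of
  rejection frequency across data-collection regimes (order 0.1% at 90
  trials per function, essentially zero at 495). A stricter
  likelihood-ratio slope test is available via
  `RejectionThresholds.flat_slope_pvalue` but is off by default: at 90
  trials per function it discards a few percent of legitimately
  fittable shallow functions (sigma ratio near 4), an order of
  magnitude more than the degeneracy criterion, which distorts the
  zero-conflict statistics it is meant to protect.

Rejected observers are dropped from an experiment (default), or
resimulated until a fit succeeds (bounded at 10 retries) for the
alternative analysis; both policies give the same qualitative
conclusions.

## Simulation Set 1 (homogeneous populations)

Axes: sigma ratio `r = sigma_B/sigma_A` (27 linear steps over [1, 4]),
observers per experiment (4–30), data-collection regime (10/25/40/55
trials per level), cue conflict `delta` in {0, 3, 6} mm split
symmetrically (`S_A = 55 + delta/2`, `S_B = 55 - delta/2`), 100
repetitions per cell; `sigma_A = 4.86` mm (roughly a haptic size cue).
The full factorial enumerates 874,800 experiments and 14,871,600
observers; the enumerator reports these counts without simulating, and
all axes are config-driven so scaled-down runs are first-class.

Each observer yields three fitted functions (cue A, cue B, integrated;
the integrated truth follows the generating model). Model predictions
are derived from the observer's *fitted* single-cue parameters — MS
takes the lower-fitted-sigma cue, PCS mixes the fitted cues at fitted
weights, MVUE averages at fitted weights — exactly as an experimenter
would. Per experiment, the observed integrated values (PSE, sigma)
across retained observers are tested against the scalar mean of the
per-observer predictions with a two-sided one-sample t-test at
alpha = 0.05 (two-sided because deviation in either direction counts
against a model; a Wilcoxon signed-rank alternative is exposed and
yields the same conclusions). Zero-variance samples resolve by
convention: p = 1 if the common value equals the point, else p = 0.

At zero conflict every significant PSE test is a false positive. The
rate is inflated well above alpha (to roughly 16% against MS and 14%
against PCS at 10 trials/level) because the point prediction is itself
estimated from the same noisy single-cue fits; a calibration oracle
that tests noisy observations against their true fixed value recovers
the nominal 5%. Pooling is over all zero-conflict experiments rather
than averaging per-cell percentages; with equal repetitions per cell
the two are nearly identical.

## Simulation Set 2 (heterogeneous populations)

Each observer draws their own ratio `r = 2^x`, `x ~ Uniform[-1, 1]`
(ratios in [0.5, 2], median 1, log-symmetric). Populations of 4, 12 or
36 observers behave by MVUE or MS under conflicts of 3 or 6 mm across
the four regimes; 1000 experiments per combination enumerate 416,000
observers (24,000 experiments) in the default factorial.

Observed PSEs and sigmas are regressed on each candidate model's
predictions (first-order least squares). The reported statistic is the
regression R², which measures the fit of the line, *not* agreement with
the identity — a perfect line with slope 5 and intercept 100 still
gives R² = 1. R² distributions over experiments are smoothed with a
Gaussian kernel (Silverman rule-of-thumb bandwidth, reflection at the
[0, 1] boundaries to conserve mass) and compared via the overlap
coefficient `eta`: the trapezoidal integral of the pointwise minimum of
the two densities on a 2001-point uniform grid (deterministic, and
grid-convergence is tested). Experiments with a degenerate (constant)
predictor are dropped and counted, not imputed. Exact `eta` values
depend on the bandwidth rule, so only ordinal trends are asserted.

Measured trends at the scaled study conditions: consistent and
inconsistent comparisons give heavily overlapping R² distributions
(eta > 0.5 in most cells); PSE overlap shrinks as the conflict grows
from 3 to 6 mm while sigma overlap is conflict-insensitive; medians
rise with trials per function. Along the observer-count axis the
separation between consistent and inconsistent distributions improves
with more observers (lower eta), while the raw medians *fall* from 4 to
36 observers — with 4 points, the R² of a two-parameter line is
mechanically inflated (null expectation 1/(n-1) = 0.33), which is
precisely why few-observer studies reporting high R² carry so little
evidential weight. Tests therefore assert the overlap form of the
observer trend rather than raw medians.

## Nuisance-cue correction

If a "single-cue" sensitivity is measured while a conflicting cue is
held constant (signalling zero change), every presented increment is
attenuated to `w_A * dS_A`, so the measured function is a stretched
copy of the true one: warp factor `k = 1/w_A`, measured spread
`sigma' = sigma_A / w_A` (derived by a change of variables on the
estimator density; the transformed density is exposed as an evaluable
function and its unit mass and spread are verified by adaptive
quadrature at 1e-9 absolute tolerance). Measuring *both* cues this way
compounds the attenuation: the measured sigma ratio is the cube of the
true one, so the cube-root correction recovers the truth. A measured
ratio of 1/27 implies a true ratio of 1/3 — reliability misestimated
ninefold.

## Seeding and reproducibility

One root seed governs a run. Every simulated unit (cell, repetition,
observer, function, retry) derives an independent generator from the
root seed plus its integer coordinates via seed-sequence spawning, so
any unit is reproducible in isolation, results are invariant to
execution order and worker count, and identical (config, seed) pairs
produce byte-identical CSV outputs.

## Problem sizes used in tests and the acceptance script

The full published factorials are enumerated but not simulated; scaled
grids keep every pipeline stage intact while shrinking the Monte-Carlo
axes. The zero-conflict false-positive rates use 9 sigma ratios spanning
[1, 4] x observer counts {4, 10, 17, 24, 30} x 20–40 repetitions at 10
trials/level (900–1800 experiments, ~46,000–92,000 fits); rejection
bookkeeping adds the 25/40/55-trial regimes at 20 repetitions; the
four-observer analysis uses 9 ratios x regimes {10, 55} x 25
repetitions; Set-2 trends use 100 experiments per cell at the three most
diagnostic cells. These sizes put Monte-Carlo standard errors
comfortably inside the tolerances asserted (e.g. under one percentage
point for a 16% rate over 1800 experiments).

## Known limitations

Simulated observers are idealised: trials are independent (no learning,
boredom or serial dependence), lapse-free, unbiased, uncontaminated by
decision noise, with designs centred on the true mean and cues
statistically independent. Real data violate most of these, so the
discrimination probabilities computed here are upper bounds on what an
actual experiment can achieve. Circular variables, correlated-noise
corrections, causal-inference gating, adaptive sampling and lapse-rate
estimation are out of scope.
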