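# Methods

This note documents the models implemented in `vibrodev`, their
assumptions, the default parameter choices and why they were made, and what
the synthetic-data generator does and does not emulate.

## The battery protocol

Five tasks run in fixed order (RT, sqAD, smAD, TOJ, DD). Every task opens
with a practice gate: practice trials at the staircase start value repeat
until three consecutive correct responses occur, with a budget of 15
attempts before the task is marked `failed_practice`. The budget is a
package choice — the protocol itself only requires "at least three"
practice trials, and a finite budget is needed for termination.

The four discrimination tasks are two-alternative forced choice (2AFC)
with a 1-up/1-down staircase over 20 scored trials:

| Task | tracked parameter | start | step | floor | ceiling |
| --- | --- | --- | --- | --- | --- |
| sqAD/smAD | amplitude difference (μm) | 200 | ±20 (additive) | 20 | 400 |
| TOJ | inter-stimulus interval (ms) | 150 | ±15% (multiplicative) | 1 | 500 |
| DD | duration difference (ms) | 250 | ±25 (additive) | 25 | 500 |

Bounds are package choices (configurable): the additive floors sit at one
step so the comparison never equals the standard and the perfect-observer
closed form survives (a perfect observer descends 200, 180, …, 20 and then
sits on the floor; final-five mean exactly 20 μm / 25 ms); the TOJ floor of
1 ms avoids a degenerate geometric staircase; ceilings at twice the start
difference (500 ms ISI for TOJ) keep guessing observers physical. TOJ
values are kept at full floating precision — no rounding to whole ms — to
avoid quantization artifacts in the multiplicative track.

Stimulus delivery alternates pseudo-randomly between the fingers in
balanced shuffled blocks of two rather than i.i.d. coin flips, so each
finger carries the correct answer exactly 10 times in 20 trials and long
single-finger runs cannot masquerade as non-compliance.

Scoring: thresholds are the arithmetic mean of the tracked value over
scored trials 16–20, computed only from complete 20-trial staircases
(partial traces yield a missing value, never a partial threshold).
Reaction time is the mean of the median six of ten latencies (two fastest
and two slowest dropped); RT variability is the sample (n−1) SD of the
same six — the n−1 convention is a package choice for small samples.

## The synthetic observer

Responses follow a log-logistic psychometric function in the stimulus
difference Δ:

    P(correct) = 0.5 + (0.5 − λ/2) · F(Δ),   F(Δ) = 1 / (1 + (Δ/θ)^(−β))

so F(0) = 0 (chance at zero difference), F(θ) = 0.5 — the true threshold θ
is the 75%-correct point of the lapse-free curve — and the ceiling is
1 − λ/2. Latencies are lognormal parameterized by their median, so trial
noise never shifts the median; the median-6-of-10 trimming then estimates
a quantity whose population value tracks the RT age curve.

Population structure: each task's true threshold is the task's reference
age curve times a unit-median lognormal person effect,
θ = f(age) · exp(σ·Z). The simultaneous amplitude threshold is coupled to
the sequential one, smAD = sqAD · (1 + (k−1)·L) with L unit-median
lognormal and k = 1.3 by default, which enforces smAD ≥ sqAD per observer.
(The shipped smAD reference curve crosses below the sqAD curve at age 3,
so generating the two independently from their curves cannot guarantee the
ordering; `couple_smad=false` restores independent person effects around
k·f_sqAD(age) for null experiments, at the price of the per-observer
guarantee.)

Comprehension: each task has a logistic-in-age probability of
understanding the instructions, ordered RT (easiest) → sqAD → smAD → DD →
TOJ (hardest; half-comprehension at age 4.5). A practice response is
correct with probability comprehension × P(correct), so young children fail
the TOJ gate most often — the generator reproduces the completion
*gradient* qualitatively, not any specific completion percentage.

### Default parameters and their calibration

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `person_spread` σ | 0.9 | log-units | see below |
| `rt_person_spread` | 0.35 | log-units | matches the RT residual/mean ratio of the reference fits (≈0.37 at age 10) |
| `psychometric_slope` β | 8 | — | steep suprathreshold 2AFC discrimination; see below |
| `lapse_rate` λ | 0.03 | probability | typical attentive-observer lapse magnitude |
| `smad_factor` k | 1.3 | — | smAD runs above sqAD with no established ratio; 1.3 keeps the two overlapping |
| RT within-observer shape | RTVar-curve/RT-curve at the observer's age | log-units | makes trimmed-SD scatter track the RT-variability age curve |

σ and β are jointly calibrated against two design requirements: the
simulated cohort's residual scatter should be of the same order as the
reference fits' RMSE values, and the 20-trial staircase must remain a
*valid* ranking instrument (Spearman ρ ≥ 0.8 between true and estimated
thresholds across observers at a fixed age). The final-five estimator's
measurement noise grows roughly proportionally with the threshold
(SD ≈ 0.25·estimate), which caps the attainable correlation; σ = 0.9 with
β = 8 achieves ρ = 0.82–0.90 per task while keeping the scatter within
~1.5× the reference RMSE at mid-cohort age — the same order of magnitude.
Smaller spreads (σ ≈ 0.5, the value the RMSE ratios alone would suggest)
make the between-observer signal too small for the short staircase to rank
reliably.

### What the generator does not emulate

Siblings and family structure, handedness, socioeconomic covariates,
response-modality differences between age groups, learning or fatigue
across the session, within-participant re-test variance (unreported in
reference data), and the exact completion percentages per band. Passing
tests therefore demonstrate properties of the *procedures* (estimators,
exclusions, fits) under a plausible population model — not properties of
any human cohort.

## Quality control

Two objective rules, applied in order after completeness:

1. **Switch rule** — exclude a discrimination task when the response finger
   switched fewer than 3 times across the 20 scored trials. The protocol's
   two phrasings of this rule disagree ("at least 3" vs "more than three");
   the methods-section reading (exclude iff switches < 3) is implemented
   and the cutoff is configurable.
2. **3-SD rule** — within each recruitment band and task, exclude outcomes
   more than 3 SD from the band mean. One pass only, mean and SD computed
   once from all compliant complete values; a value at exactly 3 SD is
   kept (strictly-greater rule). Applied to all six measures by default
   (configurable to RT/RTVar only); RT variability additionally inherits an
   RT exclusion because both derive from the same ten trials.

A third, clearly non-canonical heuristic (`flag_diverging_traces`,
disabled by default) flags staircases whose final-ten trend moves away
from convergence; it is an objective stand-in for subjective by-eye review
of staircase profiles.

Counts are conserved by construction: per band and task,
recruited = included + excluded_incomplete + excluded_switch +
excluded_outlier.

## Trajectory models

**Incremental polynomials.** Ordinary least squares, starting linear in
age; an age² and then an age³ term is added and retained only if the added
coefficient's two-sided p-value is below 0.05 (uncorrected; alternative
criteria can be configured). The procedure stops as soon as a term is
rejected. Numerical guard: if the current model already fits to machine
precision (SSE ≤ 1e−12 × SST), no further term is attempted, because the
added coefficient's t-statistic is then 0/0-degenerate.

**Power, f(x) = a·x^b + c.** Trust-region nonlinear least squares
(`scipy.optimize.least_squares`, analytic Jacobian, ftol = xtol = gtol =
1e−12, ≤ 10⁴ evaluations). Initialization: c₀ = min(y), then a log–log
regression of y − c₀ + ε on x; four additional jittered starts from a
deterministic generator keyed by the user seed. The exponent is bounded to
|b| ≤ 10.

**Two-term exponential, f(x) = a·e^{bx} + c·e^{dx}.** Solved by variable
projection: the optimizer searches the two rates (bounded ≤ 0 by default,
matching decreasing trajectories) and the amplitudes are solved by linear
least squares at every step — the same minimum as the 4-parameter problem
but far better conditioned. Starts: exponent peeling (slow component
regressed on the oldest age tercile, fast component on the young-age
residuals), a small canonical grid of rate pairs, and jittered copies.
Coefficients are reported fast-component first (b ≤ d).

**Goodness of fit and selection.** SSE = Σr², R² = 1 − SSE/SST, RMSE =
√(SSE/(n−p)) with p the number of coefficients (residual-degrees-of-freedom
convention; configurable to n). Candidates are ranked by RMSE, then R²,
then SSE — the three criteria carry no published hierarchy, so RMSE leads
and ties break towards fewer coefficients for determinism. Non-converged
fits are recorded but never selected; an outcome with zero variance
signals R² as undefined rather than returning a number.

**Plateau age.** The smallest age at which the fitted curve comes within a
tolerance (default 5%) of its value at age 23, found by bisection to 10⁻³
years after a dense-grid monotonicity check. This is an artifact-defined
operationalization of "reaching adult-like performance"; reference
descriptions of plateaus are qualitative.

## Correlation analyses

Pearson correlations over pairwise-complete observations, per subgroup
(adults = age ≥ 18, the band definition; configurable). Cells with fewer
than 3 complete pairs are reported missing. No multiplicity correction is
applied by default; a Bonferroni column is reported alongside the eight
canonical ratio trends (RT/RTVar, RT/sqAD, RT/smAD, RT/TOJ, RT/DD,
sqAD/smAD, sqAD/TOJ, TOJ/DD). Ratios drop observers with a missing outcome
or non-positive denominator (counted); a perfectly constant ratio reports
slope 0 with p = 1 rather than relying on a degenerate regression.

Because every task's mean trajectory falls with age, pooling children with
adults induces positive inter-task correlations even when person effects
are independent across tasks; the package's under-18 versus adult matrix
comparison demonstrates exactly this (the under-18 matrix shows larger
median |r| than the adult matrix on cohorts where age is the only shared
driver).

## Pipeline determinism and problem sizes

One global seed drives everything. Observers draw from substreams keyed by
(seed, band, index-within-band), so resizing one band never reshuffles
another; batteries draw from (seed, observer, task-position) substreams.
Identical (config, seed) runs produce byte-identical outputs, verified by
SHA-256 digests in the run manifest.

Simulation-based checks in the test suite use 500 observers per task for
staircase-tracking validity, 100 simulated cohorts of 142 for the
correlation-pooling property, and 100 replicates of n = 142 for noisy
trajectory recovery — sizes chosen to make the Monte-Carlo error
comfortably smaller than the margins being asserted while keeping the
whole suite fast.

## Known limitations

- The 1-up/1-down rule targets the 50%-correct point, which for 2AFC lies
  at zero difference; with 20 trials the final-five mean is therefore a
  *biased but monotone* index of sensitivity (it sits below θ for most
  observers), not a consistent threshold estimator. This matches the
  scored protocol; psychometric-function refitting is deliberately out of
  scope.
- Replayed trial logs are validated for staircase consistency against the
  default task parameters; logs collected with modified staircase settings
  must be replayed with a matching task-spec configuration.
- Exact numerical replication of reference cohort statistics is impossible
  without the underlying human data and is not attempted; printed fitted
  equations are used as generating curves and recovery targets instead.
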