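# Methods

This note documents the models, the extraction procedure, the Bayesian
analyses and the synthetic-data generators implemented in
`bottleneck_lab`, together with the numerical choices and the design
decisions that were genuinely open.

## The limited-capacity, pipelined processing framework

A simulated agent consists of two processing modules connected in series
(think perception/decision feeding motor output) that work on different
inputs simultaneously — pipelined processing. Module *i* has a processing
capacity `cap_i` in Hz (objects per second). The environment offers input
at rate `input(t)`; the system's output at any moment is

```
output(t) = max(0, min(input(t), capA_final(t), capB_final(t)))
```

so once the input rate exceeds the most restricted module's capacity,
that module is the bottleneck and output plateaus at its capacity. A task
loads each module through a difficulty factor `d ∈ (0, 1]` (1 = easiest).
Three models describe the loading:

| model          | capacity rule                | capacities      |
|----------------|------------------------------|-----------------|
| additive       | `final = initial − 1 + d`    | fixed           |
| multiplicative | `final = initial × d`        | fixed           |
| flexible       | `final = initial × d`, then shared-pool allocation | partly shared |

In the flexible model part of the system's capability lives in a central
pool (1.0 Hz total by default, 0.5 Hz contributed per module so that
cumulative capability is conserved). Each update the pool is assigned to
the weaker module: entirely, if the capacity gap exceeds the pool;
otherwise both modules are raised to the common value
`(capA + capB + pool) / 2`. Allocation conserves `capA + capB + pool`
exactly in both branches.

### Grids

* **Tasks**: the 10×10 grid `{0.1, …, 1.0}²`; `(1.0, 1.0)` is the
  baseline task.
* **Systems**: mean capacities range over `{1.0, 1.1, …, 3.5}²` Hz; a
  cell `(a, b)` is kept iff `|a − b| < a/3`, which prevents one module
  from being completely dominated. The inequality is evaluated in integer
  tenths (`3·|A − B| < A`) so that ties at exact thirds (a = 1.2,
  b = 1.6) are excluded; this is the only reading that yields the
  expected 324 systems, which the test suite confirms by independent
  rational-arithmetic enumeration. Realised capacities are
  `Normal(mean, 0.05 Hz)` truncated positive (redraw); the filter applies
  to the grid means, so the 324-cell enumeration is deterministic.

### Trial dynamics and noise

Trials are recorded at 200 frames/s. Model quantities are recomputed at
100-frame update points and linearly interpolated across intermediate
frames. The input ramp is

```
input(t) = 0.5 + 0.025·t + n/10,   n ~ N(0, 1),  clamped ≥ 0
```

with `t` indexing update points (0.5 s apart). The default trial has 281
update points → 28,001 frames ≈ 140 s, matching the human trial length,
with input ramping 0.5 → 7.5 Hz — above every grid capacity, so every
trial ends overwhelmed. Taking `t` as a literal frame index would ramp
input to ~700 Hz, three orders of magnitude off the capacity scale, so
the update-point reading is used.

Per update point, difficulties are drawn `Normal(d, 0.05)` and module
capacities `Normal(cap, 0.05 Hz)`. Final capacities are clamped at 0
(the additive rule can otherwise go negative for small capacities at
hard tasks). All recorded series — input, final capacities, output — are
interpolated between update points; the alternative of holding noise
constant between updates changes nothing material because every
downstream statistic is computed from 5 s windows spanning ≥ 10 update
intervals.

Randomness policy: one root seed; each (system, task) trial derives a
deterministic `SeedSequence` substream, so any single trial is
reproducible in isolation.

## Steady-state rate extraction

Event streams (or simulated traces) are converted to rates and summarised
by the steady-state rate (SSR):

1. events are binned into half-open per-frame intervals and scaled to Hz;
2. rates are smoothed with two iterations of a Kolmogorov–Zurbenko
   filter, a centred moving average with a 5 s window (1001 frames at
   200 frames/s); edges use the truncated window so output length equals
   input length;
3. the per-frame difference `creation − hit` is summarised by a trailing
   5 s windowed median and MAD (the MAD uses the window's own median);
4. the overwhelmed phase begins at the **latest** frame where
   `median − MAD < 0.1 Hz`. That condition literally describes keeping
   up (a small creation−hit gap), so the returned frame is the last
   moment of keeping up, i.e. the transition into the overwhelmed phase;
   the opposite (`≥`) reading is available behind a flag for sensitivity
   analysis. If the condition is never satisfied the trial is flagged
   overwhelmed-from-the-start;
5. SSR = mean hit rate from that start to the frame of peak creation
   rate. The start is then advanced one evaluation step at a time while
   (a) advancing increases the SSR or (b) the keeping-up condition held
   anywhere in the preceding 5 s, never past the peak (single-frame
   results are flagged). Rule (b) in practice pushes the start ~5 s past
   the transition, excluding ramp contamination; rule (a) is
   improvement-only, so refined SSR ≥ unrefined SSR when only it fires.

Trailing windows were chosen for the windowed statistics (the window
ends at the current frame) because detection asks for the *latest*
keeping-up frame — a causal question. Distractor events never enter the
rates; only target creations and target hits do.

### Evaluation resolution

Exact trailing-window order statistics cost O(n·w) per trial
(28,001 frames × 1001-frame windows), which is prohibitive over the
32,400-trial sweeps. The implementation therefore evaluates the windowed
median/MAD on a stride grid and subsamples window contents:

* package defaults: evaluate every 25 frames (0.125 s), sample the
  window every 5 frames — used for single-trial analyses;
* sweep setting: every 100 frames (0.5 s), window sampled every 10
  frames — the series are piecewise-linear over 100-frame segments, so
  this grid loses essentially nothing.

Exact evaluation (stride 1, subsample 1) is available and is what the
unit tests use on short series. On smooth series the coarse and exact
statistics agree to ~10⁻³ Hz, far below trial-to-trial noise; SSR means
are additionally insensitive because they average hundreds to thousands
of frames.

## Per-task regression signatures

For each model, every system's SSR in every non-baseline task is
regressed (OLS) on its SSR in the baseline task, giving 99 per-task
(slope, intercept) pairs. The predicted signatures: additive — slopes
near 1 (all systems lose the same amount); multiplicative — slopes < 1
with small intercepts (the best systems lose the most); flexible —
slopes < 1 with positive intercepts and the regression crossing the
unity line at a positive rate (the shared pool shelters weak systems).
OLS is used for these summaries; the Bayesian machinery is reserved for
cohort analyses where the priors are part of the published model.

One structural caveat, established by exact arithmetic on the grid
means: for strongly *asymmetric* tasks (e.g. one module at d = 0.7, the
other unloaded) the multiplicative model's per-task OLS intercept is
genuinely positive, up to ≈ +0.19 Hz on these grids. The systems whose
loaded module is not the baseline bottleneck form a wedge above the
dominant line, truncated asymmetrically by the grid edge, and this wedge
is ~45% of systems — robust estimators do not remove it. Symmetric
(diagonal) task changes give intercepts of exactly 0. A ±0.12 Hz band
therefore characterises near-symmetric task manipulations, not the
maximum over all 99 tasks; the acceptance suite computes and reports the
full-sweep maximum as measured.

Systems with SSR at the output floor (≤ 0.05 Hz; the additive clamp
region, where update noise smears a clamped plateau into small positive
rates) can be excluded from the regressions via `exclude_floor` —
fixed-capacity predictions are only meaningful for systems that still
produce output in both tasks.

## Bayesian analyses

Both analyses follow the Kruschke estimation style: report the posterior
mode (Gaussian-KDE argmax, Silverman bandwidth), the 95% highest-density
interval (narrowest-window algorithm on sorted samples), and a decision
against a region of practical equivalence: HDI inside ROPE → practically
equivalent; disjoint → practically different; otherwise undecided, with
the posterior mass below/inside/above the ROPE reported.

**Difference model.** Per-participant SSR differences (defined as
baseline minus harder task, so a drop is positive) are
`Normal(μ, σ)` with priors `μ ~ Normal(sample mean difference,
10·sd_baseline)` and `σ ~ Uniform(0.001·sd_baseline, 1000·sd_baseline)`.
The default ROPE for μ is ±0.30 Hz — the test-retest variability of a
single participant's SSR.

**Robust regression.** `SSR_task2 ~ t_ν(β0 + β1·SSR_task1, σ)` with
`σ ~ Uniform(0.001, 1000)`, `ν ~ Exponential(mean 30)`,
`β0 ~ Normal(0, ·)`, `β1 ~ Normal(1, ·)`. The Normal priors are read in
the precision convention (precision 0.01 → SD 10), giving vague,
data-dominated priors — consistent with reported estimates far from the
prior centres; the variance reading (SD 0.1) is available via
`precision_priors=False`. The regression is fit on raw Hz scales, since
the priors are stated on raw parameters. Default ROPEs: slope
(0.95, 1.05), intercept (−0.12, 0.12) Hz.

**Sampling.** Both posteriors are sampled with the emcee
affine-invariant ensemble (default 32 walkers, 1000 burn-in + 2000 kept
steps, seeded); scale parameters are sampled on the log scale with the
Jacobian included, and walkers are initialised near the least-squares
solution. Post-burn-in draws are grouped into 4 walker groups that play
the role of the conventional 4 chains for diagnostics: Brooks–Gelman–
Rubin shrink factor, effective sample size and Monte Carlo standard
error (arviz), and autocorrelation at lags 1/5/10/50. A fit passes when
all shrink factors are < 1.1 and ESS clears the configured floor.

**Cohort experiment.** `run_cohort_experiment` chains the difference
model (with its ROPE decision), the same model per baseline-SSR quartile
(quartile boundaries at n/4 ranks, ties broken by row order), and the
robust regression. The quartile stratification is a convenience rerun of
the difference model, not new inference.

## Synthetic data

**Cohorts** (`generate_cohort`): baseline SSRs are
`Normal(1.7, 0.4) Hz` truncated positive — a fixture choice spanning a
healthy-adult range, not an empirical claim. The harder-task SSR is
`intercept + slope·SSR₁ + scale·t_df + Normal(0, retest_sd)`. The
default retest SD is 0.15 Hz so that ±2 SD reproduces the ±0.30 Hz
ROPE. Measurement noise is applied to the task-2 column only: the
regression's data model conditions on task-1 SSR, and adding regressor
noise would attenuate recovered slopes — a deliberate mismatch the
generator avoids because the analyses assume the conditional model.

**Trials** (`generate_trial_events`): exactly 300 targets (OH/TOH) or
200 targets + 100 randomly interleaved distractors (OHA/TOHA) over
140 s. The creation rate starts at 0.5 Hz and accelerates as
`r(t) = 0.5 + a·t²` with `a` fixed by the total count, giving a final
rate of ≈ 5.4 Hz for 300 objects — comfortably above the 3.5 Hz top of
the capacity range, so every participant of interest finishes
overwhelmed, the same guarantee the simulated environment's 7.5 Hz ramp
provides (a linear ramp constrained to the same totals tops out at
≈ 3.8 Hz and cannot overwhelm the strongest participants). Event times
are the inverse-CDF images of sorted uniforms, so counts are exact for
every seed. Hits are produced by a single-server queue: the
server engages the oldest unexpired object no faster than one per
`1/capacity` seconds (lognormal jitter, CV 0.1), objects expire 1.5 s
after creation, and contacts lag engagement by 0.1 s. Early in a trial
the hit rate tracks creations (data-limited); once creations outpace
capacity the queue is never empty and the hit rate saturates at the
capacity (resource-limited), which is what SSR extraction recovers.

What the generator does *not* emulate: workspace geometry and object
kinematics, hit/miss adjudication from trajectories, distractor
inhibition failures, fatigue or motivation drift, and the human tasks'
true (unpublished) creation schedule. Passing recovery tests therefore
show that the *analysis pipeline* is correct under the assumed data
model, not that the data model captures human behaviour.

## Problem sizes and runtimes

Prediction sweeps run all 324 systems × 100 tasks × 281 update points
per model (~2 min/model single-core at the sweep evaluation
resolution). HDI calibration uses 100 cohorts of 60 participants with a
reduced sampler (24 walkers, 600 + 1200 steps); trial-level recovery
uses 11 capacities × 6 seeds. These sizes were chosen to give stable
estimates at desk scale; all are parameters, not constants.

## Known limitations

* The extraction's stride/subsample grid trades ~10⁻³ Hz accuracy in
  the windowed statistics for tractability; pathological series varying
  faster than the 5 s smoothing scale would need exact mode.
* The overwhelmed-phase rule implements the keeping-up reading of the
  detection condition (see above); both readings are exposed.
* `emcee` walker groups are not fully independent chains; shrink factors
  are interpreted accordingly (independent-ensemble replication is
  available by refitting with different seeds).
* The additive model's capacity clamp at 0 Hz makes near-floor SSRs
  noise-dominated; floor exclusion is the supported remedy.
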