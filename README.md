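# bottleneck-lab

Tools for studying how capacity limits create information bottlenecks in
ongoing rapid motor behaviour — for motor-control and cognitive-modelling
researchers who work with Object-Hit-style tasks (hit a growing stream of
moving targets until you are overwhelmed) and want to simulate competing
capacity models, extract steady-state performance from behavioural event
streams, and make Bayesian practical-equivalence decisions about task
differences.

## The models and the measure

A behaving agent is modelled as two limited-capacity modules in series
(perception/decision feeding motor output) that work on different inputs
in parallel — *pipelined* processing. With input arriving at rate
`input(t)` and final module capacities `capA`, `capB` (Hz), the output
rate is

```
output(t) = max(0, min(input(t), capA(t), capB(t)))
```

so once input outpaces the weakest module, that module is the bottleneck
and output plateaus. Task difficulty `d ∈ (0, 1]` loads a module either
additively (`cap − 1 + d`), multiplicatively (`cap · d`), or
multiplicatively with a shared central pool that is reallocated each step
to the weaker module (*flexible capacity*). Simulating grids of systems
(324) and tasks (100) distinguishes the models by the per-task regression
of task SSR on baseline SSR: additive → slope ≈ 1; multiplicative →
slope < 1, small intercept; flexible → slope < 1 with a positive
intercept (weak performers are sheltered).

Behavioural performance is summarised by the **steady-state rate (SSR)**:
the mean target-hit rate during the overwhelmed phase of a trial.
Instantaneous rates come from two passes of a Kolmogorov–Zurbenko filter
(5 s window) over binned events; the overwhelmed phase starts at the
latest frame where the trailing-window `median(creation − hit) − MAD <
0.1 Hz`, refined forward per the published rules.

Cohort comparisons are Bayesian: per-participant SSR differences are
`Normal(μ, σ)`, and paired task SSRs follow the robust regression
`SSR₂ ~ t_ν(β0 + β1·SSR₁, σ)`; each parameter is reported as posterior
mode + 95% HDI and decided against a region of practical equivalence
(ROPE): ±0.30 Hz for differences, (0.95, 1.05) for the slope,
(−0.12, 0.12) Hz for the intercept. See `docs/methods.md` for priors,
sampler and diagnostics.

## Worked example

Generate a synthetic 487-participant cohort whose harder task relates to
the baseline by `SSR₂ = 0.16 + 0.55·SSR₁ + t-noise` (the regime of
comparing Object-Hit to its hit-and-avoid variant), then run the full
Bayesian analysis:

```
python analysis/03_cohort_experiment.py
```

prints

```
n = 487 participants
mean drop 0.589 Hz; posterior mode 0.589 Hz, 95% HDI (0.563, 0.617) -> different from 0 Hz
  quartile 1: mean drop +0.399 Hz (different)
  quartile 2: mean drop +0.510 Hz (different)
  quartile 3: mean drop +0.641 Hz (different)
  quartile 4: mean drop +0.806 Hz (different)
beta1: mode 0.563, HDI (0.505, 0.630) vs truth 0.55 [covered: True] -> different
beta0: mode 0.120, HDI (0.020, 0.229) vs truth 0.16 [covered: True] -> undecided
chain diagnostics passed: True (max shrink 1.003)
```

Read: the cohort's mean performance drop (0.589 Hz ≈ 82 fewer targets
over a 140 s trial) is practically different from 0 Hz — its HDI lies
entirely outside the ±0.30 Hz ROPE; the drop grows with baseline skill
(quartile 4, the best performers, drop most); the regression slope's HDI
covers the generating 0.55 and sits wholly below the (0.95, 1.05) ROPE,
the flexible-capacity signature; and the positive intercept covers the
generating 0.16 Hz while straddling its ROPE edge, hence "undecided".

The other drivers: `analysis/01_model_predictions.py` runs the three
full simulation sweeps and prints each model's regression signature;
`analysis/02_trial_recovery.py` checks that SSR extraction recovers
known bottleneck capacities from synthetic event streams. Equivalent
one-off operations are available on the CLI:

```
bottleneck-lab simulate --model flexible --seed 1 --out results/
bottleneck-lab make-trial --capacity 1.5 --task OHA --seed 3 --out events.csv
bottleneck-lab extract-ssr --events events.csv --out ssr.json
bottleneck-lab make-cohort --n 200 --seed 5 --out cohort.csv
bottleneck-lab compare-tasks --pairs cohort.csv --seed 5 --out report.json
```

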