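"""Synthetic cohorts and trial event streams.

Human Object-Hit data are not public, so the pipeline is exercised on
synthetic stand-ins that carry the statistical structure the analysis
assumes:

* ``generate_cohort`` draws paired steady-state rates for two tasks from
  the regression data model (baseline SSR from a truncated-normal
  population, harder-task SSR = intercept + slope * baseline + t-noise,
  plus test-retest measurement noise on the harder task), so recovery of
  the generating slope and intercept can be checked end to end.
* ``generate_trial_events`` emits a whole trial's creation and hit
  events: exactly 300 targets (OH/TOH) or 200 targets + 100 distractors
  (OHA/TOHA) over ~140 s with a monotonically increasing creation rate,
  hits produced by pushing creations through a single-server bottleneck
  at the participant's capacity, so every trial ends overwhelmed and the
  extracted SSR should recover the latent capacity.

The human tasks' exact creation schedule is not published; the ramp here
starts at 0.5 Hz and rises linearly, with its slope fixed by the total
object count -- an emulation adequate for parameter recovery, not a
reconstruction of the task.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rate_analysis import EventStream

__all__ = [
    "TASKS",
    "ParticipantSpec",
    "CohortConfig",
    "generate_cohort",
    "generate_trial_events",
]

#: Object counts per task: (targets, distractors).
TASKS = {
    "OH": (300, 0),
    "TOH": (300, 0),
    "OHA": (200, 100),
    "TOHA": (200, 100),
}

DEFAULT_DURATION_S = 140.0
DEFAULT_RETEST_SD = 0.15  # Hz; +/- 2 SD spans the +/- 0.30 Hz ROPE
_START_RATE = 0.5         # Hz, creation rate at trial start
_OBJECT_LIFETIME_S = 1.5  # object expires (missed) this long after creation
_HIT_LATENCY_S = 0.1      # contact lag after the server engages an object
_SERVICE_CV = 0.1         # lognormal CV of the inter-hit service interval


@dataclass(frozen=True)
class ParticipantSpec:
    """Latent ability of one synthetic participant.

    ``capacity_hz`` is the bottleneck throughput (may be ``inf`` for an
    unbounded participant or 0 for a floor case); ``retest_sd`` is the
    trial-to-trial SD of the measured SSR.
    """

    capacity_hz: float
    retest_sd: float = DEFAULT_RETEST_SD

    def __post_init__(self) -> None:
        if self.capacity_hz < 0:
            raise ValueError("capacity must be nonnegative")
        if self.retest_sd < 0:
            raise ValueError("retest SD must be nonnegative")


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for a paired-SSR cohort.

    The harder task's SSR is ``intercept + slope * ssr1 + scale * t_df +
    Normal(0, retest_sd)``.  Baseline SSRs are Normal(1.7, 0.4) truncated
    positive by default -- a fixture choice spanning the healthy-control
    range, not an empirical claim.
    """

    n: int
    slope: float = 0.55
    intercept: float = 0.16
    residual_scale: float = 0.2
    residual_df: float = 10.0
    retest_sd: float = DEFAULT_RETEST_SD
    baseline_mean: float = 1.7
    baseline_sd: float = 0.4
    task_pair: tuple = ("OH", "OHA")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 participants")
        if self.residual_scale <= 0:
            raise ValueError("residual scale must be positive")
        if self.baseline_sd <= 0 or self.residual_df <= 0:
            raise ValueError("invalid cohort config")


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a paired SSR table: participant_id, ssr_task1_hz, ssr_task2_hz.

    Deterministic under a fixed config (identical seeds give identical
    tables).  The baseline SSR is the conditioning variable of the
    regression's data model, so measurement noise is applied to the
    task-2 column only; noise on the regressor would attenuate recovered
    slopes, which is not part of the assumed data model.
    """
    rng = np.random.default_rng(config.seed)
    ssr1 = _truncated_normal(rng, config.baseline_mean, config.baseline_sd, config.n)
    resid = config.residual_scale * rng.standard_t(config.residual_df, config.n)
    retest = (
        rng.normal(0.0, config.retest_sd, config.n) if config.retest_sd > 0 else 0.0
    )
    ssr2 = config.intercept + config.slope * ssr1 + resid + retest
    return pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(config.n)],
            "ssr_task1_hz": ssr1,
            "ssr_task2_hz": ssr2,
        }
    )


def _truncated_normal(rng, mean, sd, n):
    out = rng.normal(mean, sd, n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def _creation_times(rng, n_objects: int, duration: float) -> np.ndarray:
    """Exact-count event times with a monotonically accelerating rate.

    The rate is ``r(t) = r0 + a * t^2`` with ``a`` fixed so the integral
    equals ``n_objects``; the final rate ``3 * n / T - 2 * r0`` (~5.4 Hz
    for 300 objects over 140 s) clears the whole 1-3.5 Hz capacity range
    with margin, so every participant of interest finishes overwhelmed --
    the same guarantee the simulated environment's ramp provides.  Times
    are the inverse-CDF images of sorted uniforms (the order-statistics
    construction of an inhomogeneous Poisson process conditioned on its
    count).
    """
    r0 = _START_RATE
    if 3.0 * n_objects / duration - 2.0 * r0 <= r0:
        raise ValueError("too few objects for an increasing ramp")
    a = 3.0 * (n_objects / duration - r0) / duration**2
    total = r0 * duration + a * duration**3 / 3.0
    u = np.sort(rng.random(n_objects)) * total
    # Invert Lambda(t) = r0 t + a t^3 / 3 numerically (monotone cubic).
    grid = np.linspace(0.0, duration, 20001)
    lam = r0 * grid + a * grid**3 / 3.0
    t = np.interp(u, lam, grid)
    return np.clip(t, 0.0, duration)


def _serve_queue(
    rng,
    creation_times: np.ndarray,
    capacity_hz: float,
    duration: float,
) -> np.ndarray:
    """Push creations through a single-server bottleneck; return hit times.

    The server engages the oldest unexpired object no faster than one per
    ``1/capacity`` seconds (lognormal jitter, CV 0.1); objects not engaged
    within ``_OBJECT_LIFETIME_S`` expire as misses.  Early in the trial the
    hit rate tracks the creation rate (data-limited); once creations
    outpace capacity the queue is always occupied and the hit rate
    saturates at capacity (resource-limited), which is what the SSR
    extraction should recover.
    """
    if capacity_hz == 0:
        return np.empty(0)
    times = np.sort(creation_times)
    n = len(times)
    hits = []
    sigma = math.sqrt(math.log(1.0 + _SERVICE_CV**2))
    i = 0            # next unconsidered creation
    ready = 0.0      # server free from this time on
    pending: list[float] = []
    while True:
        # admit creations up to the server-ready time
        while i < n and times[i] <= ready:
            pending.append(times[i])
            i += 1
        # drop expired objects
        while pending and pending[0] + _OBJECT_LIFETIME_S < ready:
            pending.pop(0)
        if pending:
            serve_at = max(ready, pending[0])
        elif i < n:
            serve_at = max(ready, times[i])
            pending.append(times[i])
            i += 1
        else:
            break
        if serve_at > duration:
            break
        pending.pop(0)
        hit_time = serve_at + _HIT_LATENCY_S
        if hit_time <= duration:
            hits.append(hit_time)
        if math.isinf(capacity_hz):
            ready = serve_at
        else:
            interval = (1.0 / capacity_hz) * rng.lognormal(
                -0.5 * sigma * sigma, sigma
            )
            ready = serve_at + interval
    return np.asarray(hits)


def generate_trial_events(
    participant: ParticipantSpec,
    task: str = "OH",
    seed: int | np.random.SeedSequence = 0,
    duration_s: float = DEFAULT_DURATION_S,
    frame_rate: float = 200.0,
) -> EventStream:
    """Generate one trial's event stream for a synthetic participant.

    Exactly 300 target creations (OH/TOH) or 200 targets + 100 distractors
    (OHA/TOHA) are scheduled over ``duration_s`` with a monotonically
    increasing creation rate; hit events are the creations that survive
    the participant's capacity bottleneck.  An infinite-capacity
    participant hits everything; a zero-capacity participant hits nothing.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(TASKS)}")
    n_targets, n_distractors = TASKS[task]
    rng = np.random.default_rng(seed)

    all_times = _creation_times(rng, n_targets + n_distractors, duration_s)
    if n_distractors:
        d_idx = rng.choice(len(all_times), size=n_distractors, replace=False)
        mask = np.zeros(len(all_times), dtype=bool)
        mask[d_idx] = True
        creation_times = all_times[~mask]
        distractor_times = all_times[mask]
    else:
        creation_times = all_times
        distractor_times = np.empty(0)

    hit_times = _serve_queue(rng, creation_times, participant.capacity_hz, duration_s)
    return EventStream(
        duration_s=duration_s,
        frame_rate=frame_rate,
        creation_times=creation_times,
        hit_times=hit_times,
        distractor_times=distractor_times,
        distractor_hit_times=np.empty(0),
    )
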