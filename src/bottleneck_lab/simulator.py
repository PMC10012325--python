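"""Limited-capacity, pipelined two-module processing systems.

A simulated agent is a pair of processing modules connected in series
(e.g. perception/decision feeding motor output) that nevertheless work on
different inputs in parallel -- pipelined processing.  Each module has a
limited processing capacity in Hz (objects per second).  Once the
environment's input rate exceeds the capacity of the most restricted
module, that module forms a bottleneck and the system's output plateaus at
the bottleneck capacity.

Three models describe how task difficulty loads the modules:

* **Additive Workload** -- a harder task subtracts a fixed amount from each
  module's capacity: ``final = initial - 1 + d`` with difficulty factor
  ``d`` in (0, 1] (d = 1 is the easiest task).
* **Multiplicative Workload** -- a harder task scales capacity:
  ``final = initial * d``.
* **Flexible Capacity** -- multiplicative loading, but part of the system's
  capability lives in a shared central pool that is reallocated each step
  to shore up the weaker module.

Trials mimic the Object-Hit family of rapid motor tasks: the environment's
input rate ramps linearly until the system is overwhelmed, and the whole
trial is recorded at 200 frames/s with model quantities computed at
100-frame update points and linearly interpolated in between.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MODELS",
    "FRAME_RATE",
    "FRAMES_PER_UPDATE",
    "DEFAULT_N_UPDATES",
    "TaskEnvironment",
    "SystemSpec",
    "InputSchedule",
    "TrialTrace",
    "build_task_grid",
    "build_system_grid",
    "final_capacity_additive",
    "final_capacity_multiplicative",
    "allocate_shared",
    "input_rate",
    "step_output",
    "simulate_trial",
    "run_experiment",
    "serial_throughput",
]

MODELS = ("additive", "multiplicative", "flexible")

FRAME_RATE = 200            # samples/s, matches the robot's recording rate
FRAMES_PER_UPDATE = 100     # model quantities recomputed every 100 frames
DEFAULT_N_UPDATES = 281     # 281 update points -> 28,001 frames ~= 140 s

#: Per-update-point noise scales: difficulty draws ~ N(d, 0.05),
#: capacity draws ~ N(cap, 0.05 Hz).
DIFFICULTY_SD = 0.05
CAPACITY_SD = 0.05

_CAP_GRID_DECI = range(10, 36)   # mean capacities 1.0 .. 3.5 Hz in 0.1 steps


@dataclass(frozen=True)
class TaskEnvironment:
    """One task: a pair of module difficulty factors in (0, 1].

    ``d = 1`` is the easiest possible load for a module; smaller values
    load the module more heavily.  The baseline task is ``(1.0, 1.0)``.
    """

    d_a: float
    d_b: float

    def __post_init__(self) -> None:
        for d in (self.d_a, self.d_b):
            if not 0 < d <= 1:
                raise ValueError(f"difficulty factor {d} outside (0, 1]")

    @property
    def is_baseline(self) -> bool:
        return self.d_a == 1.0 and self.d_b == 1.0


@dataclass(frozen=True)
class SystemSpec:
    """One simulated agent: module capacities, model kind, shared pool.

    For flexible systems the stored ``cap_a``/``cap_b`` have already been
    reduced by the per-module pool contribution, so the system's total
    capability ``cap_a + cap_b + pool`` is conserved across models.
    ``mean_cap_a``/``mean_cap_b`` record the grid cell the capacities were
    drawn from (Normal with SD 0.05 Hz).
    """

    cap_a: float
    cap_b: float
    model: str
    pool: float = 0.0
    mean_cap_a: float = float("nan")
    mean_cap_b: float = float("nan")
    system_id: int = -1

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model kind {self.model!r}")
        if self.cap_a <= 0 or self.cap_b <= 0:
            raise ValueError("module capacities must be positive")
        if self.pool < 0:
            raise ValueError("pool must be nonnegative")
        if self.model != "flexible" and self.pool != 0:
            raise ValueError("only flexible systems carry a shared pool")


@dataclass(frozen=True)
class InputSchedule:
    """Linear ramp of the environment's input rate.

    ``rate(t) = base + ramp * t + n / noise_scale`` with ``t`` the update
    index and ``n`` a standard-normal draw; the realised rate is clamped
    at zero.  Defaults ramp 0.5 -> 7.5 Hz over 281 update points, which
    exceeds every grid capacity and guarantees an overwhelmed finish.
    """

    base: float = 0.5
    ramp: float = 0.025
    noise_scale: float = 10.0


@dataclass
class TrialTrace:
    """Per-frame record of one trial at ``frame_rate`` samples/s.

    All arrays have equal length ``(n_updates - 1) * 100 + 1``; values at
    frames between update points are linear interpolations of the
    bracketing update-point values.
    """

    frame_rate: float
    input: np.ndarray
    cap_a_final: np.ndarray
    cap_b_final: np.ndarray
    output: np.ndarray
    update_frames: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_frames(self) -> int:
        return len(self.input)

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) / self.frame_rate


def build_task_grid() -> list[TaskEnvironment]:
    """The 10x10 grid of task environments {0.1, ..., 1.0}^2.

    Row-major by ``(d_a, d_b)``; values exact to one decimal.
    """
    levels = [round(k / 10, 1) for k in range(1, 11)]
    return [TaskEnvironment(a, b) for a, b in itertools.product(levels, levels)]


def _kept_capacity_cells() -> list[tuple[int, int]]:
    """Grid cells (in decicapacity integers) passing the imbalance filter.

    A cell ``(a, b)`` is kept iff ``|a - b| < a / 3``, evaluated exactly in
    integer tenths (``3 * |A - B| < A``) so ties at exact thirds -- e.g.
    a = 1.2, b = 1.6 -- are excluded.  This prevents one module from being
    completely dominated by the other's bottleneck and yields 324 cells.
    """
    return [
        (A, B)
        for A in _CAP_GRID_DECI
        for B in _CAP_GRID_DECI
        if 3 * abs(A - B) < A
    ]


def build_system_grid(
    model: str,
    pool_per_module: float = 0.5,
    seed: int | np.random.SeedSequence = 0,
) -> list[SystemSpec]:
    """Draw one system per kept capacity cell (324 systems).

    Mean capacities range over {1.0, 1.1, ..., 3.5} Hz for each module;
    realised capacities are Normal(mean, 0.05 Hz) truncated positive
    (redraw).  For the flexible model, ``pool_per_module`` (paper value
    0.5 Hz) is subtracted from each drawn capacity and the shared pool is
    ``2 * pool_per_module``, conserving cumulative capability.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model kind {model!r}")
    if pool_per_module < 0:
        raise ValueError("pool_per_module must be nonnegative")
    pool_pm = pool_per_module if model == "flexible" else 0.0

    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng = np.random.default_rng(ss)

    systems = []
    for sys_id, (A, B) in enumerate(_kept_capacity_cells()):
        mean_a, mean_b = A / 10, B / 10
        cap_a = _positive_normal(rng, mean_a, CAPACITY_SD)
        cap_b = _positive_normal(rng, mean_b, CAPACITY_SD)
        if pool_pm > 0:
            if pool_pm >= min(cap_a, cap_b):
                raise ValueError(
                    f"pool_per_module {pool_pm} >= drawn capacity "
                    f"min({cap_a:.3f}, {cap_b:.3f}); would leave a module "
                    "with nonpositive capacity"
                )
            cap_a -= pool_pm
            cap_b -= pool_pm
        systems.append(
            SystemSpec(
                cap_a=cap_a,
                cap_b=cap_b,
                model=model,
                pool=2 * pool_pm,
                mean_cap_a=mean_a,
                mean_cap_b=mean_b,
                system_id=sys_id,
            )
        )
    return systems


def _positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    # Capacities are positive reals; redraw the (astronomically rare) tail.
    while True:
        x = rng.normal(mean, sd)
        if x > 0:
            return x


def final_capacity_additive(cap: float, d: float) -> float:
    """Additive Workload: ``final = cap - 1 + d``, clamped at zero.

    The easiest task (d = 1) leaves capacity unchanged; the hardest grid
    task (d = 0.1) costs 0.9 Hz.  Clamping keeps nonphysical negative
    capacities out of downstream minima.
    """
    return max(0.0, cap - 1.0 + d)


def final_capacity_multiplicative(cap: float, d: float) -> float:
    """Multiplicative Workload: ``final = cap * d``."""
    return cap * d


def allocate_shared(cap_a: float, cap_b: float, pool: float):
    """Assign the shared central pool to the weaker module.

    If the capacity gap exceeds the pool, the smaller capacity receives
    the entire pool; otherwise both modules are raised to the common value
    ``(cap_a + cap_b + pool) / 2``.  Either way the sum of the outputs is
    ``cap_a + cap_b + pool``.
    """
    if pool < 0:
        raise ValueError("pool must be nonnegative")
    if abs(cap_a - cap_b) > pool:
        if cap_a < cap_b:
            return cap_a + pool, cap_b
        return cap_a, cap_b + pool
    level = (cap_a + cap_b + pool) / 2.0
    return level, level


def input_rate(
    step: int,
    rng: np.random.Generator | None = None,
    schedule: InputSchedule = InputSchedule(),
) -> float:
    """Environment input rate at an update point, clamped at zero.

    ``step`` counts 100-frame update points (0.5 s apart at 200 frames/s),
    so the default ramp runs 0.5 Hz at step 0 to 7.5 Hz at step 280.
    """
    if step < 0:
        raise ValueError("step must be nonnegative")
    noise = 0.0
    if rng is not None and schedule.noise_scale:
        noise = rng.standard_normal() / schedule.noise_scale
    return max(0.0, schedule.base + schedule.ramp * step + noise)


def step_output(input_hz: float, cap_a_final: float, cap_b_final: float) -> float:
    """System output: ``max(0, min(input, cap_a_final, cap_b_final))``.

    The pipeline's throughput is the minimum of what the environment
    offers and what each module can process.
    """
    return max(0.0, min(input_hz, cap_a_final, cap_b_final))


def _trial_rng(seed, system_id: int, task_index: int) -> np.random.Generator:
    """Deterministic per-(system, task) substream from one root seed."""
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    child = np.random.SeedSequence(
        entropy=ss.entropy, spawn_key=(1, system_id + 1, task_index + 1)
    )
    return np.random.default_rng(child)


def simulate_trial(
    system: SystemSpec,
    task: TaskEnvironment,
    n_updates: int = DEFAULT_N_UPDATES,
    seed: int | np.random.SeedSequence | None = 0,
    rng: np.random.Generator | None = None,
    schedule: InputSchedule = InputSchedule(),
    noisy: bool = True,
    frame_rate: float = FRAME_RATE,
    frames_per_update: int = FRAMES_PER_UPDATE,
) -> TrialTrace:
    """Simulate one trial of one system in one task environment.

    At each of the ``n_updates`` update points the trial draws
    frame-specific difficulties ~ Normal(task difficulty, 0.05) and
    frame-specific capacities ~ Normal(module capacity, 0.05 Hz), applies
    the model's capacity rule (plus shared-pool allocation for flexible
    systems), and computes the output as the clamped minimum of input and
    final capacities.  All recorded series are linearly interpolated
    across the intermediate frames, giving ``(n_updates - 1) *
    frames_per_update + 1`` frames.

    With ``noisy=False`` every draw collapses to its mean (deterministic
    trace; useful for checking the bottleneck plateau analytically).
    """
    if n_updates < 2:
        raise ValueError("n_updates must be >= 2")
    if system.model not in MODELS:  # defensive; SystemSpec validates too
        raise ValueError(f"unknown model kind {system.model!r}")

    if rng is None:
        rng = np.random.default_rng(seed)

    steps = np.arange(n_updates)
    if noisy:
        d_a = rng.normal(task.d_a, DIFFICULTY_SD, n_updates)
        d_b = rng.normal(task.d_b, DIFFICULTY_SD, n_updates)
        cap_a = rng.normal(system.cap_a, CAPACITY_SD, n_updates)
        cap_b = rng.normal(system.cap_b, CAPACITY_SD, n_updates)
        noise = rng.standard_normal(n_updates) / schedule.noise_scale
    else:
        d_a = np.full(n_updates, task.d_a)
        d_b = np.full(n_updates, task.d_b)
        cap_a = np.full(n_updates, system.cap_a)
        cap_b = np.full(n_updates, system.cap_b)
        noise = np.zeros(n_updates)

    inputs = np.maximum(0.0, schedule.base + schedule.ramp * steps + noise)

    if system.model == "additive":
        fin_a = np.maximum(0.0, cap_a - 1.0 + d_a)
        fin_b = np.maximum(0.0, cap_b - 1.0 + d_b)
    else:  # multiplicative loading, optionally with flexible allocation
        fin_a = np.maximum(0.0, cap_a * d_a)
        fin_b = np.maximum(0.0, cap_b * d_b)
        if system.model == "flexible":
            gap = np.abs(fin_a - fin_b)
            whole_pool = gap > system.pool
            level = (fin_a + fin_b + system.pool) / 2.0
            a_small = fin_a < fin_b
            new_a = np.where(
                whole_pool, np.where(a_small, fin_a + system.pool, fin_a), level
            )
            new_b = np.where(
                whole_pool, np.where(a_small, fin_b, fin_b + system.pool), level
            )
            fin_a, fin_b = new_a, new_b

    outputs = np.maximum(0.0, np.minimum(inputs, np.minimum(fin_a, fin_b)))

    update_frames = steps * frames_per_update
    frames = np.arange(update_frames[-1] + 1)
    interp = lambda y: np.interp(frames, update_frames, y)  # noqa: E731
    return TrialTrace(
        frame_rate=frame_rate,
        input=interp(inputs),
        cap_a_final=interp(fin_a),
        cap_b_final=interp(fin_b),
        output=interp(outputs),
        update_frames=update_frames,
    )


def run_experiment(
    model: str,
    n_updates: int = DEFAULT_N_UPDATES,
    seed: int | np.random.SeedSequence = 0,
    pool_per_module: float = 0.5,
    tasks: list[TaskEnvironment] | None = None,
    systems: list[SystemSpec] | None = None,
    noisy: bool = True,
    smooth_window_s: float = 5.0,
    threshold: float = 0.1,
    eval_stride: int = 100,
    window_subsample: int = 10,
):
    """Simulate every system in every task and extract steady-state rates.

    Returns a tidy DataFrame with one row per (system, task) pair --
    32,400 rows for the full grids -- with columns ``system_id``,
    ``mean_cap_a``, ``mean_cap_b``, ``d_a``, ``d_b``, ``ssr_hz`` and the
    extraction bookkeeping (``overwhelmed_start``, ``flag_never_overwhelmed``).

    The trace's input series plays the role of the target creation rate
    and the output series the target hit rate; both are smoothed with the
    same two-pass Kolmogorov-Zurbenko filter applied to human event
    streams before ``steady_state_rate`` extraction.  Reproducible under a
    fixed seed: each trial uses a deterministic per-(system, task)
    substream.
    """
    import pandas as pd

    from .rate_analysis import RateSeries, kz_filter, steady_state_rate

    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    if tasks is None:
        tasks = build_task_grid()
    if systems is None:
        grid_ss = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(0,))
        systems = build_system_grid(model, pool_per_module, seed=grid_ss)

    window_frames = int(round(smooth_window_s * FRAME_RATE)) + 1

    rows = []
    for system in systems:
        for t_idx, task in enumerate(tasks):
            rng = _trial_rng(ss, system.system_id, t_idx)
            try:
                trace = simulate_trial(
                    system, task, n_updates=n_updates, rng=rng, noisy=noisy
                )
                creation = RateSeries(
                    trace.frame_rate,
                    kz_filter(trace.input, window_frames, 2),
                )
                hit = RateSeries(
                    trace.frame_rate,
                    kz_filter(trace.output, window_frames, 2),
                )
                result = steady_state_rate(
                    creation,
                    hit,
                    threshold=threshold,
                    window_s=smooth_window_s,
                    eval_stride=eval_stride,
                    window_subsample=window_subsample,
                    keep_rate_difference=False,
                )
            except Exception as exc:  # pragma: no cover - defensive
                raise RuntimeError(
                    f"trial failed for system {system.system_id} "
                    f"(means {system.mean_cap_a}, {system.mean_cap_b}), "
                    f"task ({task.d_a}, {task.d_b})"
                ) from exc
            rows.append(
                (
                    system.system_id,
                    system.mean_cap_a,
                    system.mean_cap_b,
                    task.d_a,
                    task.d_b,
                    result.ssr,
                    result.overwhelmed_start,
                    result.never_overwhelmed,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "system_id",
            "mean_cap_a",
            "mean_cap_b",
            "d_a",
            "d_b",
            "ssr_hz",
            "overwhelmed_start",
            "flag_never_overwhelmed",
        ],
    )


def serial_throughput(stage_durations_s) -> float:
    """Throughput ceiling of a strictly serial processing chain, in Hz.

    If perception, decision and movement had to finish one object before
    starting the next, the per-object time is the sum of the stage
    durations and the rate ceiling its reciprocal -- e.g. chained reaction
    times of 0.15 + 0.6 + 1.0 s give 1.75 s/object, ~0.57 Hz.  Pipelined
    processing escapes this ceiling, which is why observed steady-state
    rates approaching 2 Hz imply parallel stage execution.
    """
    total = float(np.sum(stage_durations_s))
    if total <= 0:
        raise ValueError("stage durations must sum to a positive time")
    return 1.0 / total
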