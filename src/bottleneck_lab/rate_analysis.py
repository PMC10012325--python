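"""Event streams to smoothed rates to steady-state rates.

The Object-Hit tasks record timestamped object-creation and object-hit
events.  Performance during the overwhelmed phase of a trial is summarised
by the steady-state rate (SSR): the average target hit rate from the start
of the overwhelmed phase to the frame where the target creation rate
peaks.  The extraction pipeline is

1. bin events into per-frame counts and smooth with two iterations of a
   Kolmogorov-Zurbenko (KZ) filter, 5 s window;
2. form the per-frame creation-minus-hit rate difference and its trailing
   5 s windowed median and median absolute deviation (MAD);
3. the overwhelmed phase begins at the latest frame where
   ``median - MAD < 0.1 Hz`` (the last frame of keeping up);
4. refine the start forward while doing so increases the SSR or while the
   keeping-up condition held anywhere in the preceding 5 s; the SSR is the
   mean hit rate from the refined start to the creation-rate peak.

Windowed order statistics at full frame resolution are O(n * window) per
trial; ``eval_stride`` and ``window_subsample`` evaluate them on a coarser
grid (exact when both are 1).  The smoothed series are slow-moving on the
5 s scale, so the defaults (0.125 s evaluation grid, 25 ms window
sampling) change extracted SSRs by far less than trial-to-trial noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

__all__ = [
    "EventStream",
    "RateSeries",
    "SteadyStateResult",
    "events_to_rate",
    "kz_filter",
    "windowed_median_mad",
    "detect_overwhelmed_start",
    "steady_state_rate",
]

DEFAULT_WINDOW_S = 5.0
DEFAULT_THRESHOLD_HZ = 0.1
DEFAULT_EVAL_STRIDE = 25
DEFAULT_WINDOW_SUBSAMPLE = 5

EVENT_TYPES = ("create_target", "hit_target", "create_distractor", "hit_distractor")


@dataclass
class EventStream:
    """Timestamped events of one trial.

    Only target creations and target hits enter the rate analysis;
    distractor events are carried for bookkeeping (the avoid variants
    create 100 distractors) but ignored by SSR extraction.
    """

    duration_s: float
    frame_rate: float
    creation_times: np.ndarray
    hit_times: np.ndarray
    distractor_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    distractor_hit_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        for name in (
            "creation_times",
            "hit_times",
            "distractor_times",
            "distractor_hit_times",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(self.hit_times) > len(self.creation_times):
            raise ValueError("more target hits than target creations")

    @classmethod
    def from_csv(cls, path, duration_s=None, frame_rate=200.0) -> "EventStream":
        """Read the event CSV dialect: columns ``time_s``, ``event_type``."""
        df = pd.read_csv(path)
        missing = {"time_s", "event_type"} - set(df.columns)
        if missing:
            raise ValueError(f"event CSV missing columns: {sorted(missing)}")
        unknown = set(df["event_type"]) - set(EVENT_TYPES)
        if unknown:
            raise ValueError(f"unknown event types: {sorted(unknown)}")
        if duration_s is None:
            duration_s = float(df["time_s"].max())
        times = lambda kind: df.loc[  # noqa: E731
            df["event_type"] == kind, "time_s"
        ].to_numpy()
        return cls(
            duration_s=duration_s,
            frame_rate=frame_rate,
            creation_times=times("create_target"),
            hit_times=times("hit_target"),
            distractor_times=times("create_distractor"),
            distractor_hit_times=times("hit_distractor"),
        )

    def to_csv(self, path) -> None:
        frames = [
            pd.DataFrame({"time_s": t, "event_type": kind})
            for kind, t in (
                ("create_target", self.creation_times),
                ("hit_target", self.hit_times),
                ("create_distractor", self.distractor_times),
                ("hit_distractor", self.distractor_hit_times),
            )
            if len(t)
        ]
        out = pd.concat(frames, ignore_index=True).sort_values("time_s")
        out.to_csv(path, index=False)


@dataclass
class RateSeries:
    """Instantaneous rate per frame (Hz) at ``frame_rate`` samples/s."""

    frame_rate: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SteadyStateResult:
    """SSR with overwhelmed-phase bounds for one trial."""

    ssr: float
    overwhelmed_start: int
    peak_creation_frame: int
    detected_start: int
    never_overwhelmed: bool = False
    single_frame: bool = False
    rate_difference: np.ndarray | None = None


def _truncated_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges average over the available samples."""
    x = np.asarray(x, dtype=float)
    sums = uniform_filter1d(x, window, axis=-1, mode="constant", cval=0.0) * window
    counts = (
        uniform_filter1d(
            np.ones(x.shape[-1]), window, mode="constant", cval=0.0
        )
        * window
    )
    return sums / np.round(counts)


def kz_filter(series, window_frames: int, iterations: int = 2):
    """Kolmogorov-Zurbenko filter: ``iterations`` passes of a centered
    moving average of ``window_frames`` samples (odd).

    Edges use the truncated window (mean over available samples) so the
    output length equals the input length.  Accepts a ``RateSeries`` or a
    plain array (also 2D, filtering the last axis) and returns the same
    kind.
    """
    if window_frames % 2 == 0:
        raise ValueError("window_frames must be odd")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    is_series = isinstance(series, RateSeries)
    x = series.values if is_series else np.asarray(series, dtype=float)
    if x.shape[-1] < window_frames:
        raise ValueError(
            f"window of {window_frames} frames exceeds series length {x.shape[-1]}"
        )
    for _ in range(iterations):
        x = _truncated_moving_average(x, window_frames)
    return RateSeries(series.frame_rate, x) if is_series else x


def events_to_rate(
    events,
    duration_s: float | None = None,
    frame_rate: float = 200.0,
    window_s: float = DEFAULT_WINDOW_S,
    iterations: int = 2,
) -> RateSeries:
    """Convert event times to a smoothed instantaneous rate in Hz.

    Events are binned into half-open per-frame intervals (an event at time
    ``tau`` lands in frame ``floor(tau * frame_rate)``), scaled by the
    frame rate to Hz, then KZ-filtered.  Total event mass is conserved up
    to edge truncation of the filter.
    """
    times = np.asarray(events, dtype=float)
    if duration_s is None:
        duration_s = float(times.max()) if len(times) else 0.0
    n_frames = int(round(duration_s * frame_rate)) + 1
    if len(times) and (times.min() < 0 or times.max() > duration_s):
        raise ValueError("event times outside [0, duration]")
    idx = np.minimum(np.floor(times * frame_rate).astype(int), n_frames - 1)
    counts = np.bincount(idx, minlength=n_frames).astype(float)
    rate = counts * frame_rate
    window_frames = int(round(window_s * frame_rate)) + 1
    if window_frames % 2 == 0:
        window_frames += 1
    return RateSeries(frame_rate, kz_filter(rate, window_frames, iterations))


def windowed_median_mad(
    values,
    frame_rate: float = 200.0,
    window_s: float = DEFAULT_WINDOW_S,
    eval_stride: int = 1,
    window_subsample: int = 1,
):
    """Trailing-window median and MAD per evaluated frame.

    For each evaluated frame ``f`` the statistics are taken over the
    trailing window ``[f - W + 1, f]`` (truncated at the series head),
    where ``W = window_s * frame_rate + 1`` frames.  The MAD uses the
    window's own median.  Returns ``(eval_frames, median, mad)``.

    ``eval_stride`` evaluates every k-th frame only; ``window_subsample``
    thins the window contents.  Both default to exact evaluation here;
    sweep-scale callers pass coarser settings.
    """
    x = values.values if isinstance(values, RateSeries) else np.asarray(values, float)
    if isinstance(values, RateSeries):
        frame_rate = values.frame_rate
    n = len(x)
    W = int(round(window_s * frame_rate)) + 1
    if W > n:
        raise ValueError("window longer than series")
    eval_frames = np.arange(0, n, eval_stride)
    if eval_frames[-1] != n - 1:  # always evaluate the final frame
        eval_frames = np.append(eval_frames, n - 1)
    med = np.empty(len(eval_frames))
    mad = np.empty(len(eval_frames))

    head = eval_frames < W - 1
    for i in np.flatnonzero(head):  # truncated windows at the series head
        win = x[0 : eval_frames[i] + 1 : window_subsample]
        m = np.median(win)
        med[i] = m
        mad[i] = np.median(np.abs(win - m))

    full = ~head
    if full.any():  # full windows, batched for speed
        windows = np.lib.stride_tricks.sliding_window_view(x, W)
        wins = windows[eval_frames[full] - (W - 1)][:, ::window_subsample]
        m = np.median(wins, axis=1)
        med[full] = m
        mad[full] = np.median(np.abs(wins - m[:, None]), axis=1)
    return eval_frames, med, mad


def detect_overwhelmed_start(
    creation: RateSeries,
    hit: RateSeries,
    threshold: float = DEFAULT_THRESHOLD_HZ,
    window_s: float = DEFAULT_WINDOW_S,
    eval_stride: int = DEFAULT_EVAL_STRIDE,
    window_subsample: int = DEFAULT_WINDOW_SUBSAMPLE,
    keeping_up: str = "lt",
):
    """Locate the start of the overwhelmed phase.

    The per-frame rate difference ``creation - hit`` stays near zero while
    the participant keeps up and grows once they are overwhelmed.  The
    returned frame is the latest evaluated frame at which
    ``windowed median(diff) - windowed MAD(diff) < threshold`` -- the last
    frame of keeping up, i.e. the transition into the overwhelmed phase.
    (The condition literally describes keeping up; ``keeping_up="ge"``
    flips the reading for sensitivity analysis.)

    Returns ``(start_frame, never_overwhelmed)``; if the condition is
    never satisfied the participant was overwhelmed from the start and
    ``(0, True)`` is returned.
    """
    if len(creation) != len(hit):
        raise ValueError("creation and hit series must be aligned")
    diff = creation.values - hit.values
    eval_frames, med, mad = windowed_median_mad(
        diff,
        frame_rate=creation.frame_rate,
        window_s=window_s,
        eval_stride=eval_stride,
        window_subsample=window_subsample,
    )
    crit = med - mad
    cond = crit < threshold if keeping_up == "lt" else crit >= threshold
    if not cond.any():
        return 0, True
    start = int(eval_frames[np.flatnonzero(cond)[-1]])
    return start, False


def steady_state_rate(
    creation: RateSeries,
    hit: RateSeries,
    threshold: float = DEFAULT_THRESHOLD_HZ,
    window_s: float = DEFAULT_WINDOW_S,
    eval_stride: int = DEFAULT_EVAL_STRIDE,
    window_subsample: int = DEFAULT_WINDOW_SUBSAMPLE,
    keep_rate_difference: bool = True,
) -> SteadyStateResult:
    """Extract the steady-state rate of one trial.

    SSR = mean hit rate from the overwhelmed-phase start to the frame of
    peak creation rate (inclusive).  The start is then advanced on the
    evaluation grid while either refinement condition holds: (1) advancing
    increases the SSR, or (2) the keeping-up condition
    (``median - MAD < threshold``) held at any evaluated point in the
    preceding ``window_s`` seconds.  The start never passes the peak; if
    it reaches the peak the SSR is a single-frame value and flagged.
    """
    if len(creation) != len(hit):
        raise ValueError("creation and hit series must be aligned")
    diff = creation.values - hit.values
    frame_rate = creation.frame_rate
    eval_frames, med, mad = windowed_median_mad(
        diff,
        frame_rate=frame_rate,
        window_s=window_s,
        eval_stride=eval_stride,
        window_subsample=window_subsample,
    )
    keeping = (med - mad) < threshold
    never_overwhelmed = not keeping.any()
    detected = 0 if never_overwhelmed else int(eval_frames[np.flatnonzero(keeping)[-1]])

    peak = int(np.argmax(creation.values))
    start = min(detected, peak)

    # O(1) inclusive means via a cumulative sum of the hit series.
    csum = np.concatenate([[0.0], np.cumsum(hit.values)])
    mean_to_peak = lambda s: (csum[peak + 1] - csum[s]) / (peak + 1 - s)  # noqa: E731

    W = int(round(window_s * frame_rate)) + 1
    keep_frames = eval_frames[keeping]
    step = max(1, eval_stride)
    guard = len(creation) // step + 2  # hard cap against infinite loops
    while start < peak and guard > 0:
        guard -= 1
        nxt = min(start + step, peak)
        improves = mean_to_peak(nxt) > mean_to_peak(start)
        recent_keeping_up = bool(
            np.any((keep_frames > start - W) & (keep_frames <= start))
        )
        if improves or recent_keeping_up:
            start = nxt
        else:
            break

    single = start >= peak
    ssr = float(mean_to_peak(start)) if not single else float(hit.values[peak])
    return SteadyStateResult(
        ssr=ssr,
        overwhelmed_start=start,
        peak_creation_frame=peak,
        detected_start=detected,
        never_overwhelmed=never_overwhelmed,
        single_frame=single,
        rate_difference=diff if keep_rate_difference else None,
    )
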