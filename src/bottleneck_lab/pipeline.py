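"""Study orchestration: model-prediction sweeps and cohort experiments.

``run_model_predictions`` reproduces the simulation side of the study:
every system of a model is simulated in every task environment, and for
each non-baseline task the steady-state rates are regressed (OLS) on the
baseline-task rates across systems.  The three models leave distinct
signatures in these per-task regressions:

* Additive Workload  -- slopes ~ 1 (every system loses the same amount);
* Multiplicative Workload -- slopes < 1 with intercepts ~ 0 Hz (the best
  systems lose the most, all systems keep producing);
* Flexible Capacity -- slopes < 1 with positive intercepts, the
  regression crossing the unity line at a positive rate (weak systems are
  sheltered by reallocating the shared pool).

``run_cohort_experiment`` mirrors the human-data analyses on a paired SSR
table: the Bayesian difference model with its ROPE decision, the same
model per baseline-quartile, and the robust t-regression with ROPE
decisions for slope and intercept.

Per-task summary regressions use ordinary least squares; the Bayesian
machinery is reserved for cohort analyses, where the priors are part of
the model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

from . import bayes, simulator
from .bayes import MCMCConfig, RopeInterval

__all__ = [
    "TaskRegression",
    "ModelPredictionReport",
    "run_model_predictions",
    "run_cohort_experiment",
    "targets_over_trial",
    "rope_multiple",
    "DEFAULT_FLOOR_EPS",
]

#: SSRs at or below this are treated as floored (zero-output) systems when
#: ``exclude_floor`` is set: the additive model clamps final capacities at
#: 0 Hz, and update noise smears a clamped plateau into small positive SSRs.
DEFAULT_FLOOR_EPS = 0.05


@dataclass
class TaskRegression:
    """Per-task OLS fit of SSR(task) on SSR(baseline) across systems."""

    d_a: float
    d_b: float
    slope: float
    intercept: float
    r_value: float
    n_systems: int

    @property
    def unity_crossing(self) -> float:
        """x where the fit meets the unity line (finite unless slope = 1)."""
        if self.slope == 1.0:
            return float("nan")
        return self.intercept / (1.0 - self.slope)


@dataclass
class ModelPredictionReport:
    model: str
    regressions: list[TaskRegression]
    ssr_table: pd.DataFrame = field(repr=False, default=None)

    @property
    def slopes(self) -> np.ndarray:
        return np.array([r.slope for r in self.regressions])

    @property
    def intercepts(self) -> np.ndarray:
        return np.array([r.intercept for r in self.regressions])

    def signature(self) -> dict:
        """The model's diagnostic signature over all per-task regressions."""
        slopes, intercepts = self.slopes, self.intercepts
        crossings = np.array([r.unity_crossing for r in self.regressions])
        return {
            "model": self.model,
            "n_tasks": len(self.regressions),
            "slope_min": float(slopes.min()),
            "slope_max": float(slopes.max()),
            "intercept_min": float(intercepts.min()),
            "intercept_max": float(intercepts.max()),
            "intercept_max_abs": float(np.abs(intercepts).max()),
            "all_slopes_near_unity": bool(
                (slopes > 0.95).all() and (slopes < 1.05).all()
            ),
            "all_slopes_below_unity": bool((slopes < 1.0).all()),
            "all_intercepts_near_zero": bool((np.abs(intercepts) <= 0.12).all()),
            "all_intercepts_positive": bool((intercepts > 0.0).all()),
            "crosses_unity_in_quadrant_one": bool(
                np.isfinite(crossings).all() and (crossings > 0.0).all()
            ),
        }

    def as_dict(self) -> dict:
        return {
            "signature": self.signature(),
            "per_task": [
                {
                    "d_a": r.d_a,
                    "d_b": r.d_b,
                    "slope": r.slope,
                    "intercept": r.intercept,
                    "r_value": r.r_value,
                    "n_systems": r.n_systems,
                }
                for r in self.regressions
            ],
        }


def per_task_regressions(
    ssr_table: pd.DataFrame,
    exclude_floor: bool = True,
    floor_eps: float = DEFAULT_FLOOR_EPS,
) -> list[TaskRegression]:
    """OLS of SSR(task) on SSR(baseline) for every non-baseline task.

    ``exclude_floor`` drops system pairs whose SSR sits at the output
    floor in either task; the fixed-capacity models' predictions are only
    meaningful for systems that still produce output in both tasks.
    """
    base = ssr_table[(ssr_table.d_a == 1.0) & (ssr_table.d_b == 1.0)]
    base_ssr = base.set_index("system_id")["ssr_hz"]
    out = []
    for (d_a, d_b), group in ssr_table.groupby(["d_a", "d_b"], sort=True):
        if d_a == 1.0 and d_b == 1.0:
            continue
        x = base_ssr.loc[group["system_id"]].to_numpy()
        y = group["ssr_hz"].to_numpy()
        if exclude_floor:
            keep = (x > floor_eps) & (y > floor_eps)
            x, y = x[keep], y[keep]
        fit = linregress(x, y)
        out.append(
            TaskRegression(
                d_a=float(d_a),
                d_b=float(d_b),
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                r_value=float(fit.rvalue),
                n_systems=len(x),
            )
        )
    return out


def run_model_predictions(
    models=simulator.MODELS,
    seed: int = 0,
    n_updates: int = simulator.DEFAULT_N_UPDATES,
    exclude_floor: bool = True,
    floor_eps: float = DEFAULT_FLOOR_EPS,
    keep_tables: bool = False,
    **sweep_kwargs,
) -> dict:
    """Full prediction sweep for each requested model.

    Simulates all systems in all tasks (324 x 100 trials per model at the
    default grids), extracts SSRs, fits the per-task OLS regressions and
    reports each model's signature.  Seeded and fully deterministic; each
    model uses an independent substream of ``seed``.
    """
    reports = {}
    root = np.random.SeedSequence(seed)
    for model in models:
        sub = np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(simulator.MODELS.index(model),)
        )
        table = simulator.run_experiment(
            model, n_updates=n_updates, seed=sub, **sweep_kwargs
        )
        regs = per_task_regressions(table, exclude_floor, floor_eps)
        reports[model] = ModelPredictionReport(
            model=model, regressions=regs, ssr_table=table if keep_tables else None
        )
    return reports


def _quartile_labels(values: np.ndarray) -> np.ndarray:
    """Quartiles 1..4 by value, ties broken by original order."""
    n = len(values)
    order = np.argsort(values, kind="stable")
    labels = np.empty(n, dtype=int)
    edges = [round(q * n / 4) for q in range(5)]
    for q in range(4):
        labels[order[edges[q] : edges[q + 1]]] = q + 1
    return labels


def run_cohort_experiment(
    cohort: pd.DataFrame,
    rope_diff: float = 0.30,
    rope_slope: RopeInterval = RopeInterval(0.95, 1.05),
    rope_intercept: RopeInterval = RopeInterval(-0.12, 0.12),
    config: MCMCConfig = MCMCConfig(),
    quartiles: bool = True,
) -> dict:
    """The Experiment-style analysis of one paired-SSR cohort.

    Expects columns ``participant_id``, ``ssr_task1_hz``, ``ssr_task2_hz``
    (one row per participant; unpaired rows are rejected).  Reports

    * the difference model on per-participant drops (task1 - task2) with
      its ROPE decision,
    * the same model per task-1 quartile (quartile 4 = best baseline
      performers), and
    * the robust regression of task-2 on task-1 SSR with ROPE decisions
      for slope and intercept.
    """
    required = {"participant_id", "ssr_task1_hz", "ssr_task2_hz"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if cohort[["ssr_task1_hz", "ssr_task2_hz"]].isna().any().any():
        raise ValueError("unpaired rows (missing SSR values) in cohort table")
    if cohort["participant_id"].duplicated().any():
        raise ValueError("duplicate participants in cohort table")

    ssr1 = cohort["ssr_task1_hz"].to_numpy(float)
    ssr2 = cohort["ssr_task2_hz"].to_numpy(float)
    drops = ssr1 - ssr2  # positive = performance drop in the harder task
    rope = RopeInterval.around(0.0, rope_diff)

    diff_post = bayes.estimate_mean_difference(
        drops,
        baseline_mean_1=float(np.mean(ssr1)),
        baseline_mean_2=float(np.mean(ssr2)),
        baseline_sd=float(np.std(ssr1, ddof=1)),
        rope=rope,
        config=config,
    )

    quartile_reports = {}
    if quartiles:
        labels = _quartile_labels(ssr1)
        for q in (1, 2, 3, 4):
            sel = labels == q
            quartile_reports[f"quartile_{q}"] = {
                "n": int(sel.sum()),
                "mean_drop_hz": float(np.mean(drops[sel])),
                **bayes.estimate_mean_difference(
                    drops[sel],
                    baseline_mean_1=float(np.mean(ssr1[sel])),
                    baseline_mean_2=float(np.mean(ssr2[sel])),
                    baseline_sd=float(np.std(ssr1[sel], ddof=1)),
                    rope=rope,
                    config=config,
                ).as_dict(),
            }

    reg_post = bayes.robust_linear_regression(
        ssr1,
        ssr2,
        rope_slope=rope_slope,
        rope_intercept=rope_intercept,
        config=config,
    )

    return {
        "n_participants": len(cohort),
        "mean_drop_hz": float(np.mean(drops)),
        "difference": diff_post.as_dict(),
        "quartiles": quartile_reports,
        "regression": reg_post.as_dict(),
        "_posteriors": {"difference": diff_post, "regression": reg_post},
    }


def targets_over_trial(rate_hz: float, duration_s: float = 140.0) -> float:
    """Targets represented by a rate sustained over a whole trial.

    A 0.733 Hz drop over a ~140 s trial is ~103 fewer targets hit.
    """
    return rate_hz * duration_s


def rope_multiple(value: float, rope_halfwidth: float) -> float:
    """How many ROPE half-widths a value sits from the null (0)."""
    if rope_halfwidth <= 0:
        raise ValueError("ROPE half-width must be positive")
    return abs(value) / rope_halfwidth


def provenance(config: dict) -> dict:
    """Config hash + echo for embedding in report JSON."""
    blob = json.dumps(config, sort_keys=True, default=str)
    return {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }


def write_report(report: dict, path) -> None:
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    with open(path, "w") as fh:
        json.dump(clean, fh, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, RopeInterval):
        return [obj.low, obj.high]
    raise TypeError(f"not JSON serialisable: {type(obj)}")
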