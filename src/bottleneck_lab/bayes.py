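"""Bayesian ROPE/HDI analyses of steady-state rates.

Two models, both estimated by MCMC (emcee affine-invariant ensemble) and
summarised Kruschke-style by the posterior mode, the 95% highest-density
interval (HDI), and a decision against a region of practical equivalence
(ROPE):

* **Difference model** -- per-participant SSR differences between two
  tasks are Normal(mu, sigma); the question is whether 0 Hz is a credible
  value for mu.  Priors are informed by the baseline task: mu ~
  Normal(sample difference in means, 10 * sd_baseline) and sigma ~
  Uniform(0.001 * sd_baseline, 1000 * sd_baseline).
* **Robust linear regression** -- SSR in the harder task is
  t_nu(beta0 + beta1 * SSR_baseline, sigma).  Priors: sigma ~
  Uniform(0.001, 1000), nu ~ Exponential(mean 30), beta0 ~ Normal(0, .),
  beta1 ~ Normal(1, .), where the Normal priors are read in the precision
  convention (precision 0.01 -> SD 10), so they are vague; the variance
  reading (SD 0.1) is available via ``precision_priors=False``.

Decision rule: HDI inside the ROPE -> practically equivalent; HDI and
ROPE disjoint -> practically different; otherwise undecided.  Chain
health is reported via the Brooks-Gelman-Rubin shrink factor, effective
sample size, Monte Carlo standard error and autocorrelation (arviz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
from scipy.special import gammaln
from scipy.stats import gaussian_kde

__all__ = [
    "RopeInterval",
    "MCMCConfig",
    "ParameterSummary",
    "Diagnostics",
    "DifferencePosterior",
    "RegressionPosterior",
    "hdi",
    "posterior_mode",
    "rope_decision",
    "rope_mass",
    "diagnostics",
    "estimate_mean_difference",
    "robust_linear_regression",
]


@dataclass(frozen=True)
class RopeInterval:
    """Region of practical equivalence around a null value."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("ROPE low must be < high")

    @classmethod
    def around(cls, center: float, halfwidth: float) -> "RopeInterval":
        return cls(center - halfwidth, center + halfwidth)


@dataclass(frozen=True)
class MCMCConfig:
    """Ensemble-sampler settings.

    ``n_walkers`` walkers are run for ``n_burn + n_steps`` steps; post-burn
    draws are grouped into ``n_chain_groups`` chains (walker groups) for
    convergence diagnostics.
    """

    n_walkers: int = 32
    n_steps: int = 2000
    n_burn: int = 1000
    n_chain_groups: int = 4
    seed: int | None = 0
    ess_floor: float = 400.0

    def __post_init__(self) -> None:
        if self.n_walkers % self.n_chain_groups:
            raise ValueError("n_walkers must divide evenly into chain groups")


@dataclass
class ParameterSummary:
    name: str
    mode: float
    hdi_low: float
    hdi_high: float
    rope: RopeInterval | None = None
    decision: str | None = None
    mass_below_rope: float | None = None
    mass_in_rope: float | None = None
    mass_above_rope: float | None = None

    def as_dict(self) -> dict:
        out = {
            "mode": self.mode,
            "hdi_low": self.hdi_low,
            "hdi_high": self.hdi_high,
        }
        if self.rope is not None:
            out.update(
                rope=[self.rope.low, self.rope.high],
                decision=self.decision,
                mass_below_rope=self.mass_below_rope,
                mass_in_rope=self.mass_in_rope,
                mass_above_rope=self.mass_above_rope,
            )
        return out


@dataclass
class Diagnostics:
    """Chain-health summary: shrink factor, ESS, MCSE, autocorrelation."""

    shrink_factor: dict
    ess: dict
    mcse: dict
    autocorr: dict
    passed: bool
    shrink_threshold: float = 1.1
    ess_floor: float = 400.0

    def as_dict(self) -> dict:
        return {
            "shrink_factor": self.shrink_factor,
            "ess": self.ess,
            "mcse": self.mcse,
            "autocorr": {k: list(v) for k, v in self.autocorr.items()},
            "passed": bool(self.passed),
        }


@dataclass
class _Posterior:
    """Posterior samples (chain, draw) per parameter plus summaries."""

    samples: dict
    summaries: dict
    diag: Diagnostics

    @property
    def n_chains(self) -> int:
        return next(iter(self.samples.values())).shape[0]

    def flat(self, name: str) -> np.ndarray:
        return self.samples[name].reshape(-1)

    def as_dict(self) -> dict:
        return {
            "parameters": {k: s.as_dict() for k, s in self.summaries.items()},
            "diagnostics": self.diag.as_dict(),
        }


class DifferencePosterior(_Posterior):
    pass


class RegressionPosterior(_Posterior):
    pass


def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``mass`` of the samples.

    Unlike an equal-tailed interval, the HDI of a skewed posterior hugs
    the high-density side (e.g. for Exponential(1) draws it starts at ~0).
    """
    x = np.sort(np.asarray(samples, dtype=float).reshape(-1))
    n = len(x)
    if n < 2:
        return float(x[0]), float(x[0])
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def posterior_mode(samples, max_n: int = 10000, grid: int = 512) -> float:
    """Mode of a sample cloud via a Gaussian KDE (Silverman bandwidth)."""
    x = np.asarray(samples, dtype=float).reshape(-1)
    if np.ptp(x) == 0:
        return float(x[0])
    if len(x) > max_n:  # deterministic thinning keeps the call cheap
        x = x[:: len(x) // max_n + 1]
    kde = gaussian_kde(x, bw_method="silverman")
    xs = np.linspace(x.min(), x.max(), grid)
    return float(xs[np.argmax(kde(xs))])


def rope_decision(hdi_interval, rope: RopeInterval) -> str:
    """Compare a 95% HDI against a ROPE.

    HDI inside the ROPE -> ``"equivalent"``; HDI and ROPE disjoint ->
    ``"different"``; any overlap -> ``"undecided"``.  Deterministic given
    the interval, and invariant to how the samples were ordered.
    """
    lo, hi = float(hdi_interval[0]), float(hdi_interval[1])
    if lo > hi:
        raise ValueError("HDI low must be <= high")
    if lo >= rope.low and hi <= rope.high:
        return "equivalent"
    if hi < rope.low or lo > rope.high:
        return "different"
    return "undecided"


def rope_mass(samples, rope: RopeInterval) -> tuple[float, float, float]:
    """Fractions of posterior mass below / inside / above the ROPE."""
    x = np.asarray(samples, dtype=float).reshape(-1)
    below = float(np.mean(x < rope.low))
    above = float(np.mean(x > rope.high))
    return below, 1.0 - below - above, above


def diagnostics(
    chains: dict,
    lags: tuple[int, ...] = (1, 5, 10, 50),
    shrink_threshold: float = 1.1,
    ess_floor: float = 400.0,
) -> Diagnostics:
    """Convergence diagnostics for a dict of (chain, draw) sample arrays.

    Shrink factor is the (rank-normalised) Brooks-Gelman-Rubin statistic;
    ESS and MCSE come from arviz; autocorrelation is the across-chain mean
    at the requested lags.
    """
    lengths = {v.shape for v in chains.values()}
    if any(v.ndim != 2 for v in chains.values()) or len(lengths) != 1:
        raise ValueError("chains must share a common (chain, draw) shape")
    n_chain = next(iter(chains.values())).shape[0]
    if n_chain < 2:
        raise ValueError("need >= 2 chains for convergence diagnostics")

    idata = az.from_dict(posterior={k: v for k, v in chains.items()})
    rhat = {k: float(az.rhat(idata, var_names=[k])[k]) for k in chains}
    ess = {k: float(az.ess(idata, var_names=[k])[k]) for k in chains}
    mcse = {k: float(az.mcse(idata, var_names=[k])[k]) for k in chains}
    autocorr = {}
    for k, v in chains.items():
        ac = np.mean([az.autocorr(np.asarray(c)) for c in v], axis=0)
        autocorr[k] = np.array([ac[lag] if lag < len(ac) else 0.0 for lag in lags])
    passed = all(r < shrink_threshold for r in rhat.values()) and all(
        e > ess_floor for e in ess.values()
    )
    return Diagnostics(
        shrink_factor=rhat,
        ess=ess,
        mcse=mcse,
        autocorr=autocorr,
        passed=passed,
        shrink_threshold=shrink_threshold,
        ess_floor=ess_floor,
    )


def _run_ensemble(
    log_prob,
    p0: np.ndarray,
    config: MCMCConfig,
    param_names: list[str],
    transforms: dict,
):
    """Run emcee and return per-parameter (chain_group, draw) samples."""
    n_walkers, ndim = p0.shape
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob)
    rng = np.random.default_rng(config.seed)
    sampler.random_state = np.random.RandomState(
        int(rng.integers(2**31 - 1))
    ).get_state()
    sampler.run_mcmc(p0, config.n_burn + config.n_steps, progress=False)
    chain = sampler.get_chain(discard=config.n_burn)  # (steps, walkers, dim)
    g = config.n_chain_groups
    per_group = n_walkers // g
    samples = {}
    for j, name in enumerate(param_names):
        x = chain[:, :, j]  # (steps, walkers)
        t = transforms.get(name)
        if t is not None:
            x = t(x)
        # walker groups -> chains: (g, per_group * steps)
        grouped = x.reshape(x.shape[0], g, per_group)
        samples[name] = np.transpose(grouped, (1, 0, 2)).reshape(g, -1)
    return samples


def _summarise(
    samples: dict,
    ropes: dict,
    config: MCMCConfig,
    hdi_mass: float = 0.95,
) -> dict:
    summaries = {}
    for name, draws in samples.items():
        flat = draws.reshape(-1)
        lo, hi = hdi(flat, hdi_mass)
        summary = ParameterSummary(
            name=name, mode=posterior_mode(flat), hdi_low=lo, hdi_high=hi
        )
        rope = ropes.get(name)
        if rope is not None:
            below, inside, above = rope_mass(flat, rope)
            summary.rope = rope
            summary.decision = rope_decision((lo, hi), rope)
            summary.mass_below_rope = below
            summary.mass_in_rope = inside
            summary.mass_above_rope = above
        summaries[name] = summary
    return summaries


def estimate_mean_difference(
    diffs,
    baseline_mean_1: float | None = None,
    baseline_mean_2: float | None = None,
    baseline_sd: float | None = None,
    rope: RopeInterval = RopeInterval(-0.30, 0.30),
    config: MCMCConfig = MCMCConfig(),
    precision_priors: bool = True,
) -> DifferencePosterior:
    """Estimate the mean per-participant SSR difference between two tasks.

    ``diffs`` are per-participant differences in Hz (here: baseline-task
    SSR minus harder-task SSR, so a positive value is a performance drop).
    The baseline moments set the priors; when omitted they default to the
    sample moments of the supplied differences (prior center = sample
    mean), which keeps the priors vague and data-dominated either way.
    """
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 1 or len(d) < 2:
        raise ValueError("need >= 2 difference observations")
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite differences")
    if baseline_sd is None:
        baseline_sd = float(np.std(d, ddof=1))
    if baseline_sd <= 0:
        raise ValueError("baseline SD must be positive")
    if baseline_mean_1 is None or baseline_mean_2 is None:
        prior_center = float(np.mean(d))
    else:
        prior_center = float(baseline_mean_1 - baseline_mean_2)

    # Precision reading of N(center, 1/(10*sd)^2): prior SD = 10 * sd.
    prior_sd = 10.0 * baseline_sd if precision_priors else 1.0 / (10.0 * baseline_sd)
    sig_lo, sig_hi = 0.001 * baseline_sd, 1000.0 * baseline_sd
    n = len(d)
    sum_d, sum_d2 = float(np.sum(d)), float(np.sum(d * d))

    def log_prob(theta):
        mu, log_sigma = theta
        sigma = np.exp(log_sigma)
        if not sig_lo < sigma < sig_hi:
            return -np.inf
        # Normal likelihood via sufficient statistics.
        ll = -n * (np.log(sigma) + 0.5 * np.log(2 * np.pi)) - (
            sum_d2 - 2 * mu * sum_d + n * mu * mu
        ) / (2 * sigma * sigma)
        lp = -0.5 * ((mu - prior_center) / prior_sd) ** 2
        return ll + lp + log_sigma  # Jacobian of the log-sigma transform

    rng = np.random.default_rng(
        None if config.seed is None else config.seed + 101
    )
    p0 = np.column_stack(
        [
            np.mean(d) + 0.1 * baseline_sd * rng.standard_normal(config.n_walkers),
            np.log(np.clip(np.std(d, ddof=1), sig_lo * 2, sig_hi / 2))
            + 0.1 * rng.standard_normal(config.n_walkers),
        ]
    )
    samples = _run_ensemble(
        log_prob,
        p0,
        config,
        ["mu", "sigma"],
        transforms={"sigma": np.exp},
    )
    summaries = _summarise(samples, {"mu": rope}, config)
    diag = diagnostics(samples, ess_floor=config.ess_floor)
    return DifferencePosterior(samples=samples, summaries=summaries, diag=diag)


def _t_logpdf_sum(z: np.ndarray, nu: float) -> float:
    """Sum of standard-t log densities (gammaln form, no scipy overhead)."""
    return len(z) * (
        gammaln((nu + 1) / 2) - gammaln(nu / 2) - 0.5 * np.log(nu * np.pi)
    ) - (nu + 1) / 2 * float(np.sum(np.log1p(z * z / nu)))


def robust_linear_regression(
    x,
    y,
    rope_slope: RopeInterval = RopeInterval(0.95, 1.05),
    rope_intercept: RopeInterval = RopeInterval(-0.12, 0.12),
    config: MCMCConfig = MCMCConfig(),
    precision_priors: bool = True,
    nu_mean: float = 30.0,
) -> RegressionPosterior:
    """Robust (t-likelihood) regression of harder-task SSR on baseline SSR.

    ``y ~ t_nu(beta0 + beta1 * x, sigma)`` with the vague priors described
    in the module docstring.  The heavy-tailed likelihood keeps gross
    outliers from dragging the slope, unlike ordinary least squares.
    Returns ROPE decisions for the intercept (around 0 Hz) and the slope
    (around 1), including the posterior mass beyond each ROPE edge.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1D arrays, n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x (zero variance)")

    prior_sd = 10.0 if precision_priors else 0.1
    nu_rate = 1.0 / nu_mean

    def log_prob(theta):
        b0, b1, log_sigma, log_nu = theta
        sigma = np.exp(log_sigma)
        nu = np.exp(log_nu)
        if not 0.001 < sigma < 1000.0 or not 0.1 < nu < 1e4:
            return -np.inf
        z = (y - b0 - b1 * x) / sigma
        ll = _t_logpdf_sum(z, nu) - len(x) * log_sigma
        lp = (
            -0.5 * (b0 / prior_sd) ** 2
            - 0.5 * ((b1 - 1.0) / prior_sd) ** 2
            - nu_rate * nu
        )
        return ll + lp + log_sigma + log_nu  # Jacobians

    # Initialise walkers near the OLS solution.
    A = np.column_stack([np.ones_like(x), x])
    beta_ls, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid_sd = float(np.std(y - A @ beta_ls)) or 0.1
    rng = np.random.default_rng(
        None if config.seed is None else config.seed + 202
    )
    p0 = np.column_stack(
        [
            beta_ls[0] + 0.05 * rng.standard_normal(config.n_walkers),
            beta_ls[1] + 0.05 * rng.standard_normal(config.n_walkers),
            np.log(np.clip(resid_sd, 0.002, 500.0))
            + 0.1 * rng.standard_normal(config.n_walkers),
            np.log(10.0) + 0.2 * rng.standard_normal(config.n_walkers),
        ]
    )
    samples = _run_ensemble(
        log_prob,
        p0,
        config,
        ["beta0", "beta1", "sigma", "nu"],
        transforms={"sigma": np.exp, "nu": np.exp},
    )
    summaries = _summarise(
        samples, {"beta0": rope_intercept, "beta1": rope_slope}, config
    )
    diag = diagnostics(samples, ess_floor=config.ess_floor)
    return RegressionPosterior(samples=samples, summaries=summaries, diag=diag)
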