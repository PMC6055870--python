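"""Bayesian fixed-effect and random-effects meta-analysis.

Two interchangeable engines target the normal-normal hierarchical model
(NNHM) for study-level log odds ratios:

* a deterministic **quadrature** engine on the normal-approximation
  likelihood ``delta_hat_i ~ N(delta_i, sigma_i^2)`` with study effects
  ``delta_i ~ N(delta, tau^2)``.  The overall effect delta carries a normal
  prior (vague N(0, 10) by default, variance parameterization; an improper
  flat prior is supported) and tau carries one of the heterogeneity priors.
  For fixed tau everything is conjugate, so the marginal posterior of delta
  is a one-dimensional mixture over a tau grid — no sampling involved;

* an **MCMC** engine on the exact binomial-logit likelihood
  ``logit(p_C,i) = mu_i``, ``logit(p_T,i) = mu_i + delta_i`` with
  ``mu_i ~ N(0, 4)``, ``delta ~ N(0, 10)`` (adaptive Metropolis-within-Gibbs
  with split-R-hat and effective-sample-size diagnostics).

All continuous posteriors are carried as :class:`GridDensity` — a
normalized density on an ordered support grid — and summarized with
equal-tailed credible intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence, Union

import numpy as np
from scipy import stats
from scipy.integrate import cumulative_trapezoid, trapezoid
from scipy.special import log_expit

from .freq_meta import MetaInput
from .heterogeneity_priors import HeterogeneityPrior
from .trial_data import TwoArmTrial

__all__ = [
    "NormalPrior",
    "BayesConfig",
    "GridDensity",
    "PointMass",
    "PosteriorSummary",
    "PosteriorResult",
    "ConvergenceError",
    "bayes_fixed_effect",
    "marginal_tau_posterior",
    "bayes_random_effects",
    "summarize_posterior",
    "mcmc_binomial_logit",
    "McmcResult",
]


class ConvergenceError(RuntimeError):
    """MCMC failed its convergence diagnostics (split R-hat threshold)."""


@dataclass(frozen=True)
class NormalPrior:
    """Normal prior in mean/variance parameterization.

    ``variance = inf`` denotes the improper flat prior.  ``from_sd`` is the
    loudly-labelled alternative for users who think in standard deviations.
    """

    mean: float = 0.0
    variance: float = 10.0

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError(f"prior variance must be positive, got {self.variance}")

    @classmethod
    def flat(cls) -> "NormalPrior":
        return cls(0.0, math.inf)

    @classmethod
    def from_sd(cls, mean: float, sd: float) -> "NormalPrior":
        return cls(mean, sd**2)

    @property
    def is_flat(self) -> bool:
        return math.isinf(self.variance)


@dataclass(frozen=True)
class BayesConfig:
    """Settings shared by the quadrature and MCMC engines."""

    effect_prior: NormalPrior = NormalPrior(0.0, 10.0)
    control_prior: NormalPrior = NormalPrior(0.0, 4.0)
    heterogeneity_prior: Optional[HeterogeneityPrior] = None
    engine: Literal["quadrature", "mcmc"] = "quadrature"
    credible_level: float = 0.95
    n_tau: int = 400
    n_delta: int = 800
    tau_max: float = 10.0
    chains: int = 4
    iterations: int = 10_000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 < self.credible_level < 1:
            raise ValueError("credible_level must lie in (0,1)")

    def with_prior(self, prior: HeterogeneityPrior) -> "BayesConfig":
        return replace(self, heterogeneity_prior=prior)


@dataclass(frozen=True)
class PointMass:
    """Degenerate distribution marker (all mass at one point)."""

    value: float


@dataclass
class GridDensity:
    """Normalized density of a scalar parameter on an increasing grid."""

    support: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.support.ndim != 1 or self.support.shape != self.density.shape:
            raise ValueError("support and density must be 1-d arrays of equal length")
        if np.any(np.diff(self.support) <= 0):
            raise ValueError("support grid must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    @classmethod
    def from_normal(
        cls, mean: float, sd: float, n: int = 800, halfwidth: float = 8.0
    ) -> "GridDensity":
        x = np.linspace(mean - halfwidth * sd, mean + halfwidth * sd, n)
        return cls(x, stats.norm.pdf(x, mean, sd)).normalized()

    def integral(self) -> float:
        return float(trapezoid(self.density, self.support))

    def normalized(self) -> "GridDensity":
        return GridDensity(self.support, self.density / self.integral())

    def cdf_values(self) -> np.ndarray:
        cdf = cumulative_trapezoid(self.density, self.support, initial=0.0)
        return cdf / cdf[-1]

    def quantile(self, q: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        # midpoint of the generalized-inverse interval, so quantiles stay
        # well-defined on flat CDF stretches (e.g. between separated modes)
        cdf = self.cdf_values()
        qs = np.atleast_1d(np.asarray(q, dtype=float))
        eps = 1e-9
        out = np.empty(qs.shape)
        for k, qq in enumerate(qs):
            lo = self._inv_at(cdf, qq, np.searchsorted(cdf, qq - eps, side="left"))
            hi = self._inv_at(cdf, qq, np.searchsorted(cdf, qq + eps, side="right"))
            out[k] = 0.5 * (lo + hi)
        return float(out[0]) if np.isscalar(q) else out

    def _inv_at(self, cdf: np.ndarray, qq: float, i: int) -> float:
        s = self.support
        if i <= 0:
            return float(s[0])
        if i >= len(s):
            return float(s[-1])
        c0, c1 = cdf[i - 1], cdf[i]
        if c1 == c0:
            return float(s[i])
        return float(s[i - 1] + (qq - c0) / (c1 - c0) * (s[i] - s[i - 1]))

    def cdf(self, x: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        out = np.interp(x, self.support, self.cdf_values())
        return float(out) if np.isscalar(x) else out

    def mean(self) -> float:
        return float(trapezoid(self.support * self.density, self.support))

    def sd(self) -> float:
        m = self.mean()
        v = float(trapezoid((self.support - m) ** 2 * self.density, self.support))
        return math.sqrt(max(v, 0.0))


@dataclass(frozen=True)
class PosteriorSummary:
    """Mean, median and equal-tailed credible interval of a posterior."""

    mean: float
    median: float
    cred_low: float
    cred_high: float
    level: float
    tau_summary: Optional["PosteriorSummary"] = None


def summarize_posterior(g: GridDensity, level: float = 0.95) -> PosteriorSummary:
    """Numeric mean/median and central credible interval from a grid."""
    if not 0 < level < 1:
        raise ValueError("level must lie in (0,1)")
    if abs(g.integral() - 1.0) > 1e-3:
        raise ValueError("grid density is not normalized")
    alpha = 0.5 * (1.0 - level)
    lo, med, hi = (float(v) for v in g.quantile(np.array([alpha, 0.5, 1.0 - alpha])))
    return PosteriorSummary(g.mean(), med, lo, hi, level)


@dataclass
class PosteriorResult:
    """Posterior summary plus its grid; tau posterior attached when present."""

    summary: PosteriorSummary
    grid: GridDensity
    tau_posterior: Union[GridDensity, PointMass, None] = None


# ---------------------------------------------------------------------------
# Conjugate building blocks (vectorized over a tau grid)


def _conditional_given_tau(
    y: np.ndarray, v: np.ndarray, tau: np.ndarray, prior: NormalPrior
) -> tuple[np.ndarray, np.ndarray]:
    """Conjugate posterior N(mean, var) of delta given tau (vector of taus)."""
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    w = 1.0 / (v[None, :] + tau[:, None] ** 2)  # (T, n)
    if prior.is_flat:
        prec = w.sum(axis=1)
        mean = (w * y[None, :]).sum(axis=1) / prec
    else:
        prec = 1.0 / prior.variance + w.sum(axis=1)
        mean = (prior.mean / prior.variance + (w * y[None, :]).sum(axis=1)) / prec
    return mean, 1.0 / prec


def _log_marginal_given_tau(
    y: np.ndarray, v: np.ndarray, tau: np.ndarray, prior: NormalPrior
) -> np.ndarray:
    """log m(data | tau) with the overall effect integrated out analytically.

    For a proper normal prior this is a sequential (Kalman-style) product of
    one-step-ahead normal predictive densities; for the flat prior the
    standard profile form ``(1/2) sum log w* - (1/2) log sum w* - Q*/2``
    (constants in tau dropped) is used.
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    t2 = tau**2
    if prior.is_flat:
        w = 1.0 / (v[None, :] + t2[:, None])
        sw = w.sum(axis=1)
        mu = (w * y[None, :]).sum(axis=1) / sw
        q = (w * (y[None, :] - mu[:, None]) ** 2).sum(axis=1)
        return 0.5 * np.log(w).sum(axis=1) - 0.5 * np.log(sw) - 0.5 * q
    m = np.full(tau.shape, prior.mean)
    var = np.full(tau.shape, prior.variance)
    logm = np.zeros(tau.shape)
    for yi, vi in zip(y, v):
        pv = var + vi + t2
        logm += -0.5 * np.log(2.0 * math.pi * pv) - 0.5 * (yi - m) ** 2 / pv
        gain = var / pv
        m = m + gain * (yi - m)
        var = var * (vi + t2) / pv
    return logm


def _tau_grid(prior: HeterogeneityPrior, config: BayesConfig) -> np.ndarray:
    hi = min(prior.ppf_tau(0.9999), config.tau_max)
    return np.linspace(0.0, hi, config.n_tau)


# ---------------------------------------------------------------------------
# Quadrature engine


def bayes_fixed_effect(minput: MetaInput, config: BayesConfig = BayesConfig()) -> PosteriorResult:
    """Conjugate Bayesian fixed-effect pool (no heterogeneity).

    With the (vague) normal prior N(m0, v0) on the common effect, the
    posterior is normal with precision ``1/v0 + sum w_i`` and precision-
    weighted mean; the flat-prior limit reproduces the frequentist pool.
    """
    y, v = minput.log_ors, minput.variances
    mean, var = _conditional_given_tau(y, v, np.array([0.0]), config.effect_prior)
    mean, sd = float(mean[0]), float(np.sqrt(var[0]))
    grid = GridDensity.from_normal(mean, sd, config.n_delta)
    z = stats.norm.ppf(0.5 * (1 + config.credible_level))
    summary = PosteriorSummary(
        mean, mean, mean - z * sd, mean + z * sd, config.credible_level
    )
    return PosteriorResult(summary, grid, PointMass(0.0))


def marginal_tau_posterior(
    minput: MetaInput, config: BayesConfig
) -> Union[GridDensity, PointMass]:
    """Marginal posterior p(tau | data) on a grid (prior times marginal
    likelihood of the study estimates, delta integrated out analytically).

    A point-mass heterogeneity prior returns a :class:`PointMass` marker.
    """
    prior = config.heterogeneity_prior
    if prior is None:
        raise ValueError("config.heterogeneity_prior is required")
    if prior.is_point:
        return PointMass(prior.param1)
    tau = _tau_grid(prior, config)
    logm = _log_marginal_given_tau(minput.log_ors, minput.variances, tau, config.effect_prior)
    with np.errstate(divide="ignore"):
        logp = np.log(prior.pdf_tau(tau)) + logm
    dens = np.exp(logp - np.max(logp[np.isfinite(logp)]))
    dens[~np.isfinite(dens)] = 0.0
    return GridDensity(tau, dens).normalized()


def _delta_mixture_grid(
    means: np.ndarray, sds: np.ndarray, weights: np.ndarray,
    tau: np.ndarray, n_delta: int,
) -> GridDensity:
    """Mixture over tau of conditional normal posteriors, on a delta grid
    spanning the envelope of all conditional means +/- 8 conditional SDs."""
    lo = float(np.min(means - 8.0 * sds))
    hi = float(np.max(means + 8.0 * sds))
    x = np.linspace(lo, hi, n_delta)
    cond = stats.norm.pdf(x[:, None], means[None, :], sds[None, :])  # (D, T)
    if tau.size == 1:
        dens = cond[:, 0]
    else:
        dens = trapezoid(cond * weights[None, :], tau, axis=1)
    return GridDensity(x, dens).normalized()


def bayes_random_effects(
    minput: MetaInput, config: BayesConfig
) -> PosteriorResult:
    """Bayesian random-effects pool: p(delta | data) marginal over tau.

    The posterior is the tau-mixture of conjugate conditional normals,
    weighted by the marginal posterior of tau; heterogeneity uncertainty is
    thereby propagated into the credible interval.
    """
    prior = config.heterogeneity_prior
    if prior is None:
        raise ValueError("config.heterogeneity_prior is required")
    y, v = minput.log_ors, minput.variances
    tau_post = marginal_tau_posterior(minput, config)
    if isinstance(tau_post, PointMass):
        tau = np.array([tau_post.value])
        weights = np.array([1.0])
        tau_summary = None
    else:
        tau = tau_post.support
        weights = tau_post.density
        tau_summary = summarize_posterior(tau_post, config.credible_level)
    means, variances = _conditional_given_tau(y, v, tau, config.effect_prior)
    grid = _delta_mixture_grid(means, np.sqrt(variances), weights, tau, config.n_delta)
    summary = summarize_posterior(grid, config.credible_level)
    summary = replace(summary, tau_summary=tau_summary)
    return PosteriorResult(summary, grid, tau_post)


# ---------------------------------------------------------------------------
# MCMC engine: exact binomial-logit likelihood


@dataclass
class McmcResult:
    """Post-warmup chains with convergence diagnostics.

    ``draws`` maps parameter names to arrays of shape (chains, draws) or
    (chains, draws, n_studies).
    """

    draws: dict
    rhat: dict
    ess: dict
    acceptance: dict

    def array(self, name: str) -> np.ndarray:
        return self.draws[name]

    def summary(self, name: str = "delta", level: float = 0.95) -> PosteriorSummary:
        x = np.sort(self.draws[name].reshape(-1))
        alpha = 0.5 * (1 - level)
        lo, med, hi = np.quantile(x, [alpha, 0.5, 1 - alpha])
        return PosteriorSummary(float(np.mean(x)), float(med), float(lo), float(hi), level)

    def mc_se(self, name: str = "delta") -> float:
        x = self.draws[name].reshape(-1)
        return float(np.std(x, ddof=1) / math.sqrt(max(self.ess[name], 1.0)))


def _diagnose(draws: dict) -> tuple[dict, dict]:
    import arviz as az

    scalars = {k: v for k, v in draws.items() if v.ndim == 2}
    idata = az.from_dict(posterior=scalars)
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    rhat = {k: float(rhat_ds[k].values) for k in scalars}
    ess = {k: float(ess_ds[k].values) for k in scalars}
    return rhat, ess


def mcmc_binomial_logit(
    trials: Sequence[TwoArmTrial],
    config: BayesConfig,
    model: Literal["fixed", "random"] = "fixed",
) -> McmcResult:
    """Adaptive Metropolis-within-Gibbs sampler on the exact posterior.

    Fixed model: per-study control logits ``mu_i ~ N(0,4)`` and a common
    ``delta ~ N(0,10)``.  Random model adds study effects
    ``delta_i ~ N(delta, tau^2)`` with tau from the configured
    heterogeneity prior; delta is then updated by an exact Gibbs step.
    Raises :class:`ConvergenceError` if split R-hat exceeds 1.05.
    """
    if config.seed is None:
        raise ValueError("config.seed is mandatory for the MCMC engine")
    if config.chains < 2:
        raise ValueError("at least 2 chains are required for diagnostics")
    het = config.heterogeneity_prior
    if model == "random" and het is None:
        raise ValueError("random model requires a heterogeneity prior")
    if model == "random" and het is not None and het.is_point and het.param1 == 0.0:
        # tau == 0 collapses the hierarchy onto the fixed model
        res = mcmc_binomial_logit(trials, config, "fixed")
        res.draws["tau"] = np.zeros_like(res.draws["delta"])
        return res

    rng = np.random.default_rng(config.seed)
    a = np.array([t.treatment.events for t in trials], dtype=float)
    nt = np.array([t.treatment.total for t in trials], dtype=float)
    c = np.array([t.control.events for t in trials], dtype=float)
    nc = np.array([t.control.total for t in trials], dtype=float)
    n = len(trials)
    C = config.chains
    iters = config.iterations
    burn = iters // 2

    m_mu, v_mu = config.control_prior.mean, config.control_prior.variance
    m_d, v_d = config.effect_prior.mean, config.effect_prior.variance

    def ll_control(mu):  # (C, n)
        return c * log_expit(mu) + (nc - c) * log_expit(-mu)

    def ll_treat(x):
        return a * log_expit(x) + (nt - a) * log_expit(-x)

    def lp_mu(mu):
        return -0.5 * (mu - m_mu) ** 2 / v_mu

    def lp_delta(d):
        return 0.0 if math.isinf(v_d) else -0.5 * (d - m_d) ** 2 / v_d

    # moment-matched starting values, jittered per chain
    mu = np.tile(np.log((c + 0.5) / (nc - c + 0.5)), (C, 1)) + 0.1 * rng.standard_normal((C, n))
    obs_lor = np.log((a + 0.5) / (nt - a + 0.5)) - np.log((c + 0.5) / (nc - c + 0.5))
    delta = np.full(C, float(np.mean(obs_lor))) + 0.2 * rng.standard_normal(C)

    random_model = model == "random"
    tau_fixed = het is not None and het.is_point
    if random_model:
        theta = np.tile(obs_lor, (C, 1)) + 0.1 * rng.standard_normal((C, n))
        if tau_fixed:
            tau = np.full(C, het.param1)
        else:
            tau = np.clip(het.sample(C, rng), 0.05, 2.0)
    else:
        theta = None
        tau = None

    s_mu = np.full((C, n), 0.4)
    s_th = np.full((C, n), 0.4)
    s_d = np.full(C, 0.3)
    s_tau = np.full(C, 0.3)
    acc = {k: 0.0 for k in ("mu", "theta", "delta", "tau")}
    win = {k: np.zeros_like(v) for k, v in (("mu", s_mu), ("theta", s_th), ("delta", s_d), ("tau", s_tau))}
    adapt_every = 50

    keep = iters - burn
    out_delta = np.empty((C, keep))
    out_tau = np.empty((C, keep)) if random_model else None
    out_mu = np.empty((C, keep, n))
    out_theta = np.empty((C, keep, n)) if random_model else None

    eff = theta if random_model else None

    for it in range(iters):
        x_t = mu + (theta if random_model else delta[:, None])

        # --- mu_i updates (independent across studies)
        prop = mu + s_mu * rng.standard_normal((C, n))
        xp = prop + (theta if random_model else delta[:, None])
        dlp = (ll_control(prop) + ll_treat(xp) + lp_mu(prop)) - (
            ll_control(mu) + ll_treat(x_t) + lp_mu(mu)
        )
        acc_mask = np.log(rng.random((C, n))) < dlp
        mu = np.where(acc_mask, prop, mu)
        win["mu"] += acc_mask

        if random_model:
            # --- theta_i updates
            prop = theta + s_th * rng.standard_normal((C, n))
            t2 = np.maximum(tau[:, None] ** 2, 1e-12)
            dlp = (ll_treat(mu + prop) - 0.5 * (prop - delta[:, None]) ** 2 / t2) - (
                ll_treat(mu + theta) - 0.5 * (theta - delta[:, None]) ** 2 / t2
            )
            acc_mask = np.log(rng.random((C, n))) < dlp
            theta = np.where(acc_mask, prop, theta)
            win["theta"] += acc_mask

            # --- delta: exact Gibbs draw given theta, tau
            t2 = np.maximum(tau**2, 1e-12)
            prec = n / t2 + (0.0 if math.isinf(v_d) else 1.0 / v_d)
            mean = (theta.sum(axis=1) / t2 + (0.0 if math.isinf(v_d) else m_d / v_d)) / prec
            delta = mean + rng.standard_normal(C) / np.sqrt(prec)

            # --- tau: reflected random walk (skipped for point-mass prior)
            if not tau_fixed:
                prop = np.abs(tau + s_tau * rng.standard_normal(C))
                with np.errstate(divide="ignore", invalid="ignore"):
                    def tau_lp(tv):
                        tv2 = np.maximum(tv**2, 1e-300)
                        ll = -0.5 * ((theta - delta[:, None]) ** 2 / tv2[:, None]).sum(axis=1) \
                             - n * np.log(np.sqrt(tv2))
                        pr = np.log(het.pdf_tau(np.maximum(tv, 1e-300)))
                        return ll + pr
                    dlp = tau_lp(prop) - tau_lp(tau)
                dlp = np.where(np.isfinite(dlp), dlp, -np.inf)
                acc_mask = np.log(rng.random(C)) < dlp
                tau = np.where(acc_mask, prop, tau)
                win["tau"] += acc_mask
        else:
            # --- common delta: random-walk Metropolis
            prop = delta + s_d * rng.standard_normal(C)
            dlp = (ll_treat(mu + prop[:, None]).sum(axis=1) + lp_delta(prop)) - (
                ll_treat(mu + delta[:, None]).sum(axis=1) + lp_delta(delta)
            )
            acc_mask = np.log(rng.random(C)) < dlp
            delta = np.where(acc_mask, prop, delta)
            win["delta"] += acc_mask

        # --- step-size adaptation during warmup, targeting ~30% acceptance
        if it < burn and (it + 1) % adapt_every == 0:
            for key, step in (("mu", s_mu), ("theta", s_th), ("delta", s_d), ("tau", s_tau)):
                rate = win[key] / adapt_every
                step *= np.exp(1.0 * (rate - 0.3))
                np.clip(step, 1e-3, 5.0, out=step)
                win[key][...] = 0.0

        if it >= burn:
            j = it - burn
            out_delta[:, j] = delta
            out_mu[:, j, :] = mu
            if random_model:
                out_tau[:, j] = tau
                out_theta[:, j, :] = theta

    draws = {"delta": out_delta, "mu": out_mu}
    if random_model:
        draws["tau"] = out_tau
        draws["theta"] = out_theta
    rhat, ess = _diagnose(draws)
    acc_rates = {}
    result = McmcResult(draws, rhat, ess, acc_rates)
    bad = {k: r for k, r in rhat.items() if (not math.isnan(r)) and r > 1.05}
    if bad:
        raise ConvergenceError(
            f"split R-hat above 1.05: {bad}; ess={ess}; "
            "increase iterations or check the model"
        )
    return result
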