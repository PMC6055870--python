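"""Two-step meta-analytic-predictive (MAP) analysis.

Step one derives the posterior-predictive distribution of the treatment
effect in a *new* study from the historical trials; step two uses that
predictive distribution as the prior for the new trial and updates it with
the new trial's likelihood.  No heterogeneity prior enters step two: all
borrowing behaviour is fixed by the predictive prior.

Under the fixed-effect assumption the predictive prior for a single
historical study is simply ``N(delta_H, sigma_H^2)`` (with several studies,
the pooled estimate and its variance).  Under exchangeable random effects
with *known* tau, the predictive distribution is ``N(delta_H,
2 tau^2 + sigma_H^2)``: the between-trial variance counts once for the
historical and once for the new trial.  With unknown tau the predictive
prior integrates over the joint posterior of the overall effect and tau
from a Bayesian random-effects analysis of the historical set only.

The sequential procedure is validated against the equivalent joint
("meta-analytic-combined", MAC) analysis: the study-specific posterior of
the new trial's effect from a single hierarchical model of all trials.
Both are exact factorizations of the same joint posterior and must agree
up to quadrature error.

The overall-effect prior used in the predictive construction is flat
(improper) by default, which makes the closed forms above exact; a proper
normal prior can be supplied through :class:`~mapmeta.bayes_meta.BayesConfig`
and is then used consistently in both the sequential and joint routes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
from scipy import stats
from scipy.integrate import trapezoid

from .bayes_meta import (
    BayesConfig,
    GridDensity,
    NormalPrior,
    PointMass,
    PosteriorResult,
    PosteriorSummary,
    _conditional_given_tau,
    _log_marginal_given_tau,
    _tau_grid,
    marginal_tau_posterior,
    summarize_posterior,
)
from .freq_meta import MetaInput, fixed_effect_meta
from .heterogeneity_priors import HeterogeneityPrior
from .trial_data import EffectEstimate

__all__ = [
    "PredictivePrior",
    "map_prior_fixed",
    "map_prior_random",
    "map_update",
    "mac_joint_posterior",
    "MAP_DEFAULT_CONFIG",
]

#: Default configuration for predictive-prior construction: flat prior on
#: the overall effect, so the closed-form predictive formulas hold exactly.
MAP_DEFAULT_CONFIG = BayesConfig(effect_prior=NormalPrior.flat())


@dataclass(frozen=True)
class PredictivePrior:
    """Posterior-predictive distribution of a new study's effect.

    Carried either in closed normal form (``mean``/``variance``) or as a
    :class:`GridDensity`; ``provenance`` records the historical trials and
    heterogeneity prior that produced it.
    """

    mean: Optional[float] = None
    variance: Optional[float] = None
    grid: Optional[GridDensity] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.grid is None:
            if self.mean is None or self.variance is None or not self.variance > 0:
                raise ValueError("closed-normal predictive prior needs mean and variance > 0")
        elif self.mean is not None or self.variance is not None:
            raise ValueError("supply either a closed normal or a grid, not both")

    @property
    def is_normal(self) -> bool:
        return self.grid is None

    @property
    def sd(self) -> float:
        if self.is_normal:
            return math.sqrt(self.variance)
        return self.grid.sd()

    def density_grid(self, n: int = 800) -> GridDensity:
        if self.is_normal:
            return GridDensity.from_normal(self.mean, self.sd, n)
        return self.grid


def map_prior_fixed(historical: MetaInput) -> PredictivePrior:
    """Fixed-effect predictive prior: pooled estimate with pooled variance.

    With a single historical study this is exactly ``N(delta_H, sigma_H^2)``.
    """
    pooled = fixed_effect_meta(historical)
    return PredictivePrior(
        mean=pooled.estimate,
        variance=pooled.variance,
        provenance=f"fixed-effect MAP from {', '.join(historical.labels)}",
    )


def map_prior_random(
    historical: MetaInput,
    het_prior: HeterogeneityPrior,
    config: BayesConfig = MAP_DEFAULT_CONFIG,
) -> PredictivePrior:
    """Random-effects predictive prior for a new exchangeable study.

    Point-mass tau gives the closed normal ``N(m(tau), v(tau) + tau^2)``
    where (m, v) is the conjugate overall-effect posterior at that tau —
    for one historical study and a flat overall-effect prior this is the
    known-tau form ``N(delta_H, 2 tau^2 + sigma_H^2)`` exactly.  Continuous
    priors yield a grid: the tau-mixture of those conditional predictive
    normals, weighted by the marginal posterior of tau given the historical
    data alone.
    """
    y, v = historical.log_ors, historical.variances
    prov = (
        f"random-effects MAP from {', '.join(historical.labels)} "
        f"with heterogeneity prior {het_prior.label}"
    )
    if het_prior.is_point:
        tau0 = het_prior.param1
        mean, var = _conditional_given_tau(y, v, np.array([tau0]), config.effect_prior)
        return PredictivePrior(
            mean=float(mean[0]), variance=float(var[0]) + tau0**2, provenance=prov
        )
    cfg = config.with_prior(het_prior)
    tau_post = marginal_tau_posterior(historical, cfg)
    tau, wts = tau_post.support, tau_post.density
    means, variances = _conditional_given_tau(y, v, tau, config.effect_prior)
    pred_sd = np.sqrt(variances + tau**2)
    lo = float(np.min(means - 8.0 * pred_sd))
    hi = float(np.max(means + 8.0 * pred_sd))
    x = np.linspace(lo, hi, config.n_delta)
    cond = stats.norm.pdf(x[:, None], means[None, :], pred_sd[None, :])
    dens = trapezoid(cond * wts[None, :], tau, axis=1)
    return PredictivePrior(grid=GridDensity(x, dens).normalized(), provenance=prov)


def map_update(
    prior: PredictivePrior,
    new_trial: EffectEstimate,
    level: float = 0.95,
    n_grid: int = 800,
) -> PosteriorResult:
    """Update the predictive prior with the new trial's normal likelihood.

    Closed-normal priors update conjugately; grid priors by pointwise
    product with ``N(delta_hat_new; delta, se_new^2)`` and renormalization.
    """
    y, s2 = new_trial.log_or, new_trial.variance
    if prior.is_normal:
        prec = 1.0 / prior.variance + 1.0 / s2
        mean = (prior.mean / prior.variance + y / s2) / prec
        sd = math.sqrt(1.0 / prec)
        grid = GridDensity.from_normal(mean, sd, n_grid)
        z = stats.norm.ppf(0.5 * (1 + level))
        summary = PosteriorSummary(mean, mean, mean - z * sd, mean + z * sd, level)
        return PosteriorResult(summary, grid)
    g = prior.grid
    dens = g.density * stats.norm.pdf(y, g.support, math.sqrt(s2))
    total = trapezoid(dens, g.support)
    if not total > 0:
        raise ValueError("degenerate update: prior and likelihood do not overlap")
    post = GridDensity(g.support, dens / total)
    return PosteriorResult(summarize_posterior(post, level), post)


def mac_joint_posterior(
    all_studies: MetaInput,
    new_label: str,
    het_prior: HeterogeneityPrior,
    config: BayesConfig = MAP_DEFAULT_CONFIG,
) -> PosteriorResult:
    """Study-specific posterior of one study's effect from the joint model.

    A single random-effects analysis of all studies (historical plus new);
    the returned posterior is for the study-specific effect ``delta_new``,
    the joint-model counterpart of the sequential MAP posterior.  For fixed
    tau the conditional posterior is normal:

        delta_new | data, tau ~ N(a y_new + (1-a) B,  1/P + (1-a)^2 V)

    with ``P = 1/tau^2 + 1/s_new^2``, ``a = (1/s_new^2)/P`` and (B, V) the
    overall-effect posterior from *all* studies; tau is integrated out over
    its marginal posterior given all data.  At tau = 0 the study effect
    coincides with the overall effect.
    """
    labels = list(all_studies.labels)
    if new_label not in labels:
        raise ValueError(f"unknown study label {new_label!r}; have {labels}")
    idx = labels.index(new_label)
    y_new = all_studies.log_ors[idx]
    s2_new = all_studies.variances[idx]
    y, v = all_studies.log_ors, all_studies.variances

    if het_prior.is_point:
        tau = np.array([het_prior.param1])
        wts = np.array([1.0])
        tau_post: Union[GridDensity, PointMass] = PointMass(het_prior.param1)
        tau_summary = None
    else:
        cfg = config.with_prior(het_prior)
        tau_post = marginal_tau_posterior(all_studies, cfg)
        tau, wts = tau_post.support, tau_post.density
        tau_summary = summarize_posterior(tau_post, config.credible_level)

    B, V = _conditional_given_tau(y, v, tau, config.effect_prior)
    t2 = tau**2
    with np.errstate(divide="ignore"):
        P = 1.0 / np.where(t2 > 0, t2, np.inf) + 1.0 / s2_new
        a = (1.0 / s2_new) / P
    a = np.where(t2 > 0, a, 0.0)
    P = np.where(t2 > 0, P, np.inf)
    means = a * y_new + (1.0 - a) * B
    variances = np.where(np.isinf(P), 0.0, 1.0 / P) + (1.0 - a) ** 2 * V
    sds = np.sqrt(variances)

    lo = float(np.min(means - 8.0 * sds))
    hi = float(np.max(means + 8.0 * sds))
    x = np.linspace(lo, hi, config.n_delta)
    cond = stats.norm.pdf(x[:, None], means[None, :], sds[None, :])
    if tau.size == 1:
        dens = cond[:, 0]
    else:
        dens = trapezoid(cond * wts[None, :], tau, axis=1)
    grid = GridDensity(x, dens).normalized()
    summary = replace(
        summarize_posterior(grid, config.credible_level), tau_summary=tau_summary
    )
    return PosteriorResult(summary, grid, tau_post)
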