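"""Frequentist fixed-effect and random-effects meta-analysis.

Inverse-variance pooling on the log OR scale: the fixed-effect pool uses
weights ``w_i = 1/sigma_i^2`` and the random-effects pool the adjusted
weights ``w_i* = 1/(sigma_i^2 + tau^2)``.  Heterogeneity is quantified by
Cochran's Q (chi-square test on n-1 df) and the between-study variance
``tau^2`` is estimated with the DerSimonian-Laird moment estimator by
default (REML available).  Within-study variances are treated as known.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence, Union

import numpy as np
from scipy import optimize, stats

from .trial_data import EffectEstimate, InvalidTrialError, TwoArmTrial, log_odds_ratio

__all__ = [
    "MetaInput",
    "MetaResult",
    "fixed_effect_meta",
    "cochran_q",
    "dersimonian_laird_tau2",
    "tau2_estimate",
    "random_effects_meta",
]


@dataclass(frozen=True)
class MetaInput:
    """Ordered collection of study-level effect estimates."""

    estimates: tuple[EffectEstimate, ...]

    def __post_init__(self) -> None:
        if len(self.estimates) == 0:
            raise InvalidTrialError("meta-analysis input must contain >= 1 estimate")

    @classmethod
    def from_estimates(cls, estimates: Iterable[EffectEstimate]) -> "MetaInput":
        return cls(tuple(estimates))

    @classmethod
    def from_trials(
        cls, trials: Iterable[TwoArmTrial], correction: bool = False
    ) -> "MetaInput":
        return cls(tuple(log_odds_ratio(t, correction=correction) for t in trials))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e.label for e in self.estimates)

    @property
    def log_ors(self) -> np.ndarray:
        return np.array([e.log_or for e in self.estimates])

    @property
    def variances(self) -> np.ndarray:
        return np.array([e.se**2 for e in self.estimates])

    def __len__(self) -> int:
        return len(self.estimates)

    def subset(self, labels: Sequence[str]) -> "MetaInput":
        keep = [e for e in self.estimates if e.label in set(labels)]
        return MetaInput(tuple(keep))


@dataclass(frozen=True)
class MetaResult:
    """Pooled effect with heterogeneity statistics."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    level: float
    weights: tuple[float, ...]
    model: Literal["fixed", "random"]
    tau2: float
    q_stat: float
    q_df: int
    q_p: float
    p_value: float

    @property
    def variance(self) -> float:
        return self.se**2

    def as_estimate(self, label: str) -> EffectEstimate:
        """View the pooled result as a study-level estimate (for MAP priors)."""
        return EffectEstimate(
            label, self.estimate, self.se, self.ci_low, self.ci_high,
            self.level, self.p_value, "two_sided",
        )


def _pool(minput: MetaInput, tau2: float, level: float) -> tuple:
    y = minput.log_ors
    w = 1.0 / (minput.variances + tau2)
    est = float(np.sum(w * y) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    z = stats.norm.ppf(0.5 * (1 + level))
    p = float(2 * stats.norm.sf(abs(est / se)))
    return est, se, est - z * se, est + z * se, w, p


def cochran_q(minput: MetaInput) -> tuple[float, int, float]:
    """Cochran's heterogeneity statistic Q, its df, and the chi-square p."""
    if len(minput) < 2:
        raise InvalidTrialError("Cochran's Q requires >= 2 studies")
    y = minput.log_ors
    w = 1.0 / minput.variances
    pooled = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - pooled) ** 2))
    df = len(minput) - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def dersimonian_laird_tau2(minput: MetaInput) -> float:
    """DerSimonian-Laird moment estimator of tau^2, truncated at zero."""
    if len(minput) < 2:
        raise InvalidTrialError("tau^2 estimation requires >= 2 studies")
    q, df, _ = cochran_q(minput)
    w = 1.0 / minput.variances
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    return float(max(0.0, (q - df) / denom))


def _reml_tau2(minput: MetaInput) -> float:
    y = minput.log_ors
    v = minput.variances

    def neg_restricted_ll(tau2: float) -> float:
        wi = 1.0 / (v + tau2)
        mu = np.sum(wi * y) / np.sum(wi)
        return float(
            0.5 * np.sum(np.log(v + tau2))
            + 0.5 * np.log(np.sum(wi))
            + 0.5 * np.sum(wi * (y - mu) ** 2)
        )

    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(0.0, 100.0), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(max(0.0, res.x))


def tau2_estimate(minput: MetaInput, method: Literal["dl", "reml"] = "dl") -> float:
    """Between-study variance estimate; DerSimonian-Laird by default."""
    if method == "dl":
        return dersimonian_laird_tau2(minput)
    if method == "reml":
        if len(minput) < 2:
            raise InvalidTrialError("tau^2 estimation requires >= 2 studies")
        return _reml_tau2(minput)
    raise ValueError(f"unknown tau^2 method {method!r}")


def _q_block(minput: MetaInput) -> tuple[float, int, float]:
    if len(minput) >= 2:
        return cochran_q(minput)
    return 0.0, 0, 1.0


def fixed_effect_meta(minput: MetaInput, level: float = 0.95) -> MetaResult:
    """Inverse-variance weighted fixed-effect pool with Wald interval."""
    est, se, lo, hi, w, p = _pool(minput, 0.0, level)
    q, df, qp = _q_block(minput)
    return MetaResult(est, se, lo, hi, level, tuple(w), "fixed", 0.0, q, df, qp, p)


def random_effects_meta(
    minput: MetaInput,
    tau2: Union[float, Literal["estimate"]] = "estimate",
    level: float = 0.95,
    method: Literal["dl", "reml"] = "dl",
) -> MetaResult:
    """Random-effects pool with weights ``1/(sigma_i^2 + tau^2)``.

    ``tau2`` may be a known non-negative value or ``"estimate"`` to use the
    moment (or REML) estimator.  With ``tau2 = 0`` the result coincides with
    the fixed-effect pool exactly.
    """
    if tau2 == "estimate":
        t2 = tau2_estimate(minput, method) if len(minput) >= 2 else 0.0
    else:
        t2 = float(tau2)
        if t2 < 0:
            raise InvalidTrialError(f"tau^2 must be non-negative, got {t2}")
    est, se, lo, hi, w, p = _pool(minput, t2, level)
    q, df, qp = _q_block(minput)
    return MetaResult(est, se, lo, hi, level, tuple(w), "random", t2, q, df, qp, p)
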