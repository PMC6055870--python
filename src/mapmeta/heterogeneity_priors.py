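"""Priors on the between-study heterogeneity parameter tau.

Three families are supported:

* ``half_normal`` — half-normal on tau with scale ``s`` (density
  ``2/(s sqrt(2 pi)) exp(-tau^2 / 2 s^2)`` for tau >= 0);
* ``inverse_gamma`` — inverse-gamma on tau^2 with scale ``a`` and shape
  ``b`` (equivalently, the precision 1/tau^2 is Gamma(shape b, rate a));
  the density in tau carries the Jacobian ``2 tau``;
* ``point`` — a point mass at a known tau >= 0 (handled symbolically).

Each prior translates into an interpretable "nominal" heterogeneity: the
representative tau^2 it encodes, and the implied ratio between the odds
ratios of two independent trials drawn with that heterogeneity,
``OR1/OR2 = exp(2 * 1.96 * sqrt(nominal tau^2))`` — the ratio of the 97.5th
to the 2.5th percentile of trial-level ORs.  The nominal tau^2 is
``(E tau)^2 = 2 s^2 / pi`` for the half-normal and ``scale/shape`` for the
inverse-gamma (its strict mean is undefined at shape <= 1, so the
scale/shape ratio is used as the representative value, not a moment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Optional, Union

import numpy as np
from scipy import stats

__all__ = [
    "HeterogeneityPrior",
    "PriorTranslation",
    "prior_density",
    "nominal_heterogeneity",
    "sample_prior",
]

Family = Literal["half_normal", "inverse_gamma", "point"]


@dataclass(frozen=True)
class PriorTranslation:
    """Interpretable summary of a heterogeneity prior."""

    nominal_tau2: float
    or_ratio: float


@dataclass(frozen=True)
class HeterogeneityPrior:
    """Parametric prior on the between-study heterogeneity tau.

    ``param1`` is the half-normal scale, the inverse-gamma scale, or the
    point-mass location; ``param2`` is the inverse-gamma shape (unused
    otherwise).
    """

    family: Family
    param1: float
    param2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family == "point":
            if self.param1 < 0:
                raise ValueError("point-mass tau must be >= 0")
        elif self.family == "half_normal":
            if self.param1 <= 0:
                raise ValueError("half-normal scale must be positive")
        elif self.family == "inverse_gamma":
            if self.param1 <= 0 or self.param2 is None or self.param2 <= 0:
                raise ValueError("inverse-gamma scale and shape must be positive")
        else:
            raise ValueError(f"unknown prior family {self.family!r}")

    # -- constructors -------------------------------------------------
    @classmethod
    def half_normal(cls, scale: float) -> "HeterogeneityPrior":
        return cls("half_normal", scale)

    @classmethod
    def inverse_gamma(cls, scale: float, shape: float) -> "HeterogeneityPrior":
        return cls("inverse_gamma", scale, shape)

    @classmethod
    def point(cls, tau0: float) -> "HeterogeneityPrior":
        return cls("point", tau0)

    @classmethod
    def from_config(cls, cfg: dict) -> "HeterogeneityPrior":
        """Build from a config mapping.

        Keys: ``family`` (half_normal | inverse_gamma | point), ``scale``,
        ``shape`` and ``on`` (tau | tau2).  The ``on`` keyword makes the
        parameterization explicit: the half-normal lives on tau, the
        inverse-gamma on tau^2; a mismatch raises rather than silently
        reinterpreting the parameters.
        """
        fam = str(cfg["family"]).lower().replace("-", "_")
        on = str(cfg.get("on", "tau" if fam != "inverse_gamma" else "tau2"))
        if fam in ("half_normal", "hn"):
            if on != "tau":
                raise ValueError("half-normal prior is parameterized on tau")
            return cls.half_normal(_num(cfg["scale"]))
        if fam in ("inverse_gamma", "ig"):
            if on != "tau2":
                raise ValueError("inverse-gamma prior is parameterized on tau2")
            return cls.inverse_gamma(_num(cfg["scale"]), _num(cfg["shape"]))
        if fam == "point":
            return cls.point(_num(cfg.get("value", cfg.get("scale", 0.0))))
        raise ValueError(f"unknown prior family {cfg['family']!r}")

    # -- descriptive --------------------------------------------------
    @property
    def is_point(self) -> bool:
        return self.family == "point"

    @property
    def label(self) -> str:
        if self.family == "half_normal":
            return f"HN({_fmt(self.param1)})"
        if self.family == "inverse_gamma":
            return f"IG({_fmt(self.param1)},{_fmt(self.param2)})"
        return f"tau={_fmt(self.param1)}"

    # -- distributional interface -------------------------------------
    def _frozen(self):
        if self.family == "half_normal":
            return stats.halfnorm(scale=self.param1)
        if self.family == "inverse_gamma":
            # distribution of tau^2
            return stats.invgamma(self.param2, scale=self.param1)
        raise ValueError("point-mass prior has no continuous distribution")

    def pdf_tau(self, tau: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        tau = np.asarray(tau, dtype=float)
        if np.any(tau < 0):
            raise ValueError("tau must be non-negative")
        if self.is_point:
            raise ValueError("density query on a point-mass prior")
        if self.family == "half_normal":
            out = self._frozen().pdf(tau)
        else:
            out = self._frozen().pdf(tau**2) * 2.0 * tau
        return out if out.shape else float(out)

    def cdf_tau(self, tau: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        tau = np.asarray(tau, dtype=float)
        if self.is_point:
            out = np.where(tau >= self.param1, 1.0, 0.0)
        elif self.family == "half_normal":
            out = self._frozen().cdf(tau)
        else:
            out = self._frozen().cdf(tau**2)
        return out if out.shape else float(out)

    def ppf_tau(self, q: float) -> float:
        if self.is_point:
            return self.param1
        if self.family == "half_normal":
            return float(self._frozen().ppf(q))
        return float(np.sqrt(self._frozen().ppf(q)))

    def sample(self, n: int, seed: Union[int, np.random.Generator]) -> np.ndarray:
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        if self.is_point:
            return np.full(n, self.param1)
        if self.family == "half_normal":
            return np.abs(rng.normal(0.0, self.param1, size=n))
        return np.sqrt(self._frozen().rvs(size=n, random_state=rng))

    # -- interpretability ---------------------------------------------
    def nominal_tau2(self) -> float:
        if self.family == "half_normal":
            return self.param1**2 * 2.0 / math.pi
        if self.family == "inverse_gamma":
            return self.param1 / self.param2
        return self.param1**2

    def translation(self) -> PriorTranslation:
        nt2 = self.nominal_tau2()
        return PriorTranslation(nt2, math.exp(2.0 * 1.96 * math.sqrt(nt2)))


def _num(x) -> float:
    """Accept numbers or fraction strings like '1/3'."""
    if isinstance(x, str) and "/" in x:
        return float(Fraction(x))
    return float(x)


def _fmt(x: float) -> str:
    s = f"{x:g}"
    if float(s) == x:
        return s
    frac = Fraction(x).limit_denominator(10000)
    if abs(float(frac) - x) < 1e-12 and frac.denominator <= 1000:
        return f"{frac.numerator}/{frac.denominator}"
    return s


# Functional aliases matching the module's operation names ----------------

def prior_density(prior: HeterogeneityPrior, tau) -> Union[float, np.ndarray]:
    """Prior density of tau (with the 2*tau Jacobian for IG-on-tau^2)."""
    return prior.pdf_tau(tau)


def nominal_heterogeneity(prior: HeterogeneityPrior) -> PriorTranslation:
    """Representative tau^2 and the implied between-trial OR ratio."""
    return prior.translation()


def sample_prior(prior: HeterogeneityPrior, n: int, seed: int) -> np.ndarray:
    """Reproducible draws of tau from the prior."""
    return prior.sample(n, seed)


#: The five heterogeneity priors used throughout the worked examples.
STANDARD_PRIORS: tuple[HeterogeneityPrior, ...] = (
    HeterogeneityPrior.inverse_gamma(1.0 / 3.0, 1.0),
    HeterogeneityPrior.inverse_gamma(1.0 / 7.0, 1.0),
    HeterogeneityPrior.inverse_gamma(1.0 / 1000.0, 1.0),
    HeterogeneityPrior.half_normal(1.0),
    HeterogeneityPrior.half_normal(0.5),
)
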