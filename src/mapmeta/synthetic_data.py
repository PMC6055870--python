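"""Worked-example fixtures and a synthetic trial-programme generator.

``fixtures`` returns the seven published trial tables used throughout the
package's worked examples: the two functional-dyspepsia trials (Bond,
Opera; omeprazole vs placebo, events are symptom relief, i.e. benefits),
the three adult kidney-transplant immunosuppression trials (Vitko, Lorber,
Tedesco Silva; events are treatment failures) and the two hypothetical
paediatric outcome scenarios (53 patients per arm).

``simulate_trial`` and ``simulate_programme`` generate two-arm binomial
trials under the binomial-logit data model: control events are
``Binomial(n_C, p_C)`` and treatment events ``Binomial(n_T,
expit(logit(p_C) + delta_i))`` with study effects ``delta_i ~ N(delta,
tau^2)``.  The default programme mirrors the kidney-transplant setting:
a control failure rate of 0.3, a null treatment effect, three adult trials
of 195 patients per arm and one paediatric trial of 53 per arm.

Reproducibility: every programme uses one seed; per-study generators are
split off a ``SeedSequence`` so adding studies never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .trial_data import ArmCount, TwoArmTrial

__all__ = [
    "fixtures",
    "adult_trials",
    "simulate_trial",
    "ProgrammeSpec",
    "simulate_programme",
]


def fixtures() -> dict[str, TwoArmTrial]:
    """The published trial tables, keyed by short lowercase label."""
    mk = lambda label, a, nt, c, nc, role, orient: TwoArmTrial(  # noqa: E731
        label, ArmCount(a, nt), ArmCount(c, nc), role, orient
    )
    benefit = "events_are_benefit"
    harm = "events_are_harm"
    return {
        "bond": mk("Bond", 93, 219, 57, 219, "historical", benefit),
        "opera": mk("Opera", 68, 202, 62, 203, "new", benefit),
        "vitko": mk("Vitko", 58, 194, 61, 196, "historical", harm),
        "lorber": mk("Lorber", 48, 193, 54, 196, "historical", harm),
        "tedesco": mk("Tedesco Silva", 70, 277, 67, 277, "historical", harm),
        "scenario1": mk("Scenario 1", 16, 53, 16, 53, "new", harm),
        "scenario2": mk("Scenario 2", 22, 53, 16, 53, "new", harm),
    }


def adult_trials() -> list[TwoArmTrial]:
    """The three adult kidney-transplant trials (the historical set)."""
    f = fixtures()
    return [f["vitko"], f["lorber"], f["tedesco"]]


def simulate_trial(
    control_rate: float,
    true_log_or: float,
    n_t: int,
    n_c: int,
    seed: int | np.random.Generator,
    label: str = "simulated",
    role: str = "historical",
) -> TwoArmTrial:
    """One two-arm binomial trial; the effect acts on the logit scale."""
    if not 0 < control_rate < 1:
        raise ValueError(f"control rate must lie in (0,1), got {control_rate}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_t = float(expit(logit(control_rate) + true_log_or))
    c = int(rng.binomial(n_c, control_rate))
    a = int(rng.binomial(n_t, p_t))
    return TwoArmTrial(label, ArmCount(a, n_t), ArmCount(c, n_c), role)  # type: ignore[arg-type]


@dataclass(frozen=True)
class ProgrammeSpec:
    """Design of a synthetic adult + paediatric development programme."""

    control_rate: float = 0.3
    true_log_or: float = 0.0
    tau: float = 0.0
    n_adult_trials: int = 3
    adult_arm_size: int = 195
    paediatric_arm_size: int = 53
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.control_rate < 1:
            raise ValueError("control_rate must lie in (0,1)")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if min(self.n_adult_trials, self.adult_arm_size, self.paediatric_arm_size) < 1:
            raise ValueError("trial counts and arm sizes must be >= 1")


def simulate_programme(
    spec: ProgrammeSpec,
) -> tuple[list[TwoArmTrial], TwoArmTrial, np.ndarray]:
    """Simulate the adult trials and the paediatric trial of a programme.

    Per-study true effects are drawn ``delta_i ~ N(true_log_or, tau^2)``
    (the paediatric trial is exchangeable with the adult ones); ``tau = 0``
    gives a fully homogeneous programme.  Returns the adult trials, the
    paediatric trial, and the vector of true study effects (adults first,
    paediatric last) for calibration studies.
    """
    n_studies = spec.n_adult_trials + 1
    children = np.random.SeedSequence(spec.seed).spawn(n_studies + 1)
    eff_rng = np.random.default_rng(children[0])
    true_effects = spec.true_log_or + spec.tau * eff_rng.standard_normal(n_studies)
    adults = [
        simulate_trial(
            spec.control_rate,
            float(true_effects[i]),
            spec.adult_arm_size,
            spec.adult_arm_size,
            np.random.default_rng(children[1 + i]),
            label=f"Adult {i + 1}",
            role="historical",
        )
        for i in range(spec.n_adult_trials)
    ]
    paediatric = simulate_trial(
        spec.control_rate,
        float(true_effects[-1]),
        spec.paediatric_arm_size,
        spec.paediatric_arm_size,
        np.random.default_rng(children[n_studies]),
        label="Paediatric",
        role="new",
    )
    return adults, paediatric, true_effects
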