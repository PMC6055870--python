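"""Core types for two-arm binary trials and log-odds-ratio effect estimation.

The effect scale throughout the package is the log odds ratio (log OR).
For a trial comparing a treatment arm (``a`` events out of ``n_T``) with a
control arm (``c`` events out of ``n_C``), the observed effect is

    log OR = ln[(a / (n_T - a)) / (c / (n_C - c))]

with the Woolf variance ``1/a + 1/(n_T-a) + 1/c + 1/(n_C-c)``.  Wald
confidence intervals and normal-theory p-values are attached to every
estimate.  Events are oriented as harms/failures by convention; datasets in
which events are beneficial carry that orientation as metadata and are
excluded from noninferiority decisions downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "ArmCount",
    "TwoArmTrial",
    "EffectEstimate",
    "InvalidTrialError",
    "DegenerateTableError",
    "log_odds_ratio",
    "wald_interval",
    "margin_to_log_or",
    "read_trials_csv",
    "write_trials_csv",
    "read_trials_json",
    "write_trials_json",
    "TRIAL_CSV_COLUMNS",
]

#: Bit-exact CSV schema for trial tables.
TRIAL_CSV_COLUMNS = (
    "label",
    "treatment_events",
    "treatment_total",
    "control_events",
    "control_total",
    "role",
)


class InvalidTrialError(ValueError):
    """Raised for structurally invalid trial data (e.g. an empty arm)."""


class DegenerateTableError(ValueError):
    """Raised when a 2x2 table has a zero cell and no continuity correction."""


@dataclass(frozen=True)
class ArmCount:
    """Event count and sample size of one trial arm."""

    events: int
    total: int

    def __post_init__(self) -> None:
        if self.total < 1:
            raise InvalidTrialError(f"arm total must be >= 1, got {self.total}")
        if not 0 <= self.events <= self.total:
            raise InvalidTrialError(
                f"events must lie in [0, total], got {self.events}/{self.total}"
            )

    @property
    def rate(self) -> float:
        return self.events / self.total


@dataclass(frozen=True)
class TwoArmTrial:
    """One randomized two-arm trial with binary outcome.

    ``role`` distinguishes historical (source-population) trials from the
    new (target-population) trial in extrapolation analyses.  ``orientation``
    records whether events are harms (the default; noninferiority decisions
    apply) or benefits.
    """

    label: str
    treatment: ArmCount
    control: ArmCount
    role: Literal["historical", "new"] = "historical"
    orientation: Literal["events_are_harm", "events_are_benefit"] = "events_are_harm"

    def __post_init__(self) -> None:
        if not self.label:
            raise InvalidTrialError("trial label must be non-empty")
        if self.role not in ("historical", "new"):
            raise InvalidTrialError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class EffectEstimate:
    """Log odds ratio with standard error, Wald interval and p-value."""

    label: str
    log_or: float
    se: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    p_value: float = float("nan")
    sided: Literal["one_sided", "two_sided"] = "two_sided"

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise InvalidTrialError(f"standard error must be positive, got {self.se}")
        if not 0 < self.level < 1:
            raise InvalidTrialError(f"level must be in (0,1), got {self.level}")

    @classmethod
    def from_components(
        cls,
        label: str,
        log_or: float,
        se: float,
        level: float = 0.95,
        sided: Literal["one_sided", "two_sided"] = "two_sided",
    ) -> "EffectEstimate":
        """Build an estimate from (log OR, SE), deriving CI and p-value."""
        low, high = _wald(log_or, se, level)
        z = log_or / se
        if sided == "one_sided":
            p = stats.norm.sf(z)
        else:
            p = 2.0 * stats.norm.sf(abs(z))
        return cls(label, log_or, se, low, high, level, float(p), sided)

    @property
    def variance(self) -> float:
        return self.se**2


def _wald(log_or: float, se: float, level: float) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 * (1.0 + level))
    return log_or - z * se, log_or + z * se


def log_odds_ratio(
    trial: TwoArmTrial,
    correction: bool = False,
    level: float = 0.95,
    sided: Literal["one_sided", "two_sided"] = "two_sided",
) -> EffectEstimate:
    """Observed log odds ratio of a trial with Woolf standard error.

    With ``correction=True`` and any zero cell, 0.5 is added to all four
    cells (the standard continuity correction); without it, a zero cell
    raises :class:`DegenerateTableError` naming the offending cell.
    """
    a = float(trial.treatment.events)
    b = float(trial.treatment.total - trial.treatment.events)
    c = float(trial.control.events)
    d = float(trial.control.total - trial.control.events)
    cells = {"treatment events": a, "treatment non-events": b,
             "control events": c, "control non-events": d}
    zero = [name for name, v in cells.items() if v == 0.0]
    if zero:
        if not correction:
            raise DegenerateTableError(
                f"trial {trial.label!r}: zero cell ({', '.join(zero)}); "
                "enable the continuity correction to proceed"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log((a / b) / (c / d))
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return EffectEstimate.from_components(trial.label, log_or, se, level, sided)


def wald_interval(est: EffectEstimate, level: float) -> tuple[float, float]:
    """Symmetric normal-theory interval ``log_or ± z·se`` at ``level``."""
    if not 0 < level < 1:
        raise InvalidTrialError(f"level must be in (0,1), got {level}")
    return _wald(est.log_or, est.se, level)


def margin_to_log_or(control_rate: float, rate_margin: float) -> float:
    """Translate an absolute risk noninferiority margin to the log OR scale.

    A margin of ``rate_margin`` on top of a control event rate ``p_C``
    corresponds to ``ln[odds(p_C + margin) / odds(p_C)]``; e.g. a 10-point
    margin at a control rate near 31% is roughly 0.43 log OR (OR 1.54).
    """
    p1 = control_rate + rate_margin
    if not 0.0 < control_rate < 1.0 or not 0.0 < p1 < 1.0:
        raise InvalidTrialError(
            f"rates must stay inside (0,1): control={control_rate}, "
            f"control+margin={p1}"
        )
    odds0 = control_rate / (1.0 - control_rate)
    odds1 = p1 / (1.0 - p1)
    return math.log(odds1 / odds0)


# ---------------------------------------------------------------------------
# I/O: the trial CSV / JSON schema


def _trial_to_record(t: TwoArmTrial) -> dict:
    return {
        "label": t.label,
        "treatment_events": t.treatment.events,
        "treatment_total": t.treatment.total,
        "control_events": t.control.events,
        "control_total": t.control.total,
        "role": t.role,
    }


def _record_to_trial(rec: dict) -> TwoArmTrial:
    return TwoArmTrial(
        label=str(rec["label"]),
        treatment=ArmCount(int(rec["treatment_events"]), int(rec["treatment_total"])),
        control=ArmCount(int(rec["control_events"]), int(rec["control_total"])),
        role=str(rec.get("role", "historical")),  # type: ignore[arg-type]
    )


def read_trials_csv(path: str | Path) -> list[TwoArmTrial]:
    df = pd.read_csv(path)
    missing = set(TRIAL_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidTrialError(f"trial CSV missing columns: {sorted(missing)}")
    return [_record_to_trial(rec) for rec in df.to_dict("records")]


def write_trials_csv(trials: Iterable[TwoArmTrial], path: str | Path) -> None:
    df = pd.DataFrame([_trial_to_record(t) for t in trials], columns=list(TRIAL_CSV_COLUMNS))
    df.to_csv(path, index=False)


def read_trials_json(path: str | Path) -> list[TwoArmTrial]:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    return [_record_to_trial(rec) for rec in data]


def write_trials_json(trials: Iterable[TwoArmTrial], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([_trial_to_record(t) for t in trials], fh, indent=2)
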