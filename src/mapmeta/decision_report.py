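"""Decision rules and labelled result rows for analysis batteries.

Each analysis (individual study, frequentist/Bayesian meta-analysis, MAP)
contributes one labelled row carrying the point estimate, its 95% interval,
heterogeneity information and two decision flags:

* ``significant`` — the interval excludes zero (strictly);
* ``noninferior`` — events are harms and the *upper* interval bound lies
  strictly below the noninferiority margin on the log OR scale (default
  0.43, the log-OR translation of a 10-percentage-point risk margin).
  One-sided noninferiority at 2.5% assessed through the two-sided 95%
  interval.  For benefit-oriented outcomes the flag is not applicable.

``run_comparison`` drives the full battery for a set of historical trials
and an optional new trial: individual studies, frequentist fixed/random
meta-analysis, Bayesian fixed-effect, Bayesian random-effects under a panel
of heterogeneity priors, then fixed and random MAP analyses of the new
trial.  Row order is deterministic and rows serialize to a stable CSV.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

from .bayes_meta import BayesConfig, bayes_fixed_effect, bayes_random_effects
from .freq_meta import MetaInput, fixed_effect_meta, random_effects_meta
from .heterogeneity_priors import STANDARD_PRIORS, HeterogeneityPrior
from .map_analysis import (
    MAP_DEFAULT_CONFIG,
    map_prior_fixed,
    map_prior_random,
    map_update,
)
from .trial_data import TwoArmTrial, log_odds_ratio

__all__ = [
    "DecisionConfig",
    "AnalysisRow",
    "assess",
    "run_comparison",
    "rows_to_csv",
    "write_rows_csv",
    "read_rows_csv",
    "ROW_CSV_HEADER",
]

ROW_CSV_HEADER = "method_label,estimate,ci_low,ci_high,tau2_info,significant,noninferior"

#: Priors used for the Bayesian random-effects meta-analysis rows.
DEFAULT_MA_PRIORS: tuple[HeterogeneityPrior, ...] = STANDARD_PRIORS
#: Priors used for the random-effects MAP rows (the near-degenerate
#: IG(1/1000,1) is omitted: it replicates the fixed-effect MAP row).
DEFAULT_MAP_PRIORS: tuple[HeterogeneityPrior, ...] = tuple(
    p for p in STANDARD_PRIORS
    if not (p.family == "inverse_gamma" and p.param1 <= 1e-2)
)


@dataclass(frozen=True)
class DecisionConfig:
    """Margin and orientation for the significance/noninferiority flags."""

    log_or_margin: float = 0.43
    level: float = 0.95
    direction: Literal["events_are_harm", "events_are_benefit"] = "events_are_harm"

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError("level must lie in (0,1)")
        if self.log_or_margin != self.log_or_margin or abs(self.log_or_margin) == float("inf"):
            raise ValueError("margin must be finite")


@dataclass(frozen=True)
class AnalysisRow:
    """One labelled result line of a comparison battery."""

    method_label: str
    estimate: float
    ci_low: float
    ci_high: float
    tau2_info: str
    significant: bool
    noninferior: Union[bool, Literal["not_applicable"]]

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError(
                f"{self.method_label}: estimate {self.estimate} outside interval "
                f"({self.ci_low}, {self.ci_high})"
            )


def assess(
    method_label: str,
    estimate: float,
    ci_low: float,
    ci_high: float,
    config: DecisionConfig = DecisionConfig(),
    tau2_info: str = "",
) -> AnalysisRow:
    """Apply the decision rules to an estimate with interval bounds."""
    if any(x != x for x in (estimate, ci_low, ci_high)):
        raise ValueError(f"{method_label}: missing interval bounds")
    significant = bool(ci_low > 0.0 or ci_high < 0.0)
    if config.direction == "events_are_harm":
        noninferior: Union[bool, str] = bool(ci_high < config.log_or_margin)
    else:
        noninferior = "not_applicable"
    return AnalysisRow(
        method_label, float(estimate), float(ci_low), float(ci_high),
        tau2_info, significant, noninferior,
    )


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def rows_to_csv(rows: Sequence[AnalysisRow]) -> str:
    """Serialize rows to the battery CSV (deterministic, fixed precision).

    Method labels may contain commas (e.g. ``B MA RE IG(1/3,1)``) and are
    quoted per RFC 4180.
    """
    buf = io.StringIO()
    buf.write(ROW_CSV_HEADER + "\r\n")
    writer = csv.writer(buf)
    for r in rows:
        ni = r.noninferior if isinstance(r.noninferior, str) else str(r.noninferior)
        writer.writerow(
            [r.method_label, _fmt(r.estimate), _fmt(r.ci_low), _fmt(r.ci_high),
             r.tau2_info, str(r.significant), ni]
        )
    return buf.getvalue()


def write_rows_csv(rows: Sequence[AnalysisRow], path: Union[str, Path]) -> None:
    Path(path).write_text(rows_to_csv(rows), encoding="utf-8")


def read_rows_csv(path: Union[str, Path]) -> list[AnalysisRow]:
    text = Path(path).read_text(encoding="utf-8")
    lines = text.strip().splitlines()
    if lines[0] != ROW_CSV_HEADER:
        raise ValueError(f"unexpected header {lines[0]!r}")
    rows = []
    for label, est, lo, hi, info, sig, ni in csv.reader(lines[1:]):
        rows.append(
            AnalysisRow(
                label, float(est), float(lo), float(hi), info,
                sig == "True", ni if ni == "not_applicable" else ni == "True",
            )
        )
    return rows


def run_comparison(
    history: Sequence[TwoArmTrial],
    new: Optional[TwoArmTrial],
    decision: DecisionConfig = DecisionConfig(),
    bayes: BayesConfig = BayesConfig(),
    ma_priors: Sequence[HeterogeneityPrior] = DEFAULT_MA_PRIORS,
    map_priors: Sequence[HeterogeneityPrior] = DEFAULT_MAP_PRIORS,
) -> list[AnalysisRow]:
    """Run the full comparison battery and return its rows in display order.

    Order: individual studies (history, then the new trial), frequentist
    fixed- and random-effects meta-analysis of all trials, Bayesian
    fixed-effect, Bayesian random-effects under each prior in ``ma_priors``,
    then (if a new trial is given) the fixed-effect MAP row and one
    random-effects MAP row per prior in ``map_priors``.
    """
    all_trials = list(history) + ([new] if new is not None else [])
    if not all_trials:
        raise ValueError("battery requires at least one trial")
    rows: list[AnalysisRow] = []
    level = decision.level

    for t in all_trials:
        est = log_odds_ratio(t, level=level)
        rows.append(assess(t.label, est.log_or, est.ci_low, est.ci_high, decision))

    mi_all = MetaInput.from_trials(all_trials)
    hist_mi = MetaInput.from_trials(history)
    if len(mi_all) >= 2:
        fe = fixed_effect_meta(mi_all, level)
        rows.append(
            assess("F MA FE", fe.estimate, fe.ci_low, fe.ci_high, decision,
                   f"Q={fe.q_stat:.3f};p={fe.q_p:.3f}")
        )
        re = random_effects_meta(mi_all, "estimate", level)
        rows.append(
            assess("F MA RE", re.estimate, re.ci_low, re.ci_high, decision,
                   f"tau2={re.tau2:.4f}")
        )

    bfe = bayes_fixed_effect(mi_all, bayes)
    s = bfe.summary
    rows.append(assess("B MA FE", s.median, s.cred_low, s.cred_high, decision))

    for prior in ma_priors:
        res = bayes_random_effects(mi_all, bayes.with_prior(prior))
        s = res.summary
        info = (
            f"tau_med={s.tau_summary.median:.3f}" if s.tau_summary is not None else ""
        )
        rows.append(
            assess(f"B MA RE {prior.label}", s.median, s.cred_low, s.cred_high,
                   decision, info)
        )

    if new is not None:
        new_est = log_odds_ratio(new, level=level)
        fixed_prior = map_prior_fixed(hist_mi)
        res = map_update(fixed_prior, new_est, level)
        s = res.summary
        rows.append(assess("B MAP FE", s.median, s.cred_low, s.cred_high, decision))
        for prior in map_priors:
            pred = map_prior_random(hist_mi, prior, MAP_DEFAULT_CONFIG)
            res = map_update(pred, new_est, level)
            s = res.summary
            rows.append(
                assess(f"B MAP RE {prior.label}", s.median, s.cred_low, s.cred_high,
                       decision)
            )
    return rows
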