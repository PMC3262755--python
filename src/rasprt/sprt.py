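"""Risk-adjusted sequential probability ratio test (RA-SPRT) core.

The test monitors, per hospital, whether the odds of 30-day mortality exceed
the risk-model expectation by at least a configured odds ratio.  Each case
contributes an increment ``O_i - s_i`` to a cumulative statistic, where
``O_i`` is the observed outcome and

    s_i = ln((1 - p_i) + OR * p_i) / ln(OR)

is the expected weight given the model-predicted probability ``p_i``.  The
statistic starts at zero and is compared against Wald decision boundaries

    h1 = ln((1 - beta) / alpha) / ln(OR)      (accept elevated-odds hypothesis)
    h0 = ln(beta / (1 - alpha)) / ln(OR)      (accept null)

expressed on the same ln(OR)-scaled axis.  Surveillance is terminated and the
statistic reset to zero at each reporting-period boundary so that verdicts
align with annual public reports; a period "alerts" if the upper boundary is
crossed at any point within it.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import ReportingPeriod, as_frame

__all__ = [
    "SprtConfig",
    "SprtBoundaries",
    "SprtStep",
    "SprtTrajectory",
    "compute_boundaries",
    "case_weight",
    "update_statistic",
    "run_surveillance",
    "run_all",
]

logger = logging.getLogger(__name__)

#: attained-boundary tie tolerance: T >= h1 - TIE_TOL counts as a crossing
TIE_TOL = 1e-12


@dataclass(frozen=True)
class SprtConfig:
    """Error rates, alerting odds ratio and reset behaviour.

    ``reset_policy='annual'`` restarts the statistic at zero at every
    reporting-period boundary; ``post_crossing_policy='reset_to_zero'``
    restarts it after any boundary crossing within a period so that monitoring
    continues (an ``'absorb'`` mode stops at the first crossing instead).
    """

    alpha: float = 0.05
    beta: float = 0.10
    odds_ratio: float = 2.0
    reset_policy: str = "annual"
    post_crossing_policy: str = "reset_to_zero"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 0.5:
            raise ValueError(f"alpha must be in (0, 0.5), got {self.alpha}")
        if not 0 < self.beta < 0.5:
            raise ValueError(f"beta must be in (0, 0.5), got {self.beta}")
        if self.odds_ratio <= 1:
            raise ValueError(f"odds_ratio must exceed 1, got {self.odds_ratio}")
        if self.reset_policy not in ("annual", "none"):
            raise ValueError(f"unknown reset_policy {self.reset_policy!r}")
        if self.post_crossing_policy not in ("reset_to_zero", "absorb"):
            raise ValueError(f"unknown post_crossing_policy {self.post_crossing_policy!r}")


@dataclass(frozen=True)
class SprtBoundaries:
    """Lower (accept-null) and upper (accept-alternative) decision limits."""

    h0: float
    h1: float


def compute_boundaries(config: SprtConfig) -> SprtBoundaries:
    """Wald boundaries on the ln(OR)-scaled cumulative axis."""
    log_or = math.log(config.odds_ratio)
    h1 = math.log((1.0 - config.beta) / config.alpha) / log_or
    h0 = math.log(config.beta / (1.0 - config.alpha)) / log_or
    return SprtBoundaries(h0=h0, h1=h1)


def case_weight(p, odds_ratio: float):
    """Expected per-case weight ``s_i = ln((1-p) + OR*p) / ln(OR)``.

    Accepts scalars or arrays; requires ``p`` in [0, 1) and ``odds_ratio > 1``.
    ``s`` lies in [0, 1) and satisfies ``s >= p`` (strict for p in (0, 1)).
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr >= 1)):
        raise ValueError("p must lie in [0, 1)")
    if odds_ratio <= 1:
        raise ValueError("odds_ratio must exceed 1")
    s = np.log1p((odds_ratio - 1.0) * p_arr) / math.log(odds_ratio)
    return float(s) if np.isscalar(p) else s


def update_statistic(t_prev: float, outcome: int, p: float, odds_ratio: float) -> float:
    """One sequential update: ``T_i = T_{i-1} + (O_i - s_i)``."""
    return t_prev + (float(outcome) - case_weight(p, odds_ratio))


@dataclass(frozen=True)
class SprtStep:
    """One analysed case on a control chart."""

    index: int
    case_id: str
    date: dt.date
    outcome: int
    probability: float
    weight: float
    increment: float
    cumulative: float


@dataclass
class SprtTrajectory:
    """Per-hospital-period chart: ordered steps, crossings and the alert flag."""

    hospital_id: str
    period_label: str
    boundaries: SprtBoundaries
    steps: list[SprtStep] = field(default_factory=list)
    crossings: list[tuple[int, str]] = field(default_factory=list)
    skipped_case_ids: list[str] = field(default_factory=list)

    @property
    def alerted(self) -> bool:
        return any(boundary == "h1" for _, boundary in self.crossings)

    @property
    def final_value(self) -> float:
        return self.steps[-1].cumulative if self.steps else 0.0


def _predicted_probabilities(frame: pd.DataFrame, models) -> tuple[np.ndarray, np.ndarray]:
    """Model-predicted p per row; mask of rows with no model for their month."""
    months = frame["procedure_date"].dt.to_period("M")
    p = np.full(len(frame), np.nan)
    for month, idx in months.groupby(months).groups.items():
        model = models.get(month)
        if model is None:
            continue
        sub = frame.loc[idx]
        p[frame.index.get_indexer(idx)] = model.predict(sub)
    return p, np.isnan(p)


def run_surveillance(
    cases,
    models,
    config: SprtConfig,
    hospital_id: str | None = None,
    period_label: str = "",
    boundaries: SprtBoundaries | None = None,
) -> SprtTrajectory:
    """Run the RA-SPRT over one hospital-period's time-ordered case stream.

    ``models`` maps analysis months (pandas ``Period``, freq ``M``) to fitted
    risk models; cases whose month has no model are skipped with a log entry.
    The statistic starts at zero; crossings are recorded and, under the
    default post-crossing policy, the statistic resets to zero and monitoring
    continues.  Under ``'absorb'`` monitoring stops at the first crossing.
    """
    frame = as_frame(cases)
    frame = frame.sort_values(["procedure_date", "case_id"], kind="mergesort").reset_index(drop=True)
    if hospital_id is None:
        hospitals = frame["hospital_id"].unique()
        if len(hospitals) > 1:
            raise ValueError("case stream spans several hospitals; pass one hospital's cases")
        hospital_id = str(hospitals[0]) if len(hospitals) else ""
    bounds = boundaries if boundaries is not None else compute_boundaries(config)
    traj = SprtTrajectory(hospital_id=hospital_id, period_label=period_label, boundaries=bounds)
    if frame.empty:
        return traj

    p_all, unscored = _predicted_probabilities(frame, models)
    if unscored.any():
        skipped = frame.loc[unscored, "case_id"].tolist()
        traj.skipped_case_ids.extend(skipped)
        logger.info(
            "%s/%s: skipped %d case(s) with no risk model for their month",
            hospital_id, period_label or "-", len(skipped),
        )

    scored = frame.loc[~unscored].reset_index(drop=True)
    p = p_all[~unscored]
    weights = case_weight(p, config.odds_ratio)
    outcomes = scored["outcome"].to_numpy()
    increments = outcomes - weights

    t = 0.0
    for i in range(len(scored)):
        t += increments[i]
        traj.steps.append(
            SprtStep(
                index=i,
                case_id=str(scored["case_id"].iloc[i]),
                date=scored["procedure_date"].iloc[i].date(),
                outcome=int(outcomes[i]),
                probability=float(p[i]),
                weight=float(weights[i]),
                increment=float(increments[i]),
                cumulative=t,
            )
        )
        crossed = None
        if t >= bounds.h1 - TIE_TOL:
            crossed = "h1"
        elif t <= bounds.h0 + TIE_TOL:
            crossed = "h0"
        if crossed is not None:
            traj.crossings.append((i, crossed))
            if config.post_crossing_policy == "absorb":
                break
            t = 0.0
    return traj


def run_all(
    cases,
    periods: Sequence[ReportingPeriod],
    models,
    config: SprtConfig,
) -> dict[tuple[str, str], SprtTrajectory]:
    """One trajectory per (hospital, period) with at least one case.

    With the default annual reset policy each period is an independent chart
    started at zero; cases in the CY2005/FY2006 overlap quarter contribute to
    both periods' charts.  With ``reset_policy='none'`` a single continuous
    chart per hospital is produced under the pseudo-period label ``'ALL'``.
    """
    frame = as_frame(cases)
    frame = frame.sort_values(["procedure_date", "case_id"], kind="mergesort").reset_index(drop=True)
    bounds = compute_boundaries(config)
    out: dict[tuple[str, str], SprtTrajectory] = {}

    if config.reset_policy == "none":
        for hospital, sub in frame.groupby("hospital_id", sort=True):
            out[(str(hospital), "ALL")] = run_surveillance(
                sub, models, config, hospital_id=str(hospital), period_label="ALL", boundaries=bounds
            )
        return out

    dates = frame["procedure_date"].dt.date
    for period in periods:
        in_period = frame.loc[[period.contains(d) for d in dates]]
        for hospital, sub in in_period.groupby("hospital_id", sort=True):
            out[(str(hospital), period.label)] = run_surveillance(
                sub, models, config,
                hospital_id=str(hospital), period_label=period.label, boundaries=bounds,
            )
    return out
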