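"""Surveillance evaluation: confusion matrices, operating characteristics and
the end-to-end replay pipeline.

The evaluation unit is the hospital-period ("hospital-year observation"): a
period counts as an event when the surveillance chart crossed its upper
boundary at least once, and as a gold-standard positive when the hierarchical
public-report rules flagged the hospital for that period.  Percentages are
reported rounded half-up to one decimal, matching the convention of annual
public reports.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
import time
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .gold import HierarchicalModelSpec, HospitalYearVerdict, classify_outliers, gold_standard_analysis
from .registry import write_registry, write_trajectory
from .risk import build_model_sequence
from .simulate import SimulationScenario, simulate_frame
from .sprt import SprtConfig, SprtTrajectory, case_weight, compute_boundaries, run_all

__all__ = [
    "ConfusionSummary",
    "confusion",
    "sprt_verdicts",
    "operating_characteristics",
    "replay_pipeline",
    "RunReport",
    "round_half_up_pct",
]

logger = logging.getLogger(__name__)


def round_half_up_pct(proportion: float, digits: int = 1) -> float:
    """Proportion -> percentage rounded half-up to ``digits`` decimals."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(proportion * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionSummary:
    """Hospital-period confusion counts with derived proportions."""

    tp: int
    fp: int
    tn: int
    fn: int
    note: str = "event = at least one upper-boundary crossing within the period"

    @property
    def n_units(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    @property
    def sensitivity_pct(self) -> float:
        return round_half_up_pct(self.sensitivity)

    @property
    def specificity_pct(self) -> float:
        return round_half_up_pct(self.specificity)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "n_units": self.n_units,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "note": self.note,
        }


def _as_flag_map(verdicts) -> dict[tuple[str, str], bool]:
    if isinstance(verdicts, Mapping):
        return {tuple(k): bool(v) for k, v in verdicts.items()}
    out: dict[tuple[str, str], bool] = {}
    for v in verdicts:
        if isinstance(v, HospitalYearVerdict):
            out[(v.hospital_id, v.period_label)] = v.flagged
        else:
            raise TypeError(f"cannot interpret verdict {v!r}")
    return out


def confusion(verdicts_sprt, verdicts_gold) -> ConfusionSummary:
    """Confusion counts of surveillance alerts against gold-standard flags.

    Both arguments are mappings (hospital, period) -> flag, or collections of
    :class:`HospitalYearVerdict`.  The unit sets must match exactly; a
    mismatch raises with the symmetric difference listed.
    """
    sprt = _as_flag_map(verdicts_sprt)
    gold = _as_flag_map(verdicts_gold)
    if sprt.keys() != gold.keys():
        only_sprt = sorted(sprt.keys() - gold.keys())
        only_gold = sorted(gold.keys() - sprt.keys())
        raise ValueError(
            "hospital-period sets differ: "
            f"only in surveillance verdicts {only_sprt}; only in gold verdicts {only_gold}"
        )
    tp = fp = tn = fn = 0
    for unit, g in gold.items():
        s = sprt[unit]
        if g and s:
            tp += 1
        elif g and not s:
            fn += 1
        elif not g and s:
            fp += 1
        else:
            tn += 1
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


def sprt_verdicts(trajectories: Mapping[tuple[str, str], SprtTrajectory]) -> list[HospitalYearVerdict]:
    """Hospital-period alert verdicts from a set of surveillance trajectories."""
    out = []
    for (hospital, label), traj in sorted(trajectories.items()):
        out.append(
            HospitalYearVerdict(
                hospital_id=hospital,
                period_label=label,
                source="ra_sprt",
                flagged=traj.alerted,
                basis=("h1_crossing",) if traj.alerted else (),
            )
        )
    return out


# ---------------------------------------------------------------------------
# operating characteristics

def _alert_fraction(
    volume: int,
    baseline: float,
    true_or: float,
    config: SprtConfig,
    replicates: int,
    rng: np.random.Generator,
) -> float:
    """Fraction of simulated hospital-periods with an upper-boundary alert.

    The risk model is taken as known (every case's predicted probability is
    the baseline rate), isolating the sequential test's own behaviour; true
    outcome probabilities are the baseline odds multiplied by ``true_or``.
    """
    if volume == 0:
        return 0.0
    bounds = compute_boundaries(config)
    odds = baseline / (1.0 - baseline) * true_or
    p_true = odds / (1.0 + odds)
    s = float(case_weight(baseline, config.odds_ratio))

    t = np.zeros(replicates)
    alerted = np.zeros(replicates, dtype=bool)
    for _ in range(volume):
        o = rng.random(replicates) < p_true
        t += o.astype(float) - s
        up = t >= bounds.h1 - 1e-12
        down = t <= bounds.h0 + 1e-12
        alerted |= up
        # post-crossing reset: either boundary restarts the chart at zero
        t[up | down] = 0.0
    return float(alerted.mean())


def operating_characteristics(
    volumes: Sequence[int],
    baseline_rates: Sequence[float],
    true_odds_ratios: Sequence[float],
    config: SprtConfig | None = None,
    replicates: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical per-period alert rates over a (volume, rate, OR) grid.

    Returns one row per cell with the alert fraction and its binomial
    standard error across the seeded replicates.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    config = config if config is not None else SprtConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for volume in volumes:
        for baseline in baseline_rates:
            for true_or in true_odds_ratios:
                frac = _alert_fraction(int(volume), float(baseline), float(true_or), config, replicates, rng)
                se = float(np.sqrt(frac * (1 - frac) / replicates))
                rows.append((int(volume), float(baseline), float(true_or), frac, se))
    return pd.DataFrame(rows, columns=["volume", "baseline_rate", "true_or", "alert_rate", "se"])


# ---------------------------------------------------------------------------
# end-to-end replay

@dataclass
class RunReport:
    """Everything the replay pipeline computed, plus where it was written."""

    out_dir: Path
    trajectories: dict
    sprt_verdicts: list[HospitalYearVerdict]
    gold_summaries: dict
    gold_verdicts: list[HospitalYearVerdict]
    confusion_vs_gold: ConfusionSummary | None
    confusion_vs_truth: ConfusionSummary | None
    manifest: dict = field(default_factory=dict)

    @property
    def alert_events(self) -> int:
        return sum(v.flagged for v in self.sprt_verdicts)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def replay_pipeline(
    scenario: SimulationScenario,
    config: SprtConfig | None = None,
    gold_spec: HierarchicalModelSpec | None = None,
    out_dir=None,
    seed: int | None = None,
    gold: str = "none",
    gold_cv: str | list[str] = "all",
) -> RunReport:
    """Simulate, fit monthly risk models, run surveillance and evaluate.

    Stages: registry simulation -> rolling model sequence -> per
    hospital-period surveillance charts -> (optionally, ``gold='full'``)
    per-period hierarchical gold-standard verdicts -> confusion summaries
    against the gold standard and against the injected simulation truth.
    All artifacts land under a timestamped directory inside ``out_dir`` with
    a machine-readable manifest (configuration, seeds, versions, artifact
    hashes).  Deterministic given ``seed``: numeric artifact hashes repeat.
    """
    config = config if config is not None else SprtConfig()
    t0 = time.monotonic()
    if out_dir is None:
        out_dir = Path("rasprt-runs")
    stamp = dt.datetime.now().strftime("%Y%m%dT%H%M%S")
    run_dir = Path(out_dir) / f"run-{stamp}"
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "trajectories").mkdir(exist_ok=True)

    frame = simulate_frame(scenario, seed=seed)
    write_registry(frame, run_dir / "registry.csv", scenario.schema)
    logger.info("simulated %d cases [%.1fs]", len(frame), time.monotonic() - t0)

    models = build_model_sequence(frame, scenario.schema)
    _json_dump({"models": models.to_records(), "skipped": models.skipped}, run_dir / "models.json")
    logger.info("fitted %d monthly models (%d skipped) [%.1fs]",
                len(models), len(models.skipped), time.monotonic() - t0)

    trajectories = run_all(frame, scenario.periods, models, config)
    for (hospital, label), traj in sorted(trajectories.items()):
        if traj.steps:
            write_trajectory(traj, run_dir / "trajectories" / f"{hospital}_{label}.tsv")
    verdicts = sprt_verdicts(trajectories)
    _json_dump(
        [
            {"hospital_id": v.hospital_id, "period_label": v.period_label,
             "flagged": v.flagged, "basis": list(v.basis)}
            for v in verdicts
        ],
        run_dir / "alerts.json",
    )
    logger.info("surveillance: %d hospital-periods, %d alerts [%.1fs]",
                len(verdicts), sum(v.flagged for v in verdicts), time.monotonic() - t0)

    gold_summaries: dict = {}
    gold_verdicts: list[HospitalYearVerdict] = []
    confusion_vs_gold = None
    if gold == "full":
        dates = frame["procedure_date"].dt.date
        for period in scenario.periods:
            sub = frame.loc[[period.contains(d) for d in dates]]
            if sub.empty:
                continue
            summary = gold_standard_analysis(sub, gold_spec, period_label=period.label, cv=gold_cv)
            gold_summaries[period.label] = summary
            gold_verdicts.extend(classify_outliers(summary))
            out = summary.table.copy()
            out.to_csv(run_dir / f"gold_{period.label}.tsv", sep="\t", index=False, float_format="%.6g")
            logger.info("gold standard %s done [%.1fs]", period.label, time.monotonic() - t0)
        confusion_vs_gold = confusion(verdicts, gold_verdicts)

    # confusion against the simulation's injected truth
    injected_units = {(i.hospital_id, i.period_label) for i in scenario.outlier_injections}
    truth = {(v.hospital_id, v.period_label): (v.hospital_id, v.period_label) in injected_units
             for v in verdicts}
    confusion_vs_truth = confusion(verdicts, truth) if verdicts else None

    manifest = {
        "package_version": _pkg_version,
        "seed": scenario.seed if seed is None else seed,
        "sprt_config": {
            "alpha": config.alpha, "beta": config.beta, "odds_ratio": config.odds_ratio,
            "reset_policy": config.reset_policy,
            "post_crossing_policy": config.post_crossing_policy,
        },
        "n_cases": int(len(frame)),
        "n_hospital_periods": len(verdicts),
        "alert_events": sum(v.flagged for v in verdicts),
        "timestamp": stamp,
        "hashes": {
            str(p.relative_to(run_dir)): _sha256(p)
            for p in sorted(run_dir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    if confusion_vs_gold is not None:
        manifest["confusion_vs_gold"] = confusion_vs_gold.to_dict()
    if confusion_vs_truth is not None:
        manifest["confusion_vs_truth"] = confusion_vs_truth.to_dict()
    _json_dump(manifest, run_dir / "manifest.json")

    return RunReport(
        out_dir=run_dir,
        trajectories=trajectories,
        sprt_verdicts=verdicts,
        gold_summaries=gold_summaries,
        gold_verdicts=gold_verdicts,
        confusion_vs_gold=confusion_vs_gold,
        confusion_vs_truth=confusion_vs_truth,
        manifest=manifest,
    )
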