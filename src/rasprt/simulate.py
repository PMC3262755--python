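"""Synthetic clinical-registry generator.

Emulates the statistical structure of a statewide isolated-CABG registry:
13–14 hospitals, roughly 3,400–4,600 admissions per reporting period, annual
crude 30-day mortality between about 1.4% and 2.2%, and published marginal
risk-factor prevalences.  Outcomes follow a logistic model

    logit P(death) = c + x'beta + u_j + sum(ln m)

with a per-period intercept ``c`` calibrated to the target crude mortality,
documented "true" coefficients ``beta``, optional per-hospital log-odds
offsets ``u_j``, and injected odds-ratio multipliers ``m`` for chosen
hospital-periods (the outliers surveillance should find).  Risk factors are
drawn independently from their marginal distributions; everything is
reproducible from the scenario seed.
"""

from __future__ import annotations

import datetime as dt
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .registry import (
    CaseRecord,
    ReportingPeriod,
    RiskFactorSchema,
    default_periods,
    default_schema,
    records_from_frame,
)

__all__ = [
    "OutlierInjection",
    "GenerationSegment",
    "SimulationScenario",
    "default_scenario",
    "simulate_registry",
    "simulate_frame",
    "hospital_period_count",
    "load_scenario",
    "save_scenario",
]

#: marginal risk-factor distribution of the earliest published study year,
#: used (for simplicity) for every simulated year
DEFAULT_PREVALENCES: dict[str, object] = {
    "male": 0.745,
    "renal_failure": 0.073,
    "diabetes": 0.380,
    "hypertension": 0.770,
    "peripheral_vascular_disease": 0.180,
    "prior_cabg": 0.038,
    "prior_ptca_pci": 0.186,
    "cardiogenic_shock": 0.022,
    "preop_iabp": 0.093,
    "ejection_fraction": {"ge40": 0.755, "30_39": 0.117, "lt30_or_missing": 0.128},
    "mi_timing": {"none": 0.766, "within_24h": 0.027, "1_7_days": 0.207},
    "status": {"elective": 0.343, "urgent": 0.620, "emergent_salvage": 0.037},
}

#: clinically plausible true log-odds-ratio coefficients (per design column);
#: these are the recovery targets for the risk-model tests, not published values
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "age": 0.05,
    "male": -0.25,
    "renal_failure": 0.80,
    "diabetes": 0.15,
    "hypertension": 0.10,
    "peripheral_vascular_disease": 0.35,
    "prior_cabg": 0.70,
    "prior_ptca_pci": 0.05,
    "cardiogenic_shock": 1.80,
    "ejection_fraction[30_39]": 0.35,
    "ejection_fraction[lt30_or_missing]": 0.70,
    "mi_timing[within_24h]": 0.70,
    "mi_timing[1_7_days]": 0.30,
    "status[urgent]": 0.30,
    "status[emergent_salvage]": 1.30,
    "preop_iabp": 0.60,
}


@dataclass(frozen=True)
class OutlierInjection:
    """Multiplicative odds elevation for one hospital in one reporting period."""

    hospital_id: str
    period_label: str
    odds_multiplier: float

    def __post_init__(self) -> None:
        if self.odds_multiplier <= 0:
            raise ValueError("odds_multiplier must be positive")


@dataclass(frozen=True)
class GenerationSegment:
    """A non-overlapping slice of the study timeline with its own volume.

    Reporting periods overlap on the 2005 fourth quarter, so cases are
    generated on disjoint segments and assigned to (possibly two) periods by
    date afterwards.
    """

    label: str
    start: dt.date
    end: dt.date
    volume: int
    hospitals: tuple[str, ...]
    target_mortality: float

    def __post_init__(self) -> None:
        if self.volume < 0:
            raise ValueError("volume must be non-negative")
        if not 0 < self.target_mortality < 1:
            raise ValueError("target_mortality must be a proportion in (0, 1)")


@dataclass(frozen=True)
class SimulationScenario:
    """Full data-generating description of a synthetic registry."""

    periods: tuple[ReportingPeriod, ...]
    segments: tuple[GenerationSegment, ...]
    prevalences: Mapping[str, object] = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    coefficients: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    age_mean: float = 66.5
    age_sd: float = 10.7
    age_bounds: tuple[float, float] = (18.0, 100.0)
    intercept: float | None = None          # None: calibrate per segment to target_mortality
    hospital_effects: Mapping[str, float] = field(default_factory=dict)
    outlier_injections: tuple[OutlierInjection, ...] = ()
    seed: int = 20020101
    schema: RiskFactorSchema = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        labels = {p.label for p in self.periods}
        hospitals = {h for seg in self.segments for h in seg.hospitals}
        for inj in self.outlier_injections:
            if inj.period_label not in labels:
                raise ValueError(f"injection names unknown period {inj.period_label!r}")
            if inj.hospital_id not in hospitals:
                raise ValueError(f"injection names unknown hospital {inj.hospital_id!r}")

    def with_injections(self, injections: Sequence[OutlierInjection]) -> "SimulationScenario":
        return replace(self, outlier_injections=tuple(injections))


def default_scenario(seed: int = 20020101) -> SimulationScenario:
    """Default scenario matching the published registry's shape.

    13 hospitals in the first calendar year, 14 thereafter; per-period volumes
    equal to the published admissions row (4604, 4393, 3986, 3885, 3684,
    3396); the 925 overlap-quarter cases are generated once and belong to
    both CY2005 and FY2006; per-period crude mortality targets follow the
    published yearly rates (2.17% down to 1.47%).
    """
    hospitals_13 = tuple(f"H{i:02d}" for i in range(1, 14))
    hospitals_14 = tuple(f"H{i:02d}" for i in range(1, 15))
    d = dt.date
    segments = (
        GenerationSegment("CY2002", d(2002, 1, 1), d(2002, 12, 31), 4604, hospitals_13, 0.0217),
        GenerationSegment("CY2003", d(2003, 1, 1), d(2003, 12, 31), 4393, hospitals_14, 0.0225),
        GenerationSegment("CY2004", d(2004, 1, 1), d(2004, 12, 31), 3986, hospitals_14, 0.0201),
        # CY2005 is split so the overlap quarter carries its published volume
        GenerationSegment("2005JanSep", d(2005, 1, 1), d(2005, 9, 30), 2960, hospitals_14, 0.0165),
        GenerationSegment("2005Q4", d(2005, 10, 1), d(2005, 12, 31), 925, hospitals_14, 0.0165),
        GenerationSegment("2006JanSep", d(2006, 1, 1), d(2006, 9, 30), 2759, hospitals_14, 0.0141),
        GenerationSegment("FY2007", d(2006, 10, 1), d(2007, 9, 30), 3396, hospitals_14, 0.0147),
    )
    return SimulationScenario(periods=default_periods(), segments=segments, seed=seed)


def hospital_period_count(scenario: SimulationScenario) -> int:
    """Number of unique hospital-periods implied by the scenario."""
    count = 0
    for period in scenario.periods:
        active: set[str] = set()
        for seg in scenario.segments:
            if seg.volume > 0 and seg.start <= period.end and seg.end >= period.start:
                active.update(seg.hospitals)
        count += len(active)
    return count


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    """Truncated normal via resampling (deterministic given the generator state)."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def _draw_factors(scenario: SimulationScenario, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    for f in scenario.schema.factors:
        if f.kind == "continuous":
            lo, hi = scenario.age_bounds
            cols[f.name] = np.round(
                _truncnorm(rng, scenario.age_mean, scenario.age_sd, lo, hi, n), 1
            )
        elif f.kind == "binary":
            prev = float(scenario.prevalences[f.name])  # type: ignore[arg-type]
            cols[f.name] = (rng.random(n) < prev).astype(int)
        else:
            probs_map = scenario.prevalences[f.name]
            levels = list(f.levels)
            probs = np.array([probs_map[lv] for lv in levels], dtype=float)  # type: ignore[index]
            probs = probs / probs.sum()
            cols[f.name] = np.asarray(levels, dtype=object)[rng.choice(len(levels), size=n, p=probs)]
    return cols


def _split_volume(volume: int, hospitals: Sequence[str]) -> list[int]:
    base, rem = divmod(volume, len(hospitals))
    return [base + (1 if i < rem else 0) for i in range(len(hospitals))]


def simulate_frame(scenario: SimulationScenario, seed: int | None = None) -> pd.DataFrame:
    """Simulate the registry as a DataFrame, including truth columns.

    Besides the registry columns the frame carries ``true_p`` (the generating
    probability), ``true_logit`` and ``injected`` (summed injected log-odds),
    which downstream truth-recovery tests use.  Rows are sorted by
    (procedure_date, case_id); case ids are assigned in that order.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    beta = np.array([scenario.coefficients.get(c, 0.0) for c in scenario.schema.design_columns()])
    period_by_label = {p.label: p for p in scenario.periods}

    pieces: list[pd.DataFrame] = []
    for seg in scenario.segments:
        if seg.volume == 0 or not seg.hospitals:
            continue
        counts = _split_volume(seg.volume, seg.hospitals)
        n = sum(counts)
        hosp = np.repeat(np.asarray(seg.hospitals, dtype=object), counts)
        n_days = (seg.end - seg.start).days + 1
        day_offsets = rng.integers(0, n_days, size=n)
        dates = pd.to_datetime(seg.start) + pd.to_timedelta(day_offsets, unit="D")

        factors = _draw_factors(scenario, n, rng)
        frame = pd.DataFrame({"hospital_id": hosp, "procedure_date": dates, **factors})
        xb = scenario.schema.design_matrix(frame, add_intercept=False) @ beta

        if scenario.intercept is not None:
            c = float(scenario.intercept)
        else:
            target = seg.target_mortality
            lo, hi = logit(target) - np.max(xb) - 5, logit(target) - np.min(xb) + 5
            c = brentq(lambda b: expit(b + xb).mean() - target, lo, hi, xtol=1e-12)

        hosp_eff = np.array([scenario.hospital_effects.get(h, 0.0) for h in hosp])
        injected = np.zeros(n)
        case_dates = frame["procedure_date"].dt.date
        for inj in scenario.outlier_injections:
            period = period_by_label[inj.period_label]
            mask = (hosp == inj.hospital_id) & np.array(
                [period.contains(d) for d in case_dates]
            )
            injected[mask] += np.log(inj.odds_multiplier)

        true_logit = c + xb + hosp_eff + injected
        true_p = expit(true_logit)
        frame["outcome"] = (rng.random(n) < true_p).astype(int)
        frame["true_logit"] = true_logit
        frame["true_p"] = true_p
        frame["injected"] = injected
        pieces.append(frame)

    if not pieces:
        cols = ["case_id", "hospital_id", "procedure_date", "outcome"] + list(scenario.schema.names)
        return pd.DataFrame(columns=cols)

    out = pd.concat(pieces, ignore_index=True)
    out = out.sort_values(
        ["procedure_date", "hospital_id"], kind="mergesort"
    ).reset_index(drop=True)
    out.insert(0, "case_id", [f"C{i + 1:06d}" for i in range(len(out))])
    return out


def simulate_registry(scenario: SimulationScenario, seed: int | None = None) -> list[CaseRecord]:
    """Simulate the registry as case records sorted by (date, case_id)."""
    frame = simulate_frame(scenario, seed=seed)
    return records_from_frame(frame, scenario.schema)


# ---------------------------------------------------------------------------
# scenario (de)serialisation for the CLI

def save_scenario(scenario: SimulationScenario, path) -> None:
    doc = {
        "seed": scenario.seed,
        "age_mean": scenario.age_mean,
        "age_sd": scenario.age_sd,
        "age_bounds": list(scenario.age_bounds),
        "intercept": scenario.intercept,
        "prevalences": {k: (dict(v) if isinstance(v, Mapping) else v) for k, v in scenario.prevalences.items()},
        "coefficients": dict(scenario.coefficients),
        "hospital_effects": dict(scenario.hospital_effects),
        "periods": [
            {"label": p.label, "start": p.start.isoformat(), "end": p.end.isoformat()}
            for p in scenario.periods
        ],
        "segments": [
            {
                "label": s.label, "start": s.start.isoformat(), "end": s.end.isoformat(),
                "volume": s.volume, "hospitals": list(s.hospitals),
                "target_mortality": s.target_mortality,
            }
            for s in scenario.segments
        ],
        "outlier_injections": [
            {"hospital_id": i.hospital_id, "period_label": i.period_label, "odds_multiplier": i.odds_multiplier}
            for i in scenario.outlier_injections
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_scenario(path) -> SimulationScenario:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    parse = dt.date.fromisoformat
    return SimulationScenario(
        periods=tuple(
            ReportingPeriod(p["label"], parse(p["start"]), parse(p["end"])) for p in doc["periods"]
        ),
        segments=tuple(
            GenerationSegment(
                s["label"], parse(s["start"]), parse(s["end"]), int(s["volume"]),
                tuple(s["hospitals"]), float(s["target_mortality"]),
            )
            for s in doc["segments"]
        ),
        prevalences=doc.get("prevalences", dict(DEFAULT_PREVALENCES)),
        coefficients=doc.get("coefficients", dict(DEFAULT_COEFFICIENTS)),
        age_mean=doc.get("age_mean", 66.5),
        age_sd=doc.get("age_sd", 10.7),
        age_bounds=tuple(doc.get("age_bounds", (18.0, 100.0))),
        intercept=doc.get("intercept"),
        hospital_effects=doc.get("hospital_effects", {}),
        outlier_injections=tuple(
            OutlierInjection(i["hospital_id"], i["period_label"], float(i["odds_multiplier"]))
            for i in doc.get("outlier_injections", [])
        ),
        seed=int(doc.get("seed", 20020101)),
    )
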