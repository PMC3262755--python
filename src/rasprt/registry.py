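"""Registry case records, risk-factor schema, reporting periods and file I/O.

The unit of analysis is one isolated-CABG admission: a hospital identifier, a
procedure date, a binary 30-day all-cause mortality outcome, and the fixed
risk-factor vector used by the statewide public-report risk model.  Reporting
periods are calendar years through 2005 and fiscal years (October 1 through
September 30) afterwards, so the last quarter of 2005 belongs to two periods.
"""

from __future__ import annotations

import datetime as dt
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RegistryError",
    "FactorDef",
    "RiskFactorSchema",
    "CaseRecord",
    "ReportingPeriod",
    "default_schema",
    "default_periods",
    "assign_periods",
    "read_registry",
    "write_registry",
    "as_frame",
    "records_from_frame",
    "write_trajectory",
    "read_trajectory",
]

CONTINUOUS = "continuous"
BINARY = "binary"
CATEGORICAL = "categorical"

#: columns every registry file must carry besides the risk factors
ID_COLUMNS = ("case_id", "hospital_id", "procedure_date", "outcome")


class RegistryError(ValueError):
    """Raised for malformed registry files or schema violations."""


@dataclass(frozen=True)
class FactorDef:
    """One covariate definition: name, kind and (for categoricals) levels.

    For categorical factors the first level is the reference level and is not
    expanded into a design column.
    """

    name: str
    kind: str
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, BINARY, CATEGORICAL):
            raise ValueError(f"unknown factor kind {self.kind!r}")
        if self.kind == CATEGORICAL and len(self.levels) < 2:
            raise ValueError(f"categorical factor {self.name!r} needs >= 2 levels")
        if self.kind != CATEGORICAL and self.levels:
            raise ValueError(f"levels only apply to categorical factors ({self.name!r})")


@dataclass(frozen=True)
class RiskFactorSchema:
    """Ordered risk-factor list defining the registry columns and design matrix."""

    factors: tuple[FactorDef, ...] = ()

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def factor(self, name: str) -> FactorDef:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def design_columns(self) -> list[str]:
        """Design-matrix column names, excluding the intercept."""
        cols: list[str] = []
        for f in self.factors:
            if f.kind == CATEGORICAL:
                cols.extend(f"{f.name}[{lv}]" for lv in f.levels[1:])
            else:
                cols.append(f.name)
        return cols

    def design_matrix(self, frame: pd.DataFrame, add_intercept: bool = True) -> np.ndarray:
        """Numeric design matrix for ``frame`` (intercept first when requested)."""
        cols: list[np.ndarray] = []
        if add_intercept:
            cols.append(np.ones(len(frame)))
        for f in self.factors:
            vals = frame[f.name]
            if f.kind == CATEGORICAL:
                for lv in f.levels[1:]:
                    cols.append((vals.astype(str) == lv).to_numpy(dtype=float))
            else:
                cols.append(pd.to_numeric(vals).to_numpy(dtype=float))
        if not cols:
            return np.empty((len(frame), 0))
        return np.column_stack(cols)

    def validate_frame(self, frame: pd.DataFrame) -> list[str]:
        """Return a list of human-readable problems (empty when clean).

        Row numbers refer to 1-based data rows as they appear in a file with a
        header (i.e. file line = row + 1).
        """
        problems: list[str] = []
        for col in ID_COLUMNS + self.names:
            if col not in frame.columns:
                problems.append(f"missing required column {col!r}")
        if problems:
            return problems

        outcome = pd.to_numeric(frame["outcome"], errors="coerce")
        bad = ~outcome.isin([0, 1])
        for pos in np.nonzero(bad.to_numpy())[0]:
            problems.append(f"row {pos + 1}: outcome must be 0 or 1, got {frame['outcome'].iloc[pos]!r}")

        dates = pd.to_datetime(frame["procedure_date"], errors="coerce")
        for pos in np.nonzero(dates.isna().to_numpy())[0]:
            problems.append(f"row {pos + 1}: unparseable procedure_date {frame['procedure_date'].iloc[pos]!r}")

        if frame["case_id"].duplicated().any():
            dupes = frame.loc[frame["case_id"].duplicated(), "case_id"].unique()
            problems.append(f"duplicate case_id values: {', '.join(map(str, dupes[:5]))}")

        for f in self.factors:
            vals = frame[f.name]
            if f.kind == CATEGORICAL:
                bad = ~vals.astype(str).isin(f.levels)
                for pos in np.nonzero(bad.to_numpy())[0]:
                    problems.append(
                        f"row {pos + 1}: field {f.name!r} has unknown level {vals.iloc[pos]!r}"
                    )
            elif f.kind == BINARY:
                numeric = pd.to_numeric(vals, errors="coerce")
                bad = ~numeric.isin([0, 1])
                for pos in np.nonzero(bad.to_numpy())[0]:
                    problems.append(f"row {pos + 1}: field {f.name!r} must be 0 or 1, got {vals.iloc[pos]!r}")
            else:
                numeric = pd.to_numeric(vals, errors="coerce")
                for pos in np.nonzero(numeric.isna().to_numpy())[0]:
                    problems.append(f"row {pos + 1}: field {f.name!r} must be numeric, got {vals.iloc[pos]!r}")
        return problems


def default_schema() -> RiskFactorSchema:
    """The statewide isolated-CABG risk-factor list.

    Ejection fraction below 30% and missing ejection fraction are pooled into
    a single level; myocardial-infarction timing and surgical status carry
    their clinically standard reference levels (none/older MI, elective).
    """
    return RiskFactorSchema(
        factors=(
            FactorDef("age", CONTINUOUS),
            FactorDef("male", BINARY),
            FactorDef("renal_failure", BINARY),
            FactorDef("diabetes", BINARY),
            FactorDef("hypertension", BINARY),
            FactorDef("peripheral_vascular_disease", BINARY),
            FactorDef("prior_cabg", BINARY),
            FactorDef("prior_ptca_pci", BINARY),
            FactorDef("cardiogenic_shock", BINARY),
            FactorDef("ejection_fraction", CATEGORICAL, ("ge40", "30_39", "lt30_or_missing")),
            FactorDef("mi_timing", CATEGORICAL, ("none", "within_24h", "1_7_days")),
            FactorDef("status", CATEGORICAL, ("elective", "urgent", "emergent_salvage")),
            FactorDef("preop_iabp", BINARY),
        )
    )


@dataclass(frozen=True)
class CaseRecord:
    """One admission: identifiers, date, 30-day mortality and risk factors."""

    case_id: str
    hospital_id: str
    procedure_date: dt.date
    outcome: int
    risk_factors: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outcome not in (0, 1):
            raise ValueError(f"outcome must be 0 or 1, got {self.outcome!r}")


@dataclass(frozen=True)
class ReportingPeriod:
    """A labelled inclusive date interval (calendar or fiscal year)."""

    label: str
    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"period {self.label!r} ends before it starts")

    def contains(self, date: dt.date) -> bool:
        return self.start <= date <= self.end


def default_periods() -> tuple[ReportingPeriod, ...]:
    """Study reporting periods: CY2002–CY2005 then FY2006 and FY2007.

    Fiscal years run October 1 through September 30, so FY2006 overlaps
    CY2005 on October 1 – December 31 2005; no other pair overlaps.
    """
    periods = [
        ReportingPeriod(f"CY{y}", dt.date(y, 1, 1), dt.date(y, 12, 31)) for y in range(2002, 2006)
    ]
    periods.append(ReportingPeriod("FY2006", dt.date(2005, 10, 1), dt.date(2006, 9, 30)))
    periods.append(ReportingPeriod("FY2007", dt.date(2006, 10, 1), dt.date(2007, 9, 30)))
    return tuple(periods)


def assign_periods(date: dt.date, periods: Sequence[ReportingPeriod]) -> set[str]:
    """Labels of every period whose inclusive interval contains ``date``.

    A date in the CY2005/FY2006 overlap quarter returns both labels; a date
    outside all periods returns the empty set with a warning.
    """
    if isinstance(date, (pd.Timestamp, dt.datetime)):
        date = date.date()
    labels = {p.label for p in periods if p.contains(date)}
    if not labels:
        warnings.warn(f"date {date} falls outside all reporting periods", stacklevel=2)
    return labels


# ---------------------------------------------------------------------------
# registry I/O and container conversion

def as_frame(cases: Iterable[CaseRecord] | pd.DataFrame, schema: RiskFactorSchema | None = None) -> pd.DataFrame:
    """Normalise a case collection to the canonical DataFrame layout.

    Columns: case_id, hospital_id, procedure_date (datetime64), outcome, then
    one column per schema factor.  Row order is preserved.
    """
    if isinstance(cases, pd.DataFrame):
        frame = cases.copy()
    else:
        cases = list(cases)
        rows = {
            "case_id": [c.case_id for c in cases],
            "hospital_id": [c.hospital_id for c in cases],
            "procedure_date": [c.procedure_date for c in cases],
            "outcome": [c.outcome for c in cases],
        }
        names = schema.names if schema is not None else (
            tuple(cases[0].risk_factors.keys()) if cases else ()
        )
        for name in names:
            rows[name] = [c.risk_factors[name] for c in cases]
        frame = pd.DataFrame(rows)
    frame["procedure_date"] = pd.to_datetime(frame["procedure_date"])
    frame["outcome"] = frame["outcome"].astype(int)
    return frame


def records_from_frame(frame: pd.DataFrame, schema: RiskFactorSchema) -> list[CaseRecord]:
    factor_names = schema.names
    records = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        records.append(
            CaseRecord(
                case_id=str(d["case_id"]),
                hospital_id=str(d["hospital_id"]),
                procedure_date=pd.Timestamp(d["procedure_date"]).date(),
                outcome=int(d["outcome"]),
                risk_factors={n: d[n] for n in factor_names},
            )
        )
    return records


def read_registry(
    path,
    schema: RiskFactorSchema | None = None,
    delimiter: str = ",",
    periods: Sequence[ReportingPeriod] | None = None,
) -> list[CaseRecord]:
    """Read a registry CSV/TSV and return cases sorted by (date, case_id).

    Raises :class:`RegistryError` naming row numbers (1-based data rows) for
    any malformed value; if ``periods`` is given, dates outside every period
    trigger a warning but are kept.
    """
    schema = schema if schema is not None else default_schema()
    frame = pd.read_csv(path, sep=delimiter, dtype={"case_id": str, "hospital_id": str})
    problems = schema.validate_frame(frame)
    if problems:
        raise RegistryError(f"{path}: " + "; ".join(problems))
    frame["procedure_date"] = pd.to_datetime(frame["procedure_date"])
    if periods is not None:
        for date in frame["procedure_date"].dt.date.unique():
            assign_periods(date, periods)  # warns when outside the study window
    frame = frame.sort_values(["procedure_date", "case_id"], kind="mergesort").reset_index(drop=True)
    return records_from_frame(frame, schema)


def write_registry(cases, path, schema: RiskFactorSchema | None = None, delimiter: str = ",") -> None:
    schema = schema if schema is not None else default_schema()
    frame = as_frame(cases, schema)
    out = frame[list(ID_COLUMNS) + list(schema.names)].copy()
    out["procedure_date"] = out["procedure_date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# trajectory export (chart data: one row per sequentially analysed case)

_TRAJ_COLUMNS = [
    "step", "case_id", "date", "outcome", "predicted_probability",
    "weight", "increment", "cumulative", "h0", "h1", "crossed",
]


def write_trajectory(trajectory, path) -> None:
    """Write an SPRT trajectory as TSV, one row per analysed case.

    Floats are written with 12 significant digits so a write/read round-trip
    reproduces the in-memory cumulative statistic.
    """
    steps = trajectory.steps
    if not steps:
        raise ValueError("cannot export an empty trajectory")
    crossed_at = {idx: boundary for idx, boundary in trajectory.crossings}
    with open(path, "w") as fh:
        fh.write("\t".join(_TRAJ_COLUMNS) + "\n")
        for s in steps:
            row = [
                str(s.index),
                s.case_id,
                s.date.isoformat(),
                str(s.outcome),
                format(s.probability, ".12g"),
                format(s.weight, ".12g"),
                format(s.increment, ".12g"),
                format(s.cumulative, ".12g"),
                format(trajectory.boundaries.h0, ".12g"),
                format(trajectory.boundaries.h1, ".12g"),
                crossed_at.get(s.index, ""),
            ]
            fh.write("\t".join(row) + "\n")


def read_trajectory(path) -> pd.DataFrame:
    """Read a trajectory TSV back into a DataFrame (column layout as written)."""
    return pd.read_csv(path, sep="\t", dtype={"case_id": str}, keep_default_na=False,
                       na_values=[], parse_dates=["date"])
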