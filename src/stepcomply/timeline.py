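"""Ingest step-count tables and align them on a fixed perioperative day grid.

The analysis window runs from 14 days before surgery (day index -14) through
42 days after surgery (day index 42), with the surgery day at index 0 — 57
calendar days in total.  Days are local midnight-to-midnight; hours are clock
hour labels (00:00-00:59 is bin 0).  Days with no records are materialized as
all-zero :class:`StepDay` objects so that downstream criteria score them as
non-compliant rather than silently dropping them.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DAY_MIN = -14
DAY_MAX = 42
N_DAYS = DAY_MAX - DAY_MIN + 1  # 57
DAY_INDICES = tuple(range(DAY_MIN, DAY_MAX + 1))

#: Two-week stage windows; the surgery day (index 0) belongs to no stage.
STAGE_WINDOWS: Mapping[str, frozenset[int]] = {
    "presurgery": frozenset(range(-14, 0)),
    "weeks_0_2": frozenset(range(1, 15)),
    "weeks_2_4": frozenset(range(15, 29)),
    "weeks_4_6": frozenset(range(29, 43)),
}
STAGE_NAMES = tuple(STAGE_WINDOWS)


@dataclass(frozen=True)
class StepRecord:
    """One raw step-count observation for one patient."""

    patient_id: str
    timestamp: datetime.datetime
    steps: int

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise ValueError(f"negative step count: {self.steps}")


@dataclass
class StepDay:
    """One patient-day of step counts binned into 24 clock hours."""

    day_index: int
    hourly: np.ndarray
    minutes_observed: int = 0

    def __post_init__(self) -> None:
        self.hourly = np.asarray(self.hourly, dtype=np.int64)
        if self.hourly.shape != (24,):
            raise ValueError("hourly vector must have length 24")
        if (self.hourly < 0).any():
            raise ValueError("hourly counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.hourly.sum())

    @classmethod
    def empty(cls, day_index: int) -> "StepDay":
        return cls(day_index=day_index, hourly=np.zeros(24, dtype=np.int64))


@dataclass(frozen=True)
class PatientMeta:
    patient_id: str
    surgery_date: datetime.date
    age: float
    gender: str
    bmi: float
    asa: int
    device: str

    def __post_init__(self) -> None:
        if self.device not in ("clip", "wrist"):
            raise ValueError(f"device must be 'clip' or 'wrist', got {self.device!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.bmi <= 0:
            raise ValueError("bmi must be positive")
        if not 1 <= int(self.asa) <= 5:
            raise ValueError("asa class must be in 1..5")


@dataclass
class PatientTimeline:
    """A patient's full 57-day indexed map of step days plus metadata."""

    meta: PatientMeta
    days: dict[int, StepDay]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if set(self.days) != set(DAY_INDICES):
            raise ValueError("timeline must cover exactly the 57 day indices -14..42")

    def day(self, day_index: int) -> StepDay:
        return self.days[day_index]

    @property
    def patient_id(self) -> str:
        return self.meta.patient_id


@dataclass(frozen=True)
class TableDialect:
    """Column mapping for a delimited step table."""

    patient_col: str = "patient_id"
    time_col: str = "timestamp"
    steps_col: str = "steps"
    resolution: str = "minute"  # 'minute' or 'hour'
    sep: str = ","


@dataclass
class StepTable:
    """Parsed step records grouped by patient, plus a parse report."""

    by_patient: dict[str, list[StepRecord]]
    n_rows: int = 0
    n_bad_timestamp: int = 0
    n_rejected_negative: int = 0

    def __len__(self) -> int:
        return sum(len(v) for v in self.by_patient.values())


def read_steps_table(source: str | Path, dialect: TableDialect = TableDialect()) -> StepTable:
    """Read a delimited step table into :class:`StepRecord` objects per patient.

    Rows with unparseable timestamps are skipped and counted; rows with
    negative step counts are rejected and counted.  A missing mandatory
    column raises ``KeyError``.
    """
    df = pd.read_csv(source, sep=dialect.sep)
    for col in (dialect.patient_col, dialect.time_col, dialect.steps_col):
        if col not in df.columns:
            raise KeyError(f"steps table is missing mandatory column {col!r}")
    table = StepTable(by_patient={}, n_rows=len(df))
    if df.empty:
        logger.warning("steps table %s contains no data rows", source)
        return table

    ts = pd.to_datetime(df[dialect.time_col], errors="coerce", format="mixed")
    bad_ts = ts.isna()
    table.n_bad_timestamp = int(bad_ts.sum())
    if table.n_bad_timestamp:
        logger.warning("skipped %d rows with unparseable timestamps", table.n_bad_timestamp)

    steps = pd.to_numeric(df[dialect.steps_col], errors="coerce")
    negative = steps < 0
    table.n_rejected_negative = int(negative.sum())
    if table.n_rejected_negative:
        logger.error("rejected %d rows with negative step counts", table.n_rejected_negative)

    keep = ~bad_ts & ~negative & steps.notna()
    for pid, t, s in zip(df.loc[keep, dialect.patient_col], ts[keep], steps[keep]):
        rec = StepRecord(patient_id=str(pid), timestamp=t.to_pydatetime(), steps=int(s))
        table.by_patient.setdefault(rec.patient_id, []).append(rec)
    return table


def build_timeline(records: Iterable[StepRecord], meta: PatientMeta) -> PatientTimeline:
    """Align one patient's records onto the 57-day perioperative grid.

    ``day_index`` is the whole-day difference between the record's local
    calendar date and the surgery date.  Records outside [-14, 42] are
    dropped (counted on the returned timeline).  Minute (or hour) records
    are summed into clock-hour bins; absent days become all-zero days.
    """
    hourly = {d: np.zeros(24, dtype=np.int64) for d in DAY_INDICES}
    observed = dict.fromkeys(DAY_INDICES, 0)
    n_dropped = 0
    for rec in records:
        day_index = (rec.timestamp.date() - meta.surgery_date).days
        if not DAY_MIN <= day_index <= DAY_MAX:
            n_dropped += 1
            continue
        hourly[day_index][rec.timestamp.hour] += rec.steps
        observed[day_index] += 1
    if n_dropped:
        logger.info(
            "patient %s: dropped %d records outside the perioperative window",
            meta.patient_id, n_dropped,
        )
    days = {
        d: StepDay(day_index=d, hourly=hourly[d], minutes_observed=observed[d])
        for d in DAY_INDICES
    }
    return PatientTimeline(meta=meta, days=days, n_dropped=n_dropped)


def stage_days(name: str) -> frozenset[int]:
    """Day-index set of one of the four 2-week stages."""
    try:
        return STAGE_WINDOWS[name]
    except KeyError:
        raise KeyError(
            f"unknown stage {name!r}; valid stages: {', '.join(STAGE_WINDOWS)}"
        ) from None


def read_metadata_table(source: str | Path) -> dict[str, PatientMeta]:
    """Read the patient metadata CSV keyed by patient_id."""
    df = pd.read_csv(source)
    required = {"patient_id", "surgery_date", "age", "gender", "bmi", "asa", "device"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"metadata table is missing columns: {sorted(missing)}")
    metas = {}
    for row in df.itertuples(index=False):
        meta = PatientMeta(
            patient_id=str(row.patient_id),
            surgery_date=pd.Timestamp(row.surgery_date).date(),
            age=float(row.age),
            gender=str(row.gender),
            bmi=float(row.bmi),
            asa=int(row.asa),
            device=str(row.device),
        )
        metas[meta.patient_id] = meta
    return metas


def timelines_to_long(timelines: Iterable[PatientTimeline]) -> pd.DataFrame:
    """Canonical tidy long table: patient_id x day_index x hour x steps."""
    rows = []
    for tl in timelines:
        for d in DAY_INDICES:
            day = tl.days[d]
            for h in range(24):
                rows.append((tl.patient_id, d, h, int(day.hourly[h])))
    return pd.DataFrame(rows, columns=["patient_id", "day_index", "hour", "steps"])
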