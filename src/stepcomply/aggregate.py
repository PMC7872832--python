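"""Cohort-level summaries of the compliance matrix.

All functions consume the long-format matrix produced by
:func:`stepcomply.criteria.evaluate_matrix` (columns ``patient_id``,
``day_index``, ``criterion``, ``valid``).  Compliance values are proportions
of valid days over a fixed denominator — missing days were already
materialized as invalid, so the denominator is always the window size.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .timeline import DAY_INDICES, STAGE_NAMES, stage_days

FULL_WINDOW = frozenset(DAY_INDICES)


def period_compliance(
    matrix: pd.DataFrame,
    patient_id: str,
    criterion: str,
    day_range: Iterable[int] = FULL_WINDOW,
) -> float:
    """Fraction of valid days for one patient and criterion over ``day_range``."""
    day_range = frozenset(day_range)
    if not day_range:
        raise ValueError("day_range must be nonempty")
    sub = matrix[
        (matrix["patient_id"] == patient_id)
        & (matrix["criterion"] == criterion)
        & matrix["day_index"].isin(day_range)
    ]
    return float(sub["valid"].sum()) / len(day_range)


def period_compliance_table(
    matrix: pd.DataFrame, day_range: Iterable[int] = FULL_WINDOW
) -> pd.DataFrame:
    """Tidy table of whole-period compliance: patient_id x criterion x value."""
    day_range = frozenset(day_range)
    if not day_range:
        raise ValueError("day_range must be nonempty")
    sub = matrix[matrix["day_index"].isin(day_range)]
    out = (
        sub.groupby(["patient_id", "criterion"], sort=True)["valid"]
        .sum()
        .div(len(day_range))
        .rename("value")
        .reset_index()
    )
    return out


def stage_compliance(matrix: pd.DataFrame, patient_id: str, criterion: str) -> dict[str, float]:
    """Per-stage compliance for one patient and criterion (day 0 excluded)."""
    return {
        stage: period_compliance(matrix, patient_id, criterion, stage_days(stage))
        for stage in STAGE_NAMES
    }


def stage_compliance_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Tidy table: patient_id x stage x criterion x value; 14-day denominators."""
    frames = []
    for stage in STAGE_NAMES:
        days = stage_days(stage)
        tab = period_compliance_table(matrix, days)
        tab.insert(1, "stage", stage)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def daily_sample_rate(matrix: pd.DataFrame, day_index: int, criterion: str) -> float:
    """Fraction of the cohort valid on one day under one criterion."""
    sub = matrix[(matrix["day_index"] == day_index) & (matrix["criterion"] == criterion)]
    if sub.empty:
        raise ValueError(f"no cells for day {day_index}, criterion {criterion!r}")
    return float(sub["valid"].mean())


def daily_rates_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-day per-criterion sample compliance rates (wide: one column per criterion)."""
    rates = (
        matrix.groupby(["day_index", "criterion"], sort=True)["valid"]
        .mean()
        .unstack("criterion")
    )
    return rates


def across_criteria_stats(rates: Iterable[float], ddof: int = 1) -> tuple[float, float]:
    """Arithmetic mean and standard deviation of per-criterion values.

    ``ddof=1`` (sample SD) by default; set ``ddof=0`` for the population form.
    """
    arr = np.asarray(list(rates), dtype=float)
    return float(arr.mean()), float(arr.std(ddof=ddof))


def deviation_series(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Daily per-criterion rates plus across-criteria mean and SD.

    One row per day index; criterion columns, then ``mean`` and ``sd``.
    """
    rates = daily_rates_table(matrix)
    out = rates.copy()
    out["mean"] = rates.mean(axis=1)
    out["sd"] = rates.std(axis=1, ddof=ddof)
    return out


def baseline_differences(
    period: pd.DataFrame, baseline: str = "gt0_steps"
) -> pd.DataFrame:
    """Per-patient compliance differences relative to the most lenient criterion.

    ``difference = compliance(baseline) - compliance(criterion)``, non-negative
    for every patient under the dominance property.  Rows are ordered by each
    patient's total deviation (ascending), mirroring a smallest-to-greatest
    patient ordering.
    """
    wide = period.pivot(index="patient_id", columns="criterion", values="value")
    if baseline not in wide.columns:
        raise KeyError(f"baseline criterion {baseline!r} missing from period table")
    diffs = wide[baseline].values[:, None] - wide.drop(columns=baseline)
    diffs["total_deviation"] = diffs.sum(axis=1)
    return diffs.sort_values("total_deviation").reset_index()


def per_patient_criteria_sd(period: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Across-criteria SD of each patient's whole-period compliance outcomes."""
    wide = period.pivot(index="patient_id", columns="criterion", values="value")
    out = pd.DataFrame(
        {
            "mean": wide.mean(axis=1),
            "sd": wide.std(axis=1, ddof=ddof),
        }
    )
    return out.reset_index()


def retention_report(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-criterion counts and fractions of retained vs discarded patient-days."""
    grouped = matrix.groupby("criterion", sort=True)["valid"]
    retained = grouped.sum().astype(int)
    total = grouped.count()
    out = pd.DataFrame(
        {
            "retained": retained,
            "discarded": (total - retained).astype(int),
            "retained_fraction": retained / total,
            "discarded_fraction": (total - retained) / total,
        }
    )
    return out.reset_index()
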