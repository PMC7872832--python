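"""Daily valid-day criteria and their evaluation over a cohort.

Five built-in criteria decide whether a patient-day counts as a valid day of
tracker wear:

``gt0_steps``
    at least one step anywhere in the day.
``gt500_steps``
    strictly more than 500 steps in the day.
``ge10_hours``
    at least one step in each of >= 10 distinct clock hours.
``three_a_day``
    at least one step in each of three windows: 03-11h, 11-15h, and 15h-03h
    of the following day (the third window wraps past midnight; it truncates
    at midnight for the final day, or everywhere when ``wrap=False``).
``three_of_four``
    at least one step in >= 3 of the four six-hour windows 00-06h, 06-12h,
    12-18h, 18-24h.

All-zero (gap) days are invalid under every criterion.  The registry accepts
user-defined criteria without altering the built-ins.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd

from .timeline import DAY_INDICES, DAY_MAX, PatientTimeline, StepDay

logger = logging.getLogger(__name__)

CriterionFn = Callable[[StepDay, Optional[np.ndarray]], bool]


def valid_gt0(day: StepDay, next_day_early: np.ndarray | None = None) -> bool:
    """Valid iff the day registered at least one step."""
    return day.total >= 1


def valid_gt500(day: StepDay, next_day_early: np.ndarray | None = None) -> bool:
    """Valid iff the day registered strictly more than 500 steps."""
    return day.total > 500


def valid_ge10_hours(day: StepDay, next_day_early: np.ndarray | None = None) -> bool:
    """Valid iff >= 10 distinct clock hours registered at least one step."""
    return int((day.hourly >= 1).sum()) >= 10


def valid_three_a_day(
    day: StepDay,
    next_day_early: np.ndarray | None = None,
    *,
    wrap: bool = True,
) -> bool:
    """Valid iff all three anchored windows registered at least one step.

    Windows: hours [3, 11), [11, 15), and [15, 24) plus — when ``wrap`` and
    ``next_day_early`` (hours 0-2 of the following day) is supplied — hours
    [0, 3) of the next day.
    """
    morning = day.hourly[3:11].sum() >= 1
    afternoon = day.hourly[11:15].sum() >= 1
    evening = int(day.hourly[15:24].sum())
    if wrap and next_day_early is not None:
        evening += int(np.asarray(next_day_early)[:3].sum())
    return bool(morning and afternoon and evening >= 1)


def valid_three_of_four(day: StepDay, next_day_early: np.ndarray | None = None) -> bool:
    """Valid iff >= 3 of the four six-hour windows registered a step."""
    quarters = day.hourly.reshape(4, 6).sum(axis=1)
    return int((quarters >= 1).sum()) >= 3


BUILTIN_CRITERIA: dict[str, CriterionFn] = {
    "gt0_steps": valid_gt0,
    "gt500_steps": valid_gt500,
    "ge10_hours": valid_ge10_hours,
    "three_a_day": valid_three_a_day,
    "three_of_four": valid_three_of_four,
}
CRITERION_IDS = tuple(BUILTIN_CRITERIA)

_registry: dict[str, CriterionFn] = dict(BUILTIN_CRITERIA)


def register_criterion(name: str, fn: CriterionFn) -> None:
    """Add a user-defined criterion; the five built-ins cannot be replaced."""
    if name in BUILTIN_CRITERIA:
        raise ValueError(f"cannot override built-in criterion {name!r}")
    _registry[name] = fn


def get_criterion(name: str) -> CriterionFn:
    try:
        return _registry[name]
    except KeyError:
        raise KeyError(f"unknown criterion {name!r}") from None


def evaluate_day(
    name: str,
    day: StepDay,
    next_day_early: np.ndarray | None = None,
    *,
    wrap_three_a_day: bool = True,
) -> bool:
    fn = get_criterion(name)
    if name == "three_a_day":
        return valid_three_a_day(day, next_day_early, wrap=wrap_three_a_day)
    return fn(day, next_day_early)


def evaluate_matrix(
    timelines: Iterable[PatientTimeline],
    criteria: Iterable[str] = CRITERION_IDS,
    *,
    wrap_three_a_day: bool = True,
) -> pd.DataFrame:
    """Evaluate every (patient, day, criterion) cell of the compliance matrix.

    Returns a long DataFrame with columns ``patient_id``, ``day_index``,
    ``criterion``, ``valid`` (bool), fully populated for every triple.
    """
    criteria = list(criteria)
    rows: list[tuple[str, int, str, bool]] = []
    n_patients = 0
    for tl in timelines:
        n_patients += 1
        for d in DAY_INDICES:
            day = tl.days[d]
            nxt = tl.days[d + 1].hourly if d < DAY_MAX else None
            for name in criteria:
                rows.append(
                    (tl.patient_id, d, name,
                     evaluate_day(name, day, nxt, wrap_three_a_day=wrap_three_a_day))
                )
    if n_patients == 0:
        logger.warning("evaluate_matrix called on an empty cohort")
    return pd.DataFrame(rows, columns=["patient_id", "day_index", "criterion", "valid"])
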