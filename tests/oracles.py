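"""Independent minute-level brute-force evaluators for the five criteria.

These operate on raw 1440-minute step vectors and never touch the package's
hour-binned implementations, so they serve as an independent oracle for
equivalence testing.
"""

from __future__ import annotations

import numpy as np


def minutes_to_hourly(minutes: np.ndarray) -> np.ndarray:
    assert minutes.shape == (1440,)
    return minutes.reshape(24, 60).sum(axis=1)


def oracle_gt0(minutes: np.ndarray) -> bool:
    return bool((minutes > 0).any())


def oracle_gt500(minutes: np.ndarray) -> bool:
    return int(minutes.sum()) > 500


def oracle_ge10_hours(minutes: np.ndarray) -> bool:
    hours_with_data = 0
    for h in range(24):
        if (minutes[60 * h : 60 * (h + 1)] > 0).any():
            hours_with_data += 1
    return hours_with_data >= 10


def oracle_three_a_day(
    minutes: np.ndarray,
    next_day_minutes: np.ndarray | None = None,
    wrap: bool = True,
) -> bool:
    # windows on the minute axis: 03:00-11:00, 11:00-15:00, 15:00-03:00(+1d)
    morning = (minutes[180:660] > 0).any()
    afternoon = (minutes[660:900] > 0).any()
    evening = (minutes[900:1440] > 0).any()
    if wrap and next_day_minutes is not None:
        evening = evening or (next_day_minutes[0:180] > 0).any()
    return bool(morning and afternoon and evening)


def oracle_three_of_four(minutes: np.ndarray) -> bool:
    hits = 0
    for q in range(4):
        if (minutes[360 * q : 360 * (q + 1)] > 0).any():
            hits += 1
    return hits >= 3


ORACLES = {
    "gt0_steps": lambda m, nxt: oracle_gt0(m),
    "gt500_steps": lambda m, nxt: oracle_gt500(m),
    "ge10_hours": lambda m, nxt: oracle_ge10_hours(m),
    "three_a_day": oracle_three_a_day,
    "three_of_four": lambda m, nxt: oracle_three_of_four(m),
}
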