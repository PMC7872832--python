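"""Figure rendering: activity heatmaps, compliance lines, device panels.

Plots are pure views over aggregation outputs; numeric behaviour is asserted
on the underlying tables, rendering itself is smoke-tested.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .aggregate import deviation_series
from .timeline import DAY_INDICES, DAY_MIN, DAY_MAX, PatientTimeline

logger = logging.getLogger(__name__)

HEATMAP_CLAMP = 500  # steps/hour rendered black at or above this value


def heatmap_grid(timeline: PatientTimeline) -> np.ndarray:
    """24 x 57 array of hourly steps clamped at :data:`HEATMAP_CLAMP`."""
    grid = np.zeros((24, len(DAY_INDICES)))
    for j, d in enumerate(DAY_INDICES):
        grid[:, j] = np.minimum(timeline.days[d].hourly, HEATMAP_CLAMP)
    return grid


def activity_heatmap(
    timeline: PatientTimeline, out: str | Path, dpi: int = 120
) -> Path:
    """Hour-by-day heatmap, white (0) to black (500+), red rule at day 0."""
    grid = heatmap_grid(timeline)
    fig, ax = plt.subplots(figsize=(9, 3.2))
    ax.imshow(
        grid,
        aspect="auto",
        cmap="Greys",
        vmin=0,
        vmax=HEATMAP_CLAMP,
        origin="lower",
        extent=(DAY_MIN - 0.5, DAY_MAX + 0.5, -0.5, 23.5),
    )
    ax.axvline(0, color="red", lw=1.5)
    ax.set_xlabel("Day relative to surgery")
    ax.set_ylabel("Hour of day")
    ax.set_title(f"Activity — {timeline.patient_id} ({timeline.meta.device})")
    out = Path(out)
    fig.savefig(out, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return out


def daily_compliance_plot(
    series: pd.DataFrame,
    out: str | Path,
    overlay_criteria: bool = False,
    dpi: int = 120,
) -> Path:
    """Mean daily compliance with a mean +/- SD band, red rule at day 0.

    ``series`` is the frame from :func:`stepcomply.aggregate.deviation_series`
    (indexed by day_index with criterion columns plus ``mean`` and ``sd``).
    With ``overlay_criteria`` the five per-criterion lines are drawn instead
    of the band.
    """
    fig, ax = plt.subplots(figsize=(9, 4))
    x = series.index.to_numpy()
    if overlay_criteria:
        for col in series.columns:
            if col in ("mean", "sd"):
                continue
            ax.plot(x, series[col], lw=1.2, label=col)
        ax.legend(fontsize=8)
    else:
        lo = np.clip(series["mean"] - series["sd"], 0, 1)
        hi = np.clip(series["mean"] + series["sd"], 0, 1)
        ax.fill_between(x, lo, hi, color="0.8", label="±SD between criteria")
        ax.plot(x, series["mean"], color="0.3", lw=1.6, label="mean of criteria")
        ax.legend(fontsize=8)
    ax.axvline(0, color="red", lw=1.5)
    ax.set_xlim(DAY_MIN, DAY_MAX)
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("Day relative to surgery")
    ax.set_ylabel("Proportion of sample compliant")
    out = Path(out)
    fig.savefig(out, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return out


def device_panels(
    matrices_by_device: dict[str, pd.DataFrame],
    out: str | Path,
    ddof: int = 1,
    dpi: int = 120,
) -> Path:
    """Per-device panels: daily per-criterion rates and between-criteria SD.

    ``matrices_by_device`` maps device name ('clip'/'wrist') to a long-format
    compliance matrix for that group.  Empty groups are skipped with a warning.
    """
    groups = {k: v for k, v in matrices_by_device.items() if v is not None and len(v)}
    for k in matrices_by_device:
        if k not in groups:
            logger.warning("device group %r is empty; panel skipped", k)
    if not groups:
        raise ValueError("no nonempty device groups to plot")
    fig, axes = plt.subplots(
        len(groups), 2, figsize=(10, 3.2 * len(groups)), squeeze=False
    )
    for i, (device, matrix) in enumerate(sorted(groups.items())):
        series = deviation_series(matrix, ddof=ddof)
        x = series.index.to_numpy()
        ax_rates, ax_sd = axes[i]
        for col in series.columns:
            if col in ("mean", "sd"):
                continue
            ax_rates.plot(x, series[col], lw=1.0, label=col)
        ax_rates.axvline(0, color="red", lw=1.2)
        ax_rates.set_ylim(0, 1.02)
        ax_rates.set_xlim(DAY_MIN, DAY_MAX)
        ax_rates.set_title(f"{device}: daily compliance rates", fontsize=9)
        ax_rates.legend(fontsize=6)
        ax_sd.plot(x, series["sd"], color="0.3", lw=1.4)
        ax_sd.axvline(0, color="red", lw=1.2)
        ax_sd.set_xlim(DAY_MIN, DAY_MAX)
        ax_sd.set_title(f"{device}: SD between criteria", fontsize=9)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return out
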