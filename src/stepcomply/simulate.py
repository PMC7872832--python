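"""Synthetic perioperative actigraphy cohorts.

Generates patient timelines with the structure the analysis assumes: diurnal
waking-hour step activity, day-level non-wear gaps, a sharp activity dip on
the surgery day with gradual recovery, and a device-placement effect in which
clip wearers show degraded data quality in the first two postoperative weeks.

Hourly counts are negative-binomial (gamma-Poisson) with a mean-dispersion
parameterization: mean ``mu`` and dispersion ``k`` give variance
``mu + mu**2 / k``; Poisson is the ``k -> inf`` limit.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .timeline import (
    DAY_INDICES,
    DAY_MIN,
    DAY_MAX,
    PatientMeta,
    PatientTimeline,
    StepDay,
)

logger = logging.getLogger(__name__)


def _default_diurnal() -> np.ndarray:
    """Plausible waking-hours activity profile over 24 clock hours."""
    hours = np.arange(24)
    w = np.exp(-0.5 * ((hours - 13.0) / 4.5) ** 2)
    w[:6] = 0.0
    w[23] = 0.0
    return w / w.sum()


@dataclass
class SimConfig:
    """Full parameterization of the synthetic cohort generator."""

    n_patients: int = 20
    seed: int = 0

    # wear behaviour
    wear_prob_pre: float = 0.92
    wear_prob_post_min: float = 0.70  # wear probability at day 0
    wear_recovery_days: int = 21      # days for wear probability to recover
    clip_forget_prob: float = 0.10    # extra daily non-wear probability, clip devices
    wear_start_range: tuple[int, int] = (6, 9)    # inclusive hour range
    wear_end_range: tuple[int, int] = (20, 23)

    # activity intensity
    diurnal_template: np.ndarray = field(default_factory=_default_diurnal)
    base_daily_steps: float = 6000.0
    dispersion: float = 1.2
    patient_activity_sd: float = 0.35  # lognormal sigma of per-patient factor

    # surgery response
    surgery_dip: float = 0.85
    recovery_days: int = 21
    recovery_shape: str = "linear"  # or "exp"
    overshoot: float = 0.0
    postop_hour_shrink: int = 5  # max hours cut from each wear-window end,
                                 # scaled by the unrecovered fraction of the dip

    # clip-specific postoperative degradation (days 1-14)
    clip_postop_window_shrink: int = 0   # hours removed from each end of wear window
    clip_postop_intensity: float = 1.0   # extra multiplier on hourly means

    # demographics
    device_mix: float = 0.6  # fraction wrist
    age_range: tuple[float, float] = (45.0, 80.0)
    bmi_range: tuple[float, float] = (22.0, 38.0)
    female_prob: float = 0.65
    asa_probs: tuple[float, float, float] = (0.05, 0.90, 0.05)  # ASA 1..3
    first_surgery_date: str = "2016-03-15"

    def __post_init__(self) -> None:
        self.diurnal_template = np.asarray(self.diurnal_template, dtype=float)
        if self.diurnal_template.shape != (24,):
            raise ValueError("diurnal_template must have 24 entries")
        if (self.diurnal_template < 0).any():
            raise ValueError("diurnal_template weights must be non-negative")
        total = self.diurnal_template.sum()
        if total <= 0:
            raise ValueError("diurnal_template must have positive mass")
        self.diurnal_template = self.diurnal_template / total
        for name in ("wear_prob_pre", "wear_prob_post_min", "clip_forget_prob",
                     "device_mix", "female_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.surgery_dip <= 1.0:
            raise ValueError("surgery_dip must be in [0, 1]")
        if self.recovery_days < 0:
            raise ValueError("recovery_days must be >= 0")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")


@dataclass
class SimCohort:
    timelines: list[PatientTimeline]
    truth: dict[str, dict]
    config: SimConfig


def surgery_multiplier(
    day_index: int,
    surgery_dip: float,
    recovery_days: int,
    shape: str = "linear",
    overshoot: float = 0.0,
) -> float:
    """Activity multiplier: 1 before surgery, ``1 - dip`` at day 0, then a
    ramp back to ``1 + overshoot`` by ``recovery_days``."""
    if not 0.0 <= surgery_dip <= 1.0:
        raise ValueError("surgery_dip must be in [0, 1]")
    if day_index < 0:
        return 1.0
    top = 1.0 + overshoot
    if recovery_days == 0 or day_index >= recovery_days:
        return top
    frac = day_index / recovery_days
    if shape == "linear":
        return (1.0 - surgery_dip) + (surgery_dip + overshoot) * frac
    if shape == "exp":
        # reaches ~95% of the ramp at recovery_days
        return top - (surgery_dip + overshoot) * np.exp(-3.0 * frac)
    raise ValueError(f"unknown recovery shape {shape!r}")


def wear_probability(cfg: SimConfig, day_index: int, device: str) -> float:
    """Day-specific probability that the tracker is worn at all."""
    if day_index < 0:
        p = cfg.wear_prob_pre
    elif cfg.wear_recovery_days == 0 or day_index >= cfg.wear_recovery_days:
        p = cfg.wear_prob_pre
    else:
        frac = day_index / cfg.wear_recovery_days
        p = cfg.wear_prob_post_min + (cfg.wear_prob_pre - cfg.wear_prob_post_min) * frac
    if device == "clip":
        p -= cfg.clip_forget_prob
    return float(min(max(p, 0.0), 1.0))


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, k: float) -> np.ndarray:
    """Negative-binomial draws with mean ``mu`` and dispersion ``k``."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if pos.any():
        p = k / (k + mu[pos])
        out[pos] = rng.negative_binomial(k, p)
    return out


def _draw_meta(cfg: SimConfig, idx: int, rng: np.random.Generator) -> PatientMeta:
    device = "wrist" if rng.random() < cfg.device_mix else "clip"
    gender = "female" if rng.random() < cfg.female_prob else "male"
    asa = int(rng.choice([1, 2, 3], p=np.asarray(cfg.asa_probs) / sum(cfg.asa_probs)))
    base = datetime.date.fromisoformat(cfg.first_surgery_date)
    return PatientMeta(
        patient_id=f"P{idx + 1:02d}",
        surgery_date=base + datetime.timedelta(days=int(rng.integers(0, 365))),
        age=float(np.round(rng.uniform(*cfg.age_range), 1)),
        gender=gender,
        bmi=float(np.round(rng.uniform(*cfg.bmi_range), 1)),
        asa=asa,
        device=device,
    )


def simulate_patient(
    cfg: SimConfig, meta: PatientMeta, rng: np.random.Generator
) -> tuple[PatientTimeline, dict]:
    """Simulate one patient timeline; returns the timeline and its latent truth."""
    activity_factor = float(rng.lognormal(mean=0.0, sigma=cfg.patient_activity_sd))
    clip_postop = meta.device == "clip" and (
        cfg.clip_postop_window_shrink > 0 or cfg.clip_postop_intensity != 1.0
    )
    days: dict[int, StepDay] = {}
    worn_days = []
    for d in DAY_INDICES:
        p_wear = wear_probability(cfg, d, meta.device)
        worn = rng.random() < p_wear
        if not worn:
            days[d] = StepDay.empty(d)
            continue
        worn_days.append(d)
        start = int(rng.integers(cfg.wear_start_range[0], cfg.wear_start_range[1] + 1))
        end = int(rng.integers(cfg.wear_end_range[0], cfg.wear_end_range[1] + 1))
        mult = surgery_multiplier(
            d, cfg.surgery_dip, cfg.recovery_days, cfg.recovery_shape, cfg.overshoot
        )
        if d >= 0 and mult < 1.0:
            # reduced mobility also compresses activity into fewer hours
            shrink = int(round(cfg.postop_hour_shrink * (1.0 - mult)))
            start = min(start + shrink, 22)
            end = max(end - shrink, start + 1)
        if clip_postop and 1 <= d <= 14:
            shrink = cfg.clip_postop_window_shrink
            start = min(start + shrink, 23)
            end = max(end - shrink, start + 1)
            mult *= cfg.clip_postop_intensity
        mu = cfg.base_daily_steps * activity_factor * cfg.diurnal_template * mult
        mask = np.zeros(24, dtype=bool)
        mask[start:end] = True
        mu = np.where(mask, mu, 0.0)
        hourly = _nb_sample(rng, mu, cfg.dispersion)
        days[d] = StepDay(day_index=d, hourly=hourly,
                          minutes_observed=int(mask.sum()) * 60)
    truth = {
        "activity_factor": activity_factor,
        "device": meta.device,
        "n_worn_days": len(worn_days),
        "worn_days": worn_days,
    }
    return PatientTimeline(meta=meta, days=days), truth


def simulate_cohort(cfg: SimConfig) -> SimCohort:
    """Simulate a full cohort; identical seed and config give identical output."""
    rng = np.random.default_rng(cfg.seed)
    timelines: list[PatientTimeline] = []
    truth: dict[str, dict] = {}
    for i in range(cfg.n_patients):
        meta = _draw_meta(cfg, i, rng)
        tl, t = simulate_patient(cfg, meta, rng)
        timelines.append(tl)
        truth[meta.patient_id] = t
    return SimCohort(timelines=timelines, truth=truth, config=cfg)


def simulate_stage_table(
    n_patients: int,
    seed: int,
    *,
    intercept: float = 0.6,
    criterion_effects: dict[str, float] | None = None,
    stage_effects: dict[str, float] | None = None,
    device_stage_effects: dict[tuple[str, str], float] | None = None,
    subject_sd: float = 0.08,
    noise_sd: float = 0.05,
    device_mix: float = 0.6,
) -> pd.DataFrame:
    """Simulate a stage-level model table directly from a linear-model form.

    response = intercept + criterion effect + stage effect
             + device x stage interaction + patient intercept + noise

    Used for parameter-recovery checks of the mixed-effects fitter; the
    generating effects are the ground truth.  Covariates age/gender/bmi are
    drawn independently of the response.
    """
    from .criteria import CRITERION_IDS  # local import avoids a cycle at load
    from .timeline import STAGE_NAMES

    rng = np.random.default_rng(seed)
    criterion_effects = criterion_effects or {}
    stage_effects = stage_effects or {}
    device_stage_effects = device_stage_effects or {}
    rows = []
    for i in range(n_patients):
        pid = f"S{i + 1:03d}"
        device = "wrist" if rng.random() < device_mix else "clip"
        b_patient = rng.normal(0.0, subject_sd)
        age = float(rng.uniform(45, 80))
        bmi = float(rng.uniform(22, 38))
        gender = "female" if rng.random() < 0.5 else "male"
        for criterion in CRITERION_IDS:
            for stage in STAGE_NAMES:
                y = (
                    intercept
                    + criterion_effects.get(criterion, 0.0)
                    + stage_effects.get(stage, 0.0)
                    + device_stage_effects.get((device, stage), 0.0)
                    + b_patient
                    + rng.normal(0.0, noise_sd)
                )
                rows.append((pid, criterion, stage, y, device, age, gender, bmi))
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "criterion", "stage", "compliance",
            "device", "age", "gender", "bmi",
        ],
    )


# ---------------------------------------------------------------------------
# serialization: write the same tidy tables the ingest module reads

def cohort_to_steps_frame(cohort: SimCohort) -> pd.DataFrame:
    """Hour-resolution step table (patient_id, timestamp, steps), nonzero rows."""
    rows = []
    for tl in cohort.timelines:
        sd = tl.meta.surgery_date
        for d in DAY_INDICES:
            day = tl.days[d]
            date = sd + datetime.timedelta(days=d)
            for h in np.nonzero(day.hourly)[0]:
                ts = datetime.datetime.combine(date, datetime.time(hour=int(h)))
                rows.append((tl.patient_id, ts.isoformat(sep=" "), int(day.hourly[h])))
    return pd.DataFrame(rows, columns=["patient_id", "timestamp", "steps"])


def cohort_to_metadata_frame(cohort: SimCohort) -> pd.DataFrame:
    rows = [
        (
            tl.meta.patient_id,
            tl.meta.surgery_date.isoformat(),
            tl.meta.age,
            tl.meta.gender,
            tl.meta.bmi,
            tl.meta.asa,
            tl.meta.device,
        )
        for tl in cohort.timelines
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "surgery_date", "age", "gender", "bmi", "asa", "device"]
    )


def write_cohort(cohort: SimCohort, outdir: str | Path) -> dict[str, Path]:
    """Write steps.csv, metadata.csv and truth.json under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "steps": outdir / "steps.csv",
        "metadata": outdir / "metadata.csv",
        "truth": outdir / "truth.json",
    }
    cohort_to_steps_frame(cohort).to_csv(paths["steps"], index=False)
    cohort_to_metadata_frame(cohort).to_csv(paths["metadata"], index=False)
    cfg = dataclasses.asdict(cohort.config)
    cfg["diurnal_template"] = [float(x) for x in cfg["diurnal_template"]]
    with open(paths["truth"], "w") as fh:
        json.dump({"config": cfg, "patients": cohort.truth}, fh, indent=1)
    return paths
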