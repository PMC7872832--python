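# stepcomply

Compliance analysis for perioperative activity-tracker data. The package
ingests minute- or hour-resolution step counts, aligns each patient onto a
fixed 57-day perioperative grid (day −14 through day 42, surgery at day 0),
scores every patient-day under five valid-day criteria, and summarizes how
strongly the choice of criterion changes reported compliance — per patient,
per day, and per two-week stage — together with association tests against
device placement and demographics, the standard figures, and a synthetic
cohort simulator that makes the whole pipeline testable end to end.

## The five criteria

| id | a day is valid if … |
|---|---|
| `gt0_steps` | at least one step was registered |
| `gt500_steps` | strictly more than 500 steps were registered |
| `ge10_hours` | at least one step in ≥ 10 distinct clock hours |
| `three_a_day` | ≥ 1 step in each of 03–11 h, 11–15 h, and 15 h–03 h (next day) |
| `three_of_four` | ≥ 1 step in ≥ 3 of the four 6-hour windows of the day |

Days with no data at all are kept in every denominator and scored
non-compliant under all criteria. User-defined criteria can be added via
`stepcomply.register_criterion`.

## CLI

```sh
# generate a synthetic cohort (steps.csv, metadata.csv, truth.json)
stepcomply simulate --n 20 --seed 1 --outdir scratch/sim

# run the compliance pipeline (validity, period/stage compliance,
# daily rates, deviation series, retention, manifest)
stepcomply analyze --steps scratch/sim/steps.csv --meta scratch/sim/metadata.csv \
    --resolution hour --outdir scratch/out

# correlations + mixed model on the analysis outputs
stepcomply stats --analysis-dir scratch/out --meta scratch/sim/metadata.csv

# heatmaps, daily-compliance figures, device panels
stepcomply plot --steps scratch/sim/steps.csv --meta scratch/sim/metadata.csv \
    --resolution hour --outdir scratch/figs
```

Options of note: `--include-day0/--exclude-day0` toggles whether the surgery
day enters whole-period denominators, `--three-a-day-wrap/--three-a-day-truncate`
selects whether the 15 h–03 h window crosses midnight, and `--sd-ddof`
selects sample (1, default) vs population (0) standard deviations.

## Layout

- `stepcomply.timeline` — ingest, day-grid alignment, stage windows
- `stepcomply.criteria` — the five valid-day predicates and the cohort matrix
- `stepcomply.aggregate` — period/stage compliance, daily rates, deviation series, retention
- `stepcomply.stats` — point-biserial/Pearson tests, stage-level mixed model
- `stepcomply.simulate` — synthetic cohorts with configurable surgery dip,
  wear behaviour, and device-placement effects (latent truth retained)
- `stepcomply.viz` — heatmaps, compliance lines, device panels
- `stepcomply.cli` — `simulate` / `analyze` / `stats` / `plot` subcommands
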