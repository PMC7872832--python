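import numpy as np
import pandas as pd
import pytest

from stepcomply import (
    CRITERION_IDS,
    DAY_INDICES,
    across_criteria_stats,
    baseline_differences,
    daily_sample_rate,
    deviation_series,
    evaluate_matrix,
    per_patient_criteria_sd,
    period_compliance,
    period_compliance_table,
    retention_report,
    stage_compliance,
    stage_compliance_table,
    stage_days,
)
from stepcomply.aggregate import daily_rates_table


def make_matrix(valid_map):
    """Matrix for one patient: {criterion: set of valid day indices}."""
    rows = []
    for crit in CRITERION_IDS:
        valid_days = valid_map.get(crit, set())
        for d in DAY_INDICES:
            rows.append(("P01", d, crit, d in valid_days))
    return pd.DataFrame(rows, columns=["patient_id", "day_index", "criterion", "valid"])


class TestPeriodCompliance:
    def test_full_compliance(self):
        m = make_matrix({c: set(DAY_INDICES) for c in CRITERION_IDS})
        assert period_compliance(m, "P01", "gt0_steps") == 1.0

    def test_16_of_57(self):
        m = make_matrix({"gt0_steps": set(range(1, 17))})
        value = period_compliance(m, "P01", "gt0_steps")
        assert value == pytest.approx(16 / 57)

    def test_lenient_vs_strict_gap(self):
        # patient valid every day under gt0 but 16/57 ~ 28% under ge10_hours
        m = make_matrix(
            {"gt0_steps": set(DAY_INDICES), "ge10_hours": set(range(1, 17))}
        )
        assert period_compliance(m, "P01", "gt0_steps") == 1.0
        assert period_compliance(m, "P01", "ge10_hours") == pytest.approx(
            0.28, abs=0.005
        )

    def test_empty_range_errors(self):
        m = make_matrix({})
        with pytest.raises(ValueError, match="nonempty"):
            period_compliance(m, "P01", "gt0_steps", day_range=set())

    def test_table_matches_scalar(self, small_cohort):
        m = evaluate_matrix(small_cohort.timelines)
        tab = period_compliance_table(m)
        row = tab.iloc[10]
        assert row["value"] == pytest.approx(
            period_compliance(m, row["patient_id"], row["criterion"])
        )


class TestStageCompliance:
    def test_all_valid(self):
        m = make_matrix({c: set(DAY_INDICES) for c in CRITERION_IDS})
        stages = stage_compliance(m, "P01", "gt0_steps")
        assert all(v == 1.0 for v in stages.values())

    def test_only_weeks_0_2(self):
        m = make_matrix({"gt0_steps": set(range(1, 15))})
        stages = stage_compliance(m, "P01", "gt0_steps")
        assert stages["weeks_0_2"] == 1.0
        assert stages["presurgery"] == 0.0
        assert stages["weeks_2_4"] == 0.0
        assert stages["weeks_4_6"] == 0.0

    def test_half_of_weeks_4_6(self):
        m = make_matrix({"gt0_steps": set(range(29, 36))})
        stages = stage_compliance(m, "P01", "gt0_steps")
        assert stages["weeks_4_6"] == pytest.approx(0.5)

    def test_day0_never_contributes(self):
        m = make_matrix({"gt0_steps": {0}})
        stages = stage_compliance(m, "P01", "gt0_steps")
        assert all(v == 0.0 for v in stages.values())

    def test_denominator_is_14(self):
        m = make_matrix({"gt0_steps": {1}})
        stages = stage_compliance(m, "P01", "gt0_steps")
        assert stages["weeks_0_2"] == pytest.approx(1 / 14)

    def test_conservation_with_whole_period(self, small_cohort):
        """57-day compliance = weighted stage mean plus day 0's share."""
        m = evaluate_matrix(small_cohort.timelines)
        pid = small_cohort.timelines[0].patient_id
        for crit in CRITERION_IDS:
            whole = period_compliance(m, pid, crit)
            stages = stage_compliance(m, pid, crit)
            day0 = period_compliance(m, pid, crit, {0})
            reconstructed = (14 * sum(stages.values()) + day0) / 57
            assert whole == pytest.approx(reconstructed)


class TestDailyRates:
    def test_half_valid(self):
        rows = []
        for i in range(20):
            rows.append((f"P{i:02d}", 5, "gt0_steps", i < 10))
        m = pd.DataFrame(rows, columns=["patient_id", "day_index", "criterion", "valid"])
        assert daily_sample_rate(m, 5, "gt0_steps") == 0.5

    def test_all_gap(self):
        m = make_matrix({})
        assert daily_sample_rate(m, 3, "gt0_steps") == 0.0

    def test_dominance_every_day(self, small_cohort):
        m = evaluate_matrix(small_cohort.timelines)
        rates = daily_rates_table(m)
        for crit in CRITERION_IDS:
            assert (rates["gt0_steps"] >= rates[crit] - 1e-12).all()


class TestAcrossCriteriaStats:
    def test_identical_rates(self):
        mean, sd = across_criteria_stats([0.8] * 5)
        assert mean == pytest.approx(0.8)
        assert sd == 0.0

    def test_one_hot(self):
        # sample SD of {1,0,0,0,0}: mean .2, var ((.8)^2+4(.2)^2)/4 = .2
        mean, sd = across_criteria_stats([1, 0, 0, 0, 0])
        assert mean == pytest.approx(0.2)
        assert sd == pytest.approx(np.sqrt(0.2))
        assert sd == pytest.approx(0.4472, abs=1e-4)

    def test_population_ddof(self):
        _, sd = across_criteria_stats([1, 0, 0, 0, 0], ddof=0)
        assert sd == pytest.approx(0.4)


class TestDeviationSeries:
    def test_columns_and_mean_identity(self, small_cohort):
        m = evaluate_matrix(small_cohort.timelines)
        series = deviation_series(m)
        assert "mean" in series and "sd" in series
        crit_cols = [c for c in series.columns if c not in ("mean", "sd")]
        np.testing.assert_allclose(series["mean"], series[crit_cols].mean(axis=1))

    def test_sd_zero_iff_equal(self):
        m = make_matrix({c: {5} for c in CRITERION_IDS})
        series = deviation_series(m)
        assert (series["sd"] == 0).all()

    def test_mean_bounded_by_gt0(self, small_cohort):
        m = evaluate_matrix(small_cohort.timelines)
        series = deviation_series(m)
        assert (series["mean"] <= series["gt0_steps"] + 1e-12).all()


class TestBaselineDifferences:
    def test_identical_outcomes_zero_diff(self):
        m = make_matrix({c: set(range(0, 20)) for c in CRITERION_IDS})
        diffs = baseline_differences(period_compliance_table(m))
        crit_cols = [c for c in diffs.columns if c.endswith("_steps") or c in CRITERION_IDS]
        assert (diffs[crit_cols].values == 0).all()

    def test_72_point_gap(self):
        # gt0 = 1.00, ge10_hours = 0.28 -> difference 0.72
        period = pd.DataFrame(
            {
                "patient_id": ["P20"] * 2,
                "criterion": ["gt0_steps", "ge10_hours"],
                "value": [1.00, 0.28],
            }
        )
        diffs = baseline_differences(period)
        assert diffs.loc[0, "ge10_hours"] == pytest.approx(0.72)

    def test_nonnegative_for_all_patients(self, small_cohort):
        m = evaluate_matrix(small_cohort.timelines)
        diffs = baseline_differences(period_compliance_table(m))
        value_cols = [c for c in diffs.columns if c not in ("patient_id", "total_deviation")]
        assert (diffs[value_cols].values >= -1e-12).all()

    def test_missing_baseline_raises(self):
        period = pd.DataFrame(
            {"patient_id": ["P1"], "criterion": ["ge10_hours"], "value": [0.5]}
        )
        with pytest.raises(KeyError, match="baseline"):
            baseline_differences(period)


class TestRetention:
    def test_all_valid(self):
        m = make_matrix({c: set(DAY_INDICES) for c in CRITERION_IDS})
        rep = retention_report(m).set_index("criterion")
        assert (rep["discarded"] == 0).all()
        assert (rep["retained_fraction"] == 1.0).all()

    def test_fractions_sum_to_one(self, small_cohort):
        m = evaluate_matrix(small_cohort.timelines)
        rep = retention_report(m)
        np.testing.assert_allclose(
            rep["retained_fraction"] + rep["discarded_fraction"], 1.0
        )

    def test_gt0_retains_most(self, small_cohort):
        m = evaluate_matrix(small_cohort.timelines)
        rep = retention_report(m).set_index("criterion")
        gt0 = rep.loc["gt0_steps", "retained"]
        assert (rep["retained"] <= gt0).all()

    def test_sparse_day_retention(self, meta):
        import datetime as dt
        from stepcomply import StepRecord, build_timeline

        recs = [
            StepRecord("P01", dt.datetime(2016, 5, 10, h, 0), 1) for h in (4, 12, 20)
        ]
        m = evaluate_matrix([build_timeline(recs, meta)])
        day0 = m[m["day_index"] == 0]
        assert day0["valid"].sum() == 3  # gt0, three_a_day, three_of_four


class TestPerPatientSd:
    def test_values_bounded(self, small_cohort):
        m = evaluate_matrix(small_cohort.timelines)
        tab = per_patient_criteria_sd(period_compliance_table(m))
        assert (tab["sd"] >= 0).all()
        assert (tab["mean"] <= 1.0).all()
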