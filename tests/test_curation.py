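import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hmispipe import curation, io, synthetic
from hmispipe.curation import (AdjustmentPolicy, ExclusionWindow,
                               adjust_for_completeness, apply_exclusions,
                               curate, impute_calendar_median, replay_log)


def make_year(district="D1", service="ANC1", values=None, year=2019,
              expected=20, actual=20):
    values = values if values is not None else [10.0] * 12
    rows = []
    act = actual if isinstance(actual, (list, tuple)) else [actual] * 12
    for m, v in enumerate(values):
        rows.append((district, "R1", "urban", 100_000, year * 100 + m + 1,
                     service, v, expected, act[m]))
    return pd.DataFrame(rows, columns=io.SCHEMA)


class TestAdjust:
    def test_endpoints(self):
        assert adjust_for_completeness(100, 0.8, 0) == 100.0
        assert adjust_for_completeness(100, 0.8, 1) == pytest.approx(125.0)

    def test_default_factor(self):
        assert adjust_for_completeness(100, 0.8, 0.25) == pytest.approx(106.25)

    def test_rejects_zero_completeness(self):
        with pytest.raises(ValueError, match="impute"):
            adjust_for_completeness(100, 0.0, 0.25)

    def test_rejects_bad_k(self):
        with pytest.raises(ValueError):
            adjust_for_completeness(100, 0.8, 1.5)

    @given(count=st.floats(0, 1e6), c=st.floats(0.01, 1.0),
           k=st.floats(0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_never_decreases_and_monotone_in_k(self, count, c, k):
        adj = adjust_for_completeness(count, c, k)
        assert adj >= count - 1e-9
        assert adjust_for_completeness(count, c, min(1.0, k + 0.1)) >= adj - 1e-9

    def test_vectorised(self):
        out = adjust_for_completeness([100, 100], [0.8, 1.0], 0.25)
        assert np.allclose(out, [106.25, 100.0])


class TestImputeCalendarMedian:
    def test_bruteforce_median_oracle(self):
        values = [10, 12, 14, 500, 11, 13, 10, 12, 11, 13, 12, 10]
        flagged = [v == 500 for v in values]
        clean_sorted = sorted(v for v, f in zip(values, flagged) if not f)
        assert len(clean_sorted) == 11
        expected_median = clean_sorted[5]   # independent sort-based oracle
        out, actions, med = impute_calendar_median(values, flagged)
        assert med == expected_median == 12
        assert out[3] == 12
        assert actions[3] == "imputed"

    def test_no_flags_idempotent(self):
        values = [10.0, 12.0, 11.0]
        out, actions, _ = impute_calendar_median(values, [False] * 3)
        assert np.array_equal(out, values)
        assert actions == [None, None, None]

    def test_true_zero_override(self):
        out, actions, _ = impute_calendar_median(
            [10, 0, 12], flagged=[False, True, False],
            true_zero=[False, True, False])
        assert out[1] == 0.0
        assert actions[1] == "kept_zero"

    def test_all_flagged_escalates(self):
        with pytest.raises(LookupError):
            impute_calendar_median([1, 2, 3], [True, True, True])


class TestApplyExclusions:
    def test_window_removes_exact_periods(self):
        df = pd.concat([make_year(year=2019), make_year(year=2020)],
                       ignore_index=True)
        win = ExclusionWindow("country", None, 201904, 201910, "strike")
        kept, log = apply_exclusions(df, [win])
        gone = set(range(201904, 201911))
        assert not set(kept["period"]) & gone
        assert set(log["period"]) == gone
        assert (log["action"] == "excluded").all()
        assert (log["params"] == "strike").all()

    def test_empty_window_list_noop(self):
        df = make_year()
        kept, log = apply_exclusions(df, [])
        pd.testing.assert_frame_equal(kept, df)
        assert len(log) == 0

    def test_overlapping_windows_union_single_entry(self):
        df = make_year(year=2019)
        wins = [ExclusionWindow("country", None, 201903, 201906, "a"),
                ExclusionWindow("country", None, 201905, 201908, "b")]
        kept, log = apply_exclusions(df, wins)
        union = {201903, 201904, 201905, 201906, 201907, 201908}
        assert set(log["period"]) == union
        assert len(log) == len(union)           # one entry per record
        assert set(kept["period"]) == set(df["period"]) - union

    def test_district_scope(self):
        df = pd.concat([make_year("D1"), make_year("D2")], ignore_index=True)
        win = ExclusionWindow("district", "D2", 201901, 201912, "insecure")
        kept, _ = apply_exclusions(df, [win])
        assert set(kept["district_id"]) == {"D1"}

    def test_unmatched_window_warns(self):
        df = make_year(year=2019)
        with pytest.warns(UserWarning, match="matches no records"):
            apply_exclusions(df, [ExclusionWindow("country", None,
                                                  202501, 202512)])


class TestPolicy:
    def test_k_bounds_checked(self):
        with pytest.raises(ValueError):
            AdjustmentPolicy(k_by_service={"ANC1": 1.5})

    def test_service_specific_k(self):
        p = AdjustmentPolicy(k_by_service={"DELIV": 0.5}, default_k=0.25)
        assert p.k_for("DELIV") == 0.5
        assert p.k_for("ANC1") == 0.25


class TestCurate:
    def test_clean_dataset_is_identity(self):
        df = make_year()
        curated, log = curate(df, AdjustmentPolicy())
        assert np.array_equal(curated["adjusted_value"], df["value"])
        assert len(log) == 0

    def test_low_completeness_imputed_not_adjusted(self):
        # month 3 has c = 0.7 -> imputed with calendar median, not scaled
        actual = [20] * 12
        actual[2] = 14
        df = make_year(values=[100.0] * 12, actual=actual)
        curated, log = curate(df, AdjustmentPolicy())
        assert curated["adjusted_value"].iloc[2] == 100.0  # median of clean
        entry = log[log["period"] == 201903]
        assert list(entry["action"]) == ["imputed_low_completeness"]

    def test_moderate_completeness_adjusted(self):
        actual = [20] * 12
        actual[5] = 16   # c = 0.8, above the 0.75 threshold
        df = make_year(values=[100.0] * 12, actual=actual)
        curated, log = curate(df, AdjustmentPolicy(default_k=0.25))
        assert curated["adjusted_value"].iloc[5] == pytest.approx(106.25)
        assert list(log["action"]) == ["adjusted"]

    def test_outlier_imputed(self):
        values = [10, 12, 14, 500, 11, 13, 10, 12, 11, 13, 12, 10]
        df = make_year(values=[float(v) for v in values])
        curated, log = curate(df, AdjustmentPolicy())
        assert curated["adjusted_value"].iloc[3] == 12.0
        assert list(log["action"]) == ["imputed_outlier"]

    def test_missing_imputed(self):
        values = [10.0] * 12
        values[7] = np.nan
        df = make_year(values=values)
        curated, log = curate(df, AdjustmentPolicy())
        assert curated["adjusted_value"].iloc[7] == 10.0
        assert list(log["action"]) == ["imputed_missing"]

    def test_true_zero_override_kept(self):
        values = [10.0] * 12
        values[7] = np.nan
        df = make_year(values=values)
        policy = AdjustmentPolicy(
            true_zero_overrides=frozenset({("D1", 201908, "ANC1")}))
        curated, log = curate(df, policy)
        assert curated["adjusted_value"].iloc[7] == 0.0
        assert list(log["action"]) == ["kept_zero"]

    def test_deterministic(self, messy_records):
        rec, _ = messy_records
        a_cur, a_log = curate(rec)
        b_cur, b_log = curate(rec)
        pd.testing.assert_frame_equal(a_cur, b_cur)
        pd.testing.assert_frame_equal(a_log, b_log)

    def test_never_negative_and_adjustment_never_decreases(self, messy_records):
        rec, _ = messy_records
        curated, log = curate(rec)
        assert (curated["adjusted_value"].dropna() >= 0).all()
        adj = log[log["action"] == "adjusted"]
        assert (adj["replacement"] >= adj["original"] - 1e-9).all()

    def test_log_replay_reconstructs_exactly(self, messy_records):
        rec, _ = messy_records
        curated, log = curate(rec)
        replayed = replay_log(rec, log)
        assert np.allclose(replayed["adjusted_value"].to_numpy(),
                           curated["adjusted_value"].to_numpy(),
                           equal_nan=True, rtol=0, atol=0)

    def test_every_changed_cell_logged_once(self, messy_records):
        rec, _ = messy_records
        curated, log = curate(rec)
        key = ["district_id", "period", "service"]
        assert not log.duplicated(key).any()
        merged = rec.merge(log[key + ["action"]], on=key, how="left")
        changed = ~(
            (merged["value"] == curated["adjusted_value"])
            | (merged["value"].isna() & curated["adjusted_value"].isna()))
        # rows changed but absent from the log would break the audit trail
        assert merged.loc[changed, "action"].notna().all()

    def test_synthetic_identity_with_k_equals_q(self):
        # no flags anywhere: curation reduces to the exact adjustment identity
        cfg = synthetic.ScenarioConfig(
            n_districts=6, start=201901, end=202012, services=("ANC1",),
            completeness_mean=0.9, completeness_concentration=200,
            q_nonreporting=0.25, round_counts=False, seed=5)
        rec, truth = synthetic.simulate(cfg)
        curated, _ = curate(rec, AdjustmentPolicy(default_k=0.25))
        adjusted = curated[curated["adjusted_value"].notna()]
        merged = adjusted.merge(truth, on=["district_id", "period", "service"])
        ok = np.isclose(merged["adjusted_value"], merged["true_count"],
                        atol=1e-6)
        # cells imputed for low completeness are not exact; all others are
        assert ok.mean() > 0.95

    def test_end_to_end_recovery_within_1pct(self):
        cfg = synthetic.ScenarioConfig(
            n_districts=30, start=201801, end=202012, services=("ANC1",),
            completeness_mean=0.85, completeness_concentration=30,
            q_nonreporting=0.25, seed=21)
        rec, truth = synthetic.simulate(cfg)
        curated, _ = curate(rec, AdjustmentPolicy(default_k=0.25))
        for year in (2018, 2019, 2020):
            got = curated.loc[curated["period"] // 100 == year,
                              "adjusted_value"].sum()
            want = truth.loc[truth["period"] // 100 == year,
                             "true_count"].sum()
            assert got == pytest.approx(want, rel=0.01)

    def test_exclusion_window_through_curate(self):
        df = pd.concat([make_year(year=2019), make_year(year=2020)],
                       ignore_index=True)
        policy = AdjustmentPolicy(exclusion_windows=(
            ExclusionWindow("country", None, 201904, 201910, "strike"),))
        curated, log = curate(df, policy)
        assert not ((curated["period"] >= 201904)
                    & (curated["period"] <= 201910)).any()
        assert (log["action"] == "excluded").sum() == 7
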