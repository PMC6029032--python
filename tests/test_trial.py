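"""Trial I/O, time-in-range metrics, sliding median and controller replay."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ttmloop.controller import ControllerConfig
from ttmloop.plant import PlantConfig, generate_trial
from ttmloop.trial import (
    TrialLoadError,
    TrialSeries,
    count_setting_changes,
    evaluate,
    make_series,
    read_trial_csv,
    replay_controller,
    round_half_up,
    sliding_median,
    within_range_fraction,
)

from conftest import REFERENCE_TRIALS, reference_series
from oracles import naive_change_count, naive_outside_seconds, naive_sliding_median


def simple_series(temps, heats=None, speeds=None, **meta):
    n = len(temps)
    return make_series(
        np.arange(n), temps, heats or ["32"] * n, speeds or ["slow"] * n, metadata=meta
    )


def random_series(seed, n=500):
    rng = np.random.default_rng(seed)
    temps = 38.0 + rng.normal(0, 0.6, n)
    heats = rng.choice(["21", "32", "38", "43"], n)
    speeds = rng.choice(["slow", "fast"], n)
    return make_series(np.arange(n), temps, list(heats), list(speeds))


class TestCsvRoundtrip:
    def test_write_read_preserves_series(self, tmp_path):
        series = random_series(0, 50)
        series.metadata.update({"label": "fixture", "target_temp": 38.0})
        path = tmp_path / "trial.csv"
        series.to_csv(path)
        back = read_trial_csv(path)
        assert back.df.equals(series.df)
        assert back.metadata["label"] == "fixture"

    def test_three_row_fixture(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "time_s,temp_c,heat,speed\n0,37.9,32,slow\n1,38.0,32,slow\n2,38.1,38,slow\n"
        )
        series = read_trial_csv(path)
        assert len(series) == 3
        assert list(series.df["heat"]) == ["32", "32", "38"]

    def test_heat_dialects_normalized(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "t,T,H,S\n0,38.0,c38,low\n1,38.0,38,slow\n2,38.0,ambient,high\n"
        )
        series = read_trial_csv(
            path, column_map={"time_s": "t", "temp_c": "T", "heat": "H", "speed": "S"}
        )
        assert list(series.df["heat"]) == ["38", "38", "21"]
        assert list(series.df["speed"]) == ["slow", "slow", "fast"]

    def test_unsorted_rows_are_sorted(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("time_s,temp_c,heat,speed\n2,38.2,32,slow\n0,38.0,32,slow\n1,38.1,32,slow\n")
        assert list(read_trial_csv(path).times) == [0, 1, 2]

    @pytest.mark.parametrize(
        "body",
        [
            "time_s,temp_c,heat,speed\n0,38.0,32,slow\n0,38.1,32,slow\n",  # dup time
            "time_s,temp_c,heat\n0,38.0,32\n",  # missing column
            "time_s,temp_c,heat,speed\n0,warm,32,slow\n",  # bad temp
            "time_s,temp_c,heat,speed\n0,38.0,99,slow\n",  # unknown heat
        ],
    )
    def test_descriptive_load_errors(self, tmp_path, body):
        path = tmp_path / "bad.csv"
        path.write_text(body)
        with pytest.raises(TrialLoadError):
            read_trial_csv(path)


class TestWithinRange:
    def test_reference_trial_percentages(self, a1_series, a2_series):
        """Reconstructed reference counts reproduce the published within-band
        percentages for both automated trials."""
        for series, key in ((a1_series, "A1"), (a2_series, "A2")):
            ref = REFERENCE_TRIALS[key]
            outside, within = within_range_fraction(series, 38.0, 0.5)
            assert outside == ref["outside_half_s"]
            assert within == ref["within_half_pct"]
            outside, within = within_range_fraction(series, 38.0, 1.0)
            assert outside == ref["outside_one_s"]
            assert within == ref["within_one_pct"]

    def test_constant_at_target(self):
        outside, within = within_range_fraction(simple_series([38.0] * 100), 38.0, 0.5)
        assert (outside, within) == (0, 100.00)

    def test_boundary_sample_is_inside(self):
        outside, _ = within_range_fraction(simple_series([38.5, 38.51]), 38.0, 0.5)
        assert outside == 1

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            within_range_fraction(simple_series([]), 38.0, 0.5)

    @settings(derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000), t1=st.floats(0.1, 2.0), t2=st.floats(0.1, 2.0))
    def test_monotone_in_tolerance(self, seed, t1, t2):
        series = random_series(seed, 200)
        lo, hi = sorted((t1, t2))
        assert (
            within_range_fraction(series, 38.0, lo)[1]
            <= within_range_fraction(series, 38.0, hi)[1]
        )


class TestSettingChanges:
    def test_reference_trial_rates(self, a1_series, a2_series):
        for series, key in ((a1_series, "A1"), (a2_series, "A2")):
            ref = REFERENCE_TRIALS[key]
            count, per_hour = count_setting_changes(series)
            assert count == ref["n_changes"]
            assert per_hour == ref["changes_per_hour"]

    def test_constant_and_alternating_extremes(self):
        assert count_setting_changes(simple_series([38.0] * 50))[0] == 0
        n = 60
        alternating = simple_series([38.0] * n, heats=["32", "38"] * (n // 2))
        assert count_setting_changes(alternating)[0] == n - 1

    def test_speed_only_change_counts(self):
        series = simple_series([38.0] * 4, speeds=["slow", "slow", "fast", "fast"])
        assert count_setting_changes(series)[0] == 1


@pytest.mark.parametrize("seed", range(3))
def test_metrics_agree_with_naive_oracle(seed):
    series = random_series(seed)
    for tol in (0.3, 0.5, 1.0):
        outside, _ = within_range_fraction(series, 38.0, tol)
        assert outside == naive_outside_seconds(series.temps, 38.0, tol)
    assert count_setting_changes(series)[0] == naive_change_count(
        series.df["heat"], series.df["speed"]
    )


class TestSlidingMedian:
    def test_constant_input_unchanged(self):
        series = simple_series([38.0] * 300)
        assert np.all(sliding_median(series, 120) == 38.0)

    def test_single_spike_removed(self):
        temps = [38.0] * 300
        temps[150] = 35.0
        assert np.all(sliding_median(simple_series(temps), 120) == 38.0)

    def test_window_of_one_second_is_identity(self):
        series = random_series(5, 100)
        assert np.allclose(sliding_median(series, 1), series.temps)

    def test_gappy_series_matches_naive_oracle(self):
        rng = np.random.default_rng(9)
        times = np.cumsum(rng.integers(1, 5, 80))
        temps = 38.0 + rng.normal(0, 0.5, 80)
        series = make_series(times, temps, ["32"] * 80, ["slow"] * 80)
        assert np.allclose(
            sliding_median(series, 20), naive_sliding_median(times, temps, 20)
        )

    def test_uniform_series_matches_naive_oracle(self):
        series = random_series(11, 200)
        assert np.allclose(
            sliding_median(series, 120),
            naive_sliding_median(series.times, series.temps, 120),
        )


def test_rounding_is_half_up():
    assert round_half_up(0.125) == 0.13
    assert round_half_up(77.725) == 77.73
    assert round_half_up(4.8149) == 4.81


class TestEvaluate:
    def test_report_invariants(self):
        series = random_series(2)
        report = evaluate(series, 38.0)
        assert report.within_percent[1.0] >= report.within_percent[0.5]
        for tol, outside in report.outside_seconds.items():
            expected = round_half_up(100.0 * (1 - outside / report.total_seconds))
            assert report.within_percent[tol] == expected

    def test_settling_exclusion(self):
        temps = [35.0] * 100 + [38.0] * 100
        report = evaluate(simple_series(temps), 38.0, settling_s=100)
        assert report.total_seconds == 100
        assert report.within_percent[0.5] == 100.00

    def test_filtered_scoring_absorbs_short_artifact(self):
        temps = [38.0] * 400
        temps[200:210] = [35.5] * 10
        series = simple_series(temps)
        raw = evaluate(series, 38.0)
        filtered = evaluate(series, 38.0, filtered=True)
        assert raw.within_percent[1.0] < 100.00
        assert filtered.within_percent[1.0] == 100.00


class TestReplay:
    def test_self_consistency_on_synthetic_closed_loop(self):
        """Replaying a trial generated by this package with the same config
        regenerates the recorded settings at every second."""
        config = ControllerConfig()
        series = generate_trial(PlantConfig(), config, 2 * 3600, seed=4)
        result = replay_controller(series, config)
        assert result.agreement_percent == 100.00
        assert result.n_changes_predicted == result.n_changes_recorded

    def test_different_gain_diverges(self):
        config = ControllerConfig()
        series = generate_trial(PlantConfig(), config, 2 * 3600, seed=4)
        result = replay_controller(series, ControllerConfig(scaling_factor=0.1))
        assert result.agreement_percent < 100.00

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            replay_controller(simple_series([]), ControllerConfig())
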