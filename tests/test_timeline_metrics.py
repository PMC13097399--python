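"""Minute normalization, sliding-window maxima, daily steps/active time."""

from datetime import date, timedelta, timezone

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from periwalk.timeline_metrics import (
    compute_daily_metrics,
    daily_active_time,
    daily_steps,
    normalize_to_minutes,
    sliding_window_max,
)

from conftest import distance_record, step_record

DAY = date(2024, 5, 1)


def brute_force_window_max(bins: np.ndarray, w: int) -> float:
    return max(float(bins[i : i + w].sum()) for i in range(len(bins) - w + 1))


class TestNormalizeToMinutes:
    def test_uniform_apportionment_over_two_minutes(self):
        rec = distance_record("2024-05-01", "10:00:00", "10:02:00", 120.0)
        tl = normalize_to_minutes([rec], DAY)
        assert tl.n_bins == 1440
        assert tl.bin_distance_m[600] == pytest.approx(60.0)
        assert tl.bin_distance_m[601] == pytest.approx(60.0)
        assert tl.total_m == pytest.approx(120.0)
        assert np.count_nonzero(tl.bin_distance_m) == 2

    def test_partial_minute_overlap(self):
        # 90 s spanning 10:00:30-10:02:00: thirds of the distance per rule
        rec = distance_record("2024-05-01", "10:00:30", "10:02:00", 90.0)
        tl = normalize_to_minutes([rec], DAY)
        assert tl.bin_distance_m[600] == pytest.approx(30.0)
        assert tl.bin_distance_m[601] == pytest.approx(60.0)

    def test_zero_duration_credits_start_bin(self):
        rec = distance_record("2024-05-01", "10:00:30", "10:00:30", 30.0)
        tl = normalize_to_minutes([rec], DAY)
        assert tl.bin_distance_m[600] == pytest.approx(30.0)
        assert tl.total_m == pytest.approx(30.0)

    def test_midnight_crossing_split_conserves_per_date(self):
        from conftest import ts
        from periwalk.health_export_io import ActivityRecord, RecordKind

        crossing = ActivityRecord(
            "P001",
            RecordKind.distance_walking_running,
            ts("2024-05-01", "23:59:00"),
            ts("2024-05-02", "00:01:00"),
            100.0,
            "Phone",
        )
        day1 = normalize_to_minutes([crossing], DAY)
        day2 = normalize_to_minutes([crossing], DAY + timedelta(days=1))
        assert day1.bin_distance_m[1439] == pytest.approx(50.0)
        assert day2.bin_distance_m[0] == pytest.approx(50.0)
        assert day1.total_m + day2.total_m == pytest.approx(100.0)

    def test_no_records_gives_all_zero_timeline(self):
        tl = normalize_to_minutes([], DAY)
        assert tl.n_bins == 1440
        assert tl.total_m == 0.0

    def test_contributions_from_multiple_records_sum(self):
        recs = [
            distance_record("2024-05-01", "10:00:00", "10:01:00", 40.0),
            distance_record("2024-05-01", "10:00:00", "10:01:00", 20.0),
        ]
        tl = normalize_to_minutes(recs, DAY)
        assert tl.bin_distance_m[600] == pytest.approx(60.0)

    def test_dst_fall_back_day_has_1500_bins(self):
        # offset flips +0200 -> +0100 within the civil day: a 25-hour day
        tz_summer, tz_winter = timezone(timedelta(hours=2)), timezone(timedelta(hours=1))
        early = distance_record("2024-10-27", "01:00:00", "01:10:00", 100.0, tz=tz_summer)
        late = distance_record("2024-10-27", "22:00:00", "22:10:00", 50.0, tz=tz_winter)
        tl = normalize_to_minutes([early, late], date(2024, 10, 27))
        assert tl.n_bins == 1500
        assert tl.total_m == pytest.approx(150.0)

    @settings(max_examples=200, deadline=None)
    @given(data=st.data())
    def test_conservation_on_random_records(self, data):
        n = data.draw(st.integers(1, 8))
        recs = []
        expected = 0.0
        for _ in range(n):
            start_min = data.draw(st.integers(0, 1438))
            dur = data.draw(st.integers(1, 1439 - start_min))
            meters = data.draw(st.floats(0.1, 5000))
            recs.append(
                distance_record(
                    "2024-05-01",
                    f"{start_min // 60:02d}:{start_min % 60:02d}:00",
                    f"{(start_min + dur) // 60:02d}:{(start_min + dur) % 60:02d}:00",
                    meters,
                )
            )
            expected += meters
        tl = normalize_to_minutes(recs, DAY)
        assert tl.total_m == pytest.approx(expected, rel=1e-9)


class TestSlidingWindowMax:
    def test_all_zero_timeline(self):
        assert sliding_window_max(np.zeros(1440), 6) == 0.0

    def test_isolated_spike(self):
        bins = np.zeros(1440)
        bins[700] = 100.0
        assert sliding_window_max(bins, 1) == 100.0
        assert sliding_window_max(bins, 6) == 100.0

    def test_window_longer_than_day_errors(self):
        with pytest.raises(ValueError, match="exceeds day length"):
            sliding_window_max(np.zeros(10), 11)
        with pytest.raises(ValueError, match="positive"):
            sliding_window_max(np.zeros(10), 0)

    def test_matches_brute_force_on_random_timelines(self):
        rng = np.random.default_rng(20240501)
        for _ in range(1000):
            n = int(rng.integers(6, 120))
            # dyadic grid keeps all partial sums exact in float64
            bins = np.round(rng.gamma(0.3, 50.0, size=n) * 64.0) / 64.0
            bins *= rng.random(n) < 0.3
            for w in (1, 6):
                assert sliding_window_max(bins, w) == brute_force_window_max(bins, w)

    def test_monotone_in_window_size(self):
        rng = np.random.default_rng(7)
        bins = rng.exponential(20.0, size=200)
        maxima = [sliding_window_max(bins, w) for w in range(1, 30)]
        assert all(a <= b for a, b in zip(maxima, maxima[1:]))

    def test_shift_invariance_by_whole_minutes(self):
        recs = [distance_record("2024-05-01", "10:00:00", "10:07:30", 300.0)]
        shifted = [distance_record("2024-05-01", "14:23:00", "14:30:30", 300.0)]
        for w in (1, 6):
            assert sliding_window_max(normalize_to_minutes(recs, DAY), w) == pytest.approx(
                sliding_window_max(normalize_to_minutes(shifted, DAY), w)
            )


class TestDailySteps:
    def test_no_records(self):
        assert daily_steps([], DAY) == 0

    def test_additivity_within_day(self):
        recs = [
            step_record("2024-05-01", "08:00:00", "08:10:00", 1200),
            step_record("2024-05-01", "18:00:00", "18:10:00", 800),
        ]
        assert daily_steps(recs, DAY) == 2000

    def test_midnight_spanning_record_split_proportionally(self):
        from conftest import ts
        from periwalk.health_export_io import ActivityRecord, RecordKind

        rec = ActivityRecord(
            "P001", RecordKind.step_count,
            ts("2024-05-01", "23:30:00"), ts("2024-05-02", "00:30:00"), 100.0, "Phone",
        )
        assert daily_steps([rec], DAY) == 50
        assert daily_steps([rec], DAY + timedelta(days=1)) == 50
        # start-date assignment alternative
        assert daily_steps([rec], DAY, split_by_overlap=False) == 100
        assert daily_steps([rec], DAY + timedelta(days=1), split_by_overlap=False) == 0

    def test_day_total_rounded_half_up(self):
        from conftest import ts
        from periwalk.health_export_io import ActivityRecord, RecordKind

        rec = ActivityRecord(
            "P001", RecordKind.step_count,
            ts("2024-05-01", "23:00:00"), ts("2024-05-02", "01:00:00"), 101.0, "Phone",
        )
        assert daily_steps([rec], DAY) == 51  # 50.5 rounds half-up


class TestDailyActiveTime:
    def test_no_records(self):
        assert daily_active_time([], DAY) == 0.0

    def test_single_span(self):
        rec = distance_record("2024-05-01", "10:00:00", "12:24:00", 1000.0)
        assert daily_active_time([rec], DAY) == pytest.approx(2.4)

    def test_overlapping_spans_counted_once(self):
        recs = [
            distance_record("2024-05-01", "10:00:00", "10:30:00", 100.0),
            distance_record("2024-05-01", "10:15:00", "10:45:00", 100.0),
        ]
        assert daily_active_time(recs, DAY) == pytest.approx(0.75)


class TestComputeDailyMetrics:
    def test_no_imputation_on_empty_days(self):
        recs = [distance_record("2024-05-02", "10:00:00", "10:06:00", 420.0)]
        rows = compute_daily_metrics(recs, DAY, DAY + timedelta(days=3))
        assert len(rows) == 3
        assert not rows[0].has_any_record and rows[0].max_6min_m == 0.0
        assert rows[1].has_any_record
        assert not rows[2].has_any_record and rows[2].steps == 0

    def test_constant_speed_six_minute_bout(self):
        recs = [distance_record("2024-05-01", "10:00:00", "10:06:00", 420.0)]
        (row,) = compute_daily_metrics(recs, DAY, DAY + timedelta(days=1))
        assert row.max_6min_m == pytest.approx(420.0)
        assert row.max_1min_m == pytest.approx(70.0)

    def test_empty_window(self):
        assert compute_daily_metrics([], DAY, DAY) == []

    def test_window_nesting_bound_on_random_days(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            recs = []
            for _ in range(int(rng.integers(0, 6))):
                start = int(rng.integers(0, 1380))
                dur = int(rng.integers(1, 59))
                recs.append(
                    distance_record(
                        "2024-05-01",
                        f"{start // 60:02d}:{start % 60:02d}:00",
                        f"{(start + dur) // 60:02d}:{(start + dur) % 60:02d}:00",
                        float(rng.gamma(2.0, 200.0)),
                    )
                )
            (row,) = compute_daily_metrics(recs, DAY, DAY + timedelta(days=1))
            assert row.max_6min_m >= row.max_1min_m >= row.max_6min_m / 6 - 1e-9
            assert 0.0 <= row.active_time_h <= 24.0
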