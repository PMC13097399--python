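"""Per-minute normalization of distance records and daily walk-test metrics.

The central idea: irregular time-stamped walking/running distance records
are spread uniformly over their own time span and credited to the minute
bins of the civil (phone-local) day in proportion to temporal overlap.
The resulting per-minute distance vector is the "normalized" timeline from
which the daily simulated walk tests are read off: the maximum distance
covered in any contiguous 1-minute and 6-minute window of the day.

Day boundaries are civil: a standard day has 1440 minute bins, and days on
which the recorded UTC offset changes (daylight-saving transitions) get
1380 or 1500 bins.  Windows never cross midnight — each day is scored
independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .health_export_io import ActivityRecord, RecordKind

__all__ = [
    "MinuteTimeline",
    "DailyMetrics",
    "normalize_to_minutes",
    "sliding_window_max",
    "daily_steps",
    "daily_active_time",
    "compute_daily_metrics",
    "daily_metrics_frame",
]

_UTC = timezone.utc


@dataclass(frozen=True)
class MinuteTimeline:
    """One civil day's per-minute walking distance vector.

    ``day_start``/``day_end`` are the absolute instants bounding the civil
    day; ``bin_distance_m[i]`` is the distance apportioned to the minute
    starting ``day_start + i minutes``.
    """

    patient_id: str
    date: date
    day_start: datetime
    day_end: datetime
    bin_distance_m: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.bin_distance_m.shape[0]

    @property
    def total_m(self) -> float:
        return float(self.bin_distance_m.sum())


@dataclass(frozen=True)
class DailyMetrics:
    """Derived outcomes for one patient-day."""

    patient_id: str
    date: date
    max_1min_m: float
    max_6min_m: float
    steps: int
    active_time_h: float
    has_any_record: bool


def _epoch(dt: datetime) -> float:
    return dt.timestamp()


def _day_bounds(
    day: date,
    records: Sequence[ActivityRecord],
    default_offset: timedelta = timedelta(0),
) -> tuple[datetime, datetime]:
    """Absolute instants of this civil day's local midnights.

    The UTC offset in effect at the start (end) of the day is inferred from
    the earliest (latest) record touching the day; a day with no records
    uses ``default_offset``.  A day over which the inferred offset changes
    (daylight-saving transition) is 23 or 25 hours long.
    """
    start_off = end_off = default_offset
    touching = [r for r in records if r.local_start_date() <= day <= r.local_end_date()]
    if touching:
        touching.sort(key=lambda r: r.start)
        start_off = touching[0].start.utcoffset() or default_offset
        end_off = touching[-1].end.utcoffset() or default_offset
    midnight = datetime(day.year, day.month, day.day)
    next_midnight = midnight + timedelta(days=1)
    day_start = midnight.replace(tzinfo=timezone(start_off))
    day_end = next_midnight.replace(tzinfo=timezone(end_off))
    return day_start, day_end


def normalize_to_minutes(
    records: Iterable[ActivityRecord],
    day: date,
    patient_id: str = "",
    default_offset: timedelta = timedelta(0),
) -> MinuteTimeline:
    """Apportion distance records onto the minute bins of one civil day.

    Each record's distance is spread uniformly over its ``[start, end)``
    span (constant speed within a record) and credited to each minute bin
    in proportion to overlap.  Records crossing midnight contribute only
    their overlap with this date; a zero-duration record credits its full
    value to the bin containing its start instant.  Contributions from
    multiple records sum per bin.  A day with no records yields an all-zero
    timeline.
    """
    recs = [r for r in records if r.record_kind is RecordKind.distance_walking_running]
    day_start, day_end = _day_bounds(day, recs, default_offset)
    d0, d1 = _epoch(day_start), _epoch(day_end)
    n_bins = round((d1 - d0) / 60.0)
    bins = np.zeros(n_bins)

    for rec in recs:
        s, e = _epoch(rec.start), _epoch(rec.end)
        if rec.value == 0:
            continue
        if e <= s:  # zero-duration: whole value to the start's bin
            if d0 <= s < d1:
                bins[min(int((s - d0) // 60), n_bins - 1)] += rec.value
            continue
        os_, oe = max(s, d0), min(e, d1)
        if oe <= os_:
            continue
        first = int((os_ - d0) // 60)
        last = int(math.ceil((oe - d0) / 60.0))
        edges = d0 + 60.0 * np.arange(first, last + 1)
        lo = np.maximum(edges[:-1], os_)
        hi = np.minimum(edges[1:], oe)
        overlap = np.clip(hi - lo, 0.0, None)
        bins[first:last] += rec.value * overlap / (e - s)

    return MinuteTimeline(
        patient_id=patient_id or (recs[0].patient_id if recs else ""),
        date=day,
        day_start=day_start,
        day_end=day_end,
        bin_distance_m=bins,
    )


def sliding_window_max(timeline: MinuteTimeline | np.ndarray, window_minutes: int) -> float:
    """Maximum summed distance over any contiguous minute-aligned window.

    O(n) via prefix sums.  Windows never cross midnight: only the
    ``n - w + 1`` windows fully inside the day are considered.
    """
    bins = timeline.bin_distance_m if isinstance(timeline, MinuteTimeline) else np.asarray(timeline)
    n = bins.shape[0]
    if window_minutes < 1:
        raise ValueError(f"window must be a positive number of minutes, got {window_minutes}")
    if window_minutes > n:
        raise ValueError(f"window of {window_minutes} min exceeds day length of {n} bins")
    csum = np.concatenate(([0.0], np.cumsum(bins)))
    return float(np.max(csum[window_minutes:] - csum[:-window_minutes]))


def daily_steps(
    records: Iterable[ActivityRecord],
    day: date,
    default_offset: timedelta = timedelta(0),
    split_by_overlap: bool = True,
) -> int:
    """Total step count assigned to one civil day.

    A record spanning midnight is split across dates in proportion to
    temporal overlap (or assigned wholly to its start date when
    ``split_by_overlap`` is false); the day total is rounded half-up.
    """
    recs = [r for r in records if r.record_kind is RecordKind.step_count]
    if not recs:
        return 0
    if not split_by_overlap:
        total = sum(r.value for r in recs if r.local_start_date() == day)
        return int(math.floor(total + 0.5))
    day_start, day_end = _day_bounds(day, recs, default_offset)
    d0, d1 = _epoch(day_start), _epoch(day_end)
    total = 0.0
    for rec in recs:
        s, e = _epoch(rec.start), _epoch(rec.end)
        if e <= s:
            if d0 <= s < d1:
                total += rec.value
            continue
        overlap = min(e, d1) - max(s, d0)
        if overlap > 0:
            total += rec.value * overlap / (e - s)
    return int(math.floor(total + 0.5))


def daily_active_time(
    records: Iterable[ActivityRecord],
    day: date,
    default_offset: timedelta = timedelta(0),
) -> float:
    """Hours of recorded walking/running activity in one civil day.

    Record spans are merged into their union (overlaps counted once) and
    clipped to the day, so the result is provably ≤ 24 h (25 on a
    daylight-saving fall-back day).
    """
    recs = [r for r in records if r.record_kind is RecordKind.distance_walking_running]
    if not recs:
        return 0.0
    day_start, day_end = _day_bounds(day, recs, default_offset)
    d0, d1 = _epoch(day_start), _epoch(day_end)
    spans = []
    for rec in recs:
        s = max(_epoch(rec.start), d0)
        e = min(_epoch(rec.end), d1)
        if e > s:
            spans.append((s, e))
    if not spans:
        return 0.0
    spans.sort()
    merged_total = 0.0
    cur_s, cur_e = spans[0]
    for s, e in spans[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            merged_total += cur_e - cur_s
            cur_s, cur_e = s, e
    merged_total += cur_e - cur_s
    return merged_total / 3600.0


def compute_daily_metrics(
    records: Sequence[ActivityRecord],
    start: date,
    end: date,
    patient_id: str = "",
    default_offset: timedelta = timedelta(0),
    windows: tuple[int, int] = (1, 6),
) -> list[DailyMetrics]:
    """One :class:`DailyMetrics` row per calendar date in ``[start, end)``.

    Days with no records stay in the output as all-zero rows — zero or
    very low recorded activity is neither excluded nor imputed.
    """
    if end <= start:
        return []
    if not patient_id and records:
        patient_id = records[0].patient_id

    # index records by the civil dates they touch
    by_date: dict[date, list[ActivityRecord]] = {}
    for rec in records:
        d = rec.local_start_date()
        stop = rec.local_end_date()
        while d <= stop:
            by_date.setdefault(d, []).append(rec)
            d += timedelta(days=1)

    w_short, w_long = min(windows), max(windows)
    out: list[DailyMetrics] = []
    day = start
    while day < end:
        todays = by_date.get(day, [])
        timeline = normalize_to_minutes(todays, day, patient_id, default_offset)
        out.append(
            DailyMetrics(
                patient_id=patient_id,
                date=day,
                max_1min_m=sliding_window_max(timeline, w_short),
                max_6min_m=sliding_window_max(timeline, w_long),
                steps=daily_steps(todays, day, default_offset),
                active_time_h=daily_active_time(todays, day, default_offset),
                has_any_record=bool(todays),
            )
        )
        day += timedelta(days=1)
    return out


def daily_metrics_frame(metrics: Iterable[DailyMetrics]) -> pd.DataFrame:
    """Tidy per-patient-day table of the derived outcomes."""
    rows = [
        {
            "patient_id": m.patient_id,
            "date": m.date.isoformat(),
            "max_1min_m": m.max_1min_m,
            "max_6min_m": m.max_6min_m,
            "steps": m.steps,
            "active_time_h": m.active_time_h,
            "has_any_record": m.has_any_record,
        }
        for m in metrics
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "date",
            "max_1min_m",
            "max_6min_m",
            "steps",
            "active_time_h",
            "has_any_record",
        ],
    )
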