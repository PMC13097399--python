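"""Perioperative interval assignment and per-patient interval summaries.

Patient-days are mapped to four prespecified intervals relative to the
surgery date (day offsets, half-open):

* ``baseline``      — [-183, -14): the six preoperative months, excluding
  the final two weeks so that the intervals partition the observation span;
* ``preop_last2w``  — [-14, 0): the final two preoperative weeks;
* ``early_post``    — [0, 14): surgery day through the end of week 2;
* ``late_post``     — [14, 42): postoperative weeks 2–6.

Within each patient × interval × metric cell the daily values (zeros
included) are reduced to mean, median, sample SD and the coefficient of
variation CV% = 100 · SD_daily / mean_daily, the day-to-day stability
measure.  CV is undefined (and flagged) when the mean is zero or fewer
than two days are observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IntervalSpec",
    "IntervalSummary",
    "INTERVAL_ORDER",
    "METRICS",
    "assign_interval",
    "summarize_interval",
    "build_interval_summaries",
    "interval_summary_frame",
]

INTERVAL_ORDER = ("baseline", "preop_last2w", "early_post", "late_post")
METRICS = ("max_1min_m", "max_6min_m", "steps", "active_time_h")


@dataclass(frozen=True)
class IntervalSpec:
    """Named half-open day-offset ranges relative to the surgery date."""

    ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "baseline": (-183, -14),
            "preop_last2w": (-14, 0),
            "early_post": (0, 14),
            "late_post": (14, 42),
        }
    )

    def __post_init__(self) -> None:
        spans = sorted(self.ranges.values())
        for (lo_a, hi_a), (lo_b, _) in zip(spans, spans[1:]):
            if lo_b < hi_a:
                raise ValueError("interval ranges must be pairwise disjoint")

    @classmethod
    def with_full_baseline(cls) -> "IntervalSpec":
        """Sensitivity variant: baseline spans the whole [-183, 0) window.

        The baseline then overlaps the final two preoperative weeks, so the
        spec is no longer a partition; :meth:`assign` resolves the overlap
        in favor of ``preop_last2w``.
        """
        spec = cls.__new__(cls)
        object.__setattr__(
            spec,
            "ranges",
            {
                "baseline": (-183, 0),
                "preop_last2w": (-14, 0),
                "early_post": (0, 14),
                "late_post": (14, 42),
            },
        )
        return spec

    @property
    def coverage(self) -> tuple[int, int]:
        los, his = zip(*self.ranges.values())
        return min(los), max(his)

    def assign(self, offset_days: int) -> str | None:
        hits = [name for name, (lo, hi) in self.ranges.items() if lo <= offset_days < hi]
        if not hits:
            return None
        if len(hits) == 1:
            return hits[0]
        # overlapping variant: the narrower range wins
        return min(hits, key=lambda n: self.ranges[n][1] - self.ranges[n][0])


@dataclass(frozen=True)
class IntervalSummary:
    """Aggregate of one patient's daily metric values within one interval."""

    patient_id: str
    interval: str
    metric: str
    n_days: int
    mean_daily: float | None
    median_daily: float | None
    sd_daily: float | None
    cv_percent: float | None

    @property
    def cv_defined(self) -> bool:
        return self.cv_percent is not None


def assign_interval(day: date, surgery_date: date, spec: IntervalSpec | None = None) -> str | None:
    """Interval containing ``day - surgery_date`` in whole days, or None."""
    spec = spec or IntervalSpec()
    return spec.assign((day - surgery_date).days)


def summarize_interval(
    values: Sequence[float] | np.ndarray,
    interval: str,
    patient_id: str,
    metric: str = "",
) -> IntervalSummary:
    """Mean, median, sample SD (n−1) and CV% of one patient-interval series."""
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    if n == 0:
        return IntervalSummary(patient_id, interval, metric, 0, None, None, None, None)
    mean = float(v.mean())
    median = float(np.median(v))
    sd = float(v.std(ddof=1)) if n >= 2 else None
    cv = 100.0 * sd / mean if (sd is not None and mean > 0) else None
    return IntervalSummary(patient_id, interval, metric, n, mean, median, sd, cv)


def build_interval_summaries(
    daily: pd.DataFrame,
    surgery_dates: dict[str, date],
    spec: IntervalSpec | None = None,
    metrics: Iterable[str] = METRICS,
) -> list[IntervalSummary]:
    """Interval summaries for every patient × interval × metric cell.

    ``daily`` is the tidy per-patient-day table from
    :func:`periwalk.timeline_metrics.daily_metrics_frame`; days outside all
    intervals are dropped, zero-activity days within an interval are kept.
    """
    spec = spec or IntervalSpec()
    daily = daily.copy()
    dates = pd.to_datetime(daily["date"]).dt.date
    offsets = [
        (d - surgery_dates[pid]).days for d, pid in zip(dates, daily["patient_id"])
    ]
    daily["interval"] = [spec.assign(o) for o in offsets]
    out: list[IntervalSummary] = []
    for pid, sub in daily.groupby("patient_id", sort=True):
        for interval in INTERVAL_ORDER:
            cell = sub[sub["interval"] == interval]
            for metric in metrics:
                out.append(
                    summarize_interval(
                        cell[metric].to_numpy(dtype=float), interval, str(pid), metric
                    )
                )
    return out


def interval_summary_frame(summaries: Iterable[IntervalSummary]) -> pd.DataFrame:
    """Tidy interval-summary table."""
    rows = [
        {
            "patient_id": s.patient_id,
            "interval": s.interval,
            "metric": s.metric,
            "n_days": s.n_days,
            "mean": s.mean_daily,
            "median": s.median_daily,
            "sd": s.sd_daily,
            "cv_percent": s.cv_percent,
            "cv_defined": s.cv_defined,
        }
        for s in summaries
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "interval",
            "metric",
            "n_days",
            "mean",
            "median",
            "sd",
            "cv_percent",
            "cv_defined",
        ],
    )
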