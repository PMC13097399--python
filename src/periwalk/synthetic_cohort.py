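"""Synthetic perioperative cohort generator with analytic ground truth.

Emulates the free-living record structure the pipeline assumes: each
patient-day contains a random number of walking bouts; each bout has a
start time, a duration and a constant gait speed, and is recorded as one
distance record plus one step-count record (steps = cadence × distance).
Because bouts never overlap and speed is constant within a bout, the daily
maximum 1-min and 6-min distances, step totals and active time follow in
closed form from the bout list by the same minute-apportionment convention
the pipeline uses — so the whole parse → normalize → window-max pipeline
must reproduce the generator's ground truth exactly.

Activity follows four phases around a per-patient surgery date: a stable
baseline, a preoperative decline over the final two weeks, an early
postoperative dip (weeks 0–2), and late recovery (weeks 2–6).  Phone
carriage is intermittent: each bout is recorded only with probability
``carry_probability``, so days with zero recorded activity arise naturally
and are kept (never excluded or imputed).

Default phase parameters are tuned so that synthetic cohort medians land
near a plausible perioperative trajectory for lumbar-surgery patients
(daily maximum 1-min distance roughly 98 → 82 → 82 → 105 m across the four
phases); they are generator defaults, not test assertions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .health_export_io import (
    ActivityRecord,
    CohortManifest,
    RecordKind,
    write_health_export,
    write_manifest,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseParameters",
    "GroundTruthRow",
    "DEFAULT_PHASES",
    "STABLE_SPEED_PHASES",
    "PHASE_ORDER",
    "phase_of_offset",
    "simulate_patient_day",
    "generate_cohort",
    "simulate_interval_cohort",
]

PHASE_ORDER = ("baseline", "preop_decline", "early_post", "late_post")

#: Day-offset ranges of the four activity phases (half-open, vs surgery).
PHASE_RANGES = {
    "baseline": (-183, -14),
    "preop_decline": (-14, 0),
    "early_post": (0, 14),
    "late_post": (14, 42),
}

#: Fixed UTC offset of the synthetic phones' civil clock.
_OFFSET = timezone(timedelta(hours=1))

_DAY_MINUTES = 1440
_EARLIEST_START_MIN = 6 * 60  # bouts start between 06:00 and 23:00
_LATEST_END_MIN = 23 * 60


@dataclass(frozen=True)
class PhaseParameters:
    """Bout-process parameters of one activity phase.

    bouts_per_day
        Poisson rate of walking bouts per day.
    duration_log_mu, duration_log_sigma
        Log-normal parameters of bout duration in minutes.
    speed_mean_m_per_min, speed_sd_m_per_min
        Normal gait-speed distribution (m/min), truncated at zero by
        rejection; one constant speed per bout.
    cadence_steps_per_m
        Steps recorded per meter of distance (constant).
    carry_probability
        Probability that a bout is recorded at all (phone carried).
    """

    bouts_per_day: float
    duration_log_mu: float
    duration_log_sigma: float
    speed_mean_m_per_min: float
    speed_sd_m_per_min: float
    cadence_steps_per_m: float = 1.35
    carry_probability: float = 0.85

    def __post_init__(self) -> None:
        if not (0.0 <= self.carry_probability <= 1.0):
            raise ValueError("carry_probability must lie in [0, 1]")
        for name in ("bouts_per_day", "duration_log_sigma", "speed_sd_m_per_min",
                     "cadence_steps_per_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# Medians of the daily 1-min maximum track the target trajectory
# 98 -> 82 -> 82 -> 105 m; bout rates and durations give plausible daily
# step counts (~5-6k at baseline) and active time (~1.5-2 h).
DEFAULT_PHASES: dict[str, PhaseParameters] = {
    "baseline": PhaseParameters(
        bouts_per_day=5.0, duration_log_mu=np.log(14.0), duration_log_sigma=0.55,
        speed_mean_m_per_min=38.0, speed_sd_m_per_min=48.0,
    ),
    "preop_decline": PhaseParameters(
        bouts_per_day=4.2, duration_log_mu=np.log(12.0), duration_log_sigma=0.55,
        speed_mean_m_per_min=36.0, speed_sd_m_per_min=44.0,
    ),
    "early_post": PhaseParameters(
        bouts_per_day=3.6, duration_log_mu=np.log(12.0), duration_log_sigma=0.60,
        speed_mean_m_per_min=35.0, speed_sd_m_per_min=46.0,
    ),
    "late_post": PhaseParameters(
        bouts_per_day=5.5, duration_log_mu=np.log(15.0), duration_log_sigma=0.55,
        speed_mean_m_per_min=41.0, speed_sd_m_per_min=49.0,
    ),
}

# A contrasting regime: bout counts are volatile (low, dispersed rate and
# unreliable carriage) while peak gait speed is tightly stable — daily step
# totals then fluctuate much more from day to day than the walk-test maxima.
STABLE_SPEED_PHASES: dict[str, PhaseParameters] = {
    phase: PhaseParameters(
        bouts_per_day=2.5, duration_log_mu=np.log(14.0), duration_log_sigma=0.7,
        speed_mean_m_per_min=75.0, speed_sd_m_per_min=4.0,
        carry_probability=0.7,
    )
    for phase in PHASE_ORDER
}


@dataclass(frozen=True)
class GroundTruthRow:
    """Analytic daily metrics implied by the recorded bout list."""

    patient_id: str
    date: date
    true_max_1min_m: float
    true_max_6min_m: float
    true_steps: int
    true_active_time_h: float


@dataclass(frozen=True)
class _Bout:
    start_s: int  # seconds after local midnight
    duration_s: int
    speed_m_per_min: float

    @property
    def distance_m(self) -> float:
        return self.duration_s / 60.0 * self.speed_m_per_min


def phase_of_offset(offset_days: int) -> str | None:
    for name, (lo, hi) in PHASE_RANGES.items():
        if lo <= offset_days < hi:
            return name
    return None


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return max(mean, 0.0)
    for _ in range(200):
        x = rng.normal(mean, sd)
        if x > 0:
            return x
    return abs(rng.normal(mean, sd))  # pathological parameters; keep positive


def _draw_bouts(params: PhaseParameters, rng: np.random.Generator) -> list[_Bout]:
    n = rng.poisson(params.bouts_per_day)
    bouts: list[_Bout] = []
    occupied: list[tuple[int, int]] = []
    dropped = 0
    for _ in range(n):
        dur_min = float(np.exp(rng.normal(params.duration_log_mu, params.duration_log_sigma)))
        dur_s = int(round(np.clip(dur_min, 2.0, 180.0) * 60))
        placed = False
        for _attempt in range(40):
            latest = _LATEST_END_MIN * 60 - dur_s
            start_s = int(rng.integers(_EARLIEST_START_MIN * 60, latest + 1))
            end_s = start_s + dur_s
            if all(end_s <= s or start_s >= e for s, e in occupied):
                occupied.append((start_s, end_s))
                speed = _truncated_normal(
                    rng, params.speed_mean_m_per_min, params.speed_sd_m_per_min
                )
                bouts.append(_Bout(start_s, dur_s, speed))
                placed = True
                break
        if not placed:
            dropped += 1
    if dropped:
        logger.debug("dropped %d bouts after placement retries", dropped)
    bouts.sort(key=lambda b: b.start_s)
    return bouts


def _ground_truth_from_bouts(
    bouts: Sequence[_Bout], patient_id: str, day: date, cadence: float
) -> GroundTruthRow:
    # Independent minute apportionment: loop per bout over touched minutes.
    minutes = np.zeros(_DAY_MINUTES)
    for b in bouts:
        s, e = b.start_s, b.start_s + b.duration_s
        rate = b.distance_m / (e - s)
        for m in range(s // 60, -(-e // 60)):
            overlap = min(e, (m + 1) * 60) - max(s, m * 60)
            if overlap > 0:
                minutes[m] += rate * overlap
    kern1 = minutes
    if minutes.any():
        win6 = np.convolve(minutes, np.ones(6), mode="valid")
        max6 = float(win6.max())
        max1 = float(kern1.max())
    else:
        max1 = max6 = 0.0
    steps = int(sum(round(b.distance_m * cadence) for b in bouts))
    active_h = sum(b.duration_s for b in bouts) / 3600.0
    return GroundTruthRow(patient_id, day, max1, max6, steps, active_h)


def simulate_patient_day(
    params: PhaseParameters,
    day: date,
    rng: np.random.Generator,
    patient_id: str = "",
) -> tuple[list[ActivityRecord], GroundTruthRow]:
    """One day's recorded activity and its analytic ground truth.

    Bouts are drawn, thinned by the carry probability, and emitted as one
    distance record and one step record each; ground truth is computed from
    exactly the retained bouts, so it matches what the pipeline can see.
    """
    bouts = _draw_bouts(params, rng)
    recorded = [b for b in bouts if rng.random() < params.carry_probability]
    records: list[ActivityRecord] = []
    midnight = datetime(day.year, day.month, day.day, tzinfo=_OFFSET)
    for b in recorded:
        start = midnight + timedelta(seconds=b.start_s)
        end = start + timedelta(seconds=b.duration_s)
        records.append(
            ActivityRecord(
                patient_id=patient_id,
                record_kind=RecordKind.distance_walking_running,
                start=start, end=end, value=b.distance_m, source_id="SimPhone",
            )
        )
        records.append(
            ActivityRecord(
                patient_id=patient_id,
                record_kind=RecordKind.step_count,
                start=start, end=end,
                value=float(round(b.distance_m * params.cadence_steps_per_m)),
                source_id="SimPhone",
            )
        )
    truth = _ground_truth_from_bouts(recorded, patient_id, day, params.cadence_steps_per_m)
    return records, truth


def generate_cohort(
    out_dir: Path | str,
    n_patients: int = 41,
    seed: int = 0,
    phases: Mapping[str, PhaseParameters] = DEFAULT_PHASES,
    speed_shift_m_per_min: Mapping[str, float] | None = None,
    first_surgery: date = date(2024, 3, 4),
    surgery_spread_days: int = 180,
) -> tuple[CohortManifest, pd.DataFrame]:
    """Write a full synthetic cohort: export XMLs, manifest, ground truth.

    Each patient's records span day offsets [-183, 42) around their surgery
    date.  ``speed_shift_m_per_min`` plants an additive effect on one or
    more phases' mean gait speed (e.g. a late-recovery improvement).
    Deterministic for a fixed seed and configuration.

    Returns the manifest and the ground-truth table; also writes
    ``manifest.csv`` and ``ground_truth.csv`` under ``out_dir``.
    """
    out_dir = Path(out_dir)
    exports = out_dir / "exports"
    exports.mkdir(parents=True, exist_ok=True)
    phases = dict(phases)
    if speed_shift_m_per_min:
        for phase, delta in speed_shift_m_per_min.items():
            p = phases[phase]
            phases[phase] = replace(
                p, speed_mean_m_per_min=p.speed_mean_m_per_min + delta
            )

    child_seeds = np.random.SeedSequence(seed).spawn(n_patients)
    manifest = CohortManifest()
    truth_rows: list[GroundTruthRow] = []
    for i, ss in enumerate(child_seeds):
        pid = f"P{i + 1:03d}"
        rng = np.random.default_rng(ss)
        surgery = first_surgery + timedelta(days=int(rng.integers(0, surgery_spread_days + 1)))
        records: list[ActivityRecord] = []
        for offset in range(-183, 42):
            phase = phase_of_offset(offset)
            day = surgery + timedelta(days=offset)
            day_records, truth = simulate_patient_day(phases[phase], day, rng, pid)
            records.extend(day_records)
            truth_rows.append(truth)
        path = exports / f"{pid}.xml"
        write_health_export(records, path)
        manifest.add(pid, surgery, path)

    write_manifest(manifest, out_dir / "manifest.csv")
    truth = pd.DataFrame(
        [
            {
                "patient_id": t.patient_id,
                "date": t.date.isoformat(),
                "true_max_1min_m": t.true_max_1min_m,
                "true_max_6min_m": t.true_max_6min_m,
                "true_steps": t.true_steps,
                "true_active_time_h": t.true_active_time_h,
            }
            for t in truth_rows
        ]
    )
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return manifest, truth


def simulate_interval_cohort(
    n_patients: int,
    interval_means: Mapping[str, Mapping[str, float]],
    paired_diff_sd: float,
    between_patient_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-patient interval values drawn directly at the summary level.

    A fast statistical stand-in for the full bout-level generator, used for
    error-rate and power studies of the comparison suite: patient p's value
    for metric m in interval i is μ_{m,i} + b_p + ε_{p,i} with
    b_p ~ N(0, between_patient_sd²) and ε ~ N(0, paired_diff_sd²/2), so any
    two intervals' paired difference has SD ``paired_diff_sd``.

    ``interval_means`` maps metric → {interval → μ}.  Returns a frame with
    the interval-summary schema columns the comparison suite reads
    (patient_id, interval, metric, mean, median).
    """
    within_sd = paired_diff_sd / np.sqrt(2.0)
    rows = []
    for metric, means in interval_means.items():
        intervals = list(means)
        b = rng.normal(0.0, between_patient_sd, size=n_patients)
        eps = rng.normal(0.0, within_sd, size=(n_patients, len(intervals)))
        for j, interval in enumerate(intervals):
            vals = means[interval] + b + eps[:, j]
            for p in range(n_patients):
                rows.append(
                    {
                        "patient_id": f"P{p + 1:03d}",
                        "interval": interval,
                        "metric": metric,
                        "mean": vals[p],
                        "median": vals[p],
                    }
                )
    return pd.DataFrame(rows, columns=["patient_id", "interval", "metric", "mean", "median"])
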