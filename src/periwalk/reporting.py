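"""End-to-end orchestration: manifest → tables, figures and a run log.

Outputs mirror the study's reporting: tidy CSV tables (daily metrics,
interval summaries, paired comparisons, pooled correlations, CV by
interval), boxplot figures of each metric across the four perioperative
intervals, and a correlation heatmap.  All randomness in simulation
subcommands funnels through one seed recorded in the log, and re-running
with identical inputs and config reproduces the CSVs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import timedelta
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
import seaborn as sns

from . import __version__
from .cohort_intervals import (
    INTERVAL_ORDER,
    METRICS,
    IntervalSpec,
    build_interval_summaries,
    interval_summary_frame,
)
from .health_export_io import CohortManifest, RecordKind, parse_health_export, read_manifest
from .perioperative_stats import comparison_frame, pooled_pearson, run_comparison_suite
from .timeline_metrics import compute_daily_metrics, daily_metrics_frame

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "extract_daily_metrics", "analyze_daily_metrics"]

_METRIC_LABELS = {
    "max_1min_m": "1-min walk maximum (m)",
    "max_6min_m": "6-min walk maximum (m)",
    "steps": "daily steps",
    "active_time_h": "active time (h/day)",
}


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run."""

    manifest_path: Path
    output_dir: Path
    reducer: str = "mean"  # per-patient value entering paired tests
    family: str = "per-metric"  # Hochberg family scope
    full_baseline: bool = False  # baseline spans [-183, 0) instead of [-183, -14)
    source_filter: str | None = None  # substring a sourceName must contain
    seed: int = 0
    make_figures: bool = True

    def __post_init__(self) -> None:
        if self.reducer not in ("mean", "median"):
            raise ValueError("reducer must be 'mean' or 'median'")
        if self.family not in ("per-metric", "global"):
            raise ValueError("family must be 'per-metric' or 'global'")
        self.manifest_path = Path(self.manifest_path)
        self.output_dir = Path(self.output_dir)

    def interval_spec(self) -> IntervalSpec:
        return IntervalSpec.with_full_baseline() if self.full_baseline else IntervalSpec()


def extract_daily_metrics(
    manifest: CohortManifest,
    source_filter: str | None = None,
    coverage: tuple[int, int] = (-183, 42),
) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Parse every export and derive the per-patient-day metrics table.

    Coverage is the half-open day-offset window around each surgery date.
    Returns the tidy daily table and per-patient parse bookkeeping.
    """
    predicate = (lambda s: source_filter in s) if source_filter else None
    frames = []
    parse_log: dict[str, dict[str, int]] = {}
    for pid, surgery, export in manifest:
        if not Path(export).exists():
            logger.warning("missing export for %s at %s; patient skipped", pid, export)
            parse_log[pid] = {"missing_export": 1}
            continue
        result = parse_health_export(export, patient_id=pid, source_filter=predicate)
        parse_log[pid] = {
            "n_records": len(result.records),
            "n_rejected": result.n_rejected,
            "n_skipped_type": result.n_skipped_type,
        }
        start = surgery + timedelta(days=coverage[0])
        end = surgery + timedelta(days=coverage[1])
        metrics = compute_daily_metrics(result.records, start, end, patient_id=pid)
        frames.append(daily_metrics_frame(metrics))
    if not frames:
        raise RuntimeError("empty cohort: no export could be read")
    return pd.concat(frames, ignore_index=True), parse_log


def analyze_daily_metrics(
    daily: pd.DataFrame,
    manifest: CohortManifest,
    spec: IntervalSpec,
    reducer: str = "mean",
    family: str = "per-metric",
) -> dict[str, pd.DataFrame]:
    """Interval summaries, paired comparisons, correlations, CV table."""
    summaries = build_interval_summaries(daily, manifest.surgery_dates, spec)
    summary_df = interval_summary_frame(summaries)
    comparisons = comparison_frame(
        run_comparison_suite(summary_df, reducer=reducer, family=family)
    )

    # pooled correlations use only the in-window patient-days
    lo, hi = spec.coverage
    dates = pd.to_datetime(daily["date"]).dt.date
    offsets = pd.Series(
        [(d - manifest.surgery_dates[p]).days for d, p in zip(dates, daily["patient_id"])],
        index=daily.index,
    )
    pooled = daily[(offsets >= lo) & (offsets < hi)]
    corr = pooled_pearson(pooled)
    corr_long = (
        corr.r.rename_axis("metric_a")
        .reset_index()
        .melt(id_vars="metric_a", var_name="metric_b", value_name="r")
        .merge(
            corr.p.rename_axis("metric_a")
            .reset_index()
            .melt(id_vars="metric_a", var_name="metric_b", value_name="p"),
        )
        .merge(
            corr.n.rename_axis("metric_a")
            .reset_index()
            .melt(id_vars="metric_a", var_name="metric_b", value_name="n"),
        )
    )

    cv = summary_df[summary_df["cv_defined"]][
        ["patient_id", "interval", "metric", "cv_percent"]
    ].reset_index(drop=True)
    return {
        "interval_summary": summary_df,
        "comparisons": comparisons,
        "correlations": corr_long,
        "cv": cv,
        "_corr_matrix_r": corr.r,
    }


def _boxplot_figures(summary_df: pd.DataFrame, out_dir: Path) -> list[Path]:
    paths = []
    for metric in METRICS:
        sub = summary_df[(summary_df["metric"] == metric) & summary_df["mean"].notna()]
        fig, ax = plt.subplots(figsize=(6, 4))
        sns.boxplot(data=sub, x="interval", y="mean", order=list(INTERVAL_ORDER), ax=ax)
        ax.set_xlabel("perioperative interval")
        ax.set_ylabel(f"per-patient mean {_METRIC_LABELS.get(metric, metric)}")
        fig.tight_layout()
        path = out_dir / f"boxplot_{metric}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths


def _heatmap_figure(corr_r: pd.DataFrame, out_dir: Path) -> Path:
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    sns.heatmap(corr_r, annot=True, fmt=".2f", vmin=-1, vmax=1, cmap="vlag", ax=ax)
    ax.set_title("pooled Pearson r over patient-days")
    fig.tight_layout()
    path = out_dir / "correlation_heatmap.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run manifest → tables/figures; returns paths of all artifacts."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(config.manifest_path)
    spec = config.interval_spec()
    lo, hi = spec.coverage

    daily, parse_log = extract_daily_metrics(
        manifest, source_filter=config.source_filter, coverage=(lo, hi)
    )
    tables = analyze_daily_metrics(
        daily, manifest, spec, reducer=config.reducer, family=config.family
    )

    artifacts: dict[str, Path] = {}
    daily_path = out / "daily_metrics.csv"
    daily.to_csv(daily_path, index=False)
    artifacts["daily_metrics"] = daily_path
    for name in ("interval_summary", "comparisons", "correlations", "cv"):
        path = out / f"{name}.csv"
        tables[name].to_csv(path, index=False)
        artifacts[name] = path

    if config.make_figures:
        fig_dir = out / "figures"
        fig_dir.mkdir(exist_ok=True)
        for p in _boxplot_figures(tables["interval_summary"], fig_dir):
            artifacts[p.stem] = p
        artifacts["correlation_heatmap"] = _heatmap_figure(tables["_corr_matrix_r"], fig_dir)

    log = {
        "periwalk_version": __version__,
        "config": {
            k: (str(v) if isinstance(v, Path) else v) for k, v in asdict(config).items()
        },
        "interval_ranges": {k: list(v) for k, v in spec.ranges.items()},
        "n_patients": len(manifest),
        "parse_log": parse_log,
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    artifacts["run_log"] = log_path
    return artifacts
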