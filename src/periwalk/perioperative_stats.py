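"""Paired perioperative statistics: normality-routed tests, Hochberg
step-up adjustment, and pooled descriptive correlations.

Routing rule for each interval-pair comparison: the per-patient paired
differences d = b − a are tested for normality with Shapiro–Wilk at
α = 0.05.  If p ≥ 0.05 a two-sided paired Student's t-test is applied;
otherwise the two-sided Wilcoxon signed-rank test (zero differences
discarded, mid-rank ties, exact null distribution for small samples
without ties, normal approximation with continuity correction otherwise).

Within each outcome metric, the family of six interval-pair p-values is
adjusted with the Simes–Hochberg step-up procedure, and significance is
declared at adjusted p < 0.05.

Pooled Pearson correlations across patient-days are descriptive: the
pooled table contains repeated observations per patient and no clustering
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_intervals import INTERVAL_ORDER, METRICS

__all__ = [
    "PairedComparison",
    "CorrelationMatrix",
    "ALPHA",
    "route_paired_test",
    "hochberg_adjust",
    "run_comparison_suite",
    "comparison_frame",
    "pooled_pearson",
]

ALPHA = 0.05

#: The six interval-pair contrasts, in canonical order.
INTERVAL_PAIRS = tuple(combinations(INTERVAL_ORDER, 2))


@dataclass
class PairedComparison:
    """One interval-pair test: routing decision, statistic, raw/adjusted p."""

    metric: str
    interval_a: str
    interval_b: str
    n_pairs: int
    shapiro_p: float
    test_used: str  # "paired_t" | "wilcoxon_signed_rank" | "degenerate"
    statistic: float
    p_raw: float
    p_adjusted: float = float("nan")
    significant: bool = False


def _wilcoxon(d: np.ndarray) -> tuple[float, float]:
    nz = d[d != 0.0]
    n = nz.size
    if n == 0:
        return float("nan"), 1.0
    has_ties = np.unique(np.abs(nz)).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        nz, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return float(res.statistic), float(res.pvalue)


def route_paired_test(
    a: Sequence[float] | np.ndarray,
    b: Sequence[float] | np.ndarray,
    metric: str = "",
    interval_a: str = "",
    interval_b: str = "",
    alpha: float = ALPHA,
) -> PairedComparison:
    """Shapiro–Wilk-routed paired test on per-patient values ``a`` vs ``b``.

    Pairs with a missing value on either side are dropped pairwise.
    All-zero differences short-circuit to a degenerate result with p = 1;
    constant nonzero differences (Shapiro–Wilk undefined) route to the
    signed-rank test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n = a.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs for the normality test, got {n}")
    d = b - a
    if np.all(d == 0.0):
        return PairedComparison(
            metric, interval_a, interval_b, n, float("nan"), "degenerate",
            float("nan"), 1.0,
        )
    if np.ptp(d) == 0.0:  # constant nonzero: normality test undefined
        stat, p = _wilcoxon(d)
        return PairedComparison(
            metric, interval_a, interval_b, n, float("nan"),
            "wilcoxon_signed_rank", stat, p,
        )
    shapiro_p = float(stats.shapiro(d).pvalue)
    if shapiro_p >= alpha:
        res = stats.ttest_rel(b, a)
        return PairedComparison(
            metric, interval_a, interval_b, n, shapiro_p, "paired_t",
            float(res.statistic), float(res.pvalue),
        )
    stat, p = _wilcoxon(d)
    return PairedComparison(
        metric, interval_a, interval_b, n, shapiro_p, "wilcoxon_signed_rank", stat, p,
    )


def hochberg_adjust(p_raw: Sequence[float] | np.ndarray) -> np.ndarray:
    """Simes–Hochberg step-up adjusted p-values, in the input order.

    With p(1) ≤ … ≤ p(m): adj(m) = p(m) and, stepping up,
    adj(i) = min(adj(i+1), (m − i + 1) · p(i)), capped at 1.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj = np.empty(m)
    adj[m - 1] = sorted_p[m - 1]
    for i in range(m - 2, -1, -1):
        adj[i] = min(adj[i + 1], (m - i) * sorted_p[i])
    np.clip(adj, 0.0, 1.0, out=adj)
    out = np.empty(m)
    out[order] = adj
    return out


def run_comparison_suite(
    summary: pd.DataFrame,
    metrics: Iterable[str] = METRICS,
    pairs: Sequence[tuple[str, str]] = INTERVAL_PAIRS,
    reducer: str = "mean",
    family: str = "per-metric",
    alpha: float = ALPHA,
) -> list[PairedComparison]:
    """All interval-pair comparisons for each metric, Hochberg-adjusted.

    Parameters
    ----------
    summary
        Tidy interval-summary table (``interval_summary_frame`` output).
    reducer
        Column of ``summary`` giving the per-patient value entering the
        paired tests: ``"mean"`` (default) or ``"median"`` of daily values.
    family
        ``"per-metric"`` adjusts the six pairs within each metric
        separately; ``"global"`` adjusts all metrics' comparisons jointly.
    """
    if reducer not in ("mean", "median"):
        raise ValueError("reducer must be 'mean' or 'median'")
    if family not in ("per-metric", "global"):
        raise ValueError("family must be 'per-metric' or 'global'")
    wide = summary.pivot_table(
        index="patient_id", columns=["metric", "interval"], values=reducer, sort=True
    )
    results: list[PairedComparison] = []
    families: list[list[PairedComparison]] = []
    for metric in metrics:
        fam: list[PairedComparison] = []
        for ia, ib in pairs:
            va = wide.get((metric, ia))
            vb = wide.get((metric, ib))
            if va is None or vb is None:
                raise ValueError(f"summary table lacks interval {ia!r} or {ib!r} for {metric!r}")
            fam.append(route_paired_test(va.to_numpy(), vb.to_numpy(), metric, ia, ib))
        families.append(fam)
    if family == "global":
        families = [[c for fam in families for c in fam]]
    for fam in families:
        adj = hochberg_adjust([c.p_raw for c in fam])
        for c, pa in zip(fam, adj):
            c.p_adjusted = float(pa)
            c.significant = bool(pa < alpha)
        results.extend(fam)
    return results


def comparison_frame(comparisons: Iterable[PairedComparison]) -> pd.DataFrame:
    rows = [
        {
            "metric": c.metric,
            "interval_a": c.interval_a,
            "interval_b": c.interval_b,
            "n_pairs": c.n_pairs,
            "shapiro_p": c.shapiro_p,
            "test_used": c.test_used,
            "statistic": c.statistic,
            "p_raw": c.p_raw,
            "p_adjusted": c.p_adjusted,
            "significant": c.significant,
        }
        for c in comparisons
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "metric", "interval_a", "interval_b", "n_pairs", "shapiro_p",
            "test_used", "statistic", "p_raw", "p_adjusted", "significant",
        ],
    )


@dataclass
class CorrelationMatrix:
    """Pairwise pooled Pearson correlations over patient-days."""

    metrics: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def pooled_pearson(
    daily: pd.DataFrame,
    metrics: Iterable[str] = METRICS,
) -> CorrelationMatrix:
    """Pearson r and two-sided p per metric pair, pooled over patient-days.

    Pairwise-complete observations; pairs with fewer than 3 pooled days get
    NaN.  Descriptive only: observations are repeated within patients.
    """
    metrics = tuple(metrics)
    k = len(metrics)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    cols = {m: pd.to_numeric(daily[m], errors="coerce").to_numpy(dtype=float) for m in metrics}
    for i, mi in enumerate(metrics):
        r[i, i], p[i, i], n[i, i] = 1.0, 0.0, np.sum(~np.isnan(cols[mi]))
        for j in range(i + 1, k):
            mj = metrics[j]
            x, y = cols[mi], cols[mj]
            keep = ~(np.isnan(x) | np.isnan(y))
            n[i, j] = n[j, i] = int(keep.sum())
            if n[i, j] >= 3 and np.ptp(x[keep]) > 0 and np.ptp(y[keep]) > 0:
                res = stats.pearsonr(x[keep], y[keep])
                r[i, j] = r[j, i] = float(res.statistic)
                p[i, j] = p[j, i] = float(res.pvalue)
    idx = list(metrics)
    return CorrelationMatrix(
        metrics=metrics,
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
    )
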