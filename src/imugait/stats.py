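"""Task and group comparison statistics.

Per-participant paired task contrasts (walking vs TUG) with paired t and
Wilcoxon signed-rank alternatives, Sidak multiple-comparison adjustment
and Spearman rank correlation.  Sidak and Spearman are implemented from
first principles (closed form; exact permutation null for small samples);
the repeated-measures mixed-effects machinery of full group studies is
deliberately not replicated — paired within-group contrasts are the
supported design at this scale.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatisticsError

__all__ = [
    "PairedContrast",
    "paired_task_contrast",
    "sidak_adjust",
    "spearman",
    "ComparisonReport",
    "task_comparison_report",
]


@dataclass
class PairedContrast:
    """Result of one paired task contrast (walk minus TUG)."""

    n: int
    mean_difference: float
    t_statistic: float
    p_t: float
    wilcoxon_statistic: float
    p_wilcoxon: float


def paired_task_contrast(
    values_tug: Sequence[float],
    values_walk: Sequence[float],
) -> PairedContrast:
    """Paired contrast of one metric between the two tasks.

    Returns the mean difference (walk - TUG), the paired t statistic with
    its two-sided p, and the Wilcoxon signed-rank alternative (ties/zeros
    discarded per Wilcoxon's original rule).  Identical vectors are a
    degenerate no-effect case: difference 0, p = 1.
    """
    a = np.asarray(values_tug, dtype=float)
    b = np.asarray(values_walk, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise StatisticsError("paired contrast needs two equal-length vectors")
    if len(a) < 3:
        raise StatisticsError("need at least 3 pairs")
    d = b - a
    if np.allclose(d, 0.0):
        return PairedContrast(len(d), 0.0, 0.0, 1.0, 0.0, 1.0)
    if np.std(d, ddof=1) < 1e-15:
        # constant nonzero shift: infinite t, p -> 0
        return PairedContrast(len(d), float(d.mean()), math.inf, 0.0, 0.0, 0.0)
    t_res = sps.ttest_rel(b, a)
    nz = d[d != 0.0]
    if len(nz) == 0:
        w_stat, p_w = 0.0, 1.0
    else:
        w = sps.wilcoxon(nz, zero_method="wilcox", method="auto")
        w_stat, p_w = float(w.statistic), float(w.pvalue)
    return PairedContrast(
        n=len(d),
        mean_difference=float(d.mean()),
        t_statistic=float(t_res.statistic),
        p_t=float(t_res.pvalue),
        wilcoxon_statistic=w_stat,
        p_wilcoxon=p_w,
    )


def sidak_adjust(p_values, m: Optional[int] = None) -> np.ndarray:
    """Sidak multiple-comparison adjustment, p_adj = 1 - (1 - p)^m.

    ``m`` defaults to the number of p-values and must be at least that.
    Monotone in both p and m; output clipped to [0, 1].
    """
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise StatisticsError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise StatisticsError(f"m={m} smaller than the number of p-values ({len(p)})")
    return np.clip(1.0 - (1.0 - p) ** m, 0.0, 1.0)


def _rank_average(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with midranks for ties."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    xs = x[order]
    i = 0
    while i < len(xs):
        j = i
        while j + 1 < len(xs) and xs[j + 1] == xs[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    uc = u - u.mean()
    vc = v - v.mean()
    denom = math.sqrt(float(uc @ uc) * float(vc @ vc))
    return float(uc @ vc) / denom


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    exact_max_n: int = 9,
) -> Tuple[float, float]:
    """Spearman rank correlation with a small-sample exact p-value.

    rho is the Pearson correlation of average ranks (midranks for ties).
    For n <= ``exact_max_n`` the two-sided p is exact, enumerating all n!
    permutations of one rank vector; for larger n the usual
    t-approximation ``t = rho sqrt((n-2)/(1-rho^2))`` is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatisticsError("x and y must be equal-length vectors")
    n = len(x)
    if n < 4:
        raise StatisticsError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise StatisticsError("correlation undefined for constant input")
    rx = _rank_average(x)
    ry = _rank_average(y)
    rho = _pearson(rx, ry)
    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(range(n))))
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        scale = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
        rhos = (ryc[perms] @ rxc) / scale
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return rho, p


@dataclass
class ComparisonReport:
    """Per-metric paired contrasts with Sidak-adjusted p-values, plus
    optional metric-vs-age correlations."""

    contrasts: Dict[str, PairedContrast]
    p_adjusted: Dict[str, float]
    alpha: float
    correlations: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def significant(self, metric: str) -> bool:
        return self.p_adjusted[metric] < self.alpha

    def any_significant(self) -> bool:
        return any(self.significant(m) for m in self.p_adjusted)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m, c in self.contrasts.items():
            rows.append(
                {
                    "metric": m,
                    "n": c.n,
                    "mean_difference": c.mean_difference,
                    "t": c.t_statistic,
                    "p_raw": c.p_t,
                    "p_sidak": self.p_adjusted[m],
                    "significant": self.significant(m),
                }
            )
        return pd.DataFrame(rows)


def task_comparison_report(
    metrics_tug: pd.DataFrame,
    metrics_walk: pd.DataFrame,
    metrics: Optional[Sequence[str]] = None,
    ages: Optional[Sequence[float]] = None,
    alpha: float = 0.05,
) -> ComparisonReport:
    """Compare per-participant metrics between tasks.

    Both frames are indexed by participant id with one column per metric;
    rows are matched on the shared index.  When ``ages`` is given (aligned
    with the shared index), Spearman correlations of each walking-task
    metric with age are added.
    """
    common = metrics_tug.index.intersection(metrics_walk.index)
    if len(common) < 3:
        raise StatisticsError("fewer than 3 participants with both tasks")
    if metrics is None:
        metrics = [c for c in metrics_tug.columns if c in metrics_walk.columns]
    contrasts = {
        m: paired_task_contrast(
            metrics_tug.loc[common, m].to_numpy(),
            metrics_walk.loc[common, m].to_numpy(),
        )
        for m in metrics
    }
    adj = sidak_adjust([contrasts[m].p_t for m in metrics], m=len(metrics))
    report = ComparisonReport(
        contrasts=contrasts,
        p_adjusted=dict(zip(metrics, map(float, adj))),
        alpha=alpha,
    )
    if ages is not None:
        ages = np.asarray(ages, dtype=float)
        for m in metrics:
            report.correlations[m] = spearman(ages, metrics_walk.loc[common, m].to_numpy())
    return report
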