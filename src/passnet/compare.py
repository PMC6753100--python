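"""Focal-team-vs-rivals statistical comparison.

Per metric, per-match values of the focal team are compared with the
pooled per-match values of its opponents using the two-sided Wilcoxon
rank-sum test (exact when both samples are small and tie-free, normal
approximation with tie correction otherwise).  The family of p-values is
then corrected for multiple comparisons with a step-up false-discovery-
rate procedure (Benjamini–Hochberg by default, Benjamini–Yekutieli
available) at nominal level alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .temporal import METRIC_NAMES, SeasonSummary

#: the default comparison family: classical tallies plus the spatial and
#: topological panels (shots join automatically when provided)
DEFAULT_METRICS = ("n_passes", "goals", "points", "X_mean", "Y_mean",
                   "centroid_dispersion", "advance_ratio", "C", "d",
                   "lambda1", "lambda2_alg", "EC_disp", "EC_max")

_EXACT_MAX_N = 12


@dataclass(frozen=True)
class RanksumResult:
    W: float         # rank-sum statistic of the first sample
    p: float


def ranksum_test(a, b) -> RanksumResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration when n_a + n_b <= 12 and there are no ties;
    otherwise the normal approximation with tie correction (no
    continuity correction).  W is the sum of the ranks of ``a`` in the
    pooled sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank-sum test requires non-empty samples")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        # degenerate: every observation tied; no evidence either way
        W = a.size * (pooled.size + 1) / 2
        return RanksumResult(W=W, p=1.0)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= _EXACT_MAX_N and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=False)
    W = float(res.statistic + a.size * (a.size + 1) / 2)   # U -> rank sum
    return RanksumResult(W=W, p=float(min(res.pvalue, 1.0)))


def fdr_adjust(p_values, alpha: float = 0.01,
               method: str = "bh") -> tuple[np.ndarray, float]:
    """Step-up FDR decisions over a family of p-values.

    Returns (reject flags, alpha_adjusted) where alpha_adjusted is the
    largest p-value still rejected (0.0 when nothing is rejected).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if method not in ("bh", "by"):
        raise ValueError(f"unknown FDR method {method!r}")
    reject, *_ = multipletests(p, alpha=alpha, method=f"fdr_{method}")
    alpha_adjusted = float(p[reject].max()) if reject.any() else 0.0
    return reject, alpha_adjusted


def compare_focal_vs_rivals(summary: SeasonSummary,
                            metrics=None, alpha: float = 0.01,
                            method: str = "bh") -> pd.DataFrame:
    """One rank-sum test per metric, jointly FDR-corrected.

    Returns a table indexed by metric with columns n_a, n_b, W, p_raw,
    significant; ``.attrs`` carries alpha and the FDR-implied
    alpha_adjusted actually applied.
    """
    if summary.per_match["match_id"].nunique() < 2:
        raise ValueError("comparison requires at least 2 matches")
    if metrics is None:
        metrics = [m for m in DEFAULT_METRICS if m in summary.per_match.columns]
        if "shots" in summary.per_match.columns:
            metrics = metrics + ["shots"]
    rows = []
    for m in metrics:
        a, b = summary.group_values(m)   # KeyError on unknown metric
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        res = ranksum_test(a, b)
        rows.append({"metric": m, "n_a": a.size, "n_b": b.size,
                     "W": res.W, "p_raw": res.p})
    table = pd.DataFrame(rows).set_index("metric")
    reject, alpha_adjusted = fdr_adjust(table["p_raw"].to_numpy(),
                                        alpha=alpha, method=method)
    table["significant"] = reject
    table.attrs["alpha"] = alpha
    table.attrs["alpha_adjusted"] = alpha_adjusted
    table.attrs["fdr_method"] = method
    return table
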