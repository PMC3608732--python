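"""Group-comparison utilities for per-mouse readouts.

The workflow is the one standard in small-animal intervention studies:
screen each group for normality (Shapiro-Wilk), compare two groups with a
two-sample t-test (or a rank-based Mann-Whitney U test when a group fails
the screen, flagged in the report), compare more than two with one-way
ANOVA followed by all-pairs comparisons, and control the family-wise error
of the pairwise comparisons with the Holm-Sidak step-down adjustment.
Dispersion is reported as SEM.

The t/ANOVA/Shapiro-Wilk machinery is delegated to scipy.stats; the
Holm-Sidak adjustment is implemented here.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import AnalysisError

__all__ = ["holm_sidak_adjust", "sem", "group_compare"]

DEFAULT_ALPHA = 0.05
NORMALITY_ALPHA = 0.05


def holm_sidak_adjust(p_values: Sequence[float], alpha: float = DEFAULT_ALPHA) -> tuple[np.ndarray, np.ndarray]:
    """Holm-Sidak step-down multiple-comparison adjustment.

    Sort the m raw p-values ascending; the i-th smallest (1-based) is
    adjusted to ``1 - (1 - p_(i))**(m - i + 1)``; adjusted values are then
    made monotone nondecreasing along the sorted order and mapped back to
    the input order.  Returns ``(adjusted, reject)`` with rejection at
    ``adjusted < alpha``.  Adjusted values are always >= the raw ones and
    <= 1.
    """
    p = np.asarray(p_values, float)
    if p.ndim != 1 or p.size == 0:
        raise AnalysisError("p_values must be a nonempty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise AnalysisError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adj_sorted, 1.0)
    return adjusted, adjusted < alpha


def sem(values: Sequence[float]) -> float:
    """Standard error of the mean: sd(ddof=1)/sqrt(n)."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise AnalysisError("SEM needs at least two values")
    return float(x.std(ddof=1) / np.sqrt(x.size))


def _pair_test(a: np.ndarray, b: np.ndarray, normal: bool) -> tuple[str, float, float]:
    if normal:
        kind, (stat, p) = "t", sps.ttest_ind(a, b)
    else:
        kind, (stat, p) = "mannwhitneyu", sps.mannwhitneyu(a, b, alternative="two-sided")
    # two identical constant groups have zero pooled variance: no evidence
    if np.isnan(p):
        stat, p = 0.0, 1.0
    return kind, float(stat), float(p)


def group_compare(
    groups: Mapping[str, Sequence[float]], alpha: float = DEFAULT_ALPHA
) -> dict:
    """Compare >= 2 groups of per-mouse values; returns a JSON-able report.

    Two groups: two-sample t-test (rank-based fallback when a Shapiro-Wilk
    screen fails, flagged as ``nonparametric``).  More than two: one-way
    ANOVA followed by all-pairs comparisons adjusted with
    :func:`holm_sidak_adjust`.  The report carries each group's n, mean and
    SEM, the test statistics and the adjusted p-values.
    """
    if len(groups) < 2:
        raise AnalysisError("need at least two groups")
    arrays = {name: np.asarray(v, float) for name, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise AnalysisError(f"group {name!r} has n < 2")

    summary = {}
    normal = True
    for name, arr in arrays.items():
        # Shapiro-Wilk is undefined for constant samples; treat those as normal.
        if arr.size >= 3 and arr.std() > 0:
            sw_p = float(sps.shapiro(arr).pvalue)
        else:
            sw_p = float("nan")
        if not np.isnan(sw_p) and sw_p < NORMALITY_ALPHA:
            normal = False
        summary[name] = {
            "n": int(arr.size),
            "mean": float(arr.mean()),
            "sem": sem(arr),
            "shapiro_p": sw_p,
        }

    report: dict = {
        "alpha": alpha,
        "groups": summary,
        "nonparametric": not normal,
    }
    names = list(arrays)
    if len(names) == 2:
        kind, stat, p = _pair_test(arrays[names[0]], arrays[names[1]], normal)
        adjusted, reject = holm_sidak_adjust([p], alpha)
        report["test"] = kind
        report["comparisons"] = [
            {
                "pair": names,
                "statistic": stat,
                "p_raw": p,
                "p_adjusted": float(adjusted[0]),
                "reject": bool(reject[0]),
            }
        ]
        return report

    f_stat, f_p = sps.f_oneway(*arrays.values())
    report["test"] = "anova+holm-sidak"
    report["anova"] = {"F": float(f_stat), "p": float(f_p)}
    pairs = list(combinations(names, 2))
    raws = []
    stats_ = []
    kinds = []
    for a, b in pairs:
        kind, stat, p = _pair_test(arrays[a], arrays[b], normal)
        kinds.append(kind)
        stats_.append(stat)
        raws.append(p)
    adjusted, reject = holm_sidak_adjust(raws, alpha)
    report["comparisons"] = [
        {
            "pair": list(pair),
            "test": kind,
            "statistic": stat,
            "p_raw": p,
            "p_adjusted": float(adj),
            "reject": bool(rej),
        }
        for pair, kind, stat, p, adj, rej in zip(pairs, kinds, stats_, raws, adjusted, reject)
    ]
    return report
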