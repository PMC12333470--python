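"""Group-comparison statistics for cohort syllable metrics.

Per-syllable comparisons use Kruskal-Wallis with Dunn's post hoc test and
Benjamini-Hochberg correction across the retained syllable set; scalar
session metrics (e.g., conventional locomotion velocity) use Mann-Whitney U;
the delta-metric relationships use ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "KWDunnResult",
    "kw_dunn",
    "bh_adjust",
    "mann_whitney",
    "ols_regression",
    "compare_metric_across_groups",
]


@dataclass
class KWDunnResult:
    H: float
    p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, z, p


def kw_dunn(groups) -> KWDunnResult:
    """Kruskal-Wallis H (tie-corrected) with Dunn's pairwise z tests.

    ``groups`` is a sequence of 1-D samples (per-animal values per group).
    Dunn's z uses pooled mid-rank means with the tie-adjusted variance; the
    pairwise p values are two-sided and unadjusted (feed them to
    :func:`bh_adjust`). Degenerate input with all values identical returns
    H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        pairs = pd.DataFrame(
            [(i, j, 0.0, 1.0) for i, j in combinations(range(len(groups)), 2)],
            columns=["group_a", "group_b", "z", "p"],
        )
        return KWDunnResult(H=0.0, p=1.0, pairwise=pairs)
    H, p = sps.kruskal(*groups)

    ranks = sps.rankdata(pooled)
    N = len(pooled)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1))
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        rows.append((i, j, z, 2.0 * sps.norm.sf(abs(z))))
    pairs = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
    return KWDunnResult(H=float(H), p=float(p), pairwise=pairs)


def bh_adjust(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up: adjusted p values and rejection flags.

    ``adjusted[i] = min_{k >= rank(i)} m * p_(k) / k`` capped at 1; a
    hypothesis is rejected when its adjusted p is <= ``q``.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.clip(adjusted_sorted, 0.0, 1.0)
    return adjusted, adjusted <= q


def mann_whitney(a, b):
    """Mann-Whitney U (for sample ``a``) and two-sided p.

    Exact enumeration when ``len(a) * len(b) <= 400`` and there are no ties;
    otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (a.size * b.size <= 400 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def ols_regression(x, y):
    """Least-squares line fit: (slope, intercept, R^2, p of slope)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.all(x == x[0]):
        raise ValueError("x is constant; regression undefined")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)


def compare_metric_across_groups(values_by_group: dict, q: float = 0.05) -> pd.DataFrame:
    """Per-syllable KW + BH across groups for one metric.

    ``values_by_group`` maps group name -> {syllable -> per-animal 1-D
    array}. Only syllables present in every group are tested (the BH family
    is the tested syllable set). Returns a DataFrame indexed by syllable with
    group means/sems, raw p, BH-adjusted p and the rejection flag.
    """
    names = list(values_by_group)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    shared = sorted(set.intersection(*(set(values_by_group[g]) for g in names)))
    if not shared:
        raise ValueError("no syllable is present in every group")
    rows = []
    for s in shared:
        samples = [np.asarray(values_by_group[g][s], dtype=float) for g in names]
        res = kw_dunn(samples)
        row = {"syllable": s, "p_raw": res.p, "H": res.H}
        for g, sample in zip(names, samples):
            row[f"{g}_mean"] = sample.mean()
            row[f"{g}_sem"] = sample.std(ddof=1) / np.sqrt(len(sample))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("syllable")
    adjusted, reject = bh_adjust(table["p_raw"].to_numpy(), q=q)
    table["p_adjusted"] = adjusted
    table["significant"] = reject
    return table
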