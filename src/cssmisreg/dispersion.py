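"""Rank-based dispersion comparisons between chromosome groups.

Misregulation inflates the spread of fold changes without necessarily
moving their center, so the workhorse here is the Ansari-Bradley two-sample
scale test applied to group-centered log2 fold changes ("centralized
data"), overall and stratified by raw expression intensity.

The Ansari-Bradley scores fold the pooled ranks about their middle:
a_i = min(r_i, N + 1 - r_i) with midranks under ties.  The statistic is the
sum of scores in the first sample; small values mean the first sample is
more spread out (its members occupy the extremes of the pooled sample).
The null distribution is computed exactly by dynamic programming over the
score multiset when the smaller group is small enough, otherwise by a
normal approximation with tie-corrected variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Default raw-intensity band edges: [10,100), [100,1000), [1000, inf).
DEFAULT_STRATA = (10.0, 100.0, 1000.0)

#: Exact null when min(n) <= this ...
DEFAULT_EXACT_MAX_N = 10
#: ... and the pooled sample is no larger than this (DP cost guard).
EXACT_MAX_TOTAL = 200


def centralize(values, groups, method: str = "median") -> pd.Series:
    """Subtract each group's center (median by default, or mean) from its members."""
    index = values.index if isinstance(values, pd.Series) else None
    values = pd.Series(np.asarray(values, dtype=float), index=index)
    groups = pd.Series(np.asarray(groups, dtype=object), index=values.index)
    if method not in ("median", "mean"):
        raise ValueError("method must be 'median' or 'mean'")
    out = values.copy()
    for g, idx in values.groupby(groups).groups.items():
        sub = values.loc[idx]
        if len(sub) == 0:
            raise ValueError(f"empty group {g!r}")
        center = sub.median() if method == "median" else sub.mean()
        out.loc[idx] = sub - center
    return out


def ansari_scores(pooled: np.ndarray) -> np.ndarray:
    """Folded midranks: min(rank, N + 1 - rank) over the pooled sample."""
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    return np.minimum(ranks, n + 1 - ranks)


@dataclass
class DispersionTestResult:
    group_labels: tuple[str, str]
    n1: int
    n2: int
    statistic: float | None
    p: float | None
    method: str
    stratum: str = "all"
    centering: str = "median"
    note: str = ""

    @property
    def skipped(self) -> bool:
        return self.p is None


def _exact_ansari_p(scores: np.ndarray, n1: int, statistic: float) -> float:
    """Exact two-sided p by DP over subsets of the score multiset.

    Counts, for every k and score-sum s, the number of n1-subsets of the
    pooled scores summing to s; ties are handled naturally because midrank
    scores enter the multiset as-is (doubled to integers).
    """
    s2 = np.rint(scores * 2).astype(int)  # midranks are half-integers
    total = int(s2.sum())
    n = len(s2)
    # dp[k, s] = number of size-k subsets with doubled-score sum s;
    # k runs downward so each item is counted once
    dp = np.zeros((n1 + 1, total + 1))
    dp[0, 0] = 1.0
    for a in s2:
        for k in range(min(n1, n), 0, -1):
            dp[k, a:] += dp[k - 1, : total + 1 - a]
    dist = dp[n1]
    n_subsets = dist.sum()
    obs = int(round(statistic * 2))
    p_low = dist[: obs + 1].sum() / n_subsets
    p_high = dist[obs:].sum() / n_subsets
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def ansari_bradley(
    x,
    y,
    exact_max_n: int = DEFAULT_EXACT_MAX_N,
    labels: tuple[str, str] = ("x", "y"),
    stratum: str = "all",
) -> DispersionTestResult:
    """Two-sided Ansari-Bradley test for a dispersion difference.

    Exact null (DP enumeration of the score-sum distribution) when
    min(n1, n2) <= ``exact_max_n`` and the pooled size is small enough,
    else a normal approximation with tie-corrected variance.  A pooled
    sample with all values identical has degenerate ranks; the test then
    returns p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    if n < 4 or n1 < 1 or n2 < 1:
        raise ValueError("need a pooled sample of at least 4 values")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; Ansari-Bradley ranks are degenerate")
        return DispersionTestResult(labels, n1, n2, float(n1 * (n + 1) / 2), 1.0,
                                    "degenerate", stratum)
    scores = ansari_scores(pooled)
    statistic = float(scores[:n1].sum())

    if min(n1, n2) <= exact_max_n and n <= EXACT_MAX_TOTAL:
        p = _exact_ansari_p(scores, n1, statistic)
        method = "exact"
    else:
        mean = n1 * scores.mean()
        var = n1 * n2 * np.sum((scores - scores.mean()) ** 2) / (n * (n - 1))
        z = (statistic - mean) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
        method = "normal"
    return DispersionTestResult(labels, n1, n2, statistic, p, method, stratum)


def dispersion_test(
    values,
    groups,
    group_pair: tuple[str, str],
    center: str = "median",
    exact_max_n: int = DEFAULT_EXACT_MAX_N,
    stratum: str = "all",
) -> DispersionTestResult:
    """Centralize per group then compare the two groups' dispersions."""
    values = pd.Series(np.asarray(values, dtype=float))
    groups = pd.Series(np.asarray(groups, dtype=object))
    centered = centralize(values, groups, method=center)
    x = centered[groups.to_numpy() == group_pair[0]].to_numpy()
    y = centered[groups.to_numpy() == group_pair[1]].to_numpy()
    res = ansari_bradley(x, y, exact_max_n=exact_max_n, labels=group_pair,
                         stratum=stratum)
    res.centering = center
    return res


def stratified_dispersion(
    log2_fc,
    raw_intensity,
    group_labels,
    group_pair: tuple[str, str],
    strata: tuple[float, ...] = DEFAULT_STRATA,
    center: str = "median",
    exact_max_n: int = DEFAULT_EXACT_MAX_N,
) -> list[DispersionTestResult]:
    """Dispersion tests within raw-intensity bands.

    Bands are [s0, s1), ..., [s_last, inf).  Bands where either group has
    fewer than 2 members are reported as skipped rather than tested (e.g.
    when one chromosome group simply has no highly expressed transcripts).
    """
    if list(strata) != sorted(strata):
        raise ValueError("strata must be ascending")
    fc = np.asarray(log2_fc, dtype=float)
    inten = np.asarray(raw_intensity, dtype=float)
    labels = np.asarray(group_labels, dtype=object)
    edges = list(strata) + [np.inf]
    results = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        name = f"[{lo:g},{hi:g})" if np.isfinite(hi) else f">={lo:g}"
        band = (inten >= lo) & (inten < hi)
        n_a = int(((labels == group_pair[0]) & band).sum())
        n_b = int(((labels == group_pair[1]) & band).sum())
        if n_a < 2 or n_b < 2:
            results.append(
                DispersionTestResult(
                    group_pair, n_a, n_b, None, None, "skipped", name, center,
                    note="fewer than 2 members in a group",
                )
            )
            continue
        results.append(
            dispersion_test(fc[band], labels[band], group_pair, center=center,
                            exact_max_n=exact_max_n, stratum=name)
        )
    return results


def dispersion_results_frame(results: list[DispersionTestResult]) -> pd.DataFrame:
    rows = [
        {
            "group_a": r.group_labels[0],
            "group_b": r.group_labels[1],
            "stratum": r.stratum,
            "n1": r.n1,
            "n2": r.n2,
            "statistic": r.statistic,
            "p": r.p,
            "method": r.method,
            "note": r.note,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
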