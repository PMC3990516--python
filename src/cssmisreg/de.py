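"""Differential-expression calling.

The caller follows the classic small-replicate microarray recipe: per-gene
log2 fold changes between two strain groups, an empirical-Bayes moderated
two-sample t statistic, Benjamini-Hochberg FDR adjustment, and a joint
significance rule (adjusted p below alpha AND linear fold change at least a
threshold).  Chromosome-stratified frequency tables summarize the calls.

Moderation shrinks each gene's pooled variance s_g^2 toward an ensemble
prior s_0^2 with weight d_0 prior degrees of freedom:

    s_post^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g)

and refers t = dFC / sqrt(s_post^2 (1/n_1 + 1/n_2)) to a t distribution on
d_0 + d_g df.  The hyperparameters (d_0, s_0^2) are estimated by moment
matching on log variances: under the scaled-inverse-chi-square prior,
e_g = log s_g^2 - digamma(d_g/2) + log(d_g/2) has mean
log s_0^2 - digamma(d_0/2) + log(d_0/2) and variance
trigamma(d_g/2) + trigamma(d_0/2), so the sample mean and variance of e_g
identify both hyperparameters (d_0 = +inf when the observed spread of log
variances is no larger than pure sampling noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .models import ExpressionMatrix, X_CHROM

DIR_UP = "up"
DIR_DOWN = "down"
DIR_NONE = "none"

#: Default donor boundary used to split the X into proximal/distal halves.
DEFAULT_X_SPLIT_BP = 86_497_454


def log2_fold_changes(
    expr: ExpressionMatrix,
    test_group: str,
    ref_group: str,
    age_dpp: int | None = None,
) -> pd.Series:
    """Per-probe-set log2 FC: mean log2 intensity of test minus reference."""
    test = np.log2(expr.group_values(test_group, age_dpp)).mean(axis=1)
    ref = np.log2(expr.group_values(ref_group, age_dpp)).mean(axis=1)
    fc = test - ref
    fc.name = "log2_fc"
    return fc


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton in the style of limma)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


@dataclass
class ModeratedTResult:
    """Moderated-t output plus the fitted variance prior."""

    t: pd.Series
    df: float
    p: pd.Series
    s2_post: pd.Series
    prior_df: float
    prior_s2: float


def estimate_variance_prior(s2: np.ndarray, dg: float) -> tuple[float, float]:
    """Moment-matching estimate of (d0, s0^2) from per-gene variances."""
    s2 = np.asarray(s2, dtype=float)
    s2 = np.maximum(s2, 1e-300)
    e = np.log(s2) - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) if len(e) > 1 else 0.0
    excess = e_var - float(special.polygamma(1, dg / 2.0))
    if excess <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_2 = float(
            np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    return d0, s0_2


def moderated_t(
    expr: ExpressionMatrix,
    test_group: str,
    ref_group: str,
    age_dpp: int | None = None,
    prior_df: float | None = None,
) -> ModeratedTResult:
    """Empirical-Bayes moderated two-sample t test on log2 intensities.

    ``prior_df`` overrides the estimated prior weight d0; 0 recovers the
    ordinary pooled-variance Student t, ``inf`` shrinks every gene fully to
    the ensemble variance.
    """
    x = np.log2(expr.group_values(test_group, age_dpp)).to_numpy()
    y = np.log2(expr.group_values(ref_group, age_dpp)).to_numpy()
    if x.shape[1] < 2 or y.shape[1] < 2:
        raise ValueError("each group needs at least 2 replicates")
    if x.shape[0] == 0:
        raise ValueError("no probe sets to test")
    n1, n2 = x.shape[1], y.shape[1]
    dg = n1 + n2 - 2
    diff = x.mean(axis=1) - y.mean(axis=1)
    s2 = (x.var(axis=1, ddof=1) * (n1 - 1) + y.var(axis=1, ddof=1) * (n2 - 1)) / dg

    if prior_df is None:
        d0, s0_2 = estimate_variance_prior(s2, dg)
    else:
        d0 = float(prior_df)
        _, s0_2 = estimate_variance_prior(s2, dg)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df = np.inf
    elif d0 == 0:
        s2_post = s2
        df = float(dg)
    else:
        s2_post = (d0 * s0_2 + dg * s2) / (d0 + dg)
        df = float(d0 + dg)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    idx = expr.probe_ids
    return ModeratedTResult(
        t=pd.Series(t, index=idx, name="t"),
        df=df,
        p=pd.Series(p, index=idx, name="p"),
        s2_post=pd.Series(s2_post, index=idx, name="s2_post"),
        prior_df=d0,
        prior_s2=s0_2,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_de(
    log2_fc,
    adj_p,
    fc_threshold: float = 1.50,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Direction and significance flags from fold changes and adjusted p.

    Significant iff adjusted p < alpha AND the linear fold change magnitude
    is at least ``fc_threshold``; direction follows the sign of the log2 FC.
    """
    fc = np.asarray(log2_fc, dtype=float)
    ap = np.asarray(adj_p, dtype=float)
    if fc.shape != ap.shape:
        raise ValueError("fold-change and p vectors must be aligned")
    linear = np.exp2(np.abs(fc))
    significant = (ap < alpha) & (linear >= fc_threshold)
    direction = np.where(
        ~significant, DIR_NONE, np.where(fc > 0, DIR_UP, DIR_DOWN)
    )
    index = log2_fc.index if isinstance(log2_fc, pd.Series) else None
    return pd.DataFrame(
        {"direction": direction, "significant": significant}, index=index
    )


def de_table(
    expr: ExpressionMatrix,
    test_group: str,
    ref_group: str,
    age_dpp: int | None = None,
    fc_threshold: float = 1.50,
    alpha: float = 0.05,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Full per-probe-set call table for one comparison."""
    fc = log2_fold_changes(expr, test_group, ref_group, age_dpp)
    mod = moderated_t(expr, test_group, ref_group, age_dpp, prior_df=prior_df)
    adj = bh_adjust(mod.p.to_numpy())
    calls = call_de(fc, adj, fc_threshold=fc_threshold, alpha=alpha)
    mean_test = np.log2(expr.group_values(test_group, age_dpp)).mean(axis=1)
    mean_ref = np.log2(expr.group_values(ref_group, age_dpp)).mean(axis=1)
    return pd.DataFrame(
        {
            "mean_log2_test": mean_test,
            "mean_log2_ref": mean_ref,
            "log2_fc": fc,
            "t": mod.t,
            "df": mod.df,
            "p": mod.p,
            "adj_p": adj,
            "direction": calls["direction"],
            "significant": calls["significant"],
        }
    )


def _chrom_sort_key(name: str) -> tuple[int, str]:
    try:
        return (0, f"{int(name):02d}")
    except ValueError:
        return (1, name)


def chrom_frequency_table(
    calls: pd.DataFrame,
    annotation: pd.DataFrame,
    x_split_bp: int | None = None,
    x_chrom: str = X_CHROM,
) -> pd.DataFrame:
    """Per-chromosome counts and percentages of up/down transcripts.

    ``calls`` must carry ``direction``/``significant`` for the expressed
    (i.e., analyzed) probe sets; ``annotation`` provides ``chrom`` and
    ``pos_bp``.  With ``x_split_bp`` the X row splits into proX (< split) and
    disX (>= split).  Percentages are of the expressed probe sets on that
    chromosome, rounded to 2 decimals.
    """
    missing = calls.index.difference(annotation.index)
    if len(missing):
        raise ValueError(f"probe sets without annotation, e.g. {missing[0]!r}")
    ann = annotation.loc[calls.index]
    group = ann["chrom"].astype(str).copy()
    if x_split_bp is not None:
        on_x = group == x_chrom
        group[on_x & (ann["pos_bp"] < x_split_bp)] = "proX"
        group[on_x & (ann["pos_bp"] >= x_split_bp)] = "disX"

    rows = []
    for chrom in sorted(group.unique(), key=_chrom_sort_key):
        sub = calls[group == chrom]
        expressed = len(sub)
        up = int((sub["direction"] == DIR_UP).sum())
        down = int((sub["direction"] == DIR_DOWN).sum())
        rows.append(
            {
                "chrom": chrom,
                "expressed": expressed,
                "up": up,
                "up_pct": frequency_pct(up, expressed),
                "down": down,
                "down_pct": frequency_pct(down, expressed),
            }
        )
    return pd.DataFrame(rows).set_index("chrom")


def frequency_pct(count: int, expressed: int) -> float:
    """Percentage of expressed transcripts, rounded to 2 decimals (0 if none)."""
    if expressed == 0:
        return 0.0
    return round(100.0 * count / expressed, 2)


def aggregate_frequency(table: pd.DataFrame, chroms: list[str]) -> dict:
    """Aggregate rows of a frequency table (e.g. all autosomes): summed counts
    with percentages recomputed from the sums."""
    sub = table.loc[[c for c in chroms if c in table.index]]
    expressed = int(sub["expressed"].sum())
    up = int(sub["up"].sum())
    down = int(sub["down"].sum())
    return {
        "expressed": expressed,
        "up": up,
        "up_pct": frequency_pct(up, expressed),
        "down": down,
        "down_pct": frequency_pct(down, expressed),
    }
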