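"""Parent-of-origin comparison and regulatory typing of misexpressed genes.

A substitution strain carries donor cis-regulatory elements embedded in a
host trans-acting background.  Two diagnostics ask which parent the strain's
expression tracks:

* a correlation comparison — Pearson correlations of the strain's
  log-transformed group means against each parent over a gene subset,
  compared via Fisher's z transformation;
* per-transcript typing — a misexpressed transcript whose linear expression
  ratio to the donor parent converges within a band (default strictly
  inside 1.5-fold) is "cis-regulated" (it simply adopted the donor level);
  one matching neither parent is an "incompatibility" transcript
  (donor cis-elements misread by host trans-factors).

Overlap analysis quantifies how much two differential-expression call sets
share and where the shared transcripts sit in the genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import DIR_DOWN, DIR_UP, frequency_pct
from .models import X_CHROM

TYPE_CIS = "cis_regulated"
TYPE_INCOMPAT = "incompatibility"


@dataclass
class CorrelationComparison:
    r_host: float
    r_donor: float
    n: int
    z_stat: float
    p: float


def correlation_comparison(
    mean_css: pd.Series,
    mean_host: pd.Series,
    mean_donor: pd.Series,
    subset=None,
) -> CorrelationComparison:
    """Does the substitution strain correlate better with the donor parent?

    Pearson correlations are computed on log-transformed group means over
    ``subset`` (default: all shared genes).  The two correlations are
    z-transformed and compared with an independent-samples normal statistic

        z = (atanh(r_donor) - atanh(r_host)) / sqrt(2 / (n - 3))

    with a one-sided p for r(css, donor) > r(css, host).  The correlations
    share the substitution strain's vector, so this is an approximation.
    """
    if subset is None:
        subset = mean_css.index.intersection(mean_host.index).intersection(
            mean_donor.index
        )
    css = mean_css.loc[subset].to_numpy(dtype=float)
    host = mean_host.loc[subset].to_numpy(dtype=float)
    donor = mean_donor.loc[subset].to_numpy(dtype=float)
    n = len(css)
    if n < 4:
        raise ValueError("need at least 4 genes to compare correlations")
    if np.any(css <= 0) or np.any(host <= 0) or np.any(donor <= 0):
        raise ValueError("intensities must be positive for the log transform")
    logs = [np.log(v) for v in (css, host, donor)]
    for v in logs:
        if np.std(v) == 0:
            raise ValueError("zero variance in a log-intensity vector")
    lc, lh, ld = logs
    r_host = float(np.corrcoef(lc, lh)[0, 1])
    r_donor = float(np.corrcoef(lc, ld)[0, 1])
    z = (np.arctanh(r_donor) - np.arctanh(r_host)) / np.sqrt(2.0 / (n - 3))
    p = float(stats.norm.sf(z))
    return CorrelationComparison(r_host, r_donor, n, float(z), p)


def classify_regulatory_type(
    calls: pd.DataFrame,
    mean_css: pd.Series,
    mean_donor: pd.Series,
    band: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Type each significant transcript as cis-regulated vs incompatibility.

    ``calls`` is a call table (needs ``direction``/``significant``) already
    restricted to the donor-derived region of interest.  The convergence
    ratio is mean linear css / mean linear donor; strictly inside
    (1/band, band) means the strain converged to the donor level →
    cis-regulated, otherwise incompatibility.  Returns the per-transcript
    typing and a per-direction summary (n, converged counts, percentages).
    """
    if band <= 1:
        raise ValueError("band must exceed 1")
    sig = calls[calls["significant"]]
    ids = sig.index
    donor = mean_donor.loc[ids].to_numpy(dtype=float)
    if np.any(donor == 0):
        raise ValueError("donor mean intensity of zero")
    ratio = mean_css.loc[ids].to_numpy(dtype=float) / donor
    cis = (ratio > 1.0 / band) & (ratio < band)
    typing = pd.DataFrame(
        {
            "direction": sig["direction"],
            "ratio_css_donor": ratio,
            "reg_type": np.where(cis, TYPE_CIS, TYPE_INCOMPAT),
        },
        index=ids,
    )
    rows = []
    for direction in (DIR_UP, DIR_DOWN):
        sub = typing[typing["direction"] == direction]
        n = len(sub)
        n_cis = int((sub["reg_type"] == TYPE_CIS).sum())
        rows.append(
            {
                "direction": direction,
                "n": n,
                "n_cis": n_cis,
                "pct_cis": frequency_pct(n_cis, n),
                "n_incompatibility": n - n_cis,
                "pct_incompatibility": frequency_pct(n - n_cis, n),
            }
        )
    return typing, pd.DataFrame(rows).set_index("direction")


@dataclass
class OverlapSummary:
    n_a: int
    n_b: int
    n_common: int
    pct_of_b: float
    breakdown_pct: dict[str, float]


def overlap_analysis(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    annotation: pd.DataFrame,
    x_split_bp: int | None = None,
    x_chrom: str = X_CHROM,
) -> OverlapSummary:
    """Intersection of two significant-call sets and its genomic breakdown.

    The headline percentage is 100 * |common| / |set_b|.  The breakdown
    partitions the common set into distal X (at or beyond ``x_split_bp``),
    autosomes, and other (proximal X); it sums to 100% when non-empty.
    """
    if len(calls_a.index.intersection(calls_b.index)) == 0:
        raise ValueError("call tables share no probe sets (disjoint universes)")
    set_a = set(calls_a.index[calls_a["significant"]])
    set_b = set(calls_b.index[calls_b["significant"]])
    common = sorted(set_a & set_b)
    n_common = len(common)
    breakdown: dict[str, float] = {}
    if n_common:
        ann = annotation.loc[common]
        on_x = ann["chrom"].astype(str) == x_chrom
        if x_split_bp is None:
            n_x = int(on_x.sum())
            n_dis = n_x
            n_other = 0
        else:
            n_dis = int((on_x & (ann["pos_bp"] >= x_split_bp)).sum())
            n_other = int(on_x.sum()) - n_dis
        n_auto = n_common - n_dis - n_other
        breakdown = {
            "distal_x_pct": frequency_pct(n_dis, n_common),
            "autosome_pct": frequency_pct(n_auto, n_common),
            "other_pct": frequency_pct(n_other, n_common),
        }
    return OverlapSummary(
        n_a=len(set_a),
        n_b=len(set_b),
        n_common=n_common,
        pct_of_b=round(100.0 * n_common / len(set_b), 1) if set_b else 0.0,
        breakdown_pct=breakdown,
    )


def permutation_correlation_p(
    mean_css: pd.Series,
    mean_host: pd.Series,
    mean_donor: pd.Series,
    n_perm: int = 2000,
    seed: int = 0,
) -> float:
    """Permutation reference for the correlation comparison.

    Under the null that the substitution strain tracks neither parent more
    closely, the (host, donor) value pair of each gene is exchangeable, so
    swapping the two parental strain labels gene-by-gene generates the null
    of r(css, donor) - r(css, host).  Returns the one-sided tail probability
    of the observed difference.  Serves as an assumption-free check on the
    Fisher-z approximation, which ignores that both correlations share the
    substitution strain's vector.
    """
    rng = np.random.default_rng(seed)
    shared = mean_css.index.intersection(mean_host.index).intersection(
        mean_donor.index
    )
    css = np.log(mean_css.loc[shared].to_numpy(dtype=float))
    host = np.log(mean_host.loc[shared].to_numpy(dtype=float))
    donor = np.log(mean_donor.loc[shared].to_numpy(dtype=float))
    n = len(css)

    def corr_diff(h, d):
        return np.corrcoef(css, d)[0, 1] - np.corrcoef(css, h)[0, 1]

    obs = corr_diff(host, donor)
    count = 0
    for _ in range(n_perm):
        swap = rng.random(n) < 0.5
        h = np.where(swap, donor, host)
        d = np.where(swap, host, donor)
        if corr_diff(h, d) >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)
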