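"""Sample-level structure: PCA, restoration typing, top-k ranking tables.

PCA of log2 expression profiles places each sample in a low-dimensional
space where strain groups form clusters; partially restored hybrid
individuals scatter between the host and substitution-strain clusters.  The
restoration caller assigns each such individual to the nearer reference
centroid along the first principal component, with an optional dead-band
margin that keeps ambiguous samples conservatively non-restored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ExpressionMatrix

RESTORED = "restored"
NON_RESTORED = "non_restored"


@dataclass
class PCAResult:
    """Sample scores, per-component % variance explained, and gene loadings."""

    scores: pd.DataFrame          # samples x PC1..PCk
    var_pct: np.ndarray           # length k
    loadings: pd.DataFrame        # genes x PC1..PCk

    def pc1(self) -> pd.Series:
        return self.scores["PC1"]


def pca_samples(expr: ExpressionMatrix, k: int = 3, log: bool = True) -> PCAResult:
    """PCA of samples over gene-centered (log2) expression.

    Deterministic up to sign; the sign of each component is fixed by making
    its first non-zero gene loading non-negative.  ``k`` may not exceed
    n_samples - 1 (the rank bound of the centered matrix).
    """
    n_samples = expr.values.shape[1]
    if k > n_samples - 1:
        raise ValueError(f"k={k} exceeds sample count - 1 ({n_samples - 1})")
    data = expr.log2() if log else expr.values
    x = data.to_numpy(dtype=float).T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for j in range(k):
        load = vt[j]
        nz = np.flatnonzero(np.abs(load) > 1e-12)
        if len(nz) and load[nz[0]] < 0:
            vt[j] = -load
            u[:, j] = -u[:, j]
    scores = u[:, :k] * s[:k]
    total_var = float(np.sum(s**2))
    var_pct = 100.0 * s[:k] ** 2 / total_var if total_var > 0 else np.zeros(k)
    cols = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=data.columns, columns=cols),
        var_pct=var_pct,
        loadings=pd.DataFrame(vt[:k].T, index=data.index, columns=cols),
    )


def assign_restoration(
    pca: PCAResult,
    host_samples: list[str],
    css_samples: list[str],
    f1_samples: list[str],
    margin: float = 0.0,
) -> pd.DataFrame:
    """Nearest-centroid typing of hybrid individuals on PC1.

    A sample is restored iff its PC1 distance to the host centroid is
    smaller than its distance to the substitution-strain centroid by more
    than ``margin`` (score units); anything inside the dead band stays
    non-restored.
    """
    if len(host_samples) < 2 or len(css_samples) < 2:
        raise ValueError("need at least 2 reference samples per group")
    pc1 = pca.pc1()
    host_c = float(pc1.loc[host_samples].mean())
    css_c = float(pc1.loc[css_samples].mean())
    if host_c == css_c:
        raise ValueError("degenerate reference centroids (equal on PC1)")
    rows = []
    for sid in f1_samples:
        v = float(pc1.loc[sid])
        d_host = abs(v - host_c)
        d_css = abs(v - css_c)
        call = RESTORED if d_host < d_css - margin else NON_RESTORED
        rows.append((sid, v, d_host, d_css, call))
    return pd.DataFrame(
        rows, columns=["sample_id", "pc1", "dist_host", "dist_css", "call"]
    ).set_index("sample_id")


def top_k_table(
    calls: pd.DataFrame,
    k: int = 50,
    comparison_fcs: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Top-k significant transcripts ranked by |log2 FC|.

    Ties in |log2 FC| break by adjusted p (ascending) then probe id.  For
    each comparison in ``comparison_fcs`` the same transcripts' fold changes
    are emitted alongside, showing e.g. how far a restored strain's fold
    changes shrink back toward zero.
    """
    sig = calls[calls["significant"]].copy()
    sig["_abs_fc"] = sig["log2_fc"].abs()
    sig = sig.sort_values(
        by=["_abs_fc", "adj_p"], ascending=[False, True], kind="stable"
    )
    # stable sort + index tie-break
    sig["_id"] = sig.index
    sig = sig.sort_values(
        by=["_abs_fc", "adj_p", "_id"], ascending=[False, True, True], kind="stable"
    )
    top = sig.head(k)
    out = pd.DataFrame(
        {
            "rank": np.arange(1, len(top) + 1),
            "log2_fc": top["log2_fc"],
            "adj_p": top["adj_p"],
            "direction": top["direction"],
        },
        index=top.index,
    )
    if comparison_fcs:
        for name, fc in comparison_fcs.items():
            out[f"log2_fc_{name}"] = fc.reindex(top.index)
    return out
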