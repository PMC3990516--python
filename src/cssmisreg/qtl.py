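"""Backcross QTL mapping: single-marker regression and Haley-Knott
interval mapping.

A backcross segregates two genotype classes per locus (host homozygote,
coded 0, and heterozygote, coded 1).  At a marker, the evidence for a QTL
is the regression LOD

    LOD = (n / 2) * log10(RSS0 / RSS1)

comparing the residual sum of squares of the intercept-only model with the
model including genotype.  Between markers, Haley-Knott regression replaces
the unobserved genotype with its conditional expectation given the flanking
marker genotypes under the Haldane (no-interference) map function, scanned
on a fixed-step position grid.  Significance thresholds come from trait
permutations rather than theory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import BackcrossData, haldane

#: Default uniform genetic-map rate when only physical positions are known.
DEFAULT_CM_PER_MB = 0.5


@dataclass
class LODProfile:
    positions_bp: np.ndarray
    lod: np.ndarray
    kind: str  # "single_marker" | "haley_knott"

    @property
    def peak_index(self) -> int:
        return int(np.nanargmax(self.lod))

    @property
    def peak_pos_bp(self) -> float:
        return float(self.positions_bp[self.peak_index])

    @property
    def peak_lod(self) -> float:
        return float(self.lod[self.peak_index])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pos_bp": self.positions_bp, "lod": self.lod})


def _regression_lod(y: np.ndarray, x: np.ndarray) -> float:
    """LOD of the simple regression of y on x, intercept included."""
    n = len(y)
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    if rss0 == 0.0:
        return 0.0
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        return 0.0
    sxy = float(xc @ yc)
    rss1 = rss0 - sxy * sxy / sxx
    rss1 = max(rss1, np.finfo(float).tiny)
    return float(n / 2.0 * np.log10(rss0 / rss1))


def _require_cm(marker_map: pd.DataFrame, cm_per_mb: float) -> np.ndarray:
    if "cm" in marker_map.columns and marker_map["cm"].notna().all():
        return marker_map["cm"].to_numpy(dtype=float)
    return marker_map["pos_bp"].to_numpy(dtype=float) / 1e6 * cm_per_mb


def single_marker_scan(data: BackcrossData, trait: str) -> LODProfile:
    """Per-marker regression LOD; single-genotype-class markers get NaN."""
    y_all = data.traits[trait].to_numpy(dtype=float)
    if not np.all(np.isfinite(y_all)):
        raise ValueError("trait values must be finite")
    if len(y_all) < 10:
        raise ValueError("need at least 10 progeny")
    geno = data.genotypes.to_numpy(dtype=float)
    lods = np.full(geno.shape[1], np.nan)
    for j in range(geno.shape[1]):
        g = geno[:, j]
        keep = ~np.isnan(g)
        if not keep.any():
            raise ValueError(
                f"marker {data.genotypes.columns[j]!r} has no genotypes"
            )
        g_obs = g[keep]
        if np.unique(g_obs).size < 2:
            continue  # uninformative marker: LOD left missing
        lods[j] = _regression_lod(y_all[keep], g_obs)
    return LODProfile(
        positions_bp=data.marker_map["pos_bp"].to_numpy(dtype=float),
        lod=lods,
        kind="single_marker",
    )


def _expected_genotypes(
    geno: np.ndarray, cm: np.ndarray, pos_cm: float, at_marker: int | None
) -> np.ndarray:
    """E[g | flanking genotypes] at one position for every progeny.

    Missing flanks are marginalized by moving outward to the nearest
    informative marker on each side; with no informative flank on one side,
    the position is conditioned on the other side alone; with none at all
    the expectation is the backcross prior 0.5.
    """
    n, m = geno.shape
    out = np.empty(n)
    known = ~np.isnan(geno)
    complete = known.all(axis=1)

    def pair_expectation(gl, gr, r_l, r_r, r_lr):
        # P(a->b) = r if a != b else 1 - r
        p_l1 = np.where(gl == 1, 1 - r_l, r_l)
        p_1r = np.where(gr == 1, 1 - r_r, r_r)
        p_lr = np.where(gl == gr, 1 - r_lr, r_lr)
        return p_l1 * p_1r / p_lr

    # fast path: complete genotypes share flank indices
    left = int(np.searchsorted(cm, pos_cm, side="right") - 1)
    right = left + 1
    if at_marker is not None:
        g = geno[:, at_marker]
        use = complete | known[:, at_marker]
        out[use] = g[use]
    elif left < 0:
        r = haldane(cm[0] - pos_cm)
        g = geno[:, 0]
        out[complete] = np.where(g[complete] == 1, 1 - r, r)
    elif right >= m:
        r = haldane(pos_cm - cm[m - 1])
        g = geno[:, m - 1]
        out[complete] = np.where(g[complete] == 1, 1 - r, r)
    else:
        r_l = haldane(pos_cm - cm[left])
        r_r = haldane(cm[right] - pos_cm)
        r_lr = haldane(cm[right] - cm[left])
        out[complete] = pair_expectation(
            geno[complete, left], geno[complete, right], r_l, r_r, r_lr
        )
    if at_marker is not None:
        handled = complete | known[:, at_marker]
    else:
        handled = complete

    for i in np.flatnonzero(~handled):
        row_known = np.flatnonzero(known[i])
        lefts = row_known[cm[row_known] <= pos_cm]
        rights = row_known[cm[row_known] > pos_cm]
        li = lefts[-1] if len(lefts) else None
        ri = rights[0] if len(rights) else None
        if li is not None and cm[li] == pos_cm:
            out[i] = geno[i, li]
        elif li is None and ri is None:
            out[i] = 0.5
        elif li is None:
            r = haldane(cm[ri] - pos_cm)
            out[i] = (1 - r) if geno[i, ri] == 1 else r
        elif ri is None:
            r = haldane(pos_cm - cm[li])
            out[i] = (1 - r) if geno[i, li] == 1 else r
        else:
            out[i] = pair_expectation(
                geno[i, li],
                geno[i, ri],
                haldane(pos_cm - cm[li]),
                haldane(cm[ri] - pos_cm),
                haldane(cm[ri] - cm[li]),
            )
    return out


def interval_mapping_hk(
    data: BackcrossData,
    trait: str,
    step_bp: float = 1_000_000,
    cm_per_mb: float = DEFAULT_CM_PER_MB,
) -> LODProfile:
    """Haley-Knott regression scan on a fixed-step grid over the marker span.

    The grid always includes the marker positions themselves, so with
    complete genotypes the profile coincides with the single-marker scan at
    those points.  Positions are clipped to the marker span.
    """
    marker_bp = data.marker_map["pos_bp"].to_numpy(dtype=float)
    if len(marker_bp) < 2:
        raise ValueError("interval mapping needs at least 2 markers")
    cm = _require_cm(data.marker_map, cm_per_mb)
    y = data.traits[trait].to_numpy(dtype=float)
    geno = data.genotypes.to_numpy(dtype=float)

    grid = np.arange(marker_bp[0], marker_bp[-1], step_bp)
    grid = np.unique(np.concatenate([grid, marker_bp]))
    # bp -> cM by linear interpolation between markers
    grid_cm = np.interp(grid, marker_bp, cm)
    marker_at = {bp: j for j, bp in enumerate(marker_bp)}

    lods = np.empty(len(grid))
    for gi, (bp, pos_cm) in enumerate(zip(grid, grid_cm)):
        at = marker_at.get(bp)
        xg = _expected_genotypes(geno, cm, pos_cm, at)
        lods[gi] = _regression_lod(y, xg)
    return LODProfile(positions_bp=grid, lod=lods, kind="haley_knott")


def permutation_threshold(
    data: BackcrossData,
    trait: str,
    n_perm: int = 1000,
    quantile: float = 0.95,
    seed: int = 0,
) -> float:
    """Genome-wide LOD threshold: the ``quantile`` of max single-marker LOD
    over trait permutations."""
    rng = np.random.default_rng(seed)
    y = data.traits[trait].to_numpy(dtype=float)
    maxima = np.empty(n_perm)
    shuffled = data.traits.copy()
    for b in range(n_perm):
        shuffled[trait] = rng.permutation(y)
        perm_data = BackcrossData(
            genotypes=data.genotypes,
            marker_map=data.marker_map,
            traits=shuffled,
        )
        maxima[b] = np.nanmax(single_marker_scan(perm_data, trait).lod)
    return float(np.quantile(maxima, quantile))
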