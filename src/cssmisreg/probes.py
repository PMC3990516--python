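"""Probe-set polymorphism scoring and pre-analysis filters.

Short-oligo probe sets mismeasure transcripts whose donor-genome sequence
diverges from the array's reference design: SNPs under a probe suppress
hybridization and fake downregulation.  Each probe set therefore gets a
polymorphism score built from how many of its probes are identified in the
donor genome and how many match it perfectly; probe sets scoring above a
threshold are "polymorphic" and excluded wherever the measured allele is
donor-derived.  Separate filters drop probe sets with unknown chromosome,
Y linkage, location in an undefined strain-boundary region, and low
expression intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ExpressionMatrix, StrainModel, Y_CHROM

#: Probe sets scoring at most this are treated as conserved.
CONSERVED_MAX_SCORE = 10

#: Default per-probe-set probe count on the array family modeled here.
DEFAULT_PROBES_PER_SET = 11

UNKNOWN_CHROMS = ("Un", "unknown", "", "NA")


def polymorphism_score(n_identified, n_perfect, n_total=DEFAULT_PROBES_PER_SET,
                       score_table: np.ndarray | None = None):
    """Score a probe set's divergence from the donor genome.

    With the default linear classifier a probe missing from the donor genome
    costs 3 points and an identified-but-mismatched probe costs 2:

        score = 3 * (n_total - n_identified) + 2 * (n_identified - n_perfect)

    A custom ``score_table`` of shape (n_total+1, n_total+1) may be supplied,
    indexed as ``table[n_identified, n_identified - n_perfect]``; it must be
    monotone in the same sense as the default.  Accepts scalars or arrays.
    """
    n_identified = np.asarray(n_identified)
    n_perfect = np.asarray(n_perfect)
    if np.any(n_perfect < 0) or np.any(n_perfect > n_identified) or np.any(
        n_identified > n_total
    ):
        raise ValueError(
            "counts must satisfy 0 <= n_perfect <= n_identified <= n_total"
        )
    if score_table is not None:
        score_table = np.asarray(score_table)
        if score_table.shape != (n_total + 1, n_total + 1):
            raise ValueError(
                f"score table must be {(n_total + 1, n_total + 1)} for "
                f"{n_total} probes, got {score_table.shape}"
            )
        score = score_table[n_identified, n_identified - n_perfect]
    else:
        score = 3 * (n_total - n_identified) + 2 * (n_identified - n_perfect)
    if np.ndim(score) == 0:
        return int(score)
    return np.asarray(score, dtype=int)


def score_status(score, threshold: int = CONSERVED_MAX_SCORE):
    """Map scores to conserved/polymorphic status (conserved iff <= threshold)."""
    status = np.where(np.asarray(score) <= threshold, "conserved", "polymorphic")
    if np.ndim(score) == 0:
        return str(status)
    return status


@dataclass
class FilterReport:
    """Counts removed by each pre-analysis filter; a partition of the input."""

    total: int
    removed: dict[str, int] = field(default_factory=dict)

    @property
    def retained(self) -> int:
        return self.total - sum(self.removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.total)]
        rows += [(f"removed_{k}", v) for k, v in self.removed.items()]
        rows.append(("retained", self.retained))
        return pd.DataFrame(rows, columns=["filter", "count"])


def apply_region_filters(
    annotation: pd.DataFrame,
    comparison_strains: list[StrainModel],
    unknown_chroms: tuple[str, ...] = UNKNOWN_CHROMS,
    y_chrom: str = Y_CHROM,
) -> tuple[pd.Series, FilterReport]:
    """Location- and polymorphism-based exclusion for one strain comparison.

    Removes probe sets that (in this order of attribution) have an unknown
    chromosome, are Y-linked, fall in an undefined boundary interval of
    either compared strain, or are polymorphic-status and located inside a
    donor-derived (homozygous or heterozygous) interval of either strain.
    Conserved probe sets are kept regardless of location; polymorphic probe
    sets outside any donor interval of the compared strains are also kept
    (both alleles there are host-type, so mishybridization cannot differ
    between the strains).

    ``annotation`` needs columns ``chrom``, ``pos_bp`` and ``status``.
    Returns a boolean retained mask aligned to the annotation plus a report.
    """
    required = {"chrom", "pos_bp", "status"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    if annotation["pos_bp"].isna().any():
        bad = annotation.index[annotation["pos_bp"].isna()][0]
        raise ValueError(f"probe set {bad!r} has no location record")

    chrom = annotation["chrom"].astype(str)
    pos = annotation["pos_bp"].to_numpy()

    unknown = chrom.isin(unknown_chroms) | chrom.isna()
    y_linked = (chrom == y_chrom) & ~unknown

    def _in_zone(intervals) -> np.ndarray:
        m = np.zeros(len(annotation), dtype=bool)
        for iv in intervals:
            m |= (chrom == iv.chrom).to_numpy() & (pos >= iv.start) & (pos <= iv.end)
        return m

    boundary = np.zeros(len(annotation), dtype=bool)
    donor = np.zeros(len(annotation), dtype=bool)
    for strain in comparison_strains:
        boundary |= _in_zone(strain.boundary_intervals)
        donor |= _in_zone(strain.donor_intervals)
    boundary &= ~(unknown | y_linked).to_numpy()

    polymorphic = (annotation["status"] == "polymorphic").to_numpy()
    poly_in_donor = polymorphic & donor & ~(unknown | y_linked).to_numpy() & ~boundary

    removed_any = unknown.to_numpy() | y_linked.to_numpy() | boundary | poly_in_donor
    retained = pd.Series(~removed_any, index=annotation.index, name="retained")
    report = FilterReport(
        total=len(annotation),
        removed={
            "unknown_chromosome": int(unknown.sum()),
            "y_linked": int(y_linked.sum()),
            "boundary_region": int(boundary.sum()),
            "polymorphic_in_donor_region": int(poly_in_donor.sum()),
        },
    )
    return retained, report


def intensity_filter(
    expr: ExpressionMatrix,
    strain_a: str,
    strain_b: str,
    threshold: float = 10.0,
    age_dpp: int | None = None,
) -> pd.Series:
    """Keep probe sets whose mean linear intensity exceeds ``threshold``
    (strictly) in at least one of the two compared strains."""
    mean_a = expr.group_mean(strain_a, age_dpp)
    mean_b = expr.group_mean(strain_b, age_dpp)
    mask = (mean_a > threshold) | (mean_b > threshold)
    mask.name = "retained"
    return mask
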