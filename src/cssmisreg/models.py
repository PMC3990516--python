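"""Core data containers shared across the analysis stages.

The analysis revolves around three kinds of objects: a genome layout
(chromosome sizes and gene positions), strain genome compositions
(which intervals of which chromosomes derive from the donor subspecies),
and an expression matrix (probe sets x samples, linear-scale normalized
intensities) carrying its sample metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

X_CHROM = "X"
Y_CHROM = "Y"

ZONE_DONOR = "donor"
ZONE_BOUNDARY = "boundary"
ZYG_HOM = "homozygous"
ZYG_HET = "heterozygous"


@dataclass(frozen=True)
class Interval:
    """A closed genomic interval (1-based, inclusive endpoints) with a zone label.

    ``zone`` is ``"donor"`` for donor-derived segments or ``"boundary"`` for
    the undefined recombination-boundary segments that flank them; donor
    intervals additionally carry a zygosity.
    """

    chrom: str
    start: int
    end: int
    zone: str = ZONE_DONOR
    zygosity: str = ZYG_HOM

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.zone not in (ZONE_DONOR, ZONE_BOUNDARY):
            raise ValueError(f"unknown zone label {self.zone!r}")
        if self.zygosity not in (ZYG_HOM, ZYG_HET):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class StrainModel:
    """Genome composition of one strain.

    A strain is the host background everywhere except in its listed donor
    intervals; boundary intervals mark regions where the genotype is
    undefined (and get excluded from analysis).  ``donor_background`` marks
    the pure donor parent itself, whose whole genome — including its
    trans-acting factors — is donor-derived, so no incompatibility arises.
    """

    name: str
    intervals: list[Interval] = field(default_factory=list)
    donor_background: bool = False

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs = sorted(ivs, key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"strain {self.name}: overlapping intervals on {chrom}: "
                        f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                    )

    def _zone_intervals(self, zone: str) -> list[Interval]:
        return [iv for iv in self.intervals if iv.zone == zone]

    @property
    def donor_intervals(self) -> list[Interval]:
        return self._zone_intervals(ZONE_DONOR)

    @property
    def boundary_intervals(self) -> list[Interval]:
        return self._zone_intervals(ZONE_BOUNDARY)

    def in_donor(self, chrom: str, pos: int) -> bool:
        return any(iv.contains(chrom, pos) for iv in self.donor_intervals)

    def in_boundary(self, chrom: str, pos: int) -> bool:
        return any(iv.contains(chrom, pos) for iv in self.boundary_intervals)

    def donor_zygosity(self, chrom: str, pos: int) -> str | None:
        for iv in self.donor_intervals:
            if iv.contains(chrom, pos):
                return iv.zygosity
        return None


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome sizes plus gene (probe set) positions.

    ``chromosomes`` maps name -> length in bp; ``genes`` is a frame indexed by
    gene id with columns ``chrom`` and ``pos_bp`` (1-based).
    """

    chromosomes: dict[str, int]
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.genes.index.is_unique:
            dup = self.genes.index[self.genes.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        for gid, row in self.genes.iterrows():
            length = self.chromosomes.get(row["chrom"])
            if length is None:
                raise ValueError(f"gene {gid!r} on unknown chromosome {row['chrom']!r}")
            if not 1 <= row["pos_bp"] <= length:
                raise ValueError(
                    f"gene {gid!r} position {row['pos_bp']} outside {row['chrom']} "
                    f"(length {length})"
                )

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.chromosomes if c not in (X_CHROM, Y_CHROM)]


class ExpressionMatrix:
    """Linear-scale probe-set intensities with per-sample metadata.

    ``values`` is probe sets x samples; ``samples`` is indexed by sample id
    with columns ``strain``, ``age_dpp`` and ``replicate``.  Intensities must
    be positive and finite (the statistics all operate on log2 values).
    """

    def __init__(self, values: pd.DataFrame, samples: pd.DataFrame) -> None:
        if not values.index.is_unique:
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate probe set id {dup!r}")
        missing = set(values.columns) - set(samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        arr = values.to_numpy(dtype=float)
        if arr.size and (not np.all(np.isfinite(arr)) or (arr <= 0).any()):
            raise ValueError("intensities must be positive and finite")
        self.values = values
        self.samples = samples.loc[list(values.columns)]

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    def sample_ids(self, strain: str | None = None, age_dpp: int | None = None) -> list[str]:
        meta = self.samples
        mask = pd.Series(True, index=meta.index)
        if strain is not None:
            mask &= meta["strain"] == strain
        if age_dpp is not None and "age_dpp" in meta.columns:
            mask &= meta["age_dpp"] == age_dpp
        return list(meta.index[mask])

    def group_values(self, strain: str, age_dpp: int | None = None) -> pd.DataFrame:
        ids = self.sample_ids(strain, age_dpp)
        if not ids:
            raise ValueError(f"no samples for strain {strain!r} (age {age_dpp})")
        return self.values[ids]

    def group_mean(self, strain: str, age_dpp: int | None = None) -> pd.Series:
        """Mean linear intensity over the strain's replicates."""
        return self.group_values(strain, age_dpp).mean(axis=1)

    def log2(self) -> pd.DataFrame:
        return np.log2(self.values)

    def subset(self, probe_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[probe_ids], self.samples)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({self.values.shape[0]} probe sets x "
            f"{self.values.shape[1]} samples)"
        )


def host_strain(name: str = "B6") -> StrainModel:
    """The host background strain: no donor intervals."""
    return StrainModel(name=name)


def donor_strain(layout: GenomeLayout, name: str = "MSM") -> StrainModel:
    """The pure donor parent: every chromosome is donor-derived."""
    ivs = [
        Interval(chrom, 1, length, ZONE_DONOR, ZYG_HOM)
        for chrom, length in layout.chromosomes.items()
    ]
    return StrainModel(name=name, intervals=ivs, donor_background=True)


def substitution_strain(
    layout: GenomeLayout,
    name: str,
    chrom: str,
    start: int = 1,
    end: int | None = None,
    zygosity: str = ZYG_HOM,
    boundary_bp: int = 0,
) -> StrainModel:
    """A consomic/congenic strain carrying one donor interval.

    ``boundary_bp`` adds undefined-genotype flanks of that width just outside
    the donor interval (clipped to the chromosome), mimicking the imprecise
    recombination boundaries of real substitution strains.
    """
    length = layout.chromosomes[chrom]
    if end is None:
        end = length
    ivs = [Interval(chrom, start, end, ZONE_DONOR, zygosity)]
    if boundary_bp > 0:
        if start > 1:
            ivs.append(
                Interval(chrom, max(1, start - boundary_bp), start - 1, ZONE_BOUNDARY)
            )
        if end < length:
            ivs.append(
                Interval(chrom, end + 1, min(length, end + boundary_bp), ZONE_BOUNDARY)
            )
    return StrainModel(name=name, intervals=ivs)
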