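"""Synthetic study generator with known ground truth.

Generates everything the analysis consumes: a genome layout, a regulatory
architecture (which genes are conserved between the host and donor
subspecies, which diverge in cis, which misfire through a cis/trans
incompatibility in the hybrid context), expression studies for a set of
strains, probe-set polymorphism annotations, and a backcross population for
QTL mapping.

The expression model is multiplicative: every quantity is modeled in log2
units and exponentiated, so stored intensities are linear-scale (matching
the raw-intensity expression filter) while all statistics downstream operate
on log2 values.  For a gene with baseline log2 level b in a strain s:

* conserved genes sit at b everywhere;
* cis-divergent genes sit at b + cis_effect wherever the locus is
  donor-derived (in the donor parent and inside donor intervals of
  substitution strains) — the shifted level is the donor's own level, so the
  substitution strain tracks the donor parent;
* trans-incompatible genes sit at b in both parents but at
  b + incompatibility_effect inside donor intervals of substitution strains
  (donor cis-elements meeting host trans-factors), matching neither parent;
* cascade targets (autosomal genes perturbed downstream of the primary
  misregulation) shift by an incompatibility-type effect in substitution
  strains only when cascade mode is on, emulating the genome-wide spread of
  misregulation at the later time point.

Heterozygous donor intervals contribute half the log2 effect (additive
dosage).  Incompatibility effect magnitudes follow a shifted folded normal
with a Bernoulli sign that is negative with the configured downregulation
probability, reproducing the observed downregulation bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import (
    ExpressionMatrix,
    GenomeLayout,
    StrainModel,
    X_CHROM,
    ZYG_HET,
)

CLASS_CONSERVED = "conserved"
CLASS_CIS = "cis_divergent"
CLASS_INCOMPAT = "trans_incompatible"
CLASS_CASCADE = "cascade_target"

#: mm9-flavoured chromosome lengths: autosomes shrink from chr1 to chr19.
_CHR1_BP = 197_000_000
_CHR_LAST_BP = 61_000_000
_X_BP = 166_650_000


def generate_genome(
    n_autosomes: int, genes_per_chromosome: int, seed: int
) -> GenomeLayout:
    """Lay out ``n_autosomes`` autosomes plus one X with uniform gene positions."""
    if n_autosomes < 1 or genes_per_chromosome < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    chroms: dict[str, int] = {}
    for i in range(n_autosomes):
        frac = i / max(1, n_autosomes - 1)
        chroms[str(i + 1)] = int(_CHR1_BP - frac * (_CHR1_BP - _CHR_LAST_BP))
    chroms[X_CHROM] = _X_BP
    records = []
    for chrom, length in chroms.items():
        pos = np.sort(rng.integers(1, length + 1, size=genes_per_chromosome))
        for j, p in enumerate(pos):
            records.append((f"ps_{chrom}_{j:04d}_at", chrom, int(p)))
    genes = pd.DataFrame(records, columns=["gene_id", "chrom", "pos_bp"]).set_index(
        "gene_id"
    )
    return GenomeLayout(chromosomes=chroms, genes=genes)


@dataclass(frozen=True)
class EffectLaw:
    """Shifted folded-normal magnitude with a Bernoulli sign.

    magnitude = shift + |N(0, spread)|, sign negative with probability
    ``down_prob``.  Log2 units.
    """

    shift: float
    spread: float
    down_prob: float

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        mag = self.shift + np.abs(rng.normal(0.0, self.spread, size=n))
        sign = np.where(rng.random(n) < self.down_prob, -1.0, 1.0)
        return sign * mag


@dataclass
class RegulatoryArchitecture:
    """Per-gene regulatory class and realized log2 effects.

    ``table`` is indexed by gene id with columns ``reg_class``,
    ``effect_log2`` (the realized signed shift the class implies in a
    substitution-strain context; 0 for conserved) and ``direction``.
    """

    table: pd.DataFrame
    incompat_down_prob: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.incompat_down_prob <= 1.0:
            raise ValueError("downregulation probability must be in [0, 1]")

    def classes(self) -> pd.Series:
        return self.table["reg_class"]


def assign_architecture(
    layout: GenomeLayout,
    *,
    target_chrom: str = X_CHROM,
    target_start: int = 1,
    target_end: int | None = None,
    cis_frac: float = 0.09,
    incompat_frac: float = 0.12,
    cascade_frac: float = 0.05,
    cis_law: EffectLaw = EffectLaw(shift=0.8, spread=0.4, down_prob=0.35),
    incompat_law: EffectLaw = EffectLaw(shift=1.0, spread=0.5, down_prob=0.7),
    seed: int = 0,
) -> RegulatoryArchitecture:
    """Assign regulatory classes to genes.

    Genes inside the target region (the substituted chromosome segment) are
    cis-divergent with probability ``cis_frac``, trans-incompatible with
    probability ``incompat_frac`` and conserved otherwise — roughly 20%
    misexpressed at the defaults, with the observed downregulation bias.
    Autosomal genes outside the target become cascade targets with
    probability ``cascade_frac``.
    """
    if cis_frac < 0 or incompat_frac < 0 or cis_frac + incompat_frac > 1:
        raise ValueError("class fractions must be non-negative and sum to <= 1")
    if not 0 <= cascade_frac <= 1:
        raise ValueError("cascade_frac must be in [0, 1]")
    if target_end is None:
        target_end = layout.chromosomes[target_chrom]
    rng = np.random.default_rng(seed)
    genes = layout.genes
    n = len(genes)
    reg_class = np.full(n, CLASS_CONSERVED, dtype=object)
    in_target = (
        (genes["chrom"] == target_chrom).to_numpy()
        & (genes["pos_bp"].to_numpy() >= target_start)
        & (genes["pos_bp"].to_numpy() <= target_end)
    )
    u = rng.random(n)
    reg_class[in_target & (u < cis_frac)] = CLASS_CIS
    reg_class[
        in_target & (u >= cis_frac) & (u < cis_frac + incompat_frac)
    ] = CLASS_INCOMPAT
    autosomal = (genes["chrom"] != target_chrom).to_numpy()
    reg_class[autosomal & (rng.random(n) < cascade_frac)] = CLASS_CASCADE

    effect = np.zeros(n)
    for cls, law in (
        (CLASS_CIS, cis_law),
        (CLASS_INCOMPAT, incompat_law),
        (CLASS_CASCADE, incompat_law),
    ):
        mask = reg_class == cls
        effect[mask] = law.draw(rng, int(mask.sum()))
    direction = np.where(
        reg_class == CLASS_CONSERVED, "none", np.where(effect < 0, "down", "up")
    )
    table = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "pos_bp": genes["pos_bp"],
            "reg_class": reg_class,
            "effect_log2": effect,
            "direction": direction,
        },
        index=genes.index,
    )
    return RegulatoryArchitecture(table=table, incompat_down_prob=incompat_law.down_prob)


@dataclass
class SimulationConfig:
    """Knobs of the expression simulator.

    All log2 units.  Three replicates per strain mirrors the study design
    (three mice per strain and time point); baseline levels give linear
    intensities mostly in the 10-10000 range so the >10 intensity filter
    retains most genes; cascade mode turns on the autosomal cascade targets
    (the later, 7 dpp-like epoch).
    """

    replicates: int = 3
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.8
    noise_sd: float = 0.2
    noise_sd_df: float | None = None
    cascade: bool = False
    age_dpp: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.baseline_log2_sd <= 0 or self.noise_sd <= 0:
            raise ValueError("spread parameters must be > 0")
        if self.noise_sd_df is not None and self.noise_sd_df <= 0:
            raise ValueError("noise_sd_df must be > 0 when given")


def _strain_log2_means(
    layout: GenomeLayout,
    architecture: RegulatoryArchitecture,
    strain: StrainModel,
    baseline: np.ndarray,
    cascade: bool,
) -> np.ndarray:
    """Expected log2 level of every gene in one strain (no replicate noise)."""
    tab = architecture.table
    chrom = tab["chrom"].to_numpy()
    pos = tab["pos_bp"].to_numpy()
    cls = tab["reg_class"].to_numpy()
    eff = tab["effect_log2"].to_numpy()

    dosage = np.zeros(len(tab))  # donor dosage at the locus: 0, 0.5, or 1
    for iv in strain.donor_intervals:
        inside = (chrom == iv.chrom) & (pos >= iv.start) & (pos <= iv.end)
        dosage[inside] = 0.5 if iv.zygosity == ZYG_HET else 1.0

    mu = baseline.copy()
    cis = cls == CLASS_CIS
    mu[cis] += dosage[cis] * eff[cis]
    if not strain.donor_background:
        is_sub = bool(strain.donor_intervals)
        inc = cls == CLASS_INCOMPAT
        mu[inc] += dosage[inc] * eff[inc]
        if cascade and is_sub:
            cas = cls == CLASS_CASCADE
            mu[cas] += eff[cas]
    return mu


def generate_expression_study(
    layout: GenomeLayout,
    architecture: RegulatoryArchitecture,
    strains: list[StrainModel],
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate linear-scale intensities for all strains plus the truth table.

    The truth table records, per gene, the regulatory class and the realized
    direction of its shift in a substitution-strain context (cascade targets
    count only when cascade mode is on).
    """
    rng = np.random.default_rng(config.seed)
    genes = layout.genes
    n = len(genes)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    if config.noise_sd_df is None:
        gene_sd = np.full(n, config.noise_sd)
    else:
        # per-gene replicate noise: scaled-inverse-chi-square variances around
        # noise_sd^2 with noise_sd_df prior df (genes differ in variability)
        d = config.noise_sd_df
        gene_sd = config.noise_sd * np.sqrt(d / rng.chisquare(d, size=n))

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for strain in strains:
        mu = _strain_log2_means(layout, architecture, strain, baseline, config.cascade)
        for r in range(1, config.replicates + 1):
            sid = f"{strain.name}_{config.age_dpp}dpp_r{r}"
            noise = gene_sd * rng.standard_normal(n)
            columns[sid] = np.exp2(mu + noise)
            meta_rows.append((sid, strain.name, config.age_dpp, r))

    values = pd.DataFrame(columns, index=genes.index)
    samples = pd.DataFrame(
        meta_rows, columns=["sample_id", "strain", "age_dpp", "replicate"]
    ).set_index("sample_id")
    expr = ExpressionMatrix(values, samples)

    truth = architecture.table.copy()
    if not config.cascade:
        cas = truth["reg_class"] == CLASS_CASCADE
        truth.loc[cas, "direction"] = "none"
    return expr, truth


def generate_probe_annotation(
    layout: GenomeLayout,
    strains: list[StrainModel],
    poly_rate_donor: float,
    poly_rate_host: float,
    probes_per_set: int = 11,
    seed: int = 0,
    unidentified_given_poly: float = 0.4,
) -> pd.DataFrame:
    """Simulate per-probe-set polymorphism counts.

    Each of the ``probes_per_set`` probes of a probe set is polymorphic
    against the donor genome with probability ``poly_rate_donor`` when the
    locus lies in a donor (or heterozygous donor) interval of any strain and
    ``poly_rate_host`` elsewhere.  A polymorphic probe fails to be identified
    in the donor genome with probability ``unidentified_given_poly``,
    otherwise it is identified but mismatched; only non-polymorphic probes
    match perfectly.  Scores/status come from
    :func:`cssmisreg.probes.polymorphism_score`.
    """
    from .probes import polymorphism_score, score_status

    for name, rate in (("poly_rate_donor", poly_rate_donor), ("poly_rate_host", poly_rate_host)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if probes_per_set < 1:
        raise ValueError("probes_per_set must be >= 1")
    rng = np.random.default_rng(seed)
    genes = layout.genes
    chrom = genes["chrom"].to_numpy()
    pos = genes["pos_bp"].to_numpy()
    # divergence enrichment follows the substituted segments; the pure donor
    # parent (whole genome donor-derived) does not define a "donor region"
    in_donor = np.zeros(len(genes), dtype=bool)
    for strain in strains:
        if strain.donor_background:
            continue
        for iv in strain.donor_intervals:
            in_donor |= (chrom == iv.chrom) & (pos >= iv.start) & (pos <= iv.end)
    rate = np.where(in_donor, poly_rate_donor, poly_rate_host)

    poly = rng.random((len(genes), probes_per_set)) < rate[:, None]
    unident = poly & (
        rng.random((len(genes), probes_per_set)) < unidentified_given_poly
    )
    n_identified = probes_per_set - unident.sum(axis=1)
    n_perfect = probes_per_set - poly.sum(axis=1)
    score = polymorphism_score(n_identified, n_perfect, probes_per_set)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos_bp": pos,
            "n_probes_total": probes_per_set,
            "n_identified": n_identified,
            "n_perfect": n_perfect,
            "polymorphism_score": score,
            "status": score_status(score),
        },
        index=genes.index,
    )


def generate_f1_cohort(
    expr: ExpressionMatrix,
    host: str,
    css: str,
    n_restored: int = 3,
    n_non_restored: int = 5,
    noise_sd: float = 0.2,
    seed: int = 0,
    age_dpp: int | None = None,
    name: str = "F1",
    restored_lambda: float = 0.15,
    non_restored_lambda: float = 0.85,
) -> ExpressionMatrix:
    """Build partially restored F1-like individuals between two profiles.

    Each individual's log2 profile is host + lambda * (css - host) + noise,
    with lambda small for restored individuals (expression pulled back to the
    host state) and near 1 for non-restored ones.  Returns a new matrix with
    the original samples plus the cohort; the cohort strain label is
    ``name`` and sample ids end in ``_ra``/``_nb`` for restored/non-restored.
    """
    rng = np.random.default_rng(seed)
    log_host = np.log2(expr.group_mean(host, age_dpp)).to_numpy()
    log_css = np.log2(expr.group_mean(css, age_dpp)).to_numpy()
    delta = log_css - log_host

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    age = age_dpp if age_dpp is not None else int(expr.samples["age_dpp"].iloc[0])
    letters = "abcdefghijklmnopqrstuvwxyz"
    for i in range(n_restored + n_non_restored):
        restored = i < n_restored
        lam = restored_lambda if restored else non_restored_lambda
        tag = "r" if restored else "n"
        sid = f"{name}_{age}dpp_{tag}{letters[i]}"
        noise = rng.normal(0.0, noise_sd, size=len(delta))
        cols[sid] = np.exp2(log_host + lam * delta + noise)
        meta_rows.append((sid, name, age, i + 1))

    values = pd.concat([expr.values, pd.DataFrame(cols, index=expr.values.index)], axis=1)
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "strain", "age_dpp", "replicate"]
    ).set_index("sample_id")
    samples = pd.concat([expr.samples, meta])
    return ExpressionMatrix(values, samples)


@dataclass
class BackcrossData:
    """A backcross mapping population.

    ``genotypes``: progeny x markers, coded 0 (host homozygote) or
    1 (heterozygote), NaN for missing.  ``marker_map``: per marker, chrom,
    bp and cM positions.  ``traits``: per progeny quantitative traits.
    """

    genotypes: pd.DataFrame
    marker_map: pd.DataFrame
    traits: pd.DataFrame
    qtl_truth: dict | None = None

    def __post_init__(self) -> None:
        g = self.genotypes.to_numpy(dtype=float)
        ok = np.isnan(g) | (g == 0) | (g == 1)
        if not ok.all():
            raise ValueError("genotypes must be 0, 1 or missing")
        pos = self.marker_map["pos_bp"].to_numpy()
        if not (np.diff(pos) > 0).all():
            raise ValueError("markers must be sorted by position")


def haldane(d_cm):
    """Haldane map function: recombination fraction for a distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def generate_backcross(
    n_progeny: int = 314,
    n_markers: int = 80,
    chrom_length_bp: int = 197_000_000,
    cm_per_mb: float = 0.5,
    qtl_pos_bp: int = 64_500_000,
    qtl_effect: float = 20.0,
    residual_sd: float = 20.0,
    seed: int = 0,
    chrom: str = "1",
    intercept: float = 170.0,
    trait_name: str = "testis_weight_mg",
) -> BackcrossData:
    """Simulate a backcross with one planted QTL.

    Markers are evenly spaced across the chromosome; genotypes follow a
    Markov walk with Haldane recombination fractions between adjacent loci
    (the QTL position is simulated as an extra hidden locus); the trait is
    intercept + qtl_effect * genotype(QTL) + N(0, residual_sd).  The default
    numbers mirror the mapped cross: 314 male progeny, 80 SNP markers on
    chromosome 1, a QTL in the 40-80 Mb region.
    """
    if n_progeny < 1 or n_markers < 2:
        raise ValueError("need >= 1 progeny and >= 2 markers")
    if not 0 <= qtl_pos_bp <= chrom_length_bp:
        raise ValueError("QTL position outside the chromosome")
    rng = np.random.default_rng(seed)
    marker_bp = np.linspace(1_000_000, chrom_length_bp, n_markers).round().astype(int)
    loci_bp = np.unique(np.append(marker_bp, qtl_pos_bp))
    qtl_idx = int(np.searchsorted(loci_bp, qtl_pos_bp))
    cm = loci_bp / 1e6 * cm_per_mb
    r = haldane(np.diff(cm))

    geno = np.empty((n_progeny, len(loci_bp)), dtype=int)
    geno[:, 0] = rng.random(n_progeny) < 0.5
    for j in range(1, len(loci_bp)):
        flip = rng.random(n_progeny) < r[j - 1]
        geno[:, j] = np.where(flip, 1 - geno[:, j - 1], geno[:, j - 1])

    qtl_geno = geno[:, qtl_idx]
    trait = intercept + qtl_effect * qtl_geno + rng.normal(0.0, residual_sd, n_progeny)

    keep = np.isin(loci_bp, marker_bp)
    marker_ids = [f"m{chrom}_{i + 1:03d}" for i in range(keep.sum())]
    progeny_ids = [f"bc_{i + 1:04d}" for i in range(n_progeny)]
    genotypes = pd.DataFrame(geno[:, keep], index=progeny_ids, columns=marker_ids)
    marker_map = pd.DataFrame(
        {"chrom": chrom, "pos_bp": loci_bp[keep], "cm": cm[keep]}, index=marker_ids
    )
    traits = pd.DataFrame({trait_name: trait}, index=progeny_ids)
    return BackcrossData(
        genotypes=genotypes,
        marker_map=marker_map,
        traits=traits,
        qtl_truth={"pos_bp": qtl_pos_bp, "effect": qtl_effect, "genotype": qtl_geno},
    )
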