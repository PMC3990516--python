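"""End-to-end pipeline: simulate -> filter -> DE -> dispersion -> classify
-> PCA/restoration -> QTL, from a single config, with reproducible seeds.

The pipeline emulates a two-time-point chromosome-substitution study: an
early epoch where misregulation is confined to the donor-derived region and
a later epoch where cascade effects spread it genome-wide.  Every stage
writes its table under the output directory and logs row counts; a manifest
records the seed, thresholds and package version so a run can be
reproduced bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, classify, de, dispersion, io, probes, qtl, structure
from . import synthetic as syn
from .models import X_CHROM, donor_strain, host_strain, substitution_strain

log = logging.getLogger("cssmisreg")


@dataclass
class RunConfig:
    """Everything a full synthetic-study run needs.

    Thresholds carry the study's printed defaults: intensity > 10,
    fold change >= 1.5, alpha 0.05, polymorphism score <= 10 conserved,
    convergence band 1.5, intensity strata 10/100/1000, X split at the
    distal-donor boundary.
    """

    seed: int = 1
    # simulation
    n_autosomes: int = 19
    genes_per_chromosome: int = 150
    replicates: int = 3
    noise_sd: float = 0.2
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.8
    cis_frac: float = 0.09
    incompat_frac: float = 0.12
    cascade_frac: float = 0.05
    poly_rate_donor: float = 0.12
    poly_rate_host: float = 0.01
    host: str = "B6"
    donor: str = "MSM"
    css: str = "CSSX"
    css_chrom: str = X_CHROM
    css_start: int = 1
    css_end: int | None = None
    #: second substitution strain carrying only the distal donor segment
    #: (from x_split_bp to the chromosome end); "" disables it
    css_partial: str = "CSSXT"
    boundary_bp: int = 2_000_000
    ages: tuple[int, int] = (5, 7)
    f1_restored: int = 3
    f1_non_restored: int = 5
    # thresholds
    intensity_threshold: float = 10.0
    fc_threshold: float = 1.5
    alpha: float = 0.05
    poly_score_max: int = 10
    band: float = 1.5
    strata: tuple[float, ...] = dispersion.DEFAULT_STRATA
    x_split_bp: int = de.DEFAULT_X_SPLIT_BP
    # QTL
    qtl_progeny: int = 314
    qtl_markers: int = 80
    qtl_pos_bp: int = 64_500_000
    qtl_effect: float = 20.0
    qtl_residual_sd: float = 20.0
    qtl_step_bp: float = 1_000_000
    comparisons: list = field(default_factory=list)  # populated at run time


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    if isinstance(cfg.ages, list):
        cfg.ages = tuple(cfg.ages)
    if isinstance(cfg.strata, list):
        cfg.strata = tuple(cfg.strata)
    return cfg


def validate_config(config: RunConfig) -> list[str]:
    """All violations, none silently corrected."""
    errors = []
    for name in ("intensity_threshold", "fc_threshold", "band"):
        if getattr(config, name) <= 0:
            errors.append(f"{name} must be positive")
    if not 0 <= config.alpha <= 1:
        errors.append("alpha must be in [0, 1]")
    for name in ("poly_rate_donor", "poly_rate_host"):
        if not 0 <= getattr(config, name) <= 1:
            errors.append(f"{name} must be in [0, 1]")
    if config.n_autosomes < 1 or config.genes_per_chromosome < 1:
        errors.append("genome counts must be >= 1")
    if config.replicates < 2:
        errors.append("need >= 2 replicates per strain for the moderated t")
    names = [config.host, config.donor, config.css]
    if config.css_partial:
        names.append(config.css_partial)
    if len(set(names)) < len(names):
        errors.append("host, donor and substitution strain names must differ")
    if list(config.strata) != sorted(config.strata):
        errors.append("strata must be ascending")
    if config.qtl_progeny < 10:
        errors.append("qtl_progeny must be >= 10")
    return errors


def _spawn_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage and write the report bundle under ``outdir``.

    Returns the in-memory results keyed by stage.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(config.seed, 8)
    results: dict = {}

    # --- simulate -------------------------------------------------------
    layout = syn.generate_genome(
        config.n_autosomes, config.genes_per_chromosome, seed=seeds[0]
    )
    css_end = config.css_end or layout.chromosomes[config.css_chrom]
    arch = syn.assign_architecture(
        layout,
        target_chrom=config.css_chrom,
        target_start=config.css_start,
        target_end=css_end,
        cis_frac=config.cis_frac,
        incompat_frac=config.incompat_frac,
        cascade_frac=config.cascade_frac,
        seed=seeds[1],
    )
    strains = [
        host_strain(config.host),
        donor_strain(layout, config.donor),
        substitution_strain(
            layout,
            config.css,
            config.css_chrom,
            config.css_start,
            css_end if css_end < layout.chromosomes[config.css_chrom] else None,
            boundary_bp=config.boundary_bp,
        ),
    ]
    if config.css_partial:
        strains.append(
            substitution_strain(
                layout,
                config.css_partial,
                config.css_chrom,
                config.x_split_bp,
                None,
                boundary_bp=config.boundary_bp,
            )
        )
    annotation = syn.generate_probe_annotation(
        layout,
        strains,
        config.poly_rate_donor,
        config.poly_rate_host,
        seed=seeds[2],
    )
    io.write_probe_annotation(annotation, outdir / "probe_annotation.tsv")
    io.write_strain_composition(strains, outdir / "strain_composition.tsv")
    log.info("simulated %d genes over %d chromosomes", len(layout.genes),
             len(layout.chromosomes))

    counts: list[tuple[str, int]] = [("genes", len(layout.genes))]
    expr_by_age: dict[int, syn.ExpressionMatrix] = {}
    de_by_age: dict[int, pd.DataFrame] = {}
    de_partial_by_age: dict[int, pd.DataFrame] = {}
    freq_by_age: dict[int, pd.DataFrame] = {}
    truth_by_age: dict[int, pd.DataFrame] = {}

    retained_region, report = probes.apply_region_filters(annotation, strains)
    report.to_frame().to_csv(outdir / "filter_report.tsv", sep="\t", index=False)

    for i, age in enumerate(config.ages):
        sim_cfg = syn.SimulationConfig(
            replicates=config.replicates,
            baseline_log2_mean=config.baseline_log2_mean,
            baseline_log2_sd=config.baseline_log2_sd,
            noise_sd=config.noise_sd,
            cascade=(i > 0),  # cascade mode is the later epoch
            age_dpp=age,
            seed=seeds[3] + i,
        )
        expr, truth = syn.generate_expression_study(layout, arch, strains, sim_cfg)
        truth_by_age[age] = truth
        io.write_expression(
            expr,
            outdir / f"expression_{age}dpp.tsv",
            outdir / f"samples_{age}dpp.tsv",
        )
        truth.to_csv(outdir / f"truth_{age}dpp.tsv", sep="\t", float_format="%.6g")

        # --- filter -----------------------------------------------------
        retained_int = probes.intensity_filter(
            expr, config.css, config.host, config.intensity_threshold, age
        )
        keep = retained_region & retained_int
        expr_f = expr.subset(keep.index[keep])
        counts.append((f"retained_{age}dpp", expr_f.values.shape[0]))
        log.info("%d dpp: %d probe sets retained after filtering", age,
                 expr_f.values.shape[0])
        expr_by_age[age] = expr_f

        # --- DE ---------------------------------------------------------
        calls = de.de_table(
            expr_f, config.css, config.host, age,
            fc_threshold=config.fc_threshold, alpha=config.alpha,
        )
        de_by_age[age] = calls
        io.write_table(calls, outdir / f"de_{config.css}_vs_{config.host}_{age}dpp.tsv")

        if config.css_partial:
            retained_int2 = probes.intensity_filter(
                expr, config.css_partial, config.host,
                config.intensity_threshold, age,
            )
            keep2 = retained_region & retained_int2
            expr_f2 = expr.subset(keep2.index[keep2])
            calls2 = de.de_table(
                expr_f2, config.css_partial, config.host, age,
                fc_threshold=config.fc_threshold, alpha=config.alpha,
            )
            de_partial_by_age[age] = calls2
            io.write_table(
                calls2,
                outdir / f"de_{config.css_partial}_vs_{config.host}_{age}dpp.tsv",
            )

        freq = de.chrom_frequency_table(
            calls, annotation, x_split_bp=config.x_split_bp
        )
        freq_by_age[age] = freq
        io.write_table(freq, outdir / f"frequency_table_{age}dpp.tsv")

        # --- dispersion -------------------------------------------------
        ann = annotation.loc[calls.index]
        chrom_group = np.where(
            ann["chrom"].astype(str) == X_CHROM, "X", "autosomes"
        )
        disp = [
            dispersion.dispersion_test(
                calls["log2_fc"], chrom_group, ("X", "autosomes")
            )
        ]
        raw_intensity = np.maximum(
            expr_f.group_mean(config.css, age), expr_f.group_mean(config.host, age)
        )
        disp += dispersion.stratified_dispersion(
            calls["log2_fc"], raw_intensity, chrom_group, ("X", "autosomes"),
            strata=config.strata,
        )
        io.write_table(
            dispersion.dispersion_results_frame(disp),
            outdir / f"dispersion_{age}dpp.tsv",
            index=False,
        )
        results[f"dispersion_{age}dpp"] = disp

    # --- classification (later epoch, donor-region transcripts) ---------
    age = config.ages[-1]
    expr_f = expr_by_age[age]
    calls = de_by_age[age]
    ann = annotation.loc[calls.index]
    css_model = next(s for s in strains if s.name == config.css)
    in_region = np.zeros(len(ann), dtype=bool)
    for iv in css_model.donor_intervals:
        in_region |= (
            (ann["chrom"].astype(str) == iv.chrom)
            & (ann["pos_bp"] >= iv.start)
            & (ann["pos_bp"] <= iv.end)
        ).to_numpy()
    region_ids = calls.index[in_region]
    mean_css = expr_f.group_mean(config.css, age)
    mean_host = expr_f.group_mean(config.host, age)
    mean_donor = expr_f.group_mean(config.donor, age)
    corr = classify.correlation_comparison(
        mean_css, mean_host, mean_donor, subset=region_ids
    )
    typing, typing_summary = classify.classify_regulatory_type(
        calls.loc[region_ids], mean_css, mean_donor, band=config.band
    )
    io.write_table(typing, outdir / "regulatory_typing.tsv")
    io.write_table(typing_summary, outdir / "regulatory_typing_summary.tsv")
    pd.DataFrame([asdict(corr)]).to_csv(
        outdir / "correlation_comparison.tsv", sep="\t", index=False,
        float_format="%.6g",
    )
    results["correlation"] = corr
    results["typing"] = typing
    results["typing_summary"] = typing_summary

    # --- overlap of the two substitution strains' DE sets (late epoch) ----
    if config.css_partial:
        overlap = classify.overlap_analysis(
            de_partial_by_age[age], de_by_age[age], annotation,
            x_split_bp=config.x_split_bp,
        )
    else:  # fall back to comparing the two epochs of the single strain
        overlap = classify.overlap_analysis(
            de_by_age[config.ages[0]], de_by_age[config.ages[1]], annotation,
            x_split_bp=config.x_split_bp,
        )
    pd.DataFrame([{**asdict(overlap), "breakdown_pct": str(overlap.breakdown_pct)}]).to_csv(
        outdir / "overlap_summary.tsv", sep="\t", index=False
    )
    results["overlap"] = overlap
    results["de_partial"] = de_partial_by_age

    # --- PCA + restoration typing ----------------------------------------
    expr_f1 = syn.generate_f1_cohort(
        expr_f, config.host, config.css,
        n_restored=config.f1_restored, n_non_restored=config.f1_non_restored,
        noise_sd=config.noise_sd, seed=seeds[4], age_dpp=age,
    )
    pca = structure.pca_samples(expr_f1, k=3)
    calls_restore = structure.assign_restoration(
        pca,
        expr_f1.sample_ids(config.host, age),
        expr_f1.sample_ids(config.css, age),
        expr_f1.sample_ids("F1", age),
    )
    scores = pca.scores.copy()
    scores.loc["variance_pct"] = list(pca.var_pct)
    io.write_table(scores.rename_axis("sample_id"), outdir / "pca_scores.tsv")
    io.write_table(calls_restore, outdir / "restoration_calls.tsv")
    f1_fc = np.log2(expr_f1.group_mean("F1", age)) - np.log2(
        expr_f1.group_mean(config.host, age)
    )
    topk = structure.top_k_table(calls, k=50, comparison_fcs={"F1": f1_fc})
    io.write_table(topk, outdir / "top50_fold_changes.tsv")
    results["pca"] = pca
    results["restoration"] = calls_restore
    results["top_k"] = topk

    # --- QTL --------------------------------------------------------------
    cross = syn.generate_backcross(
        n_progeny=config.qtl_progeny,
        n_markers=config.qtl_markers,
        qtl_pos_bp=config.qtl_pos_bp,
        qtl_effect=config.qtl_effect,
        residual_sd=config.qtl_residual_sd,
        seed=seeds[5],
    )
    io.write_genotypes(cross.genotypes, outdir / "backcross_genotypes.csv")
    io.write_traits(cross.traits, outdir / "backcross_traits.csv")
    io.write_marker_map(cross.marker_map, outdir / "marker_map.tsv")
    trait = cross.traits.columns[0]
    sm = qtl.single_marker_scan(cross, trait)
    hk = qtl.interval_mapping_hk(cross, trait, step_bp=config.qtl_step_bp)
    io.write_table(sm.to_frame(), outdir / "lod_single_marker.tsv", index=False)
    io.write_table(hk.to_frame(), outdir / "lod_interval_mapping.tsv", index=False)
    results["qtl_single"] = sm
    results["qtl_hk"] = hk
    results["backcross"] = cross

    results["expression"] = expr_by_age
    results["de"] = de_by_age
    results["frequency"] = freq_by_age
    results["truth"] = truth_by_age
    results["annotation"] = annotation
    results["filter_report"] = report
    results["layout"] = layout
    results["architecture"] = arch

    counts.append(("qtl_progeny", config.qtl_progeny))
    manifest = [
        f"cssmisreg {__version__}",
        f"seed {config.seed}",
        f"alpha {config.alpha}",
        f"fc_threshold {config.fc_threshold}",
        f"intensity_threshold {config.intensity_threshold}",
        f"poly_score_max {config.poly_score_max}",
        f"band {config.band}",
        f"x_split_bp {config.x_split_bp}",
    ] + [f"count_{name} {value}" for name, value in counts]
    (outdir / "manifest.txt").write_text("\n".join(manifest) + "\n")
    return results
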