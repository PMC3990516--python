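# cssmisreg

Analysis pipeline for transcriptional misregulation in inter-subspecific
**chromosome substitution strains** (CSS) — mice in which one chromosome
(or a sub-region) is replaced by the counterpart of a diverged donor
subspecies on a host genetic background.  Donor-derived genes sit with
donor *cis*-regulatory elements in a host *trans*-acting environment;
genes whose regulation has diverged between the subspecies are misexpressed,
an early molecular signature of hybrid incompatibility and reproductive
isolation.

The package is aimed at quantitative geneticists and transcriptomicists
working with probe-set-level expression matrices from such designs.  It
covers the full analysis chain:

* **probe filtering** — polymorphism scoring of probe sets against the
  donor genome (mishybridization fakes downregulation), boundary-region,
  unknown-chromosome, Y-linkage and intensity filters;
* **differential expression** — empirical-Bayes **moderated t**
  (`s²_post = (d₀s₀² + d_g s²_g)/(d₀+d_g)`, hyperparameters by moment
  matching on log variances), Benjamini-Hochberg FDR, joint significance
  rule (adjusted p < 0.05 and fold change ≥ 1.5), per-chromosome frequency
  tables with an optional proximal/distal X split;
* **dispersion analysis** — **Ansari-Bradley** rank test on group-centered
  log2 fold changes (exact null by dynamic programming for small groups),
  overall and stratified by raw intensity;
* **regulatory classification** — which parent does the CSS track?
  Fisher-z comparison of correlations with each parent, and per-transcript
  typing into *cis-regulated* (converged within 1.5-fold of the donor) vs
  *incompatibility* (matching neither parent);
* **sample structure** — PCA of expression profiles and restored /
  non-restored typing of partially restored hybrid individuals on PC1;
* **QTL mapping** — single-marker regression and **Haley-Knott** interval
  mapping (LOD = (n/2)·log10(RSS₀/RSS₁), Haldane map function, 1 Mb walk,
  permutation thresholds) on backcross populations;
* **synthetic data** — a ground-truth generator emulating the whole study
  (conserved / cis-divergent / trans-incompatible / cascade-target genes,
  donor-region-enriched probe polymorphism, partially restored F1 cohorts,
  a 314-progeny backcross with a planted QTL), so everything above is
  testable without external data.

See `docs/methods.md` for the models and their assumptions and
`docs/formats.md` for the file schemas.

## Worked example

Run the full synthetic study (simulate → filter → DE → dispersion →
classify → PCA → QTL) from the default configuration:

```python
from cssmisreg import pipeline

cfg = pipeline.RunConfig(seed=1)
res = pipeline.run_pipeline(cfg, "out/")

freq = res["frequency"][7]              # 7 dpp frequency table
print(freq.loc[["proX", "disX"]])
print(res["correlation"])
print("QTL peak: %.1f Mb, LOD %.1f" % (
    res["qtl_hk"].peak_pos_bp / 1e6, res["qtl_hk"].peak_lod))
```

prints

```
       expressed  up  up_pct  down  down_pct
chrom
proX          80   7    8.75    12     15.00
disX          56   9   16.07     6     10.71

CorrelationComparison(r_host=0.9192, r_donor=0.9454, n=136,
                      z_stat=1.6500, p=0.0495)

QTL peak: 59.0 Mb, LOD 12.4
```

Reading the output: X-linked transcripts are heavily misexpressed in the
substitution strain — roughly 10–16 % in each direction, versus
1.62 % up / 3.91 % down across autosomes at the same time point (the
genome-wide "cascade" epoch).  The strain's X expression correlates
better with the donor parent than with the host (one-sided Fisher-z
p ≈ 0.05 at n = 136), consistent with donor *cis*-elements driving much of
the change.  The backcross scan recovers the planted testis-weight QTL
(64.5 Mb) to within the resolution of a 314-progeny cross.

(Exact numbers above are from `seed=1`; any fixed seed reproduces its run
bit-for-bit.)

The same stages are available on files via the CLI:

```sh
cssmisreg run --config config.yaml --out out/
cssmisreg de --expr expr.tsv --meta meta.tsv --pair CSSX,B6 --out de.tsv
cssmisreg qtl --geno g.csv --trait t.csv --map m.tsv --method hk --out lod.tsv
```

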