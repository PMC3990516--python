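# Methods

`cssmisreg` implements the statistical pipeline used to characterize
transcriptional misregulation in inter-subspecific chromosome substitution
strains (CSS): inbred mice in which one chromosome — here the X, or its
distal half — is replaced by the counterpart of a diverged donor subspecies
on a host genetic background.  Misexpression of donor-derived genes in the
host trans-acting environment is an early molecular signature of the
hybrid incompatibilities that underlie reproductive isolation.  The package
analyzes probe-set-level microarray intensities (or any positive expression
matrix) and ships a synthetic-study generator with known ground truth so
every stage can be validated end to end without external data.

## The synthetic study generator

The generator emulates the statistical structure of a prepubertal-testis
CSS expression study:

* **Genome.** 19 autosomes with lengths shrinking from 197 Mb to 61 Mb plus
  one 166.65 Mb X; gene (probe set) positions uniform per chromosome.  The
  default 150 genes per chromosome (3 000 total) is the package's working
  problem size: large enough that chromosome-level rank tests and the
  variance-prior estimate behave as they do on a real array, small enough
  that the full pipeline runs in seconds.
* **Regulatory architecture.** Genes in the substituted target region are
  *conserved* (substitution strain ≡ host), *cis-divergent* (the strain
  adopts the donor's expression level: effect magnitude 0.8 + |N(0, 0.4)|
  log2 units, downregulated with probability 0.35), or *trans-incompatible*
  (the strain matches neither parent: magnitude 1.0 + |N(0, 0.5)| log2
  units, downregulated with probability 0.7, reproducing the observed
  downregulation bias of misexpressed genes).  Default fractions
  0.09 / 0.12 give ~21 % misexpression in the donor region.  Autosomal
  genes become *cascade targets* with probability 0.05: they shift (same
  effect law) only in substitution strains and only in cascade mode,
  emulating the genome-wide spread of misregulation at the later time
  point.  Effect laws are calibration knobs, not measured quantities — the
  source studies report direction frequencies, not effect-size
  distributions.
* **Expression model.** All modeling is in log2; stored intensities are
  `2^(mu + noise)`, reconciling linear-scale intensity filters with
  log-scale statistics.  Baseline log2 levels are N(6, 1.8) (linear
  intensities mostly 10–10 000).  Replicate noise sd defaults to 0.2 log2
  units with 3 replicates per strain (three animals per strain and time
  point is the emulated design).  Optionally (`noise_sd_df`) per-gene noise
  variances are drawn from a scaled-inverse-chi-square law around
  `noise_sd²` — the variance-heterogeneous regime real arrays exhibit and
  the regime the moderated t's empirical-Bayes prior describes.
  Heterozygous donor intervals contribute half the log2 effect (additive
  dosage); a strain flagged as pure donor background expresses every gene
  at its own (donor) level — incompatibility shifts apply only where donor
  cis-elements meet host trans-factors.
* **Partially restored hybrids.** F1-like individuals are built by
  interpolating between the host and substitution-strain log2 mean
  profiles (`host + λ·(css − host) + noise`, λ = 0.15 for restored,
  0.85 for non-restored individuals).  The sources assign restored /
  non-restored status verbally from PCA plots; this construction is the
  smallest generative stand-in that produces the between-cluster geometry
  the typing rule needs, not a fitted model of restoration.
* **Backcross.** Genotypes follow a Markov walk along markers with Haldane
  recombination fractions from inter-marker cM distances (default
  0.5 cM/Mb); the QTL is simulated as a hidden locus and the trait is
  `intercept + effect·genotype + N(0, residual_sd)`.  Defaults mirror the
  emulated cross: 314 progeny, 80 markers on a 197 Mb chromosome, QTL at
  64.5 Mb, effect = 1 residual sd (20 mg on a testis-weight-like scale).

What the generator does **not** emulate: probe-level hybridization and RMA
summarization, cell-type composition shifts between time points,
correlated co-regulation modules, batch effects, and intensity-dependent
variance. Tests passing on synthetic data therefore validate the
statistical machinery and its calibration under the stated model — they do
not certify performance on real arrays with those additional artifacts.

## Probe polymorphism scoring and filters

Sequence divergence of the donor genome under a 25-mer probe suppresses
hybridization and fakes downregulation.  Each 11-probe probe set gets a
polymorphism score; the default classifier is

    score = 3·(probes not identified in donor genome)
          + 2·(probes identified but mismatched)

with scores ≤ 10 "conserved" (a custom score matrix may be supplied; the
linear default preserves the published classifier's monotone structure and
threshold).  Polymorphic probe sets are excluded only where the measured
allele is donor-derived — inside donor (or heterozygous-donor) intervals of
either compared strain — since elsewhere both strains carry the host allele
and mishybridization cancels in the comparison.  Additional filters drop
probe sets with unknown chromosome, Y linkage (too few probe sets to
analyze), location in an undefined strain-boundary interval, and mean
linear intensity ≤ 10 in both compared strains (strict >, replicate mean
per strain).

## Differential expression

Log2 fold change is the difference of group mean log2 intensities.
Significance uses an empirical-Bayes moderated two-sample t: the pooled
per-gene variance s²_g (d_g df) is shrunk toward an ensemble prior,

    s²_post = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),

with t referred to d₀ + d_g df.  Hyperparameters (d₀, s₀²) are estimated by
moment matching on log variances (mean and variance of
`e_g = log s²_g − ψ(d_g/2) + log(d_g/2)` identify both; d₀ = ∞ when the
spread of log variances does not exceed sampling noise; the trigamma
inverse is solved by Newton iteration).  Setting the prior weight to 0
recovers the ordinary pooled-variance Student t (config fallback).
P-values are BH-adjusted (step-up, monotone, capped at 1), and a transcript
is called differentially expressed iff adjusted p < 0.05 **and** linear
fold change ≥ 1.5 (thresholds configurable).

Calibration: with per-gene variances drawn from the ensemble prior the
caller's type-I error at nominal 0.05 is exact to Monte-Carlo precision
(verified in the acceptance suite).  On data where all genes share one
common variance the estimated prior weight is finite about half the time
and the caller runs very slightly conservative (≈ 0.049 at 2 000 genes and
3+3 replicates — matching the behavior of reference implementations of
this method class on the same data); this is a known property of
moment-matched moderation, in the safe direction.

Frequency tables report, per chromosome (optionally splitting the X at the
distal-donor boundary, default 86 497 454 bp), expressed probe-set counts
and up/down counts with percentages rounded to 2 decimals; aggregates
recompute percentages from summed counts rather than averaging row
percentages.

## Dispersion analysis

Misregulation inflates the spread of fold changes without necessarily
moving their center, so chromosome groups are compared with the
Ansari-Bradley rank test on group-centered ("centralized") fold changes.
Median centering is the default (the sources do not specify; mean is a
flag), applied per group — a per-chromosome alternative is exposed as a
config option.  Scores fold the pooled midranks, `a_i = min(r_i, N+1−r_i)`.
The null distribution is exact — a dynamic program over the score multiset,
valid under ties — when min(n₁, n₂) ≤ 10 and N ≤ 200 (the spec'd small-group
condition alone would make enumeration infeasible for large pooled
samples); otherwise a normal approximation with the exact
finite-population variance of the score sum (tie-corrected by
construction) is used.  P-values are two-sided with no display floor —
only numeric underflow limits them.  A degenerate pooled sample (all values
identical) returns p = 1 with a warning.  Stratified tests repeat the
comparison within raw-intensity bands [10, 100), [100, 1000), [1000, ∞);
bands where either group has < 2 members are reported as skipped, mirroring
the situation where one chromosome group simply has no highly expressed
transcripts.

## Regulatory classification

For a gene inside the donor-derived region, the substitution strain's
expression can match the host (conserved), match the donor (cis-regulated:
the transplanted cis-elements simply impose the donor level), or match
neither (incompatibility: donor cis-elements misread by host
trans-factors).  Two diagnostics:

* **Correlation comparison.** Pearson correlations of log group means of
  the substitution strain against each parent, compared by Fisher's
  z transformation: `z = (atanh r_donor − atanh r_host)/√(2/(n−3))`,
  one-sided.  The statistic treats the two correlations as independent
  although they share the substitution strain's vector — the cross-check
  in the test suite is a per-gene parent-label (host/donor pair swap)
  permutation, which is the exchangeability the null implies and agrees
  with the analytic p to within Monte-Carlo error on null data.
* **Per-transcript typing.** The convergence ratio is mean linear CSS /
  mean linear donor (group means; per-replicate pairing is not used).  A
  significant transcript is *cis-regulated* iff the ratio lies strictly
  inside (1/1.5, 1.5) — "converged within less than 1.5-fold", so exactly
  1.5-fold is an incompatibility — else *incompatibility*.  Summaries
  report the converged fraction separately for up- and downregulated
  transcripts.

Overlap analysis intersects two significant-call sets, reports
100·|∩|/|set B|, and partitions the common set into distal X / autosomes /
other.

## PCA and restoration typing

PCA operates on gene-centered log2 profiles via SVD; scores are
deterministic up to sign, fixed by making each component's first non-zero
gene loading non-negative.  Hybrid individuals are typed *restored* iff
their PC1 coordinate is closer to the host-group centroid than to the
substitution-strain centroid by more than a dead-band margin (default 0 —
the sources give only a verbal "relatively close" criterion, so the margin
rule is a stand-in, conservative when positive).  Top-k tables rank
significant transcripts by |log2 FC| (ties by adjusted p, then probe id)
and tabulate the same transcripts' fold changes in comparison strains,
showing how far a restored strain's changes shrink toward zero.

## QTL mapping

A backcross segregates two genotype classes per locus (coded 0/1).  At a
marker, LOD = (n/2)·log10(RSS₀/RSS₁) from regressing the trait on
genotype; markers with a single observed class are reported missing.
Between markers, Haley-Knott regression substitutes the expected genotype
given the nearest informative flanking markers under the Haldane map
function r(d) = ½(1 − e^(−2d/100)) (missing flanks are marginalized
outward; no informative flank on one side conditions on the other alone;
none at all falls back to the backcross prior ½).  The scan grid steps
1 Mb and always includes the marker positions, where (with complete
genotypes) the profile equals the single-marker LOD exactly.  Genetic
positions default to a uniform 0.5 cM/Mb when only bp positions are known
(explicit and overridable — interval mapping needs a genetic map and the
emulated study printed only physical positions).  Significance thresholds
come from trait permutations (default 1 000, 95th percentile of the
genome-wide maximum), not theoretical curves.

## Numerical choices

* Coordinates are 1-based inclusive bp; intervals closed on both ends.
* Fold-change thresholding is on the linear scale (≥ 1.50 means
  |log2 FC| ≥ log2 1.5); band comparisons in typing are strict.
* Percentages are written with 2 decimals; published-style 1-decimal
  ratios must be recomputed from counts, not re-rounded.
* The trigamma inverse clips at d₀ = ∞ for non-positive excess variance;
  per-gene variances are floored at 1e−300 before logs.
* Regression LOD guards: zero trait variance → LOD 0; perfect fit floors
  RSS₁ at the smallest positive double.
* Degenerate inputs raise informative errors rather than propagating NaNs
  (empty strain groups, zero donor means, non-positive intensities,
  mis-ordered probe counts, overlapping strain intervals).

## Known limitations

* The moderated t assumes independent genes; co-regulation makes the
  variance prior slightly too confident.  Under a common-variance regime
  the caller is mildly conservative (see above).
* The Fisher-z comparison ignores the shared-vector dependence of the two
  correlations; a dependent-correlations variant would sharpen it, and the
  permutation oracle is available where exactness matters.
* Restoration typing uses PC1 only, by design; mixtures that separate on
  higher components are not caught.
* Haley-Knott regression understates residual variance between widely
  spaced markers relative to full-likelihood interval mapping; with the
  dense simulated maps used here the difference is negligible.
* The exact Ansari-Bradley path is limited to pooled samples of 200; very
  small groups embedded in very large pools fall back to the normal
  approximation.
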