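# Tabular formats

One dialect for analysis tables: tab-separated values, header row, UTF-8,
'.' decimal separator.  Genomic coordinates are 1-based inclusive bp.
Genotype and trait tables are comma-separated (mirroring the usual
supplementary layout).  Percentage columns (`*_pct`) are written with
2 decimals.  All writers produce files their readers accept.

## Expression matrix (TSV)

| column | type | notes |
|---|---|---|
| `probe_set_id` | str | unique; first column |
| one column per sample | float | linear-scale intensity, > 0, finite |

Readers reject duplicate probe ids (naming the offender), non-numeric
cells, non-positive values, and empty files.

## Sample metadata (TSV)

| column | type |
|---|---|
| `sample_id` | str, unique, matches expression columns |
| `strain` | str |
| `age_dpp` | int (days postpartum) |
| `replicate` | int |

## Probe annotation (TSV)

| column | type | notes |
|---|---|---|
| `probe_set_id` | str | unique |
| `chrom` | str | `"Un"` marks unknown location |
| `pos_bp` | int | |
| `n_probes_total` | int | default 11 |
| `n_identified` | int | probes found in the donor genome |
| `n_perfect` | int | probes perfectly matching the donor sequence |
| `polymorphism_score` | int | `0 <= n_perfect <= n_identified <= n_probes_total` |
| `status` | str | `conserved` iff score <= threshold (default 10) |

## Strain composition (TSV)

| column | type | notes |
|---|---|---|
| `strain` | str | |
| `chrom` | str | |
| `start_bp`, `end_bp` | int | closed interval |
| `zone` | str | `donor` or `boundary` (undefined genotype; excluded from analysis) |
| `zygosity` | str | `homozygous` or `heterozygous` (donor intervals) |

Intervals of one strain must not overlap within a chromosome.

## DE call table (TSV)

`probe_set_id`, `mean_log2_test`, `mean_log2_ref`, `log2_fc`, `t`, `df`,
`p`, `adj_p`, `direction` (`up`/`down`/`none`), `significant` (bool).

## Frequency table (TSV)

`chrom` (autosome name, `X`, or `proX`/`disX` when split), `expressed`,
`up`, `up_pct`, `down`, `down_pct`.

## Dispersion results (TSV)

`group_a`, `group_b`, `stratum` (intensity band or `all`), `n1`, `n2`,
`statistic`, `p`, `method` (`exact`/`normal`/`degenerate`/`skipped`), `note`.

## Genotypes (CSV)

`progeny_id` plus one column per marker; cells in `{0, 1, NA}`
(0 = host homozygote, 1 = heterozygote).

## Traits (CSV)

`progeny_id` plus one float column per trait (e.g. `testis_weight_mg`).

## Marker map (TSV)

`marker_id`, `chrom`, `pos_bp`, `cm`.  When `cm` is absent a uniform
cM/Mb rate (default 0.5) converts physical positions.

## LOD profile (TSV)

`pos_bp`, `lod` (NaN for uninformative markers in single-marker scans).
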