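"""Readers and writers for the pipeline's tabular formats.

One dialect throughout: tab-separated values, header row, UTF-8, '.'
decimal separator, genomic coordinates 1-based inclusive.  Genotype and
trait tables are comma-separated (they mirror the published
supplementary layout).  Every reader validates its schema and the writers
produce files the readers accept.  Schemas are documented in
docs/formats.md.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .models import (
    ExpressionMatrix,
    Interval,
    StrainModel,
    ZONE_BOUNDARY,
    ZONE_DONOR,
    ZYG_HOM,
)

FLOAT_FMT = "%.6g"


def _read_tsv(path, **kw) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty input file: {path}")
    df = pd.read_csv(path, sep="\t", **kw)
    if df.empty:
        raise ValueError(f"no data rows in {path}")
    return df


def write_expression(expr: ExpressionMatrix, path, meta_path=None) -> None:
    expr.values.rename_axis("probe_set_id").to_csv(
        path, sep="\t", float_format=FLOAT_FMT
    )
    if meta_path is not None:
        expr.samples.rename_axis("sample_id").to_csv(meta_path, sep="\t")


def read_expression(path, meta_path=None) -> ExpressionMatrix:
    """Expression TSV (probe_set_id + one column per sample) plus optional
    sample-metadata TSV (sample_id, strain, age_dpp, replicate)."""
    df = _read_tsv(path)
    id_col = df.columns[0]
    dup = df[id_col][df[id_col].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate probe set id {dup.iloc[0]!r}")
    df = df.set_index(id_col)
    try:
        values = df.astype(float)
    except ValueError as err:
        raise ValueError(f"non-numeric intensity cell: {err}") from err
    if meta_path is not None:
        samples = _read_tsv(meta_path).set_index("sample_id")
    else:
        samples = pd.DataFrame(
            {"strain": [c.split("_")[0] for c in values.columns]},
            index=values.columns,
        )
    return ExpressionMatrix(values, samples)


def write_probe_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.rename_axis("probe_set_id").to_csv(path, sep="\t")


def read_probe_annotation(path) -> pd.DataFrame:
    df = _read_tsv(path).set_index("probe_set_id")
    required = {"chrom", "pos_bp", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"probe annotation missing columns: {sorted(missing)}")
    return df


STRAIN_COLUMNS = ["strain", "chrom", "start_bp", "end_bp", "zone", "zygosity"]


def write_strain_composition(strains: list[StrainModel], path) -> None:
    rows = []
    for s in strains:
        for iv in s.intervals:
            rows.append((s.name, iv.chrom, iv.start, iv.end, iv.zone, iv.zygosity))
        if not s.intervals:  # host background: explicit empty marker row is omitted
            continue
    pd.DataFrame(rows, columns=STRAIN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_strain_composition(path) -> list[StrainModel]:
    """Strain composition TSV -> StrainModel list with interval validation."""
    df = _read_tsv(path)
    missing = set(STRAIN_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"strain composition missing columns: {sorted(missing)}")
    bad_zone = set(df["zone"].unique()) - {ZONE_DONOR, ZONE_BOUNDARY}
    if bad_zone:
        raise ValueError(f"unknown zone labels: {sorted(bad_zone)}")
    strains = []
    for name, sub in df.groupby("strain", sort=False):
        ivs = [
            Interval(
                chrom=str(r["chrom"]),
                start=int(r["start_bp"]),
                end=int(r["end_bp"]),
                zone=str(r["zone"]),
                zygosity=str(r.get("zygosity", ZYG_HOM)) if "zygosity" in sub else ZYG_HOM,
            )
            for _, r in sub.iterrows()
        ]
        strains.append(StrainModel(name=str(name), intervals=ivs))
    return strains


def write_genotypes(genotypes: pd.DataFrame, path) -> None:
    out = genotypes.rename_axis("progeny_id").copy()
    out = out.astype("Int64")  # keeps NA representation
    out.to_csv(path, na_rep="NA")


def read_genotypes(path) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty input file: {path}")
    df = pd.read_csv(path, na_values=["NA"]).set_index("progeny_id")
    arr = df.to_numpy(dtype=float)
    ok = np.isnan(arr) | (arr == 0) | (arr == 1)
    if not ok.all():
        raise ValueError("genotypes must be coded 0, 1 or NA")
    return df.astype(float)


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.rename_axis("progeny_id").to_csv(path, float_format=FLOAT_FMT)


def read_traits(path) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty input file: {path}")
    return pd.read_csv(path).set_index("progeny_id").astype(float)


def write_marker_map(marker_map: pd.DataFrame, path) -> None:
    marker_map.rename_axis("marker_id").to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_marker_map(path) -> pd.DataFrame:
    df = _read_tsv(path).set_index("marker_id")
    missing = {"chrom", "pos_bp"} - set(df.columns)
    if missing:
        raise ValueError(f"marker map missing columns: {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Generic result-table writer (TSV, 6 significant digits, 2-decimal
    percentage columns)."""
    out = df.copy()
    for col in out.columns:
        if str(col).endswith("_pct"):
            out[col] = out[col].map(lambda v: f"{v:.2f}" if pd.notna(v) else "")
    out.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
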