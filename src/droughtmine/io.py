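"""Readers and writers for the pipeline's tabular formats.

Conventions
-----------
* Expression matrices are TSV: first column ``gene_id``, remaining columns
  one per sample, cells are FPKM (>= 0).
* Metabolite tables are CSV: first column ``metabolite_id``, remaining
  columns one per sample, cells are peak intensities (>= 0) or ``NA`` for a
  peak not detected in that sample.  Missing values are preserved, never
  silently zeroed.
* Trait tables are CSV keyed by (genotype, condition, timepoint, replicate)
  with one column per physiological trait.
* Annotation sets are GMT: one set per line, tab-separated
  ``set_id<TAB>description<TAB>member...``; members may be gene ids or
  compound/metabolite ids.
* Sample metadata is CSV with columns sample_id, genotype, condition,
  timepoint, replicate and an optional boolean ``rewatered`` flag marking
  post-rewatering timepoints.

All numeric output is written with 6 significant digits, missing values as
the literal ``NA``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CONDITIONS = ("drought", "well_watered")

#: Trait columns recognised in trait tables (all optional except the keys).
TRAIT_KEYS = ["genotype", "condition", "timepoint", "replicate"]
WEIGHT_COLUMNS = ("fresh_weight", "dry_weight", "saturated_weight")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SampleMetadata:
    """One sequencing / metabolomics sample."""

    sample_id: str
    genotype: str
    condition: str
    timepoint: str
    replicate: int
    rewatered: bool = False

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise FormatError(
                f"sample {self.sample_id!r}: condition must be one of {CONDITIONS}, "
                f"got {self.condition!r}"
            )
        if self.replicate < 1:
            raise FormatError(f"sample {self.sample_id!r}: replicate must be >= 1")


def metadata_frame(samples: Iterable[SampleMetadata]) -> pd.DataFrame:
    """Collect SampleMetadata records into the canonical metadata frame."""
    rows = [
        (s.sample_id, s.genotype, s.condition, s.timepoint, s.replicate, s.rewatered)
        for s in samples
    ]
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "genotype", "condition", "timepoint", "replicate", "rewatered"],
    )
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample_id(s): {dupes}")
    return df.set_index("sample_id")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "timepoint": str})
    required = {"sample_id", "genotype", "condition", "timepoint", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: metadata is missing columns {sorted(missing)}")
    if "rewatered" not in df.columns:
        df["rewatered"] = False
    records = [
        SampleMetadata(
            sample_id=str(r.sample_id),
            genotype=str(r.genotype),
            condition=str(r.condition),
            timepoint=str(r.timepoint),
            replicate=int(r.replicate),
            rewatered=bool(r.rewatered),
        )
        for r in df.itertuples(index=False)
    ]
    return metadata_frame(records)


def write_sample_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    out = metadata.copy()
    out["rewatered"] = out["rewatered"].astype(bool)
    out.to_csv(path, index=True, index_label="sample_id")


def timepoint_order(metadata: pd.DataFrame) -> list[str]:
    """Total order over timepoints (lexicographic over the ordered labels)."""
    return sorted(metadata["timepoint"].unique())


def select_samples(
    metadata: pd.DataFrame,
    genotype: str | None = None,
    condition: str | None = None,
    timepoint: str | None = None,
) -> pd.DataFrame:
    sub = metadata
    if genotype is not None:
        sub = sub[sub["genotype"] == genotype]
    if condition is not None:
        sub = sub[sub["condition"] == condition]
    if timepoint is not None:
        sub = sub[sub["timepoint"] == timepoint]
    return sub


def _check_columns_against_metadata(
    columns: Iterable[str], metadata: pd.DataFrame, path: str | Path
) -> None:
    known = set(metadata.index)
    for col in columns:
        if col not in known:
            raise FormatError(
                f"{path}: column {col!r} does not match any sample in the metadata"
            )


def read_expression_matrix(path: str | Path, metadata: pd.DataFrame) -> pd.DataFrame:
    """Gene x sample FPKM matrix; every column must map to a metadata sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "gene_id":
        raise FormatError(f"{path}: first column must be 'gene_id', got {df.index.name!r}")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate gene_id(s): {dupes}")
    _check_columns_against_metadata(df.columns, metadata, path)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][:1]
            raise FormatError(
                f"{path}: non-numeric FPKM for gene {bad[0]!r} in sample {col!r}"
            )
    if df.isna().any().any():
        gene, col = _first_offender(df, df.isna())
        raise FormatError(f"{path}: missing FPKM for gene {gene!r} in sample {col!r}")
    if (df.values < 0).any():
        gene, col = _first_offender(df, df < 0)
        raise FormatError(f"{path}: negative FPKM for gene {gene!r} in sample {col!r}")
    return df


def _first_offender(df: pd.DataFrame, mask: pd.DataFrame) -> tuple[str, str]:
    stacked = mask.stack()
    gene, col = stacked[stacked].index[0]
    return str(gene), str(col)


def read_metabolite_table(path: str | Path, metadata: pd.DataFrame) -> pd.DataFrame:
    """Metabolite x sample peak intensities; NA marks an undetected peak."""
    df = pd.read_csv(path, index_col=0, na_values=["NA"], keep_default_na=False)
    if df.index.name != "metabolite_id":
        raise FormatError(
            f"{path}: first column must be 'metabolite_id', got {df.index.name!r}"
        )
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate metabolite_id(s): {dupes}")
    _check_columns_against_metadata(df.columns, metadata, path)
    df = df.apply(pd.to_numeric)
    if (df.values < 0).any():
        met, col = _first_offender(df, df < 0)
        raise FormatError(f"{path}: negative intensity for {met!r} in sample {col!r}")
    return df


def read_trait_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"timepoint": str}, na_values=["NA"], keep_default_na=False)
    missing = set(TRAIT_KEYS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: trait table is missing key columns {sorted(missing)}")
    trait_cols = [c for c in df.columns if c not in TRAIT_KEYS]
    df[trait_cols] = df[trait_cols].apply(pd.to_numeric)
    if all(c in df.columns for c in WEIGHT_COLUMNS):
        w = df[list(WEIGHT_COLUMNS)].dropna()
        bad = ~((w["dry_weight"] <= w["fresh_weight"]) & (w["fresh_weight"] <= w["saturated_weight"]))
        if bad.any():
            raise FormatError(
                f"{path}: leaf weights must satisfy dry <= fresh <= saturated "
                f"(row {w.index[bad][0]})"
            )
    if "soil_water_content" in df.columns:
        swc = df["soil_water_content"].dropna()
        if ((swc < 0) | (swc > 100)).any():
            raise FormatError(f"{path}: soil_water_content must lie in [0, 100]")
    return df


def read_annotation_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """GMT file -> ``{set_id: (description, members)}``.

    Members may be gene ids or compound ids; a set may mix both.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            set_id, description, *members = fields
            if set_id in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set_id {set_id!r}")
            sets[set_id] = (description, frozenset(m for m in members if m))
    return sets


def write_annotation_gmt(
    sets: Mapping[str, tuple[str, frozenset[str]]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for set_id in sets:
            description, members = sets[set_id]
            fh.write("\t".join([set_id, description, *sorted(members)]) + "\n")


def _format_cell(x: object) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    if isinstance(x, (bool, np.bool_)):
        return str(bool(x))
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, (float, np.floating)):
        return f"{float(x):.6g}"
    return str(x)


def write_table(df: pd.DataFrame, path: str | Path, sep: str | None = None, index: bool = True) -> None:
    """Write a table with 6-significant-digit numerics and NA for missing.

    The separator defaults to TAB for .tsv paths and comma otherwise.
    """
    if sep is None:
        sep = "\t" if str(path).endswith(".tsv") else ","
    out = df.map(_format_cell)
    out.to_csv(path, sep=sep, index=index, na_rep="NA")


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "gene_id"
    write_table(out, path, sep="\t")


def write_metabolite_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "metabolite_id"
    write_table(out, path, sep=",")
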