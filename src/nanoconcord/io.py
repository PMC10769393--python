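"""Readers and writers for the plain-text formats the pipeline consumes.

Counts and annotations are TSV/CSV; module catalogs and term libraries are
GMT; contrast tables and homolog maps are TSV. A minimal reader for a
simplified per-sample lane file (header lines, then ``gene,count`` rows) is
provided for convenience; it covers only a subset of the vendor RCC format.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, FormatError

__all__ = [
    "read_counts",
    "read_gmt",
    "write_gmt",
    "read_contrasts",
    "read_homolog_map",
    "read_gene_list",
    "read_rcc_dir",
]

ANNOT_COLUMNS = ("strain", "sex", "age_months", "batch")


def _read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=index_col)


def read_counts(
    counts_path: str | Path, annotations_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a gene x sample count matrix and its sample annotations.

    Samples are aligned between the two files; any mismatch is reported with
    the offending sample ids. Counts must be non-negative integers.
    """
    counts = _read_table(counts_path)
    annot = _read_table(annotations_path)

    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene identifiers: {dup}")
    if counts.columns.duplicated().any():
        dup = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample identifiers: {dup}")

    for col in counts.columns:
        vals = counts[col]
        if not np.issubdtype(vals.dtype, np.number):
            bad = vals[pd.to_numeric(vals, errors="coerce").isna()]
            gene = bad.index[0] if len(bad) else "?"
            raise FormatError(f"non-numeric count at ({gene}, {col})")
    arr = counts.to_numpy()
    neg = np.argwhere(arr < 0)
    if len(neg):
        g, s = neg[0]
        raise FormatError(
            f"negative count {arr[g, s]} at ({counts.index[g]}, {counts.columns[s]})"
        )
    frac = np.argwhere(arr != np.floor(arr))
    if len(frac):
        g, s = frac[0]
        raise FormatError(
            f"non-integer count {arr[g, s]} at ({counts.index[g]}, {counts.columns[s]})"
        )

    missing_annot = [s for s in counts.columns if s not in annot.index]
    missing_counts = [s for s in annot.index if s not in counts.columns]
    if missing_annot or missing_counts:
        raise AlignmentError(
            f"samples in counts without annotations: {missing_annot}; "
            f"annotated samples without counts: {missing_counts}"
        )
    missing_cols = [c for c in ANNOT_COLUMNS if c not in annot.columns]
    if missing_cols:
        raise FormatError(f"annotation file missing columns: {missing_cols}")
    annot = annot.loc[counts.columns]
    return counts.astype(np.int64), annot


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file: ``name TAB description TAB gene...`` per line."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            name, _desc, *genes = fields
            if any(not g.strip() for g in genes):
                raise FormatError(f"{path}:{lineno}: blank gene field")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def read_contrasts(path: str | Path, key: str | None = None) -> dict[str, pd.Series]:
    """Read a long-format contrast table into ``{contrast_id: log2FC Series}``.

    The first column identifies the contrast (module id or cohort.subtype);
    remaining columns are ``human_gene`` and ``log2FC``.
    """
    df = _read_table(path, index_col=None)
    if key is None:
        key = df.columns[0]
    for col in (key, "human_gene", "log2FC"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if not np.isfinite(df["log2FC"].to_numpy(dtype=float)).all():
        raise FormatError(f"{path}: non-finite log2FC values")
    out: dict[str, pd.Series] = {}
    for cid, grp in df.groupby(key, sort=False):
        if grp["human_gene"].duplicated().any():
            dup = grp.loc[grp["human_gene"].duplicated(), "human_gene"].tolist()
            raise FormatError(f"{path}: duplicate genes {dup} in contrast {cid!r}")
        out[str(cid)] = pd.Series(
            grp["log2FC"].to_numpy(dtype=float), index=grp["human_gene"].tolist(), name="log2FC"
        )
    return out


def read_homolog_map(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, index_col=None)
    for col in ("human_gene", "mouse_gene"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    df = df[["human_gene", "mouse_gene"]].drop_duplicates()
    return df.reset_index(drop=True)


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_rcc_dir(directory: str | Path) -> pd.DataFrame:
    """Read a directory of simplified per-sample lane files into a count matrix.

    Each ``*.rcc``-like file: lines starting with ``#`` are header metadata,
    every other non-empty line is ``gene,count``. The sample id is the file
    stem. This is a documented subset of the vendor format, not a full RCC
    parser.
    """
    directory = Path(directory)
    columns: dict[str, pd.Series] = {}
    for path in sorted(directory.glob("*.rcc")):
        genes, counts = [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                try:
                    gene, value = line.split(",")
                    counts.append(int(value))
                    genes.append(gene)
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: expected 'gene,count'") from exc
        columns[path.stem] = pd.Series(counts, index=genes)
    if not columns:
        raise FormatError(f"no .rcc files found in {directory}")
    df = pd.DataFrame(columns)
    if df.isna().any().any():
        raise AlignmentError("lane files do not share an identical gene list")
    return df.astype(np.int64)
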