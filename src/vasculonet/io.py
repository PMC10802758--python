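"""Readers, writers and validation for every table the pipeline touches.

Canonical in-memory containers are plain pandas objects:

* abundance matrix -- ``DataFrame`` of log2 abundances, proteins (rows,
  ``"Symbol|Accession"`` ids) by samples (columns); ``NaN`` marks missing.
* batch design -- ``DataFrame`` indexed by sample id with columns
  ``batch`` (label) and ``is_gis`` (bool).
* sample traits -- ``DataFrame`` indexed by sample id with diagnosis and
  covariate columns (age, sex, PMI, CERAD, Braak, CAA, gliosis, APOE4_dose).
* marker sets -- ``dict[str, set[str]]`` of uppercase gene symbols.

The canonical on-disk dialect is tab-separated text with ``NA`` as the
missing token; CSV is accepted through ``sep=","``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

NA_TOKEN = "NA"

CELL_TYPES = (
    "endothelial",
    "pericyte",
    "SMC",
    "fibroblast",
    "astrocyte",
    "microglia/macrophage",
    "neuron",
    "oligodendrocyte",
    "OPC",
)


class FormatError(ValueError):
    """A file violated the documented dialect (duplicates, bad cells...)."""


def symbol_of(protein_id: str) -> str:
    """Gene symbol used for gene-based joins (markers, GWAS, biofluids).

    The symbol prefix of ``"Symbol|Accession"``, uppercased; on
    multi-symbol entries (``"SYM1;SYM2|ACC"``) the first symbol wins.
    """
    sym = str(protein_id).split("|", 1)[0]
    sym = sym.split(";", 1)[0]
    return sym.strip().upper()


def _check_unique(values, what: str, path) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dups = sorted(idx[idx.duplicated()].unique().tolist())
        raise FormatError(f"{path}: duplicate {what}: {dups}")


def read_abundance_matrix(path, sep: str = "\t") -> pd.DataFrame:
    """Read a proteins x samples log2 abundance TSV.

    First column holds protein ids, the header row sample ids.  Empty
    cells and ``NA`` become missing.  Duplicate ids or non-numeric cells
    are hard errors naming the offender.
    """
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                      keep_default_na=False, na_values=[NA_TOKEN, ""])
    _check_unique(raw.index, "protein ids", path)
    _check_unique(raw.columns, "sample ids", path)
    try:
        values = raw.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError):
        for j, col in enumerate(raw.columns):
            conv = pd.to_numeric(raw[col], errors="coerce")
            bad = conv.isna() & raw[col].notna()
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise FormatError(
                    f"{path}: non-numeric value {raw[col].iloc[i]!r} at "
                    f"row {raw.index[i]!r}, column {col!r}"
                ) from None
        raise
    values.index = values.index.astype(str)
    values.index.name = "protein"
    if not np.isfinite(values.to_numpy(float)[~np.isnan(values.to_numpy(float))]).all():
        raise FormatError(f"{path}: non-finite abundance values present")
    return values.astype(float)


def write_abundance_matrix(matrix: pd.DataFrame, path, sep: str = "\t") -> None:
    matrix.to_csv(path, sep=sep, na_rep=NA_TOKEN, index_label="protein")


def filter_missingness(matrix: pd.DataFrame, max_missing_fraction: float = 0.50) -> pd.DataFrame:
    """Retain proteins whose missing fraction is strictly below the cutoff.

    A protein missing in exactly half the samples is dropped at the 0.50
    default (the retention rule is "less than", not "at most").  Row
    order is preserved.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    frac = matrix.isna().mean(axis=1)
    return matrix.loc[frac < max_missing_fraction]


def read_batch_design(path, sep: str = "\t") -> pd.DataFrame:
    """Read sample -> batch / GIS-flag design table (columns sample, batch, is_gis)."""
    df = pd.read_csv(path, sep=sep, dtype={"sample": str, "batch": str})
    for col in ("sample", "batch", "is_gis"):
        if col not in df.columns:
            raise FormatError(f"{path}: design table lacks column {col!r}")
    _check_unique(df["sample"], "sample ids", path)
    out = df.set_index("sample")[["batch", "is_gis"]]
    out["is_gis"] = out["is_gis"].astype(bool)
    return out


def write_batch_design(design: pd.DataFrame, path, sep: str = "\t") -> None:
    design.to_csv(path, sep=sep, index_label="sample")


def validate_design(matrix: pd.DataFrame, design: pd.DataFrame,
                    require_gis: bool = True) -> None:
    missing = [s for s in matrix.columns if s not in design.index]
    if missing:
        raise FormatError(f"samples without a batch assignment: {missing}")
    if require_gis:
        sub = design.loc[list(matrix.columns)]
        for batch, grp in sub.groupby("batch"):
            if not grp["is_gis"].any():
                raise FormatError(f"batch {batch!r} contains no GIS sample")


def read_traits(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype={"sample": str})
    if "sample" not in df.columns:
        raise FormatError(f"{path}: trait table lacks column 'sample'")
    _check_unique(df["sample"], "sample ids", path)
    return df.set_index("sample")


def write_traits(traits: pd.DataFrame, path, sep: str = "\t") -> None:
    traits.to_csv(path, sep=sep, na_rep=NA_TOKEN, index_label="sample")


def read_marker_gmt(path) -> dict[str, set[str]]:
    """Read cell-type marker sets from a GMT file.

    Each line is ``name<TAB>description<TAB>symbol...``; symbols are
    uppercased.  Lines with fewer than three fields raise with the line
    number.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            symbols = {f.strip().upper() for f in fields[2:] if f.strip()}
            if not symbols:
                raise FormatError(f"{path}:{lineno}: empty marker set {name!r}")
            sets[name] = symbols
    return sets


def write_marker_gmt(sets: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name, symbols in sets.items():
            fh.write("\t".join([name, name] + sorted(s.upper() for s in symbols)) + "\n")


def read_gene_pvalues(path, sep: str = "\t") -> pd.Series:
    """Read one study's gene-level association table (columns GENE, P)."""
    df = pd.read_csv(path, sep=sep)
    for col in ("GENE", "P"):
        if col not in df.columns:
            raise FormatError(f"{path}: gene p-value table lacks column {col!r}")
    genes = df["GENE"].astype(str).str.upper()
    _check_unique(genes, "gene symbols", path)
    p = pd.Series(df["P"].to_numpy(float), index=genes, name="P")
    if ((p <= 0) | (p > 1)).any():
        raise FormatError(f"{path}: p-values outside (0, 1]")
    return p


def write_gene_pvalues(p: pd.Series, path, sep: str = "\t") -> None:
    pd.DataFrame({"GENE": p.index, "P": p.to_numpy()}).to_csv(path, sep=sep, index=False)


def read_biofluid_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a biofluid differential-abundance table (protein, log2FC, p)."""
    df = pd.read_csv(path, sep=sep)
    for col in ("protein", "log2FC", "p"):
        if col not in df.columns:
            raise FormatError(f"{path}: biofluid table lacks column {col!r}")
    df = df.copy()
    df["protein"] = df["protein"].astype(str).str.upper()
    _check_unique(df["protein"], "protein symbols", path)
    return df[["protein", "log2FC", "p"]]


def write_table(result: pd.DataFrame, path, sep: str = "\t", index: bool = False) -> None:
    """Write any result table in the canonical TSV dialect."""
    result.to_csv(path, sep=sep, na_rep=NA_TOKEN, index=index)


def read_table(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, na_values=[NA_TOKEN])
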