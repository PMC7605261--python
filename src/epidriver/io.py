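"""Readers and writers for the tabular dialects the pipeline consumes.

All tables are tab-separated text. Matrices are gene-by-sample (or
CpG-by-sample) with the identifier in the first column. Readers sort
genes lexicographically and keep samples in file order so outputs are
reproducible regardless of input row order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, is_dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    CNA_CODES,
    NONSYNONYMOUS_CLASSES,
    FormatError,
    GeneAnnotation,
)

log = logging.getLogger(__name__)


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    for col in columns:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def read_mutation_table(
    path,
    gene_col: str = "Hugo_Symbol",
    sample_col: str = "Tumor_Sample_Barcode",
    class_col: str = "Variant_Classification",
    nonsyn_classes: Optional[Iterable[str]] = None,
    samples: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Collapse a MAF-minimal mutation table to gene x sample counts.

    Each record is one somatic mutation call; only records whose variant
    class is in ``nonsyn_classes`` (default: the standard nonsynonymous
    classes) are counted. Silent/synonymous records are dropped. A gene
    seen only with silent records still appears as an all-zero row.

    Parameters
    ----------
    samples : optional full cohort sample list; samples without any
        mutation record then appear as all-zero columns.
    """
    classes = NONSYNONYMOUS_CLASSES if nonsyn_classes is None else set(nonsyn_classes)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, [gene_col, sample_col, class_col], path)
    if df.empty:
        warnings.warn(f"{path}: mutation table has no records")
        cols = list(samples) if samples is not None else []
        return pd.DataFrame(np.zeros((0, len(cols)), dtype=int), columns=cols)

    keep = df[class_col].isin(classes)
    counts = (
        df.loc[keep]
        .groupby([gene_col, sample_col], sort=False)
        .size()
        .unstack(fill_value=0)
    )
    genes = sorted(df[gene_col].unique())
    if samples is None:
        # samples in order of first appearance in the file
        sample_order = list(dict.fromkeys(df[sample_col]))
    else:
        sample_order = list(samples)
    out = counts.reindex(index=genes, columns=sample_order, fill_value=0)
    out.index.name = "gene"
    return out.astype(int)


def read_matrix(path, dtype=float) -> pd.DataFrame:
    """Read a gene x sample matrix TSV (first column = gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene rows {dups}")
    df = df.sort_index()
    df.index.name = "gene"
    return df.astype(dtype)


def read_cna_matrix(path) -> pd.DataFrame:
    """Read a GISTIC-style gene-level call matrix coded -2..+2."""
    df = read_matrix(path, dtype=float)
    values = df.to_numpy()
    bad = np.isfinite(values) & ~np.isin(values, CNA_CODES)
    bad |= ~np.isfinite(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: CNA value {df.iat[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} is not in {{-2, -1, 0, 1, 2}}"
        )
    return df.astype(int)


def read_expression_tables(z_path, counts_path=None):
    """Read a Z-score matrix and (optionally) a raw count matrix.

    NA cells are preserved as missing, not coerced to zero. Negative
    counts are rejected.
    """
    z = read_matrix(z_path, dtype=float)
    counts = None
    if counts_path is not None:
        counts = read_matrix(counts_path, dtype=float)
        values = counts.to_numpy()
        bad = np.isfinite(values) & (values < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"{counts_path}: negative count {counts.iat[i, j]!r} at row "
                f"{counts.index[i]!r}, column {counts.columns[j]!r}"
            )
    return z, counts


def read_methylation_table(path):
    """Read a CpG table (cpg_id, chrom, pos, then sample beta columns).

    Returns ``(betas, coords)``: a CpG x sample beta matrix and a
    coordinate frame with columns chrom, pos.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, ["cpg_id", "chrom", "pos"], path)
    if df["cpg_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate cpg_id rows")
    df = df.set_index("cpg_id").sort_index()
    coords = df[["chrom", "pos"]].copy()
    coords["pos"] = coords["pos"].astype(int)
    betas = df.drop(columns=["chrom", "pos"]).astype(float)
    finite = betas.to_numpy()[np.isfinite(betas.to_numpy())]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise FormatError(f"{path}: methylation betas outside [0, 1]")
    return betas, coords


def read_compendium(path) -> List[GeneAnnotation]:
    """Read the regulator-gene compendium table.

    Columns: symbol, chromosome, strand, tss, erg_class, and optionally
    hallmarks (comma-separated), tsg_flag, oncogene_flag.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["symbol", "chromosome", "strand", "tss", "erg_class"], path)
    if df["symbol"].duplicated().any():
        dups = df.loc[df["symbol"].duplicated(), "symbol"].tolist()
        raise FormatError(f"{path}: duplicate gene symbols {dups}")
    annotations = []
    for i, row in df.iterrows():
        hallmarks = frozenset()
        if "hallmarks" in df.columns and isinstance(row.get("hallmarks"), str) and row["hallmarks"]:
            hallmarks = frozenset(row["hallmarks"].split(","))
        try:
            annotations.append(
                GeneAnnotation(
                    symbol=row["symbol"],
                    chromosome=str(row["chromosome"]),
                    strand=row["strand"],
                    tss=int(row["tss"]),
                    erg_class=row["erg_class"],
                    hallmarks=hallmarks,
                    tsg_flag=str(row.get("tsg_flag", "")).lower() in ("1", "true"),
                    oncogene_flag=str(row.get("oncogene_flag", "")).lower() in ("1", "true"),
                )
            )
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path}: row {i} ({row['symbol']!r}): {exc}") from exc
    return annotations


def write_compendium(annotations: Sequence[GeneAnnotation], path) -> None:
    rows = []
    for a in annotations:
        rows.append({
            "symbol": a.symbol, "chromosome": a.chromosome, "strand": a.strand,
            "tss": a.tss, "erg_class": a.erg_class,
            "hallmarks": ",".join(sorted(a.hallmarks)),
            "tsg_flag": int(a.tsg_flag), "oncogene_flag": int(a.oncogene_flag),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_hallmark_map(path) -> dict:
    """Read a gene-to-hallmark membership table (gene, hallmark)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["gene", "hallmark"], path)
    out: dict = {}
    for gene, hm in zip(df["gene"], df["hallmark"]):
        out.setdefault(gene, set()).add(hm)
    return out


def read_consensus_driver_scores(path) -> pd.DataFrame:
    """Read an external consensus driver score table (gene, cancer, score)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene", "cancer", "score"], path)
    return df.astype({"score": float})


def write_matrix(df: pd.DataFrame, path, float_format="%.6g") -> None:
    """Write a matrix TSV that round-trips through :func:`read_matrix`."""
    df.to_csv(path, sep="\t", float_format=float_format, na_rep="")


def write_result_table(records, path, sort: bool = True, float_format="%.6g") -> None:
    """Write analysis records to a deterministic TSV.

    ``records`` may be a DataFrame, a list of dicts, or a list of
    dataclass instances sharing one schema. Rows are sorted by every
    column (left to right) unless ``sort=False``; NA is written as an
    empty field and re-read as missing.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = [asdict(r) if is_dataclass(r) else dict(r) for r in records]
        df = pd.DataFrame(rows)
    if sort and len(df):
        df = df.sort_values(list(df.columns), kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format=float_format, na_rep="")
    log.debug("wrote %d records to %s", len(df), path)


def read_result_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
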