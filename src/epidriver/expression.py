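"""Expression integration: Z-score aberration rates, alteration-expression
correlation, promoter eQTM scanning, and differential-expression
post-processing.

Correlations are plain Pearson; for the mutation track the predictor is
the 0/1 mutated indicator, making the statistic a point-biserial
correlation. FDR control is Benjamini-Hochberg, applied per cancer type
and per track.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_fdr
from .types import AnalysisThresholds, CohortOmics, DEFAULT_THRESHOLDS, GeneAnnotation

log = logging.getLogger(__name__)


def zscore_aberration_rates(expr_z: pd.DataFrame, z_cut: float = 2.0) -> pd.DataFrame:
    """Fraction of samples with aberrant expression per gene.

    ``up_frac`` counts samples with Z > z_cut, ``down_frac`` Z < -z_cut;
    denominators exclude missing cells. A gene with all-missing Z gets
    NaN for both.
    """
    z = expr_z.to_numpy(dtype=float)
    valid = np.isfinite(z)
    denom = valid.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        up = np.where(denom > 0, (valid & (z > z_cut)).sum(axis=1) / denom, np.nan)
        down = np.where(denom > 0, (valid & (z < -z_cut)).sum(axis=1) / denom, np.nan)
    return pd.DataFrame(
        {"up_frac": up, "down_frac": down, "n_samples": denom},
        index=expr_z.index,
    )


def correlate_alteration_expression(
    cohort: CohortOmics,
    track: str,
    thresholds: AnalysisThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-gene Pearson correlation between an alteration track and Z.

    ``track='CNA'`` uses the -2..+2 call as a numeric predictor;
    ``track='SNA'`` uses the mutated indicator (point-biserial). Genes
    with zero predictor variance or fewer than 3 paired observations are
    skipped, with the reason recorded. The R-squared filter is 30% for
    CNA and 10% for SNA, both with FDR < 0.05.
    """
    if track not in ("CNA", "SNA"):
        raise ValueError(f"track must be 'CNA' or 'SNA', got {track!r}")
    pred_matrix = cohort.cna if track == "CNA" else (cohort.sna > 0).astype(int)
    r2_cut = thresholds.r2_cna if track == "CNA" else thresholds.r2_sna

    rows = []
    for gene in cohort.sna.index:
        x = pred_matrix.loc[gene].to_numpy(dtype=float)
        y = cohort.expr_z.loc[gene].to_numpy(dtype=float)
        mask = np.isfinite(x) & np.isfinite(y)
        row = {"gene": gene, "cancer_code": cohort.cancer_code, "track": track,
               "n": int(mask.sum()), "r": np.nan, "r_squared": np.nan,
               "p_value": np.nan, "skip_reason": ""}
        if mask.sum() < 3:
            row["skip_reason"] = "fewer than 3 paired observations"
        elif np.ptp(x[mask]) == 0:
            row["skip_reason"] = "zero predictor variance"
        elif np.ptp(y[mask]) == 0:
            row["skip_reason"] = "zero expression variance"
        else:
            r, p = stats.pearsonr(x[mask], y[mask])
            row.update(r=r, r_squared=r * r, p_value=p)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p_value"])
    out["passes_filter"] = (out["r_squared"] > r2_cut) & (out["fdr"] < thresholds.fdr_sig)
    out["passes_filter"] = out["passes_filter"].fillna(False)
    return out


def promoter_window(annotation: GeneAnnotation, upstream: int = 1000,
                    downstream: int = 500) -> Tuple[int, int]:
    """Strand-aware promoter interval around the TSS, 1-based inclusive.

    On the + strand the window is [tss - upstream, tss + downstream]; on
    the - strand it is mirrored to [tss - downstream, tss + upstream].
    """
    if annotation.strand == "+":
        return annotation.tss - upstream, annotation.tss + downstream
    return annotation.tss - downstream, annotation.tss + upstream


def eqtm_scan(
    methylation: pd.DataFrame,
    cpg_coords: pd.DataFrame,
    expression_counts: pd.DataFrame,
    annotations: Sequence[GeneAnnotation],
    window: Tuple[int, int] = (-1000, 500),
    log_transform: bool = True,
    drop_sex_chroms: bool = False,
) -> pd.DataFrame:
    """Expression quantitative trait methylation scan over promoter CpGs.

    A CpG is tested against a gene when it lies in the strand-aware
    promoter window (default 1000 bp upstream to 500 bp downstream of the
    TSS) on the gene's chromosome; a CpG inside two genes' windows is
    tested against both. The statistic is the Pearson correlation between
    the CpG beta and the gene's expression -- log2(count + 1) by default,
    raw counts when ``log_transform=False``. BH FDR is taken over all
    tested pairs; per gene, the minimum-p CpG is flagged
    ``is_top_for_gene``.
    """
    upstream, downstream = -window[0], window[1]
    shared = [s for s in methylation.columns if s in expression_counts.columns]
    if len(shared) < 3:
        raise ValueError("fewer than 3 samples shared between methylation and expression")
    betas = methylation[shared]
    expr = expression_counts[shared].astype(float)
    if log_transform:
        expr = np.log2(expr + 1.0)

    rows = []
    coords = cpg_coords
    for ann in annotations:
        if drop_sex_chroms and ann.chromosome in ("X", "Y"):
            continue
        if ann.symbol not in expr.index:
            continue
        lo, hi = promoter_window(ann, upstream, downstream)
        in_win = coords.index[
            (coords["chrom"] == ann.chromosome)
            & (coords["pos"] >= lo) & (coords["pos"] <= hi)
        ]
        y = expr.loc[ann.symbol].to_numpy()
        for cpg in in_win:
            x = betas.loc[cpg].to_numpy(dtype=float)
            mask = np.isfinite(x) & np.isfinite(y)
            if mask.sum() < 3 or np.ptp(x[mask]) == 0 or np.ptp(y[mask]) == 0:
                continue
            r, p = stats.pearsonr(x[mask], y[mask])
            rows.append({
                "gene": ann.symbol, "cpg_id": cpg,
                "cpg_position": int(coords.at[cpg, "pos"]),
                "pearson_r": r, "p_value": p,
            })
    out = pd.DataFrame(rows, columns=["gene", "cpg_id", "cpg_position",
                                      "pearson_r", "p_value"])
    out["fdr"] = bh_fdr(out["p_value"]) if len(out) else []
    out["is_top_for_gene"] = False
    if len(out):
        top = out.groupby("gene")["p_value"].idxmin()
        out.loc[top, "is_top_for_gene"] = True
        multi = out["cpg_id"].value_counts()
        for cpg in multi[multi > 1].index:
            log.info("CpG %s overlaps %d promoter windows", cpg, multi[cpg])
    return out.reset_index(drop=True)


def nb_wald_de(
    tumor_counts: pd.DataFrame, normal_counts: pd.DataFrame
) -> pd.DataFrame:
    """Simple negative-binomial Wald test for tumor vs normal counts.

    Library sizes are normalized with median-of-ratios size factors; the
    per-gene dispersion is a method-of-moments estimate pooled across both
    groups; the Wald statistic tests log2 fold change of the normalized
    group means. This is a deliberately plain built-in so the pipeline
    runs end-to-end on its own; the method name is recorded in the output
    so downstream consumers can distinguish it from external DE tools.
    """
    genes = tumor_counts.index
    if not genes.equals(normal_counts.index):
        raise ValueError("tumor and normal count matrices must share the gene axis")
    combined = pd.concat([tumor_counts, normal_counts], axis=1)
    sf = median_of_ratios_size_factors(combined)
    norm = combined.div(sf, axis=1)
    nt, nn = tumor_counts.shape[1], normal_counts.shape[1]
    tum, nor = norm.iloc[:, :nt], norm.iloc[:, nt:]

    m1 = tum.mean(axis=1).to_numpy()
    m0 = nor.mean(axis=1).to_numpy()
    v1 = tum.var(axis=1, ddof=1).to_numpy()
    v0 = nor.var(axis=1, ddof=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        phi1 = (v1 - m1) / m1**2
        phi0 = (v0 - m0) / m0**2
    phi1 = np.where(np.isfinite(phi1), phi1, 0.0)
    phi0 = np.where(np.isfinite(phi0), phi0, 0.0)
    phi = np.clip((phi1 + phi0) / 2.0, 0.0, None)

    pc = 0.5
    log2fc = np.log2((m1 + pc) / (m0 + pc))
    ln2sq = math.log(2.0) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_log2 = (1.0 / np.maximum(m1, pc) + phi) / (nt * ln2sq) \
            + (1.0 / np.maximum(m0, pc) + phi) / (nn * ln2sq)
    se = np.sqrt(var_log2)
    z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame({
        "gene": genes,
        "total_reads": combined.sum(axis=1).to_numpy(),
        "log2_fc": log2fc,
        "pvalue": p,
        "fdr": bh_fdr(p),
        "method": "nb-wald-mom",
    })
    return out.reset_index(drop=True)


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors from ratios to the geometric-mean reference."""
    logs = np.log(counts.to_numpy(dtype=float))
    with np.errstate(invalid="ignore"):
        ref = logs.mean(axis=1)
    usable = np.isfinite(ref)
    if not usable.any():
        raise ValueError("no gene with all-positive counts; cannot normalize")
    sf = np.exp(np.median(logs[usable] - ref[usable, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def de_postprocess(
    de_table: pd.DataFrame, thresholds: AnalysisThresholds = DEFAULT_THRESHOLDS
) -> Tuple[pd.DataFrame, Tuple[int, int]]:
    """Filter a differential-expression table and count up/down genes.

    Keeps rows with total reads >= ``de_min_reads`` (10), |log FC| >
    ``logfc_cut`` and FDR < ``de_fdr``. Returns the surviving rows and
    the counts of up- (log FC > 0) and down-regulated genes. The fold
    change column may be named ``log2_fc`` or ``log10_fc``; the filter
    applies to whichever is present.
    """
    fc_col = next((c for c in ("log2_fc", "log10_fc", "log_fc")
                   if c in de_table.columns), None)
    for col in ("gene", "total_reads", "fdr"):
        if col not in de_table.columns:
            raise ValueError(f"DE table missing required column {col!r}")
    if fc_col is None:
        raise ValueError("DE table missing a fold-change column "
                         "(log2_fc, log10_fc or log_fc)")
    keep = (
        (de_table["total_reads"] >= thresholds.de_min_reads)
        & (de_table[fc_col].abs() > thresholds.logfc_cut)
        & (de_table["fdr"] < thresholds.de_fdr)
    )
    filtered = de_table.loc[keep.fillna(False)].reset_index(drop=True)
    n_up = int((filtered[fc_col] > 0).sum())
    n_down = int((filtered[fc_col] < 0).sum())
    return filtered, (n_up, n_down)


def updown_proportion_test(up1: int, down1: int, up2: int, down2: int
                           ) -> Tuple[float, float]:
    """Two-sample pooled test of up- vs down-regulation proportions.

    Compares up/(up+down) between two gene sets (e.g. the regulator
    compendium vs all genes) with the pooled two-proportion z statistic;
    returns (z, two-sided p). z > 0 means group 1 leans more toward
    up-regulation.
    """
    n1, n2 = up1 + down1, up2 + down2
    if n1 <= 0 or n2 <= 0:
        raise ValueError("each group needs at least one up- or down-regulated gene")
    p1, p2 = up1 / n1, up2 / n2
    pooled = (up1 + up2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return z, p
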