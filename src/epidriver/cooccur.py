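"""Pairwise co-occurrence / mutual exclusivity of genetic alterations.

A sample counts as altered for a gene when it carries any of: at least
one nonsynonymous mutation, a fusion, a deep amplification, or a deep
deletion. Per cancer type, every gene pair gets a 2x2 table, an odds
ratio (with the Haldane-Anscombe +0.5 correction applied only when a
cell is zero), a two-sided Fisher exact p on the uncorrected table, and
BH FDR across pairs. Significant odds ratios are then averaged across
cancer types into a single per-pair direction call.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_fdr
from .types import AnalysisThresholds, CohortOmics, DEFAULT_THRESHOLDS

log = logging.getLogger(__name__)


def altered_matrix(cohort: CohortOmics) -> pd.DataFrame:
    """Boolean gene x sample matrix of 'any alteration' status."""
    altered = (cohort.sna > 0) | (cohort.cna.abs() == 2)
    if cohort.fusions is not None:
        altered |= cohort.fusions.reindex_like(altered).fillna(False).astype(bool)
    return altered


def haldane_odds_ratio(n11: int, n10: int, n01: int, n00: int) -> tuple:
    """Odds ratio with the Haldane-Anscombe correction.

    0.5 is added to all four cells if and only if at least one cell is
    zero. Returns ``(odds_ratio, correction_applied)``.
    """
    cells = np.array([n11, n10, n01, n00], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells
    return float((a * d) / (b * c)), corrected


def fisher_exact_two_sided(n11: int, n10: int, n01: int, n00: int) -> float:
    """Two-sided Fisher exact p-value of an (uncorrected) 2x2 table."""
    _, p = stats.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
    return float(p)


def pairwise_association(
    cohort: CohortOmics, genes: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Per-pair alteration association within one cohort.

    Returns one row per unordered gene pair with the 2x2 table counts,
    the (Haldane-corrected where needed) odds ratio, the two-sided Fisher
    exact p-value on the uncorrected table, BH FDR across all pairs of
    the cohort, and ``cooc_frac`` = fraction of samples with both genes
    altered.
    """
    alt = altered_matrix(cohort)
    if genes is None:
        genes = list(alt.index)
    present = [g for g in genes if g in alt.index]
    skipped = [g for g in genes if g not in alt.index]
    if skipped:
        log.warning("cohort %s: genes absent from matrices skipped from "
                    "pair analysis: %s", cohort.cancer_code, skipped[:10])
    if len(present) < 2:
        raise ValueError("need at least 2 genes for pairwise association")
    mat = alt.loc[present].to_numpy(dtype=bool)
    n = mat.shape[1]
    rows = []
    for i, j in combinations(range(len(present)), 2):
        a, b = mat[i], mat[j]
        n11 = int(np.sum(a & b))
        n10 = int(np.sum(a & ~b))
        n01 = int(np.sum(~a & b))
        n00 = n - n11 - n10 - n01
        odds, corrected = haldane_odds_ratio(n11, n10, n01, n00)
        p = fisher_exact_two_sided(n11, n10, n01, n00)
        ga, gb = sorted((present[i], present[j]))
        rows.append({
            "gene_a": ga, "gene_b": gb, "cancer_code": cohort.cancer_code,
            "n11": n11, "n10": n10, "n01": n01, "n00": n00,
            "odds_ratio": odds, "haldane_applied": corrected,
            "p_value": float(p), "cooc_frac": n11 / n,
            "marginal_a": (n11 + n10) / n, "marginal_b": (n11 + n01) / n,
        })
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p_value"])
    return out


def meta_cooccurrence(
    per_cancer: pd.DataFrame,
    thresholds: AnalysisThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Cross-cancer meta summary of pair associations.

    Per pair, a cancer type contributes when its FDR < ``fdr_sig`` and,
    for co-occurrence candidates (OR > 1), the fraction of samples with
    both genes altered reaches ``cooc_min_frac``; exclusivity candidates
    (OR <= 1) are instead required to have both marginal alteration
    fractions at that level (a both-altered filter would suppress
    exclusivity by construction). Surviving odds ratios are averaged on
    the natural scale; the direction is ``cooccur`` when all surviving
    ORs exceed 1, ``exclusive`` when all are below 1, ``mixed`` when they
    disagree, and ``none`` when no cancer survives.
    """
    rows = []
    for (ga, gb), grp in per_cancer.groupby(["gene_a", "gene_b"]):
        sig = grp["fdr"] < thresholds.fdr_sig
        cooc_ok = (grp["odds_ratio"] > 1) & (grp["cooc_frac"] >= thresholds.cooc_min_frac)
        excl_ok = (
            (grp["odds_ratio"] <= 1)
            & (grp["marginal_a"] >= thresholds.cooc_min_frac)
            & (grp["marginal_b"] >= thresholds.cooc_min_frac)
        )
        surviving = grp.loc[sig & (cooc_ok | excl_ok)]
        ors = surviving["odds_ratio"].to_numpy()
        if len(ors) == 0:
            direction = "none"
            mean_or = np.nan
        elif (ors > 1).all():
            direction = "cooccur"
            mean_or = float(ors.mean())
        elif (ors < 1).all():
            direction = "exclusive"
            mean_or = float(ors.mean())
        else:
            direction = "mixed"
            mean_or = float(ors.mean())
        rows.append({
            "gene_a": ga, "gene_b": gb,
            "mean_significant_or": mean_or,
            "n_significant_cancers": int(len(ors)),
            "direction": direction,
        })
    return pd.DataFrame(rows)
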