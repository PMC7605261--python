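"""Driver prioritization: competition ranking, the Pan-Cancer Driver
score, the Multi-Omics Driver score, and Fisher set enrichment.

The Pan-Cancer Driver ranking rewards recurrence of alteration across
cancer types. Four tracks are ranked independently -- mutations (SNA),
deep copy-number events sharing one direction (CNA), expression Z-score
aberration, and tumor/normal fold change -- each by competition ranking
on (number of qualifying cancer types, mean alteration percentage). The
four ranking scores are combined with weights SNA=1, CNA=1, Z=0.5,
FC=0.5, and the final score is the ordinal position by descending
combined score (1 = strongest candidate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import compute_alteration_frequencies
from ._stats import bh_fdr, bonferroni
from .types import AnalysisThresholds, CohortOmics, DEFAULT_THRESHOLDS

log = logging.getLogger(__name__)


def _abs_z_fraction(expr_z: pd.DataFrame, z_cut: float) -> pd.Series:
    """Fraction of non-missing samples with |Z| > z_cut, counted in one
    pass (numerically identical to a direct tally)."""
    z = expr_z.to_numpy(dtype=float)
    valid = np.isfinite(z)
    denom = valid.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0,
                        (valid & (np.abs(z) > z_cut)).sum(axis=1) / denom,
                        np.nan)
    return pd.Series(frac, index=expr_z.index)


def competition_rank(primary: pd.Series, secondary: pd.Series) -> pd.Series:
    """Ascending competition ranking score on (primary, secondary).

    Each gene's score is ``1 + (number of genes strictly lower in the
    lexicographic order on (primary count, secondary value))``. Genes
    tied on both keys share one score, and the gene after a tie group of
    size x at score y gets score y + x -- the standard competition
    ("1224") ranking.
    """
    primary = pd.Series(primary)
    secondary = pd.Series(secondary).reindex(primary.index)
    if secondary.isna().any():
        bad = secondary.index[secondary.isna()].tolist()
        raise ValueError(f"NaN secondary ranking value for {bad[:5]}")
    order = np.lexsort((secondary.to_numpy(), primary.to_numpy()))
    scores = np.empty(len(primary), dtype=int)
    prev_key = None
    prev_score = 0
    for pos, idx in enumerate(order):
        key = (primary.iloc[idx], secondary.iloc[idx])
        if key == prev_key:
            scores[idx] = prev_score
        else:
            scores[idx] = pos + 1
            prev_key, prev_score = key, pos + 1
    return pd.Series(scores, index=primary.index, name="ranking_score")


@dataclass
class _Track:
    """One ranking track: per-gene qualifying-cancer counts and means."""

    primary: pd.Series  # number of qualifying cancer types
    secondary: pd.Series  # mean alteration measure over qualifying cancers

    def rank(self) -> pd.Series:
        """Competition ranking over qualified genes (primary >= 1)."""
        qualified = self.primary[self.primary >= 1].index
        if len(qualified) == 0:
            return pd.Series(dtype=int)
        return competition_rank(self.primary[qualified], self.secondary[qualified])


def _count_and_mean(frac: pd.DataFrame, cutoff: float) -> _Track:
    """Track from a gene x cancer fraction table: count cancers at or
    above the cutoff; secondary = mean fraction over those cancers."""
    qual = frac >= cutoff
    primary = qual.sum(axis=1)
    sums = frac.where(qual).sum(axis=1)
    with np.errstate(invalid="ignore"):
        secondary = (sums / primary).fillna(0.0)
    return _Track(primary=primary.astype(int), secondary=secondary)


def pan_cancer_driver_score(
    cohorts: Sequence[CohortOmics],
    thresholds: AnalysisThresholds = DEFAULT_THRESHOLDS,
    fc_tables: Optional[Dict[str, pd.DataFrame]] = None,
) -> pd.DataFrame:
    """Pan-Cancer Driver score table over a set of cohorts.

    Tracks qualify a gene per cancer type as follows: SNA -- mutated in
    at least ``driver_freq_min_frac`` (5%) of samples; CNA -- deep
    event of one direction in at least 5% of samples, the gene's
    direction being the one qualifying in more cancer types (ties broken
    by the higher mean frequency, then toward amplification); Z -- at
    least ``z_sample_frac`` (15%) of samples with |Z| > 2; FC -- FDR <
    ``de_fdr`` and |log10 FC| > ``logfc_cut`` in the per-cancer
    tumor/normal table (``fc_tables``: cancer_code -> frame with columns
    gene, log10_fc, fdr; cancers without normals simply contribute no FC
    counts).

    Genes unqualified on a track carry no rank there and that track
    contributes 0 to the combined score, so single-track candidates stay
    comparable. Genes qualified on no track are dropped. Returns a frame
    sorted by ``pan_cancer_score`` (1 = strongest, ties share the smaller
    position).
    """
    genes = cohorts[0].sna.index
    sna_frac = pd.DataFrame(index=genes)
    amp_frac = pd.DataFrame(index=genes)
    del_frac = pd.DataFrame(index=genes)
    z_frac = pd.DataFrame(index=genes)
    for cohort in cohorts:
        prof = compute_alteration_frequencies(cohort, list(genes))
        sna_frac[cohort.cancer_code] = prof["sna_frac"]
        amp_frac[cohort.cancer_code] = prof["deep_amp_frac"]
        del_frac[cohort.cancer_code] = prof["deep_del_frac"]
        z_frac[cohort.cancer_code] = _abs_z_fraction(
            cohort.expr_z, thresholds.z_cut).reindex(genes)

    cut = thresholds.driver_freq_min_frac
    sna_track = _count_and_mean(sna_frac.fillna(0.0), cut)
    amp_track = _count_and_mean(amp_frac.fillna(0.0), cut)
    del_track = _count_and_mean(del_frac.fillna(0.0), cut)
    z_track = _count_and_mean(z_frac.fillna(0.0), thresholds.z_sample_frac)

    # the CNA track keeps, per gene, the direction qualifying in more cancers
    take_amp = (amp_track.primary > del_track.primary) | (
        (amp_track.primary == del_track.primary)
        & (amp_track.secondary >= del_track.secondary)
    )
    cna_primary = amp_track.primary.where(take_amp, del_track.primary)
    cna_secondary = amp_track.secondary.where(take_amp, del_track.secondary)
    cna_direction = pd.Series(
        np.where(cna_primary >= 1, np.where(take_amp, "amp", "del"), "NA"),
        index=genes,
    )
    cna_track = _Track(primary=cna_primary.astype(int), secondary=cna_secondary)

    if fc_tables:
        fc_primary = pd.Series(0, index=genes, dtype=int)
        fc_sums = pd.Series(0.0, index=genes)
        for cancer, table in fc_tables.items():
            t = table.set_index("gene")
            qual = (t["fdr"] < thresholds.de_fdr) & (
                t["log10_fc"].abs() > thresholds.logfc_cut
            )
            qual = qual.reindex(genes, fill_value=False)
            fc_primary += qual.astype(int)
            fc_sums += t["log10_fc"].abs().reindex(genes).where(qual, 0.0).fillna(0.0)
        with np.errstate(invalid="ignore"):
            fc_secondary = (fc_sums / fc_primary).fillna(0.0)
        fc_track = _Track(primary=fc_primary, secondary=fc_secondary)
    else:
        fc_track = _Track(
            primary=pd.Series(0, index=genes, dtype=int),
            secondary=pd.Series(0.0, index=genes),
        )

    tracks = {"sna": sna_track, "cna": cna_track, "z": z_track, "fc": fc_track}
    ranks = {name: track.rank() for name, track in tracks.items()}
    scored = sorted(set().union(*[set(r.index) for r in ranks.values()]))
    if not scored:
        log.warning("no gene passes any driver track filter; empty score table")
        return pd.DataFrame(
            columns=["sna_rank", "cna_rank", "cna_direction", "z_rank",
                     "fc_rank", "combined", "pan_cancer_score"]
        )

    out = pd.DataFrame(index=pd.Index(scored, name="gene"))
    combined = pd.Series(0.0, index=out.index)
    for name in ("sna", "cna", "z", "fc"):
        col = ranks[name].reindex(out.index)
        out[f"{name}_rank"] = col
        out[f"{name}_n_cancers"] = tracks[name].primary.reindex(out.index)
        combined += thresholds.weights[name] * col.fillna(0.0)
    out["cna_direction"] = cna_direction.reindex(out.index)
    out["combined"] = combined
    out["pan_cancer_score"] = (
        combined.rank(method="min", ascending=False).astype(int)
    )
    return out.sort_values(["pan_cancer_score", "gene"])


def multi_omics_driver_score(
    cohort: CohortOmics, thresholds: AnalysisThresholds = DEFAULT_THRESHOLDS
) -> pd.Series:
    """Within-cancer Multi-Omics Driver score in [0, 1] per gene.

    The score is the equal-weight mean of the within-cancer percentile
    ranks of three per-gene alteration measures: mutation frequency, deep
    copy-number frequency (the larger of the two directions), and the
    fraction of samples with |Z| > 2. A gene at the within-cancer maximum
    on all three scores 1.0.
    """
    if len(cohort.sna.index) < 2:
        raise ValueError(
            f"cohort {cohort.cancer_code}: need at least 2 genes to rank"
        )
    prof = compute_alteration_frequencies(cohort)
    measures = pd.DataFrame({
        "sna": prof["sna_frac"],
        "cna": prof[["deep_amp_frac", "deep_del_frac"]].max(axis=1),
        "z": _abs_z_fraction(cohort.expr_z, thresholds.z_cut).reindex(prof.index),
    })
    pct = measures.rank(pct=True, method="average")
    score = pct.mean(axis=1)
    score.name = f"multi_omics_score_{cohort.cancer_code}"
    return score


@dataclass(frozen=True)
class EnrichmentResult:
    """One Fisher-exact set-enrichment result."""

    set_name: str
    overlap: int
    set_size: int
    universe_size: int
    category_size: int
    odds_ratio: float
    p_value: float
    adjusted_p: float
    adjustment: str


def set_enrichment_fisher(
    query_set: Iterable,
    category_set: Iterable,
    universe: Iterable,
    adjustment: str = "none",
    n_comparisons: int = 1,
    set_name: str = "",
) -> EnrichmentResult:
    """One-sided (enrichment) Fisher exact test of a 2x2 overlap table.

    The universe defines the background; both sets must be subsets of it.
    ``adjustment='bonferroni'`` multiplies the p-value by
    ``n_comparisons`` (capped at 1).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query: Set = set(query_set)
    category: Set = set(category_set)
    if not query <= universe or not category <= universe:
        raise ValueError("query and category sets must be subsets of the universe")
    a = len(query & category)
    b = len(query - category)
    c = len(category - query)
    d = len(universe) - a - b - c
    odds_ratio, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    if adjustment == "bonferroni":
        adj = float(min(1.0, p * n_comparisons))
    elif adjustment == "none":
        adj = float(p)
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    return EnrichmentResult(
        set_name=set_name, overlap=a, set_size=len(query),
        universe_size=len(universe), category_size=len(category),
        odds_ratio=float(odds_ratio), p_value=float(p),
        adjusted_p=adj, adjustment=adjustment,
    )


def hallmark_enrichment(
    altered_genes: Iterable,
    hallmark_map: Dict[str, Iterable],
    universe: Iterable,
    adjustment: str = "bonferroni",
) -> pd.DataFrame:
    """Fisher enrichment of an altered-gene set in each cancer hallmark.

    ``hallmark_map`` maps gene -> hallmark labels; the test is run per
    hallmark with Bonferroni adjustment across hallmarks by default.
    """
    universe = set(universe)
    altered = set(altered_genes) & universe
    labels = sorted({h for hs in hallmark_map.values() for h in hs})
    results = []
    for label in labels:
        members = {g for g, hs in hallmark_map.items() if label in hs} & universe
        res = set_enrichment_fisher(
            altered, members, universe, adjustment="none", set_name=label
        )
        results.append(res)
    df = pd.DataFrame([r.__dict__ for r in results])
    if len(df):
        if adjustment == "bonferroni":
            df["adjusted_p"] = bonferroni(df["p_value"])
        elif adjustment == "bh":
            df["adjusted_p"] = bh_fdr(df["p_value"])
        df["adjustment"] = adjustment
    return df
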