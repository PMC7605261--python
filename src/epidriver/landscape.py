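"""Per-gene, per-cancer genetic alteration landscape.

Copy-number calls are regrouped for category labels to three levels --
no alteration, deep amplification (+2), deep deletion (-2) -- while the
shallow calls (+/-1) are retained in the all-CNA burden used for
chromosome-level summaries. A gene counts as altered in a cancer type
only if at least 1% of samples carry the alteration.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import AnalysisThresholds, CohortOmics, DEFAULT_THRESHOLDS, GeneAnnotation

log = logging.getLogger(__name__)

#: Per-sample alteration categories (mutually exclusive, exhaustive).
SAMPLE_CATEGORIES = ("amp_SNA", "del_SNA", "amp", "del", "SNA", "none")

#: Per-gene category labels (sample categories plus the multiple-alteration label).
GENE_CATEGORIES = ("SNA", "amp", "amp_SNA", "del", "del_SNA", "ma", "none")


def classify_sample_category(sna_count: int, cna_call: int) -> str:
    """Category of one (gene, sample) cell from its SNA count and CNA call.

    Deep events only; shallow calls (+/-1) behave as no CNA.
    """
    if cna_call not in (-2, -1, 0, 1, 2):
        raise ValueError(f"CNA call {cna_call!r} outside {{-2..2}}")
    has_sna = sna_count > 0
    if cna_call == 2:
        return "amp_SNA" if has_sna else "amp"
    if cna_call == -2:
        return "del_SNA" if has_sna else "del"
    return "SNA" if has_sna else "none"


def compute_alteration_frequencies(
    cohort: CohortOmics, genes: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Alteration frequencies per gene for one cohort.

    Returns a frame indexed by gene with columns ``cancer_code``,
    ``sna_frac`` (fraction of samples with >=1 nonsynonymous mutation),
    ``deep_amp_frac`` / ``deep_del_frac`` (calls +/-2), ``shallow_*``
    (+/-1), ``any_cna_frac`` (any nonzero call), and the co-occurrence
    fractions ``amp_sna_frac`` / ``del_sna_frac`` (deep event and SNA in
    the same sample) used by the gene-level category rule. Genes absent
    from the cohort get NaN frequencies, not zero.
    """
    if genes is None:
        genes = list(cohort.sna.index)
    present = [g for g in genes if g in cohort.sna.index]
    missing = [g for g in genes if g not in cohort.sna.index]
    if missing:
        log.warning(
            "cohort %s: %d requested genes missing from matrices: %s",
            cohort.cancer_code, len(missing), missing[:10],
        )
    sna = cohort.sna.loc[present]
    cna = cohort.cna.loc[present]
    n = sna.shape[1]
    mutated = sna.to_numpy() > 0
    calls = cna.to_numpy()
    out = pd.DataFrame(
        {
            "cancer_code": cohort.cancer_code,
            "sna_frac": mutated.mean(axis=1),
            "deep_amp_frac": (calls == 2).mean(axis=1),
            "deep_del_frac": (calls == -2).mean(axis=1),
            "shallow_amp_frac": (calls == 1).mean(axis=1),
            "shallow_del_frac": (calls == -1).mean(axis=1),
            "any_cna_frac": (calls != 0).mean(axis=1),
            "amp_sna_frac": ((calls == 2) & mutated).mean(axis=1),
            "del_sna_frac": ((calls == -2) & mutated).mean(axis=1),
            "n_samples": n,
        },
        index=pd.Index(present, name="gene"),
    )
    if missing:
        pad = pd.DataFrame(
            np.nan, index=pd.Index(missing, name="gene"), columns=out.columns
        )
        pad["cancer_code"] = cohort.cancer_code
        out = pd.concat([out, pad])
    return out.sort_index()


def classify_gene_category(
    profile: pd.Series, thresholds: AnalysisThresholds = DEFAULT_THRESHOLDS
) -> str:
    """Category label of one gene in one cancer from its frequency profile.

    Rules: a type counts only when its fraction reaches
    ``altered_min_frac`` (1%). When both deep amplification and deep
    deletion qualify, the one at least ``twice_rule_ratio`` times as
    prevalent as the other wins; otherwise the gene is labeled ``ma``
    (multiple alterations). When a deep CNA direction and SNA both
    qualify, the subcategory (e.g. ``amp`` vs ``amp_SNA``) follows the
    plurality of sample-level categories among the deep-event samples;
    ties give ``ma``.
    """
    t = thresholds.altered_min_frac
    sna_q = profile["sna_frac"] >= t
    amp_q = profile["deep_amp_frac"] >= t
    del_q = profile["deep_del_frac"] >= t
    if not (sna_q or amp_q or del_q):
        return "none"
    direction = None
    if amp_q and del_q:
        if profile["deep_amp_frac"] >= thresholds.twice_rule_ratio * profile["deep_del_frac"]:
            direction = "amp"
        elif profile["deep_del_frac"] >= thresholds.twice_rule_ratio * profile["deep_amp_frac"]:
            direction = "del"
        else:
            return "ma"
    elif amp_q:
        direction = "amp"
    elif del_q:
        direction = "del"
    if direction is None:
        return "SNA"
    if not sna_q:
        return direction
    co = profile[f"{direction}_sna_frac"]
    solo = profile[f"deep_{direction}_frac"] - co
    if co > solo:
        return f"{direction}_SNA"
    if co < solo:
        return direction
    return "ma"


def annotate_gene_categories(
    profiles: pd.DataFrame, thresholds: AnalysisThresholds = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Add the per-gene ``category`` column to a frequency profile frame."""
    out = profiles.copy()
    categories = []
    for _, row in out.iterrows():
        if not np.isfinite(row["sna_frac"]):
            categories.append("none")
        else:
            categories.append(classify_gene_category(row, thresholds))
    out["category"] = categories
    return out


def stratify_summaries(
    profiles: pd.DataFrame, annotations: Sequence[GeneAnnotation]
):
    """Summaries by functional class and by chromosome.

    Returns ``(per_class, per_chromosome)``:

    * ``per_class`` -- for each (cancer, erg_class): the fraction of class
      members with any alteration (category != none) plus the per-category
      breakdown of altered members.
    * ``per_chromosome`` -- for each (cancer, chromosome): the mean
      all-CNA burden (``any_cna_frac``) over resident genes, suitable for
      circos-style tracks.

    Every profiled gene must be annotated; classes with no member in the
    input are omitted with a warning.
    """
    ann = {a.symbol: a for a in annotations}
    unannotated = sorted(set(profiles.index) - set(ann))
    if unannotated:
        raise ValueError(f"unannotated genes in profiles: {unannotated}")
    if "category" not in profiles.columns:
        raise ValueError("profiles must carry a 'category' column; "
                         "run annotate_gene_categories first")
    df = profiles.copy()
    df["erg_class"] = [ann[g].erg_class for g in df.index]
    df["chromosome"] = [ann[g].chromosome for g in df.index]

    rows = []
    for (cancer, klass), grp in df.groupby(["cancer_code", "erg_class"]):
        altered = grp["category"] != "none"
        row = {
            "cancer_code": cancer,
            "erg_class": klass,
            "n_genes": len(grp),
            "altered_frac": float(altered.mean()),
        }
        for cat in ("SNA", "amp", "amp_SNA", "del", "del_SNA", "ma"):
            row[f"frac_{cat}"] = float((grp["category"] == cat).mean())
        rows.append(row)
    per_class = pd.DataFrame(rows)
    seen = set(per_class["erg_class"]) if len(per_class) else set()
    absent = sorted({a.erg_class for a in annotations} - seen)
    if absent:
        log.warning("classes with no profiled member omitted: %s", absent)

    chrom_rows = []
    for (cancer, chrom), grp in df.groupby(["cancer_code", "chromosome"]):
        chrom_rows.append({
            "cancer_code": cancer,
            "chromosome": chrom,
            "n_genes": len(grp),
            "mean_any_cna_frac": float(grp["any_cna_frac"].mean()),
        })
    per_chromosome = pd.DataFrame(chrom_rows)
    return per_class, per_chromosome
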