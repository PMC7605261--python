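"""Pooled CRISPR knockout screen: guide counting from reads, library
representation QC, per-guide enrichment/depletion testing, cross-method
and cross-timepoint consensus hit-calling, and the metastatic-vs-
nonmetastatic mutation comparison for screen hits.

Guide counting matches each read against the 20-nt spacer sequences of
the library as a substring in as-sequenced orientation (exact by
default; a mismatch budget and reverse-complement search are available
for real data). Reads matching more than one guide are discarded as
ambiguous so the accounting mapped + ambiguous + unmapped always equals
the read total.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_fdr
from .expression import median_of_ratios_size_factors
from .types import AnalysisThresholds, CohortOmics, DEFAULT_THRESHOLDS, FormatError

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_guide_library(path) -> pd.DataFrame:
    """Read a guide library TSV (guide_id, gene, spacer) and validate it."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("guide_id", "gene", "spacer"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    validate_guide_library(df)
    return df


def validate_guide_library(library: pd.DataFrame) -> None:
    if library["spacer"].duplicated().any():
        dups = library.loc[library["spacer"].duplicated(), "spacer"].tolist()
        raise FormatError(f"duplicate spacers in guide library: {dups[:5]}")
    if library["guide_id"].duplicated().any():
        raise FormatError("duplicate guide_id in guide library")
    bad = library.loc[~library["spacer"].str.fullmatch("[ACGT]+"), "spacer"]
    if len(bad):
        raise FormatError(f"spacers with non-ACGT characters: {bad.tolist()[:5]}")
    per_gene = library.groupby("gene").size()
    if (per_gene > 4).any():
        raise FormatError("more than 4 guides for genes "
                          f"{per_gene[per_gene > 4].index.tolist()[:5]}")


def _iter_fastq(path):
    """Yield (read_index, sequence) from a FASTQ file (gzip-free text)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    idx = 0
    with open(path) as fh:
        records = FastqGeneralIterator(fh)
        while True:
            try:
                _, seq, _ = next(records)
            except StopIteration:
                return
            except ValueError as exc:
                raise FormatError(
                    f"{path}: malformed FASTQ record at index {idx}: {exc}"
                ) from exc
            yield idx, seq.upper()
            idx += 1


def _match_read(seq: str, spacer_index: dict, spacer_len: int,
                max_mismatch: int, spacers: Optional[List[Tuple[str, str]]]) -> set:
    """Guide ids whose spacer occurs in ``seq`` within the mismatch budget."""
    hits = set()
    if max_mismatch == 0:
        for start in range(len(seq) - spacer_len + 1):
            guide = spacer_index.get(seq[start:start + spacer_len])
            if guide is not None:
                hits.add(guide)
        return hits
    for guide_id, spacer in spacers:
        found = False
        for start in range(len(seq) - spacer_len + 1):
            window = seq[start:start + spacer_len]
            mm = sum(a != b for a, b in zip(window, spacer))
            if mm <= max_mismatch:
                found = True
                break
        if found:
            hits.add(guide_id)
    return hits


def count_guides_from_fastq(
    fastq_paths: Dict[str, str],
    library: pd.DataFrame,
    max_mismatch: int = 0,
    search_revcomp: bool = False,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Count guide occurrences in FASTQ files, one file per condition.

    Parameters
    ----------
    fastq_paths : mapping condition label -> FASTQ path.
    library : guide library frame (guide_id, gene, spacer).

    Returns
    -------
    counts : guide x condition integer frame (library order).
    mapping_stats : per condition mapped / ambiguous / unmapped / total.
    """
    validate_guide_library(library)
    spacer_len = len(library["spacer"].iloc[0])
    if library["spacer"].str.len().nunique() != 1:
        raise FormatError("spacers must share one length")
    spacer_index = dict(zip(library["spacer"], library["guide_id"]))
    spacers = list(zip(library["guide_id"], library["spacer"]))
    counts = pd.DataFrame(
        0, index=pd.Index(library["guide_id"], name="guide_id"),
        columns=list(fastq_paths),
    )
    stats_rows = []
    for condition, path in fastq_paths.items():
        mapped = ambiguous = unmapped = total = 0
        tally: Dict[str, int] = {}
        for _, seq in _iter_fastq(path):
            total += 1
            hits = _match_read(seq, spacer_index, spacer_len, max_mismatch, spacers)
            if search_revcomp and not hits:
                hits = _match_read(reverse_complement(seq), spacer_index,
                                   spacer_len, max_mismatch, spacers)
            if len(hits) == 1:
                guide = hits.pop()
                tally[guide] = tally.get(guide, 0) + 1
                mapped += 1
            elif len(hits) > 1:
                ambiguous += 1
            else:
                unmapped += 1
        if tally:
            counts[condition] = pd.Series(tally).reindex(counts.index, fill_value=0)
        stats_rows.append({
            "condition": condition, "total": total, "mapped": mapped,
            "ambiguous": ambiguous, "unmapped": unmapped,
        })
    return counts, pd.DataFrame(stats_rows)


def gini_coefficient(values) -> float:
    """Gini coefficient of a nonnegative count vector (0 = perfectly even)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    total = x.sum()
    if n == 0 or total == 0:
        raise ValueError("cannot compute Gini of an empty or all-zero vector")
    i = np.arange(1, n + 1)
    return float(2.0 * np.sum(i * x) / (n * total) - (n + 1) / n)


def library_representation(
    counts: pd.DataFrame, condition: str, target_coverage: Optional[float] = None
) -> dict:
    """QC summary of per-guide coverage in one (baseline) condition.

    Reports mean and median coverage, the fraction of dropout guides
    (zero counts), the 90th/10th percentile skew ratio, and the Gini
    coefficient of count inequality.
    """
    if condition not in counts.columns:
        raise ValueError(f"condition {condition!r} not in counts")
    x = counts[condition].to_numpy(dtype=float)
    if len(x) == 0:
        raise ValueError("empty counts")
    p10, p90 = np.percentile(x, [10, 90])
    report = {
        "condition": condition,
        "n_guides": int(len(x)),
        "mean_coverage": float(x.mean()),
        "median_coverage": float(np.median(x)),
        "zero_fraction": float((x == 0).mean()),
        "skew_ratio_p90_p10": float(p90 / p10) if p10 > 0 else float("inf"),
        "gini": gini_coefficient(x),
    }
    if target_coverage is not None:
        report["coverage_vs_target"] = report["mean_coverage"] / target_coverage
    return report


def test_guides(
    counts: pd.DataFrame,
    comparison: Tuple[str, str],
    library: Optional[pd.DataFrame] = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-guide enrichment/depletion test between two conditions.

    ``comparison`` names (late, early) condition columns. Counts are
    normalized with median-of-ratios size factors over the two columns;
    the per-guide log2 ratio is standardized against the library-wide
    median and MAD (the null model being that most guides are unchanged),
    yielding a robust z, a two-sided normal p, and BH FDR. This is a
    self-contained per-guide test; externally computed tables (e.g. from
    dedicated count-model packages) can be fed to
    :func:`consensus_hits` in its place.
    """
    late, early = comparison
    for cond in comparison:
        if cond not in counts.columns:
            raise ValueError(f"condition {cond!r} not in counts table")
    pair = counts[[late, early]].astype(float)
    sf = median_of_ratios_size_factors(pair + 1.0)
    norm = pair.div(sf, axis=1)
    lr = np.log2((norm[late] + pseudocount) / (norm[early] + pseudocount))
    med = float(np.median(lr))
    mad = float(stats.median_abs_deviation(lr, scale="normal"))
    if mad == 0:
        z = pd.Series(np.zeros(len(lr)), index=lr.index)
    else:
        z = (lr - med) / mad
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame({
        "guide_id": counts.index,
        "comparison": f"{late}_vs_{early}",
        "log2_ratio": lr.to_numpy(),
        "z": z.to_numpy(),
        "p_value": p,
        "fdr": bh_fdr(p),
        "direction": np.where(z > 0, "enriched", "depleted"),
    })
    if library is not None:
        out = out.merge(library[["guide_id", "gene"]], on="guide_id", how="left")
    return out


def consensus_hits(
    per_method_calls: Dict[str, pd.DataFrame],
    required_comparisons: Sequence[str],
    thresholds: AnalysisThresholds = DEFAULT_THRESHOLDS,
    min_guides: int = 1,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cross-method, cross-timepoint consensus hit calling.

    A guide is a consensus hit for one comparison when every supplied
    method calls it below that method's p threshold (``screen_p``) with
    one consistent direction. A gene is a candidate when at least
    ``min_guides`` of its guides are consensus hits in *every* required
    comparison, all with one direction; genes whose guides hit in
    opposite directions are reported with direction ``mixed`` and
    excluded from candidates.

    Input frames need columns guide_id, gene, comparison, p_value,
    direction.

    Returns ``(gene_calls, guide_consensus, intersection_counts)`` where
    ``intersection_counts`` gives, per direction, the number of consensus
    guides shared by every subset of the required comparisons
    (Venn-style).
    """
    methods = list(per_method_calls)
    if not methods:
        raise ValueError("need at least one method's calls")
    for method in methods:
        if method not in thresholds.screen_p:
            raise ValueError(f"no p threshold configured for method {method!r}")
    merged = None
    for method, calls in per_method_calls.items():
        t = calls[["guide_id", "gene", "comparison", "p_value", "direction"]].copy()
        t = t.rename(columns={"p_value": f"p_{method}", "direction": f"dir_{method}"})
        merged = t if merged is None else merged.merge(
            t, on=["guide_id", "gene", "comparison"], how="inner"
        )
    if merged is None or merged.empty:
        raise ValueError("no overlapping guides between the methods' call tables")

    passing = np.ones(len(merged), dtype=bool)
    for method in methods:
        passing &= (merged[f"p_{method}"] < thresholds.screen_p[method]).to_numpy()
    same_dir = np.ones(len(merged), dtype=bool)
    first_dir = merged[f"dir_{methods[0]}"]
    for method in methods[1:]:
        same_dir &= (merged[f"dir_{method}"] == first_dir).to_numpy()
    merged["consensus"] = passing & same_dir
    merged["direction"] = first_dir
    guide_consensus = merged[["guide_id", "gene", "comparison",
                              "direction", "consensus"]].copy()

    hits = guide_consensus[guide_consensus["consensus"]]
    gene_rows = []
    for gene, grp in guide_consensus.groupby("gene"):
        gh = grp[grp["consensus"]]
        per_comp_dirs = {}
        for comp in required_comparisons:
            sub = gh[gh["comparison"] == comp]
            dirs = {
                d for d, cnt in sub.groupby("direction").size().items()
                if cnt >= min_guides
            }
            per_comp_dirs[comp] = dirs
        common = set.intersection(*per_comp_dirs.values()) if per_comp_dirs else set()
        all_dirs = set().union(*per_comp_dirs.values()) if per_comp_dirs else set()
        if len(common) == 1:
            direction, candidate = common.pop(), True
        elif len(common) > 1 or (len(all_dirs) > 1 and not common):
            direction, candidate = "mixed", False
        else:
            direction, candidate = "", False
        gene_rows.append({"gene": gene, "direction": direction,
                          "candidate": candidate})
    gene_calls = pd.DataFrame(gene_rows)

    inter_rows = []
    for direction, grp in hits.groupby("direction"):
        per_comp = {
            comp: set(grp.loc[grp["comparison"] == comp, "guide_id"])
            for comp in required_comparisons
        }
        for k in range(1, len(required_comparisons) + 1):
            for subset in combinations(required_comparisons, k):
                shared = set.intersection(*[per_comp[c] for c in subset])
                inter_rows.append({
                    "direction": direction,
                    "comparisons": "&".join(subset),
                    "n_guides": len(shared),
                })
    intersection_counts = pd.DataFrame(
        inter_rows, columns=["direction", "comparisons", "n_guides"]
    )
    return gene_calls, guide_consensus, intersection_counts


def metastasis_mutation_comparison(
    cohorts: Sequence[CohortOmics],
    gene_set: Iterable[str],
    pooled_test: bool = False,
) -> pd.DataFrame:
    """Mutation frequency of screen-hit genes in metastatic vs
    nonmetastatic clinical subsets.

    Per cancer type, each gene's mutation frequency is computed among M0
    and among M1 samples (samples with missing labels excluded); the
    per-gene result is the unweighted mean percentage across cancer types
    with at least one sample in both subsets. ``pooled_test=True`` adds
    an exploratory Fisher exact p on counts pooled across cancers.
    """
    genes = list(gene_set)
    rows = []
    for gene in genes:
        pcts_m0, pcts_m1 = [], []
        pooled = np.zeros(4, dtype=int)  # mut_m1, tot_m1, mut_m0, tot_m0
        for cohort in cohorts:
            if cohort.metastasis is None:
                continue
            if gene not in cohort.sna.index:
                log.warning("gene %s absent from cohort %s; skipped",
                            gene, cohort.cancer_code)
                continue
            labels = cohort.metastasis.reindex(cohort.sna.columns)
            m0 = labels == "M0"
            m1 = labels == "M1"
            if m0.sum() == 0 or m1.sum() == 0:
                continue
            mutated = cohort.sna.loc[gene] > 0
            pcts_m0.append(100.0 * mutated[m0.to_numpy()].mean())
            pcts_m1.append(100.0 * mutated[m1.to_numpy()].mean())
            pooled += [int(mutated[m1.to_numpy()].sum()), int(m1.sum()),
                       int(mutated[m0.to_numpy()].sum()), int(m0.sum())]
        row = {
            "gene": gene,
            "n_cancers": len(pcts_m0),
            "mean_pct_m0": float(np.mean(pcts_m0)) if pcts_m0 else np.nan,
            "mean_pct_m1": float(np.mean(pcts_m1)) if pcts_m1 else np.nan,
        }
        row["diff_pct"] = row["mean_pct_m1"] - row["mean_pct_m0"]
        if pooled_test and row["n_cancers"]:
            m1_mut, m1_tot, m0_mut, m0_tot = pooled
            _, p = stats.fisher_exact(
                [[m1_mut, m1_tot - m1_mut], [m0_mut, m0_tot - m0_mut]]
            )
            row["pooled_fisher_p_exploratory"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows)
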