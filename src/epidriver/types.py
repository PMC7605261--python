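"""Core domain types shared by every analysis stage.

The package operates on per-cancer gene-by-sample matrices in the
cBioPortal export dialects: nonsynonymous mutation counts (SNA),
GISTIC-style five-level copy-number calls (CNA), expression Z-scores and
raw read counts, and CpG methylation betas with genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: The twelve functional classes of epigenetic regulator genes:
#: histone methylation/acetylation and DNA methylation writers, editors
#: and readers, chromatin remodeling complex members, helicases, and a
#: residual "other" class.
ERG_CLASSES = (
    "HM_e", "HM_w", "HM_r",
    "DM_w", "DM_e", "DM_r",
    "HA_e", "HA_w", "HA_r",
    "ChRC", "helicase", "other",
)

#: The ten hallmarks of cancer used for gene-set enrichment.
HALLMARKS = (
    "sustaining_proliferative_signaling",
    "evading_growth_suppressors",
    "resisting_cell_death",
    "enabling_replicative_immortality",
    "inducing_angiogenesis",
    "activating_invasion_and_metastasis",
    "genome_instability_and_mutation",
    "tumor_promoting_inflammation",
    "deregulating_cellular_energetics",
    "avoiding_immune_destruction",
)

#: Variant classes counted as nonsynonymous when collapsing a mutation
#: table to per-(gene, sample) counts. Configurable at read time.
NONSYNONYMOUS_CLASSES = frozenset({
    "Missense", "Missense_Mutation",
    "Nonsense", "Nonsense_Mutation",
    "Frame_Shift", "Frame_Shift_Del", "Frame_Shift_Ins",
    "Splice_Site",
    "In_Frame", "In_Frame_Del", "In_Frame_Ins",
    "Translation_Start_Site",
    "Nonstop", "Nonstop_Mutation",
})

#: Valid five-level copy-number codes: -2 deep deletion, -1 shallow
#: deletion, 0 diploid, +1 shallow gain, +2 deep amplification.
CNA_CODES = (-2, -1, 0, 1, 2)

VALID_CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")


class FormatError(ValueError):
    """Raised when an input table violates its declared dialect."""


@dataclass(frozen=True)
class GeneAnnotation:
    """Annotation of one epigenetic regulator gene.

    Attributes
    ----------
    symbol : HGNC-style gene symbol (unique within a compendium).
    chromosome : chromosome label in {1..22, X, Y}.
    strand : '+' or '-'.
    tss : 1-based coordinate of the transcription start site.
    erg_class : one of the twelve functional classes in :data:`ERG_CLASSES`.
    hallmarks : subset of :data:`HALLMARKS` the gene participates in.
    tsg_flag, oncogene_flag : curated tumor-suppressor / oncogene flags.
    """

    symbol: str
    chromosome: str
    strand: str
    tss: int
    erg_class: str
    hallmarks: frozenset = frozenset()
    tsg_flag: bool = False
    oncogene_flag: bool = False

    def __post_init__(self):
        if self.erg_class not in ERG_CLASSES:
            raise FormatError(
                f"gene {self.symbol!r}: unknown erg_class {self.erg_class!r}; "
                f"expected one of {sorted(ERG_CLASSES)}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.symbol!r}: strand must be '+' or '-'")
        if self.tss < 1:
            raise FormatError(f"gene {self.symbol!r}: tss must be >= 1")
        if str(self.chromosome) not in VALID_CHROMOSOMES:
            raise FormatError(
                f"gene {self.symbol!r}: chromosome {self.chromosome!r} not in 1..22, X, Y"
            )
        unknown = set(self.hallmarks) - set(HALLMARKS)
        if unknown:
            raise FormatError(f"gene {self.symbol!r}: unknown hallmarks {sorted(unknown)}")


@dataclass
class CohortOmics:
    """All per-cancer omics matrices for one cohort.

    Gene-indexed matrices (``sna``, ``cna``, ``expr_z``, ``tumor_counts``)
    share one gene axis; ``methylation`` is CpG-indexed with coordinates in
    ``cpg_coords``. In SNA/CNA matrices absence of an event is coded 0; in
    expression and methylation matrices missing cells stay NaN and are
    never silently treated as zero.
    """

    cancer_code: str
    sna: pd.DataFrame
    cna: pd.DataFrame
    expr_z: pd.DataFrame
    fusions: Optional[pd.DataFrame] = None
    tumor_counts: Optional[pd.DataFrame] = None
    normal_counts: Optional[pd.DataFrame] = None
    methylation: Optional[pd.DataFrame] = None
    cpg_coords: Optional[pd.DataFrame] = None  # index cpg_id; columns chrom, pos
    metastasis: Optional[pd.Series] = None  # per sample, values in {M0, M1, NA}

    def __post_init__(self):
        genes = self.sna.index
        for name in ("cna", "expr_z"):
            other = getattr(self, name)
            if not genes.equals(other.index):
                raise FormatError(
                    f"cohort {self.cancer_code}: {name} gene axis differs from sna"
                )
        bad = ~np.isin(self.cna.to_numpy(), CNA_CODES)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"cohort {self.cancer_code}: CNA call "
                f"{self.cna.iat[i, j]!r} at gene {self.cna.index[i]!r}, "
                f"sample {self.cna.columns[j]!r} outside {{-2..2}}"
            )
        if self.methylation is not None:
            betas = self.methylation.to_numpy(dtype=float)
            finite = betas[np.isfinite(betas)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise FormatError(
                    f"cohort {self.cancer_code}: methylation betas outside [0, 1]"
                )

    @property
    def samples(self) -> list:
        return list(self.sna.columns)

    @property
    def genes(self) -> list:
        return list(self.sna.index)


@dataclass
class AnalysisThresholds:
    """Every numeric constant of the analysis, in one place.

    No other module hard-codes a threshold; changing a value here changes
    it pipeline-wide.

    Attributes
    ----------
    altered_min_frac : minimum fraction of samples altered for a gene to
        count as genetically altered at all (1%).
    cna_track_min_frac : CNA prevalence required before a gene is called
        amplified/deleted rather than merely mutated in multi-omics
        summaries (10%).
    driver_freq_min_frac : per-cancer alteration prevalence for a cancer
        type to count toward a driver-ranking track (5%).
    z_cut : expression Z-score magnitude deemed aberrant.
    z_sample_frac : fraction of samples with \\|Z\\| > z_cut required for
        the expression track of the pan-cancer driver ranking (15%).
    logfc_cut : \\|log fold change\\| cutoff for differential expression
        (default 1.0; the stricter 2.0 variant is configurable).
    de_fdr : FDR cutoff for differential expression.
    de_min_reads : minimum read coverage for a gene to enter DE results.
    r2_cna, r2_sna : R-squared cutoffs for CNA- and SNA-expression
        correlation filters (30% and 10%).
    fdr_sig : generic FDR significance level.
    cooc_min_frac : minimum fraction of samples with both genes altered
        for a co-occurrence call (0.05 or 0.10 depending on the view).
    weights : track weights combining the four driver rankings.
    twice_rule_ratio : amplification/deletion dominance ratio in gene
        category labels.
    screen_p : per-method p-value cutoffs for CRISPR-screen hit calling.
    """

    altered_min_frac: float = 0.01
    cna_track_min_frac: float = 0.10
    driver_freq_min_frac: float = 0.05
    z_cut: float = 2.0
    z_sample_frac: float = 0.15
    logfc_cut: float = 1.0
    de_fdr: float = 0.05
    de_min_reads: int = 10
    r2_cna: float = 0.30
    r2_sna: float = 0.10
    fdr_sig: float = 0.05
    cooc_min_frac: float = 0.05
    weights: dict = field(
        default_factory=lambda: {"sna": 1.0, "cna": 1.0, "z": 0.5, "fc": 0.5}
    )
    twice_rule_ratio: float = 2.0
    screen_p: dict = field(
        default_factory=lambda: {"methodA": 0.001, "methodB": 0.01}
    )

    def __post_init__(self):
        for name in ("altered_min_frac", "cna_track_min_frac", "driver_freq_min_frac",
                     "z_sample_frac", "de_fdr", "r2_cna", "r2_sna", "fdr_sig",
                     "cooc_min_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("track weights must be positive")


DEFAULT_THRESHOLDS = AnalysisThresholds()
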