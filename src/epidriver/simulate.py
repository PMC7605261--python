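"""Synthetic multi-cancer cohorts and pooled-screen data with planted,
parameterized signal.

The generator emulates the statistical structure of public pan-cancer
multi-omics exports: per-cancer background mutation and deep
copy-number rates around 1% per gene, copy-number events arranged in
contiguous blocks along each chromosome (deep events nested inside
wider shallow blocks), expression Z-scores linearly coupled to the
copy-number call, promoter CpG betas anticorrelated (or correlated)
with expression on the logit scale, negative-binomial tumor/normal read
counts, and Dirichlet-multinomial guide counts for the knockout screen.
Every planted effect is returned in truth tables so downstream stages
have a ground-truth recovery surface; no analysis module reads the
truth tables.

Reproducibility contract: one master seed with named substreams per
matrix, so the same (seed, params) always produces byte-identical
output and adding a new matrix leaves existing ones untouched.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import ERG_CLASSES, HALLMARKS, CohortOmics, GeneAnnotation

log = logging.getLogger(__name__)


class ParameterError(ValueError):
    """Raised when simulation parameters are internally inconsistent."""


def _rng(seed: int, *labels) -> np.random.Generator:
    """Named RNG substream derived from the master seed."""
    entropy = [int(seed)] + [zlib.crc32(str(l).encode()) for l in labels]
    return np.random.default_rng(entropy)


@dataclass(frozen=True)
class PlantedDriver:
    """A gene altered well above background in a set of cancer types."""

    gene: str
    sna_rate: float = 0.15
    cna_rate: float = 0.15
    cna_direction: str = "amp"  # amp | del
    cancers: Optional[Tuple[str, ...]] = None  # None = every cancer type


@dataclass(frozen=True)
class PlantedPair:
    """A gene pair with a planted alteration association (target OR)."""

    gene_a: str
    gene_b: str
    association: str = "cooccur"  # cooccur | exclusive
    strength: float = 8.0  # target odds ratio
    marginal: float = 0.2  # per-gene alteration probability


@dataclass(frozen=True)
class PlantedEQTM:
    """A promoter CpG whose beta tracks its gene's expression."""

    gene: str
    cpg_offset: int = -200  # relative to the TSS in promoter coordinates
    sign: int = -1
    strength: float = 0.9  # target |Pearson r| on the logit scale


@dataclass(frozen=True)
class PlantedMetastasisGene:
    """A gene mutated more often in metastatic (M1) samples."""

    gene: str
    rate_m1: float = 0.3
    rate_m0: float = 0.05


@dataclass(frozen=True)
class ScreenParams:
    """Pooled CRISPR screen layout: 1-4 guides per gene, one baseline
    (D0) library draw and shared underlying proportions across later
    timepoints."""

    n_genes: int = 426
    depth: int = 100_000
    concentration: float = 50.0  # Dirichlet concentration per guide
    timepoints: Tuple[str, ...] = ("D14", "D21", "D28")
    n_enriched: int = 10
    n_depleted: int = 10
    fold: float = 16.0
    spacer_length: int = 20
    flank5: str = "TATCTTGTGGAAAGGACGAAACACCG"
    flank3: str = "GTTTTAGAGCTAGAAATAGCAAGTT"


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the synthetic multi-cancer cohorts."""

    seed: int
    n_cancers: int = 6
    n_genes: int = 300
    samples_per_cancer: int = 200
    background_sna_rate: float = 0.01
    background_deep_cna_rate: float = 0.01
    mean_cna_block: float = 3.0
    cna_expr_slope: float = 0.8
    expr_noise_sd: float = 0.5
    counts_base_mean: float = 200.0
    counts_dispersion: float = 0.05
    n_normal_samples: int = 20
    de_genes: Tuple[Tuple[str, float], ...] = ()
    planted_drivers: Tuple[PlantedDriver, ...] = ()
    planted_pairs: Tuple[PlantedPair, ...] = ()
    eqtm_genes: Tuple[PlantedEQTM, ...] = ()
    metastasis_genes: Tuple[PlantedMetastasisGene, ...] = ()
    n_background_cpgs: int = 30
    metastasis_probs: Tuple[float, float, float] = (0.55, 0.35, 0.10)  # M0, M1, NA
    screen: ScreenParams = field(default_factory=ScreenParams)

    def __post_init__(self):
        for name in ("background_sna_rate", "background_deep_cna_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.expr_noise_sd <= 0:
            raise ParameterError("expr_noise_sd must be > 0")
        if self.counts_dispersion <= 0:
            raise ParameterError("counts_dispersion must be > 0")

    @property
    def cancer_codes(self) -> List[str]:
        return [f"C{i + 1:02d}" for i in range(self.n_cancers)]

    @classmethod
    def study_default(cls, seed: int) -> "SimulationParams":
        """The default desk-scale study: 6 cancers x 300 genes x 200
        samples, 1% background rates, five pan-cancer drivers at
        10-20% alteration rates, one co-occurring (OR 8) and one
        mutually exclusive (OR 0.1) pair, one strong negative promoter
        eQTM, two differentially expressed genes, and one
        metastasis-enriched gene."""
        driver_rates = (0.10, 0.125, 0.15, 0.175, 0.20)
        drivers = tuple(
            PlantedDriver(
                gene=f"G{10 + 40 * i:04d}", sna_rate=r, cna_rate=r,
                cna_direction="amp" if i % 2 == 0 else "del",
            )
            for i, r in enumerate(driver_rates)
        )
        return cls(
            seed=seed,
            planted_drivers=drivers,
            planted_pairs=(
                PlantedPair("G0251", "G0252", "cooccur", strength=8.0),
                PlantedPair("G0253", "G0254", "exclusive", strength=0.1),
            ),
            eqtm_genes=(PlantedEQTM("G0261", cpg_offset=-200, sign=-1, strength=0.9),),
            de_genes=(("G0271", 3.0), ("G0272", -3.0)),
            metastasis_genes=(PlantedMetastasisGene("G0281"),),
        )


def synthetic_annotations(
    n_genes: int, seed: int, prefix: str = "G"
) -> List[GeneAnnotation]:
    """Deterministic synthetic gene annotation.

    Genes are laid out in contiguous chromosome blocks over chromosomes
    1..22 with one gene every 100 kb, alternating strands, cycling
    through the twelve functional classes, and random hallmark
    membership (30% per hallmark).
    """
    rng = _rng(seed, "annotation", prefix, n_genes)
    annotations = []
    per_chrom = -(-n_genes // 22)  # ceil
    for i in range(n_genes):
        chrom = str(i // per_chrom + 1)
        pos_in_chrom = i % per_chrom
        hallmarks = frozenset(
            h for h in HALLMARKS if rng.random() < 0.3
        )
        annotations.append(GeneAnnotation(
            symbol=f"{prefix}{i + 1:04d}",
            chromosome=chrom,
            strand="+" if i % 2 == 0 else "-",
            tss=100_000 * (pos_in_chrom + 1),
            erg_class=ERG_CLASSES[i % len(ERG_CLASSES)],
            hallmarks=hallmarks,
        ))
    return annotations


def generate_compendium(n_genes: int = 426, seed: int = 0) -> List[GeneAnnotation]:
    """A synthetic regulator-gene compendium covering all twelve classes."""
    return synthetic_annotations(n_genes, seed, prefix="ERG")


def joint_pair_probabilities(p_a: float, p_b: float, odds_ratio: float):
    """Cell probabilities (p11, p10, p01, p00) with given marginals and OR.

    Solves the standard quadratic for p11; raises
    :class:`ParameterError` when no valid joint distribution exists.
    """
    if odds_ratio <= 0:
        raise ParameterError("odds_ratio must be positive")
    if odds_ratio == 1.0:
        p11 = p_a * p_b
    else:
        k = odds_ratio - 1.0
        s = 1.0 + (p_a + p_b) * k
        disc = s * s - 4.0 * odds_ratio * k * p_a * p_b
        if disc < 0:
            raise ParameterError("no joint distribution for these marginals and OR")
        p11 = (s - np.sqrt(disc)) / (2.0 * k)
    p10, p01 = p_a - p11, p_b - p11
    p00 = 1.0 - p_a - p_b + p11
    probs = (p11, p10, p01, p00)
    if any(p < -1e-12 for p in probs):
        raise ParameterError(
            f"pair strength OR={odds_ratio} infeasible at marginals "
            f"({p_a}, {p_b}): joint cell probabilities {probs}"
        )
    return tuple(max(p, 0.0) for p in probs)


def _chromosome_bounds(annotations: Sequence[GeneAnnotation]):
    """Half-open [start, stop) index ranges of each chromosome block."""
    bounds = []
    start = 0
    for i in range(1, len(annotations) + 1):
        if i == len(annotations) or annotations[i].chromosome != annotations[start].chromosome:
            bounds.append((start, i))
            start = i
    return bounds


def _simulate_cna(params: SimulationParams, annotations, rng) -> np.ndarray:
    """Background CNA matrix with block structure along chromosomes.

    Deep events (+/-2) occur in geometric-length runs of consecutive
    genes; each run is nested inside a wider shallow (+/-1) block,
    mimicking focal-within-broad copy-number structure.
    """
    n_genes = len(annotations)
    n_samples = params.samples_per_cancer
    cna = np.zeros((n_genes, n_samples), dtype=int)
    p_start = params.background_deep_cna_rate / params.mean_cna_block
    bounds = _chromosome_bounds(annotations)
    chrom_of = np.empty(n_genes, dtype=int)
    for b, (lo, hi) in enumerate(bounds):
        chrom_of[lo:hi] = b
    starts_matrix = rng.random((n_genes, n_samples)) < p_start
    for s in range(n_samples):
        for g in np.nonzero(starts_matrix[:, s])[0]:
            lo, hi = bounds[chrom_of[g]]
            length = rng.geometric(1.0 / params.mean_cna_block)
            sign = 2 if rng.random() < 0.5 else -2
            end = min(g + length, hi)
            cna[g:end, s] = sign
            # shallow flanks around the deep run
            ext_left = rng.geometric(0.5)
            ext_right = rng.geometric(0.5)
            left = max(g - ext_left, lo)
            right = min(end + ext_right, hi)
            for idx in range(left, g):
                if cna[idx, s] == 0:
                    cna[idx, s] = sign // 2
            for idx in range(end, right):
                if cna[idx, s] == 0:
                    cna[idx, s] = sign // 2
    return cna


def _logit_coupled_betas(x: np.ndarray, sign: int, strength: float, rng) -> np.ndarray:
    """Betas whose logit is linearly coupled to standardized x with the
    requested correlation sign and magnitude."""
    sd = x.std()
    x_std = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    if not 0 < strength < 1:
        raise ParameterError("eQTM strength must lie in (0, 1)")
    slope = strength / np.sqrt(1.0 - strength**2)
    logit = sign * slope * x_std + rng.normal(0.0, 1.0, size=x.shape)
    return 1.0 / (1.0 + np.exp(-0.8 * logit))


def simulate_multi_cancer_cohorts(
    params: SimulationParams,
    annotations: Optional[Sequence[GeneAnnotation]] = None,
):
    """Generate one :class:`CohortOmics` per cancer type plus truth tables.

    Returns ``(cohorts, annotations, truth)`` where ``truth`` maps table
    names (drivers, pairs, eqtms, metastasis_genes) to frames listing
    every planted effect. Truth tables exist for test oracles only.
    """
    if annotations is None:
        annotations = synthetic_annotations(params.n_genes, params.seed)
    gene_index = pd.Index([a.symbol for a in annotations], name="gene")
    gene_pos = {a.symbol: i for i, a in enumerate(annotations)}
    ann_by_symbol = {a.symbol: a for a in annotations}
    for planted in (
        [d.gene for d in params.planted_drivers]
        + [p.gene_a for p in params.planted_pairs]
        + [p.gene_b for p in params.planted_pairs]
        + [e.gene for e in params.eqtm_genes]
        + [m.gene for m in params.metastasis_genes]
    ):
        if planted not in gene_pos:
            raise ParameterError(f"planted gene {planted!r} not in the annotation")

    n_samples = params.samples_per_cancer
    cohorts = []
    for code in params.cancer_codes:
        samples = [f"{code}_S{j + 1:04d}" for j in range(n_samples)]

        rng_sna = _rng(params.seed, "sna", code)
        sna = (rng_sna.random((params.n_genes, n_samples))
               < params.background_sna_rate).astype(int)

        rng_cna = _rng(params.seed, "cna", code)
        cna = _simulate_cna(params, annotations, rng_cna)

        rng_drv = _rng(params.seed, "drivers", code)
        for drv in params.planted_drivers:
            if drv.cancers is not None and code not in drv.cancers:
                continue
            g = gene_pos[drv.gene]
            sna[g] = (rng_drv.random(n_samples) < drv.sna_rate).astype(int)
            deep = rng_drv.random(n_samples) < drv.cna_rate
            cna[g] = np.where(deep, 2 if drv.cna_direction == "amp" else -2, 0)

        rng_pair = _rng(params.seed, "pairs", code)
        for pair in params.planted_pairs:
            if pair.association == "cooccur" and pair.strength <= 1:
                raise ParameterError("cooccur pair needs strength (OR) > 1")
            if pair.association == "exclusive" and pair.strength >= 1:
                raise ParameterError("exclusive pair needs strength (OR) < 1")
            p11, p10, p01, _ = joint_pair_probabilities(
                pair.marginal, pair.marginal, pair.strength
            )
            u = rng_pair.random(n_samples)
            both = u < p11
            only_a = (u >= p11) & (u < p11 + p10)
            only_b = (u >= p11 + p10) & (u < p11 + p10 + p01)
            sna[gene_pos[pair.gene_a]] = (both | only_a).astype(int)
            sna[gene_pos[pair.gene_b]] = (both | only_b).astype(int)

        rng_z = _rng(params.seed, "expr_z", code)
        z = params.cna_expr_slope * cna + rng_z.normal(
            0.0, params.expr_noise_sd, size=cna.shape
        )

        rng_counts = _rng(params.seed, "tumor_counts", code)
        mu = params.counts_base_mean * np.power(2.0, 0.5 * z)
        r = 1.0 / params.counts_dispersion
        tumor_counts = rng_counts.negative_binomial(r, r / (r + mu))

        # methylation: planted promoter CpGs, decoys in the same
        # windows, and background CpGs placed away from promoters
        rng_meth = _rng(params.seed, "methylation", code)
        cpg_rows, beta_rows = [], []
        log_expr = np.log2(tumor_counts + 1.0)
        for eq in params.eqtm_genes:
            ann = ann_by_symbol[eq.gene]
            offset = eq.cpg_offset if ann.strand == "+" else -eq.cpg_offset
            cpg_rows.append((f"cg_{eq.gene}_planted", ann.chromosome,
                             ann.tss + offset))
            beta_rows.append(_logit_coupled_betas(
                log_expr[gene_pos[eq.gene]], eq.sign, eq.strength, rng_meth
            ))
            for k, decoy_offset in enumerate((-700, 300)):
                off = decoy_offset if ann.strand == "+" else -decoy_offset
                cpg_rows.append((f"cg_{eq.gene}_decoy{k}", ann.chromosome,
                                 ann.tss + off))
                beta_rows.append(rng_meth.beta(2.0, 2.0, size=n_samples))
        for k in range(params.n_background_cpgs):
            ann = annotations[int(rng_meth.integers(0, params.n_genes))]
            cpg_rows.append((f"cg_bg{k:04d}", ann.chromosome,
                             ann.tss + 50_000 + int(rng_meth.integers(0, 40_000))))
            beta_rows.append(rng_meth.beta(2.0, 2.0, size=n_samples))
        cpg_ids = [r[0] for r in cpg_rows]
        cpg_coords = pd.DataFrame(
            {"chrom": [r[1] for r in cpg_rows], "pos": [r[2] for r in cpg_rows]},
            index=pd.Index(cpg_ids, name="cpg_id"),
        )
        methylation = pd.DataFrame(
            np.vstack(beta_rows) if beta_rows else np.empty((0, n_samples)),
            index=pd.Index(cpg_ids, name="cpg_id"), columns=samples,
        )

        rng_meta = _rng(params.seed, "metastasis", code)
        labels = rng_meta.choice(
            ["M0", "M1", "NA"], size=n_samples, p=list(params.metastasis_probs)
        )
        for mg in params.metastasis_genes:
            g = gene_pos[mg.gene]
            draw = rng_meta.random(n_samples)
            rates = np.where(labels == "M1", mg.rate_m1,
                             np.where(labels == "M0", mg.rate_m0,
                                      params.background_sna_rate))
            sna[g] = (draw < rates).astype(int)

        cohorts.append(CohortOmics(
            cancer_code=code,
            sna=pd.DataFrame(sna, index=gene_index, columns=samples),
            cna=pd.DataFrame(cna, index=gene_index, columns=samples),
            expr_z=pd.DataFrame(z, index=gene_index, columns=samples),
            tumor_counts=pd.DataFrame(tumor_counts, index=gene_index,
                                      columns=samples),
            methylation=methylation,
            cpg_coords=cpg_coords,
            metastasis=pd.Series(labels, index=samples, name="metastasis"),
        ))

    truth = {
        "drivers": pd.DataFrame([{
            "gene": d.gene, "sna_rate": d.sna_rate, "cna_rate": d.cna_rate,
            "cna_direction": d.cna_direction,
            "cancers": ",".join(d.cancers) if d.cancers else "all",
        } for d in params.planted_drivers]),
        "pairs": pd.DataFrame([{
            "gene_a": p.gene_a, "gene_b": p.gene_b,
            "association": p.association, "strength": p.strength,
            "marginal": p.marginal,
        } for p in params.planted_pairs]),
        "eqtms": pd.DataFrame([{
            "gene": e.gene, "cpg_id": f"cg_{e.gene}_planted",
            "sign": e.sign, "strength": e.strength,
        } for e in params.eqtm_genes]),
        "metastasis_genes": pd.DataFrame([{
            "gene": m.gene, "rate_m1": m.rate_m1, "rate_m0": m.rate_m0,
        } for m in params.metastasis_genes]),
    }
    return cohorts, list(annotations), truth


def simulate_tumor_normal_counts(
    params: SimulationParams,
    n_tumor: Optional[int] = None,
    n_normal: Optional[int] = None,
    annotations: Optional[Sequence[GeneAnnotation]] = None,
):
    """Negative-binomial tumor and adjacent-normal count matrices.

    Per-gene base means are log-normal around ``counts_base_mean``;
    tumor means of the planted DE genes are scaled by 2**effect;
    per-sample library size factors are uniform in [0.7, 1.4]. Returns
    ``(tumor_counts, normal_counts)``.
    """
    if annotations is None:
        annotations = synthetic_annotations(params.n_genes, params.seed)
    genes = pd.Index([a.symbol for a in annotations], name="gene")
    n_tumor = params.samples_per_cancer if n_tumor is None else n_tumor
    n_normal = params.n_normal_samples if n_normal is None else n_normal
    rng = _rng(params.seed, "tumor_normal_counts")
    mu = np.exp(rng.normal(np.log(params.counts_base_mean), 0.5, size=len(genes)))
    effect = pd.Series(0.0, index=genes)
    for gene, log2_effect in params.de_genes:
        if gene not in effect.index:
            raise ParameterError(f"DE gene {gene!r} not in the annotation")
        effect[gene] = log2_effect
    mu_tumor = mu * np.power(2.0, effect.to_numpy())
    lib_t = rng.uniform(0.7, 1.4, size=n_tumor)
    lib_n = rng.uniform(0.7, 1.4, size=n_normal)
    r = 1.0 / params.counts_dispersion

    def draw(mu_vec, libs, label):
        m = np.outer(mu_vec, libs)
        return pd.DataFrame(
            rng.negative_binomial(r, r / (r + m)),
            index=genes, columns=[f"{label}{j + 1:03d}" for j in range(len(libs))],
        )

    return draw(mu_tumor, lib_t, "T"), draw(mu, lib_n, "N")


@dataclass
class ScreenSimulation:
    """Everything one simulated screen run produced."""

    library: pd.DataFrame  # guide_id, gene, spacer
    counts: pd.DataFrame  # guide x condition
    truth: pd.DataFrame  # planted guide effects
    fastq_paths: Dict[str, str]


def simulate_screen_data(
    params: SimulationParams, out_dir: Optional[str] = None
) -> ScreenSimulation:
    """Simulate the pooled knockout screen.

    Day-0 counts are Dirichlet-multinomial around an even library; at
    each later timepoint the underlying proportions of planted guides
    are multiplied by the fold effect (enriched) or its inverse
    (depleted) and counts are re-drawn at the same depth. When
    ``out_dir`` is given, one uncompressed FASTQ per condition is
    written with each guide's spacer embedded in fixed flanking
    sequence, one read per count.
    """
    sc = params.screen
    rng_lib = _rng(params.seed, "screen", "library")
    genes = [f"SG{i + 1:04d}" for i in range(sc.n_genes)]
    guides_per_gene = rng_lib.integers(1, 5, size=sc.n_genes)
    rows = []
    seen = set()
    alphabet = np.array(list("ACGT"))
    for gene, k in zip(genes, guides_per_gene):
        for j in range(k):
            while True:
                spacer = "".join(rng_lib.choice(alphabet, size=sc.spacer_length))
                if spacer not in seen:
                    seen.add(spacer)
                    break
            rows.append({"guide_id": f"{gene}_g{j + 1}", "gene": gene,
                         "spacer": spacer})
    library = pd.DataFrame(rows)
    n_guides = len(library)

    rng_counts = _rng(params.seed, "screen", "counts")
    p0 = rng_counts.dirichlet(np.full(n_guides, sc.concentration))
    conditions = {"D0": rng_counts.multinomial(sc.depth, p0)}

    planted_idx = rng_counts.choice(
        n_guides, size=sc.n_enriched + sc.n_depleted, replace=False
    )
    fold_vec = np.ones(n_guides)
    fold_vec[planted_idx[:sc.n_enriched]] = sc.fold
    fold_vec[planted_idx[sc.n_enriched:]] = 1.0 / sc.fold
    weights = p0 * fold_vec
    p_late = weights / weights.sum()
    for tp in sc.timepoints:
        conditions[tp] = rng_counts.multinomial(sc.depth, p_late)
    counts = pd.DataFrame(
        conditions, index=pd.Index(library["guide_id"], name="guide_id")
    )

    truth = library.iloc[planted_idx][["guide_id", "gene"]].copy()
    truth["direction"] = (["enriched"] * sc.n_enriched
                          + ["depleted"] * sc.n_depleted)
    truth["fold"] = np.where(truth["direction"] == "enriched",
                             sc.fold, 1.0 / sc.fold)
    truth = truth.reset_index(drop=True)

    fastq_paths: Dict[str, str] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rng_fq = _rng(params.seed, "screen", "fastq")
        spacers = library["spacer"].to_numpy()
        for condition in counts.columns:
            vec = counts[condition].to_numpy()
            order = rng_fq.permutation(np.repeat(np.arange(n_guides), vec))
            path = out / f"screen_{condition}.fastq"
            with open(path, "w") as fh:
                for read_no, guide_idx in enumerate(order):
                    seq = sc.flank5 + spacers[guide_idx] + sc.flank3
                    fh.write(f"@{condition}_read{read_no}\n{seq}\n+\n"
                             f"{'I' * len(seq)}\n")
            fastq_paths[condition] = str(path)
    return ScreenSimulation(library=library, counts=counts, truth=truth,
                            fastq_paths=fastq_paths)
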