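# Methods

`epidriver` re-implements, as a tested library, a pan-cancer multi-omics
analysis of epigenetic regulator genes (ERGs): genes encoding writers,
editors and readers of DNA methylation and histone marks, chromatin
remodelers and helicases. The pipeline integrates per-cancer somatic
mutation (SNA), gene-level copy-number (CNA), expression and promoter
methylation matrices, ranks candidate driver genes, tests pairwise
co-occurrence of alterations, and calls consensus hits from pooled
CRISPR knockout screens. Because the original clinical inputs are
consortium-scale (tens of thousands of tumors), the package ships a
synthetic-cohort generator that emulates their statistical structure at
desk scale and plants known signal, so every stage has a ground-truth
recovery surface.

## Data model and conventions

All gene-indexed matrices in a `CohortOmics` share one gene axis; genes
sort lexicographically, samples keep file order. Coordinates are 1-based
inclusive (cBioPortal/MAF convention). CNA calls use the five-level
code: −2 deep deletion, −1 shallow deletion, 0 diploid, +1 shallow gain,
+2 deep amplification. In mutation and CNA matrices an absent event is
0; in expression and methylation matrices missing stays `NaN` and never
silently becomes 0. Every numeric constant lives in
`AnalysisThresholds`; no other module hard-codes a threshold.

Mutation tables collapse to per-(gene, sample) counts of nonsynonymous
records; the nonsynonymous class list (missense, nonsense, frameshift,
splice-site, in-frame indel, translation-start, nonstop) is configurable
because export dialects vary.

## Alteration landscape

Per gene and cancer type we report the fraction of samples with ≥1
nonsynonymous mutation, with deep (±2) and shallow (±1) events per
direction, and with any CNA. For category labels copy number is
regrouped to three levels (none / deep amp / deep del); shallow-only
events are excluded from labels but retained in the all-CNA burden used
for chromosome summaries. A gene counts as altered only when an
alteration type reaches `altered_min_frac` (1% of samples). When both
deep directions qualify, the direction at least twice as prevalent wins,
otherwise the gene is labeled `ma` (multiple alterations). When a deep
direction co-qualifies with mutations, the subcategory (`amp` vs
`amp_SNA`) follows the plurality of sample-level categories among the
deep-event samples, ties giving `ma` — the frequency-level rules do not
themselves decide this split, so the plurality rule was chosen for
determinism and is exercised by exhaustive boundary fixtures.

## Driver scores

**Competition ranking.** Items are ordered ascending on (primary count,
secondary value); an item's ranking score is 1 + the number of items
strictly lower; full ties share one score and the next distinct item
skips by the tie-group size ("1224" ranking). The implementation is
checked against the quadratic brute-force definition on a thousand
random instances.

**Pan-Cancer Driver score.** Four tracks qualify a gene per cancer
type: SNA — mutated in ≥5% of samples; CNA — deep events of one
direction in ≥5% (the gene's direction is the one qualifying in more
cancers; ties break to the higher mean frequency, then toward
amplification); Z — ≥15% of samples with |Z| > 2; FC — FDR < 0.05 and
|log₁₀FC| above `logfc_cut` in a tumor/normal table (default 1.0; 2.0
available, as both cutoffs appear in the source analyses). Each track is
competition-ranked on (number of qualifying cancers, mean alteration
percentage over those cancers; mean chosen over max for stability). The
four ranking scores combine as 1·SNA + 1·CNA + 0.5·Z + 0.5·FC (the two
expression tracks share one unit of weight), and the final score is the
ordinal position by descending combined score, 1 = strongest, ties
sharing the smaller position. A gene unqualified on a track contributes
0 there rather than a minimum rank, so single-track candidates remain
comparable. Cancers without normal tissue simply contribute no FC
counts.

**Multi-Omics Driver score.** The within-cancer score is the
equal-weight mean of the percentile ranks of three per-gene measures:
mutation frequency, deep-CNA frequency (larger direction), and the
|Z| > 2 sample fraction. The exact formula of the original score is not
published in the article text, so this percentile-mean definition is a
documented stand-in with the same inputs and intent; it is validated
against a brute-force percentile oracle, not against published values.

**Set enrichment.** Driver-set and hallmark enrichment use the
one-sided Fisher exact test on the 2×2 overlap table, Bonferroni-
adjusted across the ten hallmarks. The background universe is an
explicit required argument because enrichment is meaningless without
one.

## Co-occurrence / mutual exclusivity

A sample is altered for a gene if it carries a nonsynonymous mutation, a
fusion, or a deep CNA. Per cancer type each unordered gene pair gets a
2×2 table; the odds ratio applies the Haldane–Anscombe correction (+0.5
to all four cells) if and only if a cell is zero, while the two-sided
Fisher exact p is computed on the uncorrected table; BH FDR is taken
across pairs within each cancer type (matching per-cancer reporting).
Significant (FDR < 0.05) odds ratios are averaged across cancer types on
the natural scale. Co-occurrence candidates (OR > 1) must additionally
have ≥`cooc_min_frac` (5%, configurable to 10%) of samples with both
genes altered; exclusivity candidates are instead required to have both
marginal alteration fractions at that level, since a both-altered filter
would suppress exclusivity by construction. The pair direction is
`cooccur`/`exclusive` when all surviving ORs agree, `mixed` otherwise,
`none` with no surviving cancer.

## Expression integration

Z-aberration rates count samples beyond |Z| > 2 over non-missing cells.
Alteration–expression correlation is Pearson with the CNA call (−2..+2)
or the 0/1 mutation indicator (point-biserial) as predictor; genes with
<3 paired observations or zero predictor variance are skipped with a
recorded reason; the significance filter is R² > 30% (CNA) or > 10%
(SNA) with FDR < 0.05, FDR families per cancer and track.

The eQTM scan assigns a CpG to a gene when it falls in the strand-aware
promoter window (1000 bp upstream to 500 bp downstream of the TSS,
mirrored on the − strand) and correlates the beta with
log₂(count + 1)-transformed expression by default (Pearson on raw counts
is unstable; a raw mode exists for the literal protocol). BH FDR runs
over all tested pairs; the minimum-p CpG per gene is flagged as the
gene's top association. A `drop_sex_chroms` switch exists because
X-linked correlations can be confounded in mixed-sex cohorts.

Differential expression is consumed, not owned: the post-processing
filter (total reads ≥ 10, |logFC| > cutoff, FDR < 0.05) and the pooled
two-proportion z-test of up- vs down-regulated counts operate on any DE
table. A deliberately plain built-in (`nb_wald_de`: median-of-ratios
size factors, method-of-moments NB dispersion, Wald test on log₂ fold
change) exists so the pipeline runs without external tools; it labels
its output `nb-wald-mom` and makes no claim to replicate shrinkage-based
DE packages.

## CRISPR screen

Guide counting matches each read against the library's 20-nt spacers as
substrings in as-sequenced orientation, exact by default (the amplicon
design fixes orientation); reverse-complement search and a Hamming
mismatch budget are available for real data. Reads matching more than
one guide are discarded as ambiguous, and mapped + ambiguous + unmapped
always equals the read total. Library QC reports mean/median coverage,
dropout fraction, the p90/p10 skew ratio and the Gini coefficient.

The per-guide test normalizes the late/early pair with median-of-ratios
size factors, takes log₂ ratios with a 0.5 pseudocount, and standardizes
against the library-wide median and MAD — the null model being that most
guides are unchanged — yielding a robust z, two-sided normal p and BH
FDR. It is a self-contained substitute for external count-model tools,
whose p-value tables can be supplied directly to the consensus step to
reproduce the original two-package design (cutoffs 0.001 and 0.01 per
method). A guide is a consensus hit when every supplied method passes
its threshold with one direction; a gene is a candidate when ≥1 of its
guides (configurable to ≥2) is a consensus hit in *every* required
timepoint comparison with a single direction; genes hit in opposite
directions are reported `mixed` and excluded. Venn-style intersection
counts across comparisons are emitted.

For screen hits, mutation frequencies are compared between metastatic
(M1) and nonmetastatic (M0) clinical subsets: per cancer type the
frequency in each subset, then the unweighted mean percentage across
cancer types with samples in both subsets; a pooled Fisher test is
available but flagged exploratory since the comparison is descriptive.

## Synthetic cohorts: what they emulate, and what they do not

Defaults are 6 cancer types × 300 genes × 200 samples; background
mutation and deep-CNA rates 1% per gene; CNA events in geometric-length
runs (mean 3 genes) along chromosome blocks, each deep run nested in a
wider shallow block, mimicking focal-within-broad structure; expression
Z = 0.8·CNA + N(0, 0.5); planted pair associations realized by sampling
the exact joint distribution with the requested marginals and odds ratio
(Plackett construction); promoter CpG betas logit-linearly coupled to
log expression with a chosen correlation sign and magnitude, next to
decoy and background CpGs; tumor/normal counts negative-binomial
(dispersion 0.05, log-normal gene means around 200, uniform 0.7–1.4
library factors); screen counts Dirichlet-multinomial (concentration 50,
depth 10⁵) over a 426-gene, 1–4-guides-per-gene library, with planted
guides' underlying proportions multiplied by a 16-fold effect at the
later timepoints and FASTQ reads embedding each spacer in fixed flanks.
One master seed with named substreams per matrix makes output
byte-identical for identical parameters and insensitive to adding new
matrices.

The generator makes no attempt to match real mutation spectra,
trinucleotide signatures, chromosome lengths, GISTIC peak structure, or
inter-gene expression correlation. Passing recovery tests therefore
demonstrates that the statistical machinery detects the effects it
claims to detect at realistic effect sizes and sample counts — not that
it would rank any particular real gene as a driver.

## Numerical choices and degenerate inputs

Fisher p-values for degenerate 2×2 margins (an empty row or column) are
1.0. The Haldane correction applies only when a cell is zero, asserted
pairwise in tests. The Z-aberration measure inside the driver scores is
a direct |Z| > 2 tally rather than a sum of the up and down fractions,
because the float epsilon of the sum can split percentile-rank tie
groups. Competition ranking requires a non-NaN secondary key and raises
otherwise. Pair odds ratios of exactly 1 are excluded from co-occurrence
candidacy (strict OR > 1). With a zero MAD the guide test reports z = 0
for all guides rather than dividing by zero. All simulation fractions
are validated into [0, 1]; expression noise and NB dispersion must be
positive.

## Problem sizes

The test suite runs the full stack at the sizes above: 20-seed recovery
and calibration loops for drivers, pairs, eQTMs and screen hits, an
exhaustive Fisher-vs-enumeration sweep over all 2×2 margin symmetry
classes up to n = 60 (~87,000 tables), and 1000 random ranking
instances; the whole suite completes in well under a minute on one core.
`scripts/acceptance.py` recomputes the same quantities at 10 stochastic
seeds per block in a few seconds.

## Known limitations

The Multi-Omics Driver score is a documented stand-in (above). The
built-in DE and guide tests are intentionally simple; for publication-
grade calls users should feed external DE/count-model tables into
`de_postprocess` and `consensus_hits`. Co-occurrence averages odds
ratios on the natural scale to match the source procedure; a geometric
mean is arguably better-behaved when mixing OR > 1 and OR < 1 and can be
computed from the per-cancer table the pipeline emits. Fusion calls
default to absent when no fusion matrix is provided. The guide counter
is pure Python and intended for desk-scale FASTQ (~10⁵–10⁶ reads); real
screens at much greater depth would want an indexed aligner upstream.
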