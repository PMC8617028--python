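# Methods

This note records the models implemented by `tme_atlas`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer should know about.

## Coordinate and format conventions

All genomic coordinates are 0-based half-open `[start, end)` (BED /
10x-fragments convention). Gene annotation arrives as a TSV already in
this convention; GTF/GFF conversion is out of scope. Mitochondrial genes
are identified by contig name (default `chrMT`, with `MT`/`chrM`
accepted as aliases), not by symbol prefix, because mito gene lists vary
across references; the contig name is configurable. Genes without
annotation stay in expression analyses but are excluded from CNV and
gene-activity computations, which need positions.

## Cell QC and normalization

Removal rules are strict inequalities — a cell is removed when its
total UMI count is *less than* 2000, detected genes *less than* 500,
mitochondrial percentage *more than* 20, UMIs *above* 70,000 or detected
genes *above* 10,000 — so boundary cells are kept. The kept set is the
conjunction of the rules and is order-independent; per-rule attrition
counts do depend on order, so `sequential_attrition` reports them in the
fixed order depth → complexity → mito → doublet ceilings alongside the
order-free flags. Filtering is monotone under threshold relaxation.

Normalization scales each cell to a common target (default: the median
of per-cell totals, the common library-size default) and applies
natural-log1p. Zero-total cells are left all-zero with a warning rather
than dropped, since dropping is QC's job.

HVG selection ranks genes by the z-score of their dispersion
(variance/mean of log-normalized values) within 20 equal-occupancy
mean-expression bins; z ties break by raw dispersion, then gene id, so
the selection is deterministic. Covariate residualization is per-gene
OLS with an intercept; collinear covariate columns are dropped greedily
(rank test) with a warning naming them. The heat-shock-protein covariate
accepts a user gene list and otherwise falls back to the `HSP` symbol
prefix with a warning, because published analyses typically leave that
list unstated.

## Expression-inferred CNV

Log-normalized expression is centered per gene on the mean over
baseline (nonmalignant stromal/immune) cells and clipped to ±3; a
moving average over 101 genes ordered by chromosome and start smooths
the centered values, with windows truncated (shrunk) at chromosome ends
so the profile keeps one value per gene and never crosses a chromosome
boundary; finally the mean baseline profile is subtracted so the normal
karyotype sits at zero. Window 101 and clip ±3 are the documented
defaults of the standard expression-CNV tool; both are parameters (the
bundled toy genome, with ≤ 100 genes per chromosome, uses window 31).
The smoothing is linear, and baseline cells' post-subtraction per-bin
means are zero to numerical precision.

The malignancy score is our own minimal operationalization of the
qualitative "large-scale CNVs present/absent" judgment: the per-cell
mean of squared profile values, thresholded at the 0.95 quantile of the
baseline cells' scores. Denoising and HMM segmentation are deliberately
not reimplemented; the profile is a relative-expression proxy, not an
absolute copy number.

## Mixability entropy

Per-cell Shannon entropy (base 2) of the patient composition among the
k = 80 nearest neighbors by Euclidean distance in a supplied
low-dimensional embedding, with 0·log 0 := 0. Cohorts above 25,000
cells are uniformly subsampled first, and neighbors are computed within
the subsample (a flag allows searching against all cells instead).
Neighbor search is exact — chunked all-pairs distances with ties broken
by ascending cell index — because approximate or tie-arbitrary search
would make the statistic run-dependent. H is invariant to patient-label
permutation and rigid embedding transforms, bounded by log2(D), and
never increased by merging patient labels.

## Signatures, markers, transfer, druggability

Gene-set scores are unweighted means of log-normalized expression over
the set genes present in the matrix (no background-gene subtraction —
matching the plain-average definition), optionally min–max scaled to
0–1 per set. Marker ranking is one-vs-rest Wilcoxon rank-sum with the
normal approximation (tie and continuity corrected) and BH adjustment
within each group; log2 fold changes use a 1e-9 pseudocount. The test
choice is a documented default and swappable. DEG and expression
filters follow the printed cutoffs exactly: log2FC strictly greater
than 0.2, adjusted P strictly below 0.05, expressed = nonzero in at
least 10% of cells (boundary included).

Cross-dataset comparison aggregates the union of each population's
top-50 markers (restricted to genes shared by all datasets) into mean
expression profiles and correlates them pairwise (Pearson). Origin
transfer assigns each query cell the reference centroid with the
highest Spearman correlation over shared marker genes — rank-based, so
invariant to monotone per-cell transforms — with ties resolved to the
lexicographically first label and flagged. Druggable-gene intersection
takes each group's top-100 markers against a drug–gene category table,
dropping rows in excluded categories (default: the sequence/structure-
predicted "druggable genome" catch-all); genes in several categories
count once per category.

## scATAC and ChIP

Each fragment contributes two Tn5 insertion events, at `start` and
`end − 1` (10x fragments files are already shift-corrected; the
convention is configurable to `(start, end)`). Insertions are counted
into non-overlapping 2.5 kb windows tiling each chromosome, the last
window truncated at the chromosome end, so per-cell insertion totals
are exactly twice the summed fragment counts.

Cell QC keeps cells with 1000–20,000 fragments in peaks (inclusive),
FRiP > 0.10, TSS enrichment > 2, blacklist ratio < 0.05 and nucleosome
signal < 4. TSS enrichment and nucleosome signal have no printed
formulas anywhere we could anchor them, so the standard definitions are
used and documented as assumptions tied to the printed cutoffs: TSS
enrichment is position-averaged insertion coverage within ±500 bp of
the TSSs over the mean coverage in the two 100 bp flanks at ±(900–1000)
bp (flank floored at 0.1 to guard empty flanks); nucleosome signal is
the count of mono-nucleosome-length fragments (147–294 bp) over
sub-nucleosomal fragments (< 147 bp), denominator floored at 1. Any
rule can be disabled explicitly; disabling is required when no TSS list
is supplied.

TF-IDF follows the printed formula on the binarized matrix: term
frequency divides each cell by its total, inverse document frequency is
`ln(1 + n_cells / n_cells_containing_feature)` (natural log; base
configurable). The description "binarized and then log-normalized" is
reconciled with that formula as binarize → TF-IDF, with an optional
log1p of the weighted values off by default. All-zero cells are dropped
with a warning; all-zero features get a feature-sum floor of 1 and are
flagged. LSI is a truncated SVD of the TF-IDF matrix; the cell
embedding is U·S with the first, depth-correlated component dropped by
default (components 2–30), and a fixed sign convention (largest feature
loading positive per component) plus a seeded start vector make it
deterministic.

Gene activity counts insertions in the gene body extended 2 kb upstream
of the TSS, strand-aware, clamped at chromosome bounds; the extent is
configurable since only "gene-associated accessibility" is specified.
Active promoters are genes with an H3K4me3 peak whose interval lies
within 1000 bp of the TSS (interval-to-point distance; we bind the
distance to the H3K4me3 peak, the stated rule's plainest reading) and
which overlaps an H3K27ac peak by ≥ 1 bp; the rule is monotone in the
distance cutoff. Co-accessibility networks keep Pearson edges with
r ≥ 0.15 over per-gene activity profiles, excluding zero-variance genes
with a warning. Peak calling, motif analysis and DA testing are out of
scope; peaks and blacklists are inputs.

## Synthetic cohorts: what is and is not emulated

The generator draws UMI counts from a negative binomial whose mean is
`base_mean_g × patient_factor × program_fold × cnv_fold × libsize_c`
with one shared dispersion (θ = 2). The default design is 15 patients
across three subtypes, 200 cells each, on a toy genome of 192 nuclear
genes (two chromosomes, 10 kb gene spacing) plus 8 mitochondrial genes
— small enough that the full suite runs in well under a minute. Planted
structure: a chr22 fold-0.5 loss in malignant cells (≈ half the
genome's genes, emulating an arm-level loss), disjoint 10-gene fold-3
marker programs for the TAM/T/fibroblast types, a 5% mitochondrial
fraction, lognormal library (σ = 0.25) and patient (σ = 0.10) factors,
and 1% doublet-like cells at 12× depth (doublets are modeled only as
total-count inflation because the in-scope doublet rule is a
threshold). Programs are kept to ~5% of the toy genome deliberately:
in real data cell-type programs are a vanishing fraction of the
genome-wide average the CNV profile relies on, and inflating them
further would let program-bearing baseline cells dominate the
mean-squared CNV score — a toy-genome artifact, not a property of the
method. `expected_centered_shift` provides the design's analytic
expectation for the centered log expression (exact NB pmf summation
with the depth factor integrated out by Gauss–Hermite quadrature),
which recovery tests compare against.

Embeddings are Gaussian blobs around per-patient ("separated") or
per-cell-type ("mixed") centroids on a wide circle — designed entropy
extremes, not UMAP geometry. Fragments concentrate in each type's
designated 2.5 kb windows (default 90%) with uniform noise elsewhere
and a realistic sub-/mono-nucleosomal length mixture; no TSS pileup is
planted, so the pipeline's synthetic ATAC branch disables the
TSS-enrichment rule and states so. ChIP peaks realize a designed
active-gene list exactly (joint marks near the TSS) while inactive
genes get one mark or distal marks only.

Consequently, passing tests demonstrate that each statistic recovers
the effect it targets under its own model assumptions at toy scale;
they do not demonstrate robustness to ambient RNA, batch-specific
gene-length effects, realistic manifold geometry, per-gene dispersion
heterogeneity, or controlled-access cohort scale, none of which the
generator emulates. Headline counts of the motivating studies
(e.g. total retained cells) depend on restricted patient data and
external tool stages and are not reproduced here.

## Determinism and problem sizes

Every stochastic step flows from one master seed; stage seeds are
derived by hashing `"{seed}:{stage}"` (kept below 2^31). Reruns with
the same config and seed are hash-identical on all stage outputs; the
run report omits wall-clock times so it regenerates byte-identically
from a manifest. Default analysis sizes — 3000-cell cohorts for
RNA-side checks, 120 cells × 1500 fragments for the ATAC branch,
5-patient 1500-cell cohorts for entropy regimes — were chosen so the
full pipeline completes in a few seconds while keeping every planted
effect comfortably above its detection threshold.

## Known limitations

- The CNV malignancy score is a package-specific operationalization;
  published analyses typically judge profiles visually or with HMMs.
- The Wilcoxon p-value uses the normal approximation; for very small
  groups an exact test is preferable (tests verify 0.02 agreement at
  n = 6).
- Gene-activity counting is plain insertion counting without distance
  weighting or size-factor correction.
- The kNN search is exact and O(n²) in memory-chunked passes; beyond
  ~50k cells an approximate index would be the practical choice, at the
  cost of the determinism guaranteed here.
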