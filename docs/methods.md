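# Methods

This note documents the models and procedures implemented in `skintx`, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not demonstrate.

## Synthetic cohort model

Counts are drawn from a gamma–Poisson (negative binomial) model:
gene g has a log-normal base mean μ_g ~ LogNormal(−0.7, 1), cell i a
log-normal size factor s_i ~ LogNormal(0, 0.3), and the observed count is
Poisson(λ) with λ ~ Gamma(1/φ, φ·s_i·μ_g·f_ig), giving variance
m + φ·m² around the mean m. The single dispersion φ (default 0.3) is in
the range typically estimated for droplet scRNA-seq. The per-cell fold
f_ig carries all planted structure:

* **CNV blocks** multiply block-gene means by 2^(log2FC) in a donor's
  malignant cells. By default each donor's clone gains/loses three whole
  donor-specific autosomes at |log2FC| = 1 — clonal aberrations in this
  malignancy are typically arm- to chromosome-scale, and whole-chromosome
  blocks keep the planted fold analytically checkable.
* **Lineage skew**: each malignant cell is assigned TH2 with the donor's
  skew probability (default 0.6; the remainder split TH1/TH17), and its
  marker factor's mean (TBX21/GATA3/RORC) is raised to 3.0 against a 0.05
  baseline, so detection-by-argmax is informative but not noise-free.
* **Shared activity programs** (default: one 30-gene set shared by all
  donors) multiply the program genes' means 8× in a random 30% of each
  member donor's malignant cells — a bimodal, high-dispersion pattern of
  the kind NMF factorizes into a module.
* **Outliers**: 5% of cells get doublet scores drawn far above the lane
  median (Beta(25,12) vs Beta(2,40) baseline) and 5% get mito fractions
  above the QC cut (Beta(12,18) vs Beta(2.5,30)).

The gene annotation is deterministic: 22 autosomes + X with genes evenly
spaced, the lineage factors and 13 `MT-` genes placed at the end of X so
auto-placed (autosomal) CNV blocks never overlap them. Default sizes — 6
donors × 400 cells × 3,450 genes (150 genes per chromosome) — were chosen
so every chromosome holds more genes than the default 101-gene CNV window
while a full pipeline run stays interactive on one CPU; the recovery
tests use these sizes, with 2,000 cells/donor for the TH2-fraction check
where the binomial sampling error must fall below ±0.05.

The generator does **not** emulate ambient RNA, UMI collisions, batch
effects beyond size factors, cell-cycle structure, realistic gene-gene
correlation, subclonal CNV hierarchies, or read-level artifacts. Passing
recovery tests therefore demonstrate correctness of the implemented
procedures under the stated generative model, not robustness to every
failure mode of real tissue data.

## QC

All inequalities are strict exactly as stated (mito > 0.20 fails; detected
genes < 400 fails; counts < 1,000 fails; a cell on every boundary passes).
MAD is the raw median absolute deviation — no 1.4826 consistency scaling —
because the rule is stated in plain MAD units; the multiplier (default 4)
is configurable. Doublet thresholds are computed per sequencing lane
(column `lane`; one global lane is assumed when absent). Filter order is
doublets → cell rules → gene rule, with gene prevalence recomputed after
cell removal; the order is a documented choice. When `mito_frac` metadata
is absent it is computed as the count share of genes whose symbol starts
with `MT-`.

## CNV inference and malignancy calling

This is a deliberately simplified reference-based scheme, not a
reimplementation of HMM-based CNV callers. Steps per cell: (1) scale to
10,000 counts and log2(x+1) — the transform is a standard choice, (2)
subtract each gene's mean over reference cells, (3) clamp to ±3, (4)
sliding mean over 101 genes within each chromosome, truncated at
chromosome ends (101 is the cited convention for fixed-length windows;
configurable), (5) subtract the cell's median, (6) subtract the per-gene
reference mean of the smoothed matrix. Chromosomes with fewer genes than
the window are dropped with a warning. X is ordered last; Y/MT genes are
outside the annotation and thus never enter the analysis.

The malignancy score — mean squared smoothed value — and its threshold
(reference mean + k·s.d., k = 3) are this package's operational definition
of "extensive CNV burden"; published studies typically read malignancy off
the heat map. Clone partitioning uses average-linkage clustering on
1 − Pearson correlation of CNV profiles, cut at correlation 0.5; linkage
and cut are configurable since no standard exists. At least 10 reference
cells are required to estimate the threshold.

## Expression programs and metaprograms

Normalization is 10,000-count scaling + natural log1p. HVG selection ranks
genes by dispersion (variance/mean of log-normalized values) z-scored
within 20 equal-width mean bins — a binned-dispersion stand-in for the
common variable-feature heuristic; bins with no spread contribute z = 0,
so a set of planted genes isolated in its own bin can in principle be
under-ranked (the recovery tests run at the default broad selection of
2,000 HVGs where this does not bite). Scaling fits per-gene OLS of
expression on mito fraction, z-scores the residuals and clips at ±10;
residual s.d. below 1e−10 of the gene scale counts as zero (degenerate
genes are set to 0).

NMF uses Lee–Seung multiplicative updates minimizing Frobenius error,
seeded uniform initialization, stop at relative error change < 1e−4 or 500
iterations, factors ranked by explained energy ‖W_j‖·‖H_j‖. One rank-10
factorization is run per tumor (a multi-rank survey would also be valid;
one fit is deterministic and fast, and the rank is configurable). A
program's per-cell score is its H row scaled to unit maximum; the s.d.
filter (> 0.1) applies to that score — the underlying quantity is not
standardized anywhere, so this definition is documented rather than
asserted as canonical. Programs are computed on malignant cells only.

Metaprogram clustering is average linkage on 1 − Jaccard, cut at
1 − j_min (j_min = 0.25); clusters spanning ≥ 2 tumors qualify, and
consensus genes are ranked by recurrence. Method and cut are this
package's choices.

## Lineage, stage comparison, pseudo-bulk

The classification rule — strict argmax among the three factors, requiring
detection (> min_expr, default 0) — is an operational definition; ties or
all-zero cells stay unassigned and are excluded from fraction
denominators. The rank-sum test enumerates all C(n, n₁) assignments of the
observed pooled values when n ≤ 12 (an exact permutation test, valid with
ties) and otherwise uses the tie-corrected normal approximation with
continuity correction; its type-I error is calibrated in the acceptance
suite at the study's group sizes (18 vs 21). Pseudo-bulk DE (CPM
fold-change with +1 pseudocount, rank-sum p across donors, exact
Benjamini–Hochberg) is a simple donor-replicate stand-in and is documented
as non-equivalent to count-model quasi-likelihood tests.

## Spatial axis and microenvironments

Adjacency links spots within 1.2× the interspot distance — on both square
and hexagonal lattices this captures exactly the nearest neighbors.
Surface spots are epidermis-flagged spots with fewer neighbors than a full
neighborhood (4 on square, 6 on hexagonal layouts; layout detected from
array-coordinate parity). Distances are Euclidean to the nearest surface
spot in units of the interspot distance (100 μm). Distance bins round half
up (1.49 → 1, 1.5 → 2); per bin the population s.d. is reported (0 for
singleton bins) with two bands: mean ± 2·s.d./√n (default confidence band)
and mean ± 2·s.d. (spread band) — both are emitted because "2 s.d.
confidence interval" conventions differ. Microenvironment NMF shares the
core factorizer (cell types × spots orientation); per-type weights are
normalized to sum 1, assignment is argmax, all-zero types get uniform
weights and a flag. Silhouettes use Euclidean distance on the normalized
weight vectors, with singleton clusters scored 0.

## Numerical notes and limitations

* All randomness flows from one `numpy` Generator per entry point;
  identical config + seed reproduces outputs bit-for-bit, including
  written fixture bytes.
* Ties are broken deterministically everywhere (lexicographic gene ids in
  program extraction and clonotype calls; smallest minimum barcode for
  tissue-component ties).
* The CNV stand-in has no denoising beyond window averaging and no
  subclone trees; closely related subclones within a donor are merged at
  the default correlation cut.
* `pseudobulk_de` treats donors as exchangeable replicates; no covariate
  adjustment or paired designs.
* The exact rank-sum branch is O(C(n, n₁)) and capped at pooled n = 12.
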