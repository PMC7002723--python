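# Methods

This note documents the model, the algorithms, the simulator, and the
numerical and design choices behind `tacna`, in the package's own words.

## Model

Bulk tumor expression is modeled as an additive mixture of latent regulatory
factors. For a standardized gene × sample matrix **X** (p genes, n samples;
each gene row mean 0, sample variance 1 with denominator n−1):

    X ≈ Sᵀ M

where **S** (i × p) holds *estimated sources* — per-gene weights describing
how strongly and in which direction a latent factor moves each gene's
expression — and **M** (i × n) holds the per-sample *mixing coefficients*
(factor activities). Sources whose extreme weights concentrate in a
contiguous genomic region are interpreted as the transcriptional footprint of
a copy-number alteration (CNA-CES); the remainder capture dispersed regulation
(proliferation programs, microenvironment composition, technical factors).
Within a CNA-CES, a gene's absolute weight is read as the inverse of its
*degree of transcriptional adaptation*: maximal weight means expression
follows copy number proportionally, vanishing weight means the CNA is fully
buffered.

## Consensus ICA

**Whitening / component count.** The SVD of X is computed once. Explained
variance fractions are σ²ₖ/Σσ²; the component count *i* is the smallest
number of top components reaching the `variance_threshold` (default 0.85).
Because gene rows are already centered, the SVD is taken directly on X with
no further column centering — this keeps the additive identity below exact.
Singular-vector signs are canonicalized (largest-|entry| of each left
singular vector positive), which makes whitening — and therefore the entire
decomposition — invariant to the order of the input samples.

**Per-run ICA.** Fixed-point ICA (log-cosh contrast, symmetric/parallel
updates; scikit-learn's `FastICA` with `whiten=False`) is run on the whitened
gene-side factors Y = U·√p. Defaults: 25 runs, `max_iter=500`, `tol=1e-4` —
the noise-floor components of a ≥85%-variance subspace rarely reach a tighter
tolerance, and the stable components are unchanged by it (we verified
identical cluster structure at `max_iter=1500, tol=3e-4`). A run hitting the
iteration cap is retried once with a derived seed and then returned with a
recorded `IcaConvergenceWarning`; per-run seeds come from one master seed via
a counter-based seed sequence, so results do not depend on execution order.
Each run's sources are rescaled to unit gene-variance (mixing rescaled
inversely), so every run satisfies sourcesᵀ·mixing = rank-i PCA approximation
of X exactly.

The decomposition requires centered gene rows but does not *require* unit
gene variance: standardization is the normal preparation for real data, but a
noiseless low-rank matrix must not be rescaled per gene — there each gene's
variance comes entirely from the k sources, so per-gene rescaling divides
every loading vector by its own norm, collapsing the loadings onto the unit
sphere and destroying the independence structure ICA needs. The Laplacian
test bed (`simulate_laplacian_dataset`) therefore centers without rescaling.

**Clustering and consensus.** Sources from all runs are clustered greedily
(icasso-style): seeds are visited in descending (run, component) order; a
seed collects from each other run its best-correlated unclustered component
when |Pearson r| > `r_threshold` (0.9), so a cluster holds at most one member
per run. Members are sign-aligned to the seed before averaging (unaligned
averaging would cancel, since ICA is sign-indeterminate). The credibility
index of a cluster is its size divided by the number of runs; clusters below
`credibility_min` (0.5) are dropped. Consensus sources are rescaled to unit
gene-variance and oriented so their largest-magnitude weight is positive.

**Mixing refit.** When the data matrix is available (the pipeline default)
the consensus mixing matrix is refit by least squares against X rather than
taken as the member mean. This restores the model's defining property —
the inner product of weights and coefficients reproduces the (rank-i)
expression level — exactly: with credibility filtering disabled, consensus
sources span the full i-dimensional PCA subspace and the refit reconstruction
equals the rank-i PCA approximation to machine precision (measured RMS
~5·10⁻¹⁵ at p=2000, n=200). Member-mean coefficients remain available by
calling `consensus()` without X.

**Projection.** New standardized samples are profiled against a fixed source
set by least squares on the shared gene set (≥50% overlap required), which is
what makes the method usable across platforms and cohorts.

## Region detection

Per source: genes are flagged *extreme* when |weight − median| exceeds
`z_threshold` (3.0) robust standard deviations (1.4826·MAD; mean/SD fallback
when the MAD is zero). A `window_size`-gene window (50) slides along each
chromosome in genome order (windows never span chromosomes; a chromosome
shorter than the window is one window of its own length). A window is
significant when its extreme count strictly exceeds the binomial critical
value at level α/(number of windows tested), with success probability equal
to the genome-wide extreme fraction — Bonferroni across windows within a
source, no correction across sources (each source is an independent call).

Significant windows overlapping or within `merge_gap` (10) genes are merged.
Within each merged span, extreme genes are grouped at gaps ≤ `merge_gap`;
each group is trimmed to its outermost extreme genes, extended over runs of
adjacent extremes (regions are maximal: one more gene is either non-extreme
or on another chromosome), and kept only with ≥ `min_extreme_in_region` (10)
extremes. The grouping step is the package's boundary-precision choice:
windows overlapping a true region's edge are significant on in-region
extremes alone, so the merged span contains up to a window of flank; without
grouping, a single stray extreme flag there (ICA estimation noise) drags the
boundary tens of genes outward. Grouping reuses the existing `merge_gap`
parameter and implies that consecutive extremes within one region are never
more than `merge_gap` genes apart.

**Known limitation — small genomes.** The null success probability is the
*genome-wide* extreme fraction, which includes the signal itself. On a toy
genome where one region is a fifth of all genes, the inflated fraction raises
the critical value to the region size and the scan stays silent. At realistic
gene counts (regions ≪ genome) the contamination is negligible. The scan is
also conservative by construction (Bonferroni): on 100 pure-noise sources at
the reference genome we observe 0 false CNA-CES calls.

## TACNA reconstruction

Non-CNA-CES components are removed; within CNA-CESs, weights outside marked
regions are set to zero; TACNA profiles are the product of this masked weight
matrix with the mixing matrix. Genes outside every marked region therefore
have identically zero rows. Centering subtracts, per gene, the Hodges–Lehmann
estimate (median of all Walsh averages (xᵢ+xⱼ)/2, i ≤ j) of the gene's TACNA
values over normal samples, giving zero the interpretation of a two-copy
state. Enumeration is exact up to 10⁴ normals, with a seeded subsample
beyond. Centering is global (per dataset), not per tumor type. The complement
reconstruction — all components except CNA-CESs with ≥ `min_region_genes`
(50) region genes — captures the non-CNA transcriptome; by construction it
and the excluded components' reconstruction sum exactly to the full one.

## Derived metrics

- **Degree of adaptation:** within each marked region of ≥2 genes, absolute
  weights are rank-transformed (average ties) to (rank−1)/(m−1) ∈ [0, 1];
  the highest |weight| maps to 0. A rank-based scale (not min–max) keeps the
  metric distribution-free so genes can be pooled across regions. When a gene
  lies in several marked regions the minimum metric is recorded.
- **CNA burden:** per sample, the sum of *absolute* mixing coefficients over
  CNA-CESs with ≥50 region genes, min–max normalized within tumor type.
  Absolute values because mixing signs depend on the arbitrary source
  orientation; a raw sum would let gains and losses cancel.
- **Immune metric:** per sample, each panel gene's expression is ranked
  (ascending, average ties) among all genes; the mean panel rank is min–max
  normalized within tumor type. Default panel (CD8⁺ T/NK activity): CD2,
  CD3E, CD247, GZMK, NKG7, PRF1; configurable. Rank-based, hence invariant to
  any monotone transform of the expression scale.
- **TACNA-vs-CNA correlation:** per sample, Pearson r between the TACNA
  column and the gene-level segment means (each gene takes the seg_mean of
  the segment containing its interval midpoint), over genes inside ≥1 marked
  region (all-genes variant available). Samples whose copy-number vector has
  zero variance — e.g. CNA-free normals — are reported missing: a correlation
  with a constant is undefined, and any fixed-pattern surrogate would be
  chance-limited at ~1/√(#regions) regardless of signal amplitude. The
  substantive normal-tissue check is amplitude: in the reference simulation
  normals' in-region TACNA RMS is ~0.13× the tumors'.
- **Cross-dataset CNA-CES comparison:** Spearman ρ on absolute weights over
  shared genes in the union of two components' marked regions (≥10 genes).
  Matched components across replicate cohorts correlate at ρ ≈ 0.5–0.7 — not
  higher, because per-gene standardization rescales weights by a gene
  variance that fluctuates between cohorts — while components for *different*
  regions anti-correlate strongly (complementary support on the union).

## The simulator

`simulate_dataset` generates X = true_sourcesᵀ·true_mixing + noise, then
standardizes per gene. Reference conditions (the packaged defaults):
4000 genes on 8 chromosomes (1-kb genes, uniform spacing), 300 samples with
10% normal tissue, 6 CNA sources with non-overlapping regions of 60–150 genes
(round-robin over chromosomes), 6 confounders, gene-level noise SD 0.3, seed 7.

- **CNA sources:** weight (1−a) inside the region, 0 outside, with per-gene
  attenuation a ~ U(0, 0.9). Mixing coefficients are discrete copy states
  {−1, 0, +1, +2} (loss/neutral/gain/amplification) drawn with probabilities
  0.15/0.55/0.20/0.10 for tumors and exactly 0 for normals — block-structured
  like real CNAs, so expression correlates region-wise with the SEG truth.
- **Confounders:** five diffuse programs with Laplace(0, 0.25) weights over
  all genes plus one proliferation-like program hitting a random 10% of genes
  with N(0, 1) weights. The Laplace scale is set so latent programs account
  for roughly 80% of standardized variance — the regime of bulk expression
  data, where biological structure dominates measurement noise — which places
  the 85%-variance component count at a few dozen: the selected subspace
  contains all planted sources plus a noise margin, as in real cohorts.
- **SEG truth:** per sample, each chromosome is tiled into background
  segments (seg_mean 0) and one segment per planted region with
  seg_mean = log2((2+c)/2); the gene-level mapping of this file reproduces
  the planted truth exactly.
- **Seeding:** one seed drives everything; an optional `structure_seed`
  replays the same planted genome (regions, attenuation) under different
  sampling, for cross-cohort experiments.

What the simulator does **not** emulate: platform/probe effects, batch
structure, count noise, correlated gene–gene coexpression beyond the planted
factors, subclonal or partially overlapping CNAs, and normals with their own
(noisy) measured copy-number profiles. Passing tests therefore demonstrate
correct recovery under the stated factor model, not performance on any
particular real platform.

## Determinism

Identical inputs and seeds give bit-identical outputs (same build of
numpy/scikit-learn). Sample-order invariance holds up to component order with
|r| > 0.99, enabled by the canonical SVD signs. The CLI writes a JSON
provenance record (version, resolved config, seeds, input checksums) with
every run.

## Degenerate inputs

Constant gene rows are dropped at standardization (their z-score is undefined
and they carry no signal). Constant weight vectors flag no extremes. A
zero-variance copy-number vector yields a missing correlation. Regions with a
single gene are skipped by the adaptation transform (its 0–1 scale needs two
genes). Tumor types with one sample get a missing normalized burden/immune
score. An empty consensus (all clusters below the credibility threshold) and
an empty CNA-CES set (nothing to reconstruct) are typed errors, as is
centering without normals — which the error message says to skip explicitly.
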