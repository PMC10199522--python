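# Methods

This note documents the models implemented in `embryosex`, the assumptions
behind the synthetic-data generator, and the numerical and design choices
made where the problem left them open.

## Synthetic data generator

`simulate_counts` emulates the structure of two-species pre-implantation
single-cell datasets: stage-labelled cells of both sexes, negative-binomial
counts with excess zeros, X/Y/autosomal gene classes, and planted effects
for every downstream module to recover.

**Count model.** Counts are NB draws, sampled as gamma–Poisson mixtures,
with gene/cell mean

    mu_gc = baseline_g × program_m(g)(stage_c) × 2^(±log2FC if planted)

and dispersion following the trend `alpha(mu) = a0 + a1/mu`. There is no
explicit zero-inflation: excess zeros arise from low means, which matches
the premise of deconvolution normalization without adding unidentifiable
parameters. Baselines are log-normal (`exp N(1.0, 1.2)` by default), giving
a realistic spread from sub-detection to hundreds of counts.

**Defaults** (chosen once; all overridable through `SimConfig`): 2000
genes, 4 stages, 30 cells per stage per sex; 5% X-linked and 2% Y-linked
genes; 8% transcription factors and 4% epigenetic enzymes; 20 planted
sex-differential genes per stage at |log2FC| = 2 (stage-disjoint, never
Y-linked, never the markers); dispersion trend `0.1 + 1/mu`, typical of
UMI-free single-cell protocols.

**Sex structure.** Y-linked genes are structurally zero in female cells.
The X-linked female marker (Xist-like) is constitutively high in females
(mean 50) and near-silent in males (mean 0.2) from the first simulated
stage — it is treated as a technical control, not a dynamic readout. The
Y-linked male marker (Eif2s3y-like) has mean 30 in males, so a male cell
fails to express it with probability ≈ 1e-5.

**Stage programs.** A configurable fraction of genes (60% by default)
belongs to one of `n_metagenes` programs whose stage profiles are smooth
bumps peaking at different stages; these drive the PCA stage clustering and
give the PPI simulator its module structure.

For factorization benchmarks, `simulate_metagene_matrix` plants an explicit
`V ≈ W₀H₀` with block-structured gene loadings and Dirichlet-mixed sample
columns sharpened toward each sample's block. The mixing matters: with hard
block assignments every under-ranked factorization is perfectly stable
(its consensus matrix is exactly ultrametric, cophenetic = 1), and no
stability criterion can prefer the true rank. Dirichlet mixing produces
genuinely ambiguous boundary samples — as adjacent embryonic stages do —
which destabilizes under-ranked fits while leaving the planted rank
recoverable.

**What the generator does not model:** zygotic-genome-activation dynamics,
batch effects, doublets, X-dosage compensation dynamics, gene-length
effects. Passing tests therefore demonstrate correctness of the estimators
under the stated NB model, not robustness to those real-data artifacts.

## QC

Genes detected in fewer than `min_cells` (default 3) cells are removed
first; cells with fewer than `min_features` (default 350) detected genes —
recomputed after gene removal — are removed second. The fixed gene-then-
cell order makes the filter deterministic and idempotent. RIKEN clones are
identified by the case-insensitive symbol suffix `Rik`. "Expressed" in a
cell group always means detected (count > 0) in at least one cell of the
group; expressed fractions are reported per chromosome class relative to
annotated genes of that class.

## Deconvolution size factors

Per-cell median-of-ratios scaling fails on sparse counts because most
gene-wise ratios are 0/0. Instead, cells are ordered on a ring by library
size and overlapping windows (default widths 21, 41, 61, 81, 101, clipped
to `n_cells − 1`) are pooled. Each pool contributes one equation: the
median, over genes with mean count ≥ `min_mean` (default 0.1), of pooled
count over the average pseudo-cell estimates the sum of the pool's factors.
Each cell also contributes one augmentation row of weight 1e-4 tying its
factor to its library-size factor, which anchors the scale-free system
without ridge regularization. The sparse system is solved by LSQR at
tolerance 1e-12; non-positive solutions are floored at 1e-8 with a warning
and factors are rescaled to mean 1 exactly. No pre-clustering is applied
(the intended datasets are a few hundred cells). Log-normalization is
`log2(count/sf + 1)`; base 2 keeps fold changes and loadings on the same
scale as the DE output.

## Sexing

The per-cell rule, on raw counts (raw rather than normalized, to avoid
circularity with size-factor estimation): Y-marker zero with X-marker
expressed → female; Y-marker expressed with X/Y ratio < 1 → male; ratio
≥ 1 → ambiguous; both markers zero → ambiguous (insufficient signal).
Ratio exactly 1 is ambiguous by declaration. Ambiguous cells are removed
from downstream metadata with a logged count. `y_presence` mode (for
datasets sexed upstream by Y expression) labels male iff summed Y-linked
counts exceed a threshold, default 0.

## Variance partition

PCA is computed by SVD of the per-gene-centered, unscaled log-normalized
matrix with samples as observations. Variance partitioning is per-gene
one-way R² (between-group over total sum of squares): stage across all
cells, sex within each stage — a per-stage readout of the sex contribution
rather than a joint two-factor decomposition, because the quantity of
interest is how the sex effect decays across stages. Constant genes score
0; stages with a single sex report missing values. Under the null, E[R²]
≈ 1/(n−1), which the tests verify.

## Sex-differential expression

Within each stage, every non-all-zero gene is fit with an NB GLM (log
link): `log mu = b0 + b1·female + log sf`, so `b1 > 0` means female-biased
(declared orientation, used everywhere). Single cells are treated as
replicates within stage; no pseudo-bulking.

*Dispersion:* method-of-moments `alpha = max(0, (s² − mu)/mu²)` on
size-factor-scaled counts, a Huber-robust regression of positive estimates
on `1/mu` for the trend, and a geometric-mean shrink
`trend^w · alpha^(1−w)` with `w = 0.5`, floored at 1e-8. This replaces the
full empirical-Bayes machinery of reference DE packages; the contract is
calibration and power, verified by simulation (null false-positive rate,
KS uniformity of Wald p-values, ≥ 90% power at planted log2FC = 2 with
mu = 20, alpha = 0.1, n = 20/20), not bit-compatibility.

*Wald test:* IRLS with fixed per-gene dispersion, vectorized across genes
(binary design → closed-form 2×2 weighted normal equations per gene),
linear predictor clipped to ±30, convergence at step < 1e-8 within 100
iterations. Non-converged genes (typically genes expressed in only one
sex, e.g. Y-linked) keep estimates but report missing p-values. p-values
are two-sided normal.

*Shrinkage:* zero-centered normal prior on `b1`; with the normal
approximation to the likelihood the posterior mode is
`b1 · tau²/(tau² + se²)`. The prior SD is fitted by matching the 95th
percentile of |b1| to the quantile implied by `b1 ~ N(0, tau² + med(se²))`,
floored so the prior stays proper. Shrunken magnitudes never exceed raw
ones.

*Thresholds:* BH within each stage; biased iff `|log2FC_shrunk| ≥ 0.58`
and `padj < 0.05`. Upset-style intersection tables count each gene once
under its exclusive membership pattern.

## Enrichment grids

Each (stage, direction, category) cell is a hypergeometric test with the
universe = genes tested (expressed) at that stage. `p_over = P(X ≥ k)` and
`p_under = P(X ≤ k)` both include the observed point, so they sum to ≥ 1.
Categories are protein-coding, TF, epigenetic enzyme, autosome, X, Y; the
chromosome categories partition any DEG set. Cells with fewer than 5 DEGs
or 5 category members are flagged low-confidence; no correction is applied
across grid cells (flags are reported instead). The regulator census ranks
genes per stage by mean normalized expression (ties broken by gene id) and
counts TF/EE flags among the top 1000.

## NMF and rank selection

Generalized KL divergence `D(V‖WH)` is minimized by Lee–Seung
multiplicative updates from seeded uniform-(0,1] initializations scaled to
the data mean; the objective trace is recorded and is non-increasing by
construction. Convergence is declared at relative objective change < 1e-6
(default) or `max_iter`. For rank selection, each rank is fit from 10
seeded starts; samples are partitioned by argmax of H; the consensus
matrix is the fraction of runs co-assigning each sample pair; and the
cophenetic coefficient correlates `1 − C` with the cophenetic distances of
its average-linkage dendrogram (defined as 1 when all dissimilarities are
equal). The chosen rank maximizes the cophenetic curve, smallest rank on
ties. Gene→metagene assignment is argmax of the W row; all-zero rows are
left unassigned. Known limitation: stability-based selection degrades for
small sample tables (a few tens of samples), where under-ranked fits can
be spuriously stable; the tests treat recovery at the smallest table size
as a majority-over-replicates property.

## Pre-ranked GSEA

Genes are ranked by non-negative scores (metagene loadings), descending,
ties broken by gene id. The running sum adds `w^p / Σ_hits w^p` (exponent
p = 1) at members and subtracts `1/(N − |set|)` at non-members; ES is the
running maximum (positive scoring). Sets are filtered to [15, 500] after
intersection with the ranked universe. The null redraws the member labels
uniformly (size-preserving gene permutation), `p = (1 + #{ES* ≥ ES})/(1 +
n_perm)` with default n_perm = 1000, `NES = ES / mean(ES*)`, BH across
sets. This Monte-Carlo null estimates the same estimand as adaptive
multilevel schemes but is directly verifiable against exhaustive set
enumeration on small universes.

## PPI edge classes

Stage subgraphs keep edges whose endpoints are both expressed at the stage
(same detection rule as QC). Endpoints are labelled male-biased / female-
biased / non-DE; the six unordered pair classes are counted. Within-class
counts are normalized by the class's node count; cross-class counts by the
geometric mean of the two class sizes (a declared extension — the
within-class convention does not determine a cross-class denominator).
Empty classes report missing, not zero. The hive layout places each class
on a pair of axes, alternating nodes in degree order, position = rank
within the axis, ties by gene id.

## Cross-species conservation

Cells are mapped onto shared generalized developmental groups (S1–S4).
For each ortholog pair, group-mean profiles are z-scored within species
(removing species-level scale) and scored by Pearson correlation across
groups; constant profiles are reported missing. Significance comes from
shuffling the ortholog pairing (`n_perm` global permutations, +1-corrected
p). This is a defined, testable statistic standing in for embedding-based
positional similarity, which cannot be specified precisely; outputs are
labelled accordingly. The top-expression mask marks entries strictly above
the gene's q-quantile across samples (default q = 0.9, i.e. the top
decile).

## Problem sizes in tests and acceptance

The test suite and `scripts/acceptance.py` use the generator defaults
(2000 × 240 for sexing; 500 genes × 100 cells × 20 seeds for null DE
calibration; 200 planted + 200 null genes at n = 20/20 for power; 150 × 60
with 3 metagenes for NMF; 200 ortholog pairs over 4 groups for
conservation) — sizes at which every Monte-Carlo check has comfortable
resolution while the full suite runs in well under a minute of compute per
module.
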