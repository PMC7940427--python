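# Methods

This note documents the models, defaults and numerical choices behind
`scstage`, and what the synthetic benchmarks do and do not establish.

## Synthetic experiments (`scstage.synthdata`)

The generator emulates a time-resolved, multi-sample, multi-batch
droplet-based scRNA-seq study of a tissue undergoing staged progression.

**Latent stage and composition.** Each sample carries a stage
`s ∈ [0, 1]` (default: an even grid over the cohort, with optional
jitter). Cell-type proportions follow a logit-linear trend,
`p_t(s) = softmax(log b_t + β_t s)`, with Dirichlet noise
(concentration 300, giving within-stage proportion SDs of a few percent)
and multinomial cell sampling. The defaults mirror the study design being
emulated: the first type (an "Avd"-like secretory alveolar state) has
base proportion 2% and slope +3.2, expanding to roughly 40% at `s = 1`;
two fibroblast-like types contract (slopes −1.0 and −0.8); other types
are stable. These slopes are the ground-truth differential-abundance
effects.

**Expression.** Counts are negative binomial with mean
`sf_cell · bf_batch,gene · μ_type,gene(s)` and a common dispersion of 0.1
(variance `μ + 0.1 μ²`). Per-gene baselines are log-normal (σ = 1.2),
normalised so an average cell yields 5000 UMIs. Each type up-regulates 30
marker genes 8-fold; a 50-gene stage program scales its mean by
`2^(2s)` in the designated (expanding) type, which is what makes the
pseudo-bulk axis monotone in stage. Cell size factors are log-normal
(σ = 0.3, mean 1); batch effects are multiplicative log-normal per
(batch, gene) with σ = 0.1 — roughly orthogonal, gene-wise shifts, the
regime the MNN correction assumes. Mitochondrial genes carry 8% of the
library; haemoglobin genes are essentially silent outside RBCs
(2×10⁻⁵ of the library), so that the non-zero-median haemoglobin rule has
a true negative class.

**Correlation modules.** Condition-specific gene–anchor correlation is
planted through a one-factor Gaussian copula: latent
`z_g = ρ̃_g f + √(1−ρ̃_g²) ε`, with `ρ̃ = 2 sin(π ρ_S/6)` converting the
target Spearman to the latent Pearson scale, transformed to counts by the
NB quantile function with each cell's own mean. Module genes (and the
anchor) get a fixed moderate mean (8) because rank correlations on counts
attenuate with sparsity; residual attenuation of roughly 0.05–0.1 from
count discreteness and normalisation noise remains and is expected — the
benchmarks therefore plant ρ = 0.6 and test recovery against the
|Δρ| > 0.3 hit threshold, not exact equality.

**Artifacts.** `inject_artifacts` appends, to a singlet-only experiment:
doublets (element-wise sums of two same-sample cells, allocated per
sample in proportion to its size; optionally constrained to cross-type
pairs), RBC-like contaminants (haemoglobin at ~60% of the library,
everything else at 2% of the tissue profile), and stripped nuclei.
Nuclei are modelled as losing cytoplasmic identity: their mean is the
sample's average profile with mitochondrial genes ×0.001 (fraction
< 0.005), an overall ×0.15, and a deterministic ~10% "nuclear-retained"
gene set ×20. The retained-set enrichment makes nuclei a coherent
expression state that clusters separately — without it the
cluster-median mitochondrial rule has no cluster to act on.

What the generator does **not** emulate: ambient RNA, UMI collisions,
read-level structure, gene-length effects, or cross-type correlated
programs beyond the planted modules. Passing benchmarks therefore shows
the pipeline's rules behave as specified under their own assumptions, not
that those assumptions hold in any particular real data set.

## QC rules (`scstage.qc`)

Genes-detected and total-UMI rules are two-sided median ± 3·MAD on the
log1p scale (MAD scaled by 1.4826 throughout); mitochondrial fraction is
one-sided upper at 5·MAD; the detection-trend residual is one-sided lower
at 6·MAD. The detection trend is a cubic B-spline regression (df = 5,
knots at quantiles) of log genes-detected on log UMIs. Thresholds are
estimated per batch by default (a global mode exists) and can be frozen
and re-applied, which makes filtering idempotent.

## Normalisation (`scstage.normalize`)

Size factors use pooling–deconvolution per batch: cells ordered on a ring
by library size (ascending on one half, descending on the other),
sliding pools of 21…101 cells (step 5, the published default grid — a
sparser grid measurably degrades the deconvolution), each pool summarised
by the median gene-wise ratio to the batch's average cell, plus low-weight
(0.1) per-cell library-size anchor equations; the sparse system is solved
by LSQR. Negative solutions are clipped to the smallest positive value
with a warning; factors are centred to mean 1 per batch. Batches are then
rescaled by mean coverage (library size per size-factor unit) relative to
the lowest-coverage batch, and expression is `log2(x/sf + 1)`.

HVGs come from a per-batch loess (span 0.3) trend of variance on mean of
log-expression; the trend is the technical component, the residual the
biological one, combined across batches by residual-df weights. Genes
with positive residual qualify; ribosomal- and mitochondrial-flagged
genes are excluded.

## Doublets and contaminants (`scstage.doublets`)

Doublet scores compare kernel densities of simulated doublets (sums of
random cell pairs, library-size normalised) and of observed cells in a
25-dimensional HVG PCA space; the Gaussian bandwidth is the median
distance to the 50th cell neighbour. Flagging is cluster-level:

* Round 1 (per sample, on highly resolved SNN/walktrap clusters —
  k = 8 neighbours, 3 walktrap steps, chosen small to keep per-sample
  clusters fine-grained): clusters whose median score exceeds
  median + 1.5·MAD of cluster-median scores *and* that hold < 5% of the
  sample.
* Round 2 (dataset-wide coarse clusters): clusters whose round-1 fraction
  exceeds median + 2·MAD of the fractions. Because typically most
  clusters contain no round-1 cells, the MAD collapses to zero and the
  raw rule would flag any cluster containing a single round-1 cell; a
  guard requires at least 10% round-1 cells before a cluster is removed.

Contaminant rules: a cluster is RBC-like if the median summed
haemoglobin log-expression exceeds 0, and stripped-nuclei-like if the
median mitochondrial fraction is below 0.005. A cell receives one removal
reason with precedence doublet → RBC → nucleus.

## Clustering (`scstage.cluster`)

PCA uses a deterministic sign convention (largest-|loading| entry
positive). MNN correction merges batches sequentially (largest first);
each incoming cell moves by the mean of its own mutual-pair vectors
(k = 20), with exact matches taking precedence — so duplicated batches
are left untouched — and unpaired cells receive kernel-smoothed
corrections. Mutual-neighbour matching recovers batch shifts that are
roughly orthogonal to the biological structure; an in-manifold shift
larger than the local structure is not identifiable by any such matcher.
SNN graphs use the rank weight `k − r/2`, where `r` is the smallest sum
of neighbour ranks over shared neighbours (cells count as their own
rank-0 neighbour). Communities come from walktrap (default 7 steps,
modularity-optimal cut). Cluster merging tests every pair with per-gene
Welch t-tests on log-expression (BH within the pair; DE = q < 0.1 and
|logFC| ≥ 1, flagged genes excluded) and iteratively merges the pair with
the fewest DE genes while below 10, with ties broken by combined size
then label; protected pairs never merge.

## Staging (`scstage.staging`)

TMM follows the trimmed-mean-of-M-values recipe exactly: M and A values
against a reference (auto: sample whose upper-quartile expression is
closest to the cohort mean) on doubly-expressed genes, 30%/5% trims by
rank, inverse-asymptotic-variance weights, `2^f`, geometric-mean
renormalisation. The PCA enters `log2(CPM + 1)` with TMM-adjusted library
sizes, restricted to genes with CPM > 1 in ≥ 2 samples and gene-centred.
PC1's sign is flipped if the anchor (early/wild-type-like) samples'
mean exceeds the cohort mean; the scaled axis maps the extremes to 0
and 1. Stage bins are equal-width on [0, 1] by default (four bins), with
explicit boundaries to reproduce any manual staging, and designated
tumour samples bypass binning. Held-out samples are projected with the
training reference, renormalisation constant, centering means and
loadings; their scaled values may legitimately fall outside [0, 1].
Pseudo-bulk uses all cells by default; subset before calling to stage on
a compartment.

## Differential abundance (`scstage.abundance`)

Abundance is `log2((x + p_s)/(N_s + 2 p_s)·10⁶)` with the library-size-
adjusted prior `p_s = 2 N_s / mean(N)`. The regression direction is
abundance-on-PC1 (the reported coefficient is a change in abundance per
unit of the 0–1 axis). The robust Wald test divides the Huber slope by a
sandwich standard error `κ² s² Σψ²/(n−p) / (mean ψ')² · (XᵀX)⁻¹`, with
Huber's small-sample correction `κ = 1 + (p/n)·var(ψ')/mean(ψ')²`,
referred to `t(n−2)`; Monte-Carlo calibration at n = 12 gives a type-I
rate of ~0.06 at α = 0.05. Tumour-designated samples are excluded from
the fit scope by the caller; only clusters averaging more than 10
cells per in-scope sample are tested, and BH runs over tested clusters
only.

## Differential correlation (`scstage.diffcor`)

Genes need ≥ 10 non-zero observations in both groups. The statistic is
`Δρ = ρ_A − ρ_B` (conditions in sorted order); the null permutes group
labels over the pooled cells; p-values use the add-one convention and an
exhaustive-enumeration mode exists for tiny instances. Permutations are a
plain cell-level shuffle by default: stratifying by sample — an available
option — is a no-op when condition is a sample-level attribute. Hits
require FDR < 0.001 and |Δρ| > 0.3; per-condition distances to the median
correlation are reported for the two-axis visualisation. Note that with
sample-level conditions, real between-sample structure (batch terms,
stage programs, normalisation coupling to planted modules) shifts null
genes' Δρ by up to ~0.1; the permutation test sees this as signal, which
is precisely why the effect-size threshold |Δρ| > 0.3 matters.

## Interactions (`scstage.interactions`)

Score = (mean ligand log-expression in sender + mean receptor in
receiver)/2, gated on > 10% detection in the respective clusters; the
null shuffles cluster labels (1000 permutations by default); BH runs per
stage across all gated (pair, sender, receiver) tests. Stage deltas count
significant interactions per directed type pair and subtract. Label
grouping (e.g. basal subtypes → "Basal") is a caller-supplied mapping.

## Benchmark problem sizes

The validation benchmarks (`scstage.validation`, also driven by
`scripts/acceptance.py`) use cohort sizes chosen to finish in minutes on
one core while leaving clear statistical margins: staging recovery uses
20 cohorts of 12 samples × 2000 cells × 300 genes; DA calibration 1000
null replicates of 12 samples × 8 clusters (power: 50 cohorts, with the
scaled true stage standing in for scaled PC1 — the staging benchmark
separately establishes their rank agreement); the artifact pipeline 10
seeds of 3 samples × 800 cells with two types, 5% cross-type doublets, 2%
RBCs and 2% nuclei; differential correlation 600 cells per condition with
20 planted module genes among ~200 genes (9999 permutations, because a
hit needs q < 0.001 and the attainable q floor is `m/(rank·(n_perm+1))`;
the panel is kept at 200 genes because with far fewer genes the planted
module becomes a large fraction of the library and normalisation
coupling inflates null Δρ well beyond anything realistic),
plus a 520-gene random-split calibration at 1000 permutations; the
interaction benchmarks 900–1200 cells, 5 types, and up to 120 pairs for
the null-calibration rate (many distinct gene pairs, because tests
sharing genes and permutations are correlated and the single-run
rejection-rate estimate needs enough independent information). All randomness
derives from a single seed.

## Known limitations

* The cluster-merging step is O(K²) pairwise scans per iteration — fine
  for tens of clusters, slow for hundreds.
* Doublet-score densities are computed by chunked exact pairwise
  distances (O(n²) per sample); samples beyond ~10⁴ cells would want an
  approximate density.
* The robust Wald test is one of several plausible "robust F" variants;
  the drop-in-deviance flavour is not implemented.
* TMM, deconvolution factors and the MNN correction are faithful
  re-implementations of the published algorithms but not bug-for-bug
  replicas of their R reference implementations.
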