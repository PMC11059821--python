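# Methods

## Transformation chains

Five elementary statistics operate on the cells x genes matrix: total-
count normalization (`e / sum(e) * target_sum`, per cell, default target
20000), `log2(e + 1)`, l2 normalization (per cell), min-max scaling and
z-scoring. The chain grammar is `[total] -> [log2] -> [at most one of
l2norm | minmax | zscore]`; its product is exactly 16 chains, covering
every composition commonly seen in practice (raw input, each single
statistic, total->X, log2->X, total->log2->X). The grammar also encodes a
safety rule: `log2` may never follow a step that can produce negatives,
which the ordering enforces structurally.

Two numerical conventions matter for reproducibility:

- **Standard deviation is population (divide by n).** Z-scored vectors
  then have mean 0 and population sd 1 exactly, which the tests assert
  at 1e-9.
- **Degenerate vectors.** Constant vectors map to all-zeros under
  min-max and z-score rather than erroring — constant genes are common
  in subsampled data. Constancy is detected by exact max == min, not by
  `std == 0`: for a constant vector the floating-point standard
  deviation can be tiny noise rather than exactly zero, and dividing by
  it would produce garbage ±1 outputs. Zero-sum cells (total) and
  zero-norm cells (l2) raise errors naming the offending cells, because
  they indicate an upstream QC failure the caller must resolve.
- **Axis defaults.** The statistics are all defined on per-cell vectors;
  total and l2norm act per cell, while minmax and zscore default to per
  gene — the standardization convention of mainstream toolkits — with a
  configurable axis. This default is a design choice, not a claim about
  any particular external protocol.

## Synthetic data generator

`simulate_counts` draws negative-binomial counts with a mean/dispersion
parameterization (variance mu + mu^2/theta, default theta = 2), then
applies an independent constant-probability dropout mask (default 0.2).
A cell of type t in batch b has mean `depth_b * gene_factors_b *
profile_t`. Cell-type profiles are a shared lognormal baseline with a
disjoint block of ~12% marker genes up-regulated 8-fold per type —
strong, discrete cell identities of the kind seen in pancreas or immune
data.

The central study condition is the **depth-scaled scenario**: batches
share gene factors (all 1) and differ only by a per-cell depth factor
(default x5), so the batch effect is exactly a per-cell positive scaling
and is removed exactly by total or l2 normalization. The default scale
is 3 cell types x 2 batches x 100 cells per type per batch (600 cells)
x 200 genes — large enough for stable ARI estimates, small enough that
the whole grid runs in seconds. What passing on this scenario shows is
that the machinery correctly identifies a *removable* batch effect; it
does not show performance under gene-specific batch distortions (those
can be simulated via `gene_factors` but no transformation removes them
exactly), ambient RNA, doublets, or mean-dependent dropout, which are
out of scope.

`simulate_trajectory_counts` produces staged differentiation data: half
of the dynamic genes rise and half fall monotonically across stages with
total fold change `effect_size` (default 4). The defaults used in the
trajectory checks — 5 stages x 60 cells, 200 genes of which 100 dynamic,
dropout 0.1 — reflect early-development data where a large fraction of
the transcriptome is stage-dependent. With few dynamic genes the
stage signal sinks below the negative-binomial noise floor and no method
recovers it; the generator exposes that regime but the recovery tests do
not run in it.

Randomness: one global seed; per-batch sub-streams are spawned
deterministically, so the same seed always yields the same matrix.

## Embeddings and clustering sweeps

t-SNE and UMAP are always 2-D: t-SNE with random (not PCA)
initialization, UMAP with spectral initialization. Perplexity 30 and
UMAP (n_neighbors 15, min_dist 0.1) are ordinary defaults, recorded in
the run manifest. PCA centers but never rescales — rescaling is the
transform chain's job and doing it twice would mask chain differences.

K-Means sweeps k from ceil(L/2) to L + 4, where L is the number of
reference labels (L = 13 gives the 11 values 7..17), with 20 random
restarts of at most 50 iterations per k. DBSCAN sweeps eps over 0.5,
1.0, ..., 10.0 (20 values) with min_samples fixed at 8. Both return the
partition maximizing a pluggable score: ARI against reference labels
when they exist (the benchmarking protocol), silhouette otherwise. In
unsupervised mode the K-Means range is anchored at a configurable
reference count (default 8). Louvain runs on a kNN graph (default k=15,
resolution 1.0) via igraph's multilevel method with a seeded RNG.

DBSCAN noise points (-1) count as one extra cluster in ARI/bARI — the
behavior of standard ARI implementations fed raw labels — but are
excluded from the reported cluster count.

## Metrics

ARI is computed from the contingency table,
`(sum_ij C(n_ij,2) - E) / (max - E)` with
`E = sum_i C(a_i,2) sum_j C(b_j,2) / C(n,2)` and
`max = [sum_i C(a_i,2) + sum_j C(b_j,2)] / 2`. The implementation is
authored here (it is the package's core statistic) and is pinned in the
tests to an independent O(n^2) pair-counting oracle at 1e-12 over 200
random instances. When both partitions are trivial the index is defined
as 1 (identical) or 0. bARI is ARI between cluster labels and batch
ids; 1-bARI is reported alongside and can exceed 1 when bARI < 0. With
a single batch bARI is undefined and returned as missing with a
warning. NMI uses arithmetic-mean normalization; silhouette is the mean
euclidean silhouette width, undefined for a single cluster.

## Recommendation rule

Given the grid, chains are ranked by: (1) keep rows with |bARI| <=
threshold (default 0.05); if none qualify, keep the lowest-|bARI|
quartile; (2) among kept rows, rank by |n_clusters - expected_n_types|
when an expected count is supplied; (3) break ties by higher silhouette.
The 0.05 threshold operationalizes "batches are effectively mixed"; no
principled universal cutoff exists, so the threshold is a parameter and
the quartile fallback keeps the rule total. The rule is a pure function
of the grid (row order cannot change the ranking) and each ranked chain
carries a rationale string citing its bARI, cluster count and
silhouette.

## Diffusion pseudotime

A symmetric kNN graph (default k=15) is built with a Gaussian kernel
whose bandwidth adapts to the local scale (sigma_i = distance to the
k-th neighbor; edge weight exp(-d_ij^2 / (sigma_i sigma_j))), making
pseudotime invariant to uniform rescaling of the input coordinates. The
kernel is row-normalized into a transition operator; its top nontrivial
eigenpairs (default 15) give diffusion coordinates scaled by
lambda/(1-lambda), and a cell's pseudotime is its euclidean distance
from the root in those coordinates. Eigenpairs come from the symmetric
conjugate D^-1/2 W D^-1/2 (dense eigh below 200 cells, Lanczos above)
for numerical stability. Disconnected graphs fall back to the root's
component with a warning; other cells get NaN. When no root is given,
the medoid of the earliest-stage cells is used — a deterministic,
outlier-robust anchor for "the start of the process". One test
cross-checks the ordering against an independent diffusion-pseudotime
implementation on a noisy line (Spearman >= 0.95).

## Neural feature encoders

Four encoders share one building block — fully connected layer, batch
normalization, rectifier — implemented directly in numpy with
hand-written backward passes (verified against finite differences at
1e-4 relative). The autoencoder uses one hidden layer of 1024 units by
default with a mirrored decoder and mean-squared reconstruction error.
The VAE uses a [1024, 128] trunk, separate linear heads for the latent
mean and scale (softplus keeps sigma positive), the reparametrization
trick, and loss MSE + beta*KL against a standard normal (beta = 1).
The prototypical network trains episodically: each episode samples 5
support and 5 query cells per class, prototypes are mean support
embeddings, and queries incur softmax cross-entropy over negative
squared euclidean distances to the prototypes. The variational variant
draws its latent by reparametrization from the VAE trunk before the
same loss. Optimization is Adam at 1e-3, 100 epochs, minibatch 128
(tests use smaller stacks — hidden 32-64 — which preserve every
qualitative property at a fraction of the cost).

The cross-batch protocol trains `n_runs` encoders (default 10) on one
batch only, encodes all batches with each, embeds, clusters, and scores;
the best run by ARI is reported with all per-run records. On the
depth-scaled scenario this realizes the garbage-in-garbage-out effect:
encoders trained on un-normalized data overfit the depth signal and
cluster by batch, while total-normalized input yields cell-type
clusters — the median-over-runs ARI gap is large and stable across
seeds (about 0.3 vs 0.9 for the autoencoder).

## Grid harness

`run_grid` evaluates all combinations, isolating failures: a chain that
errors (e.g. total on a zero-sum cell) produces a flagged row, never an
aborted sweep. The manifest records seeds, configurations and problem
sizes. Result CSVs serialize floats at full precision (round-trip better
than 1e-12) and contain no timing, so same-seed re-runs are
byte-identical.

## Known limitations

- The recommendation rule assumes at least two batches; single-batch
  grids have no bARI and cannot be ranked by it.
- DBSCAN's fixed eps grid (0.5..10) presumes embedding coordinates on
  the usual t-SNE/UMAP/PCA scale; data in wildly different units needs
  rescaling first.
- t-SNE/UMAP determinism holds per library version and platform; across
  versions coordinates (not conclusions) may shift.
- The numpy encoders are CPU-bound and meant for datasets up to a few
  thousand cells; they trade speed for zero heavy dependencies.
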