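# Methods

This note documents the models and procedures `coexnet` implements, the
defaults it ships, the numerical choices behind them, and what its
synthetic-data tests do and do not establish.

## Normalization

All methods except quantile are per-sample rescalings, so within-sample
value ratios are preserved exactly.

* **Median**: sample *j* is multiplied by `mean of all sample medians /
  median of sample j`; afterwards every sample has the same median.
  Zeros are included in the median; a sample with median 0 is an error
  rather than a silent skip.
* **Quantile**: each sample's sorted values are replaced by the
  across-sample mean at that sort rank, making all per-sample empirical
  distributions identical. Tied values receive the mean of the reference
  values their positions span (Bolstad-style), so output does not depend
  on how a stable sort orders equal inputs.
* **Median-of-ratios** (DESeq-style): genes with a zero anywhere are
  excluded from the reference geometric means; the size factor of sample
  *j* is the median over remaining genes of `value / geometric mean`.
  Raw factors are only defined up to one global constant, so they are
  recentred to geometric mean 1; this makes the operation exactly
  idempotent while leaving all between-sample ratios untouched.
* **TMM**: reference sample = the one whose upper quartile of
  library-scaled values is closest to the mean upper quartile. M (log2
  expression ratio) and A (average log intensity) are computed over genes
  positive in both sample and reference, doubly trimmed (30 % of each
  tail on M, 5 % on A, average-rank ties), and combined as an
  inverse-variance-weighted mean with delta-method binomial weights
  `w = (N_s−y_s)/(N_s y_s) + (N_r−y_r)/(N_r y_r)`. Factors are recentred
  to log-mean 0 and counts divided by `library size × factor`. If
  trimming empties the gene set (tiny inputs) the untrimmed weighted
  mean is used.
* **Housekeeping**: like median normalization but the median is taken
  over a user-supplied housekeeping gene list; genes absent from the
  matrix are ignored, an entirely absent list is an error.

Filtering drops genes by mean or variance, either the lowest floor(f·n)
genes (default f = 0.25 on the mean — the usual empirical de-noising
choice) or below an absolute threshold; ties at the boundary are resolved
stably by input order so the result is deterministic. An optional
`log2(x + pseudocount)` transform is provided but off by default: the
recommended correlation for raw RNA-Seq is Spearman, which is invariant
to monotone transforms.

## Network construction

Correlation (Pearson, or Spearman = Pearson on average ranks) is used
directly as the edge weight; soft-threshold adjacency powers are
deliberately out of scope. Significance is the exact null transform
`t = rho·sqrt((n−2)/(1−rho²))` on n−2 degrees of freedom (two-sided;
|rho| = 1 maps to p = 0), with Benjamini–Hochberg adjustment across
*all* evaluated pairs, not only those passing the correlation cut.
Defaults: Spearman, |rho| ≥ 0.8, FDR ≤ 0.05 — the correlation threshold
is a conventional choice and, like everything else, flag-configurable.
An optional positive-only filter exists because negative co-expression
is often not biologically interpretable.

Constant-expression genes have undefined correlation; they are skipped
with a logged count, never an abort. Fewer than three samples is an
error (no degrees of freedom); zero surviving edges is a warning, not an
error. All-pairs computation proceeds in row chunks with a fixed
reduction order, so `--threads` can change wall time but never output
bytes. Memory holds the standardized matrix and the per-pair statistic
vectors, not an n×n edge structure.

Merging keeps an edge present in at least `min_support` input networks
and averages its weights; p-values/FDRs are dropped because they are not
meaningful for an aggregated edge. This min-support contract is this
package's own definition of network aggregation.

## Module identification

The similarity of two genes is their relative interconnectedness
`s = (h+a)/(c_i+c_j−h−a)` (shared neighbours h, adjacency a ∈ {0,1},
degrees c), which lies in [0, 1]; it is 0 by convention when h + a = 0.
Modules are grown agglomeratively: merge the edge-connected cluster pair
with the highest average pairwise similarity while that average is at
least the cutoff (default 0.5); clusters of at least `min_module_size`
(default 3) genes become modules. Choices the underlying measure leaves
open and that are fixed here: average linkage (robust to chaining),
merges restricted to edge-connected cluster pairs (keeps every module a
connected subgraph, matching the co-regulation reading), lexicographic
smallest-pair tie-break (full determinism, edge-order independence).
Similarities are computed on demand from adjacency sets; no dense
similarity matrix is materialized.

## Function annotation

**Enrichment.** For a target with n annotated associates (direct
neighbours, or module co-members), of which k carry a term present in M
of N background genes, the p-value is the hypergeometric upper tail,
evaluated by a log-space sum of `exp(lgamma)`-based terms (stable for
large backgrounds; agrees with rational enumeration to < 1e-9
everywhere tested). The background defaults to genes that are both in
the network and annotated — genes that can never vote should not
inflate M — and can be switched to all annotated genes. BH-FDR is
applied jointly across every (target, term) test of a run; both raw and
adjusted values are reported because the choice of which to threshold is
a user decision.

**Random walk with restart.** W is the column-normalized unweighted
adjacency (a flag switches to |rho| weights); p₀ is uniform over seeds
or follows given weights. Iteration `p ← αp₀ + (1−α)Wp` stops when the
L1 change drops below 1e-10 (defaults: α = 0.5, ≤ 1000 iterations).
Because α·1 + (1−α)·1 = 1 with a column-stochastic W, the iterate's
mass is exactly 1 at every step; no renormalization is applied, so the
conservation property is observable. A zero-degree column would teleport
its mass to p₀ (logged); with networks defined by their edges this case
cannot arise from file input.

**Accuracy evaluation.** Leave-one-out over annotated network genes:
hide gene g's labels, predict with the chosen mode, score a hit if any
true term is among the FDR-passing predictions. Genes with no annotated
associates after hiding are excluded from the denominator and reported
separately. The identical procedure runs on a degree-preserving shuffle
of the network (double-edge swaps, default 10 accepted swaps per edge;
swaps creating self-edges or duplicates are rejected; a network with no
legal swap, such as a single triangle, is returned unchanged with a
warning). The real-minus-control gap is the evidence that predictions
exploit co-expression structure rather than node degree. "Accuracy" here
is this package's concrete definition — any-true-term recall under
leave-one-out — chosen because it is simple, symmetric across genes, and
directly comparable between real and control networks.

## Synthetic data

`make_block_matrix` plants B blocks of latent-factor genes:
`x_g = a·z_b + σ·ε`, with `a = σ·sqrt(r/(1−r))` so the expected
within-block Pearson correlation is exactly the target r (default 0.9,
σ = 1, 3 blocks × 10 genes × 20 samples). Gaussian values are shifted by
the global minimum — a correlation-preserving translation — to satisfy
the non-negativity of expression matrices; a count mode exponentiates
(2^x) instead for normalization testing. `make_annotation` labels a
seeded random fraction of each block with its block term.

The generator emulates exactly the feature the pipeline exploits —
shared latent programs — and nothing else: no sequencing-depth
variation, no negative-binomial dispersion, no between-block
correlation, no DAG structure over terms. A green end-to-end test
therefore establishes that the statistics and the plumbing are correct,
not that the defaults are tuned for any particular real dataset. One
practical corollary observed in testing: per-sample normalization of
data that has no library-size effects can only inject noise into
rank-based correlations, so the demonstration pipeline normalizes with
the scaling methods (which are Spearman-neutral up to the estimated
factors) rather than quantile substitution.

## Limitations

* Term IDs are opaque strings: no GO-DAG propagation, term similarity,
  or pathway topology.
* No hub/switch-gene detection, soft thresholding, mutual information,
  or partial correlation.
* No batch correction or gene-length (TPM/FPKM) normalization.
* The all-pairs correlation stage is vectorized but still O(n²) in gene
  count; very large gene sets should be filtered first.
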