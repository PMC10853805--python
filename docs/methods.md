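# Methods

## Model

`hetnetcc` detects overlapping co-modules — paired sets of genes and miRNAs
that act together — from an attributed heterogeneous network. The working
assumptions are the usual ones for this problem class: (i) molecules in one
functional module interact across layers more often than chance, (ii) they
share expression patterns across samples, and (iii) known interaction
matrices are incomplete, so link prediction from node attributes can densify
them before clustering. The pipeline composes three stages whose contracts
are independent, so each is testable in isolation.

### Stage 1 — attribute views and VGAE fusion

Genes occupy node indices `0..g-1` and miRNAs `g..g+m-1` of one shared
graph whose only edges are the known bipartite interactions (block adjacency
`[[0, W12], [W12ᵀ, 0]]`). Each per-layer omics matrix becomes one view over
all nodes: the owning layer's block is its PCA score matrix (top `d_ini`
components of the column-centered data), the other layer's block is a
constant — the scalar median over all entries of the reduced block. The
constant padding carries no information about the other layer by design; it
merely keeps every view defined on the full node set. Median padding makes
`build_attribute_view` invariant to row permutations of the other layer,
which the tests assert indirectly through the constant-block check.

PCA is computed by direct SVD rather than a library estimator so the sign
convention can be pinned exactly (the largest-magnitude loading of each
component is made positive); this makes view construction bit-reproducible
across runs and linear-algebra backends. Components beyond the numerical
rank are zero-padded with a warning rather than an error, because rank
deficits are routine (centering alone costs one rank).

Sequences enter as overlapping k-mer counts (default k=4, 256 columns,
lexicographic order). A window containing any non-ACGT symbol is skipped
entirely rather than recoded — inventing counts for ambiguous bases would
bias the features.

One VGAE per view is trained on the shared adjacency: a two-layer GCN
encoder on the symmetrically normalized adjacency with self-loops, Gaussian
latents (`z = μ + ε·exp(logσ)` during training, `z = μ` at inference), and
an inner-product decoder `A_rec = sigmoid(ZZᵀ)`. The loss is dense
binary cross-entropy with positives reweighted by `#non-edges/#edges`
(standard sparsity correction; no negative sampling is needed at these graph
sizes) plus the KL divergence from `N(0, I)` scaled by `1/(g+m)²`, i.e. the
conventional per-node-per-normalizer scaling of the reference VGAE
formulation. The model is a compact dense numpy implementation with
hand-derived gradients (verified against finite differences during
development) and an Adam optimizer; at a few hundred nodes a full training
run takes well under a second. Defaults — hidden 32, latent 16, 200 epochs,
learning rate 0.01 — are conventional VGAE settings and are all exposed in
the config.

Each reconstruction's gene×miRNA block is refined by keeping all known pairs
at value 1 plus the top-`t` highest-scored novel pairs (ties broken by
(row, column) index for determinism). Refined matrices are binarized by
default so they enter the factorization on the same scale as the binary
`W12`; a flag preserves raw scores. `t` defaults to the number of known
interactions (density doubling), a deliberate middle ground between ignoring
the reconstruction and trusting it wholesale. Per-view seeds are
`base_seed + view_index`: reproducible, yet independent across views.

### Stage 2 — adaptive weighted co-clustering

The objective (README, Method §2) couples a weighted tri-factorization of
the association stack with a shared-basis factorization of both expression
matrices through the common cluster-distribution factors `G1, G2`, an
orthogonality penalty `β‖G_lᵀG_l − I‖²F` that discourages redundant
clusters, and a weight regularizer `γ‖w‖²` that keeps the view weights from
collapsing onto the single best-fitting view as γ grows.

Factor updates are the standard multiplicative rules from the KKT conditions,
each factor multiplied by the ratio of the positive and negative parts of
half its gradient; the orthogonality term contributes `+2βG` (numerator) and
`+2βG GᵀG` (denominator). Numerators are clamped at zero so non-negativity
survives even when the (shifted) data are not strictly positive, and
denominators carry an `ε = 1e-12` underflow guard. The weight update is
solved exactly: minimizing `Σ wᵢLᵢ + γΣ wᵢ²` on the simplex is the Euclidean
projection of `−L/(2γ)` onto the simplex, computed by the sort-based
water-filling algorithm. `γ = 0` degenerates to a linear program; the
implementation returns the indicator of the minimal loss (ties split
uniformly) with a warning. Weights are updated after each full factor sweep
so the residuals they respond to are current.

Initialization is seeded uniform(0, 1) for all factors and uniform `1/v`
weights. Convergence is declared when the relative objective change drops
below `tol` (default 1e-6) or after `max_iter` (default 500) sweeps. The
exact weight step never increases the objective; the multiplicative sweeps
are heuristic for the orthogonality-augmented objective, so monotonicity is
enforced empirically: the test suite asserts a non-increasing trace (within
`1e-9·(1+|f|)`) over 200 iterations on twenty random instances, and the
acceptance script reports the count of increases along its own run (0 in all
observed runs). Default `α = β = γ = 1` treats the three couplings equally;
all are exposed. Note that with γ at this scale relative to typical residual
magnitudes, the weight vector is effectively a selector of the most
consistent view — larger γ interpolates toward uniform weighting.

Expression matrices are shifted to a non-negative range before factorization
(real expression data are non-negative; the synthetic Gaussian profiles are
not), and an optional `log2(x+1)` flag covers count-like inputs.
Differential-expression pre-filtering is left to the user's upstream
tooling.

### Stage 3 — module discovery and evaluation

Column z-scores of `G1`/`G2` use the population (1/N) standard deviation
with no finite-sample correction, and membership requires strictly exceeding
the threshold; constant columns get all-zero z-scores with a warning.
Default `T1 = T2 = 1.0`. For balanced planted blocks of fraction `p`, the
in-block z-level of a clean column is `√((1−p)/p)` (≈1.41 at `p = 1/3`), so
T = 1 separates members from non-members with margin on the benchmark
designs. Triple-layer linking ranks all gene-set pairs by Jaccard similarity
(ties by index), keeps the best pairs (default 2), and merges each pair with
the gene union, annotating the shared genes.

Because membership may overlap, modularity is computed on a hard partition:
each assigned molecule goes to its highest-z module, unassigned molecules
become singletons. On that partition Newman's `Q = Σ_c (e_c/E − (d_c/2E)²)`
is evaluated through networkx (a direct-formula oracle backs it in the
tests). This hard-partition Newman score is the package's declared
convention for overlapping assignments, documented here because other
overlap-aware modularity variants exist. Significance uses a
degree-preserving null: double-edge swaps within the bipartite block (10
swap attempts per edge), re-scoring the same assignment, with the add-one
estimator `p = (1 + #{Q_null ≥ Q_obs})/(1 + n_perm)` so p is never 0.
"Average precision" against a reference molecule list is the unweighted mean
over non-empty modules of the fraction of members in the reference; recall
is reported per module and pooled.

## Synthetic benchmark

The generator plants `k_true` blocks aligned across layers (gene block b
pairs with miRNA block b), which is what gives the factors a well-defined
ground truth on both layers. Bipartite and gene–gene edges follow a
planted-partition model (`p_in = 0.6`, `p_out = 0.05` by default); expression
rows are a per-block mean profile drawn once from `N(0, effect²I)`
(`effect = 2`) plus `N(0, noise_sd²)` noise (`noise_sd = 0.5`); sequences are
uniform ACGT with a block-specific random 8-mer inserted at a random
position in every member, so 4-mer counts carry block signal. Two presets
are used throughout: `small` (g=30, m=20, n=10, 2 blocks) for unit tests and
`recovery` (g=90, m=60, n=20, 3 blocks) for the end-to-end
parameter-recovery experiment — sizes at which the full pipeline runs in
seconds while leaving each block enough members for stable statistics.

What passing on this benchmark shows — and does not. The generator matches
the method's structural assumptions exactly: aligned blocks, block-wise
co-expression, informative sequences. Real regulatory networks have degree
heterogeneity, unbalanced and nested modules, batch effects and count-noise
marginals, none of which are emulated. Recovery of the planted partition
(ARI 1.0 on both layers at the default settings) therefore validates the
machinery — fusion preserves and densifies block structure, the optimizer
finds it, thresholding reads it out — not performance on any real dataset.

## Known limitations

- The multiplicative updates carry no formal monotonic-convergence proof for
  the orthogonality-augmented objective; the guarantee is empirical and
  test-enforced.
- `k` is user-supplied; no model selection is built in.
- The VGAE trains full-batch on a dense adjacency: appropriate up to a few
  thousand nodes, not beyond.
- Modularity on overlapping assignments is a hard-partition approximation
  (max-z), and the permutation null rewires only the bipartite block,
  holding intra-layer structure fixed.
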