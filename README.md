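# hetnetcc

Heterogeneous-network co-clustering for overlapping **gene–miRNA co-module**
discovery.

Functional modules that span two molecular layers — a set of genes and the
miRNAs that co-regulate them — are hard to find from any single data type:
known gene–miRNA interaction networks are sparse, and expression profiles
alone miss cross-layer regulation. `hetnetcc` addresses this for systems
biologists who have (a) a binary bipartite interaction matrix
`W12 ∈ {0,1}^{g×m}`, (b) per-layer omics attributes (expression,
intra-layer interactions, nucleotide sequences), and want overlapping
co-modules plus quality scores, without external annotation databases.

## Method

**1. Multi-omics fusion.** Both layers are merged into one node set with
block adjacency `A = [[0, W12], [W12ᵀ, 0]]`. Each per-layer attribute matrix
is PCA-reduced to `d_ini` dimensions and padded over the other layer with the
scalar median of the reduced block, giving `v` attribute views `H_i` over all
`g+m` nodes (sequences are featurized as overlapping 4-mer counts, 256
columns). One variational graph autoencoder per view — a two-layer graph
convolution encoder with Gaussian latents and an inner-product decoder —
reconstructs edge probabilities; the gene×miRNA block `W'_i = A'_i[1:g,
g+1:g+m]` is refined by keeping every known pair plus the top-`t`
highest-scored novel pairs.

**2. Adaptive weighted co-clustering.** The refined association stack
`{W_i}` and both expression matrices `X11 (g×n)`, `X21 (m×n)` are jointly
factorized:

```
min  Σᵢ wᵢ‖Wᵢ − G1 Sᵢ G2ᵀ‖²F + α Σ_{l=1,2} ‖X_l1 − G_l B‖²F
     + β Σ_{l=1,2} ‖G_lᵀG_l − I‖²F + γ‖w‖²F
s.t. G_l ≥ 0, Sᵢ ≥ 0, wᵀ1 = 1, wᵢ ≥ 0
```

solved by alternating KKT-derived multiplicative updates for `G1, G2, {Sᵢ},
B` and an exact simplex-projected update for the view weights `w`.

**3. Module discovery.** Column z-scores of `G1`/`G2` (population σ) are
thresholded (`z > T`) into overlapping indicator matrices `F1`, `F2`; a
column of the pair is one co-module. Two runs sharing the gene layer link
into triple-layer (e.g. gene–miRNA–lncRNA) modules via Jaccard similarity of
their gene sets.

Detected co-modules are scored by Newman modularity on the heterogeneous
graph with a degree-preserving permutation p-value, precision/recall against
reference molecule lists, and adjusted Rand index against planted labels on
synthetic benchmarks.

## Worked example

```python
import numpy as np
from hetnetcc import (PipelineConfig, SyntheticScenario, generate,
                      modularity, recovery_ari, run_pipeline)

bundle = generate(SyntheticScenario.recovery(seed=0))   # g=90, m=60, 3 blocks
config = PipelineConfig(k=3, seed=0)
result = run_pipeline(bundle, config)

print(recovery_ari(result.assignment, bundle.gene_blocks, bundle.mirna_blocks))
print(result.state.w, round(modularity(result.adjacency, result.assignment), 4))
```

prints

```
{'gene': 1.0, 'mirna': 1.0}
[0. 0. 1. 0. 0.] 0.5175
```

i.e. the three planted co-modules are recovered exactly on both layers
(adjusted Rand index 1.0), the adaptive weights concentrated on the most
consistent association view, and the detected co-modules have modularity
0.52 on the interaction graph (0 would mean no structure beyond degree).

The same pipeline is available from a shell:

```bash
hetnetcc simulate --seed 0 --preset recovery --out data/
hetnetcc pipeline --config cfg.yaml --data data/ --out run/
hetnetcc evaluate --data data/ --modules-dir run/ --out metrics.json
```

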