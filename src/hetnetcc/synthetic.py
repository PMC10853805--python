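"""Seeded synthetic data with planted co-module structure.

Emulates the inputs of a gene-miRNA co-module study at desk scale: a
bipartite interaction matrix drawn from a planted-partition model whose
blocks are aligned across layers, correlated per-block expression profiles,
an intra-layer gene-gene network from the same block model, and nucleotide
sequences carrying a block-specific motif so k-mer features are informative.
The generator targets the structural assumptions of the method, not the
marginal distributions of any real dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import write_fasta, write_matrix


@dataclass
class SyntheticScenario:
    """Sizes, block probabilities and noise levels of one planted dataset.

    ``p_in``/``p_out`` are the within/cross-block bipartite edge
    probabilities; ``effect`` scales the separation of per-block expression
    mean profiles (each drawn once from N(0, effect^2 I)) against Gaussian
    observation noise of standard deviation ``noise_sd``. Every member of a
    block carries the block's random ``motif_len``-mer at a random position
    of its otherwise uniform sequence.
    """

    g: int = 30
    m: int = 20
    n: int = 10
    k_true: int = 2
    p_in: float = 0.6
    p_out: float = 0.05
    effect: float = 2.0
    noise_sd: float = 0.5
    seq_len: int = 120
    motif_len: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if self.k_true > min(self.g, self.m):
            raise ValueError("k_true exceeds a layer size")

    @classmethod
    def small(cls, seed: int = 0) -> "SyntheticScenario":
        """Unit-test preset: g=30, m=20, n=10, two blocks."""
        return cls(seed=seed)

    @classmethod
    def recovery(cls, seed: int = 0) -> "SyntheticScenario":
        """Parameter-recovery preset: g=90, m=60, n=20, three blocks, low noise."""
        return cls(g=90, m=60, n=20, k_true=3, seed=seed)


@dataclass
class SyntheticBundle:
    """Everything one pipeline run consumes, plus the planted truth."""

    W12: np.ndarray  # g x m binary
    X11: np.ndarray  # g x n gene expression
    X21: np.ndarray  # m x n miRNA expression
    gene_gene: np.ndarray  # g x g symmetric binary
    gene_sequences: list[tuple[str, str]]
    mirna_sequences: list[tuple[str, str]]
    gene_labels: list[str]
    mirna_labels: list[str]
    gene_blocks: np.ndarray  # planted block label per gene
    mirna_blocks: np.ndarray
    scenario: SyntheticScenario

    def write(self, outdir: str | Path) -> None:
        """Write the bundle in the formats the readers understand."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        samples = [f"s{i}" for i in range(self.X11.shape[1])]
        write_matrix(outdir / "W12.tsv", self.W12, self.gene_labels, self.mirna_labels)
        write_matrix(outdir / "X11.tsv", self.X11, self.gene_labels, samples)
        write_matrix(outdir / "X21.tsv", self.X21, self.mirna_labels, samples)
        write_matrix(
            outdir / "gene_gene.tsv", self.gene_gene, self.gene_labels, self.gene_labels
        )
        write_fasta(outdir / "genes.fasta", self.gene_sequences)
        write_fasta(outdir / "mirnas.fasta", self.mirna_sequences)
        write_matrix(
            outdir / "gene_blocks.tsv",
            self.gene_blocks[:, None].astype(float),
            self.gene_labels,
            ["block"],
        )
        write_matrix(
            outdir / "mirna_blocks.tsv",
            self.mirna_blocks[:, None].astype(float),
            self.mirna_labels,
            ["block"],
        )


def _balanced_blocks(n: int, k: int) -> np.ndarray:
    sizes = [len(chunk) for chunk in np.array_split(np.arange(n), k)]
    return np.repeat(np.arange(k), sizes)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _block_sequences(
    rng: np.random.Generator,
    blocks: np.ndarray,
    motifs: list[str],
    seq_len: int,
    prefix: str,
) -> list[tuple[str, str]]:
    out = []
    for i, b in enumerate(blocks):
        seq = _random_sequence(rng, seq_len)
        motif = motifs[b]
        pos = int(rng.integers(0, seq_len - len(motif) + 1))
        seq = seq[:pos] + motif + seq[pos + len(motif) :]
        out.append((f"{prefix}{i:04d}", seq))
    return out


def generate(scenario: SyntheticScenario) -> SyntheticBundle:
    """Draw one dataset with planted, layer-aligned co-module structure."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    gene_blocks = _balanced_blocks(sc.g, sc.k_true)
    mirna_blocks = _balanced_blocks(sc.m, sc.k_true)

    same_block = gene_blocks[:, None] == mirna_blocks[None, :]
    probs = np.where(same_block, sc.p_in, sc.p_out)
    W12 = (rng.uniform(size=(sc.g, sc.m)) < probs).astype(float)

    # expression: one mean profile per block, shared across the two layers so
    # co-modules are co-expressed, plus i.i.d. Gaussian noise
    block_means = rng.normal(scale=sc.effect, size=(sc.k_true, sc.n))
    X11 = block_means[gene_blocks] + rng.normal(scale=sc.noise_sd, size=(sc.g, sc.n))
    X21 = block_means[mirna_blocks] + rng.normal(scale=sc.noise_sd, size=(sc.m, sc.n))

    same_gg = gene_blocks[:, None] == gene_blocks[None, :]
    probs_gg = np.where(same_gg, sc.p_in, sc.p_out)
    upper = np.triu((rng.uniform(size=(sc.g, sc.g)) < probs_gg), k=1)
    gene_gene = (upper | upper.T).astype(float)

    gene_motifs = [_random_sequence(rng, sc.motif_len) for _ in range(sc.k_true)]
    mirna_motifs = [_random_sequence(rng, sc.motif_len) for _ in range(sc.k_true)]
    gene_seqs = _block_sequences(rng, gene_blocks, gene_motifs, sc.seq_len, "g")
    mirna_seqs = _block_sequences(rng, mirna_blocks, mirna_motifs, sc.seq_len, "mir")

    return SyntheticBundle(
        W12=W12,
        X11=X11,
        X21=X21,
        gene_gene=gene_gene,
        gene_sequences=gene_seqs,
        mirna_sequences=mirna_seqs,
        gene_labels=[name for name, _ in gene_seqs],
        mirna_labels=[name for name, _ in mirna_seqs],
        gene_blocks=gene_blocks,
        mirna_blocks=mirna_blocks,
        scenario=sc,
    )
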