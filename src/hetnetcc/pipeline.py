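"""End-to-end orchestration: views -> fusion -> co-clustering -> modules."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .awcc import CoClusterState, fit_awcc
from .config import PipelineConfig
from .features import (
    AttributeView,
    HeterogeneousAdjacency,
    build_adjacency,
    build_attribute_view,
    kmer_featurize,
)
from .modules import ModuleAssignment, threshold_modules
from .synthetic import SyntheticBundle
from .vgae import AssociationStack, VgaeHyper, fuse_all

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    adjacency: HeterogeneousAdjacency
    views: list[AttributeView]
    stack: AssociationStack
    state: CoClusterState
    assignment: ModuleAssignment
    config: PipelineConfig


def _maybe_log2(X: np.ndarray, enabled: bool) -> np.ndarray:
    return np.log2(X - X.min() + 1.0) if enabled else X


def _nonneg(X: np.ndarray) -> np.ndarray:
    """Shift to non-negative range for the multiplicative factorization."""
    lo = X.min()
    return X - lo if lo < 0 else X


def build_views(
    W12: np.ndarray,
    X11: np.ndarray,
    X21: np.ndarray,
    gene_gene: np.ndarray | None,
    gene_sequences: list[tuple[str, str]] | None,
    mirna_sequences: list[tuple[str, str]] | None,
    config: PipelineConfig,
) -> list[AttributeView]:
    """Assemble the padded attribute views from the available omics layers.

    Always includes the two expression views; the gene-gene network and the
    two 4-mer sequence-feature views are added when supplied. ``d_ini`` is
    clipped per view to the matrix dimensions (rank deficits pad with zeros).
    """
    g, m = W12.shape
    views: list[AttributeView] = []

    def add(X: np.ndarray, side: str, name: str) -> None:
        rows = g if side == "gene" else m
        # column centering costs one rank, hence rows - 1
        d_eff = min(config.d_ini, max(rows - 1, 1), X.shape[1])
        views.append(
            build_attribute_view(
                X, side, g, m, d_eff, seed=config.seed, source_name=name
            )
        )

    add(_maybe_log2(np.asarray(X11, float), config.log2_expression), "gene", "gene_expression")
    if gene_gene is not None:
        add(np.asarray(gene_gene, float), "gene", "gene_gene")
    if gene_sequences is not None:
        add(kmer_featurize([s for _, s in gene_sequences]).astype(float), "gene", "gene_kmer")
    add(_maybe_log2(np.asarray(X21, float), config.log2_expression), "mirna", "mirna_expression")
    if mirna_sequences is not None:
        add(kmer_featurize([s for _, s in mirna_sequences]).astype(float), "mirna", "mirna_kmer")
    return views


def run_pipeline(bundle: SyntheticBundle, config: PipelineConfig) -> PipelineResult:
    """Run fusion, co-clustering and module discovery on one input bundle.

    The bundle may come from :func:`hetnetcc.synthetic.generate` or be
    assembled from files read through :mod:`hetnetcc.io`; only the fields
    W12/X11/X21 are mandatory (optional omics layers may be None).
    """
    adjacency = build_adjacency(bundle.W12)
    views = build_views(
        bundle.W12,
        bundle.X11,
        bundle.X21,
        bundle.gene_gene,
        bundle.gene_sequences,
        bundle.mirna_sequences,
        config,
    )
    logger.info("fusing %d attribute views", len(views))
    hyper = VgaeHyper(
        hidden_dim=config.hidden_dim,
        latent_dim=config.latent_dim,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
    )
    stack = fuse_all(
        adjacency,
        views,
        hyper=hyper,
        t=config.t,
        seed=config.seed,
        binarize=config.binarize_associations,
    )
    X11 = _nonneg(_maybe_log2(np.asarray(bundle.X11, float), config.log2_expression))
    X21 = _nonneg(_maybe_log2(np.asarray(bundle.X21, float), config.log2_expression))
    logger.info("co-clustering with k=%d over %d views", config.k, len(stack))
    state = fit_awcc(stack.W_list, X11, X21, config)
    assignment = threshold_modules(
        state.G1,
        state.G2,
        config.T1,
        config.T2,
        gene_labels=bundle.gene_labels,
        mirna_labels=bundle.mirna_labels,
    )
    return PipelineResult(
        adjacency=adjacency,
        views=views,
        stack=stack,
        state=state,
        assignment=assignment,
        config=config,
    )
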