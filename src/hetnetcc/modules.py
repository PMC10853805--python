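"""Overlapping co-module extraction and triple-layer linking.

A molecule joins co-module j when the column z-score of its cluster
distribution exceeds the layer threshold (strict inequality), so membership
can overlap and molecules may stay unassigned. Two co-module collections
sharing the gene layer are linked into triple-layer modules through the
Jaccard similarity of their gene sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ModuleAssignment:
    """Binary indicator matrices F1 (genes) and F2 (miRNAs) plus provenance."""

    F1: np.ndarray  # g x k binary
    F2: np.ndarray  # m x k binary
    T1: float
    T2: float
    z1: np.ndarray  # column z-scores behind F1 (used for max-z hardening)
    z2: np.ndarray
    gene_labels: list[str] | None = None
    mirna_labels: list[str] | None = None

    @property
    def k(self) -> int:
        return self.F1.shape[1]

    def module_members(self, j: int) -> tuple[list[str], list[str]]:
        """Member labels of co-module j, both layers (indices if unlabeled)."""
        genes = np.flatnonzero(self.F1[:, j])
        mirnas = np.flatnonzero(self.F2[:, j])
        gl = self.gene_labels or [str(i) for i in range(self.F1.shape[0])]
        ml = self.mirna_labels or [str(i) for i in range(self.F2.shape[0])]
        return [gl[i] for i in genes], [ml[i] for i in mirnas]

    def empty_modules(self) -> list[int]:
        """Indices of modules with no member in either layer."""
        return [
            j
            for j in range(self.k)
            if not self.F1[:, j].any() and not self.F2[:, j].any()
        ]

    def summary(self) -> list[dict]:
        out = []
        for j in range(self.k):
            genes, mirnas = self.module_members(j)
            out.append(
                {
                    "module": j,
                    "n_genes": len(genes),
                    "n_mirnas": len(mirnas),
                    "genes": genes,
                    "mirnas": mirnas,
                    "empty": not genes and not mirnas,
                }
            )
        return out


@dataclass
class TripleLayerModule:
    """A linked pair of co-modules sharing the gene layer."""

    module_a: int
    module_b: int
    jaccard: float
    genes: list[str]  # union of the two gene sets
    shared_genes: list[str]  # the overlapped area
    layer2: list[str]  # second layer of assignment A (e.g. miRNAs)
    layer3: list[str]  # second layer of assignment B (e.g. lncRNAs)


def column_zscores(G: np.ndarray) -> np.ndarray:
    """Column-wise z-scores with population (1/N) standard deviation.

    Constant columns (sigma = 0) map to all-zero z-scores with a warning.
    """
    G = np.asarray(G, dtype=float)
    mu = G.mean(axis=0)
    sigma = G.std(axis=0)  # population std: ddof=0
    zero = sigma == 0
    if zero.any():
        warnings.warn(
            f"constant columns {np.flatnonzero(zero).tolist()} have zero "
            "standard deviation; their z-scores are set to 0",
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, sigma)
    z = (G - mu) / safe
    z[:, zero] = 0.0
    return z


def threshold_modules(
    G1: np.ndarray,
    G2: np.ndarray,
    T1: float,
    T2: float,
    gene_labels: list[str] | None = None,
    mirna_labels: list[str] | None = None,
) -> ModuleAssignment:
    """Assign molecules to co-modules where their column z-score exceeds T.

    The inequality is strict ("exceeds"); membership may overlap and some
    molecules may end up in no module. Modules empty in both layers are
    logged.
    """
    G1 = np.asarray(G1, dtype=float)
    G2 = np.asarray(G2, dtype=float)
    if G1.shape[1] != G2.shape[1]:
        raise ValueError("G1 and G2 must share the number of co-clusters k")
    z1 = column_zscores(G1)
    z2 = column_zscores(G2)
    assign = ModuleAssignment(
        F1=(z1 > T1).astype(int),
        F2=(z2 > T2).astype(int),
        T1=T1,
        T2=T2,
        z1=z1,
        z2=z2,
        gene_labels=gene_labels,
        mirna_labels=mirna_labels,
    )
    empty = assign.empty_modules()
    if empty:
        logger.warning("modules %s are empty in both layers", empty)
    return assign


def jaccard(set_a, set_b) -> float:
    """|A n B| / |A u B|; 0 when both sets are empty."""
    set_a, set_b = set(set_a), set(set_b)
    union = set_a | set_b
    if not union:
        return 0.0
    return len(set_a & set_b) / len(union)


def link_triple_layer(
    assign_a: ModuleAssignment,
    assign_b: ModuleAssignment,
    top_pairs: int = 2,
) -> list[TripleLayerModule]:
    """Link two co-module collections through their shared gene layer.

    Computes the Jaccard similarity between every gene-layer module of
    ``assign_a`` and of ``assign_b`` (over gene label sets) and merges the
    ``top_pairs`` most similar pairs into triple-layer modules whose gene set
    is the union of the pair, with the overlap annotated. Ties break by
    (module_a, module_b) index order.
    """
    ga = assign_a.gene_labels or [str(i) for i in range(assign_a.F1.shape[0])]
    gb = assign_b.gene_labels or [str(i) for i in range(assign_b.F1.shape[0])]
    sets_a = {
        j: {ga[i] for i in np.flatnonzero(assign_a.F1[:, j])}
        for j in range(assign_a.k)
        if assign_a.F1[:, j].any()
    }
    sets_b = {
        j: {gb[i] for i in np.flatnonzero(assign_b.F1[:, j])}
        for j in range(assign_b.k)
        if assign_b.F1[:, j].any()
    }
    if not sets_a or not sets_b:
        warnings.warn("one side has no non-empty gene-layer modules", stacklevel=2)
        return []
    scored = sorted(
        ((ja, jb, jaccard(sa, sb)) for ja, sa in sets_a.items() for jb, sb in sets_b.items()),
        key=lambda x: (-x[2], x[0], x[1]),
    )
    out = []
    for ja, jb, sim in scored[:top_pairs]:
        genes_a, layer2 = assign_a.module_members(ja)
        genes_b, layer3 = assign_b.module_members(jb)
        union = sorted(set(genes_a) | set(genes_b))
        shared = sorted(set(genes_a) & set(genes_b))
        out.append(
            TripleLayerModule(
                module_a=ja,
                module_b=jb,
                jaccard=sim,
                genes=union,
                shared_genes=shared,
                layer2=layer2,
                layer3=layer3,
            )
        )
    return out
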