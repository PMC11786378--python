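"""Per-sample weights combining tree-derived sample-set similarity with
relative expression level.

Two weights are computed for each sample (tissue/biosample):

1. *similarity* — from a hierarchical clustering of the samples, a
   CLUSTALW-style recursion over branch lengths and descendant-leaf
   counts that down-weights redundant, highly similar samples:
   ``w(node) = d(node, parent) / v(node) + w(parent)``, ``w(root) = 0``,
   with the resulting leaf weights rescaled so the maximum is 1.
2. *expression* — a gene's total (median-normalized, log-scale)
   expression in each sample relative to the maximum across samples.

Their elementwise product is the final weight used by every weighted
statistic (entropy, divergence, Tau).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from genediverse.errors import UnexpressedGeneError
from genediverse.tree import SampleTree, TreeNode

__all__ = [
    "WeightVector",
    "cluster_samples",
    "similarity_weights",
    "expression_weights",
    "combined_weights",
]


@dataclass(frozen=True)
class WeightVector:
    """Mapping sample id -> weight in [0, 1], tagged with provenance."""

    weights: pd.Series
    provenance: str  # similarity | expression | combined

    def __post_init__(self):
        w = self.weights
        if ((w < -1e-12) | (w > 1 + 1e-12)).any():
            raise ValueError("weights must lie in [0, 1]")
        if not (w > 0).any():
            raise ValueError("at least one weight must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.weights.index)

    def __getitem__(self, sample: str) -> float:
        return float(self.weights[sample])

    def reindex(self, samples) -> pd.Series:
        return self.weights.reindex(samples)


def cluster_samples(matrix: pd.DataFrame) -> SampleTree:
    """Average-linkage hierarchy of samples on 1 - Pearson correlation.

    ``matrix`` is genes x samples.  Branch lengths are merge-height
    differences (clipped at zero).  A constant sample column has no
    defined correlation and is rejected by name.
    """
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples to cluster")
    if matrix.shape[0] < 1:
        raise ValueError("need at least one gene to cluster samples")
    stds = matrix.std(axis=0, ddof=0)
    constant = stds.index[stds == 0].tolist()
    if constant:
        raise ValueError(
            f"constant expression column(s) {constant}: Pearson correlation undefined"
        )
    corr = np.corrcoef(matrix.to_numpy(dtype=float), rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce symmetry
    Z = linkage(squareform(dist, checks=False), method="average")
    return SampleTree.from_linkage(Z, list(matrix.columns))


def similarity_weights(tree: SampleTree) -> WeightVector:
    """Tree-derived sample-set similarity weights, max-rescaled to 1.

    Degenerate all-zero-branch-length trees (including single-sample
    trees) yield uniform weights of 1.
    """
    raw: dict[str, float] = {}

    def visit(node: TreeNode, parent_weight: float) -> None:
        w = parent_weight if node.parent is None else (
            node.length / node.n_leaves() + parent_weight
        )
        if node.is_leaf:
            raw[node.name] = w
        for child in node.children:
            visit(child, w)

    visit(tree.root, 0.0)
    values = pd.Series(raw, dtype=float).reindex(tree.leaf_names())
    top = values.max()
    if top <= 0:
        values[:] = 1.0
    else:
        values = values / top
    return WeightVector(values, provenance="similarity")


def expression_weights(tensor, gene: str) -> WeightVector:
    """Relative expression weight per sample for one gene.

    Sums the median-normalized log10 expression of the gene's isoforms
    in each sample and rescales by the maximum across samples.  Raises
    :class:`UnexpressedGeneError` when the gene has no expression
    anywhere (callers must exclude such genes).
    """
    eps = tensor.normalized_gene(gene)  # isoforms x samples
    totals = eps.sum(axis=0)
    top = totals.max()
    if top <= 0:
        raise UnexpressedGeneError(gene)
    return WeightVector(totals / top, provenance="expression")


def combined_weights(w1: WeightVector, w2: WeightVector) -> WeightVector:
    """Elementwise product of similarity and expression weights."""
    if set(w1.samples) != set(w2.samples):
        raise ValueError("weight vectors cover different sample sets")
    prod = w1.weights * w2.weights.reindex(w1.weights.index)
    return WeightVector(prod, provenance="combined")
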