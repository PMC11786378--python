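"""Weighted isoform-usage diversity per gene.

Two per-gene summaries over an isoform expression tensor:

* mean intratissue entropy — the weighted mean, over samples, of the
  Shannon entropy (bits) of the gene's isoform-proportion distribution
  within each sample; high when many isoforms are co-expressed evenly.
* mean intertissue divergence — the weighted mean Kullback-Leibler
  divergence (bits) of each sample's isoform profile from the weighted
  mean profile; high when samples use different isoform mixtures.

Both use the same combined similarity x expression weights.  Samples
where the gene is unexpressed are excluded from the weighted means
(their expression weight is zero anyway); genes annotated with a single
isoform are excluded outright.  ``effective_isoform_count`` converts
entropy to the equivalent number of equally expressed isoforms (2**H).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from genediverse.errors import SingleIsoformGeneError, UnexpressedGeneError
from genediverse.tensor import IsoformExpressionTensor
from genediverse.weights import (
    WeightVector,
    combined_weights,
    expression_weights,
    similarity_weights,
)

__all__ = [
    "DiversityResult",
    "isoform_proportions",
    "tissue_entropy",
    "mean_intratissue_entropy",
    "effective_isoform_count",
    "mean_profile",
    "mean_intertissue_divergence",
    "diversity_table",
]


@dataclass(frozen=True)
class DiversityResult:
    gene: str
    n_isoforms: int
    mean_entropy: float | None
    effective_isoforms: float | None
    mean_divergence: float | None
    excluded: bool = False
    reason: str = ""


def isoform_proportions(
    tensor: IsoformExpressionTensor, gene: str, sample: str
) -> pd.Series:
    """Isoform proportion vector x for one gene in one sample."""
    abundances = tensor.gene_matrix(gene)[sample]
    total = abundances.sum()
    if total <= 0:
        raise UnexpressedGeneError(gene)
    return abundances / total


def tissue_entropy(proportions) -> float:
    """Shannon entropy in bits of a proportion vector.

    Zero entries are skipped (0 * log 0 := 0); the vector must sum to 1.
    """
    x = np.asarray(proportions, dtype=float)
    if (x < 0).any():
        raise ValueError("proportions must be non-negative")
    if abs(x.sum() - 1.0) > 1e-6:
        raise ValueError(f"proportions sum to {x.sum():.6g}, expected 1")
    nz = x[x > 0]
    return float(-(nz * np.log2(nz)).sum() + 0.0)  # +0.0 avoids -0.0


def effective_isoform_count(entropy_bits: float) -> float:
    """2**H: the number of equally expressed isoforms with entropy H."""
    if entropy_bits < 0:
        raise ValueError("entropy must be non-negative")
    return float(2.0 ** entropy_bits)


def _active_samples(gene_tpm: pd.DataFrame, weights: WeightVector) -> pd.Index:
    """Samples with positive weight where the gene is expressed."""
    w = weights.reindex(gene_tpm.columns)
    if w.isna().any():
        missing = list(gene_tpm.columns[w.isna()])
        raise ValueError(f"weights missing for samples {missing[:5]}")
    totals = gene_tpm.sum(axis=0)
    return gene_tpm.columns[(w > 0) & (totals > 0)]


def _check_multi_isoform(tensor: IsoformExpressionTensor, gene: str) -> pd.DataFrame:
    gene_tpm = tensor.gene_matrix(gene)
    if gene_tpm.shape[0] < 2:
        raise SingleIsoformGeneError(gene)
    return gene_tpm


def mean_intratissue_entropy(
    tensor: IsoformExpressionTensor, gene: str, weights: WeightVector
) -> float:
    """Weighted mean over samples of per-sample isoform entropy (bits)."""
    gene_tpm = _check_multi_isoform(tensor, gene)
    active = _active_samples(gene_tpm, weights)
    if len(active) == 0:
        raise UnexpressedGeneError(gene)
    w = weights.reindex(active)
    ent = np.array(
        [tissue_entropy(isoform_proportions(tensor, gene, s)) for s in active]
    )
    return float((w.to_numpy() * ent).sum() / w.sum())


def mean_profile(
    tensor: IsoformExpressionTensor, gene: str, weights: WeightVector
) -> pd.Series:
    """Weighted mean isoform-proportion profile q across samples.

    Isoforms with zero expression in every sample are dropped first, so
    q_i > 0 wherever any active sample expresses isoform i.
    """
    gene_tpm = _check_multi_isoform(tensor, gene)
    active = _active_samples(gene_tpm, weights)
    if len(active) == 0:
        raise UnexpressedGeneError(gene)
    w = weights.reindex(active)
    props = pd.DataFrame(
        {s: isoform_proportions(tensor, gene, s) for s in active}
    )
    q = (props * w).sum(axis=1) / w.sum()
    q = q[q > 0]  # never-expressed isoforms dropped
    return q / q.sum()


def mean_intertissue_divergence(
    tensor: IsoformExpressionTensor, gene: str, weights: WeightVector
) -> float:
    """Weighted mean KL divergence (bits) of each sample's isoform
    profile from the weighted mean profile q."""
    gene_tpm = _check_multi_isoform(tensor, gene)
    active = _active_samples(gene_tpm, weights)
    if len(active) == 0:
        raise UnexpressedGeneError(gene)
    w = weights.reindex(active)
    q = mean_profile(tensor, gene, weights)
    dkl = np.empty(len(active))
    for j, s in enumerate(active):
        x = isoform_proportions(tensor, gene, s)
        nz = x[x > 0]
        q_nz = q.reindex(nz.index)
        # q_i = 0 with x_{t,i} > 0 for a positively weighted sample is
        # impossible: q averages over exactly these samples.
        assert not q_nz.isna().any() and (q_nz > 0).all()
        dkl[j] = float((nz * np.log2(nz / q_nz)).sum())
    return float((w.to_numpy() * dkl).sum() / w.sum())


def gene_diversity(
    tensor: IsoformExpressionTensor,
    gene: str,
    sim_weights: WeightVector,
) -> DiversityResult:
    """Entropy/divergence summary for one gene with per-gene combined
    weights (similarity x expression)."""
    n_iso = len(tensor.isoforms(gene))
    try:
        expr_w = expression_weights(tensor, gene)
        w = combined_weights(sim_weights, expr_w)
        h = mean_intratissue_entropy(tensor, gene, w)
        d = mean_intertissue_divergence(tensor, gene, w)
    except (SingleIsoformGeneError, UnexpressedGeneError) as exc:
        return DiversityResult(
            gene=gene,
            n_isoforms=n_iso,
            mean_entropy=None,
            effective_isoforms=None,
            mean_divergence=None,
            excluded=True,
            reason=exc.reason,
        )
    return DiversityResult(
        gene=gene,
        n_isoforms=n_iso,
        mean_entropy=h,
        effective_isoforms=effective_isoform_count(h),
        mean_divergence=d,
    )


def diversity_table(
    tensor: IsoformExpressionTensor,
    tree=None,
) -> pd.DataFrame:
    """Per-gene diversity table over the whole tensor.

    The sample tree is clustered from summed gene expression when not
    supplied.
    """
    if tree is None:
        from genediverse.weights import cluster_samples

        gene_level = tensor.matrix.groupby(
            tensor.matrix.index.map(tensor.gene_of)
        ).sum()
        tree = cluster_samples(gene_level)
    sim = similarity_weights(tree)
    rows = [gene_diversity(tensor, g, sim) for g in tensor.genes]
    return pd.DataFrame(
        {
            "gene": [r.gene for r in rows],
            "n_isoforms": [r.n_isoforms for r in rows],
            "mean_entropy_bits": [r.mean_entropy for r in rows],
            "effective_isoforms": [r.effective_isoforms for r in rows],
            "mean_divergence_bits": [r.mean_divergence for r in rows],
            "excluded": [r.excluded for r in rows],
            "reason": [r.reason for r in rows],
        }
    ).set_index("gene")
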