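"""Expression normalization chain and weighted Tau specificity.

The chain is strictly ordered: raw -> tpm (protein-coding,
non-mitochondrial renormalization) -> log (log10(x+1)) ->
median_normalized (per-sample median centering with grand-median
re-offset).  Calling a stage out of order is an error.  The
median-normalized output is exactly the epsilon consumed by the
relative-expression weight computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from genediverse.weights import WeightVector

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "filter_and_renormalize",
    "log_transform",
    "median_normalize",
    "weighted_tau",
]

_STAGES = ("raw", "tpm", "log", "median_normalized")

MITO_CHROMS = {"MT", "chrM", "chrMT", "M"}


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample abundance matrix with a processing-stage tag.

    ``meta`` carries per-gene 'biotype' and 'chromosome' columns (indexed
    by gene).  ``raw_nonzero`` records which entries were nonzero at the
    raw stage; median normalization is computed over these entries only.
    """

    values: pd.DataFrame
    stage: str = "raw"
    meta: pd.DataFrame | None = None
    raw_nonzero: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage in ("raw", "tpm") and (self.values < 0).any().any():
            raise ValueError(f"negative abundances at stage {self.stage!r}")

    def _require_stage(self, expected: str, op: str) -> None:
        if self.stage != expected:
            raise ValueError(
                f"{op} requires stage {expected!r}, matrix is at {self.stage!r} "
                f"(pipeline order is {' -> '.join(_STAGES)})"
            )


def filter_and_renormalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop non-protein-coding and mitochondrial genes, then rescale each
    sample column of the retained set to sum to 1e6 (TPM)."""
    matrix._require_stage("raw", "filter_and_renormalize")
    if matrix.meta is None:
        raise ValueError("gene metadata (biotype, chromosome) required")
    meta = matrix.meta.reindex(matrix.values.index)
    keep = (meta["biotype"] == "protein_coding") & ~meta["chromosome"].isin(MITO_CHROMS)
    vals = matrix.values.loc[keep]
    totals = vals.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"sample(s) {zero} have zero total expression after filtering")
    vals = vals / totals * 1e6
    return ExpressionMatrix(
        values=vals,
        stage="tpm",
        meta=matrix.meta,
        raw_nonzero=vals > 0,
    )


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """x -> log10(x + 1)."""
    matrix._require_stage("tpm", "log_transform")
    nonzero = matrix.raw_nonzero if matrix.raw_nonzero is not None else matrix.values > 0
    return replace(
        matrix,
        values=np.log10(matrix.values + 1.0),
        stage="log",
        raw_nonzero=nonzero,
    )


def median_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-sample median centering with grand-median re-offset.

    For each sample, the median of the log values over genes that were
    nonzero at the raw stage is subtracted, then the grand median of
    those per-sample medians is added back, keeping values on the
    original scale.  Negatives produced by the shift are clipped to 0
    (count logged); zeros (unexpressed entries) stay zero.
    """
    matrix._require_stage("log", "median_normalize")
    vals = matrix.values
    nonzero = matrix.raw_nonzero if matrix.raw_nonzero is not None else vals > 0
    masked = vals.where(nonzero)
    sample_medians = masked.median(axis=0)
    sample_medians = sample_medians.fillna(0.0)
    grand = float(sample_medians.median())
    shifted = vals.sub(sample_medians, axis=1) + grand
    shifted = shifted.where(nonzero, 0.0)
    n_clipped = int((shifted < 0).sum().sum())
    if n_clipped:
        logger.info("median_normalize: clipped %d negative values to 0", n_clipped)
    shifted = shifted.clip(lower=0.0)
    return replace(matrix, values=shifted, stage="median_normalized")


def normalize_chain(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Full raw -> median_normalized chain."""
    return median_normalize(log_transform(filter_and_renormalize(matrix)))


def weighted_tau(expression: pd.Series, weights: WeightVector | pd.Series) -> float:
    """Weighted Tau expression-specificity index in [0, 1].

    Base Tau is sum(1 - x/max(x)) / (m - 1).  The weighted variant
    rescales the weight vector so its maximum is 1 (leaving the
    classical uniform case untouched) and uses

        tau_w = sum_t w_t (1 - x_t / max(x)) / (sum_t w_t - 1)

    which reduces to base Tau for uniform weights and is invariant to
    duplicating a sample (the duplicated pair's similarity weights sum
    to the weight a single leaf would receive).

    0 = uniform expression, 1 = expressed in a single sample.
    """
    x = pd.Series(expression, dtype=float)
    if len(x) < 2:
        raise ValueError("weighted_tau requires at least two samples")
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    top = x.max()
    if top <= 0:
        raise ValueError("weighted_tau undefined for an all-zero expression vector")
    w = weights.weights if isinstance(weights, WeightVector) else pd.Series(weights, dtype=float)
    w = w.reindex(x.index)
    if w.isna().any():
        raise ValueError("weights missing for some samples")
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    w = w / w.max()
    denom = w.sum() - 1.0
    if denom <= 0:
        raise ValueError("effective sample count <= 1; Tau undefined")
    tau = float((w * (1.0 - x / top)).sum() / denom)
    return min(max(tau, 0.0), 1.0)
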