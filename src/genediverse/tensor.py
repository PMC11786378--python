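"""Isoform expression tensor: per-gene isoform x sample abundances.

Backed by a single transcripts x samples TPM matrix plus a
transcript -> gene map.  The median-normalized log10 view (epsilon)
used by the expression weights is computed lazily from the full matrix
and cached.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["IsoformExpressionTensor"]


class IsoformExpressionTensor:
    def __init__(self, matrix: pd.DataFrame, gene_of: Mapping[str, str]):
        """``matrix``: transcripts x samples, non-negative TPM.
        ``gene_of``: transcript id -> gene id for every row."""
        if (matrix < 0).any().any():
            raise ValueError("abundances must be non-negative")
        if not np.isfinite(matrix.to_numpy(dtype=float)).all():
            raise ValueError("abundances must be finite")
        if matrix.index.duplicated().any():
            raise ValueError("duplicate transcript ids in matrix")
        missing = [t for t in matrix.index if t not in gene_of]
        if missing:
            raise ValueError(f"transcripts without gene mapping: {missing[:5]}")
        self.matrix = matrix.astype(float)
        self.gene_of = dict(gene_of)
        self._by_gene: dict[str, list[str]] = {}
        for t in matrix.index:
            self._by_gene.setdefault(self.gene_of[t], []).append(t)
        self._eps: pd.DataFrame | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def genes(self) -> list[str]:
        return list(self._by_gene)

    def isoforms(self, gene: str) -> list[str]:
        try:
            return list(self._by_gene[gene])
        except KeyError:
            raise KeyError(f"gene {gene!r} not present in tensor") from None

    def gene_matrix(self, gene: str) -> pd.DataFrame:
        """Raw TPM sub-matrix (isoforms x samples) for one gene."""
        return self.matrix.loc[self.isoforms(gene)]

    def normalized(self) -> pd.DataFrame:
        """Median-normalized log10(TPM+1) matrix (epsilon), cached."""
        if self._eps is None:
            from genediverse.specificity import (
                ExpressionMatrix,
                log_transform,
                median_normalize,
            )

            em = ExpressionMatrix(
                values=self.matrix, stage="tpm", raw_nonzero=self.matrix > 0
            )
            self._eps = median_normalize(log_transform(em)).values
        return self._eps

    def normalized_gene(self, gene: str) -> pd.DataFrame:
        return self.normalized().loc[self.isoforms(gene)]
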