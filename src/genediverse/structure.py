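"""Gene/transcript/exon structural features.

All coordinates are 1-based inclusive (GTF convention) end to end.
Gene length is the genomic span (end - start + 1, introns included);
transcript length is the sum of exon lengths.  Structural analyses use
the canonical transcript only; first/middle/last exon partitioning is
strand-aware via the exon rank field (rank 1 = first exon transcribed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from genediverse.errors import ExcludedInputError

__all__ = [
    "AnnotationTable",
    "ExonPartition",
    "gene_length",
    "transcript_length",
    "exon_partition",
    "single_exon_fraction",
    "regress_log",
]


@dataclass
class AnnotationTable:
    """Gene, transcript and exon records.

    genes: gene_id (index), label, chromosome, start, end, strand, biotype
    transcripts: transcript_id (index), gene_id, canonical (bool)
    exons: transcript_id, start, end, rank (rank 1 = first transcribed)
    """

    genes: pd.DataFrame
    transcripts: pd.DataFrame
    exons: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        g, t, e = self.genes, self.transcripts, self.exons
        if (g["start"] > g["end"]).any():
            bad = g.index[g["start"] > g["end"]].tolist()
            raise ValueError(f"gene(s) with start > end: {bad[:5]}")
        if (e["start"] > e["end"]).any():
            raise ValueError("exon(s) with start > end")
        canon_counts = t.groupby("gene_id")["canonical"].sum()
        bad = canon_counts[canon_counts != 1]
        if len(bad):
            raise ValueError(
                f"genes without exactly one canonical transcript: {list(bad.index)[:5]}"
            )
        for tid, grp in e.groupby("transcript_id"):
            ranks = sorted(grp["rank"])
            if ranks != list(range(1, len(ranks) + 1)):
                raise ValueError(f"transcript {tid!r}: exon ranks not contiguous from 1")

    def canonical_transcripts(self) -> pd.DataFrame:
        return self.transcripts[self.transcripts["canonical"]]

    def transcript_exons(self, transcript_id: str) -> pd.DataFrame:
        ex = self.exons[self.exons["transcript_id"] == transcript_id]
        return ex.sort_values("rank")


@dataclass(frozen=True)
class ExonPartition:
    transcript_id: str
    first_prop: float
    middle_prop: float | None  # absent (None) for two-exon transcripts
    last_prop: float
    exon_count: int
    transcript_length: int


def gene_length(gene: pd.Series) -> int:
    """Genomic span in nt: end - start + 1 (strand-independent)."""
    length = int(gene["end"]) - int(gene["start"]) + 1
    if length <= 0:
        raise ValueError("gene has non-positive span")
    return length


def transcript_length(exons: pd.DataFrame) -> int:
    """Sum of exon lengths in nt.  Exons of one transcript must not
    overlap."""
    if len(exons) == 0:
        raise ValueError("transcript has zero exons")
    ivs = sorted(zip(exons["start"], exons["end"]))
    for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
        if s2 <= e1:
            raise ValueError(f"overlapping exons: ({s1},{e1}) and starting {s2}")
    return int(sum(e - s + 1 for s, e in ivs))


def exon_partition(transcript_id: str, exons: pd.DataFrame) -> ExonPartition:
    """Fractions of transcript length in the first, aggregated-middle and
    last exon (transcription order via rank).  Single-exon transcripts
    are excluded."""
    exons = exons.sort_values("rank")
    n = len(exons)
    if n < 2:
        raise ExcludedInputError(
            f"transcript {transcript_id!r} is single-exon; partition undefined",
            reason="single_exon",
        )
    lengths = (exons["end"] - exons["start"] + 1).to_numpy(dtype=float)
    total = lengths.sum()
    first = lengths[0] / total
    last = lengths[-1] / total
    middle = None if n == 2 else float(lengths[1:-1].sum() / total)
    return ExonPartition(
        transcript_id=transcript_id,
        first_prop=float(first),
        middle_prop=middle,
        last_prop=float(last),
        exon_count=n,
        transcript_length=int(total),
    )


def single_exon_fraction(table: AnnotationTable, group: str) -> tuple[int, int, float]:
    """(k, n, k/n): canonical transcripts that are single-exon within a
    gene group."""
    genes = table.genes[table.genes["label"] == group]
    if len(genes) == 0:
        raise ValueError(f"no genes in group {group!r}")
    canon = table.canonical_transcripts()
    canon = canon[canon["gene_id"].isin(genes.index)]
    exon_counts = table.exons.groupby("transcript_id").size()
    k = int((exon_counts.reindex(canon.index).fillna(0) == 1).sum())
    n = len(canon)
    return k, n, k / n


def regress_log(
    x,
    y,
    log_x: bool = True,
    log_y: bool = True,
) -> tuple[float, float, float]:
    """OLS of (optionally log10) y on (optionally log10) x.

    Returns (slope, intercept, R^2).  Requires n >= 3, finite positive
    values wherever a log is applied, and nonzero variance in x.
    """
    from scipy import stats as sps

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("regression requires at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in regression input")
    if log_x:
        if (x <= 0).any():
            raise ValueError("log10 transform requires positive x")
        x = np.log10(x)
    if log_y:
        if (y <= 0).any():
            raise ValueError("log10 transform requires positive y")
        y = np.log10(y)
    if np.var(x) == 0:
        raise ValueError("zero variance in x")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def structure_features(table: AnnotationTable) -> pd.DataFrame:
    """Per-gene structural feature table over canonical transcripts."""
    canon = table.canonical_transcripts()
    exon_counts = table.exons.groupby("transcript_id").size()
    rows = []
    for tid, rec in canon.iterrows():
        gid = rec["gene_id"]
        gene = table.genes.loc[gid]
        exons = table.transcript_exons(tid)
        n_exons = len(exons)
        part = (None, None, None)
        if n_exons >= 2:
            p = exon_partition(tid, exons)
            part = (p.first_prop, p.middle_prop, p.last_prop)
        rows.append(
            {
                "gene": gid,
                "label": gene["label"],
                "gene_length": gene_length(gene),
                "transcript_length": transcript_length(exons),
                "exon_count": n_exons,
                "first_prop": part[0],
                "middle_prop": part[1],
                "last_prop": part[2],
                "n_transcripts": int(
                    (table.transcripts["gene_id"] == gid).sum()
                ),
            }
        )
    return pd.DataFrame(rows).set_index("gene")
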