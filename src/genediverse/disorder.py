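"""Intrinsically disordered region (IDR) statistics per protein.

Residue intervals are 1-based inclusive within [1, length].  Stored
intervals may overlap or abut; they are merged (adjacent intervals
joined) before any fraction or maximum-length computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from genediverse.errors import ExcludedInputError

__all__ = [
    "ProteinDisorder",
    "merge_intervals",
    "disordered_fraction",
    "max_disordered_length",
    "has_disorder",
    "read_disorder_tsv",
    "write_disorder_tsv",
    "disorder_features",
]


@dataclass(frozen=True)
class ProteinDisorder:
    protein_id: str
    length: int
    intervals: tuple = field(default_factory=tuple)  # ((start, end), ...)

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"protein {self.protein_id!r}: length must be >= 1")
        for s, e in self.intervals:
            if not (1 <= s <= e <= self.length):
                raise ValueError(
                    f"protein {self.protein_id!r}: interval ({s},{e}) outside "
                    f"[1, {self.length}]"
                )


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Sort and merge overlapping or adjacent (end+1 == next start)
    intervals, preserving the residue union."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    for s, e in ivs:
        if s > e:
            raise ValueError(f"interval ({s},{e}) has start > end")
        if s < 1:
            raise ValueError(f"interval ({s},{e}) starts below 1")
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def disordered_fraction(record: ProteinDisorder) -> float:
    """Fraction of residues in merged disordered intervals, in [0, 1]."""
    merged = merge_intervals(record.intervals)
    covered = sum(e - s + 1 for s, e in merged)
    return covered / record.length


def max_disordered_length(record: ProteinDisorder) -> int:
    """Length (residues) of the longest merged disordered interval."""
    if not record.intervals:
        raise ExcludedInputError(
            f"protein {record.protein_id!r} has no disorder annotation",
            reason="no_disorder",
        )
    merged = merge_intervals(record.intervals)
    return max(e - s + 1 for s, e in merged)


def has_disorder(record: ProteinDisorder) -> bool:
    return len(record.intervals) > 0


def read_disorder_tsv(path: str | Path) -> dict[str, ProteinDisorder]:
    """Read one interval per row: protein_id, length, start, end.
    Rows with empty start/end declare a protein without intervals.
    Multiple rows per protein are concatenated."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    records: dict[str, list] = {}
    lengths: dict[str, int] = {}
    for _, row in df.iterrows():
        pid = row["protein_id"]
        lengths[pid] = int(row["length"])
        records.setdefault(pid, [])
        if pd.notna(row.get("start")) and pd.notna(row.get("end")):
            records[pid].append((int(row["start"]), int(row["end"])))
    return {
        pid: ProteinDisorder(pid, lengths[pid], tuple(ivs))
        for pid, ivs in records.items()
    }


def write_disorder_tsv(records: dict[str, ProteinDisorder], path: str | Path) -> None:
    rows = []
    for pid in sorted(records):
        rec = records[pid]
        if rec.intervals:
            for s, e in rec.intervals:
                rows.append({"protein_id": pid, "length": rec.length, "start": s, "end": e})
        else:
            rows.append({"protein_id": pid, "length": rec.length, "start": None, "end": None})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def disorder_features(records: dict[str, ProteinDisorder]) -> pd.DataFrame:
    """Per-protein table: length, has_disorder, fraction, max IDR length
    (NaN for proteins without annotation)."""
    rows = []
    for pid, rec in records.items():
        rows.append(
            {
                "protein": pid,
                "length": rec.length,
                "has_disorder": has_disorder(rec),
                "disordered_fraction": disordered_fraction(rec),
                "max_idr_length": (
                    max_disordered_length(rec) if rec.intervals else None
                ),
            }
        )
    return pd.DataFrame(rows).set_index("protein")
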