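"""Multiprotein-complex partner counting.

A gene's *partners* are all members of its complexes other than itself.
A partner present in every one of the gene's complexes is constitutive;
one present in only some is variable.  Genes in one or fewer complexes
are excluded from partner counting (variable/constitutive is undefined
with a single complex).  Distinct complexes are counted by curated id:
two ids with identical membership are two complexes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from genediverse.errors import ExcludedInputError

__all__ = [
    "ComplexTable",
    "complexes_of",
    "mean_complex_size",
    "variable_partners",
    "complex_summary",
    "kat6a_preset",
]


@dataclass
class ComplexTable:
    """Mapping complex id -> member set.  Duplicate member entries are
    collapsed; empty member sets are rejected."""

    members: dict[str, frozenset]

    def __init__(self, members: Mapping[str, Iterable[str]]):
        collapsed = {}
        for cid, ms in members.items():
            s = frozenset(ms)
            if not s:
                raise ValueError(f"complex {cid!r} has an empty member set")
            collapsed[cid] = s
        self.members = collapsed

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ComplexTable":
        """Read 'complex_id<TAB>member1,member2,...' lines (header
        allowed if the first field is 'complex_id')."""
        members = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            cid, field = line.split("\t")[:2]
            if cid == "complex_id":
                continue
            members[cid] = [m.strip() for m in field.split(",") if m.strip()]
        return cls(members)

    def write_tsv(self, path: str | Path) -> None:
        lines = ["complex_id\tmembers"]
        for cid in sorted(self.members):
            lines.append(f"{cid}\t{','.join(sorted(self.members[cid]))}")
        Path(path).write_text("\n".join(lines) + "\n")


def complexes_of(table: ComplexTable, gene: str) -> set[str]:
    """Ids of all complexes containing the gene (possibly empty)."""
    return {cid for cid, ms in table.members.items() if gene in ms}


def mean_complex_size(table: ComplexTable, gene: str) -> float:
    """Arithmetic mean member-set size over the gene's complexes."""
    cids = complexes_of(table, gene)
    if not cids:
        raise ExcludedInputError(
            f"gene {gene!r} is in no complex", reason="no_complex"
        )
    return float(np.mean([len(table.members[c]) for c in cids]))


def variable_partners(
    table: ComplexTable, gene: str
) -> tuple[int, int, dict[str, set[str]]]:
    """(n_variable, n_constitutive, {'variable': ..., 'constitutive': ...}).

    Requires the gene to be in >= 2 complexes.
    """
    cids = sorted(complexes_of(table, gene))
    if len(cids) <= 1:
        raise ExcludedInputError(
            f"gene {gene!r} is associated with {len(cids)} complex(es); "
            "partner counting requires at least 2",
            reason="too_few_complexes",
        )
    partner_sets = [set(table.members[c]) - {gene} for c in cids]
    union = set().union(*partner_sets)
    constitutive = set.intersection(*partner_sets) if partner_sets else set()
    variable = union - constitutive
    return (
        len(variable),
        len(constitutive),
        {"variable": variable, "constitutive": constitutive},
    )


def complex_summary(table: ComplexTable, labels: Mapping[str, str]) -> pd.DataFrame:
    """Per-group summary: fraction of genes in >= 1 complex, complex
    counts, mean sizes and variable-partner counts per gene.

    ``labels`` maps gene -> group; every labeled gene is considered
    (genes absent from the table count as having zero complexes).
    """
    rows = []
    for gene, group in labels.items():
        cids = complexes_of(table, gene)
        n_complexes = len(cids)
        row = {
            "gene": gene,
            "label": group,
            "n_complexes": n_complexes,
            "mean_complex_size": (
                mean_complex_size(table, gene) if n_complexes else None
            ),
        }
        if n_complexes >= 2:
            n_var, n_con, _ = variable_partners(table, gene)
            row["n_variable"] = n_var
            row["n_constitutive"] = n_con
        else:
            row["n_variable"] = None
            row["n_constitutive"] = None
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def kat6a_preset() -> ComplexTable:
    """The three-complex worked example: a focal gene with two
    constitutive partners and three variable BRPF-species partners."""
    return ComplexTable(
        {
            "CPX-1": ["KAT6A", "ING5", "MEAF6", "BRPF1"],
            "CPX-2": ["KAT6A", "ING5", "MEAF6", "BRPF2"],
            "CPX-3": ["KAT6A", "ING5", "MEAF6", "BRPF3"],
        }
    )
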