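"""Phenotype-ontology traversal and disease classification.

Maps disease phenotype terms to *major body systems* — the direct
children of a designated root phenotypic-abnormality term — by ancestor
closure over a child->parent DAG, after filtering out somatic-mutation
and susceptibility-factor disease records.  Inheritance-mode flags are
OR-ed per gene over its retained diseases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyGraph",
    "major_systems",
    "map_terms_to_systems",
    "filter_diseases",
    "systems_per_gene",
    "inheritance_summary",
    "read_disease_annotations",
]

_MODES = {"dominant", "recessive", "other"}


@dataclass
class OntologyGraph:
    """Directed child -> parent term graph with a designated root
    phenotype term.  Must be acyclic with every term reaching the root."""

    graph: nx.DiGraph
    root: str

    def __init__(self, edges: Iterable[tuple[str, str]], root: str):
        g = nx.DiGraph()
        g.add_node(root)
        for child, parent in edges:
            g.add_edge(child, parent)
        if root not in g:
            raise ValueError(f"root term {root!r} absent from ontology")
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology contains a cycle")
        unreachable = [
            n for n in g.nodes if n != root and root not in nx.descendants(g, n)
        ]
        if unreachable:
            raise ValueError(f"terms not reaching root: {unreachable[:5]}")
        self.graph = g
        self.root = root
        self._ancestors: dict[str, frozenset] = {}

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def ancestors(self, term: str) -> frozenset:
        """All ancestors of a term plus the term itself (memoized)."""
        if term not in self.graph:
            raise KeyError(f"unknown ontology term {term!r}")
        cached = self._ancestors.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self.graph, term)) | {term}
            self._ancestors[term] = cached
        return cached

    @classmethod
    def read_edges_tsv(cls, path: str | Path, root: str) -> "OntologyGraph":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(list(zip(df["child"], df["parent"])), root=root)

    def write_edges_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.graph.edges), columns=["child", "parent"]
        ).to_csv(path, sep="\t", index=False)


def major_systems(graph: OntologyGraph, include: Iterable[str] | None = None) -> set[str]:
    """Direct children of the root phenotype term, optionally
    restricted to an include-list."""
    systems = set(graph.graph.predecessors(graph.root))
    if include is not None:
        systems &= set(include)
    return systems


def map_terms_to_systems(
    graph: OntologyGraph, terms: Iterable[str], systems: set[str] | None = None
) -> set[str]:
    """Union over terms of (ancestors + self), intersected with the
    major-system set.  Unknown terms are an error."""
    if systems is None:
        systems = major_systems(graph)
    hit: set[str] = set()
    for term in terms:
        hit |= graph.ancestors(term) & systems
    return hit


def normalize_mode(mode: str) -> str:
    m = str(mode).strip().lower()
    if m in _MODES:
        return m
    if "dominant" in m:
        return "dominant"
    if "recessive" in m:
        return "recessive"
    logger.warning("unknown inheritance mode %r treated as 'other'", mode)
    return "other"


def read_disease_annotations(path: str | Path) -> pd.DataFrame:
    """TSV columns: gene, disease, modes (semicolon-separated), somatic,
    susceptibility, terms (semicolon-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df["somatic"] = df["somatic"].astype(str).str.lower().isin(("true", "1", "yes"))
    df["susceptibility"] = (
        df["susceptibility"].astype(str).str.lower().isin(("true", "1", "yes"))
    )
    df["modes"] = df["modes"].fillna("").map(
        lambda s: frozenset(normalize_mode(m) for m in s.split(";") if m.strip())
    )
    df["terms"] = df["terms"].fillna("").map(
        lambda s: frozenset(t.strip() for t in s.split(";") if t.strip())
    )
    return df


def filter_diseases(annotations: pd.DataFrame) -> pd.DataFrame:
    """Remove somatic-mutation and susceptibility-factor records."""
    mask = ~(annotations["somatic"] | annotations["susceptibility"])
    removed = int((~mask).sum())
    if removed:
        logger.info(
            "filter_diseases: removed %d of %d records (somatic/susceptibility)",
            removed,
            len(annotations),
        )
    return annotations[mask].copy()


def systems_per_gene(graph: OntologyGraph, annotations: pd.DataFrame) -> pd.DataFrame:
    """Per gene: union of major systems over its (filtered) diseases.

    Genes with no retained diseases are absent from the output.
    """
    systems = major_systems(graph)
    rows = []
    for gene, grp in annotations.groupby("gene"):
        hit: set[str] = set()
        for terms in grp["terms"]:
            hit |= map_terms_to_systems(graph, terms, systems)
        rows.append({"gene": gene, "n_systems": len(hit), "systems": hit})
    return pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["n_systems", "systems"]
    )


def inheritance_summary(annotations: pd.DataFrame) -> pd.DataFrame:
    """Per gene: any_dominant / any_recessive flags (OR over diseases)."""
    rows = []
    for gene, grp in annotations.groupby("gene"):
        modes: set[str] = set().union(*grp["modes"]) if len(grp) else set()
        rows.append(
            {
                "gene": gene,
                "any_dominant": "dominant" in modes,
                "any_recessive": "recessive" in modes,
            }
        )
    return pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["any_dominant", "any_recessive"]
    )
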