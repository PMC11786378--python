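"""Synthetic data generators for every pipeline input, with ground truth.

Each generator draws from its own deterministic stream derived from the
single integer seed in :class:`SimConfig`, so artifacts are reproducible
independently of generation order.  Generators return the data object
together with a ground-truth record (planted group labels, true
variable-partner counts, trajectory classes, term-to-system maps) for
recovery tests.

The isoform tensor uses a hierarchical Dirichlet scheme: each gene
draws a base isoform-proportion profile from a symmetric
Dirichlet(``dirichlet_base_concentration``), and each tissue draws its
profile from Dirichlet(``between_tissue_concentration`` x base).  Large
between-tissue concentration makes tissues identical (low divergence);
small values make them divergent.  Entropy responds to the annotated
isoform count and the base concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from genediverse.complexes import ComplexTable
from genediverse.disorder import ProteinDisorder
from genediverse.phenotype import OntologyGraph
from genediverse.structure import AnnotationTable
from genediverse.tensor import IsoformExpressionTensor
from genediverse.tree import SampleTree

__all__ = [
    "SimConfig",
    "gen_annotation",
    "gen_isoform_tensor",
    "gen_complex_table",
    "gen_disorder_table",
    "gen_ontology",
    "gen_disease_annotations",
    "gen_temporal_profiles",
]

GROUPS = ("epigene", "non_epigene", "histone")

# distinct stream ids so each artifact has an independent substream
_STREAMS = {
    "annotation": 1,
    "tensor": 2,
    "complexes": 3,
    "disorder": 4,
    "ontology": 5,
    "disease": 6,
    "temporal": 7,
}


def _default_tree_spec(n: int) -> str:
    leaves = ",".join(f"T{i + 1}:1.0" for i in range(n))
    return f"({leaves});"


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 100
    n_tissues: int = 6
    group_fractions: dict = field(
        default_factory=lambda: {"epigene": 0.3, "non_epigene": 0.6, "histone": 0.1}
    )
    # (mu, sigma) of log10 gene length per group
    length_lognormal_params: dict = field(
        default_factory=lambda: {
            "epigene": (4.6, 0.4),
            "non_epigene": (4.3, 0.4),
            "histone": (3.0, 0.2),
        }
    )
    # mean exons per kb of genomic span, per group
    exon_rate: dict = field(
        default_factory=lambda: {"epigene": 0.5, "non_epigene": 0.4, "histone": 0.0}
    )
    # Poisson mean of extra isoforms beyond the first, per group
    isoform_count_params: dict = field(
        default_factory=lambda: {"epigene": 4.0, "non_epigene": 2.0, "histone": 0.3}
    )
    dirichlet_base_concentration: float = 1.0
    between_tissue_concentration: float = 20.0
    tree_spec: str | None = None
    complex_params: dict = field(
        default_factory=lambda: {
            "n_complexes": {"epigene": 3, "non_epigene": 2, "histone": 0},
            "constitutive_size": 2,
            "variable_pool_size": None,  # None -> one distinct member per complex
        }
    )
    disorder_params: dict = field(
        default_factory=lambda: {
            "prob_disordered": {"epigene": 0.8, "non_epigene": 0.5, "histone": 0.9},
            "interval_rate": 1.0,
            "mean_interval_length": 40,
            "protein_length_params": (2.8, 0.25),
        }
    )
    ontology_params: dict = field(
        default_factory=lambda: {
            "n_systems": 4,
            "terms_per_system": 5,
            "multi_parent_prob": 0.1,
        }
    )
    disease_params: dict = field(
        default_factory=lambda: {
            "prob_disease": {"epigene": 0.5, "non_epigene": 0.3, "histone": 0.1},
            "max_diseases": 3,
            "max_terms": 3,
            "p_somatic": 0.1,
            "p_susceptibility": 0.1,
            "mode_probs": {"dominant": 0.4, "recessive": 0.4, "other": 0.2},
        }
    )
    trajectory_params: dict = field(
        default_factory=lambda: {
            "class_fractions": {
                "increasing": 0.3,
                "decreasing": 0.3,
                "oscillating": 0.3,
                "flat": 0.1,
            },
            "noise_sd": 0.02,
            "n_subregions": 3,
            "ages": (8.0, 9.0, 12.0, 16.0, 21.0, 24.0, 35.0, 37.0),
        }
    )

    def __post_init__(self):
        self.validate()
        if self.tree_spec is None:
            self.tree_spec = _default_tree_spec(self.n_tissues)

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed: must be an integer")
        if self.n_genes < 1:
            raise ValueError("n_genes: must be >= 1")
        if self.n_tissues < 1:
            raise ValueError("n_tissues: must be >= 1")
        total = sum(self.group_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group_fractions: must sum to 1, got {total}")
        if set(self.group_fractions) - set(GROUPS):
            raise ValueError(
                f"group_fractions: unknown group(s) "
                f"{sorted(set(self.group_fractions) - set(GROUPS))}"
            )
        if self.dirichlet_base_concentration <= 0:
            raise ValueError("dirichlet_base_concentration: must be > 0")
        if self.between_tissue_concentration <= 0:
            raise ValueError("between_tissue_concentration: must be > 0")
        for group, rate in self.exon_rate.items():
            if rate < 0:
                raise ValueError(f"exon_rate[{group}]: must be >= 0")
        cp = self.complex_params
        if cp["constitutive_size"] < 0:
            raise ValueError("complex_params.constitutive_size: must be >= 0")
        vp = cp.get("variable_pool_size")
        if vp is not None and vp < 1:
            raise ValueError("complex_params.variable_pool_size: must be >= 1")
        fr = self.trajectory_params["class_fractions"]
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError("trajectory_params.class_fractions: must sum to 1")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([_STREAMS[stream], self.seed])

    def _per_group(self, value, group):
        return value[group] if isinstance(value, Mapping) else value


def _assign_groups(config: SimConfig, rng: np.random.Generator) -> pd.Series:
    """Deterministic group counts (largest remainder), shuffled."""
    n = config.n_genes
    quotas = {g: config.group_fractions.get(g, 0.0) * n for g in GROUPS}
    counts = {g: int(np.floor(q)) for g, q in quotas.items()}
    leftover = n - sum(counts.values())
    by_rem = sorted(GROUPS, key=lambda g: quotas[g] - counts[g], reverse=True)
    for g in by_rem[:leftover]:
        counts[g] += 1
    labels = np.array([g for g in GROUPS for _ in range(counts[g])], dtype=object)
    rng.shuffle(labels)
    gene_ids = [f"G{i + 1:05d}" for i in range(n)]
    return pd.Series(labels, index=gene_ids, name="label")


def _gene_groups(config: SimConfig) -> pd.Series:
    # group assignment is shared by every generator: draw from the
    # annotation stream without consuming the rest of its state
    return _assign_groups(config, config.rng("annotation"))


def gen_annotation(config: SimConfig) -> AnnotationTable:
    """Gene/transcript/exon annotation with planted group length shift.

    Gene lengths are log-normal on log10 scale per group; exon counts
    are 1 + Poisson(exon_rate * span_kb); each gene's first transcript
    is canonical.  Exons are disjoint within a transcript and ranked in
    transcription order (strand-aware).
    """
    rng = config.rng("annotation")
    labels = _assign_groups(config, rng)
    gene_rows, tx_rows, exon_rows = [], [], []
    for gene_id, group in labels.items():
        mu, sigma = config.length_lognormal_params[group]
        length = max(50, int(round(10 ** rng.normal(mu, sigma))))
        start = int(rng.integers(1, 100_000_000))
        end = start + length - 1
        strand = "+" if rng.random() < 0.5 else "-"
        gene_rows.append(
            {
                "gene_id": gene_id,
                "label": group,
                "chromosome": "chr1",
                "start": start,
                "end": end,
                "strand": strand,
                "biotype": "protein_coding",
            }
        )
        n_tx = 1 + int(rng.poisson(config.isoform_count_params[group]))
        rate = config.exon_rate[group]
        for t in range(n_tx):
            tx_id = f"{gene_id}.T{t + 1}"
            tx_rows.append(
                {"transcript_id": tx_id, "gene_id": gene_id, "canonical": t == 0}
            )
            k = 1 + int(rng.poisson(rate * length / 1000.0))
            k = min(k, length // 2)  # need 2k distinct positions in the span
            k = max(k, 1)
            if k == 1:
                ivs = [(start, end)]
            else:
                cuts = np.sort(rng.choice(length, size=2 * k, replace=False))
                ivs = [
                    (start + int(cuts[2 * j]), start + int(cuts[2 * j + 1]))
                    for j in range(k)
                ]
            ordered = ivs if strand == "+" else list(reversed(ivs))
            for rank, (s, e) in enumerate(ordered, start=1):
                exon_rows.append(
                    {"transcript_id": tx_id, "start": s, "end": e, "rank": rank}
                )
    genes = pd.DataFrame(gene_rows).set_index("gene_id")
    transcripts = pd.DataFrame(tx_rows).set_index("transcript_id")
    exons = pd.DataFrame(exon_rows)
    return AnnotationTable(genes=genes, transcripts=transcripts, exons=exons)


def gen_isoform_tensor(
    config: SimConfig, annotation: AnnotationTable | None = None
) -> tuple[IsoformExpressionTensor, SampleTree]:
    """Hierarchical-Dirichlet isoform abundances plus the true sample tree.

    Isoform ids match :func:`gen_annotation` output for the same config.
    """
    if annotation is None:
        annotation = gen_annotation(config)
    tree = SampleTree.from_newick(config.tree_spec)
    if tree.n_samples != config.n_tissues:
        raise ValueError(
            f"tree_spec has {tree.n_samples} leaves but n_tissues={config.n_tissues}"
        )
    samples = tree.leaf_names()
    rng = config.rng("tensor")
    alpha0 = config.dirichlet_base_concentration
    c = config.between_tissue_concentration
    # tissue expression factors follow Brownian motion on the tree so
    # sample-sample correlation reflects the generating topology
    nodes = list(tree.root.iter_nodes())
    node_idx = {id(n): i for i, n in enumerate(nodes)}
    branch_sd = np.array([np.sqrt(max(n.length, 0.0)) for n in nodes])
    rows = {}
    for gene_id in annotation.genes.index:
        isoforms = annotation.transcripts.index[
            annotation.transcripts["gene_id"] == gene_id
        ].tolist()
        k = len(isoforms)
        if k == 1:
            profiles = np.ones((len(samples), 1))
        else:
            base = rng.dirichlet(np.full(k, alpha0))
            base = np.clip(base, 1e-8, None)
            base /= base.sum()
            profiles = rng.dirichlet(c * base, size=len(samples))
        gene_scale = 10 ** rng.normal(1.5, 0.5)  # overall gene expression level
        deviates = rng.normal(0.0, 0.3, size=len(nodes)) * branch_sd
        log_factor = {}
        for node in nodes:  # parents precede children in iter_nodes order
            parent_lf = log_factor.get(id(node.parent), 0.0)
            log_factor[id(node)] = parent_lf + deviates[node_idx[id(node)]]
        tissue_factors = np.array(
            [10 ** log_factor[id(leaf)] for leaf in tree.leaves()]
        )
        for i, iso in enumerate(isoforms):
            rows[iso] = gene_scale * tissue_factors * profiles[:, i]
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    gene_of = annotation.transcripts["gene_id"].to_dict()
    return IsoformExpressionTensor(matrix, gene_of), tree


def gen_complex_table(config: SimConfig) -> tuple[ComplexTable, pd.DataFrame]:
    """Complex membership with known constitutive/variable structure.

    Each focal gene with k >= 1 complexes gets complexes
    {focal} | constitutive set | {one variable member}; variable members
    are drawn from a per-gene pool (pool size defaults to k, so each
    complex carries a distinct variable member).  Ground truth records
    the true variable-partner count per focal gene.
    """
    labels = _gene_groups(config)
    cp = config.complex_params
    members: dict[str, list[str]] = {}
    truth_rows = []
    for gene_id, group in labels.items():
        k = int(config._per_group(cp["n_complexes"], group))
        if k < 1:
            truth_rows.append(
                {"gene": gene_id, "label": group, "n_complexes": 0, "n_variable": 0}
            )
            continue
        constitutive = [f"{gene_id}_C{j + 1}" for j in range(cp["constitutive_size"])]
        v = cp.get("variable_pool_size") or k
        pool = [f"{gene_id}_V{j + 1}" for j in range(v)]
        used: list[str] = []
        for i in range(k):
            var = pool[i % v]
            used.append(var)
            members[f"CPX_{gene_id}_{i + 1}"] = [gene_id, *constitutive, var]
        # a pool member present in every complex is constitutive, not variable
        counts = pd.Series(used).value_counts()
        n_variable = int((counts < k).sum()) if k >= 2 else 0
        truth_rows.append(
            {
                "gene": gene_id,
                "label": group,
                "n_complexes": k,
                "n_variable": n_variable,
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("gene")
    return ComplexTable(members), truth


def gen_disorder_table(
    config: SimConfig,
) -> tuple[dict[str, ProteinDisorder], pd.DataFrame]:
    """Per-protein disorder intervals with ground-truth disorder flags."""
    labels = _gene_groups(config)
    rng = config.rng("disorder")
    dp = config.disorder_params
    mu, sigma = dp["protein_length_params"]
    records: dict[str, ProteinDisorder] = {}
    truth_rows = []
    for gene_id, group in labels.items():
        length = max(50, int(round(10 ** rng.normal(mu, sigma))))
        prob = config._per_group(dp["prob_disordered"], group)
        intervals: list[tuple[int, int]] = []
        if rng.random() < prob:
            n_iv = 1 + int(rng.poisson(dp["interval_rate"]))
            for _ in range(n_iv):
                iv_len = min(int(rng.geometric(1.0 / dp["mean_interval_length"])), length)
                s = int(rng.integers(1, length - iv_len + 2))
                intervals.append((s, s + iv_len - 1))
        records[gene_id] = ProteinDisorder(gene_id, length, tuple(intervals))
        truth_rows.append(
            {"gene": gene_id, "label": group, "has_disorder": bool(intervals)}
        )
    truth = pd.DataFrame(truth_rows).set_index("gene")
    return records, truth


ROOT_TERM = "SYS:ROOT"


def gen_ontology(config: SimConfig) -> tuple[OntologyGraph, pd.DataFrame]:
    """Single-rooted DAG: root -> systems -> terms, with occasional
    multi-parent terms.  Ground truth maps each term to its system set."""
    rng = config.rng("ontology")
    op = config.ontology_params
    n_sys = int(op["n_systems"])
    if n_sys < 2:
        raise ValueError("ontology_params.n_systems: must be >= 2")
    systems = [f"SYS:{i + 1}" for i in range(n_sys)]
    edges = [(s, ROOT_TERM) for s in systems]
    truth_rows = [{"term": s, "systems": frozenset([s])} for s in systems]
    for i, s in enumerate(systems):
        for j in range(int(op["terms_per_system"])):
            term = f"TERM:{i + 1}.{j + 1}"
            parents = {s}
            if n_sys > 1 and rng.random() < op["multi_parent_prob"]:
                other = systems[int(rng.integers(n_sys - 1))]
                if other == s:
                    other = systems[-1]
                parents.add(other)
            for p in sorted(parents):
                edges.append((term, p))
            truth_rows.append({"term": term, "systems": frozenset(parents)})
    graph = OntologyGraph(edges, root=ROOT_TERM)
    truth = pd.DataFrame(truth_rows).set_index("term")
    return graph, truth


def gen_disease_annotations(
    config: SimConfig, ontology: OntologyGraph | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-disease-term records with somatic/susceptibility flags.

    Ground truth marks which rows survive filtering and each gene's true
    system set over retained diseases.
    """
    if ontology is None:
        ontology, _ = gen_ontology(config)
    labels = _gene_groups(config)
    rng = config.rng("disease")
    dp = config.disease_params
    terms = sorted(t for t in ontology.graph.nodes if t.startswith("TERM:"))
    if not terms:  # fall back to system terms for tiny ontologies
        terms = sorted(ontology.graph.predecessors(ontology.root))
    mode_names = list(dp["mode_probs"])
    mode_p = np.array([dp["mode_probs"][m] for m in mode_names], dtype=float)
    mode_p /= mode_p.sum()
    rows = []
    disease_n = 0
    for gene_id, group in labels.items():
        if rng.random() >= config._per_group(dp["prob_disease"], group):
            continue
        for _ in range(1 + int(rng.integers(dp["max_diseases"]))):
            disease_n += 1
            n_terms = 1 + int(rng.integers(dp["max_terms"]))
            dz_terms = list(rng.choice(terms, size=min(n_terms, len(terms)), replace=False))
            mode = str(rng.choice(mode_names, p=mode_p))
            rows.append(
                {
                    "gene": gene_id,
                    "disease": f"DZ{disease_n:05d}",
                    "modes": frozenset([mode]),
                    "somatic": bool(rng.random() < dp["p_somatic"]),
                    "susceptibility": bool(rng.random() < dp["p_susceptibility"]),
                    "terms": frozenset(dz_terms),
                }
            )
    annotations = pd.DataFrame(
        rows, columns=["gene", "disease", "modes", "somatic", "susceptibility", "terms"]
    )
    truth = annotations.copy()
    truth["filtered"] = truth["somatic"] | truth["susceptibility"]
    return annotations, truth


_TRAJECTORY_SHAPES = {
    "increasing": lambda t: 0.2 + 0.8 * t,
    "decreasing": lambda t: 1.0 - 0.8 * t,
    "oscillating": lambda t: 0.6 + 0.35 * np.sin(2.0 * np.pi * 2.0 * t),
    "flat": lambda t: np.full_like(t, 0.6),
}


def gen_temporal_profiles(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format temporal samples plus ground-truth trajectory classes.

    Each gene is assigned a trajectory class (shared across subregions)
    and emits value = scale * shape(t) + Gaussian noise at each age.
    """
    rng = config.rng("temporal")
    tp = config.trajectory_params
    ages = np.asarray(tp["ages"], dtype=float)
    if not (np.diff(ages) > 0).all():
        raise ValueError("trajectory_params.ages: must be strictly increasing")
    labels = _gene_groups(config)
    fractions = tp["class_fractions"]
    classes = list(fractions)
    n = len(labels)
    counts = {cl: int(np.floor(fractions[cl] * n)) for cl in classes}
    leftover = n - sum(counts.values())
    by_rem = sorted(classes, key=lambda cl: fractions[cl] * n - counts[cl], reverse=True)
    for cl in by_rem[:leftover]:
        counts[cl] += 1
    assignment = np.array([cl for cl in classes for _ in range(counts[cl])], dtype=object)
    rng.shuffle(assignment)
    t01 = (ages - ages.min()) / max(ages.max() - ages.min(), 1e-12)
    rows = []
    for r in range(int(tp["n_subregions"])):
        subregion = f"SR{r + 1}"
        for gene_id, cl in zip(labels.index, assignment):
            shape = _TRAJECTORY_SHAPES[cl](t01)
            scale = 100.0
            noise = rng.normal(0.0, tp["noise_sd"], size=len(ages)) if tp["noise_sd"] > 0 else 0.0
            values = np.clip(scale * (shape + noise), 0.0, None)
            for age, v in zip(ages, values):
                rows.append(
                    {"subregion": subregion, "age_pcw": age, "gene": gene_id, "value": v}
                )
    samples = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {"gene": labels.index, "label": labels.values, "trajectory_class": assignment}
    ).set_index("gene")
    return samples, truth
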