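"""End-to-end pipeline orchestration.

A pipeline run reads a YAML/JSON config, generates (or loads) every
input, executes each analysis stage, and writes per-stage TSVs plus a
group-comparison summary table and a manifest recording seeds and
parameters so any run can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from genediverse import __version__, simulate
from genediverse.complexes import complex_summary
from genediverse.disorder import disorder_features
from genediverse.diversity import diversity_table
from genediverse.phenotype import (
    filter_diseases,
    inheritance_summary,
    systems_per_gene,
)
from genediverse.specificity import (
    ExpressionMatrix,
    normalize_chain,
    weighted_tau,
)
from genediverse.stats import geometric_mean, permutation_test
from genediverse.structure import structure_features
from genediverse.temporal import (
    assign_genes,
    cluster_seed_genes,
    filter_by_range,
    metacluster,
    prepare_profiles,
    scale_max,
)
from genediverse.weights import similarity_weights

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

_KNOWN_TOP = {"output_dir", "simulate", "params", "inputs"}
_KNOWN_PARAMS = {
    "n_perm",
    "seed",
    "focal_label",
    "sided",
    "assign_threshold",
    "cluster_cut",
    "min_timepoints",
    "range_min",
    "max_age",
}


@dataclass
class PipelineConfig:
    output_dir: Path
    sim: simulate.SimConfig
    n_perm: int = 1000
    seed: int = 0
    focal_label: str = "epigene"
    sided: str = "two-sided"
    assign_threshold: float = 0.8
    cluster_cut: float = 0.2
    min_timepoints: int = 5
    range_min: float = 0.5
    max_age: float = 40.0


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML/JSON pipeline config, collecting all
    violations before raising."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    problems: list[str] = []
    unknown = set(raw) - _KNOWN_TOP
    if unknown:
        problems.append(f"unknown top-level key(s): {sorted(unknown)}")
    params = raw.get("params", {}) or {}
    unknown_p = set(params) - _KNOWN_PARAMS
    if unknown_p:
        problems.append(f"unknown params key(s): {sorted(unknown_p)}")
    if "output_dir" not in raw:
        problems.append("missing required key: output_dir")
    for key in ("n_perm", "seed"):
        if key in params and not isinstance(params[key], int):
            problems.append(f"params.{key}: must be an integer")
    for key, p in (raw.get("inputs", {}) or {}).items():
        if not Path(p).exists():
            problems.append(f"inputs.{key}: path does not exist: {p}")
    sim_kwargs = dict(raw.get("simulate", {}) or {})
    sim_fields = set(simulate.SimConfig.__dataclass_fields__)
    unknown_s = set(sim_kwargs) - sim_fields
    if unknown_s:
        problems.append(f"unknown simulate key(s): {sorted(unknown_s)}")
        sim_kwargs = {k: v for k, v in sim_kwargs.items() if k in sim_fields}
    if problems:
        raise ValueError("invalid config:\n  " + "\n  ".join(problems))
    try:
        sim = simulate.SimConfig(**sim_kwargs)
    except ValueError as exc:
        raise ValueError(f"invalid config:\n  simulate.{exc}") from exc
    known = {k: v for k, v in params.items() if k in _KNOWN_PARAMS}
    return PipelineConfig(output_dir=Path(raw["output_dir"]), sim=sim, **known)


def _group_summary(values: pd.Series, labels: pd.Series, focal: str) -> dict:
    """Geometric mean per group when all values are positive, arithmetic
    mean otherwise."""
    out = {}
    for group in sorted(labels.unique()):
        v = values[labels == group].dropna()
        if len(v) == 0:
            out[group] = None
        elif (v > 0).all():
            out[group] = geometric_mean(v)
        else:
            out[group] = float(v.mean())
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on synthetic inputs; returns the manifest dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    sim = config.sim

    def stage(name):
        logger.info("stage: %s", name)
        stages.append(name)

    try:
        stage("simulate")
        annotation = simulate.gen_annotation(sim)
        tensor, tree = simulate.gen_isoform_tensor(sim, annotation)
        cx_table, cx_truth = simulate.gen_complex_table(sim)
        dis_records, _ = simulate.gen_disorder_table(sim)
        ontology, _ = simulate.gen_ontology(sim)
        diseases, _ = simulate.gen_disease_annotations(sim, ontology)
        temporal_samples, temporal_truth = simulate.gen_temporal_profiles(sim)
        labels = annotation.genes["label"]

        stage("structure")
        struct = structure_features(annotation)
        struct.to_csv(out / "structure.tsv", sep="\t")

        stage("weights")
        sim_w = similarity_weights(tree)
        sim_w.weights.rename("w_similarity").rename_axis("sample").to_csv(
            out / "weights.tsv", sep="\t"
        )

        stage("diversity")
        div = diversity_table(tensor, tree)
        div.to_csv(out / "diversity.tsv", sep="\t")

        stage("complexes")
        cx = complex_summary(cx_table, labels.to_dict())
        cx.to_csv(out / "complexes.tsv", sep="\t")

        stage("disorder")
        dis = disorder_features(dis_records)
        dis["label"] = labels.reindex(dis.index)
        dis.to_csv(out / "disorder.tsv", sep="\t")

        stage("phenotype")
        retained = filter_diseases(diseases)
        systems = systems_per_gene(ontology, retained)
        inher = inheritance_summary(retained)
        pheno = systems.join(inher, how="outer")
        pheno["systems"] = pheno["systems"].map(
            lambda s: ";".join(sorted(s)) if isinstance(s, (set, frozenset)) else ""
        )
        pheno.to_csv(out / "phenotype.tsv", sep="\t")

        stage("specificity")
        gene_expr = tensor.matrix.groupby(tensor.matrix.index.map(tensor.gene_of)).sum()
        meta = annotation.genes[["biotype", "chromosome"]]
        em = ExpressionMatrix(values=gene_expr, stage="raw", meta=meta)
        norm = normalize_chain(em)
        taus = {}
        for gene in norm.values.index:
            vec = norm.values.loc[gene]
            if vec.max() > 0:
                taus[gene] = weighted_tau(vec, sim_w)
        tau_df = pd.Series(taus, name="tau").rename_axis("gene").to_frame()
        tau_df.to_csv(out / "specificity.tsv", sep="\t")

        stage("temporal")
        profiles = prepare_profiles(
            temporal_samples,
            min_timepoints=config.min_timepoints,
            max_age=config.max_age,
        )
        seed_genes = labels.index[labels == config.focal_label].tolist()
        cluster_sets = []
        for profile in profiles.values():
            filtered, _ = filter_by_range(profile, min_range=config.range_min)
            scaled = scale_max(filtered)
            present_seeds = [g for g in seed_genes if g in scaled.matrix.index]
            if len(present_seeds) < 2:
                continue
            cs = cluster_seed_genes(scaled, present_seeds, cut=config.cluster_cut)
            cs = assign_genes(cs, scaled, threshold=config.assign_threshold)
            cluster_sets.append(cs)
        if len(cluster_sets) >= 2:
            meta_table = metacluster(cluster_sets, cut=config.cluster_cut)
        else:
            meta_table = pd.DataFrame(columns=["subregion", "cluster", "metacluster"])
        meta_table.to_csv(out / "metaclusters.tsv", sep="\t", index=False)

        stage("summary")
        features = {
            "gene_length": struct["gene_length"],
            "transcript_length": struct["transcript_length"],
            "n_transcripts": struct["n_transcripts"],
            "mean_entropy": div["mean_entropy_bits"],
            "mean_divergence": div["mean_divergence_bits"],
            "n_complexes": cx["n_complexes"],
            "n_variable_partners": cx["n_variable"],
            "disordered_fraction": dis["disordered_fraction"],
            "max_idr_length": dis["max_idr_length"],
            "n_systems": systems["n_systems"] if len(systems) else pd.Series(dtype=float),
            "tau": tau_df["tau"],
        }
        rows = []
        for name, values in features.items():
            values = pd.Series(values, dtype=float).dropna()
            feat_labels = labels.reindex(values.index).dropna()
            values = values.reindex(feat_labels.index)
            row = {"feature": name}
            row.update(
                {
                    f"{g}_summary": v
                    for g, v in _group_summary(values, feat_labels, config.focal_label).items()
                }
            )
            if (
                (feat_labels == config.focal_label).sum() >= 2
                and (feat_labels != config.focal_label).sum()
                >= (feat_labels == config.focal_label).sum()
            ):
                res = permutation_test(
                    values.to_numpy(),
                    feat_labels.to_numpy(),
                    focal_label=config.focal_label,
                    statistic="mean",
                    n_perm=config.n_perm,
                    seed=config.seed,
                    sided=config.sided,
                )
                row["p_value"] = (
                    res.p_two_sided if config.sided == "two-sided" else res.p_one_sided
                )
                row["p_display"] = res.p_display
            else:
                row["p_value"] = None
                row["p_display"] = "NA"
            rows.append(row)
        summary = pd.DataFrame(rows).set_index("feature")
        summary.to_csv(out / "summary.tsv", sep="\t")
    except Exception as exc:
        failed = stages[-1] if stages else "setup"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "stages": stages,
        "seed": config.seed,
        "sim_seed": sim.seed,
        "n_perm": config.n_perm,
        "focal_label": config.focal_label,
        "params": {
            "assign_threshold": config.assign_threshold,
            "cluster_cut": config.cluster_cut,
            "min_timepoints": config.min_timepoints,
            "range_min": config.range_min,
            "max_age": config.max_age,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
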