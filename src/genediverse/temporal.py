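"""Temporal co-expression clustering and cross-subregion metaclustering.

Per subregion: same-age samples are averaged, columns converted
RPKM -> TPM, low-range genes removed, each gene max-scaled, then the
seed-gene group is clustered by average linkage on 1 - weighted Pearson
correlation with time weights from equal-weight 10-week developmental
bins (0-40 post-conception weeks).  Remaining genes are assigned to the
best-correlated cluster mean when that correlation exceeds a threshold.
Cluster means across subregions are imputed onto a common age grid
(nearest timepoint, earlier age on ties) and clustered again into
metaclusters.  The whole pipeline is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TemporalProfile",
    "ClusterSet",
    "prepare_profiles",
    "filter_by_range",
    "scale_max",
    "binned_time_weights",
    "weighted_pearson",
    "cluster_seed_genes",
    "assign_genes",
    "impute_nearest",
    "metacluster",
]


@dataclass(frozen=True)
class TemporalProfile:
    subregion: str
    ages: tuple  # strictly increasing post-conception weeks
    matrix: pd.DataFrame  # genes x ages
    units: str = "RPKM"  # RPKM | TPM | scaled

    def __post_init__(self):
        ages = tuple(self.ages)
        if list(ages) != sorted(set(ages)):
            raise ValueError("ages must be strictly increasing")
        if self.units != "scaled" and (self.matrix < 0).any().any():
            raise ValueError("negative expression before scaling")


@dataclass
class ClusterSet:
    subregion: str
    clusters: dict  # cluster id -> {"seed": [...], "assigned": {gene: corr}}
    means: pd.DataFrame  # cluster id x ages, mean of seed trajectories
    ages: tuple


def prepare_profiles(
    samples: pd.DataFrame,
    min_timepoints: int = 5,
    max_age: float = 40.0,
) -> dict[str, TemporalProfile]:
    """Build per-subregion profiles from long-format samples.

    ``samples`` columns: subregion, age_pcw, gene, value (RPKM).
    Same-age samples within a subregion are averaged first, then each
    age column is rescaled to TPM (x / sum * 1e6).  Ages beyond
    ``max_age`` are dropped; subregions with fewer than
    ``min_timepoints`` remaining ages are dropped.
    """
    out: dict[str, TemporalProfile] = {}
    for subregion, grp in samples.groupby("subregion"):
        grp = grp[grp["age_pcw"] <= max_age]
        if grp.empty:
            continue
        mat = grp.pivot_table(
            index="gene", columns="age_pcw", values="value", aggfunc="mean"
        )
        mat = mat.reindex(sorted(mat.columns), axis=1)
        if mat.shape[1] < min_timepoints:
            continue
        totals = mat.sum(axis=0)
        mat = mat / totals * 1e6
        out[subregion] = TemporalProfile(
            subregion=subregion,
            ages=tuple(mat.columns),
            matrix=mat,
            units="TPM",
        )
    return out


def filter_by_range(
    profile: TemporalProfile, min_range: float = 0.5
) -> tuple[TemporalProfile, list[str]]:
    """Drop genes whose temporal expression range (max - min) is
    strictly below ``min_range``.  Returns (profile, dropped genes)."""
    rng = profile.matrix.max(axis=1) - profile.matrix.min(axis=1)
    keep = rng >= min_range
    dropped = list(profile.matrix.index[~keep])
    return replace(profile, matrix=profile.matrix[keep]), dropped


def scale_max(profile: TemporalProfile) -> TemporalProfile:
    """Divide each gene's trajectory by its maximum (max becomes 1)."""
    if (profile.matrix < 0).any().any():
        raise ValueError("negative expression value before max-scaling")
    maxes = profile.matrix.max(axis=1)
    assert (maxes > 0).all(), "zero-max gene survived the range filter"
    return replace(profile, matrix=profile.matrix.div(maxes, axis=0), units="scaled")


def binned_time_weights(
    ages: Sequence[float],
    n_bins: int = 4,
    span: tuple[float, float] = (0.0, 40.0),
) -> pd.Series:
    """Equal-weight developmental time bins.

    The span is split into ``n_bins`` equal bins; each *non-empty* bin
    receives total weight 1/(number of non-empty bins), split equally
    among its ages.  Weights sum to 1.
    """
    ages = list(ages)
    lo, hi = span
    width = (hi - lo) / n_bins
    bin_of = {}
    for a in ages:
        if not (lo < a <= hi):
            raise ValueError(f"age {a} outside ({lo}, {hi}]")
        b = min(int(np.ceil((a - lo) / width)) - 1, n_bins - 1)
        bin_of[a] = b
    counts = pd.Series(bin_of).value_counts()
    n_nonempty = len(counts)
    w = pd.Series(
        {a: 1.0 / n_nonempty / counts[bin_of[a]] for a in ages}, dtype=float
    ).reindex(ages)
    return w


def weighted_pearson(x, y, w) -> float:
    """Weighted Pearson correlation; reduces to ordinary Pearson for
    uniform weights."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (len(x) == len(y) == len(w)):
        raise ValueError("x, y, w must have equal length")
    if len(x) < 2:
        raise ValueError("need at least two observations")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    mx = (w * x).sum()
    my = (w * y).sum()
    cov = (w * (x - mx) * (y - my)).sum()
    vx = (w * (x - mx) ** 2).sum()
    vy = (w * (y - my) ** 2).sum()
    if vx <= 0 or vy <= 0:
        raise ValueError("zero weighted variance; correlation undefined")
    return float(np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0))


def _weighted_corr_matrix(mat: np.ndarray, w: np.ndarray) -> np.ndarray:
    w = w / w.sum()
    means = mat @ w
    centered = mat - means[:, None]
    cov = (centered * w) @ centered.T
    sd = np.sqrt(np.diag(cov))
    if (sd <= 0).any():
        raise ValueError("gene(s) with zero weighted variance")
    return np.clip(cov / np.outer(sd, sd), -1.0, 1.0)


def cluster_seed_genes(
    profile: TemporalProfile,
    seed_genes: Sequence[str],
    weights: pd.Series | None = None,
    cut: float = 0.2,
) -> ClusterSet:
    """Average-linkage clustering of seed genes on 1 - weighted Pearson,
    cut at ``cut`` (distance).  Cluster ids are 1-based, ordered by
    first member appearance."""
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    seed_genes = [g for g in seed_genes if g in profile.matrix.index]
    if len(seed_genes) < 2:
        raise ValueError("need at least two seed genes present in the profile")
    if weights is None:
        weights = binned_time_weights(profile.ages)
    w = weights.reindex(list(profile.ages)).to_numpy(dtype=float)
    mat = profile.matrix.loc[seed_genes].to_numpy(dtype=float)
    corr = _weighted_corr_matrix(mat, w)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=cut, criterion="distance")
    clusters: dict[int, dict] = {}
    relabel: dict[int, int] = {}
    for gene, lab in zip(seed_genes, labels):
        cid = relabel.setdefault(int(lab), len(relabel) + 1)
        clusters.setdefault(cid, {"seed": [], "assigned": {}})["seed"].append(gene)
    means = pd.DataFrame(
        {
            cid: profile.matrix.loc[info["seed"]].mean(axis=0)
            for cid, info in clusters.items()
        }
    ).T
    return ClusterSet(
        subregion=profile.subregion,
        clusters=clusters,
        means=means,
        ages=profile.ages,
    )


def assign_genes(
    cluster_set: ClusterSet,
    profile: TemporalProfile,
    weights: pd.Series | None = None,
    threshold: float = 0.8,
) -> ClusterSet:
    """Assign each non-seed gene to its best-correlated cluster mean iff
    that correlation exceeds ``threshold`` (strict); ties break to the
    lowest cluster id."""
    if weights is None:
        weights = binned_time_weights(profile.ages)
    w = weights.reindex(list(profile.ages)).to_numpy(dtype=float)
    seeded = {g for info in cluster_set.clusters.values() for g in info["seed"]}
    cids = sorted(cluster_set.clusters)
    for gene in profile.matrix.index:
        if gene in seeded:
            continue
        x = profile.matrix.loc[gene].to_numpy(dtype=float)
        best_cid, best_r = None, -np.inf
        for cid in cids:
            try:
                r = weighted_pearson(x, cluster_set.means.loc[cid].to_numpy(), w)
            except ValueError:
                continue
            if r > best_r:
                best_cid, best_r = cid, r
        if best_cid is not None and best_r > threshold:
            cluster_set.clusters[best_cid]["assigned"][gene] = best_r
    return cluster_set


def impute_nearest(trajectory: pd.Series, target_ages: Sequence[float]) -> pd.Series:
    """Project a trajectory onto new ages using the value at the nearest
    source age; equidistant ties take the earlier age."""
    source = np.asarray(trajectory.index, dtype=float)
    if source.size == 0:
        raise ValueError("trajectory has no timepoints")
    values = trajectory.to_numpy(dtype=float)
    out = {}
    for b in target_ages:
        deltas = np.abs(source - b)
        # stable argmin picks the earlier age on ties (source is sorted)
        out[b] = values[int(np.argmin(deltas))]
    return pd.Series(out)


def metacluster(
    cluster_sets: Sequence[ClusterSet],
    cut: float = 0.2,
) -> pd.DataFrame:
    """Cluster the per-subregion cluster means into metaclusters.

    Means are imputed onto the union age grid (nearest timepoint), time
    weights recomputed on that grid, then average linkage on
    1 - weighted Pearson is cut at ``cut``.  Returns a table with one
    row per (subregion, cluster) and its metacluster id.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    entries = [
        (cs.subregion, cid, cs.means.loc[cid])
        for cs in cluster_sets
        for cid in sorted(cs.clusters)
    ]
    if len(entries) < 2:
        raise ValueError("metaclustering needs at least two tissue clusters")
    grid = sorted({a for cs in cluster_sets for a in cs.ages})
    mat = np.vstack(
        [impute_nearest(mean, grid).to_numpy() for _, _, mean in entries]
    )
    w = binned_time_weights(grid).to_numpy(dtype=float)
    corr = _weighted_corr_matrix(mat, w)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=cut, criterion="distance")
    relabel: dict[int, int] = {}
    rows = []
    for (subregion, cid, _), lab in zip(entries, labels):
        mid = relabel.setdefault(int(lab), len(relabel) + 1)
        rows.append({"subregion": subregion, "cluster": cid, "metacluster": mid})
    return pd.DataFrame(rows)
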