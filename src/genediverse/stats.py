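"""Inferential machinery: resampling-based permutation tests,
two-sample proportion tests, Bonferroni correction, geometric means.

The permutation test contrasts a focal gene group against the pool of
remaining genes: the pool is repeatedly sampled *without replacement*
at the focal-group size, the chosen aggregate statistic is evaluated on
each contrast set, and the observed focal statistic is located in that
null distribution.  With ``n_perm`` resamples the smallest reportable
one-sided significance level is ``1 / n_perm`` (e.g. 1e-5 at 100,000);
internally an add-one estimator is used so p is never exactly zero, and
saturated results are flagged for "< floor" display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from statsmodels.stats.proportion import proportions_ztest

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "STATISTICS",
    "permutation_test",
    "proportion_test",
    "bonferroni",
    "geometric_mean",
]


def geometric_mean(values: Sequence[float]) -> float:
    """exp(mean(log x)) over strictly positive values.

    Zeros are excluded (their count is logged); negatives are an error;
    an empty input (after zero exclusion) is an error.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size and (arr < 0).any():
        raise ValueError("geometric_mean requires non-negative values")
    n_zero = int((arr == 0).sum())
    if n_zero:
        logger.info("geometric_mean: excluding %d zero values", n_zero)
        arr = arr[arr > 0]
    if arr.size == 0:
        raise ValueError("geometric_mean of an empty (or all-zero) set")
    return float(np.exp(np.mean(np.log(arr))))


def _prop_above(threshold: float) -> Callable[[np.ndarray], float]:
    def stat(x: np.ndarray) -> float:
        return float(np.mean(np.asarray(x) > threshold))

    stat.__name__ = f"prop_above_{threshold}"
    return stat


#: Named aggregate statistics usable by :func:`permutation_test`.
STATISTICS: dict[str, Callable[[np.ndarray], float]] = {
    "mean": lambda x: float(np.mean(x)),
    "median": lambda x: float(np.median(x)),
    "geometric_mean": geometric_mean,
}


def resolve_statistic(statistic: str | Callable) -> Callable[[np.ndarray], float]:
    if callable(statistic):
        return statistic
    if statistic.startswith("prop_above:"):
        return _prop_above(float(statistic.split(":", 1)[1]))
    try:
        return STATISTICS[statistic]
    except KeyError:
        raise ValueError(
            f"unknown statistic {statistic!r}; choose from "
            f"{sorted(STATISTICS)} or 'prop_above:<t>'"
        ) from None


@dataclass
class PermutationResult:
    observed: float
    p_one_sided: float
    p_two_sided: float
    n_perm: int
    floor: float
    seed: int
    sided: str
    saturated: bool
    statistic: str
    null: np.ndarray = field(repr=False)

    @property
    def p_display(self) -> str:
        """Display form: '< floor' when no resample was as extreme."""
        p = self.p_two_sided if self.sided == "two-sided" else self.p_one_sided
        if self.saturated:
            bound = self.floor if self.sided != "two-sided" else min(1.0, 2 * self.floor)
            return f"< {bound:g}"
        return f"{p:g}"

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "p_one_sided": self.p_one_sided,
            "p_two_sided": self.p_two_sided,
            "n_perm": self.n_perm,
            "floor": self.floor,
            "seed": self.seed,
            "sided": self.sided,
            "saturated": self.saturated,
            "statistic": self.statistic,
            "p_display": self.p_display,
        }


def permutation_test(
    values: Sequence[float],
    labels: Sequence,
    focal_label,
    statistic: str | Callable = "mean",
    n_perm: int = 1000,
    seed: int = 0,
    sided: str = "greater",
) -> PermutationResult:
    """Contrast-set permutation test of the focal group against the pool.

    Parameters
    ----------
    values, labels
        Per-gene statistic values and their group labels (equal length).
    focal_label
        Label identifying the focal group; all other genes form the pool.
    statistic
        Named aggregator ('mean', 'median', 'geometric_mean',
        'prop_above:<t>') or a callable.
    sided
        'greater', 'less', or 'two-sided'.  Two-sided doubles the more
        extreme one-sided p (symmetry assumption), capped at 1.
    """
    if sided not in ("greater", "less", "two-sided"):
        raise ValueError(f"sided must be greater/less/two-sided, got {sided!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    focal_mask = labels == focal_label
    focal = values[focal_mask]
    pool = values[~focal_mask]
    if focal.size == 0:
        raise ValueError(f"focal group {focal_label!r} is empty")
    if pool.size < focal.size:
        raise ValueError(
            f"contrast pool (n={pool.size}) smaller than focal group (n={focal.size})"
        )
    stat = resolve_statistic(statistic)
    observed = stat(focal)

    rng = np.random.default_rng(seed)
    k = focal.size
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = stat(rng.choice(pool, size=k, replace=False))

    n_ge = int(np.sum(null >= observed))
    n_le = int(np.sum(null <= observed))
    # add-one estimator: never exactly zero
    p_upper = (1 + n_ge) / (1 + n_perm)
    p_lower = (1 + n_le) / (1 + n_perm)
    if sided == "greater":
        p_one = p_upper
        saturated = n_ge == 0
    elif sided == "less":
        p_one = p_lower
        saturated = n_le == 0
    else:
        p_one = min(p_upper, p_lower)
        saturated = min(n_ge, n_le) == 0
    p_two = min(1.0, 2.0 * min(p_upper, p_lower))
    return PermutationResult(
        observed=observed,
        p_one_sided=p_one,
        p_two_sided=p_two,
        n_perm=n_perm,
        floor=1.0 / n_perm,
        seed=seed,
        sided=sided,
        saturated=saturated,
        statistic=getattr(stat, "__name__", str(statistic)),
        null=null,
    )


def proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sample test of proportions (z/chi-square, no continuity
    correction).  Identical proportions give p = 1 exactly."""
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0 <= k <= n:
            raise ValueError(f"count {k} outside [0, {n}]")
    if k1 * n2 == k2 * n1:  # equal proportions; avoids 0/0 at the boundary
        return 1.0
    _, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return float(p)


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """min(1, m * p) per test; m defaults to the number of tests."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m={m} smaller than number of tests ({p.size})")
    return np.minimum(1.0, m * p)
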