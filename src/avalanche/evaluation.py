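"""Cluster and dissimilarity evaluation statistics.

Mantel correlation between dissimilarity matrices (Spearman, permutation p),
cophenetic correlation of a hierarchy against its source dissimilarities,
adjusted Rand agreement between partitions, distance-based within-cluster
sum of squares, within/between distance summaries and the Kruskal–Wallis
test of elevation differences among clusters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "mantel_test",
    "cophenetic_correlation",
    "adjusted_rand",
    "wss",
    "cluster_distance_stats",
    "kruskal_wallis",
    "EvaluationReport",
]


def _tril(values: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(len(values), k=-1)
    return values[i, j]


def mantel_test(
    d1, d2, n_perm: int = 9999, seed: int = 0, method: str = "spearman"
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    The statistic is the Spearman (default) or Pearson correlation of the
    strictly-lower-triangle entries; the null distribution permutes the
    rows/columns of the second matrix simultaneously. The p-value uses the
    add-one estimator (1 + #{perm >= obs}) / (1 + n_perm), one-sided for
    positive association.
    """
    x = np.asarray(d1, dtype=float)
    y = np.asarray(d2, dtype=float)
    if x.shape != y.shape or x.shape[0] != x.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    xt, yt = _tril(x), _tril(y)
    if np.ptp(xt) == 0 or np.ptp(yt) == 0:
        raise ValueError("Mantel statistic undefined for constant matrices")
    if method == "spearman":
        xt = stats.rankdata(xt)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    n = len(x)
    il, jl = np.tril_indices(n, k=-1)
    rng = np.random.default_rng(seed)

    def corr(yv: np.ndarray) -> np.ndarray:
        yr = stats.rankdata(yv, axis=-1) if method == "spearman" else yv
        xa = (xt - xt.mean()) / xt.std()
        ya = (yr - yr.mean(axis=-1, keepdims=True)) / yr.std(axis=-1, keepdims=True)
        return (xa * ya).mean(axis=-1)

    obs = float(corr(yt[None, :])[0])
    count = 0
    chunk = 200
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.stack([rng.permutation(n) for _ in range(m)])
        ys = y[perms[:, il], perms[:, jl]]  # m x n_pairs
        count += int((corr(ys) >= obs - 1e-12).sum())
        done += m
    p = (1 + count) / (1 + n_perm)
    return obs, float(p)


def _common_depth_matrix(hierarchy) -> np.ndarray:
    """Pairwise depth of the deepest common hierarchy node."""
    n = hierarchy.n_samples
    depth = np.zeros((n, n), dtype=int)
    for lv in range(1, hierarchy.max_levels + 1):
        labels = hierarchy.cut(lv)
        same = labels[:, None] == labels[None, :]
        depth += same.astype(int)
    return depth


def cophenetic_correlation(hierarchy, d) -> float:
    """Pearson correlation of dissimilarities with dendrogram distances.

    The dendrogram distance between two samples is
    max_levels + 1 - depth(deepest common node), the natural height scale
    of a fixed-depth divisive hierarchy.
    """
    values = np.asarray(d, dtype=float)
    if hierarchy.n_samples != len(values):
        raise ValueError("hierarchy does not cover the dissimilarity matrix")
    if hierarchy.n_clusters_at(hierarchy.max_levels) < 2:
        raise ValueError("cophenetic correlation undefined for a single cluster")
    depth = _common_depth_matrix(hierarchy)
    dendro = hierarchy.max_levels + 1 - depth
    r, _ = stats.pearsonr(_tril(values), _tril(dendro.astype(float)))
    return float(r)


def adjusted_rand(p1, p2) -> float:
    """Hubert–Arabie chance-adjusted Rand index between two partitions."""
    a = np.asarray(p1)
    b = np.asarray(p2)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same samples")
    return float(adjusted_rand_score(a.astype(str), b.astype(str)))


def wss(d, assignment) -> float:
    """Distance-based within-cluster sum of squares.

    Sum over clusters of (sum of squared within-cluster dissimilarities of
    unordered pairs) / cluster size; coincides with the sum of squared
    distances to centroids when the dissimilarities are Euclidean.
    """
    values = np.asarray(d, dtype=float)
    labels = np.asarray(assignment)
    total = 0.0
    for cid in np.unique(labels):
        idx = np.flatnonzero(labels == cid)
        if len(idx) < 2:
            continue
        sub = values[np.ix_(idx, idx)]
        total += (sub**2).sum() / 2.0 / len(idx)
    return float(total)


@dataclass
class DistanceStats:
    per_cluster_within: dict
    mean_within: float
    mean_between: float


def cluster_distance_stats(d, assignment) -> DistanceStats:
    """Mean dissimilarity within each cluster, pooled within, and between.

    Within means pool over unordered within-cluster pairs; singleton
    clusters report NaN. With a single cluster the between mean is NaN.
    """
    values = np.asarray(d, dtype=float)
    labels = np.asarray(assignment)
    ids = np.unique(labels)
    per_cluster = {}
    within_vals = []
    for cid in ids:
        idx = np.flatnonzero(labels == cid)
        if len(idx) < 2:
            per_cluster[cid] = float("nan")
            continue
        sub = values[np.ix_(idx, idx)]
        pairs = _tril(sub)
        per_cluster[cid] = float(pairs.mean())
        within_vals.append(pairs)
    same = labels[:, None] == labels[None, :]
    il, jl = np.tril_indices(len(values), k=-1)
    between = values[il, jl][~same[il, jl]]
    return DistanceStats(
        per_cluster_within=per_cluster,
        mean_within=float(np.concatenate(within_vals).mean()) if within_vals else float("nan"),
        mean_between=float(between.mean()) if between.size else float("nan"),
    )


def kruskal_wallis(values, assignment) -> tuple[float, int, float]:
    """Tie-corrected Kruskal–Wallis H with chi-square p.

    Returns (H, df, p); identical values across all groups give H = 0,
    p = 1 rather than an error.
    """
    v = np.asarray(values, dtype=float)
    labels = np.asarray(assignment)
    groups = [v[labels == cid] for cid in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    df = len(groups) - 1
    if np.ptp(v) == 0:
        return 0.0, df, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), df, float(p)


@dataclass
class EvaluationReport:
    """Bundle of the evaluation metrics for a pair of hierarchies."""

    mantel_rho: float
    mantel_p: float
    mantel_n_perm: int
    cophenetic: dict
    adjusted_rand_between: float
    wss: dict
    mean_within: dict
    mean_between: dict
    n_clusters: dict
    kruskal_wallis: dict

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent, default=str)
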