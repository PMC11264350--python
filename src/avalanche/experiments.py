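"""Reproducible study-scale experiments on synthetic inventories.

These functions bundle the full pipeline at the generator's study
conditions: elevation-zoned, phylogenetically clustered assemblages sampled
as ~hundreds of three-subplot cluster plots. They back the package's
headline checks — parameter recovery of the true assemblages by the
Discriminating Avalanche hierarchy, the directional comparison of dA- vs
Bray–Curtis-based clusterings, and null calibration of the permutation and
rank tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from .dissimilarity import pairwise_matrix
from .evaluation import (
    adjusted_rand,
    cluster_distance_stats,
    cophenetic_correlation,
    kruskal_wallis,
    mantel_test,
    wss,
)
from .inventory import build_community_matrix, filter_clusters
from .isopam import IsopamClustering
from .phylo import species_distance_matrix
from .synthetic import SyntheticConfig, generate_dataset

__all__ = [
    "generate_study",
    "true_level",
    "recovery_experiment",
    "comparison_experiment",
    "mantel_null_calibration",
    "kruskal_null_calibration",
    "study_summary",
]

#: reduced search grid for multi-seed sweeps (full defaults elsewhere)
SWEEP_GRID = dict(
    candidate_k_neighbors=(5, 9, 13, 17),
    candidate_axes=(2, 3, 4),
    candidate_children=(2, 3, 4),
)


def generate_study(seed: int, n_clusters: int = 200, **cfg_kw):
    """Synthetic study bundle: community, species distances, truth, elevation."""
    cfg = SyntheticConfig(n_clusters=n_clusters, seed=seed, **cfg_kw)
    tree, _, stems, truth, _ = generate_dataset(cfg)
    retained, _ = filter_clusters(stems)
    community = build_community_matrix(retained)
    sdist = species_distance_matrix(tree, list(community.columns))
    truth_labels = truth.loc[community.index, "true_assemblage"].to_numpy()
    elevation = truth.loc[community.index, "elevation_m"].to_numpy()
    return cfg, community, sdist, truth_labels, elevation


def true_level(hierarchy, n_assemblages: int) -> int:
    """Hierarchy level whose cluster count best matches the generating truth."""
    return min(
        range(1, hierarchy.max_levels + 1),
        key=lambda lv: (abs(hierarchy.n_clusters_at(lv) - n_assemblages), lv),
    )


def recovery_experiment(seed: int = 11, n_clusters: int = 200) -> dict:
    """Can the dA hierarchy recover the generating assemblages?

    Runs the full default pipeline on a synthetic inventory with
    phylogenetically clustered pools on disjoint elevation niches, cuts the
    dA hierarchy at the level matching the true assemblage count, and
    reports the adjusted Rand index against truth plus the Kruskal–Wallis
    elevation contrast across the recovered clusters.
    """
    cfg, community, sdist, truth_labels, elevation = generate_study(seed, n_clusters)
    model = IsopamClustering(
        dissimilarity="avalanche", species_distances=sdist, seed=seed
    ).fit(community)
    level = true_level(model.hierarchy_, cfg.n_assemblages)
    labels = model.hierarchy_.cut(level)
    _, _, kw_p = kruskal_wallis(elevation, labels)
    return {
        "n_samples": len(community),
        "true_level": level,
        "n_clusters_at_true_level": model.hierarchy_.n_clusters_at(level),
        "ari_vs_truth": adjusted_rand(labels, truth_labels),
        "kruskal_wallis_p": kw_p,
    }


def comparison_experiment(seeds, n_clusters: int = 150) -> dict:
    """dA-based vs BC-based clustering across seeds (each on its own matrix).

    For every seed both hierarchies are built on the same community with the
    sweep grid; WSS and mean within-cluster distance are measured on the
    dissimilarity matrix each hierarchy clustered, mirroring how the two
    classifications are compared in practice.
    """
    rows = []
    for seed in seeds:
        _, community, sdist, _, _ = generate_study(seed, n_clusters)
        rec = {"seed": seed}
        for name, kind in (("bc", "bray_curtis"), ("da", "avalanche")):
            model = IsopamClustering(
                dissimilarity=kind, species_distances=sdist, seed=seed, **SWEEP_GRID
            ).fit(community)
            d = model.dissimilarity_matrix_
            rec[f"wss_{name}"] = wss(d, model.labels_)
            rec[f"within_{name}"] = cluster_distance_stats(d, model.labels_).mean_within
            rec[f"n_clusters_{name}"] = model.n_clusters_
        rows.append(rec)
    table = pd.DataFrame(rows)
    return {
        "per_seed": table,
        "da_lower_wss": int((table["wss_da"] < table["wss_bc"]).sum()),
        "da_lower_within": int((table["within_da"] < table["within_bc"]).sum()),
        "n_seeds": len(table),
    }


def mantel_null_calibration(
    n_rep: int = 500, n: int = 20, n_perm: int = 999, alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the Mantel test under independence."""
    rng = np.random.default_rng(seed)
    hits = 0
    for rep in range(n_rep):
        d1 = squareform(pdist(rng.random((n, 3))))
        d2 = squareform(pdist(rng.random((n, 3))))
        _, p = mantel_test(d1, d2, n_perm=n_perm, seed=int(rng.integers(2**31)))
        hits += p <= alpha
    return hits / n_rep


def kruskal_null_calibration(
    n_rep: int = 500, n: int = 30, k: int = 3, alpha: float = 0.05, seed: int = 0
) -> float:
    """Empirical type-I error of Kruskal–Wallis with identical groups."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_rep):
        values = rng.normal(size=n)
        labels = np.repeat(np.arange(k), n // k)[:n]
        _, _, p = kruskal_wallis(values, labels)
        hits += p <= alpha
    return hits / n_rep


def study_summary(seed: int, n_clusters: int = 200, mantel_perm: int = 999) -> dict:
    """Full BC-vs-dA comparison on one synthetic study, default parameters."""
    cfg, community, sdist, truth_labels, elevation = generate_study(seed, n_clusters)
    d_bc = pairwise_matrix(community, "bc")
    d_da = pairwise_matrix(community, "da", species_distances=sdist)
    rho, mantel_p = mantel_test(d_bc, d_da, n_perm=mantel_perm, seed=seed)
    out = {
        "n_samples": len(community),
        "n_species": community.shape[1],
        "mantel_rho": rho,
        "mantel_p": mantel_p,
    }
    models = {}
    for name, dmat in (("bc", d_bc), ("da", d_da)):
        tri = dmat.to_numpy()[np.triu_indices(len(dmat), k=1)]
        out[f"{name}_mean"] = float(tri.mean())
        out[f"{name}_min"] = float(tri.min())
        out[f"{name}_max"] = float(tri.max())
        model = IsopamClustering(dissimilarity="precomputed", seed=seed).fit(
            dmat, community=community
        )
        models[name] = model
        stats = cluster_distance_stats(dmat, model.labels_)
        out[f"n_clusters_{name}"] = model.n_clusters_
        out[f"wss_{name}"] = wss(dmat, model.labels_)
        out[f"mean_within_{name}"] = stats.mean_within
        out[f"mean_between_{name}"] = stats.mean_between
        out[f"cophenetic_{name}"] = cophenetic_correlation(model.hierarchy_, dmat)
        _, _, kw_p = kruskal_wallis(elevation, model.labels_)
        out[f"kruskal_wallis_p_{name}"] = kw_p
        level = true_level(model.hierarchy_, cfg.n_assemblages)
        out[f"ari_vs_truth_{name}"] = adjusted_rand(
            model.hierarchy_.cut(level), truth_labels
        )
    out["ari_between"] = adjusted_rand(models["bc"].labels_, models["da"].labels_)
    return out
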