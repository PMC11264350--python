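"""End-to-end orchestration: data -> community -> dissimilarities -> clusters.

A single :class:`RunConfig` (loadable from YAML) drives the whole analysis:
synthetic generation or file ingestion, inventory filtering, the community
matrix, normalized interspecies distances, both dissimilarity matrices
(Bray–Curtis and Discriminating Avalanche), one isopam hierarchy per index,
indicator tables, and the evaluation report. Reruns with the same config and
seed are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dissimilarity import DissimilarityOptions, pairwise_matrix
from .evaluation import (
    EvaluationReport,
    adjusted_rand,
    cluster_distance_stats,
    cophenetic_correlation,
    kruskal_wallis,
    mantel_test,
    wss,
)
from .indicators import isotab
from .inventory import (
    FilterConfig,
    build_community_matrix,
    filter_clusters,
    read_stem_table,
    sample_elevation,
)
from .isopam import IsopamClustering, IsopamParams
from .phylo import consolidate_infraspecific, read_newick, species_distance_matrix
from .rasters import read_ascii_grid
from .synthetic import SyntheticConfig, write_dataset

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "InputPaths", "run_pipeline", "validate_inputs"]


@dataclass
class InputPaths:
    stems: str
    tree: str
    raster: str | None = None
    truth: str | None = None


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    output_dir: str = "avalanche_run"
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    inputs: InputPaths | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    dissimilarity: DissimilarityOptions = field(default_factory=DissimilarityOptions)
    isopam: IsopamParams = field(default_factory=IsopamParams)
    mantel_permutations: int = 999
    isotab_level: int = 2

    def __post_init__(self):
        if self.synthetic is None and self.inputs is None:
            raise ValueError("config needs either synthetic settings or input paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "synthetic" in kwargs and kwargs["synthetic"] is not None:
            kwargs["synthetic"] = SyntheticConfig(**kwargs["synthetic"])
        if "inputs" in kwargs and kwargs["inputs"] is not None:
            kwargs["inputs"] = InputPaths(**kwargs["inputs"])
        if "filter" in kwargs:
            fc = dict(kwargs["filter"])
            if "allowed_landuse" in fc:
                fc["allowed_landuse"] = frozenset(fc["allowed_landuse"])
            kwargs["filter"] = FilterConfig(**fc)
        if "dissimilarity" in kwargs:
            kwargs["dissimilarity"] = DissimilarityOptions(**kwargs["dissimilarity"])
        if "isopam" in kwargs:
            ip = dict(kwargs["isopam"])
            for key in ("candidate_k_neighbors", "candidate_axes", "candidate_children"):
                if key in ip and ip[key] is not None:
                    ip[key] = tuple(ip[key])
            kwargs["isopam"] = IsopamParams(**ip)
        return cls(**kwargs)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _southwest_subplot_rows(stems: pd.DataFrame) -> pd.DataFrame:
    """One row per cluster: coordinates of the southwestern subplot."""
    first = (
        stems.sort_values(["y", "x", "subplot_id"], kind="mergesort")
        .groupby("cluster_id", sort=True)
        .first()
    )
    return first[["x", "y", "gps_error_m"]]


def validate_inputs(cfg: RunConfig) -> dict:
    """Schema/consistency check; returns {'fatal': [...], 'warnings': [...]}."""
    fatal: list[str] = []
    warnings: list[str] = []
    if cfg.synthetic is not None:
        return {"fatal": fatal, "warnings": warnings}
    try:
        stems = read_stem_table(cfg.inputs.stems)
    except Exception as exc:
        return {"fatal": [f"stems: {exc}"], "warnings": warnings}
    if (stems["dbh_cm"] < 8).any():
        fatal.append("stems: DBH below the 8 cm census threshold")
    if not set(stems["subplot_id"]).issubset({1, 2, 3}):
        fatal.append("stems: subplot_id outside {1,2,3}")
    try:
        tree = read_newick(Path(cfg.inputs.tree).read_text())
        tips = {leaf.taxon.label.replace("_", " ") for leaf in tree.leaf_node_iter()}
        mapping = consolidate_infraspecific(sorted(stems["species"].unique()))
        unmatched = sorted(
            {p for p in mapping.values() if p not in tips and "spp." not in p}
        )
        if unmatched:
            warnings.append(f"species absent from tree: {unmatched}")
    except Exception as exc:
        fatal.append(f"tree: {exc}")
    if cfg.inputs.raster:
        try:
            read_ascii_grid(cfg.inputs.raster)
        except Exception as exc:
            fatal.append(f"raster: {exc}")
    return {"fatal": fatal, "warnings": warnings}


def _consolidate_columns(community: pd.DataFrame) -> pd.DataFrame:
    """Merge infraspecific columns onto their parental binomials (summing)."""
    mapping = consolidate_infraspecific(list(community.columns))
    out = community.T.groupby(community.columns.map(mapping)).sum().T
    out.columns.name = None
    return out


def run_pipeline(cfg: RunConfig) -> EvaluationReport:
    """Run the full comparison and write all artifacts to ``cfg.output_dir``."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    if cfg.synthetic is not None:
        paths = write_dataset(cfg.synthetic, out / "inputs")
        stems_path, tree_path = paths["stems"], paths["tree"]
        raster_path, truth_path = paths["raster"], paths["truth"]
    else:
        stems_path, tree_path = cfg.inputs.stems, cfg.inputs.tree
        raster_path, truth_path = cfg.inputs.raster, cfg.inputs.truth
    stems = read_stem_table(stems_path)
    tree = read_newick(Path(tree_path).read_text())

    # --- ingest -----------------------------------------------------------
    retained, rejections = filter_clusters(stems, cfg.filter)
    n_all = stems["cluster_id"].nunique()
    n_keep = retained["cluster_id"].nunique()
    log.info("filter: retained %d/%d clusters (%.0f%%)", n_keep, n_all, 100 * n_keep / n_all)
    rejections.to_csv(out / "rejections.tsv", sep="\t", index=False)
    community = _consolidate_columns(build_community_matrix(retained))
    community.to_csv(out / "community.csv")

    # --- phylogeny --------------------------------------------------------
    sdist = species_distance_matrix(tree, list(community.columns))
    sdist.to_csv(out / "species_distances.csv")

    # --- dissimilarities --------------------------------------------------
    d_bc = pairwise_matrix(community, "bc", options=cfg.dissimilarity)
    d_da = pairwise_matrix(community, "da", species_distances=sdist, options=cfg.dissimilarity)
    d_bc.to_csv(out / "dissimilarity_bc.csv")
    d_da.to_csv(out / "dissimilarity_da.csv")
    rho, p_mantel = mantel_test(
        d_bc, d_da, n_perm=cfg.mantel_permutations, seed=cfg.seed
    )

    # --- clustering -------------------------------------------------------
    hierarchies = {}
    for name, dmat in (("bc", d_bc), ("da", d_da)):
        model = IsopamClustering(
            dissimilarity="precomputed",
            max_levels=cfg.isopam.max_levels,
            candidate_k_neighbors=cfg.isopam.candidate_k_neighbors,
            candidate_axes=cfg.isopam.candidate_axes,
            candidate_children=cfg.isopam.candidate_children,
            min_cluster_size=cfg.isopam.min_cluster_size,
            alpha_indicator=cfg.isopam.alpha_indicator,
            seed=cfg.seed,
        ).fit(dmat, community=community)
        hierarchies[name] = model
        hier = model.hierarchy_
        hier.level_table().to_csv(out / f"hierarchy_{name}.tsv", sep="\t", index=False)
        (out / f"hierarchy_{name}.json").write_text(json.dumps(hier.to_dict(), indent=2))
        (out / f"dendrogram_{name}.nwk").write_text(hier.to_newick())
        level = min(cfg.isotab_level, cfg.isopam.max_levels)
        table = isotab(hier, level, community)
        table.long.to_csv(out / f"isotab_{name}_level{level}.csv", index=False)
        table.synoptic.to_csv(out / f"isotab_{name}_level{level}_synoptic.tsv", sep="\t")

    # --- elevations -------------------------------------------------------
    kw = {}
    if raster_path:
        raster = read_ascii_grid(raster_path)
        sw = _southwest_subplot_rows(retained).loc[community.index]
        elevations = pd.Series(
            [
                sample_elevation(raster, (row.x, row.y), 15.0, row.gps_error_m)
                for row in sw.itertuples()
            ],
            index=community.index,
            name="elevation_m",
        )
        elevations.to_csv(out / "elevations.csv")
        for name, model in hierarchies.items():
            h, df, p = kruskal_wallis(elevations.to_numpy(), model.labels_)
            kw[name] = {"H": h, "df": df, "p": p}

    # --- evaluation -------------------------------------------------------
    report = EvaluationReport(
        mantel_rho=rho,
        mantel_p=p_mantel,
        mantel_n_perm=cfg.mantel_permutations,
        cophenetic={
            name: cophenetic_correlation(m.hierarchy_, m.dissimilarity_matrix_)
            for name, m in hierarchies.items()
        },
        adjusted_rand_between=adjusted_rand(
            hierarchies["bc"].labels_, hierarchies["da"].labels_
        ),
        wss={
            name: wss(m.dissimilarity_matrix_, m.labels_)
            for name, m in hierarchies.items()
        },
        mean_within={
            name: cluster_distance_stats(m.dissimilarity_matrix_, m.labels_).mean_within
            for name, m in hierarchies.items()
        },
        mean_between={
            name: cluster_distance_stats(m.dissimilarity_matrix_, m.labels_).mean_between
            for name, m in hierarchies.items()
        },
        n_clusters={name: m.n_clusters_ for name, m in hierarchies.items()},
        kruskal_wallis=kw,
    )
    (out / "evaluation.json").write_text(report.to_json())
    provenance = {
        "package_version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "n_clusters_input": int(n_all),
        "n_clusters_retained": int(n_keep),
        "n_species": int(community.shape[1]),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    if truth_path:
        truth = pd.read_csv(truth_path, index_col=0)
        shared = community.index.intersection(truth.index)
        tr = truth.loc[shared, "true_assemblage"].to_numpy()
        ari = {
            name: adjusted_rand(
                pd.Series(m.labels_, index=community.index).loc[shared].to_numpy(), tr
            )
            for name, m in hierarchies.items()
        }
        (out / "truth_recovery.json").write_text(json.dumps(ari, indent=2))
    return report
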