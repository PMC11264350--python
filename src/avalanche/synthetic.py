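"""Synthetic forest-inventory data with known assemblage structure.

Emulates the statistical shape of a national forest inventory: ~1000 cluster
plots of three subplots censused on nested concentric circles, ~90 woody
species on an ultrametric phylogeny, per-plot species richness around 5 +/- 2
and mean basal area around 30 m^2/ha, with assemblages arranged along an
elevation gradient and species pools that are phylogenetically clustered
(each assemblage draws from a focal clade).

Everything is driven by one seeded random stream, so runs are
bit-reproducible, and a truth table records each plot's generating
assemblage for parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .inventory import MIN_DBH_CM, expansion_factor, stem_basal_area
from .rasters import AsciiGrid, write_ascii_grid

__all__ = [
    "SyntheticConfig",
    "AssemblagePools",
    "generate_phylogeny",
    "generate_assemblage_pools",
    "generate_inventory",
    "generate_dataset",
]


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults mirror the inventory the pipeline targets: ~90 species, 1000
    cluster plots, four elevation-zoned assemblages, richness ~ N(5, 2.1)
    clipped to [1, 12] and per-plot basal area ~ N(30, 0.42*30) m^2/ha
    (coefficient of variation ~42%). ``phylo_signal`` is the probability
    that a pool member comes from the assemblage's focal clade rather than
    uniformly from the whole species list. Noise fractions inject dead
    stems, slopover subplots and genus-only labels to exercise the filters.
    """

    n_species: int = 90
    n_clusters: int = 1000
    n_assemblages: int = 4
    elevation_range: tuple[float, float] = (100.0, 2600.0)
    niche_width: float = 150.0
    richness_mean: float = 5.0
    richness_sd: float = 2.1
    richness_max: int = 12
    ba_mean: float = 30.0
    ba_cv: float = 0.42
    dbh_lognormal_params: tuple[float, float] = (3.0, 0.45)
    phylo_signal: float = 1.0
    dead_fraction: float = 0.05
    slopover_fraction: float = 0.05
    genus_label_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_assemblages < 2:
            raise ValueError("need at least 2 assemblages")
        if self.n_species < self.n_assemblages:
            raise ValueError("need at least as many species as assemblages")
        if self.niche_width <= 0:
            raise ValueError("niche_width must be positive")
        if not 0.0 <= self.phylo_signal <= 1.0:
            raise ValueError("phylo_signal must lie in [0, 1]")


def generate_phylogeny(n_species: int, seed: int) -> dendropy.Tree:
    """Random ultrametric binary tree via a coalescent-style merge process.

    Tips are labelled with synthetic binomials; all tips are equidistant
    from the root by construction.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species for a phylogeny")
    rng = np.random.default_rng([seed, 101])
    labels = [f"Genus{i // 5:02d} species{i:03d}" for i in range(n_species)]
    # active lineages: (newick fragment, height of its root); labels are
    # quoted because they contain spaces
    active: list[tuple[str, float]] = [(f"'{lbl}'", 0.0) for lbl in labels]
    height = 0.0
    while len(active) > 1:
        k = len(active)
        height += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (si, hi), (sj, hj) = active[i], active[j]
        merged = f"({si}:{height - hi:.10f},{sj}:{height - hj:.10f})"
        active = [a for idx, a in enumerate(active) if idx not in (i, j)]
        active.append((merged, height))
    newick = active[0][0] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def _partition_into_clades(tree: dendropy.Tree, n_parts: int) -> list[list[str]]:
    """Split the tree into n_parts disjoint clades covering all tips.

    Repeatedly replaces the largest current clade by its two children, so
    each part's tips form a connected clade by construction.
    """
    order = {id(n): i for i, n in enumerate(tree.preorder_node_iter())}
    parts = [tree.seed_node]
    while len(parts) < n_parts:
        splittable = [p for p in parts if p.child_nodes()]
        node = max(splittable, key=lambda p: (len(p.leaf_nodes()), -order[id(p)]))
        parts.remove(node)
        parts.extend(node.child_nodes())
    return [[leaf.taxon.label for leaf in p.leaf_nodes()] for p in parts]


@dataclass
class AssemblagePools:
    """Per-assemblage species weights and elevation niche centers."""

    weights: pd.DataFrame  # species x assemblage, columns sum to 1
    niche_centers: np.ndarray  # metres, one per assemblage
    species: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.species = list(self.weights.index)


def generate_assemblage_pools(
    tree: dendropy.Tree, cfg: SyntheticConfig
) -> AssemblagePools:
    """Build phylogenetically clustered species pools on an elevation gradient.

    Each assemblage owns a focal clade; pool members are the clade's tips
    with probability ``phylo_signal`` and uniform draws otherwise. Weights
    are Dirichlet within each pool (summing to 1) and niche centers are
    evenly spaced across the elevation range.
    """
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(tips) < cfg.n_species:
        raise ValueError("tree has fewer tips than cfg.n_species")
    rng = np.random.default_rng([cfg.seed, 202])
    clades = _partition_into_clades(tree, cfg.n_assemblages)
    lo, hi = cfg.elevation_range
    centers = lo + (np.arange(cfg.n_assemblages) + 0.5) * (hi - lo) / cfg.n_assemblages
    weights = pd.DataFrame(0.0, index=tips, columns=range(cfg.n_assemblages))
    for a in range(cfg.n_assemblages):
        clade = clades[a]
        members: set[str] = set()
        for _ in range(len(clade)):
            if rng.random() < cfg.phylo_signal:
                pool_src = [t for t in clade if t not in members]
            else:
                pool_src = [t for t in tips if t not in members]
            if not pool_src:
                continue
            members.add(pool_src[rng.integers(len(pool_src))])
        member_list = sorted(members)
        w = rng.dirichlet(np.ones(len(member_list)))
        weights.loc[member_list, a] = w
    return AssemblagePools(weights=weights, niche_centers=centers)


def _elevation_raster(cfg: SyntheticConfig) -> AsciiGrid:
    """West-east elevation ramp spanning the configured range."""
    ncols, nrows, cellsize = 400, 60, 30.0
    lo, hi = cfg.elevation_range
    xs = (np.arange(ncols) + 0.5) * cellsize
    ramp = lo + xs / (ncols * cellsize) * (hi - lo)
    values = np.tile(ramp, (nrows, 1))
    return AsciiGrid(values=values, xllcorner=0.0, yllcorner=0.0, cellsize=cellsize)


def _draw_dbh(rng: np.random.Generator, mu: float, sigma: float) -> float:
    """Lognormal DBH truncated at the census threshold (rejection sampling)."""
    while True:
        dbh = rng.lognormal(mu, sigma)
        if dbh >= MIN_DBH_CM:
            return dbh


def generate_inventory(
    pools: AssemblagePools, cfg: SyntheticConfig
) -> tuple[pd.DataFrame, pd.DataFrame, AsciiGrid]:
    """Generate stem records, the truth table and the elevation raster.

    Each cluster plot draws an elevation uniformly, belongs to the
    assemblage whose Gaussian niche is densest there, and receives species
    from that assemblage's pool. Stems accumulate per species until the
    plot's basal-area target is met; each stem lands on the concentric
    circle its DBH qualifies for. Dead stems, slopover subplots and
    genus-only labels are injected at the configured fractions.
    """
    rng = np.random.default_rng([cfg.seed, 303])
    raster = _elevation_raster(cfg)
    lo, hi = cfg.elevation_range
    width = raster.ncols * raster.cellsize
    mu, sigma = cfg.dbh_lognormal_params
    w = pools.weights.to_numpy()
    species = np.array(pools.species)
    rows: list[tuple] = []
    truth: list[tuple] = []
    for c in range(cfg.n_clusters):
        cluster_id = f"C{c:04d}"
        elev = rng.uniform(lo, hi)
        dens = np.exp(
            -0.5 * ((elev - pools.niche_centers) / cfg.niche_width) ** 2
        ) / cfg.niche_width
        assemblage = int(np.argmax(dens))
        truth.append((cluster_id, assemblage, elev))
        # position consistent with the raster's west-east elevation ramp
        x = (elev - lo) / (hi - lo) * (width - 60.0) + 30.0
        y = rng.uniform(150.0, raster.nrows * raster.cellsize - 150.0)
        pw = w[:, assemblage]
        available = int((pw > 0).sum())
        r = int(np.clip(round(rng.normal(cfg.richness_mean, cfg.richness_sd)),
                        1, min(cfg.richness_max, available)))
        chosen = rng.choice(len(species), size=r, replace=False, p=pw)
        ba_target = max(2.5, rng.normal(cfg.ba_mean, cfg.ba_cv * cfg.ba_mean))
        shares = rng.dirichlet(np.ones(r)) * ba_target
        slopover_subplot = (
            int(rng.integers(1, 4)) if rng.random() < cfg.slopover_fraction else 0
        )
        n_stem = 0
        for sp_idx, target in zip(chosen, shares):
            acc = 0.0
            while acc < target:
                dbh = _draw_dbh(rng, mu, sigma)
                acc += stem_basal_area(dbh) * expansion_factor(dbh) / 3.0
                subplot = n_stem % 3 + 1 if n_stem < 3 else int(rng.integers(1, 4))
                n_stem += 1
                status = "living"
                rows.append(
                    (cluster_id, subplot, species[sp_idx], round(dbh, 1), status,
                     "Forest", subplot == slopover_subplot, round(x, 1),
                     round(y, 1), 5.0)
                )
        n_dead = rng.binomial(n_stem, cfg.dead_fraction)
        for _ in range(n_dead):
            dbh = _draw_dbh(rng, mu, sigma)
            sp_idx = rng.choice(chosen)
            subplot = int(rng.integers(1, 4))
            rows.append(
                (cluster_id, subplot, species[sp_idx], round(dbh, 1), "dead",
                 "Forest", subplot == slopover_subplot, round(x, 1),
                 round(y, 1), 5.0)
            )
        if rng.random() < cfg.genus_label_fraction:
            # relabel one stem to a genus-only taxon, tripping the filter
            idx = len(rows) - 1 - int(rng.integers(n_stem + n_dead))
            rows[idx] = rows[idx][:2] + ("Deciduous spp.",) + rows[idx][3:]
    stems = pd.DataFrame(
        rows,
        columns=["cluster_id", "subplot_id", "species", "dbh_cm", "status",
                 "landuse_class", "slopover_flag", "x", "y", "gps_error_m"],
    )
    truth_df = pd.DataFrame(
        truth, columns=["cluster_id", "true_assemblage", "elevation_m"]
    ).set_index("cluster_id")
    return stems, truth_df, raster


def generate_dataset(cfg: SyntheticConfig):
    """Full bundle: (tree, pools, stems, truth, raster)."""
    tree = generate_phylogeny(cfg.n_species, cfg.seed)
    pools = generate_assemblage_pools(tree, cfg)
    stems, truth, raster = generate_inventory(pools, cfg)
    return tree, pools, stems, truth, raster


def write_dataset(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle to disk (CSV stems/truth, Newick tree, ASCII raster)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree, pools, stems, truth, raster = generate_dataset(cfg)
    paths = {
        "stems": outdir / "stems.csv",
        "tree": outdir / "phylogeny.nwk",
        "raster": outdir / "elevation.asc",
        "truth": outdir / "truth.csv",
    }
    stems.to_csv(paths["stems"], index=False)
    paths["tree"].write_text(
        tree.as_string(schema="newick", unquoted_underscores=True)
    )
    write_ascii_grid(raster, paths["raster"])
    truth.to_csv(paths["truth"])
    return paths
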