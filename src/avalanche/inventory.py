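"""National-forest-inventory ingestion: plot filters and the community matrix.

Stems are censused on three concentric circles per subplot — a stem qualifies
for the r = 15 m circle at DBH >= 30 cm, r = 10 m at DBH >= 15 cm and r = 5 m
at DBH >= 8 cm (the census threshold). Per-hectare abundance therefore uses
the standard concentric-area expansion factor 10000 / (pi r^2) matched to the
stem's circle.

Cluster plots enter the analysis only when they carry an allowed land-use
class, no boundary-intersecting ("slopover") subplot, the full complement of
non-empty subplots, and exclusively species-level taxon labels. The community
matrix holds mean basal area (m^2/ha) per species and cluster plot: basal
area of living stems, expanded to per-hectare, summed per cluster and species
and divided by the number of subplots (3).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .rasters import AsciiGrid

__all__ = [
    "STEM_COLUMNS",
    "FilterConfig",
    "read_stem_table",
    "filter_clusters",
    "stem_basal_area",
    "expansion_factor",
    "build_community_matrix",
    "sample_elevation",
]

STEM_COLUMNS = [
    "cluster_id", "subplot_id", "species", "dbh_cm", "status",
    "landuse_class", "slopover_flag", "x", "y", "gps_error_m",
]

#: DBH (cm) thresholds and matching census circle radii (m), largest first
NESTED_CIRCLES = ((30.0, 15.0), (15.0, 10.0), (8.0, 5.0))

MIN_DBH_CM = 8.0


@dataclass
class FilterConfig:
    """Cluster-level inclusion rules.

    ``genus_pattern`` flags taxon labels not resolved to species level:
    anything containing an "spp."-style epithet or consisting of a single
    word. A synonym map (original -> accepted name) is applied before the
    pattern check.
    """

    allowed_landuse: frozenset[str] = frozenset({"Forest"})
    required_subplots: int = 3
    species_level_only: bool = True
    exclude_slopover: bool = True
    exclude_empty_subplots: bool = True
    genus_pattern: str = r"(?:\bspp?\.)|(?:^\S+$)"
    synonyms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.required_subplots < 1:
            raise ValueError("required_subplots must be >= 1")


def read_stem_table(path: str | Path) -> pd.DataFrame:
    stems = pd.read_csv(path)
    missing = [c for c in STEM_COLUMNS if c not in stems.columns]
    if missing:
        raise ValueError(f"stem table missing columns: {missing}")
    return stems


def _is_genus_level(name: str, cfg: FilterConfig) -> bool:
    name = cfg.synonyms.get(name, name)
    return re.search(cfg.genus_pattern, name.strip()) is not None


def filter_clusters(
    stems: pd.DataFrame, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cluster-level inclusion rules.

    Returns the retained stem rows and a rejection log with one row per
    dropped cluster. Rules are evaluated in a fixed order — land use,
    slopover, subplot completeness, species-level labels — and the log
    records the first failing rule, so rejection reasons are deterministic.
    """
    if cfg is None:
        cfg = FilterConfig()
    if stems.empty:
        raise ValueError("empty stem table")
    rejections: list[tuple[str, str]] = []
    keep_ids: list[str] = []
    for cluster_id, grp in stems.groupby("cluster_id", sort=True):
        if not set(grp["landuse_class"]).issubset(cfg.allowed_landuse):
            rejections.append((cluster_id, "landuse"))
            continue
        if cfg.exclude_slopover and grp["slopover_flag"].astype(bool).any():
            rejections.append((cluster_id, "slopover"))
            continue
        nonempty = grp["subplot_id"].nunique()
        if cfg.exclude_empty_subplots and nonempty != cfg.required_subplots:
            rejections.append((cluster_id, "incomplete_subplots"))
            continue
        if cfg.species_level_only and any(
            _is_genus_level(s, cfg) for s in grp["species"].unique()
        ):
            rejections.append((cluster_id, "non_species_taxon"))
            continue
        keep_ids.append(cluster_id)
    retained = stems[stems["cluster_id"].isin(keep_ids)].copy()
    if retained.empty:
        raise ValueError("all clusters rejected: empty sample")
    if cfg.synonyms:
        retained["species"] = retained["species"].map(lambda s: cfg.synonyms.get(s, s))
    log = pd.DataFrame(rejections, columns=["cluster_id", "reason"])
    return retained, log


def stem_basal_area(dbh_cm: float) -> float:
    """Cross-sectional area (m^2) at breast height: pi * (dbh/200)^2."""
    dbh = np.asarray(dbh_cm, dtype=float)
    if np.any(dbh <= 0):
        raise ValueError("DBH must be positive")
    out = math.pi * (dbh / 200.0) ** 2
    return float(out) if np.isscalar(dbh_cm) else out


def expansion_factor(dbh_cm: float) -> float:
    """Stems-per-hectare factor 10000 / (pi r^2) for the stem's census circle."""
    dbh = np.asarray(dbh_cm, dtype=float)
    if np.any(dbh < MIN_DBH_CM):
        raise ValueError(f"DBH below census threshold of {MIN_DBH_CM} cm")
    radius = np.where(dbh >= 30.0, 15.0, np.where(dbh >= 15.0, 10.0, 5.0))
    out = 10000.0 / (math.pi * radius**2)
    return float(out) if np.isscalar(dbh_cm) else out


def build_community_matrix(
    stems: pd.DataFrame, n_subplots: int = 3
) -> pd.DataFrame:
    """Samples x species mean basal area (m^2/ha).

    Per-hectare basal area of every living stem is summed per cluster and
    species and divided by the number of subplots; dead stems never
    contribute. Clusters left without any living stem are dropped.
    """
    living = stems[stems["status"] == "living"]
    if living.empty:
        raise ValueError("no living stems")
    contrib = (
        stem_basal_area(living["dbh_cm"].to_numpy())
        * expansion_factor(living["dbh_cm"].to_numpy())
        / n_subplots
    )
    table = (
        pd.DataFrame(
            {
                "cluster_id": living["cluster_id"].to_numpy(),
                "species": living["species"].to_numpy(),
                "ba": contrib,
            }
        )
        .pivot_table(index="cluster_id", columns="species", values="ba",
                     aggfunc="sum", fill_value=0.0)
        .sort_index()
    )
    table = table.loc[table.sum(axis=1) > 0]
    table.columns.name = None
    table.index.name = "cluster_id"
    return table


def sample_elevation(
    raster: AsciiGrid,
    center: tuple[float, float],
    radius_m: float = 15.0,
    gps_error_m: float = 0.0,
) -> float:
    """Median elevation of all cells touched by the subplot circle.

    The circle (radius + GPS error) is intersected with the grid; every cell
    whose square touches the circle contributes its value, no-data cells are
    excluded, and the median of the remaining values is returned.
    """
    cx, cy = center
    r = radius_m + gps_error_m
    if r <= 0:
        raise ValueError("circle radius must be positive")
    cs = raster.cellsize
    col_lo = max(0, int(math.floor((cx - r - raster.xllcorner) / cs)))
    col_hi = min(raster.ncols - 1, int(math.floor((cx + r - raster.xllcorner) / cs)))
    ytop = raster.yllcorner + raster.nrows * cs
    row_lo = max(0, int(math.floor((ytop - (cy + r)) / cs)))
    row_hi = min(raster.nrows - 1, int(math.floor((ytop - (cy - r)) / cs)))
    if col_lo > col_hi or row_lo > row_hi:
        raise ValueError("subplot circle lies outside the raster")
    values = []
    for row in range(row_lo, row_hi + 1):
        for col in range(col_lo, col_hi + 1):
            xmin, ymin, xmax, ymax = raster.cell_bounds(row, col)
            # distance from circle center to the nearest point of the square
            dx = max(xmin - cx, 0.0, cx - xmax)
            dy = max(ymin - cy, 0.0, cy - ymax)
            if dx * dx + dy * dy <= r * r:
                v = raster.values[row, col]
                if v != raster.nodata:
                    values.append(v)
    if not values:
        raise ValueError("no valid raster cells under the subplot circle")
    return float(np.median(values))
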