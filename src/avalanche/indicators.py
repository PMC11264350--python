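"""Indicator-species statistics: frequencies, Fisher significance, equalized phi.

A species indicates a cluster when its presence is concentrated there beyond
chance. Significance is the one-sided Fisher's exact (hypergeometric
enrichment) test on the 2x2 presence/membership table; fidelity is the phi
association coefficient computed on a "virtually equalized" table in which
every cluster is re-weighted to the same size N/k before collapsing to
in-cluster vs out-of-cluster, so large clusters cannot dominate.

``isotab`` assembles the synoptic table: per-cluster percentage frequencies
with phi and p per cell, plus a filtered headline view (defaults: p <= .001
and total frequency >= 50%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "presence_frequencies",
    "fisher_indicator",
    "equalized_phi",
    "fisher_p_matrix",
    "equalized_phi_matrix",
    "isotab",
    "IndicatorTable",
]


def _presence_bool(presence: pd.DataFrame) -> pd.DataFrame:
    return presence.astype(float) > 0


def _cluster_ids(assignment) -> np.ndarray:
    labels = np.asarray(assignment)
    ids = np.unique(labels)
    return ids


def presence_frequencies(
    presence: pd.DataFrame, assignment
) -> tuple[pd.DataFrame, pd.Series]:
    """Percentage occurrence of each species per cluster and overall.

    Returns (species x clusters frequency table in %, total frequency %).
    """
    pb = _presence_bool(presence)
    labels = np.asarray(assignment)
    if len(labels) != len(pb):
        raise ValueError("assignment length does not match sample count")
    ids = _cluster_ids(labels)
    out = {}
    for cid in ids:
        mask = labels == cid
        if mask.sum() == 0:
            raise ValueError(f"empty cluster {cid!r}")
        out[cid] = 100.0 * pb[mask].mean(axis=0)
    freq = pd.DataFrame(out)
    total = 100.0 * pb.mean(axis=0)
    return freq, total


def fisher_p_matrix(presence: pd.DataFrame, assignment) -> pd.DataFrame:
    """One-sided Fisher enrichment p for every (species, cluster) pair.

    Equals the hypergeometric upper tail P(X >= a) with a = in-cluster
    presences, which is exactly Fisher's exact test with the "greater"
    alternative — evaluated vectorized across the whole table.
    """
    pb = _presence_bool(presence).to_numpy()
    labels = np.asarray(assignment)
    ids = _cluster_ids(labels)
    n_total = pb.shape[0]
    k_present = pb.sum(axis=0)  # per species
    cols = {}
    for cid in ids:
        mask = labels == cid
        n_c = int(mask.sum())
        a = pb[mask].sum(axis=0)
        cols[cid] = hypergeom.sf(a - 1, n_total, k_present, n_c)
    return pd.DataFrame(cols, index=presence.columns).clip(upper=1.0)


def fisher_indicator(presence: pd.DataFrame, assignment, species, cluster) -> float:
    """One-sided Fisher's exact p for a single species/cluster pair."""
    return float(fisher_p_matrix(presence, assignment).loc[species, cluster])


def equalized_phi_matrix(presence: pd.DataFrame, assignment) -> pd.DataFrame:
    """Equalized phi for every (species, cluster) pair.

    Clusters are virtually resized to the common size s = N/k using their
    within-cluster relative frequencies; phi is then the 2x2 association
    coefficient of the collapsed (target vs rest) table. Degenerate margins
    yield phi = 0.
    """
    pb = _presence_bool(presence).to_numpy()
    labels = np.asarray(assignment)
    ids = _cluster_ids(labels)
    k = len(ids)
    if k < 2:
        raise ValueError("equalized phi needs at least 2 clusters")
    n_total = pb.shape[0]
    s = n_total / k
    f = np.stack([pb[labels == cid].mean(axis=0) for cid in ids])  # k x S
    a = f * s  # equalized in-cluster presences, k x S
    tot = a.sum(axis=0)  # equalized total presences per species
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n_total * a - s * tot[None, :]
        den = np.sqrt(s * (n_total - s) * tot * (n_total - tot))[None, :]
        phi = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return pd.DataFrame(phi.T, index=presence.columns, columns=ids)


def equalized_phi(presence: pd.DataFrame, assignment, species, cluster) -> float:
    """Equalized phi for a single species/cluster pair."""
    return float(equalized_phi_matrix(presence, assignment).loc[species, cluster])


@dataclass
class IndicatorTable:
    """Synoptic indicator table for one hierarchy level.

    long : tidy per-(species, cluster) rows with frequency, phi, p.
    synoptic : species x clusters cells formatted "freq% (phi, p)".
    headline : the long table filtered to p <= p_max and total
        frequency >= min_total_freq, sorted by significance then fidelity.
    """

    long: pd.DataFrame
    synoptic: pd.DataFrame
    headline: pd.DataFrame
    p_max: float
    min_total_freq: float


def isotab(
    hierarchy,
    level: int,
    community: pd.DataFrame,
    p_max: float = 0.001,
    min_total_freq: float = 50.0,
) -> IndicatorTable:
    """Build the indicator table at a hierarchy level.

    ``hierarchy`` is anything exposing ``cut(level)`` (a ClusterHierarchy);
    an explicit assignment vector is also accepted.
    """
    if hasattr(hierarchy, "cut"):
        assignment = hierarchy.cut(level)
    else:
        assignment = np.asarray(hierarchy)
    presence = community > 0
    freq, total = presence_frequencies(presence, assignment)
    pmat = fisher_p_matrix(presence, assignment)
    phimat = equalized_phi_matrix(presence, assignment)
    long = (
        freq.stack().rename("frequency_pct").to_frame()
        .join(phimat.stack().rename("phi"))
        .join(pmat.stack().rename("p_value"))
        .reset_index()
        .rename(columns={"level_0": "species", "level_1": "cluster"})
    )
    long["total_frequency_pct"] = long["species"].map(total)
    long = long.sort_values(
        ["p_value", "phi"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
    synoptic = pd.DataFrame(
        {
            cid: [
                f"{freq.loc[s, cid]:.0f}% ({phimat.loc[s, cid]:.2f}, "
                f"{pmat.loc[s, cid]:.3g})"
                for s in freq.index
            ]
            for cid in freq.columns
        },
        index=freq.index,
    )
    headline = long[
        (long["p_value"] <= p_max) & (long["total_frequency_pct"] >= min_total_freq)
    ].reset_index(drop=True)
    return IndicatorTable(
        long=long, synoptic=synoptic, headline=headline,
        p_max=p_max, min_total_freq=min_total_freq,
    )
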