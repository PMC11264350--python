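"""Pairwise sample dissimilarities: Bray–Curtis and Discriminating Avalanche.

Bray–Curtis (BC) is species-neutral:

    BC(a, b) = sum_i |a_i - b_i| / sum_i (a_i + b_i)

The Discriminating Avalanche (dA) weights abundance differences by
interspecies phylogenetic distance. With p_i^a the relative frequency of
species i in sample a and Delta_i = |p_i^a - p_i^b|:

    dA(a, b) = 1/2 * sum_i sum_j Delta_i * d_ij * Delta_j       (d_ii = 0)

Because the attainable maximum of dA under equal interspecies distances is
1 - 1/n (n = number of species), raw dA values are rescaled to [0, 1]; the
default divides by the theoretical bound, an observed min-max mode is also
available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

log = logging.getLogger(__name__)

__all__ = [
    "bray_curtis",
    "discriminating_avalanche",
    "normalize_da",
    "pairwise_matrix",
]


def bray_curtis(a, b) -> float:
    """Bray–Curtis dissimilarity between two abundance vectors.

    1 for disjoint supports, 0 for identical samples; undefined (error)
    when both vectors are all-zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("abundance vectors differ in length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("abundances must be non-negative")
    denom = (a + b).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined: both samples empty")
    return float(np.abs(a - b).sum() / denom)


def _relative(v: np.ndarray) -> np.ndarray:
    s = v.sum()
    if s == 0:
        raise ValueError("cannot form relative frequencies of an empty sample")
    return v / s


def discriminating_avalanche(a, b, d: np.ndarray | pd.DataFrame) -> float:
    """Raw (unnormalized) Discriminating Avalanche dissimilarity.

    Abundances are converted to within-sample relative frequencies before the
    quadratic form is evaluated, so the index is invariant to rescaling
    either sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    dm = np.asarray(d, dtype=float)
    if a.shape != b.shape:
        raise ValueError("abundance vectors differ in length")
    if dm.shape != (a.size, a.size):
        raise ValueError(
            f"species distance matrix {dm.shape} does not match vectors of length {a.size}"
        )
    delta = np.abs(_relative(a) - _relative(b))
    return float(0.5 * delta @ dm @ delta)


def normalize_da(
    raw: pd.DataFrame | np.ndarray,
    n_species: int,
    mode: str = "theoretical",
) -> pd.DataFrame | np.ndarray:
    """Rescale raw dA values to [0, 1].

    mode="theoretical" (default) divides by the bound 1 - 1/n_species; any
    value pushed above 1 (possible for species-poor pairs) is clipped and the
    clipping is logged. mode="observed" applies min-max over the off-diagonal
    entries, which forces the extremes to 0 and 1 exactly.
    """
    values = np.asarray(raw, dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError("raw dA matrix must be square")
    if n_species < 2:
        raise ValueError("need at least 2 species to normalize dA")
    offmask = ~np.eye(len(values), dtype=bool)
    if mode == "theoretical":
        out = values / (1.0 - 1.0 / n_species)
        n_clip = int((out > 1.0).sum())
        if n_clip:
            log.info("normalize_da: clipped %d entries above 1", n_clip // 2)
            out = np.clip(out, 0.0, 1.0)
    elif mode == "observed":
        off = values[offmask]
        lo, hi = off.min(), off.max()
        if hi == lo:
            raise ValueError("observed min-max undefined: constant dissimilarities")
        out = np.clip((values - lo) / (hi - lo), 0.0, 1.0)
        np.fill_diagonal(out, 0.0)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if isinstance(raw, pd.DataFrame):
        return pd.DataFrame(out, index=raw.index, columns=raw.columns)
    return out


def _pairwise_da_raw(x: np.ndarray, d: np.ndarray, chunk: int = 20000) -> np.ndarray:
    """Vectorized all-pairs raw dA on a samples x species abundance array."""
    p = x / x.sum(axis=1, keepdims=True)
    n = len(p)
    iu, ju = np.triu_indices(n, k=1)
    out = np.empty(iu.size)
    for start in range(0, iu.size, chunk):
        sl = slice(start, start + chunk)
        delta = np.abs(p[iu[sl]] - p[ju[sl]])
        out[sl] = 0.5 * np.einsum("ks,ks->k", delta @ d, delta)
    return squareform(out)


@dataclass
class DissimilarityOptions:
    """Configuration of the two indices.

    bc_relative : compute BC on relative frequencies rather than raw mean
        basal area (off by default, matching standard vegan behavior).
    da_normalization : "theoretical" or "observed".
    """

    bc_relative: bool = False
    da_normalization: str = "theoretical"


def pairwise_matrix(
    community: pd.DataFrame,
    index: str,
    species_distances: pd.DataFrame | None = None,
    options: DissimilarityOptions | None = None,
) -> pd.DataFrame:
    """All-pairs dissimilarity matrix for a community table.

    Parameters
    ----------
    community : DataFrame
        Samples x species mean basal area (m^2/ha); every row must have at
        least one positive entry.
    index : {"bc", "da"}
    species_distances : DataFrame, required for "da"
        Normalized cophenetic distances covering every community column.
    """
    if options is None:
        options = DissimilarityOptions()
    x = community.to_numpy(dtype=float)
    if np.any(x.sum(axis=1) == 0):
        raise ValueError("community matrix contains all-zero samples")
    index = index.lower()
    if index == "bc":
        if options.bc_relative:
            x = x / x.sum(axis=1, keepdims=True)
        mat = squareform(pdist(x, metric="braycurtis"))
    elif index == "da":
        if species_distances is None:
            raise ValueError("dA requires a species distance matrix")
        missing = [s for s in community.columns if s not in species_distances.index]
        if missing:
            raise ValueError(f"species missing from distance matrix: {missing}")
        d = species_distances.loc[community.columns, community.columns].to_numpy(float)
        raw = _pairwise_da_raw(x, d)
        mat = normalize_da(raw, n_species=community.shape[1], mode=options.da_normalization)
    else:
        raise ValueError(f"unknown index {index!r}; expected 'bc' or 'da'")
    out = pd.DataFrame(mat, index=community.index, columns=community.index)
    out.attrs["index"] = index.upper() if index == "bc" else "dA"
    out.attrs["da_normalization"] = options.da_normalization if index == "da" else None
    return out
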