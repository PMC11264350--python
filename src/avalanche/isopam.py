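"""Isopam-style divisive clustering: isomap ordination + PAM, indicator-guided.

Each split of a sample set proceeds by (1) building geodesic distances on a
k-nearest-neighbour graph of the dissimilarity matrix, (2) classical scaling
(isomap) of the geodesics into a low-dimensional ordination, (3) partitioning
around medoids on the ordination's Euclidean distances, and (4) scoring the
candidate partition by the number and fidelity of significant indicator
species. The (k, axes, children) grid is searched exhaustively and the
best-scoring partition kept; recursion continues to a maximum depth, giving
a nested hierarchy of classes, branches and terminal assemblages.

The search grid defaults are an explicit operationalization (the published
engine does not pin them down): odd k from 3 to min(30, n-1), 2-10 ordination
axes, 2-6 children per split, minimum cluster size 3, indicator significance
0.05. Everything is deterministic: ties break to the lowest sample index or
the first grid entry.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .dissimilarity import DissimilarityOptions, pairwise_matrix
from .indicators import equalized_phi_matrix, fisher_p_matrix

log = logging.getLogger(__name__)

__all__ = [
    "IsopamParams",
    "ClusterHierarchy",
    "HierarchyNode",
    "IsopamClustering",
    "geodesic_distances",
    "embed",
    "pam",
    "split_quality",
    "best_split",
    "build_hierarchy",
    "cut",
]


@dataclass
class IsopamParams:
    """Search-grid and stopping parameters for the divisive clustering."""

    max_levels: int = 4
    candidate_k_neighbors: tuple[int, ...] | None = None  # default: odd 3..min(30,n-1)
    candidate_axes: tuple[int, ...] | None = None  # default: 2..min(10, n-2)
    candidate_children: tuple[int, ...] = (2, 3, 4, 5, 6)
    min_cluster_size: int = 3
    alpha_indicator: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.max_levels < 1:
            raise ValueError("max_levels must be >= 1")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")

    def k_grid(self, n: int) -> list[int]:
        if self.candidate_k_neighbors is not None:
            return [k for k in self.candidate_k_neighbors if 2 <= k < n]
        return [k for k in range(3, min(30, n - 1) + 1, 2)]

    def axes_grid(self, n: int) -> list[int]:
        if self.candidate_axes is not None:
            return [a for a in self.candidate_axes if a < n]
        return list(range(2, min(10, n - 2) + 1))


def geodesic_distances(d: np.ndarray, k: int) -> np.ndarray:
    """All-pairs shortest paths on the symmetric k-NN graph of ``d``.

    Disconnected components are bridged by their minimum inter-component
    dissimilarity edge, keeping geodesics finite without altering local
    structure.
    """
    d = np.asarray(d, dtype=float)
    n = len(d)
    if n < 3:
        raise ValueError("need at least 3 samples for geodesic distances")
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n, got k={k}, n={n}")
    order = np.argsort(d, axis=1, kind="stable")
    mask = np.zeros_like(d, dtype=bool)
    rows = np.repeat(np.arange(n), k)
    cols = order[:, 1 : k + 1].ravel()  # skip self at position 0
    mask[rows, cols] = True
    mask |= mask.T

    def as_graph(m: np.ndarray) -> csr_matrix:
        # zero dissimilarities get an epsilon floor so the sparse graph
        # representation (where 0 means "no edge") keeps them
        return csr_matrix(np.where(m, np.maximum(d, 1e-12), 0.0))

    sparse = as_graph(mask)
    n_comp, labels = connected_components(sparse, directed=False)
    while n_comp > 1:
        best = (np.inf, -1, -1)
        for i in range(n):
            for j in range(i + 1, n):
                if labels[i] != labels[j] and d[i, j] < best[0]:
                    best = (d[i, j], i, j)
        _, i, j = best
        mask[i, j] = mask[j, i] = True
        sparse = as_graph(mask)
        n_comp, labels = connected_components(sparse, directed=False)
    geo = shortest_path(sparse, method="D", directed=False)
    np.fill_diagonal(geo, 0.0)
    return geo


def embed(geodesic: np.ndarray, n_axes: int) -> np.ndarray:
    """Classical scaling of a distance matrix onto ``n_axes`` coordinates.

    Double-centers the squared distances, takes the top non-negative
    eigenpairs, and fixes each axis's sign so its largest-magnitude loading
    is positive. If fewer positive eigenvalues exist than requested, the
    available axes are returned (logged).
    """
    g = np.asarray(geodesic, dtype=float)
    n = len(g)
    if n_axes >= n:
        raise ValueError("n_axes must be smaller than the number of samples")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (g**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    idx = np.argsort(evals)[::-1]
    evals, evecs = evals[idx], evecs[:, idx]
    pos = evals > 1e-12
    avail = int(pos.sum())
    if avail < n_axes:
        log.info("embed: only %d positive axes available (%d requested)", avail, n_axes)
    take = min(n_axes, max(avail, 1))
    coords = evecs[:, :take] * np.sqrt(np.maximum(evals[:take], 0.0))
    for ax in range(coords.shape[1]):
        i_max = np.argmax(np.abs(coords[:, ax]))
        if coords[i_max, ax] < 0:
            coords[:, ax] *= -1
    return coords


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    n = len(d)
    first = int(np.argmin(d.sum(axis=1)))
    medoids = [first]
    dnear = d[:, first].copy()
    while len(medoids) < k:
        gains = np.maximum(dnear[:, None] - d, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        nxt = int(np.argmax(gains))
        medoids.append(nxt)
        dnear = np.minimum(dnear, d[:, nxt])
    return sorted(medoids)


def pam(d: np.ndarray, n_clusters: int, seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids (BUILD + SWAP), fully deterministic.

    Returns (medoid indices sorted ascending, assignment of each sample to
    a medoid position). The SWAP phase applies the single best-improving
    swap per iteration (ties to the lowest sample indices) until no swap
    lowers the objective sum of distances to the nearest medoid.
    """
    d = np.asarray(d, dtype=float)
    n = len(d)
    if not 2 <= n_clusters <= n:
        raise ValueError("n_clusters must lie in [2, n_samples]")
    if n_clusters == n:
        medoids = np.arange(n)
        return medoids, np.arange(n)
    medoids = _pam_build(d, n_clusters)
    while True:
        med = np.array(medoids)
        dm = d[:, med]  # n x k
        nearest_pos = np.argmin(dm, axis=1)
        d1 = dm[np.arange(n), nearest_pos]
        dm_inf = dm.copy()
        dm_inf[np.arange(n), nearest_pos] = np.inf
        d2 = dm_inf.min(axis=1)
        others = np.array([h for h in range(n) if h not in set(medoids)])
        a = d[:, others]  # n x H
        m_term = np.minimum(a, d2[:, None]) - d1[:, None]  # if i loses its medoid
        t_term = np.minimum(a - d1[:, None], 0.0)  # otherwise
        delta = np.empty((len(med), len(others)))
        base = t_term.sum(axis=0)
        diff = m_term - t_term
        for pos in range(len(med)):
            maskm = nearest_pos == pos
            delta[pos] = base + diff[maskm].sum(axis=0)
        best_flat = int(np.argmin(delta))
        best_val = delta.flat[best_flat]
        if best_val < -1e-12:
            pos, h_idx = divmod(best_flat, len(others))
            medoids.remove(int(med[pos]))
            medoids.append(int(others[h_idx]))
            medoids = sorted(medoids)
        else:
            break
    med = np.array(sorted(medoids))
    assignment = np.argmin(d[:, med], axis=1)
    return med, assignment


def split_quality(
    assignment, presence: pd.DataFrame, alpha: float = 0.05
) -> float:
    """Indicator-based quality of a candidate partition.

    Sum, over species whose best one-sided Fisher p across clusters is below
    ``alpha``, of the species' maximum (non-negative) equalized phi. A
    perfect block structure scores the species count; a partition with no
    significant indicator scores 0.
    """
    labels = np.asarray(assignment)
    ids, counts = np.unique(labels, return_counts=True)
    if len(ids) < 2:
        raise ValueError("split quality needs at least 2 clusters")
    if counts.min() == 0:
        raise ValueError("empty cluster")
    pmat = fisher_p_matrix(presence, labels)
    phimat = equalized_phi_matrix(presence, labels)
    sig = pmat.min(axis=1) < alpha
    best_phi = phimat.max(axis=1).clip(lower=0.0)
    return float(best_phi[sig].sum())


@dataclass
class SplitResult:
    labels: np.ndarray
    k_neighbors: int
    n_axes: int
    n_children: int
    score: float


def best_split(
    d: np.ndarray, presence: pd.DataFrame, params: IsopamParams
) -> SplitResult | None:
    """Grid search over (k, axes, children); returns the best split or None.

    None ("no split") when no candidate yields a significant indicator or
    every candidate violates the minimum cluster size.
    """
    n = len(d)
    if n < 2 * params.min_cluster_size:
        return None
    best: SplitResult | None = None
    for k in params.k_grid(n):
        try:
            geo = geodesic_distances(d, k)
        except ValueError:
            continue
        # one eigendecomposition serves every axes count
        for n_axes in params.axes_grid(n):
            coords = embed(geo, n_axes)
            edist = squareform(pdist(coords))
            for m in params.candidate_children:
                if m * params.min_cluster_size > n or m >= n:
                    continue
                _, labels = pam(edist, m)
                _, counts = np.unique(labels, return_counts=True)
                if len(counts) < m or counts.min() < params.min_cluster_size:
                    continue
                score = split_quality(labels, presence, params.alpha_indicator)
                if score > 0 and (best is None or score > best.score):
                    best = SplitResult(labels, k, n_axes, m, score)
    return best


@dataclass
class HierarchyNode:
    node_id: str
    level: int  # 0 = root
    members: np.ndarray  # positional sample indices
    medoid: int | None = None
    split_params: tuple[int, int, int] | None = None  # (k, axes, children)
    score: float | None = None
    children: list[str] = field(default_factory=list)
    stop_reason: str | None = None  # depth | size | no_indicators | None


class ClusterHierarchy:
    """Nested partition of samples across up to ``max_levels`` levels.

    Node ids encode the path ("2.1.3"); ``cut(level)`` labels every sample
    by its deepest ancestor node at or above that level, so terminal nodes
    shallower than the cut keep their terminal label and every deeper cut
    refines every shallower one.
    """

    def __init__(self, sample_ids, max_levels: int):
        self.sample_ids = np.asarray(sample_ids)
        self.max_levels = max_levels
        self.nodes: dict[str, HierarchyNode] = {}
        self.root_id = "0"

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def terminal_nodes(self) -> list[HierarchyNode]:
        return [n for n in self.nodes.values() if not n.children]

    @property
    def n_terminal_clusters(self) -> int:
        return len(self.terminal_nodes())

    def n_clusters_at(self, level: int) -> int:
        return len(np.unique(self.cut(level)))

    def cut(self, level: int) -> np.ndarray:
        """Assignment vector (node-id labels) at a hierarchy level."""
        if not 1 <= level <= self.max_levels:
            raise ValueError(f"level must lie in [1, {self.max_levels}]")
        labels = np.empty(self.n_samples, dtype=object)
        stack = [self.nodes[self.root_id]]
        while stack:
            node = stack.pop()
            if node.level == level or not node.children:
                labels[node.members] = node.node_id
            else:
                stack.extend(self.nodes[c] for c in node.children)
        return labels

    def level_table(self) -> pd.DataFrame:
        """Flat per-level assignment table (sample_id, level_1..level_L)."""
        data = {"sample_id": self.sample_ids}
        for lv in range(1, self.max_levels + 1):
            data[f"level_{lv}"] = self.cut(lv)
        return pd.DataFrame(data)

    def to_dict(self) -> dict:
        """JSON-serializable tree with per-node diagnostics."""
        def node_dict(nid: str) -> dict:
            n = self.nodes[nid]
            return {
                "id": n.node_id,
                "level": n.level,
                "n_members": int(len(n.members)),
                "medoid": None if n.medoid is None else str(self.sample_ids[n.medoid]),
                "split_params": n.split_params,
                "score": n.score,
                "stop_reason": n.stop_reason,
                "children": [node_dict(c) for c in n.children],
            }
        return node_dict(self.root_id)

    def to_newick(self) -> str:
        """Dendrogram string with node heights equal to level depths."""
        def rec(nid: str) -> str:
            n = self.nodes[nid]
            if not n.children:
                depth_left = self.max_levels + 1 - n.level
                return f"{n.node_id.replace('.', '_')}:{depth_left}"
            inner = ",".join(rec(c) for c in n.children)
            return f"({inner}):1"
        return rec(self.root_id) + ";"


def build_hierarchy(
    d: pd.DataFrame | np.ndarray,
    community: pd.DataFrame,
    params: IsopamParams | None = None,
) -> ClusterHierarchy:
    """Recursive divisive clustering of a dissimilarity matrix.

    ``community`` supplies the presence/absence structure that scores each
    candidate split. Recursion stops at ``max_levels``, below twice the
    minimum cluster size, or when no candidate split has a significant
    indicator species; each node records why it became terminal.
    """
    if params is None:
        params = IsopamParams()
    if isinstance(d, pd.DataFrame):
        sample_ids = np.asarray(d.index)
        dm = d.to_numpy(dtype=float)
    else:
        dm = np.asarray(d, dtype=float)
        sample_ids = np.asarray(community.index) if community is not None else np.arange(len(dm))
    presence_all = community > 0
    hier = ClusterHierarchy(sample_ids, params.max_levels)
    root = HierarchyNode("0", 0, np.arange(len(dm)))
    hier.nodes["0"] = root
    queue = [root]
    while queue:
        node = queue.pop(0)
        members = node.members
        node.medoid = int(members[np.argmin(dm[np.ix_(members, members)].sum(axis=1))])
        if node.level >= params.max_levels:
            node.stop_reason = "depth"
            continue
        if len(members) < 2 * params.min_cluster_size:
            node.stop_reason = "size"
            continue
        sub_d = dm[np.ix_(members, members)]
        sub_presence = presence_all.iloc[members]
        result = best_split(sub_d, sub_presence, params)
        if result is None:
            node.stop_reason = "no_indicators"
            continue
        node.split_params = (result.k_neighbors, result.n_axes, result.n_children)
        node.score = result.score
        prefix = "" if node.node_id == "0" else node.node_id + "."
        for child_pos in range(result.n_children):
            child_id = f"{prefix}{child_pos + 1}"
            child = HierarchyNode(
                child_id, node.level + 1, members[result.labels == child_pos]
            )
            hier.nodes[child_id] = child
            node.children.append(child_id)
            queue.append(child)
    return hier


def cut(hierarchy: ClusterHierarchy, level: int) -> np.ndarray:
    """Module-level convenience wrapper over ``ClusterHierarchy.cut``."""
    return hierarchy.cut(level)


class IsopamClustering(ClusterMixin, BaseEstimator):
    """Scikit-learn style interface to the divisive isopam hierarchy.

    Parameters
    ----------
    dissimilarity : {"bray_curtis", "avalanche", "precomputed"}
        How to derive sample dissimilarities from the community matrix
        passed to :meth:`fit`. "avalanche" requires ``species_distances``.
    species_distances : DataFrame, optional
        Normalized interspecies cophenetic distances (for "avalanche").
    max_levels, candidate_k_neighbors, candidate_axes, candidate_children,
    min_cluster_size, alpha_indicator : see :class:`IsopamParams`.
    da_normalization : {"theoretical", "observed"}

    Attributes
    ----------
    labels_ : terminal assemblage label per sample (node-id strings).
    hierarchy_ : the full :class:`ClusterHierarchy`.
    dissimilarity_matrix_ : the samples x samples matrix clustered.
    n_clusters_ : number of terminal assemblages.
    """

    def __init__(
        self,
        dissimilarity: str = "bray_curtis",
        species_distances: pd.DataFrame | None = None,
        max_levels: int = 4,
        candidate_k_neighbors: tuple[int, ...] | None = None,
        candidate_axes: tuple[int, ...] | None = None,
        candidate_children: tuple[int, ...] = (2, 3, 4, 5, 6),
        min_cluster_size: int = 3,
        alpha_indicator: float = 0.05,
        da_normalization: str = "theoretical",
        seed: int = 0,
    ):
        self.dissimilarity = dissimilarity
        self.species_distances = species_distances
        self.max_levels = max_levels
        self.candidate_k_neighbors = candidate_k_neighbors
        self.candidate_axes = candidate_axes
        self.candidate_children = candidate_children
        self.min_cluster_size = min_cluster_size
        self.alpha_indicator = alpha_indicator
        self.da_normalization = da_normalization
        self.seed = seed

    def _params(self) -> IsopamParams:
        return IsopamParams(
            max_levels=self.max_levels,
            candidate_k_neighbors=self.candidate_k_neighbors,
            candidate_axes=self.candidate_axes,
            candidate_children=tuple(self.candidate_children),
            min_cluster_size=self.min_cluster_size,
            alpha_indicator=self.alpha_indicator,
            seed=self.seed,
        )

    def fit(self, X: pd.DataFrame, y=None, community: pd.DataFrame | None = None):
        """Cluster samples.

        X is the community matrix (samples x species mean basal area), or a
        precomputed square dissimilarity matrix when
        ``dissimilarity="precomputed"`` — in that case the community matrix
        must be supplied via ``community`` for indicator scoring.
        """
        if self.dissimilarity == "precomputed":
            if community is None:
                raise ValueError("precomputed dissimilarity requires community=")
            dmat = X if isinstance(X, pd.DataFrame) else pd.DataFrame(
                X, index=community.index, columns=community.index
            )
        else:
            community = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
            index = {"bray_curtis": "bc", "avalanche": "da"}.get(self.dissimilarity)
            if index is None:
                raise ValueError(f"unknown dissimilarity {self.dissimilarity!r}")
            dmat = pairwise_matrix(
                community,
                index,
                species_distances=self.species_distances,
                options=DissimilarityOptions(da_normalization=self.da_normalization),
            )
        self.hierarchy_ = build_hierarchy(dmat, community, self._params())
        self.labels_ = self.hierarchy_.cut(self.max_levels)
        self.dissimilarity_matrix_ = dmat
        self.n_clusters_ = len(np.unique(self.labels_))
        return self

    def fit_predict(self, X, y=None, **fit_params):
        return self.fit(X, **fit_params).labels_
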