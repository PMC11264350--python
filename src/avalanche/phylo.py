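"""Phylogeny handling for community analysis.

Parses ultrametric Newick trees, consolidates infraspecific taxa onto their
parental species, matches tips against an observed species list and derives
the normalized cophenetic (tip-to-tip path length) distance matrix that the
Discriminating Avalanche dissimilarity consumes.

Distances are normalized by the maximum observed tip pair so that every
off-diagonal entry lies in (0, 1] with the most distant pair at exactly 1.
"""

from __future__ import annotations

import io
import re

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "read_newick",
    "write_newick",
    "consolidate_infraspecific",
    "cophenetic_distances",
    "normalize_distances",
    "species_distance_matrix",
]

#: tokens that mark a rank below species level
_INFRASPECIFIC_MARKERS = {"subsp.", "ssp.", "var.", "subvar.", "f.", "forma"}


def _canonical(name: str) -> str:
    """Normalize a taxon label: underscores become spaces, whitespace collapsed."""
    return re.sub(r"\s+", " ", name.replace("_", " ")).strip()


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree with branch lengths.

    Parameters
    ----------
    text : str
        Newick serialization; internal node labels are optional but every
        edge below the root must carry a length.

    Raises
    ------
    ValueError
        On malformed input (message carries dendropy's position report) or
        when a non-root edge lacks a branch length.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            label = node.taxon.label if node.taxon else "<internal>"
            raise ValueError(f"missing branch length above node {label!r}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree back to Newick (branch lengths preserved)."""
    return tree.as_string(schema="newick", unquoted_underscores=True).strip()


def consolidate_infraspecific(names: list[str]) -> dict[str, str]:
    """Map each taxon name to its parental binomial.

    Names containing an infraspecific marker (``subsp.``, ``var.``, ``f.`` ...)
    collapse to the leading genus+epithet pair; plain binomials map to
    themselves.

    >>> consolidate_infraspecific(["Alnus glutinosa subsp. barbata"])
    {'Alnus glutinosa subsp. barbata': 'Alnus glutinosa'}
    """
    if not names:
        raise ValueError("empty name list")
    out: dict[str, str] = {}
    for name in names:
        tokens = _canonical(name).split(" ")
        if any(t.lower() in _INFRASPECIFIC_MARKERS for t in tokens[2:]):
            out[name] = " ".join(tokens[:2])
        else:
            out[name] = _canonical(name)
    return out


def _tip_ancestor_paths(tree: dendropy.Tree):
    """For every leaf, the cumulative distance to each of its ancestors."""
    paths = {}
    for leaf in tree.leaf_node_iter():
        dist, node, acc = 0.0, leaf, {}
        while node is not None:
            acc[id(node)] = dist
            if node.edge.length is not None:
                dist += node.edge.length
            node = node.parent_node
        paths[leaf] = acc
    return paths


def cophenetic_distances(
    tree: dendropy.Tree, species: list[str] | None = None
) -> pd.DataFrame:
    """Raw cophenetic distances: total branch length between each tip pair.

    Parameters
    ----------
    tree : dendropy.Tree
    species : list of str, optional
        Labels (consolidated binomials; spaces and underscores equivalent)
        to extract, in the returned row/column order. Defaults to all tips.

    Raises
    ------
    KeyError
        When requested species are absent from the tree; the message lists
        every unmatched name so the caller can drop or fix them.
    """
    tip_by_label = {_canonical(leaf.taxon.label): leaf for leaf in tree.leaf_node_iter()}
    if species is None:
        labels = sorted(tip_by_label)
    else:
        labels = [_canonical(s) for s in species]
        missing = [s for s in labels if s not in tip_by_label]
        if missing:
            raise KeyError(f"species not found in tree: {missing}")
    paths = _tip_ancestor_paths(tree)
    n = len(labels)
    mat = np.zeros((n, n))
    tips = [tip_by_label[s] for s in labels]
    for i in range(n):
        pi = paths[tips[i]]
        for j in range(i + 1, n):
            pj = paths[tips[j]]
            # the LCA minimizes the summed distances over shared ancestors
            d = min(pi[a] + pj[a] for a in pi.keys() & pj.keys())
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


def normalize_distances(raw: pd.DataFrame) -> pd.DataFrame:
    """Divide by the maximum off-diagonal entry so distances land in (0, 1].

    Idempotent and invariant to a global rescaling of branch lengths.
    """
    values = np.asarray(raw, dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(values, values.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(values), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    off = values[~np.eye(len(values), dtype=bool)]
    if off.size == 0 or off.max() <= 0:
        raise ValueError("all distances are zero; cannot normalize")
    return raw / off.max()


def species_distance_matrix(
    tree: dendropy.Tree, species: list[str]
) -> pd.DataFrame:
    """Convenience: consolidated, matched, normalized interspecies distances."""
    mapping = consolidate_infraspecific(species)
    parents = sorted(set(mapping.values()))
    return normalize_distances(cophenetic_distances(tree, parents))
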