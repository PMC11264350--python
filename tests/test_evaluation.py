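"""Mantel, cophenetic correlation, ARI, WSS, distance stats, Kruskal-Wallis."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from avalanche.evaluation import (
    adjusted_rand,
    cluster_distance_stats,
    cophenetic_correlation,
    kruskal_wallis,
    mantel_test,
    wss,
)
from avalanche.isopam import IsopamClustering, IsopamParams, build_hierarchy


def _random_distance(rng, n):
    return squareform(pdist(rng.random((n, 3))))


class TestMantel:
    def test_identity_rho_one(self, rng):
        d = _random_distance(rng, 12)
        rho, p = mantel_test(d, d, n_perm=99, seed=0)
        assert rho == pytest.approx(1.0)
        assert p <= 0.05

    def test_monotone_transform_rho_one(self, rng):
        d = _random_distance(rng, 12)
        rho, _ = mantel_test(d, np.sqrt(d) + d**2, n_perm=99, seed=0)
        assert rho == pytest.approx(1.0)

    def test_symmetric_in_arguments(self, rng):
        d1, d2 = _random_distance(rng, 10), _random_distance(rng, 10)
        r12, _ = mantel_test(d1, d2, n_perm=9, seed=1)
        r21, _ = mantel_test(d2, d1, n_perm=9, seed=1)
        assert r12 == pytest.approx(r21)

    def test_seeded_p_reproducible(self, rng):
        d1, d2 = _random_distance(rng, 10), _random_distance(rng, 10)
        assert mantel_test(d1, d2, 199, seed=7) == mantel_test(d1, d2, 199, seed=7)

    def test_constant_matrix_error(self):
        with pytest.raises(ValueError):
            mantel_test(np.zeros((5, 5)), np.ones((5, 5)) - np.eye(5), n_perm=9)


class TestCopheneticCorrelation:
    @staticmethod
    def _block_hierarchy_and_d():
        rng = np.random.default_rng(0)
        # 2 blocks of 8, each split into 2 subblocks of 4
        base = np.full((16, 16), 0.9)
        for blk in (slice(0, 8), slice(8, 16)):
            base[blk, blk] = 0.5
        for sub in (slice(0, 4), slice(4, 8), slice(8, 12), slice(12, 16)):
            base[sub, sub] = 0.1
        np.fill_diagonal(base, 0.0)
        base += rng.normal(0, 0.005, base.shape)
        base = np.clip((base + base.T) / 2, 0, 1)
        np.fill_diagonal(base, 0.0)
        community = pd.DataFrame(np.zeros((16, 8)))
        for s in range(4):
            community.iloc[4 * s : 4 * s + 4, 2 * s : 2 * s + 2] = 1.0
        params = IsopamParams(candidate_children=(2,), max_levels=2, min_cluster_size=2)
        hier = build_hierarchy(pd.DataFrame(base), community, params)
        return hier, base

    def test_block_structure_high_correlation(self):
        hier, d = self._block_hierarchy_and_d()
        assert cophenetic_correlation(hier, d) > 0.9

    def test_matches_lca_oracle(self):
        hier, d = self._block_hierarchy_and_d()
        # brute-force: deepest common node by walking node membership
        n = hier.n_samples
        dendro = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                depth = 0
                for node in hier.nodes.values():
                    if i in node.members and j in node.members:
                        depth = max(depth, node.level)
                dendro[i, j] = hier.max_levels + 1 - depth
        il, jl = np.tril_indices(n, k=-1)
        expected = np.corrcoef(d[il, jl], dendro[il, jl])[0, 1]
        assert cophenetic_correlation(hier, d) == pytest.approx(expected, abs=1e-12)

    def test_sample_permutation_invariant(self, small_bundle):
        model = IsopamClustering(
            dissimilarity="bray_curtis", max_levels=2,
            candidate_k_neighbors=(5,), candidate_axes=(2,), candidate_children=(2,),
        ).fit(small_bundle["community"])
        d = model.dissimilarity_matrix_.to_numpy()
        c1 = cophenetic_correlation(model.hierarchy_, d)
        assert np.isfinite(c1) and -1 <= c1 <= 1


def _all_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def _pair_counting_ari(labels_a, labels_b):
    """Hubert-Arabie ARI by direct pair counting."""
    n = len(labels_a)
    ss = sd = ds = dd = 0
    for i, j in itertools.combinations(range(n), 2):
        sa = labels_a[i] == labels_a[j]
        sb = labels_b[i] == labels_b[j]
        ss += sa and sb
        sd += sa and not sb
        ds += (not sa) and sb
        dd += (not sa) and (not sb)
    total = ss + sd + ds + dd
    expected = (ss + sd) * (ss + ds) / total
    maximum = ((ss + sd) + (ss + ds)) / 2
    if maximum == expected:
        return 1.0
    return (ss - expected) / (maximum - expected)


class TestAdjustedRand:
    def test_identical_partitions(self):
        assert adjusted_rand([0, 0, 1, 1], ["a", "a", "b", "b"]) == 1.0

    def test_singletons_vs_lump(self):
        assert adjusted_rand(list(range(6)), [0] * 6) == pytest.approx(0.0)

    def test_matches_pair_counting_on_all_partitions_of_five(self):
        items = list(range(5))
        parts = []
        for part in _all_partitions(items):
            labels = np.empty(5, dtype=int)
            for ci, cluster in enumerate(part):
                labels[cluster] = ci
            parts.append(labels)
        for a in parts:
            for b in parts:
                assert adjusted_rand(a, b) == pytest.approx(
                    _pair_counting_ari(a, b), abs=1e-12
                )

    def test_symmetry(self, rng):
        a, b = rng.integers(0, 3, 20), rng.integers(0, 4, 20)
        assert adjusted_rand(a, b) == pytest.approx(adjusted_rand(b, a))


class TestWss:
    def test_singletons_zero(self):
        d = np.ones((4, 4)) - np.eye(4)
        assert wss(d, np.arange(4)) == 0.0

    def test_pair_hand_value(self):
        d = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert wss(d, [0, 0]) == pytest.approx(0.5**2 / 2)

    def test_euclidean_matches_centroid_ss(self, rng):
        pts = rng.random((12, 3))
        labels = rng.integers(0, 3, 12)
        d = squareform(pdist(pts))
        centroid_ss = 0.0
        for c in np.unique(labels):
            sub = pts[labels == c]
            centroid_ss += ((sub - sub.mean(axis=0)) ** 2).sum()
        assert wss(d, labels) == pytest.approx(centroid_ss, abs=1e-9)

    def test_splitting_decreases_wss(self, rng):
        for _ in range(10):
            d = _random_distance(rng, 14)
            labels = rng.integers(0, 2, 14)
            idx = np.flatnonzero(labels == 0)
            if len(idx) < 2:
                continue
            split = labels.copy()
            split[idx[: len(idx) // 2]] = 2
            assert wss(d, split) <= wss(d, labels) + 1e-12


class TestClusterDistanceStats:
    def test_two_block_hand_values(self):
        d = np.full((4, 4), 0.9)
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.1
        np.fill_diagonal(d, 0.0)
        stats = cluster_distance_stats(d, [0, 0, 1, 1])
        assert stats.per_cluster_within == {0: pytest.approx(0.1), 1: pytest.approx(0.1)}
        assert stats.mean_within == pytest.approx(0.1)
        assert stats.mean_between == pytest.approx(0.9)

    def test_pooled_within_is_pair_weighted(self, rng):
        d = _random_distance(rng, 15)
        labels = np.array([0] * 3 + [1] * 5 + [2] * 7)
        stats = cluster_distance_stats(d, labels)
        weights = {0: 3, 1: 10, 2: 21}  # C(size, 2)
        manual = sum(
            stats.per_cluster_within[c] * w for c, w in weights.items()
        ) / sum(weights.values())
        assert stats.mean_within == pytest.approx(manual)

    def test_singleton_within_nan_single_cluster_between_nan(self):
        d = np.ones((3, 3)) - np.eye(3)
        stats = cluster_distance_stats(d, [0, 0, 1])
        assert np.isnan(stats.per_cluster_within[1])
        lone = cluster_distance_stats(d, [0, 0, 0])
        assert np.isnan(lone.mean_between)


class TestKruskalWallis:
    def test_hand_computed_h(self):
        h, df, p = kruskal_wallis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert h == pytest.approx(27 / 7, abs=1e-3)  # 3.857 without ties
        assert df == 1
        assert 0 < p < 1

    def test_scale_shift_invariance(self, rng):
        v = rng.random(20)
        labels = rng.integers(0, 3, 20)
        h1, _, _ = kruskal_wallis(v, labels)
        h2, _, _ = kruskal_wallis(v * 100 - 7, labels)
        assert h1 == pytest.approx(h2)

    def test_all_identical_values(self):
        h, df, p = kruskal_wallis([5.0] * 6, [0, 0, 1, 1, 2, 2])
        assert (h, p) == (0.0, 1.0)
        assert df == 2
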