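"""Geodesic distances, classical scaling, PAM and the divisive hierarchy."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from avalanche.isopam import (
    IsopamClustering,
    IsopamParams,
    best_split,
    build_hierarchy,
    embed,
    geodesic_distances,
    pam,
    split_quality,
)


class TestGeodesicDistances:
    def test_complete_graph_equals_metric_input(self, rng):
        pts = rng.random((8, 2))
        d = squareform(pdist(pts))
        geo = geodesic_distances(d, k=7)
        np.testing.assert_allclose(geo, d, atol=1e-12)

    def test_chain_path_sum(self):
        d = np.array([[0.0, 1.0, 10.0], [1.0, 0.0, 1.0], [10.0, 1.0, 0.0]])
        geo = geodesic_distances(d, k=2)  # k=2 keeps only the two unit edges plus union
        assert geo[0, 2] == pytest.approx(2.0)

    def test_disconnected_components_bridged(self):
        # two tight pairs far apart; k=1-style graph would disconnect them
        d = np.array(
            [
                [0.0, 0.1, 5.0, 5.2],
                [0.1, 0.0, 5.1, 5.3],
                [5.0, 5.1, 0.0, 0.1],
                [5.2, 5.3, 0.1, 0.0],
            ]
        )
        geo = geodesic_distances(d, k=2)
        assert np.isfinite(geo).all()
        # bridge uses the minimum inter-pair dissimilarity (5.0)
        assert geo[0, 2] == pytest.approx(5.0)

    def test_symmetric_zero_diagonal(self, rng):
        d = squareform(pdist(rng.random((10, 3))))
        geo = geodesic_distances(d, k=3)
        np.testing.assert_allclose(geo, geo.T)
        np.testing.assert_allclose(np.diag(geo), 0.0)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            geodesic_distances(np.zeros((2, 2)), 1)


class TestEmbed:
    def test_collinear_points_one_axis_exact(self):
        coords = np.array([0.0, 1.0, 3.0])
        d = np.abs(coords[:, None] - coords[None, :])
        emb = embed(d, 1)
        rec = np.abs(emb[:, 0][:, None] - emb[:, 0][None, :])
        np.testing.assert_allclose(rec, d, atol=1e-9)

    def test_identical_samples_identical_coordinates(self):
        d = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        emb = embed(d, 1)
        np.testing.assert_allclose(emb[0], emb[1], atol=1e-12)

    def test_stress_monotone_in_axes(self, rng):
        pts = rng.random((15, 5))
        d = squareform(pdist(pts))
        stresses = []
        for n_axes in (1, 2, 3, 4, 5):
            emb = embed(d, n_axes)
            rec = squareform(pdist(emb))
            stresses.append(((rec - d) ** 2).sum())
        assert all(a >= b - 1e-9 for a, b in zip(stresses, stresses[1:]))

    def test_deterministic_sign_convention(self, rng):
        d = squareform(pdist(rng.random((10, 3))))
        a, b = embed(d, 3), embed(d, 3)
        np.testing.assert_array_equal(a, b)
        for ax in range(a.shape[1]):
            assert a[np.argmax(np.abs(a[:, ax])), ax] >= 0


def exhaustive_pam_objective(d: np.ndarray, k: int) -> float:
    """Optimal PAM objective by enumerating all medoid subsets."""
    n = len(d)
    best = np.inf
    for medoids in itertools.combinations(range(n), k):
        obj = d[:, medoids].min(axis=1).sum()
        best = min(best, obj)
    return best


class TestPam:
    def test_two_separated_pairs(self):
        d = np.array(
            [
                [0.0, 0.2, 9.0, 9.1],
                [0.2, 0.0, 9.2, 9.3],
                [9.0, 9.2, 0.0, 0.3],
                [9.1, 9.3, 0.3, 0.0],
            ]
        )
        medoids, labels = pam(d, 2)
        assert labels[0] == labels[1] != labels[2] == labels[3]
        obj = d[:, medoids].min(axis=1).sum()
        assert obj == pytest.approx(exhaustive_pam_objective(d, 2))

    def test_matches_exhaustive_optimum(self, rng):
        for trial in range(25):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(2, 4))
            pts = rng.random((n, 2))
            d = squareform(pdist(pts))
            medoids, _ = pam(d, k)
            obj = d[:, medoids].min(axis=1).sum()
            assert obj == pytest.approx(exhaustive_pam_objective(d, k), abs=1e-12)

    def test_k_equals_n(self):
        d = squareform(pdist(np.random.default_rng(0).random((5, 2))))
        medoids, labels = pam(d, 5)
        assert sorted(medoids) == list(range(5))
        assert d[np.arange(5), np.array(medoids)[labels]].sum() == 0.0

    def test_deterministic(self, rng):
        d = squareform(pdist(rng.random((12, 2))))
        assert np.array_equal(pam(d, 3)[1], pam(d, 3)[1])


def _block_presence(n_groups: int, per_group: int, species_per_group: int) -> pd.DataFrame:
    """Perfect indicator structure: each species confined to one group."""
    rows = []
    for g in range(n_groups):
        for _ in range(per_group):
            row = np.zeros(n_groups * species_per_group)
            row[g * species_per_group : (g + 1) * species_per_group] = 1.0
            rows.append(row)
    cols = [f"sp{i}" for i in range(n_groups * species_per_group)]
    return pd.DataFrame(rows, columns=cols)


class TestSplitQuality:
    def test_perfect_indicators_score_species_count(self):
        presence = _block_presence(2, 6, 4)
        labels = np.repeat([0, 1], 6)
        assert split_quality(labels, presence, alpha=0.05) == pytest.approx(8.0)

    def test_ubiquitous_species_contribute_zero(self):
        presence = pd.DataFrame(np.ones((10, 3)), columns=list("abc"))
        labels = np.repeat([0, 1], 5)
        assert split_quality(labels, presence, alpha=0.05) == 0.0

    def test_label_permutation_invariant(self):
        presence = _block_presence(3, 5, 2)
        labels = np.repeat([0, 1, 2], 5)
        relabeled = np.array([2, 0, 1])[labels]
        assert split_quality(labels, presence) == pytest.approx(
            split_quality(relabeled, presence)
        )

    def test_single_cluster_error(self):
        with pytest.raises(ValueError):
            split_quality(np.zeros(6), _block_presence(2, 3, 2))


class TestBestSplit:
    def test_recovers_two_separated_assemblages(self):
        presence = _block_presence(2, 8, 5)
        d = squareform(pdist(presence.to_numpy(), metric="braycurtis"))
        result = best_split(d, presence, IsopamParams())
        assert result is not None
        truth = np.repeat([0, 1], 8)
        from avalanche.evaluation import adjusted_rand

        assert adjusted_rand(result.labels, truth) == 1.0

    def test_no_split_without_indicators(self):
        presence = pd.DataFrame(np.ones((12, 1)), columns=["only"])
        d = np.zeros((12, 12))
        assert best_split(d, presence, IsopamParams()) is None

    def test_deterministic(self):
        presence = _block_presence(2, 6, 3)
        d = squareform(pdist(presence.to_numpy(), metric="braycurtis"))
        r1 = best_split(d, presence, IsopamParams())
        r2 = best_split(d, presence, IsopamParams())
        assert np.array_equal(r1.labels, r2.labels)
        assert (r1.k_neighbors, r1.n_axes, r1.n_children) == (
            r2.k_neighbors, r2.n_axes, r2.n_children,
        )


def _nested_community() -> pd.DataFrame:
    """Two major blocks, each containing two subgroups, 6 samples apiece."""
    rng = np.random.default_rng(3)
    n_sub, per = 4, 6
    blocks = []
    for sub in range(n_sub):
        for _ in range(per):
            major = np.zeros(4)
            major[sub // 2 * 2 : sub // 2 * 2 + 2] = 1.0  # block species
            marker = np.zeros(n_sub * 3)
            marker[sub * 3 : (sub + 1) * 3] = 1.0  # subgroup species
            blocks.append(np.concatenate([major, marker]) * (1 + rng.random(16) * 0.1))
    cols = [f"s{i}" for i in range(16)]
    return pd.DataFrame(blocks, columns=cols)


class TestBuildHierarchy:
    def test_nested_blocks_recovered_level_by_level(self):
        community = _nested_community()
        d = squareform(pdist(community.to_numpy(), metric="braycurtis"))
        params = IsopamParams(candidate_children=(2,), max_levels=2)
        hier = build_hierarchy(pd.DataFrame(d), community, params)
        assert hier.n_clusters_at(1) == 2
        assert hier.n_clusters_at(2) == 4
        truth_major = np.repeat([0, 1], 12)
        truth_sub = np.repeat([0, 1, 2, 3], 6)
        from avalanche.evaluation import adjusted_rand

        assert adjusted_rand(hier.cut(1), truth_major) == 1.0
        assert adjusted_rand(hier.cut(2), truth_sub) == 1.0

    def test_max_levels_one_single_partition(self):
        community = _nested_community()
        d = squareform(pdist(community.to_numpy(), metric="braycurtis"))
        hier = build_hierarchy(pd.DataFrame(d), community, IsopamParams(max_levels=1))
        for node in hier.terminal_nodes():
            assert node.level <= 1

    def test_homogeneous_data_single_leaf(self):
        community = pd.DataFrame(np.ones((10, 2)), columns=["a", "b"])
        d = np.zeros((10, 10))
        hier = build_hierarchy(pd.DataFrame(d), community, IsopamParams())
        assert hier.n_terminal_clusters == 1
        assert hier.nodes["0"].stop_reason == "no_indicators"

    def test_cuts_refine(self, small_bundle):
        model = IsopamClustering(
            dissimilarity="bray_curtis",
            candidate_k_neighbors=(5, 9), candidate_axes=(2, 3),
            candidate_children=(2, 3),
        ).fit(small_bundle["community"])
        hier = model.hierarchy_
        for lv in range(1, hier.max_levels):
            coarse, fine = hier.cut(lv), hier.cut(lv + 1)
            # every fine cluster sits inside exactly one coarse cluster
            df = pd.DataFrame({"c": coarse, "f": fine})
            assert (df.groupby("f")["c"].nunique() == 1).all()

    def test_cut_bounds(self, small_bundle):
        model = IsopamClustering(
            dissimilarity="bray_curtis",
            candidate_k_neighbors=(5,), candidate_axes=(2,), candidate_children=(2,),
            max_levels=2,
        ).fit(small_bundle["community"])
        with pytest.raises(ValueError):
            model.hierarchy_.cut(0)
        with pytest.raises(ValueError):
            model.hierarchy_.cut(3)


class TestEstimatorInterface:
    def test_sklearn_params_roundtrip(self):
        model = IsopamClustering(max_levels=2, min_cluster_size=4)
        params = model.get_params()
        assert params["max_levels"] == 2
        clone = IsopamClustering(**params)
        assert clone.get_params() == params

    def test_precomputed_requires_community(self):
        with pytest.raises(ValueError):
            IsopamClustering(dissimilarity="precomputed").fit(np.zeros((4, 4)))

    def test_fit_predict_matches_labels(self, small_bundle):
        model = IsopamClustering(
            dissimilarity="bray_curtis", max_levels=2,
            candidate_k_neighbors=(5,), candidate_axes=(2,), candidate_children=(2,),
        )
        labels = model.fit_predict(small_bundle["community"])
        assert np.array_equal(labels, model.labels_)
        assert model.n_clusters_ == len(np.unique(labels))
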