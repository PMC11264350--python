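import numpy as np
import pytest

from avalanche import (
    SyntheticConfig,
    build_community_matrix,
    filter_clusters,
    generate_dataset,
    species_distance_matrix,
)


@pytest.fixture(scope="session")
def toy_newick() -> str:
    return "((A:1,B:1):2,C:3);"


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic inventory shared across test modules."""
    cfg = SyntheticConfig(n_species=40, n_clusters=60, seed=5)
    tree, pools, stems, truth, raster = generate_dataset(cfg)
    retained, rejections = filter_clusters(stems)
    community = build_community_matrix(retained)
    sdist = species_distance_matrix(tree, list(community.columns))
    return {
        "cfg": cfg,
        "tree": tree,
        "pools": pools,
        "stems": stems,
        "truth": truth,
        "raster": raster,
        "retained": retained,
        "rejections": rejections,
        "community": community,
        "sdist": sdist,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
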