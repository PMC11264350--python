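# avalanche

Phylogenetically weighted discrimination of woody-species assemblages from
national-forest-inventory (NFI) data.

## The problem

NFIs census trees on permanent nested plots: each cluster plot holds three
subplots, and a stem is recorded on the concentric circle its diameter at
breast height (DBH) qualifies for — r = 15 m at DBH ≥ 30 cm, r = 10 m at
DBH ≥ 15 cm, r = 5 m at DBH ≥ 8 cm. From these records one can build a
community matrix of mean basal area (BA, m²/ha) per species and plot and ask:
which assemblages of co-occurring woody species does the landscape hold, and
do they track biogeographic gradients such as elevation?

Classical β-diversity indices treat every species as equally distinct. The
Bray–Curtis dissimilarity between plots *a* and *b* with abundances *p*:

    BC = Σᵢ |pᵢᵃ − pᵢᵇ| / Σᵢ (pᵢᵃ + pᵢᵇ)

The **Discriminating Avalanche** (dA) instead weights abundance differences
by the phylogenetic distance between species, so replacing a species with a
close relative costs little:

    dA = ½ ΣᵢΣⱼ Δᵢ · dᵢⱼ · Δⱼ ,   Δᵢ = |pᵢᵃ − pᵢᵇ| (relative frequencies)

where dᵢⱼ is the cophenetic distance (total branch length between tips *i*
and *j* on an ultrametric phylogeny) normalized to (0, 1]. Raw dA is rescaled
by its attainable bound 1 − 1/n (n species).

Plots are clustered from either dissimilarity matrix with an isopam-style
divisive algorithm: isomap ordination (geodesic distances on a k-NN graph,
classical scaling) followed by partitioning around medoids, choosing the
(neighborhood, axes, children) combination that maximizes the number and
fidelity (equalized phi, Fisher's exact test) of indicator species, recursed
to at most four hierarchy levels. Hierarchies are evaluated with Mantel
correlation, cophenetic correlation, adjusted Rand, within-cluster sum of
squares, within/between distances, and a Kruskal–Wallis test of elevation
differences.

Because real NFI data are not bundled, the package ships a first-class
synthetic generator that emulates the target inventory: ~90 species on a
random ultrametric phylogeny, assemblages drawing from focal clades along an
elevation gradient, three-subplot cluster plots with richness ≈ 5 ± 2 and
BA ≈ 30 m²/ha, and configurable noise (dead stems, slopover subplots,
genus-only labels) to exercise every filter.

## Worked example

```python
from avalanche import (SyntheticConfig, generate_dataset, filter_clusters,
                       build_community_matrix, species_distance_matrix,
                       IsopamClustering, adjusted_rand, wss,
                       cluster_distance_stats, kruskal_wallis)

cfg = SyntheticConfig(n_clusters=120, seed=7)
tree, pools, stems, truth, raster = generate_dataset(cfg)
retained, rejections = filter_clusters(stems)
community = build_community_matrix(retained)
sdist = species_distance_matrix(tree, list(community.columns))
model = IsopamClustering(dissimilarity="avalanche",
                         species_distances=sdist).fit(community)
```

prints (via the accompanying summaries):

```
retained 107 of 120 cluster plots, 80 species
rejections: {'slopover': 7, 'non_species_taxon': 6}
mean per-plot richness 4.02, mean basal area 30.2 m2/ha
clusters per level: [6, 18, 19, 19]
ARI vs generating assemblages: 0.924
WSS 0.892, mean within 0.053, mean between 0.765
Kruskal-Wallis on elevation: H=98.8, df=5, p=9.48e-20
```

Thirteen plots fall to the inclusion filters (boundary-intersecting
subplots, taxa not resolved to species level). The level-1 cut of the
dA-based hierarchy recovers the generating assemblages almost exactly
(adjusted Rand 0.92), its clusters are compact relative to their separation
(mean within-cluster dissimilarity 0.053 vs 0.765 between), and recovered
clusters occupy clearly distinct elevation bands (Kruskal–Wallis p ≈ 1e-19).

`IsopamClustering` is a scikit-learn-style estimator (`fit`, `fit_predict`,
`labels_`, `hierarchy_`, `get_params`); the same machinery is available as a
CLI (`avalanche synth | ingest | phylo-dist | dissim | cluster | isotab |
evaluate | run-all`) driven by a YAML config.

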