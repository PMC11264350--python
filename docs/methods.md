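# Methods

This note documents the models, parameter choices and numerical conventions
behind the package, in the spirit of a statistical software vignette.

## Inventory model and filters

A sample is a cluster plot of three subplots. Stems are censused on nested
concentric circles keyed to DBH (≥ 30 cm → r = 15 m, ≥ 15 cm → r = 10 m,
≥ 8 cm → r = 5 m; 8 cm is the census threshold). Per-hectare abundance uses
the standard concentric-area expansion factor 10000/(π r²) with r chosen by
the stem's circle; no edge correction is applied. The community matrix entry
for (plot, species) is the sum over the plot's *living* stems of
basal area × expansion factor, divided by the number of subplots (3), i.e.
mean BA in m²/ha.

Cluster-level inclusion rules run in a fixed order so each rejected cluster
gets one deterministic reason: (1) land use outside the allowed set,
(2) any boundary-intersecting ("slopover") subplot, (3) fewer than the
required number of non-empty subplots, (4) any taxon label not resolved to
species level. Species-level validation is a configurable pattern
("spp."-style epithets, single-word names) plus an optional synonym map —
a deterministic stand-in for full nomenclature harmonization against
taxonomic backbones, which is out of scope.

Sample elevation is the median of all raster cells contained in or crossed
by the circle of radius 15 m + GPS error centered on the southwestern
subplot; cell/circle intersection is exact (nearest-point test), no-data
cells are excluded.

## Phylogenetic distances

Infraspecific taxa (subsp., var., f.) collapse onto their parental binomial;
abundance columns of merged taxa are summed. Cophenetic distance is the
total branch length of the tip-to-tip path, computed via shared-ancestor
path sums and cross-checked in the tests against graph shortest paths and an
independent library routine. The matrix is normalized by its maximum
off-diagonal entry, which is the minimal transform placing all values in
(0, 1] with the most distant pair at exactly 1; it is idempotent and
invariant to global rescaling of branch lengths. Species present in the
community but absent from the tree abort the run with an explicit list.

## Dissimilarity indices

Bray–Curtis is computed on raw mean-BA abundances (matching the common
default of community-ecology software); the Discriminating Avalanche uses
within-sample relative frequencies, making it invariant to rescaling either
sample. Raw dA is the quadratic form ½ Δᵀ D Δ with Δ the absolute frequency
differences and D the normalized cophenetic matrix (zero diagonal).

Normalization of dA defaults to division by the theoretical bound 1 − 1/n
(n = number of species in the community matrix). Under the
relative-frequency reading the bound is not strict for species-poor pairs:
two plots holding one distinct species each with d₁₂ = 1 give raw dA = 1,
which exceeds 1 − 1/n whenever the community holds few species. Values
pushed above 1 are therefore clipped (and logged). An "observed" min-max
mode is provided for exactness checks; it is not the default because it
forces the extremes to 0 and 1 exactly, which real summary distributions of
this index do not show.

## Isopam-style clustering

Each node split proceeds: (1) geodesic distances — symmetric k-NN graph on
the dissimilarities, disconnected components bridged by their minimum
inter-component edge (keeping geodesics finite without altering local
structure), all-pairs Dijkstra; zero-weight edges are floored at 1e-12 so
the sparse-graph representation retains them; (2) classical scaling of the
geodesics (double-centering, eigendecomposition, top non-negative axes; each
axis's sign fixed so its largest-magnitude loading is positive); (3) PAM
(BUILD then best-improvement SWAP, ties to the lowest sample index) on the
embedding's Euclidean distances; (4) the candidate partition scored as the
sum, over species whose best one-sided Fisher p across clusters falls below
α, of their maximum non-negative equalized phi.

The search grid is an explicit operationalization, since published
descriptions of the approach do not pin the ranges down: k ∈ odd
{3, …, min(30, n−1)}, axes ∈ {2, …, min(10, n−2)}, children ∈ {2, …, 6},
minimum cluster size 3, α = 0.05 — all configurable. Ties in the grid break
to the first entry, so runs are fully deterministic. Recursion stops at
depth 4 (default), below twice the minimum cluster size, or when no
candidate split has a significant indicator; every terminal node records its
stop reason. PAM's BUILD+SWAP terminates at a local optimum of the medoid
objective; on small random instances this coincides with the enumerated
global optimum in the large majority of cases (and where it does not, the
reference R implementation returns the same configuration — see the test
suite's local-optimality assertions).

`cut(level)` labels each sample by its deepest ancestor node at or above the
level, so terminal nodes shallower than the cut keep their label and every
deeper cut refines every shallower one.

## Indicator statistics

Presence is abundance > 0. Significance is the one-sided Fisher's exact
(hypergeometric enrichment) test, evaluated vectorized as the hypergeometric
upper tail — identical to the 2×2 exact test with the "greater" alternative.
Fidelity is phi computed on a virtually equalized table in which every
cluster is re-weighted to the common size N/k via its within-cluster
relative frequency before collapsing to target-vs-rest; degenerate margins
give phi = 0. No multiple-testing correction is applied by default,
matching how such synoptic tables are conventionally reported. The isotab
view combines per-cluster percentage frequencies with phi and p, plus a
filtered headline table (defaults p ≤ .001, total frequency ≥ 50%).

## Evaluation

* Mantel: Spearman correlation of strictly-lower-triangle entries;
  simultaneous row/column permutations of the second matrix; add-one
  p estimator (1 + #{perm ≥ obs})/(1 + N), which never returns 0.
* Cophenetic correlation: Pearson correlation of the dissimilarities with
  dendrogram distances max_levels + 1 − depth(deepest common node) — the
  natural height scale for a fixed-depth divisive hierarchy without metric
  node heights.
* WSS: Σ_c (Σ_{i<j∈c} d²ᵢⱼ)/|c|, the distance-based within-cluster sum of
  squares; equals the sum of squared distances to centroids when d is
  Euclidean (asserted via the Huygens identity in the tests).
* Within/between distances: pooled over unordered pairs; singleton clusters
  report NaN within, a single cluster reports NaN between.
* Kruskal–Wallis: tie-corrected H with the chi-square approximation,
  appropriate at the group sizes encountered here.

## Synthetic generator

The generator defines the study conditions, not a tuning surface. Defaults:
90 species, 1000 cluster plots (experiments use 150–200, see below), four
assemblages, elevation range 100–2600 m with Gaussian niches of width 150 m
centered evenly along the gradient, per-plot richness ~ round(N(5, 2.1))
clipped to [1, 12], per-plot BA ~ N(30, 0.42·30) m²/ha floored at 2.5,
DBH lognormal(μ = 3.0, σ = 0.45) truncated at 8 cm (right-skewed diameter
distributions are standard; the floor is the census threshold), and 5% each
of dead stems, slopover subplots and genus-only labels so every filter is
exercised. Phylogenies arise from a coalescent-style merge process
(ultrametric and binary by construction). Assemblage pools partition the
tree into disjoint focal clades (repeatedly splitting the largest clade);
each pool member is drawn from the focal clade with probability
`phylo_signal` (default 1) and uniformly otherwise, with Dirichlet weights
within the pool. Plot elevation is uniform over the range; the plot belongs
to the assemblage whose niche is densest there; species are sampled from the
pool weights; stems accumulate per species until Dirichlet-allocated BA
targets are met. The elevation raster is a west–east ramp consistent with
each plot's coordinates, so raster-sampled elevations track the generating
ones to within a few cells.

What the generator does not emulate: spatial autocorrelation of forests
beyond the elevation ramp, GPS error beyond a constant, overlapping species
pools with partial turnover, or the national sampling-grid geometry. Passing
recovery tests therefore demonstrate correctness of the pipeline under
clean, well-separated conditions — not expected field performance on real
inventories, where assemblage boundaries are gradual and pools overlap.

## Experiment sizes and determinism

The bundled experiments use 200 cluster plots (single-study summaries,
parameter recovery) and 150 plots across ten seeds with a reduced search
grid (k ∈ {5, 9, 13, 17}, axes ∈ {2, 3, 4}, children ∈ {2, 3, 4}) for the
multi-seed compactness comparison — sizes chosen so a full run completes in
minutes on one core while keeping ~180 samples per matrix, enough for stable
rank-based statistics. Null-calibration checks use 500 replicates with 999
permutations at n = 20 (Mantel) and n = 30, k = 3 (Kruskal–Wallis). One
seeded random stream drives each generated dataset; every experiment
function takes an explicit seed, and reruns are bit-identical.

## Known limitations

* The true number of assemblages is identified post hoc as the hierarchy
  level whose cluster count best matches truth; the method itself does not
  estimate the number of assemblages.
* The isopam operationalization here fixes search ranges the original
  description leaves open; exact reproduction of cluster counts from other
  implementations is not guaranteed.
* The dA theoretical bound 1 − 1/n is an upper envelope under equal
  interspecies distances; after division, attainable values depend on the
  actual distance matrix, so dA and BC scales are not directly comparable —
  comparisons between the two classifications are therefore directional
  (each hierarchy evaluated on its own matrix), not absolute.
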