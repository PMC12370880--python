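# Methods

## The mapping model

`scalemap` matches cells between two spatial-omics samples that need not
share any spatial structure. Matching is phrased as a Linear Assignment
Problem (LAP): query cells are "workers", reference cells are "tasks", and
the assignment minimises a total cost

    C_ij = Σ_k (1 − S_ij^(k)),

the unweighted sum of reciprocals over a user-chosen stack of similarity
matrices S^(k). The matrices span several biological scales, addressed by
single letters:

| letter | metric      | score                                            | range   |
|--------|-------------|--------------------------------------------------|---------|
| f      | cell        | Pearson r of cell expression signals              | [−1, 1] |
| n      | niche       | Pearson r of neighbourhood-mean signals           | [−1, 1] |
| t      | territory   | Pearson r of territory-mean signals               | [−1, 1] |
| c      | composition | frequency-aware Jaccard of niche label multisets  | [0, 1]  |
| y      | label       | 0/1 indicator of cell-type label agreement        | {0, 1}  |

Correlation scores are used raw, so a correlation metric can contribute up
to 2 to the cost; deliberately no rescaling and no weights. Categorical
metrics (c, y) encode prior biological knowledge and are naturally more
discriminative, which shows up in the diagnostics (below) rather than in
explicit weighting. Custom matrices can be appended through
`custom_similarity` / `CellMapper(custom_matrices=...)`.

The frequency-aware Jaccard uniquifies repeated labels before the set
operations (A, A.1, A.2, …), which is equivalent to multiset intersection
over multiset union (per-label min over max of counts); `{A,A,B}` vs
`{A,B,B}` scores 2/4 = 0.5.

### Signals

Counts are library-size normalised to the median library and log1p'd
(TF-IDF is available as an alternative). Each sample's top-n genes by
dispersion (variance/mean of the normalised layer; n = 2000 by default) form
its signal; the two samples' feature sets are intersected before
correlation. A PCA embedding (30 components by default) can replace the HVG
signal. The niche signal replaces a cell's column with the mean over its
spatial neighbourhood; the territory signal with the mean over its
territory.

Niches are defined by k-nearest neighbours (default k = 6), by graph depth
on the Delaunay triangulation (the dual of the Voronoi tessellation), or by
a radius in coordinate units. Two choices the literature leaves open are
made explicit and configurable:

* **Centre inclusion.** The niche mean includes the centre cell by default
  (`include_center=True`), which keeps single-cell niches defined and makes
  the niche a superset of the cell. Excluding the centre is supported; an
  empty centre-excluded niche raises unless `fallback_to_cell` is set.
* **Hull pruning.** Delaunay triangulations of bounded point sets create
  spurious long edges along the convex hull; edges longer than the 99th
  percentile of edge lengths are pruned before the graph-depth search.

Territory labels are taken from the data when provided (the preferred
route, e.g. curated spatial-domain annotations). A fallback detector —
k-means on the embedding followed by splitting each expression cluster into
spatially connected components on the Delaunay graph — is supplied for
unannotated data. It is an approximation to image-based territory
segmentation, not a re-implementation of it: it guarantees spatially
contiguous territories but inherits k-means' sensitivity to k.

### Candidate filtering

Before solving, query cells with no realistic match can be dropped: a cell
survives if at least one reference cell scores above the threshold
(default 0.9) in *any* correlation/Jaccard matrix (the "at least one match"
reading; a per-matrix conjunction would be stricter). Independently, with
label filtering enabled, a query cell whose cell-type label matches zero
reference cells is dropped. Filtering all query cells is an error, not an
empty result.

### Batching, epochs, retention

With a requested batch size B (default 1000), each epoch shuffles the query
set and partitions it into batches; reference cells are drawn without
replacement from a shuffled pool that, when exhausted, is refilled with a
freshly shuffled copy — so a smaller reference set is padded by duplication
and never by invented ids. The LAP is solved per batch (scipy's
shortest-augmenting-path solver, of the Jonker–Volgenant family) on cost
submatrices sliced from the single precomputed stack; scores do not depend
on batching, so slicing is exact and much faster than recomputation. Across
epochs (default 25) a query cell's retained pair is replaced only by a
*strictly* cheaper one, so per-query retained cost is non-increasing and
ties keep the earlier epoch's pair. Epoch e uses seed + e, making runs
reproducible from a single integer. A greedy pass by ascending cost
(`one_to_one=True`) reduces the many-to-many output to one-to-one.

### Interpretability diagnostics

Per metric, the coefficient of variation (sd/mean) of its cost contribution
1 − S over the active cost matrix measures discriminative ability, and the
proportion of contribution POC_k = (1 − S^(k)_ij)/C_ij measures, per mapped
pair, how much of the total cost the metric carries. POCs sum to 1 for every
pair with positive cost; zero-cost pairs are excluded with a reported count.

## Synthetic regimes

The generator produces ground-truth samples as uniform points in the unit
square partitioned into background and territory/layer regions:

* **circle** — 5 circular territories (radius ~ U(0.05, 0.2), centres
  uniform with the circle fully inside the square), re-drawn until all 5
  contain cells so every sample presents every territory; overlaps are
  resolved in favour of the later-drawn circle. Each territory holds 2 cell
  types, assigned per cell at random; background holds one.
* **layer** — one circle (radius ~ U(0.2, 0.4), larger so all bands are
  populated) split into 5 equal-width concentric layers; background and each
  layer hold 2 cell types.
* **dropped** — 2 circles with 1–3 layers and 1–2 types per region, chosen
  per sample, so regions are deliberately not shared across samples.
* **random_one / random_two** — 1–3 territories of random shape with 0–4
  layers and at most one (resp. up to two) types per region. "Rod" is a
  capsule (segment with half-width) of random orientation; "chaos map" is
  the set of cells within 0.03 of a bounded Clifford-type quadratic
  attractor's point cloud scaled into a random sub-box.

Counts are gamma-Poisson (negative binomial): gene baseline means are
log-normal(ln 0.5, 1), dispersion 0.3, and each cell type carries a
fold-change vector whose genes are flagged differentially expressed with
probability 0.5 at the territory/cell-type level and 0.05 at the layer
level, with log-normal(0, 0.5) fold changes. Fold changes compose
hierarchically (territory factor × layer factor × within-region variant
factor) for the layered regimes; in the circle regime each territory type
draws its own independent fold-change vector at p = 0.5. The per-type model
is drawn once per regime from the regime seed and shared by all samples, so
same-type cells are exchangeable across samples — the property that makes
cross-sample mapping well-posed.

Ground-truth spatial context is an "interaction" label per cell: the
lexicographically sorted cell-type labels of its k = 6 nearest neighbours
joined with `@`, so the label is invariant to neighbour discovery order.

What the generator does *not* emulate: empirical library-size variation,
dropout structure beyond what gamma-Poisson implies, batch effects,
continuous expression gradients within a region, or irregular tissue
boundaries. Passing tests on these regimes therefore demonstrate the
mechanics and the relative value of context metrics under a known truth,
not performance on any particular real assay.

## Evaluation and clustering

Mapped pairs are scored by (i) the Adjusted Rand Index between the query
and reference cell-type labels of mapped pairs and (ii) the frequency-aware
Jaccard between the interaction neighbourhoods (k-NN label multisets) of
the two cells of each pair. Co-mapping clustering ranks each query's
candidate references by ascending cost (best first — ranking is by
*preference*, not by the raw sort order of the costs), keeps the top n
(default 30), and clusters queries on 1 − Jaccard of these sets with
average-linkage hierarchical clustering (Leiden/Louvain available behind the
same distance). Sample-level clustering symmetrises the query×reference
mean-cost matrix by averaging the two directions, zeroes the diagonal, and
cuts the average-linkage tree at height 0.5 by default. Differential
expression between mapped groups is a per-gene two-sided Wilcoxon rank-sum
test with Benjamini–Hochberg correction at adjusted p < 0.05.

## Numerical choices and degenerate inputs

* Constant signal columns would make Pearson r undefined; they score 0 and
  emit a warning.
* BLAS correlation products can exceed ±1 by ~1e−16; scores are clipped to
  the declared range.
* HVG ranking and the one-to-one greedy pass use stable sorts, so ties
  break by input order, deterministically.
* Composition similarity with two empty (centre-excluded) niches is 0.
* All randomness flows from integer seeds through `numpy.random.default_rng`;
  epoch e of a mapping uses seed + e, and sample i of a regime seeds a
  generator with the (regime seed, stream, i) tuple.

## Problem sizes in the shipped checks

The test-suite and the reproduction script exercise the full 12-sample
generator contract at the default 5000 cells × 2000 genes, and run the
mapping protocol on scaled-down instances chosen to keep a laptop run
comfortable: 3 circle samples at 1000 cells × 500 genes, batch size 250,
10–25 epochs, with the 6 ordered mapping events of the 3-sample collection
for the configuration contrast ("fnc" vs "f"). Bookkeeping quantities (132
ordered events from 12 samples; the 14 benchmark cost configurations) are
exact counts independent of the sample size used to enumerate them.

## Known limitations

* The fallback territory detector is a stand-in for image-based
  segmentation; with provided annotations the t metric reflects them
  exactly, without them it reflects k-means structure.
* The per-batch LAP is exact, but the epoch scheme is a stochastic
  refinement: the final many-to-many mapping is not a global optimum over
  all batches jointly (nor is it meant to be).
* Composition and label metrics require cell-type labels of comparable
  vocabulary between samples; nothing reconciles divergent nomenclatures.
* The pairwise-Jaccard step of co-mapping clustering is quadratic in the
  number of query cells; it is intended for cell populations of up to a few
  thousand queries, not whole large assays.
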