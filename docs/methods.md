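# Methods

## Model

A cell's fate commitment is modeled as a point in the (N−1)-simplex whose
vertices are N user-chosen terminally differentiated cell types
(2 ≤ N ≤ 4). The coordinate chain is:

| step | operation | output |
|------|-----------|--------|
| 1 | centroid `V[:, n]` = mean profile of terminal cluster n | G′ × N |
| 2 | Euclidean distance `D[c, n]` from cell c to `V[:, n]` | C × N, ≥ 0 |
| 3 | row normalization `D[c, :] /= ΣD[c, :]` | rows sum to 1 |
| 4 | kernel `S = exp(−D/σ)` | entries in (0, 1] |
| 5 | range scaling per column onto [0, 1] | column min 0, max 1 |
| 6 | row L1 normalization → barycentric `B` | row-stochastic |

The coordinates are then projected for plotting as `B · V_simplex` with
fixed vertex conventions: segment {0, 1}; triangle (0,0), (1,0),
(1/2, √3/2); tetrahedron (0,0,0), (1,0,0), (1/2, √3/2, 0),
(1/2, √3/6, √6/3).

Assumptions worth spelling out: the chosen terminal clusters are genuinely
terminal and transcriptionally distinct (coinciding centroids abort with
an error at step 3); the barycentric coordinate is a *relative* affinity —
range scaling compares each cell against the population per vertex, so
coordinates are cohort-dependent, not an absolute measure; and simplexes
with more than four vertices are unsupported by design.

### Kernel bandwidth

The similarity kernel uses a single scalar bandwidth σ applied to
row-normalized distances, with the exponent in the first power of the
distance. Because step 3 puts every cell's distances on a unit-sum scale,
a global scalar is well-posed; σ = 0.08 is the default and is exposed on
every entry point. Smaller σ sharpens contrast (cells saturate toward
their nearest vertex), larger σ pulls everything toward the center. A
squared-exponent (true Gaussian) variant was considered and not adopted;
the first-power form is the package's defined behavior.

## Feature selection

**Markers (default).** For each terminal fate, a two-sided Wilcoxon
rank-sum test per feature of that fate's cells against the cells of the
*other chosen terminals* — not against all cells, because the simplex
contrasts terminal fates against each other and the centroids are built
only from terminal clusters. Recipe: midranks for ties; normal
approximation with tie-corrected variance
`σ²_W = n₁n₂/12 · (n+1 − Σ(t³−t)/(n(n−1)))` and 0.5 continuity
correction; zero variance (all pooled values identical) yields p = 1.
Ranking is by ascending p, ties broken by descending log2 fold change
(pseudocount 1e-9 on both means), then lexicographic feature id. Only
positive-fold-change features qualify; top k = 30 per fate by default. The
union over fates, ordered lexicographically, is the single shared subspace
used for all vertices.

Accuracy of the approximation: against the exhaustive permutation
distribution the p-value is within 0.088 of exact over *every* achievable
untied configuration up to group sizes 6 vs 6 (verified exhaustively in
the test suite). Extreme tie patterns at very small n (e.g. 7 of 8 pooled
values identical) can deviate by ~0.5 — a known limitation of any normal
approximation; at realistic cluster sizes this is immaterial, and the
fully tied case returns p = 1 exactly.

No multiple-testing correction is applied: selection is top-k by rank, not
thresholded significance.

**PCA (alternative).** Cells are scored on the leading principal
components of the feature-centered (not scaled) matrix via SVD. Sign
convention: each component's largest-magnitude loading is positive, so
output is deterministic. Requesting more components than the data rank is
an error. The full-rank embedding preserves inter-cell distances, so the
downstream chain is unchanged in that limit.

## Velocity aggregation

Fate potential of cell c toward terminal n is the mean outgoing edge
weight into cluster n, absent edges counted as zero and the self-edge
excluded (denominator |n| − 1 for in-cluster cells, |n| otherwise).
Averaging over the whole target cluster rather than connected neighbors
makes the statistic deterministic under kNN sparsification and linear in
the graph. The graph is read as source→target on rows; callers with
transposed conventions must transpose before input.

Grid binning uses `resolution`^(N−1) axis-aligned bins (default 10 per
axis) over the bounding box of the *vertex polytope*, not the data extent,
so bin boundaries are dataset-independent; intervals are half-open with
the last bin closed. Per occupied bin: weights = mean of member cells'
potentials, then L1-normalized across the N fates (mean-then-normalize,
in that order); the arrow toward vertex n has length weight × `max_len`.
Normalization is within-grid, so arrow lengths compare fates within one
grid, not magnitudes across grids.

## Determinism and degenerate inputs

* Vertex-permutation equivariance is bit-exact by construction: the
  pipeline computes in sorted-terminal-label order internally and permutes
  output columns to the requested order at the end; the marker union is
  ordered lexicographically, which is invariant to label order.
* Cell-order invariance is bit-exact as well: centroid means and
  fold-change means are accumulated over cells in barcode-sorted order, so
  floating-point summation order cannot depend on input row order.
* Degenerate cases warn loudly instead of failing: a constant similarity
  column maps to 0.5; a cell with zero scaled similarity to every vertex
  gets uniform 1/N; a grid bin whose cells all have zero potential gets
  uniform arrow weights; an all-zero cell passes through normalization
  unchanged. Two cases are hard errors because no sensible output exists:
  coinciding terminal centroids, and a singleton terminal cluster in the
  fate-potential denominator.
* File outputs (`coordinates.tsv`, `markers.tsv`, `velocity.tsv`,
  `manifest.json`) are byte-identical across runs of the same config and
  seed; floats are printed with `%.12g`.

## Synthetic data

`FixtureSpec`/`generate` emulate a differentiation snapshot: K terminal
clusters (default 3 × 100 cells), each with a disjoint block of marker
features (default 10 of 200) whose Poisson rate is base (1.0) plus an
uplift (+5.0), and a progenitor population (default 100 cells) whose
expected profile is a convex mixture of the terminal means (default
uniform). Counts are integer Poisson or gamma-Poisson (negative binomial,
shape `dispersion`), stressing sparse-integer paths as in droplet data.
The transition graph gives each progenitor edges to 20 random cells of
each terminal cluster with total mass equal to the mixture weight;
terminal cells have no outgoing edges. Default magnitudes were chosen once
as a clearly structured but noisy regime: at rate 1.0 vs 6.0 per marker
gene, single cells overlap heavily gene-by-gene but separate over a
10-gene block, which is what typical cluster markers look like after QC.

What the generator does *not* emulate: sequencing-depth variation between
cells, gene–gene correlation beyond the block structure, doublets,
batch effects, ATAC fragment statistics (an "atac" run is just a second
count matrix), or realistic velocity-graph sparsity patterns. A green
recovery test therefore establishes that the chain orders cells correctly
under block-marker structure with count noise — not that any particular
biological dataset will separate.

## Known limitations

* Range scaling makes coordinates cohort-relative; adding or removing
  cells changes column extremes and hence everyone's coordinates.
* The barycentric placement carries no uncertainty; upstream velocity
  uncertainty is likewise not propagated or displayed.
* RNA and ATAC modalities are processed identically (no TF-IDF style
  normalization for accessibility data); multi-omic pairing is handled by
  running each modality separately against shared annotations.
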