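# Methods

## The supra-hexagonal lattice

The output space is a bounded hexagonal disc: circle 1 is the centre node,
circle `k ≥ 2` holds `6(k−1)` nodes, so a radius-`r` map has
`1 + 3r(r−1)` nodes. Cells are addressed in axial coordinates `(q, r)` with
hex distance `(|q| + |r| + |q + r|)/2` and embedded "pointy-top" in the
plane (`x = q + r/2`, `y = r·√3/2`), putting adjacent hexagons at Cartesian
distance exactly 1. Node 1 is the centre; each circle is numbered
anti-clockwise starting from its cell on the positive-x axis, axial
`(k−1, 0)`. The start cell and rotation origin of the published numbering
cannot be pinned down from prose alone, so this convention is *declared*;
any fixed choice preserves the map semantics (training, statistics and
partitioning are equivariant under lattice automorphisms, and the U-matrix
test exercises that equivariance explicitly). The disc has no wrap-around:
outer-circle corner nodes have 3 neighbours, other outer nodes 4, interior
nodes 6.

## Training

Batch training is the default: per epoch, every prototype is replaced by the
kernel-weighted mean of the input rows, weighted by the kernel evaluated at
the output-space distance between each row's best-matching unit (BMU) and
the prototype's node. Nodes receiving zero total weight keep their previous
prototype (logged). The sequential rule updates prototypes row by row with a
learning rate α, presentation order re-shuffled per epoch from the seed.
BMU search uses Euclidean distance in input space; co-minimal nodes within
an absolute tolerance of 1e−12 are recorded as ties, the lowest index wins.

Defaults and their rationale:

- **Map size** — smallest radius with at least `5·√G` nodes (capped at 15):
  the usual SOM sizing heuristic, giving ~5 genes per node at desk scale.
- **Initialisation** — "linear": prototypes spread over the plane of the
  first two principal axes of the data, scaled to the data's extent along
  each (SVD with a fixed sign convention, so the result is deterministic and
  independent of row order); falls back to seeded componentwise-uniform
  draws when the data has rank < 2.
- **Schedule** — rough phase: 10 epochs, σ from `max(r/2, 1)` down to 1
  (α 0.5 → 0.05 for the sequential rule); fine-tune phase: 40 epochs at
  σ = 1 (α 0.05 → 0.01). σ and α interpolate linearly within a phase. The
  fine-tune neighbourhood is deliberately **held at one lattice step**: with
  a gaussian kernel much narrower than the lattice spacing the weight on the
  nearest neighbour collapses (≈ 0.004 at σ = 0.3), the batch update
  degenerates into independent per-node k-means, and the U-matrix acquires
  spurious noise minima that fragment the later meta-clustering. Measured on
  the seeded planted-cluster fixture, σ_end = 0.3 produces 8–10 seeds and
  adjusted Rand index 0.64–0.81 over six generator seeds, versus 6–7 seeds
  and 0.82–0.91 at σ_end = 1. Keeping the terminal radius at 1 is also the
  classical recommendation for SOM fine-tuning.
- **Kernels** — gaussian `exp(−d²/2σ²)` (default), bubble `1[d ≤ σ]`,
  cut-gaussian, Epanechnikov `max(0, 1 − (d/σ)²)`. In the σ → 0 limit one
  batch epoch equals one k-means Lloyd step, which the tests verify.

## Node statistics and partitioning

The U-matrix value of a node is the mean input-space distance from its
prototype to its adjacent prototypes (0 by convention on a radius-1 map);
low values mark cluster interiors. The hit histogram counts genes per BMU
node and always sums to G.

Meta-clustering seeds are the local minima of a node field (the U-matrix by
default): a connected plateau of equal values qualifies when no neighbouring
node is lower, and its lowest-index member represents it — equal-value
plateaus are a real occurrence on small or degenerate maps, and the
lowest-index rule keeps seeding deterministic. Remaining nodes are grouped
either with the nearest seed prototype (fast, possibly fragmented) or by
greedy region growing: repeatedly assign, over all frontier pairs of an
unassigned node adjacent to a growing cluster, the pair minimising the
input-space distance between the node's prototype and the *seed's*
prototype (ties: lower node index, then lower cluster id). Growing from the
seed prototype rather than a running cluster mean keeps the result
independent of assignment order and guarantees each cluster is a connected
patch of the map, which is the property the method promises.

## Sample landscape

Sample feature vectors are the columns of the codebook (length M) or of the
input matrix (length G); alternatively the rows of the S × S pairwise
similarity matrix serve as S-dimensional features, which is much cheaper for
tall matrices. "Covariance matrix" in this context means that pairwise
similarity/distance matrix, not the strict statistical covariance.
Implemented metrics: Pearson; Spearman (Pearson on average ranks); Kendall
tau-b; cosine; Euclidean; cityblock; and mutual information with a plug-in
estimator on `ceil(√F)` equal-width bins per variable, reported in bits (the
MI diagonal is the marginal entropy). Zero-variance vectors yield 0 under
the correlation-family metrics, with a warning.

The layout is a small sheet-topology SOM on an `nx × ny` grid with
`nx = ceil(√S)`, `ny = ceil(S/nx)` (near-square, minimal), Euclidean output
distances on integer cell centres, trained with the same batch machinery and
schedule as the main map. Each sample is placed at its BMU cell; collisions
are resolved deterministically by processing samples in decreasing order of
BMU margin (runner-up minus winner distance — the most confidently placed
samples claim their cells first) and moving a colliding sample to the
nearest free cell (Euclidean, ties row-major). The display order of samples
is row-major over cells with ties broken by sample id, so it depends only on
ids and placements, never on input column order.

## Overlay

For gene `i` with co-best nodes `T_i`, the weight on node `j` is
`w_ij = (1/|T_i|) Σ_{b∈T_i} k(d(b, j); σ)` — the unit mass of a tied gene is
split equally across its co-best nodes. Weighted hits are `h_j = Σ_i w_ij`
and the overlaid value of a layer `y` is `O_j = Σ_i w_ij y_i / h_j`. Nodes
with `h_j < 1e−9` are flagged undefined rather than divided through. The
defaults are a gaussian kernel with σ = 1, matching the terminal
neighbourhood of the training schedule; with a bubble kernel below one
lattice step the overlay reduces to plain per-BMU group means. Key algebraic
properties (verified by the tests): a constant layer overlays to that
constant at every defined node, the operation is linear in the layer, and a
0/1 layer stays within [0, 1] (a per-node probability).

`overlay_as_codebook` repackages an overlay as an artificial codebook over
the overlay's columns so the landscape machinery can reorder the *overlaid*
samples; undefined nodes are imputed as the mean of their defined map
neighbours, iterated until closure (on a connected disc this always
terminates unless every node is undefined, which is an error).

## Synthetic data

The generator emulates the structure the method assumes: a background
fraction `f` of genes drawn componentwise from `Normal(0, σ_n²)` (genes that
"do not change"), the rest split evenly over C clusters whose centroids are
drawn once from `Normal(0, τ²)` per component, genes being centroid plus
`Normal(0, σ_n²)` noise. Defaults — 600 genes, 6 samples, 4 clusters,
f = 0.3, τ = 3, σ_n = 0.3 — give well-separated but non-trivial clusters at
desk scale; f = 0.3 honours the design rationale that most genes are
uninformative while keeping clusters recoverable. Matched overlay columns
are either logical (probability `p_in` of a 1 inside designated clusters,
`p_out` outside — emulating promoter-class indicator vectors) or numeric
(cluster-shifted Gaussian levels).

What a green test on this generator does *not* establish: real omics
matrices have heavy tails, correlated noise across samples, batch effects
and cluster sizes spanning orders of magnitude; Gaussian spherical clusters
are chosen for analytic tractability, so recovery results here bound the
method's behaviour only in the benign regime.

## Numerical and I/O choices

- Tie detection tolerance 1e−12 (absolute) throughout; tie-breaks are always
  lowest node index, then lowest cluster id.
- Floats are serialised with 17 significant digits, so written results
  round-trip float64 exactly.
- Matrix loading drops any row with a missing or non-numeric cell (count
  logged) and rejects duplicate gene ids by name.
- SVG rendering writes one hexagon polygon per node plus a 32-segment colour
  bar with no timestamps or hashed ids, so re-rendering identical input is
  byte-identical; the colour scale is diverging and anchored at 0 when the
  field spans zero, sequential otherwise.
- Every stochastic step (uniform initialisation, sequential shuffling,
  synthetic generation) draws from `numpy.random.default_rng(seed)`; batch
  training with linear initialisation is fully deterministic regardless of
  seed.

## Known limitations

- Only the bounded-disc topology is provided for the gene map (no sheet,
  cylinder or toroid alternatives) and only Euclidean BMU search during
  training; alternative metrics apply to the sample landscape only.
- Region growing is greedy; it guarantees contiguity, not a globally optimal
  partition.
- The mutual-information estimator is the plug-in estimate on equal-width
  bins; it is biased upward for small F and is intended for ranking sample
  pairs, not for absolute information values.
- Hit assignment materialises a G × M distance matrix; fine for desk-scale
  G (10⁴–10⁵), not for millions of rows.
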