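# Methods

## The model

`trabnet` describes the trabecular bone visible in a 2D micro-CT slice as a
spatial multigraph. After thresholding and topology-preserving thinning, each
skeleton pixel is classified by its number of 8-connected skeleton
neighbors: 1 → endpoint, 2 → ridge interior, ≥ 3 → junction. A ridge pixel
has exactly two skeleton neighbors by construction, so tracing from a node
pixel through an adjacent ridge pixel is deterministic and terminates at
another node (or back at the start, giving a self-loop). Edges carry their
ordered pixel path and a physical length: the chamfer (1, √2) arc length of
the path times the pixel size. We use arc length rather than endpoint
distance because the length of a curved trabecula is the length along it.

Three deliberate conventions shape the graph:

- **Junction clusters merge.** Thinning yields multi-pixel junction
  clusters; 8-connected clusters collapse to one vertex at their centroid.
  Without this, vertex counts measure a thinning artifact.
- **Both junctions and endpoints are vertices.** Counts per kind are kept
  separately (`NetworkGraph.vertex_counts`), so either counting convention
  can be reported; "number of vertices" defaults to their sum.
- **Isolated cycles become anchored self-loops.** A closed ridge loop with
  no junction has no natural vertex; we anchor it at its first pixel in
  scan order as a synthetic degree-2 "anchor" vertex. This keeps the pixel
  bookkeeping exact: every skeleton pixel belongs to exactly one node
  cluster or one edge interior.

## Graph statistics

For a simple undirected graph (self-loops dropped, parallel edges
collapsed; the vertex set is unchanged):

- Clustering: C_i = 2E_i / (k_i(k_i − 1)), the fraction of a vertex's
  neighbor pairs that are themselves connected; C is the arithmetic mean
  with vertices of degree < 2 contributing 0. Endpoint-heavy trabecular
  graphs would otherwise leave C undefined; excluding low-degree vertices
  is available as an option through networkx if needed, but the default
  keeps the mean defined.
- Characteristic path length: L is the mean unweighted BFS distance over
  unordered vertex pairs. Real slices are routinely disconnected, where a
  literal all-pairs mean is infinite; L is computed on the largest
  connected component by default, with per-component pair-weighted
  averaging as an option. Distances count edges, not micrometers.
- Small-worldness: σ = (C/C_r) / (L/L_r). The reference ensemble is
  uniform G(N, E) with matched vertex and edge counts (20 samples by
  default), the simplest null model consistent with "an equivalent random
  network"; degree-preserving rewiring could be substituted but requires a
  choice of rewiring depth the data do not constrain.
- Undefined values (L of an edgeless graph, σ when C_r = 0) propagate as
  NaN and serialize as null — never as 0, which would silently bias group
  means.

The clustering and BFS kernels are hand-written from the definitions;
networkx implementations serve as independent cross-checks in the tests,
and brute-force enumeration (neighbor pairs; exhaustive BFS) is the oracle
of record on small random graphs.

## Phantoms

The phantom generator exists so that every stage has inputs with known
answers. A slice is the ridge graph of a Voronoi tessellation of uniform
random seed points — a planar strut lattice. Anisotropy stretches one axis
before the tessellation; fragmentation deletes whole edges with a given
probability (keeping the ground-truth component count exact by
construction); the surviving ridges are rasterized, thickened by a disc of
radius `strut_thickness_px − 1`, and Gaussian grayscale noise is added.
Per-slice modifiers emulate depth dependence. Determinism is strict: a spec
regenerates bit-identical images, with per-slice generators spawned from
`(rng_seed, slice_index)` and per-sample cohort seeds `rng_seed + i`.

Default regimes used in examples and experiments, chosen to mirror the
documented contrasts between diseased and healthy trabecular structure
(denser, thicker, more fragmented networks with shorter struts in disease):

| parameter            | control-like | disease-like |
|----------------------|--------------|--------------|
| seed points (256 px) | 40           | 80           |
| strut thickness (px) | 2            | 4–6          |
| fragmentation prob   | 0.0          | 0.25–0.4     |
| noise σ (grayscale)  | 0.05         | 0.05         |

The classification experiment uses the strongly separated pair
(thickness 2 vs 6 px, fragmentation 0 vs 0.4) so that the task is solvable
by construction and failures indicate pipeline defects, not task ambiguity.

What the phantoms do **not** emulate: gray-level texture of marrow and
partial-volume effects, beam hardening and ring artifacts, plate-like
(rather than strut-like) trabeculae, and correlated 3D continuity across
slices. Passing phantom-based tests therefore validates the algorithmic
chain (segmentation → skeleton → graph → statistics → classifier), not
clinical performance on scanner data.

## Image processing choices

- Automatic threshold: Otsu's method — standard for bimodal bone/background
  histograms; a manual threshold overrides it.
- Connectivity: 8-connected foreground, 4-connected background holes (the
  standard duality).
- Thinning: Zhang–Suen-class iterative thinning (`skimage.morphology.thin`),
  which preserves 8-topology and leaves no 2×2 block, so the
  one-pixel-wide skeleton invariant holds exactly.
- Cleaning defaults: objects < 20 px and holes < 20 px are removed — at a
  20.5 μm pixel this is ~0.008 mm², below one trabecular cross-section,
  removing speckle without touching anatomy.
- RGB inputs are converted by ITU-R luminance weighting; 8/16-bit integers
  rescale to [0, 1] by bit depth.

## Morphometry (2D analogues)

The volumetric morphometric panel is replaced by per-slice 2D analogues,
labeled as such: bone area fraction; mean trabecular thickness via the
local-thickness transform (largest inscribed disc covering each pixel,
painted in decreasing-radius order; a disc of integer radius r spans
2r − 1 pixels, and the transform is exact to one pixel of discretization);
separation as the same transform on the background; and box-counting
fractal dimension (boundary mode by default, area mode by flag; box sizes
2–32 px). Volume-based vendor measures (structure model index, degree of
anisotropy, trabecular pattern factor, trabecular number) have no
well-defined 2D slice analogue and are intentionally absent.

## Depth profiles and statistics

Per-slice records become per-specimen depth profiles (depth = slice index ×
slice spacing). Group curves are mean ± sample SD per depth, linearly
interpolated onto the grid of the shortest profile (a no-op for aligned
stacks). Group tests use the per-specimen region mean as the unit of
analysis — slices within a specimen are not independent — over three
regions: proximal half `[0, n/2)`, distal half `[n/2, n)`, whole. The test
is the unpaired Student's t (Welch by flag), with Shapiro–Wilk normality
p-values reported per group and significance at α = 0.05. No covariate
adjustment (age/sex) is attempted: the package ships no covariate data, and
outputs are labeled unadjusted. Its type-I error is verified by simulation
(1,000 null replicates; acceptance band 3–7%).

## The classifier

The network is deliberately small: four blocks of 3×3 stride-1 convolution
(same padding) + batch normalization + ReLU, with 2×2 stride-2 max pooling
after blocks 1–3; the 16× spatially reduced feature map is flattened into
two fully connected layers (64 → 2) and a softmax. Channel widths default
to 8/16/32/64, giving 1,073,394 trainable parameters at 128×128 input. It
is implemented directly on NumPy (im2col convolutions, exact max-pool
gradients with tie splitting, Adam at lr 1e-3, cross-entropy), with seeded
He initialization and seeded shuffling; training is reproducible per BLAS
backend. Batch norm keeps running statistics (momentum 0.9) for inference.

The two-arm experiment trains the same architecture, with the same
stratified 90/10 split and seeds, on (i) raw slices and (ii) binary
renderings of the extracted networks (edge paths + 3×3 vertex blocks),
both resized to the input resolution. The rendered-network encoding is the
natural image-shaped representation of the graph; a metrics-vector variant
would be a different (non-convolutional) model and is not part of the
experiment. Unstated training hyperparameters (optimizer, rate, epochs,
batch size) are fixed at the defaults above and are all overridable.

## Problem sizes

The shipped verification uses: 200 random graphs (≤ 15 vertices) for oracle
equivalence; 20 noiseless 512² phantoms for topology recovery (component
count must match exactly; junction count within ±10%); a 4-slice noisy
depth-modulated stack for pixel conservation; 1,000 null replicates for
test calibration; 24 G(30, 60) draws for σ self-consistency; and a
100-per-class cohort (60 per class in the acceptance script) at 128×128
input for the two-arm experiment.

## Known limitations

- Everything is 2D; no cross-slice (3D) graph merging.
- Junction recovery on phantoms is within, not at, ground truth: thinning
  can split or shift junction clusters where lattice vertices are only a
  few pixels apart (observed mean ratio ≈ 1.02–1.05 on thin-strut
  phantoms).
- σ on planar strut lattices is typically < 1 (clustering in a cross-section
  arises only from triangular cells); the metric is reported, not a claim
  that trabecular slices are small-world.
- The G(N, E) reference with 20 samples carries sampling noise into σ for
  small graphs; raise `n_reference_samples` when σ differences matter.
- Extraction quality degrades with heavy noise if cleaning thresholds are
  left at defaults; they are physical-scale parameters and should follow
  the pixel size.
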