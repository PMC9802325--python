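# trabnet

Network analysis of trabecular bone micro-CT slices.

Trabecular (spongy) bone is a lattice of struts and plates. In hip
osteoarthritis the subchondral trabecular structure of the femoral head
remodels — struts thicken, compress, and fragment — and conventional
volumetric morphometry (bone volume fraction, trabecular thickness and
separation) summarizes whole volumes without resolving how the architecture
changes with depth. `trabnet` treats each 2D micro-CT slice as a spatial
graph instead: trabecular junctions and strut endpoints are vertices, the
struts between them are edges, and graph statistics become per-slice,
depth-resolved descriptors of the microarchitecture.

The pipeline:

1. **Preprocessing** (`trabnet.imageproc`) — read 8/16-bit TIFF/PNG slices,
   percentile contrast stretch, optional region of interest, Otsu or manual
   thresholding, speckle/hole cleaning, and Zhang–Suen-class thinning to a
   one-pixel-wide skeleton.
2. **Graph extraction** (`trabnet.graphx`) — classify skeleton pixels by
   8-neighbor count (endpoint = 1, ridge = 2, junction ≥ 3), merge touching
   junction pixels into single vertices, trace each ridge into an edge with
   its pixel path and chamfer arc length in micrometers.
3. **Graph metrics** (`trabnet.netmetrics`) — vertex/edge/component counts,
   mean clustering coefficient C (with C_i = 2E_i / k_i(k_i − 1)),
   characteristic path length L (mean BFS distance over vertex pairs in the
   largest component), edge-length statistics, and small-worldness
   σ = (C/C_r) / (L/L_r) against matched G(N, E) random graphs.
4. **Morphometry** (`trabnet.morpho`) — 2D per-slice analogues: bone area
   fraction, local-thickness-based trabecular thickness and separation,
   box-counting fractal dimension.
5. **Depth profiles and statistics** (`trabnet.depth`) — per-specimen depth
   curves, group mean ± SD bands, Shapiro–Wilk normality checks and unpaired
   t tests of per-specimen region means (proximal half / distal half /
   whole).
6. **Classification** (`trabnet.cnn`) — a compact NumPy CNN (four 3×3
   stride-1 conv + batch-norm + ReLU blocks, three 2×2 max pools, two fully
   connected layers, softmax) trained in a two-arm experiment: raw slices
   versus rendered extracted networks, evaluated with confusion matrices and
   ROC/AUC.
7. **Phantoms** (`trabnet.phantom`) — seeded Voronoi-ridge lattice phantoms
   with exact ground-truth graphs, emulating control-like and
   osteoarthritis-like regimes (strut thickness, cell size, anisotropy,
   fragmentation, depth modulation), so the whole pipeline is testable
   without clinical scans.

## Worked example

```python
import trabnet as tn

# a control-like and a diseased-like phantom slice
ctrl = tn.PhantomSpec(image_size=256, seed_points=40, strut_thickness_px=2,
                      fragmentation_prob=0.0, noise_sigma=0.05, rng_seed=1)
hoa = tn.PhantomSpec(image_size=256, seed_points=80, strut_thickness_px=4,
                     fragmentation_prob=0.25, noise_sigma=0.05, rng_seed=2)
params = tn.ExtractionParams(min_object_px=10, min_hole_px=10)
for name, spec in (("CTRL", ctrl), ("HOA", hoa)):
    img, truth = tn.generate_slice(spec, 0)
    g = tn.extract_network(img, params)
    rec = tn.compute_all(g, seed=0)
    print(f"{name}: {rec.n_vertices} vertices, {rec.n_edges} edges, "
          f"{rec.n_components} components, C={rec.mean_clustering:.3f}, "
          f"L={rec.char_path_length:.2f}, "
          f"mean edge {rec.mean_edge_length_um:.0f} um, sigma={rec.sigma:.2f}")
```

prints

```
CTRL: 50 vertices, 70 edges, 1 components, C=0.037, L=5.01, mean edge 654 um, sigma=0.80
HOA: 87 vertices, 100 edges, 10 components, C=0.011, L=7.27, mean edge 505 um, sigma=0.54
```

The diseased-like slice shows the expected contrasts: more vertices and
edges, more graph components (fragmentation), longer characteristic path
length, and shorter edges (compressed struts in a denser, finer lattice).
`sigma < 1` says these planar strut lattices are less clustered than matched
random graphs — clustering in a planar cross-section comes only from
triangular cells, so σ is reported per slice rather than assumed > 1.

The same pipeline is available from the shell:

```sh
trabnet phantom --out stack/ --n-slices 8 --seed 1
trabnet extract --images stack/ --out nets/
trabnet analyze --images CTRL ctrl_stack/ --images HOA hoa_stack/ --out analysis/
trabnet classify --out classify/ --n-per-group 100 --seed 1
```

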