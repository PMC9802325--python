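"""Synthetic trabecular-slice phantoms with exact ground-truth networks.

A phantom slice is built from the ridge graph of a Voronoi tessellation of
random seed points — a planar strut lattice that visually and topologically
resembles a trabecular cross-section. The surviving lattice after random edge
deletion ("fragmentation") is the exact ground truth; the image is its
rasterization, thickened to the requested strut width, plus Gaussian noise.
Because fragmentation deletes whole edges rather than eroding pixels, the
ground-truth component count stays exact by construction.

Controllable structure parameters map onto the morphometric axes that
distinguish diseased from healthy trabecular bone: seed density (cell size /
separation), strut thickness, anisotropy (axis stretch), fragmentation
(disconnection), and per-depth modulation of all three.

Determinism contract: a spec (including ``rng_seed``) regenerates
bit-identical images and ground truth. Per-slice generators are spawned as
``SeedSequence(rng_seed, spawn_key=(slice_index,))`` and consume draws in a
fixed order: seed points, then the Bernoulli edge-survival mask over in-frame
ridges, then pixel noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import Voronoi
from skimage import draw as _draw
from skimage import morphology

from .imageproc import DEFAULT_PIXEL_SIZE_UM, SliceImage

#: depth-profile modifier triple: multiplies (seed_points, strut_thickness_px,
#: fragmentation_prob) for a given slice index
DepthProfile = Callable[[int], tuple[float, float, float]]


def identity_profile(_: int) -> tuple[float, float, float]:
    return (1.0, 1.0, 1.0)


def linear_profile(seed_slope: float = 0.0, strut_slope: float = 0.0,
                   frag_slope: float = 0.0) -> DepthProfile:
    """Depth profile with modifiers growing linearly in the slice index."""

    def profile(i: int) -> tuple[float, float, float]:
        return (1.0 + seed_slope * i, 1.0 + strut_slope * i, 1.0 + frag_slope * i)

    return profile


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters and seed for one synthetic slice stack.

    ``strut_thickness_px`` is the rasterized strut width parameter: ridges are
    dilated by a disc of radius ``strut_thickness_px - 1``, so 1 leaves the
    one-pixel rasterization untouched and each increment widens struts by two
    pixels.
    """

    image_size: int = 512
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_slices: int = 1
    seed_points: int = 60
    strut_thickness_px: int = 2
    anisotropy: float = 1.0
    fragmentation_prob: float = 0.0
    noise_sigma: float = 0.05
    depth_profile: DepthProfile = identity_profile
    rng_seed: int = 0
    explicit_points: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.fragmentation_prob <= 1.0):
            raise ValueError("fragmentation_prob must lie in [0, 1]")
        if self.strut_thickness_px < 1:
            raise ValueError("strut_thickness_px must be >= 1")
        if self.seed_points < 4:
            raise ValueError("seed_points must be >= 4")
        if self.anisotropy < 1.0:
            raise ValueError("anisotropy must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Exact surviving lattice behind one phantom slice.

    ``vertices`` are (row, col) junction coordinates; ``edges`` are
    (vertex_id_a, vertex_id_b, polyline) with the polyline an ordered pixel
    path; ``n_components`` is the component count of the lattice graph.
    """

    vertices: tuple[tuple[float, float], ...]
    edges: tuple[tuple[int, int, tuple[tuple[int, int], ...]], ...]
    n_components: int

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for i, (r, c) in enumerate(self.vertices):
            g.add_node(i, row=r, col=c)
        for a, b, poly in self.edges:
            g.add_edge(a, b, n_path_pixels=len(poly))
        return g

    @property
    def n_junctions(self) -> int:
        """Vertices with lattice degree >= 3."""
        g = self.to_networkx()
        return sum(1 for _, d in g.degree if d >= 3)


def _slice_rng(spec: PhantomSpec, slice_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=spec.rng_seed, spawn_key=(slice_index,))
    return np.random.default_rng(ss)


def _modified(spec: PhantomSpec, slice_index: int) -> PhantomSpec:
    ms, mt, mf = spec.depth_profile(slice_index)
    return replace(
        spec,
        seed_points=max(4, int(round(spec.seed_points * ms))),
        strut_thickness_px=max(1, int(round(spec.strut_thickness_px * mt))),
        fragmentation_prob=float(np.clip(spec.fragmentation_prob * mf, 0.0, 1.0)),
    )


def lattice_ridges(points: np.ndarray, image_size: int,
                   anisotropy: float = 1.0):
    """Voronoi ridge graph of ``points``, clipped to the image frame.

    The tessellation is computed in a row-compressed space (rows divided by
    ``anisotropy``) and mapped back, elongating cells along the row axis.
    Ridges with any endpoint outside the frame (or at infinity) are dropped.

    Returns ``(vertex_coords, ridge_pairs)`` where ridge_pairs index into
    vertex_coords, in scipy's ridge enumeration order.
    """
    stretched = points / np.array([anisotropy, 1.0])
    vor = Voronoi(stretched)
    verts = vor.vertices * np.array([anisotropy, 1.0])
    hi = image_size - 1
    keep: list[tuple[int, int]] = []
    for a, b in vor.ridge_vertices:
        if a == -1 or b == -1:
            continue
        pa, pb = verts[a], verts[b]
        if (0 <= pa[0] <= hi and 0 <= pa[1] <= hi
                and 0 <= pb[0] <= hi and 0 <= pb[1] <= hi):
            keep.append((a, b))
    return verts, keep


def generate_slice(spec: PhantomSpec, slice_index: int) -> tuple[SliceImage, GroundTruth]:
    """Generate one phantom slice and its exact ground-truth lattice."""
    if not (0 <= slice_index < spec.n_slices):
        raise IndexError(f"slice_index {slice_index} outside [0, {spec.n_slices})")
    mod = _modified(spec, slice_index)
    rng = _slice_rng(spec, slice_index)

    if mod.explicit_points is not None:
        points = np.asarray(mod.explicit_points, float)
    else:
        points = rng.uniform(0, mod.image_size, size=(mod.seed_points, 2))
    verts, ridges = lattice_ridges(points, mod.image_size, mod.anisotropy)

    survive = rng.random(len(ridges)) >= mod.fragmentation_prob

    img = np.zeros((mod.image_size, mod.image_size), bool)
    vid_map: dict[int, int] = {}
    gt_vertices: list[tuple[float, float]] = []
    gt_edges: list[tuple[int, int, tuple[tuple[int, int], ...]]] = []
    for (a, b), s in zip(ridges, survive):
        if not s:
            continue
        ra, ca = verts[a]
        rb, cb = verts[b]
        rr, cc = _draw.line(int(round(ra)), int(round(ca)), int(round(rb)), int(round(cb)))
        img[rr, cc] = True
        for v in (a, b):
            if v not in vid_map:
                vid_map[v] = len(gt_vertices)
                gt_vertices.append((float(verts[v][0]), float(verts[v][1])))
        gt_edges.append((vid_map[a], vid_map[b], tuple(zip(rr.tolist(), cc.tolist()))))

    if mod.strut_thickness_px > 1:
        img = morphology.dilation(img, morphology.disk(mod.strut_thickness_px - 1))

    pixels = img.astype(float)
    if mod.noise_sigma > 0:
        pixels = np.clip(pixels + rng.normal(0.0, mod.noise_sigma, pixels.shape), 0.0, 1.0)

    truth = GroundTruth(tuple(gt_vertices), tuple(gt_edges), _component_count(gt_vertices, gt_edges))
    return SliceImage(pixels, mod.pixel_size_um, slice_index), truth


def _component_count(vertices: Sequence, edges: Sequence) -> int:
    g = nx.Graph()
    g.add_nodes_from(range(len(vertices)))
    g.add_edges_from((a, b) for a, b, _ in edges)
    return nx.number_connected_components(g)


def generate_stack(spec: PhantomSpec) -> list[tuple[SliceImage, GroundTruth]]:
    """Generate the full depth-modulated stack (one pair per slice)."""
    return [generate_slice(spec, i) for i in range(spec.n_slices)]


@dataclass(frozen=True)
class LabeledCohort:
    """Balanced two-group phantom image set for classification experiments."""

    images: tuple[SliceImage, ...]
    truths: tuple[GroundTruth, ...]
    labels: np.ndarray  # 0 = control-like, 1 = HOA-like
    group_names: tuple[str, str] = ("CTRL", "HOA")

    def __len__(self) -> int:
        return len(self.images)


def make_cohort(control_spec: PhantomSpec, hoa_spec: PhantomSpec,
                n_per_group: int) -> LabeledCohort:
    """Draw ``n_per_group`` single-slice samples per group.

    Sample ``i`` of each group uses ``rng_seed + i``, so cohorts are exactly
    reproducible and groups differ only through their spec parameters.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    images: list[SliceImage] = []
    truths: list[GroundTruth] = []
    labels: list[int] = []
    for label, spec in ((0, control_spec), (1, hoa_spec)):
        for i in range(n_per_group):
            img, gt = generate_slice(replace(spec, rng_seed=spec.rng_seed + i), 0)
            images.append(img)
            truths.append(gt)
            labels.append(label)
    return LabeledCohort(tuple(images), tuple(truths), np.asarray(labels))
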