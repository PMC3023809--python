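"""Deterministic synthetic inputs for every workspace, generated offline.

All generators are pure functions of a :class:`FixtureSpec`: the same spec
produces bit-identical files.  A single seed threads through all
sub-generators (each derives its stream with a fixed offset), so fixtures
for different modules built from one spec stay mutually consistent.

* :func:`make_atlas` builds an atlas bundle whose label regions are nested
  axis-aligned boxes mirroring the generated hierarchy tree — child boxes
  sit strictly inside their parent's box, so region voxel counts and
  containment have exact closed forms for oracle tests.  An optional second
  "functional" label layer groups the anatomic structures coarsely to
  exercise multi-label-set lookup.
* :func:`make_warped_pair` renders a smooth template image and pushes it
  through a known rigid/affine/TPS transform, returning exact landmark
  correspondences and the ground-truth transform for recovery tests.
* :func:`make_mock_registry` builds N deterministic in-memory search
  sources, optionally including one that always fails (fault injection).
* :func:`make_large_volume` writes a raw out-of-core volume whose base
  value at voxel (i, j, k) is its linear file offset ``i + ni*j + ni*nj*k``
  (plus optional noise), paired with an in-memory twin for oracles.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from . import atlas as atl
from . import hierarchy as hi
from . import registration as reg
from . import volume_io as vio
from .errors import ValidationError
from .federated_search import DataSource, Query, ResultRecord, SourceRegistry
from .hierarchy import LabelNode, LabelSet
from .volume_io import Image2D, ImageVolume

__all__ = [
    "FixtureSpec",
    "make_label_tree",
    "make_atlas",
    "make_warped_pair",
    "make_mock_registry",
    "make_large_volume",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters shared by all generators; same spec => identical output."""

    seed: int = 0
    volume_shape: tuple[int, int, int] = (24, 24, 24)
    n_structures: int = 7
    hierarchy_depth: int = 3
    noise_sigma: float = 0.0


# ---------------------------------------------------------------------------
# Hierarchy + nested-box atlas
# ---------------------------------------------------------------------------

_NAMES = [
    "Brain", "Forebrain", "Midbrain", "Hindbrain", "Cerebral cortex",
    "Basal ganglia", "Amygdala", "Hypothalamus",
    "Dorsomedial nucleus of the hypothalamus", "Putamen", "Thalamus",
    "Cerebellum", "Pons", "Medulla", "Hippocampus", "Striatum",
]
_ABBREVS = [
    "Br", "FB", "MB", "HB", "Ctx", "BG", "Amy", "Hy", "DMH", "Pu", "Th",
    "Cb", "Pn", "Md", "Hip", "Str",
]


def _structure_label(i: int) -> tuple[str, str]:
    if i < len(_NAMES):
        return _ABBREVS[i], _NAMES[i]
    return f"S{i}", f"Structure {i}"


def make_label_tree(spec: FixtureSpec, set_name: str = "anatomic") -> LabelSet:
    """A deterministic single-root tree with ``n_structures`` nodes of depth
    at most ``hierarchy_depth``, distinct colors, anatomy-flavored names."""
    if spec.n_structures < 1:
        raise ValidationError("n_structures must be >= 1")
    rng = np.random.default_rng(spec.seed + 1)
    nodes = []
    for i in range(spec.n_structures):
        abbrev, name = _structure_label(i)
        color = tuple(int(c) for c in rng.integers(1, 256, size=3))
        nodes.append(LabelNode(id=i + 1, abbrev=abbrev, name=name, color=color))
    depths = {0: 0}
    for i in range(1, spec.n_structures):
        # attach to a uniformly chosen earlier node whose depth allows a child
        candidates = [j for j in range(i) if depths[j] < max(1, spec.hierarchy_depth - 1)]
        parent = int(rng.choice(candidates))
        nodes[parent].children.append(nodes[i])
        depths[i] = depths[parent] + 1
    return LabelSet(set_name=set_name, roots=[nodes[0]])


def _assign_boxes(labelset: LabelSet, shape) -> dict[int, tuple]:
    """Nested axis-aligned boxes per node: each child strictly inside its
    parent, siblings split along the parent's longest axis with 1-voxel
    margins."""
    boxes: dict[int, tuple] = {}

    def rec(node: LabelNode, lo, hi) -> None:
        boxes[node.id] = (tuple(lo), tuple(hi))
        if not node.children:
            return
        # shrink by a 1-voxel margin per axis, but only where there is room,
        # so deeply nested boxes on tight axes stay non-empty
        ilo = [l + 1 if h - l >= 2 else l for l, h in zip(lo, hi)]
        ihi = [h - 1 if h - l >= 2 else h for l, h in zip(lo, hi)]
        axis = int(np.argmax([ihi[a] - ilo[a] for a in range(3)]))
        n = len(node.children)
        span = ihi[axis] - ilo[axis]
        if span < 2 * n - 1:
            raise ValidationError(
                f"structures do not fit: node {node.id} needs {n} child boxes "
                f"in a span of {span} voxels along axis {axis}"
            )
        step = span / n
        for ci, ch in enumerate(node.children):
            clo, chi = list(ilo), list(ihi)
            clo[axis] = ilo[axis] + int(round(ci * step))
            chi[axis] = ilo[axis] + int(round((ci + 1) * step)) - 1
            if chi[axis] < clo[axis]:
                chi[axis] = clo[axis]
            rec(ch, clo, chi)

    margin = 1
    root_lo = [margin] * 3
    root_hi = [s - 1 - margin for s in shape]
    if any(h - l < 1 for l, h in zip(root_lo, root_hi)):
        raise ValidationError(f"volume shape {shape} too small for any structure")
    for r in labelset.roots:
        rec(r, root_lo, root_hi)
    return boxes


def _paint_labels(labelset: LabelSet, boxes, shape) -> np.ndarray:
    """Deepest structure wins: paint parents first, children over them."""
    ids = np.zeros(shape, dtype=np.int16)
    order = sorted(labelset.index, key=lambda i: labelset.depth_map()[i])
    for label_id in order:
        lo, hi = boxes[label_id]
        ids[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = label_id
    return ids


def make_atlas(
    spec: FixtureSpec,
    out_dir: str | os.PathLike | None = None,
    second_layer: bool = True,
) -> atl.Atlas:
    """Build a synthetic atlas (and optionally write it as a bundle).

    The anatomic layer's regions are nested boxes matching the generated
    hierarchy; the reference volume is a smoothed ramp plus optional
    Gaussian noise.  With ``second_layer`` a coarser "functional" layer is
    added that merges each top-level subtree into one region, so the same
    voxel carries different labels in the two contexts.
    """
    labelset = make_label_tree(spec)
    shape = tuple(spec.volume_shape)
    boxes = _assign_boxes(labelset, shape)
    ids = _paint_labels(labelset, boxes, shape)

    rng = np.random.default_rng(spec.seed + 2)
    i, j, k = np.mgrid[0:shape[0], 0:shape[1], 0:shape[2]].astype(float)
    ref = np.sin(i / 4.0) + np.cos(j / 5.0) + k / shape[2]
    ref = ndi.gaussian_filter(ref, sigma=1.0)
    if spec.noise_sigma > 0:
        ref = ref + rng.normal(0.0, spec.noise_sigma, size=shape)
    reference = ImageVolume(ref.astype(np.float32))

    layers = [atl.LabelLayer(atl.LabelVolume(ids), labelset)]

    if second_layer:
        root = labelset.roots[0]
        func_nodes = []
        func_ids = np.zeros(shape, dtype=np.int16)
        rng2 = np.random.default_rng(spec.seed + 3)
        for gi, top in enumerate([root] + root.children):
            fid = 100 + gi
            abbrev = f"F{gi}"
            name = f"Functional zone {gi}"
            color = tuple(int(c) for c in rng2.integers(1, 256, size=3))
            func_nodes.append(LabelNode(id=fid, abbrev=abbrev, name=name, color=color))
            members = (
                {root.id}
                if gi == 0
                else hi.descendants(labelset, top.id)
            )
            func_ids[np.isin(ids, list(members))] = fid
        func_root = func_nodes[0]
        func_root.children = func_nodes[1:]
        func_set = LabelSet(set_name="functional", roots=[func_root])
        layers.append(atl.LabelLayer(atl.LabelVolume(func_ids), func_set))

    atlas = atl.Atlas(label_layers=layers, reference=reference, active_index=0,
                      name=f"synthetic-{spec.seed}")
    if out_dir is not None:
        atl.save_atlas(atlas, out_dir)
    return atlas


# ---------------------------------------------------------------------------
# Warped registration pairs
# ---------------------------------------------------------------------------

def _template_image(spec: FixtureSpec, size: int = 64) -> Image2D:
    """A smooth, asymmetric test pattern (sum of Gaussian blobs)."""
    rng = np.random.default_rng(spec.seed + 11)
    ys, xs = np.mgrid[0:size, 0:size].astype(float)
    img = np.zeros((size, size))
    for _ in range(6):
        cx, cy = rng.uniform(size * 0.2, size * 0.8, size=2)
        sig = rng.uniform(size * 0.05, size * 0.15)
        amp = rng.uniform(0.3, 1.0)
        img += amp * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sig**2))
    img /= img.max()
    return Image2D(pixels=img)


def _truth_transform(spec: FixtureSpec, model_kind: str, magnitude: float,
                     size: int) -> reg.TransformModel:
    c = (size - 1) / 2.0
    if model_kind == "rigid":
        th = math.radians(magnitude)
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        t = np.array([c, c]) - R @ np.array([c, c]) + np.array([magnitude * 0.1, -magnitude * 0.05])
        return reg.TransformModel(kind="rigid", matrix=np.hstack([R, t[:, None]]))
    if model_kind == "affine":
        shear = magnitude * 0.01
        A = np.array([[1.0 + shear, shear * 0.5], [shear * 0.25, 1.0 - shear * 0.5]])
        t = np.array([c, c]) - A @ np.array([c, c])
        return reg.TransformModel(kind="affine", matrix=np.hstack([A, t[:, None]]))
    if model_kind == "tps":
        # smooth sinusoidal displacement sampled at a coarse grid of anchors
        g = np.linspace(size * 0.15, size * 0.85, 4)
        src = np.array([(x, y) for y in g for x in g])
        dx = magnitude * np.sin(2 * np.pi * src[:, 1] / size)
        dy = magnitude * np.cos(2 * np.pi * src[:, 0] / size)
        dst = src + np.column_stack([dx, dy])
        return reg.fit_tps(reg.LandmarkSet(src, dst), lam=0.0)
    raise ValidationError(f"model_kind must be rigid, affine or tps, got {model_kind!r}")


def make_warped_pair(
    spec: FixtureSpec, model_kind: str = "rigid", magnitude: float = 10.0,
    size: int = 64, n_grid: int = 3,
):
    """A (source, template, landmarks, truth) tuple for registration tests.

    The template is rendered first; the ground-truth transform ``T`` maps
    source coordinates to template coordinates, and the source image is
    produced by resampling the template through ``T`` (so that warping the
    source by ``T`` recovers the template).  Landmarks sample an
    ``n_grid x n_grid`` interior grid of source points with their exact
    images under ``T``.
    """
    template = _template_image(spec, size=size)
    truth = _truth_transform(spec, model_kind, magnitude, size)
    if magnitude == 0:
        source = Image2D(pixels=template.pixels.copy())
    elif model_kind == "tps":
        # sample template at T(p) for each source pixel p: direct evaluation
        h, w = template.shape
        ys, xs = np.mgrid[0:h, 0:w]
        grid = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        mapped = truth.transform_points(grid)
        coords = np.stack([mapped[:, 1], mapped[:, 0]])
        px = ndi.map_coordinates(template.pixels, coords, order=1, mode="constant", cval=0.0)
        source = Image2D(pixels=px.reshape(h, w))
    else:
        inv = reg.TransformModel(kind=truth.kind, matrix=truth.inverse_matrix())
        source = reg.apply_transform(template, inv, template.shape, "bilinear")

    g = np.linspace(size * 0.2, size * 0.8, n_grid)
    src_pts = np.array([(x, y) for y in g for x in g])
    tgt_pts = truth.transform_points(src_pts)
    landmarks = reg.LandmarkSet(src_pts, tgt_pts)
    return source, template, landmarks, truth


# ---------------------------------------------------------------------------
# Mock search registries
# ---------------------------------------------------------------------------

_DATA_TYPES = ["2D Image", "3D Volume", "Gene Expression", "Probe"]


def make_mock_registry(
    spec: FixtureSpec,
    n_sources: int = 3,
    record_counts: tuple[int, ...] | None = None,
    failing: tuple[int, ...] = (),
) -> SourceRegistry:
    """A registry of deterministic in-memory sources.

    Source *i* is named ``mock<i>``, supports keywords (even *i*) or both
    search types (odd *i*), and returns ``record_counts[i]`` records whose
    ids derive from the seed.  Indices in ``failing`` always raise, for
    fault-injection tests.
    """
    if n_sources < 1:
        raise ValidationError("n_sources must be >= 1")
    rng = np.random.default_rng(spec.seed + 21)
    counts = record_counts or tuple(int(c) for c in rng.integers(1, 6, size=n_sources))
    registry = SourceRegistry()
    for i in range(n_sources):
        name = f"mock{i}"
        dtype = _DATA_TYPES[i % len(_DATA_TYPES)]
        n_rec = counts[i] if i < len(counts) else 1
        rec_ids = [int(v) for v in
                   np.random.default_rng(spec.seed + 100 + i).integers(0, 10_000, size=n_rec)]
        records = [
            ResultRecord(
                source=name, data_type=dtype,
                annotations=(("record_id", rid), ("score", float(ri + 1)),
                             ("title", f"{name} record {rid}")),
            )
            for ri, rid in enumerate(rec_ids)
        ]

        if i in failing:
            def execute(query: Query, _name=name) -> list[ResultRecord]:
                raise RuntimeError(f"injected fault in {_name}")
        else:
            def execute(query: Query, _records=records) -> list[ResultRecord]:
                return list(_records)

        registry.register(DataSource(
            name=name,
            search_types={"keyword"} if i % 2 == 0 else {"keyword", "query_term"},
            data_types=[dtype],
            execute=execute,
        ))
    return registry


# ---------------------------------------------------------------------------
# Large out-of-core volumes
# ---------------------------------------------------------------------------

def make_large_volume(
    spec: FixtureSpec, path: str | os.PathLike,
    shape: tuple[int, int, int] = (64, 64, 64),
):
    """Write a raw out-of-core volume and return ``(descriptor_path, twin)``.

    The base value at voxel (i, j, k) is its linear Fortran-order file
    offset ``i + ni*j + ni*nj*k`` (a ramp), plus Gaussian noise of
    ``spec.noise_sigma``; the in-memory twin array serves as the oracle for
    streamed reads.
    """
    ni, nj, nk = shape
    i, j, k = np.mgrid[0:ni, 0:nj, 0:nk].astype(np.float32)
    data = i + ni * j + (ni * nj) * k
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + 31)
        data = data + rng.normal(0.0, spec.noise_sigma, size=shape).astype(np.float32)
    data = data.astype(np.float32)
    descriptor = vio.write_lvol(Path(path), data)
    return descriptor, data
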