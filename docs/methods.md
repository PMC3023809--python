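# Methods

This note records the models, conventions and numerical choices behind
atlaskit, and what the synthetic test data does and does not show.

## Atlas model and conventions

An atlas is a reference intensity volume plus an ordered list of *label
layers*; each layer owns its own integer label volume and label set. We
deliberately do not share one id array across label sets: a voxel can carry
different structures in different contexts (anatomic vs functional, or
overlapping probabilistic delineations), which a single shared id array
cannot encode. One layer is *active*; per-voxel lookup reports the active
layer's label first and the remaining layers in order.

Conventions, chosen once and used everywhere:

* Voxel indices are 0-based; world coordinates use the voxel-center
  convention, `xyz = origin + ijk ⊙ voxel_size` (mm). The inverse rounds
  to the nearest voxel and flags out-of-grid results rather than raising.
* Background label id is 0.
* Slices are indexed per array axis; no anatomical relabeling is applied.
  Only the permutation/flip part of a NIfTI orientation matrix is honored —
  oblique affines are read but not resampled (out of scope).
* Intensity normalization for display divides by the volume's *global*
  value range, not per slice, so stepping through a cine series does not
  flicker and slices are photometrically comparable.

### Selection and overlay semantics

Double-clicking a voxel toggles the individual label under the cursor in
the active layer (an involution); group selection goes through subtree
selection, which adds a node and all of its descendants (inclusive of the
node itself — selecting "forebrain" highlights the forebrain and every
substructure). Subtree selection is idempotent and monotone. An *empty*
selection renders all delineations: a freshly opened atlas shows its
labels before any interaction. With a non-empty selection, a pixel is
painted with its structure's color at the requested opacity iff its id is
selected or descends from a selected id; everything else is fully
transparent.

### Event synchronization

A synchronous FIFO event bus links the atlas view, the ontology graph view
and the search workspace. Both the atlas and graph handlers apply
`select`/`deselect` payload id-sets to their own state, so after the queue
drains the two sets are identical regardless of which side initiated the
event — this is the bidirectional-synchronization invariant the test suite
exercises with random mixed event sequences. Graph-side selection expands
a node to its full subtree *before* publishing. Events published while a
handler runs are queued (re-entrancy safe), and a handler exception is
logged without blocking other handlers. Structure names and cursor
locations are handed to search as keyword lists and `("location",
"x,y,z")` terms respectively.

## Hierarchies

The ILF dialect is defined here as XML (the toolkit's own documented
grammar): a `labelset` root with nested `label` elements carrying `id`,
`abbrev`, `name`, `color="R,G,B"`; nesting encodes parentage. OBO 1.2 is
parsed through obonet; `is_a` must reduce to a tree, so terms with several
parents keep the lexically first parent and every dropped edge is recorded
as a warning. Cyclic `is_a` is a hard error. Text search is a
case-insensitive plain substring over abbreviation and full name — the
simplest predictable reading of pattern matching, with no regex surprises.

Layouts are exact functions of depth. Radial: a node at generation *g*
sits at radius `g·ring_spacing`; each child receives an angular sector
nested in its parent's, proportional to its leaf count (ties broken by
child order), and is drawn on the sector bisector. Linear: `x =
depth·column_spacing`; leaves take consecutive integer y in depth-first
order and internal nodes sit at the mean of their children's y. Both are
deterministic for a fixed input.

## Registration

Landmarks are (source, template) pixel-coordinate pairs `(x, y) = (col,
row)`; the fitted map sends source to template coordinates.

* **Rigid**: closed-form 2D orthogonal Procrustes on the centered
  cross-covariance, determinant forced to +1. Requires ≥ 2 pairs and
  non-coincident sources.
* **Affine**: least-squares 2×3 matrix via `lstsq`; ≥ 3 non-collinear
  pairs; exact on affine-consistent data.
* **TPS**: kernel `U(r) = r² log r²` with `U(0) = 0`, solved as the dense
  bordered system with regularization `λ ≥ 0` added to the kernel block.
  The side conditions (`Pᵀw = 0`) hold by construction; `λ = 0`
  interpolates landmarks exactly and the kernel weights vanish on
  affine-consistent landmarks. Note that λ is not scale-free: the kernel
  magnitude grows like `r² log r²` with the landmark spread, so a λ that
  smooths visibly on a unit-scale point set is negligible on a
  hundred-pixel one; choose λ relative to the squared landmark extent.
  No landmark subsampling — systems are
  desk-scale (tens of points), so a direct solve is both simplest and most
  accurate. TPS is the canonical landmark-interpolating spline and is the
  spline family implemented here.

Resampling inverts linear maps analytically. A TPS warp has no closed-form
inverse, so the full pipeline fits the *reverse-direction* spline
(template → source) and evaluates it directly on the output grid; the
forward fit is still reported for residuals and provenance. Interpolation
is nearest or bilinear (`scipy.ndimage.map_coordinates`, zero-filled
outside). 2D–3D alignment is realized as slice selection followed by
2D–2D registration; no volumetric pose search is attempted.

Backends are a name-keyed registry with a minimal call contract; the
built-in `landmark_warp` backend wraps the three models above. A backend
crash is wrapped in a backend-failure error naming the backend and leaves
core state untouched.

## Compositing

Transform composition order is fixed and documented: scale, then rotation
about the layer image center, then pan — typical viewer behavior. Canvas
rendering inverse-maps each canvas pixel into layer space and samples
bilinearly with transparent out-of-bounds, then blends with the
straight-alpha (non-premultiplied) over operator; the canvas starts from
an opaque background, so output alpha is 1 everywhere. Photometry uses a
mid-gray pivot, `out = clamp(γ(in − ½) + ½ + β, 0, 1)` with brightness
β ∈ [−1, 1] and contrast γ > 0; a LUT maps `v ↦ lut[round(255 v)]/255`,
exact on 8-bit-quantized inputs (arbitrary floats are quantized to 256
levels by the lookup — inherent to any finite table). Linked groups mirror
master-initiated deltas to every member, which preserves pairwise relative
pans/rotations/scales; slave-initiated deltas stay local. Cine stepping
clamps at the series ends rather than wrapping — predictable boundary
behavior. Rendering is a pure function of canvas state: identical state
produces bit-identical rasters, which the tests check at the PNG-byte
level.

## Out-of-core volumes

The streaming unit is one whole plane along the file's fastest-varying
(contiguous) axis — axis 2 for Fortran-layout files, axis 0 for C layout —
under an LRU cache with a byte budget that must hold at least one plane.
Raw volumes are described by a small text descriptor (`.lvol`: dtype,
shape, order, data file, geometry) and are written Fortran-ordered;
uncompressed `.nii` files stream directly (no intensity scaling, since
scaled reads could not be bit-identical to the in-memory load). Slices
orthogonal to the cached plane axis are assembled plane-by-plane through
the cache — correct but cache-unfriendly by design; the simple
whole-plane-LRU contract is easy to reason about and to verify against a
reference LRU simulation, which the tests do exactly (`disk_reads` counts
on-demand plane fetches). The global value range needed for display
normalization is computed by one streaming pass at open time, outside the
read counter.

## Federated search

A query carries keywords and structured `(field, value)` terms. Routing
narrows the query per source to the search types it declares; a source
that supports none of the populated parts is skipped with an explicit
"unsupported search type" status, and a raising source gets a
`failed: ...` status without touching any other group. Multi-keyword
matching is AND within a record, case-insensitive — the strictest
unambiguous choice. Result grouping is `(source, data_type)`, sorted, so
the table is a deterministic function of the per-source result sets
regardless of completion order. All table operations (stable sort with
missing values last, hide/show, reorder, expand/collapse) act on view
state only and never alter record content. Live adapters to the 2010-era
public services are intentionally absent — the service-provider interface
plus local directory/table/mock sources carry the architecture and keep
every test offline. A per-source timeout is a configuration value; in the
bundled synchronous sources it is only reported, not enforced
preemptively.

## Synthetic data

Generators are pure functions of a `FixtureSpec` (seed, volume shape,
structure count, hierarchy depth, noise σ); one global seed threads through
all sub-generators with fixed offsets. The synthetic atlas uses *nested
axis-aligned boxes* mirroring the hierarchy — child boxes sit inside their
parent's box with a one-voxel margin wherever the axis has room — so
containment and region voxel counts are exact closed forms for oracle
tests, and the optional second "functional" layer merges top-level
subtrees so multi-label lookup is exercised. Warped registration pairs
are built by pushing a rendered template through a *known* transform and
sampling exact landmark correspondences, so recovery accuracy is measured
against ground truth rather than another fit. The large-volume ramp value
at voxel (i, j, k) equals its linear file offset, making streamed-read
errors immediately visible.

What this does *not* show: synthetic boxes have none of the geometric
complexity of real delineations (thin structures, disconnected regions,
partial-volume boundaries), reference volumes are smooth analytic fields
rather than modality-realistic images, and registration truth transforms
are noise-free unless noise is added explicitly. Passing tests demonstrate
the correctness of the mechanisms — lookup, selection algebra, event
convergence, fitting, blending, caching, fan-out — not segmentation or
registration quality on real data.

## Problem sizes and tolerances

Exhaustive per-voxel checks run on ≤16³ atlases; out-of-core checks on
64³ volumes; sync experiments on 200 random event sequences;
layout sweeps on 50 random trees; registration recovery on 100 random
transforms. These sizes make every oracle exact while keeping the full
suite and the acceptance script fast. Tolerances: 1e-9 for closed-form
recoveries and layout geometry, 1e-6 for TPS interpolation and kernel
weight vanishing at λ=0, bit-identity for round-trips, streaming reads and
re-renders.
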