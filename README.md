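# atlaskit

A scriptable, GUI-free toolkit for digital-atlasing workflows: gather data
through a federated search over pluggable sources, align it to a reference
atlas with landmark registration, and compare it by compositing layers over
a labeled volume — all from Python or a thin command-line interface.

## Who it is for

Digital atlases couple a volumetric reference image (e.g. an MR volume of a
mouse brain) with a *label volume* that assigns each voxel an integer
structure id, and a *label set* — a single-parent hierarchy mapping ids to
names, abbreviations and display colors. Researchers use atlases as a
common spatial and semantic frame: find a structure by clicking a voxel,
select a whole subtree of substructures from the ontology, query external
data sources for the structures found, align retrieved images to the atlas,
and overlay everything for visual comparison. atlaskit implements that
whole loop as a library so it can be scripted, tested, and run headless.

## What is inside

| Module | Role |
| --- | --- |
| `atlaskit.volume_io` | NIfTI-1 / Analyze 7.5 volumes (via nibabel), PNG/TIFF/JPEG images, orthogonal slicing, voxel↔world coordinates, out-of-core slice streaming under an LRU byte budget |
| `atlaskit.hierarchy` | Label sets from ILF-dialect XML and OBO 1.2, subtree traversal, text search, radial and linear graph layouts |
| `atlaskit.atlas` | The atlas model: multiple label layers over one reference, per-voxel multi-label lookup (active set first), selection state, background masking, colored overlay rendering, and the event bus that keeps atlas selection and ontology-graph highlights synchronized in both directions |
| `atlaskit.compositor` | Layer stacks with pan/rotate/scale, opacity/brightness/contrast/LUT, master–slave linked groups, straight-alpha *over* compositing, dual-view juxtaposition |
| `atlaskit.registration` | Landmark-based 2D alignment — closed-form rigid (Procrustes), least-squares affine, thin-plate spline with kernel `U(r) = r² log r²` — behind a pluggable backend registry |
| `atlaskit.federated_search` | One query fanned out to sources declaring their search types, grouped result tables with view-only column operations, and a global cart |
| `atlaskit.synthetic_fixtures` | Deterministic generators (nested-box atlases, warped image pairs, mock source registries, large raw volumes) so everything runs offline |
| `atlaskit.cli` | `atlaskit atlas|hierarchy|register|search|canvas|fixtures ...` |

The core models, in standard notation:

* **Rigid fit** minimizes `Σᵢ ‖R sᵢ + t − tᵢ‖²` over rotations `R` (det +1)
  and translations `t`, solved in closed form from the SVD of the centered
  cross-covariance `Σᵢ (sᵢ − s̄)(tᵢ − t̄)ᵀ`.
* **TPS fit** solves the bordered system `[[K + λI, P], [Pᵀ, 0]] [w; a] =
  [T; 0]` with `K_{ij} = U(‖sᵢ − sⱼ‖)`, `P = [1 | s]`, so the kernel
  weights `w` satisfy the side conditions; `λ = 0` interpolates landmarks
  exactly, `λ → ∞` recovers the affine fit.
* **Compositing** applies, bottom-to-top, `C ← C_layer·α_eff + C·(1 −
  α_eff)` with `α_eff = α · sampled alpha`, after photometric adjustment
  `out = clamp(γ(in − ½) + ½ + β, 0, 1)` and inverse-mapped bilinear
  resampling under each layer's transform.

## Worked example

Build a synthetic atlas bundle, inspect it, and run a thin-plate-spline
registration on a synthetically warped pair:

```bash
$ atlaskit --config cfg.yaml fixtures make-atlas --seed 7 --shape 16,16,16
out/synthetic.atlas

$ atlaskit atlas info out/synthetic.atlas
synthetic-7: shape (16, 16, 16), 2 layer(s), active 0
  layer 'anatomic': 7 labels
  layer 'functional': 6 labels

$ atlaskit atlas labels-at out/synthetic.atlas --ijk 8,8,8
anatomic	5	Ctx	Cerebral cortex	147,112,100
functional	103	F3	Functional zone 3	131,40,35

$ atlaskit --config cfg.yaml fixtures make-warped-pair --seed 3 --model tps --magnitude 2
$ atlaskit --config cfg.yaml register run out/pair_source.png \
      out/pair_template.png out/pair_landmarks.txt --model tps
tps: residual=3.65007e-15 px -> out/aligned.png
```

Reading the output: the atlas carries two label layers — the same voxel
(8,8,8) is "Cerebral cortex" in the anatomic context and "Functional zone
3" in the functional context, with the active set printed first. The
registration residual is the RMS distance between the mapped source
landmarks and the template landmarks; with λ = 0 the spline interpolates
the nine grid landmarks to machine precision, and `out/aligned.png` is the
source resampled into template geometry.

The same operations are one-liners from Python:

```python
import atlaskit as ak
atlas = ak.synthetic_fixtures.make_atlas(ak.FixtureSpec(seed=7))
ws = ak.SyncedWorkspace(atlas)
ws.graph_select_node(0, node_id=1)        # select a subtree in the graph...
ws.state.layer_selected(0)                 # ...atlas selection follows
img = ak.render_label_overlay(atlas, ws.state, ak.SliceSpec(2, 8), opacity=0.6)
```

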