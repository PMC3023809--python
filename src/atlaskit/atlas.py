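"""The 3D atlas model: label layers over a reference volume.

An :class:`Atlas` couples an optional reference intensity volume with one or
more *label layers*.  Each layer pairs an integer label volume (value 0 =
background) with its own hierarchical label set, so the same voxel can carry
different labels in different contexts (anatomic, functional, ...).  One
layer is *active* at a time: lookups report the active layer's label first.

Selection state (which structures are enabled) is kept per layer.  A small
synchronous event bus links the atlas to an ontology graph view and to the
search workspace: selecting a region in the atlas highlights its node in
the graph, selecting a parent node in the graph selects the whole subtree in
the atlas, and the current selection or cursor location can be sent to the
search workspace as query input.  The synchronization is bidirectional and
converges: after all events are delivered the atlas selection and the graph
highlight set are identical.
"""

from __future__ import annotations

import logging
import os
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import yaml

from . import hierarchy as hi
from . import volume_io as vio
from .errors import BoundsError, StateError, ValidationError
from .hierarchy import LabelSet, descendants
from .volume_io import Image2D, ImageVolume, SliceSpec

logger = logging.getLogger("atlaskit.atlas")

__all__ = [
    "LabelVolume",
    "LabelLayer",
    "Atlas",
    "SelectionState",
    "AtlasEvent",
    "EventBus",
    "SyncedWorkspace",
    "load_atlas",
    "save_atlas",
    "labels_at",
    "toggle_label",
    "select_subtree",
    "deselect_subtree",
    "region_mask",
    "mask_background",
    "render_label_overlay",
]

BACKGROUND_ID = 0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class LabelVolume:
    """A 3D integer array assigning a label id per voxel; 0 is background."""

    ids: np.ndarray
    background_id: int = BACKGROUND_ID

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        if self.ids.ndim != 3:
            raise ValidationError(f"label volume must be 3D, got shape {self.ids.shape}")
        if not np.issubdtype(self.ids.dtype, np.integer):
            raise ValidationError(f"label volume must be integer-typed, got {self.ids.dtype}")
        if self.ids.min() < 0:
            raise ValidationError("label ids must be non-negative")

    @property
    def shape(self):
        return self.ids.shape

    def present_ids(self) -> set[int]:
        return {int(v) for v in np.unique(self.ids)} - {self.background_id}


@dataclass
class LabelLayer:
    """One labeling context: a label volume plus its label set."""

    label_volume: LabelVolume
    label_set: LabelSet

    def unresolved_ids(self) -> set[int]:
        """Nonzero ids present in the volume but missing from the label set."""
        return {i for i in self.label_volume.present_ids() if i not in self.label_set}


@dataclass
class Atlas:
    """Reference volume plus ordered label layers and an active-layer index."""

    label_layers: list[LabelLayer]
    reference: ImageVolume | None = None
    active_index: int = 0
    name: str = "atlas"
    load_warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.label_layers:
            raise ValidationError("an atlas needs at least one label layer")
        if not (0 <= self.active_index < len(self.label_layers)):
            raise ValidationError(
                f"active_index {self.active_index} out of range "
                f"[0, {len(self.label_layers)})"
            )
        shapes = {tuple(l.label_volume.shape) for l in self.label_layers}
        if self.reference is not None:
            shapes.add(tuple(self.reference.shape))
        if len(shapes) > 1:
            raise ValidationError(f"layer/reference shapes disagree: {sorted(shapes)}")

    @property
    def shape(self):
        return self.label_layers[0].label_volume.shape

    @property
    def active_layer(self) -> LabelLayer:
        return self.label_layers[self.active_index]


@dataclass
class SelectionState:
    """Per-layer selected and expanded label-id sets."""

    selected: dict[int, set[int]] = field(default_factory=dict)
    expanded: dict[int, set[int]] = field(default_factory=dict)

    def layer_selected(self, layer_index: int) -> set[int]:
        return self.selected.setdefault(layer_index, set())

    def layer_expanded(self, layer_index: int) -> set[int]:
        return self.expanded.setdefault(layer_index, set())

    def copy(self) -> "SelectionState":
        return SelectionState(
            selected={k: set(v) for k, v in self.selected.items()},
            expanded={k: set(v) for k, v in self.expanded.items()},
        )


_EVENT_KINDS = {
    "select",
    "deselect",
    "expand",
    "collapse",
    "send_names_to_search",
    "send_location_to_search",
}


@dataclass(frozen=True)
class AtlasEvent:
    """An immutable workspace event; payload is an id tuple, name tuple, or
    a world coordinate depending on ``kind``."""

    kind: str
    layer_index: int
    payload: tuple

    def __post_init__(self) -> None:
        if self.kind not in _EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        object.__setattr__(self, "payload", tuple(self.payload))


# ---------------------------------------------------------------------------
# Bundle I/O (.atlas)
# ---------------------------------------------------------------------------

_MANIFEST = "atlas.yaml"


def save_atlas(atlas: Atlas, path: str | os.PathLike) -> Path:
    """Save an atlas as a bundle directory with a YAML manifest.

    The bundle holds ``atlas.yaml`` plus one NIfTI per volume and one ILF
    file per label set; the manifest lists the reference path and, per
    layer, the label-volume path, hierarchy path and set name.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"name": atlas.name, "active_index": atlas.active_index, "layers": []}
    if atlas.reference is not None:
        vio.write_volume(atlas.reference, path / "reference.nii", "nifti")
        manifest["reference"] = "reference.nii"
    for i, layer in enumerate(atlas.label_layers):
        vol_name = f"labels_{i}.nii"
        ilf_name = f"labels_{i}.ilf.xml"
        lv = layer.label_volume
        vio.write_volume(ImageVolume(lv.ids), path / vol_name, "nifti")
        hi.write_ilf(layer.label_set, path / ilf_name)
        manifest["layers"].append(
            {"volume": vol_name, "hierarchy": ilf_name, "set_name": layer.label_set.set_name}
        )
    (path / _MANIFEST).write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path


def load_atlas(path: str | os.PathLike) -> Atlas:
    """Load an atlas bundle; cross-validates layers and collects warnings
    for label ids present in a volume but absent from its label set."""
    path = Path(path)
    manifest_path = path / _MANIFEST if path.is_dir() else path
    if not manifest_path.exists():
        raise FileNotFoundError(f"atlas manifest not found: {manifest_path}")
    base = manifest_path.parent
    manifest = yaml.safe_load(manifest_path.read_text())
    reference = None
    if manifest.get("reference"):
        reference = vio.read_volume(base / manifest["reference"])
    layers: list[LabelLayer] = []
    warnings: list[str] = []
    for entry in manifest.get("layers", []):
        vol = vio.read_volume(base / entry["volume"])
        ids = vol.data
        if not np.issubdtype(ids.dtype, np.integer):
            ids = ids.astype(np.int32)
        labelset = hi.parse_ilf(base / entry["hierarchy"])
        if entry.get("set_name"):
            labelset.set_name = entry["set_name"]
        layer = LabelLayer(LabelVolume(ids), labelset)
        for missing in sorted(layer.unresolved_ids()):
            warnings.append(
                f"layer {labelset.set_name!r}: label id {missing} present in volume "
                f"but absent from label set"
            )
        layers.append(layer)
    atlas = Atlas(
        label_layers=layers,
        reference=reference,
        active_index=int(manifest.get("active_index", 0)),
        name=manifest.get("name", base.name),
    )
    atlas.load_warnings = warnings
    return atlas


# ---------------------------------------------------------------------------
# Lookup, selection, masking
# ---------------------------------------------------------------------------

def _check_ijk(atlas: Atlas, ijk) -> tuple[int, int, int]:
    i, j, k = (int(v) for v in ijk)
    shape = atlas.shape
    if not (0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]):
        raise BoundsError(f"voxel {ijk} outside grid {shape}")
    return i, j, k


def labels_at(atlas: Atlas, ijk) -> list[tuple[str, int, str, str, tuple[int, int, int]]]:
    """All labels at a voxel, one entry per layer with a resolvable nonzero
    id there: ``(set_name, id, abbrev, name, color)``, active layer first,
    remaining layers in order."""
    i, j, k = _check_ijk(atlas, ijk)
    order = [atlas.active_index] + [
        n for n in range(len(atlas.label_layers)) if n != atlas.active_index
    ]
    out = []
    for n in order:
        layer = atlas.label_layers[n]
        label_id = int(layer.label_volume.ids[i, j, k])
        if label_id == layer.label_volume.background_id:
            continue
        node = layer.label_set.index.get(label_id)
        if node is None:
            continue
        out.append((layer.label_set.set_name, node.id, node.abbrev, node.name, node.color))
    return out


def toggle_label(state: SelectionState, atlas: Atlas, ijk) -> SelectionState:
    """Flip the active layer's label under the cursor in or out of the
    selection (double-click semantics).  Background voxels are a no-op."""
    i, j, k = _check_ijk(atlas, ijk)
    layer = atlas.active_layer
    label_id = int(layer.label_volume.ids[i, j, k])
    new = state.copy()
    if label_id == layer.label_volume.background_id:
        logger.info("toggle_label at %s: background voxel, nothing to toggle", (i, j, k))
        return new
    sel = new.layer_selected(atlas.active_index)
    if label_id in sel:
        sel.discard(label_id)
    else:
        sel.add(label_id)
    return new


def select_subtree(
    state: SelectionState, atlas: Atlas, layer_index: int, node_id: int
) -> SelectionState:
    """Select a node and every substructure below it (monotone, idempotent)."""
    layer = atlas.label_layers[layer_index]
    ids = descendants(layer.label_set, node_id)
    new = state.copy()
    new.layer_selected(layer_index).update(ids)
    return new


def deselect_subtree(
    state: SelectionState, atlas: Atlas, layer_index: int, node_id: int
) -> SelectionState:
    """Remove a node and its substructures from the selection."""
    layer = atlas.label_layers[layer_index]
    ids = descendants(layer.label_set, node_id)
    new = state.copy()
    new.layer_selected(layer_index).difference_update(ids)
    return new


def region_mask(atlas: Atlas, layer_index: int, ids) -> np.ndarray:
    """Boolean mask, true where the layer's label value is in ``ids``."""
    layer = atlas.label_layers[layer_index]
    ids = list(ids)
    if not ids:
        return np.zeros(layer.label_volume.shape, dtype=bool)
    return np.isin(layer.label_volume.ids, ids)


def mask_background(atlas: Atlas) -> ImageVolume:
    """A copy of the reference with intensity zeroed wherever the active
    label volume is background."""
    if atlas.reference is None:
        raise StateError("atlas has no reference volume to mask")
    lv = atlas.active_layer.label_volume
    data = atlas.reference.data.copy()
    data[lv.ids == lv.background_id] = 0
    return ImageVolume(
        data=data,
        voxel_size=atlas.reference.voxel_size,
        origin=atlas.reference.origin,
        axis_labels=atlas.reference.axis_labels,
    )


def render_label_overlay(
    atlas: Atlas, state: SelectionState, spec: SliceSpec, opacity: float = 0.5
) -> Image2D:
    """Render the active layer's delineations on a slice as straight-alpha
    RGBA.

    A pixel gets its structure's color with ``alpha = opacity`` when the
    label id there is nonzero and resolvable and either no selection exists
    (an untouched atlas shows all delineations) or the id is selected or
    descends from a selected structure; otherwise the pixel is fully
    transparent.
    """
    if not (0.0 <= opacity <= 1.0):
        raise ValidationError(f"opacity must be in [0,1], got {opacity}")
    layer = atlas.active_layer
    dummy = ImageVolume(layer.label_volume.ids)
    plane = vio.extract_slice_raw(dummy, spec)  # validates bounds

    labelset = layer.label_set
    selected = state.layer_selected(atlas.active_index)
    if selected:
        visible: set[int] = set()
        for sid in selected:
            if sid in labelset:
                visible |= descendants(labelset, sid)
    else:
        visible = None  # show all

    h, w = plane.shape
    out = np.zeros((h, w, 4), dtype=float)
    for label_id in np.unique(plane):
        label_id = int(label_id)
        if label_id == layer.label_volume.background_id:
            continue
        node = labelset.index.get(label_id)
        if node is None:
            continue
        if visible is not None and label_id not in visible:
            continue
        m = plane == label_id
        out[m, 0] = node.color[0] / 255.0
        out[m, 1] = node.color[1] / 255.0
        out[m, 2] = node.color[2] / 255.0
        out[m, 3] = opacity
    rest = [1.0, 1.0]
    if atlas.reference is not None:
        rest = [atlas.reference.voxel_size[a] for a in range(3) if a != spec.axis]
    return Image2D(pixels=out, pixel_size=(rest[0], rest[1]))


# ---------------------------------------------------------------------------
# Event bus and workspace synchronization
# ---------------------------------------------------------------------------

class EventBus:
    """Synchronous FIFO event bus with re-entrancy-safe delivery.

    Events published while a handler runs are queued and delivered after the
    current event finishes, so delivery order per publisher is FIFO.  A
    handler exception is caught and logged; remaining handlers still run.
    """

    def __init__(self) -> None:
        self._handlers: list[Callable[[AtlasEvent], None]] = []
        self._queue: deque[AtlasEvent] = deque()
        self._delivering = False
        self.log: list[AtlasEvent] = []

    def subscribe(self, handler: Callable[[AtlasEvent], None]) -> None:
        self._handlers.append(handler)

    def publish(self, event: AtlasEvent) -> None:
        self._queue.append(event)
        if self._delivering:
            return
        self._delivering = True
        try:
            while self._queue:
                ev = self._queue.popleft()
                self.log.append(ev)
                for handler in list(self._handlers):
                    try:
                        handler(ev)
                    except Exception:
                        logger.exception("event handler failed for %s", ev.kind)
        finally:
            self._delivering = False


class SyncedWorkspace:
    """Atlas selection, graph highlights and search input wired together.

    Both the atlas view and the graph view subscribe to ``select`` /
    ``deselect`` events and apply the payload ids to their own set, so after
    the queue drains the two sets are identical (the bidirectional
    invariant).  Graph-side selection of a parent expands to the whole
    subtree before publishing.  ``send_names_to_search`` and
    ``send_location_to_search`` append entries to ``search_inbox``.
    """

    def __init__(self, atlas: Atlas, bus: EventBus | None = None):
        self.atlas = atlas
        self.state = SelectionState()
        self.graph_highlights: dict[int, set[int]] = {}
        self.search_inbox: list[dict] = []
        self.bus = bus or EventBus()
        self.bus.subscribe(self._on_event)

    # -- handlers ---------------------------------------------------------
    def _on_event(self, ev: AtlasEvent) -> None:
        if ev.kind in ("select", "deselect"):
            ids = {int(v) for v in ev.payload}
            sel = self.state.layer_selected(ev.layer_index)
            hil = self.graph_highlights.setdefault(ev.layer_index, set())
            if ev.kind == "select":
                sel |= ids
                hil |= ids
            else:
                sel -= ids
                hil -= ids
        elif ev.kind in ("expand", "collapse"):
            exp = self.state.layer_expanded(ev.layer_index)
            ids = {int(v) for v in ev.payload}
            if ev.kind == "expand":
                exp |= ids
            else:
                exp -= ids
        elif ev.kind == "send_names_to_search":
            self.search_inbox.append({"keywords": list(ev.payload)})
        elif ev.kind == "send_location_to_search":
            self.search_inbox.append({"location": tuple(ev.payload)})

    # -- atlas-side actions ----------------------------------------------
    def click_voxel(self, ijk) -> None:
        """Double-click a voxel: toggle the active layer's label there."""
        layer = self.atlas.active_layer
        i, j, k = _check_ijk(self.atlas, ijk)
        label_id = int(layer.label_volume.ids[i, j, k])
        if label_id == layer.label_volume.background_id:
            logger.info("click at %s hit background", (i, j, k))
            return
        kind = (
            "deselect"
            if label_id in self.state.layer_selected(self.atlas.active_index)
            else "select"
        )
        self.bus.publish(AtlasEvent(kind, self.atlas.active_index, (label_id,)))

    def select_ids(self, layer_index: int, ids, deselect: bool = False) -> None:
        kind = "deselect" if deselect else "select"
        self.bus.publish(AtlasEvent(kind, layer_index, tuple(sorted(ids))))

    # -- graph-side actions ----------------------------------------------
    def graph_select_node(self, layer_index: int, node_id: int, deselect: bool = False) -> None:
        """Select (or deselect) a graph node: expands to its whole subtree."""
        labelset = self.atlas.label_layers[layer_index].label_set
        ids = descendants(labelset, node_id)
        kind = "deselect" if deselect else "select"
        self.bus.publish(AtlasEvent(kind, layer_index, tuple(sorted(ids))))

    # -- search handoff ---------------------------------------------------
    def send_selection_to_search(self) -> None:
        layer_index = self.atlas.active_index
        labelset = self.atlas.label_layers[layer_index].label_set
        names = tuple(
            labelset.index[i].name
            for i in sorted(self.state.layer_selected(layer_index))
            if i in labelset
        )
        self.bus.publish(AtlasEvent("send_names_to_search", layer_index, names))

    def send_location_to_search(self, ijk) -> None:
        _check_ijk(self.atlas, ijk)
        geom = self.atlas.reference or ImageVolume(self.atlas.label_layers[0].label_volume.ids)
        xyz = vio.voxel_to_world(geom, ijk)
        self.bus.publish(
            AtlasEvent("send_location_to_search", self.atlas.active_index, tuple(xyz))
        )
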