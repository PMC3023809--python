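"""Atlas model: bundle I/O, lookup, selection, masking, overlay, and the
bidirectional atlas <-> graph synchronization."""

import numpy as np
import pytest

from atlaskit import atlas as atl
from atlaskit import hierarchy as hi
from atlaskit import synthetic_fixtures as sf
from atlaskit.atlas import AtlasEvent, EventBus, SelectionState, SyncedWorkspace
from atlaskit.errors import BoundsError, StateError
from atlaskit.hierarchy import LabelNode, LabelSet
from atlaskit.volume_io import SliceSpec


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

def test_save_load_roundtrip(tmp_path, atlas):
    atl.save_atlas(atlas, tmp_path / "b.atlas")
    back = atl.load_atlas(tmp_path / "b.atlas")
    assert len(back.label_layers) == len(atlas.label_layers) == 2
    assert back.active_index == atlas.active_index
    assert back.load_warnings == []
    for la, lb in zip(atlas.label_layers, back.label_layers):
        assert np.array_equal(la.label_volume.ids, lb.label_volume.ids)
        assert set(la.label_set.index) == set(lb.label_set.index)
    assert np.allclose(back.reference.data, atlas.reference.data)


def test_load_warns_on_unresolvable_label(tmp_path, atlas):
    ids = atlas.label_layers[0].label_volume.ids.copy()
    ids[0, 0, 0] = 99  # not in the hierarchy
    bad = atl.Atlas(
        label_layers=[atl.LabelLayer(atl.LabelVolume(ids),
                                     atlas.label_layers[0].label_set)],
        reference=atlas.reference,
    )
    atl.save_atlas(bad, tmp_path / "warn.atlas")
    back = atl.load_atlas(tmp_path / "warn.atlas")
    assert any("99" in w for w in back.load_warnings)


# ---------------------------------------------------------------------------
# Lookup
# ---------------------------------------------------------------------------

def test_labels_at_background_voxel_empty(atlas):
    assert atl.labels_at(atlas, (0, 0, 0)) == []


def test_labels_at_active_layer_first(atlas):
    # find a voxel labeled in both layers
    both = (atlas.label_layers[0].label_volume.ids > 0) & \
           (atlas.label_layers[1].label_volume.ids > 0)
    ijk = tuple(int(v) for v in np.argwhere(both)[0])
    atlas.active_index = 0
    rows = atl.labels_at(atlas, ijk)
    assert [r[0] for r in rows] == ["anatomic", "functional"]
    atlas.active_index = 1
    rows = atl.labels_at(atlas, ijk)
    assert [r[0] for r in rows] == ["functional", "anatomic"]
    atlas.active_index = 0


def test_labels_at_matches_dictionary_oracle(atlas, rng):
    for _ in range(50):
        ijk = tuple(int(v) for v in rng.integers(0, atlas.shape))
        rows = atl.labels_at(atlas, ijk)
        oracle = []
        order = [atlas.active_index] + [
            n for n in range(len(atlas.label_layers)) if n != atlas.active_index
        ]
        for n in order:
            layer = atlas.label_layers[n]
            lid = int(layer.label_volume.ids[ijk])
            if lid != 0 and lid in layer.label_set:
                node = layer.label_set.index[lid]
                oracle.append((layer.label_set.set_name, lid, node.abbrev,
                               node.name, node.color))
        assert rows == oracle


def test_labels_at_out_of_grid(atlas):
    with pytest.raises(BoundsError):
        atl.labels_at(atlas, (99, 0, 0))


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def test_toggle_label_is_involution(atlas):
    fg = np.argwhere(atlas.label_layers[0].label_volume.ids > 0)
    ijk = tuple(int(v) for v in fg[0])
    lid = int(atlas.label_layers[0].label_volume.ids[ijk])
    s0 = SelectionState()
    s1 = atl.toggle_label(s0, atlas, ijk)
    assert lid in s1.layer_selected(0)
    s2 = atl.toggle_label(s1, atlas, ijk)
    assert s2.layer_selected(0) == s0.layer_selected(0) == set()
    # layer isolation: layer 1 selection untouched throughout
    assert s1.layer_selected(1) == set()


def test_toggle_background_is_noop(atlas):
    s = SelectionState()
    s.layer_selected(0).add(3)
    out = atl.toggle_label(s, atlas, (0, 0, 0))
    assert out.layer_selected(0) == {3}


def test_select_subtree_matches_dfs_oracle(atlas):
    labelset = atlas.label_layers[0].label_set
    root_id = labelset.roots[0].id
    s = atl.select_subtree(SelectionState(), atlas, 0, root_id)
    assert s.layer_selected(0) == hi.descendants(labelset, root_id) == set(labelset.index)
    leaf = next(n for n in labelset.index.values() if not n.children)
    s2 = atl.select_subtree(SelectionState(), atlas, 0, leaf.id)
    assert s2.layer_selected(0) == {leaf.id}


def test_select_subtree_idempotent_and_monotone(atlas):
    labelset = atlas.label_layers[0].label_set
    nid = labelset.roots[0].children[0].id
    s1 = atl.select_subtree(SelectionState(), atlas, 0, nid)
    s2 = atl.select_subtree(s1, atlas, 0, nid)
    assert s1.layer_selected(0) == s2.layer_selected(0)
    assert s1.layer_selected(0) <= atl.select_subtree(s1, atlas, 0,
                                                      labelset.roots[0].id).layer_selected(0)


# ---------------------------------------------------------------------------
# Masks and overlay
# ---------------------------------------------------------------------------

def test_region_mask_against_membership_oracle(atlas, rng):
    ids = atlas.label_layers[0].label_volume.ids
    subset = {2, 5}
    mask = atl.region_mask(atlas, 0, subset)
    oracle = np.zeros_like(ids, dtype=bool)
    it = np.nditer(ids, flags=["multi_index"])
    for v in it:
        oracle[it.multi_index] = int(v) in subset
    assert np.array_equal(mask, oracle)
    assert not atl.region_mask(atlas, 0, set()).any()
    all_ids = {int(v) for v in np.unique(ids)} - {0}
    assert np.array_equal(atl.region_mask(atlas, 0, all_ids), ids != 0)


def test_mask_background(atlas):
    masked = atl.mask_background(atlas)
    lv = atlas.active_layer.label_volume
    assert np.all(masked.data[lv.ids == 0] == 0)
    assert np.array_equal(masked.data[lv.ids != 0],
                          atlas.reference.data[lv.ids != 0])
    no_ref = atl.Atlas(label_layers=atlas.label_layers)
    with pytest.raises(StateError):
        atl.mask_background(no_ref)


def _overlay_oracle(atlas, state, spec, opacity):
    layer = atlas.active_layer
    plane = np.take(layer.label_volume.ids, spec.index, axis=spec.axis)
    labelset = layer.label_set
    selected = state.layer_selected(atlas.active_index)
    if selected:
        visible = set()
        for sid in selected:
            visible |= hi.descendants(labelset, sid)
    else:
        visible = set(labelset.index)
    out = np.zeros(plane.shape + (4,))
    for a in range(plane.shape[0]):
        for b in range(plane.shape[1]):
            lid = int(plane[a, b])
            if lid != 0 and lid in labelset.index and lid in visible:
                node = labelset.index[lid]
                out[a, b] = [node.color[0] / 255, node.color[1] / 255,
                             node.color[2] / 255, opacity]
    return out


def test_overlay_matches_per_pixel_oracle(atlas):
    labelset = atlas.label_layers[0].label_set
    some = list(labelset.index)[:2]
    for sel in (set(), set(some)):
        state = SelectionState()
        state.layer_selected(0).update(sel)
        spec = SliceSpec(2, atlas.shape[2] // 2)
        img = atl.render_label_overlay(atlas, state, spec, opacity=0.8)
        assert np.allclose(img.pixels, _overlay_oracle(atlas, state, spec, 0.8))


def test_overlay_opacity_zero_transparent(atlas):
    img = atl.render_label_overlay(atlas, SelectionState(), SliceSpec(2, 8), opacity=0.0)
    assert np.all(img.pixels[:, :, 3] == 0)


def test_overlay_single_structure_exact_color():
    node = LabelNode(1, "r", "Red region", (255, 0, 0))
    ids = np.zeros((4, 4, 4), dtype=np.int16)
    ids[1:3, 1:3, :] = 1
    a = atl.Atlas(label_layers=[atl.LabelLayer(atl.LabelVolume(ids),
                                               LabelSet("s", roots=[node]))])
    state = SelectionState()
    state.layer_selected(0).add(1)
    img = atl.render_label_overlay(a, state, SliceSpec(2, 0), opacity=1.0)
    assert np.array_equal(img.pixels[1, 1], [1.0, 0.0, 0.0, 1.0])
    assert np.array_equal(img.pixels[0, 0], [0.0, 0.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# Event bus and synchronization
# ---------------------------------------------------------------------------

def test_publish_without_subscribers_is_logged():
    bus = EventBus()
    ev = AtlasEvent("select", 0, (1,))
    bus.publish(ev)
    assert bus.log == [ev]


def test_handler_exception_does_not_block_others():
    bus = EventBus()
    seen = []
    bus.subscribe(lambda ev: (_ for _ in ()).throw(RuntimeError("boom")))
    bus.subscribe(lambda ev: seen.append(ev.kind))
    bus.publish(AtlasEvent("select", 0, (1,)))
    assert seen == ["select"]


def test_atlas_select_highlights_graph(atlas):
    ws = SyncedWorkspace(atlas)
    fg = np.argwhere(atlas.label_layers[0].label_volume.ids > 0)
    ijk = tuple(int(v) for v in fg[0])
    lid = int(atlas.label_layers[0].label_volume.ids[ijk])
    ws.click_voxel(ijk)
    assert lid in ws.graph_highlights[0]
    assert ws.state.layer_selected(0) == ws.graph_highlights[0]
    ws.click_voxel(ijk)  # toggle off propagates too
    assert lid not in ws.graph_highlights[0]


def test_graph_parent_selection_selects_subtree(atlas):
    ws = SyncedWorkspace(atlas)
    labelset = atlas.label_layers[0].label_set
    root_id = labelset.roots[0].id
    ws.graph_select_node(0, root_id)
    assert ws.state.layer_selected(0) == set(labelset.index)
    assert ws.graph_highlights[0] == set(labelset.index)


def test_bidirectional_sync_random_sequences(atlas, rng):
    """After any mixed sequence of atlas- and graph-side (de)selections,
    atlas selection and graph highlights are identical sets."""
    labelset = atlas.label_layers[0].label_set
    all_ids = sorted(labelset.index)
    fg = np.argwhere(atlas.label_layers[0].label_volume.ids > 0)
    for _ in range(60):
        ws = SyncedWorkspace(atlas)
        for _ in range(int(rng.integers(1, 12))):
            action = rng.integers(0, 3)
            if action == 0:
                ws.click_voxel(tuple(int(v) for v in fg[rng.integers(0, len(fg))]))
            elif action == 1:
                ws.graph_select_node(0, int(rng.choice(all_ids)),
                                     deselect=bool(rng.integers(0, 2)))
            else:
                ws.select_ids(0, {int(rng.choice(all_ids))},
                              deselect=bool(rng.integers(0, 2)))
        assert ws.state.layer_selected(0) == ws.graph_highlights.get(0, set())


def test_send_selection_and_location_to_search(atlas):
    ws = SyncedWorkspace(atlas)
    labelset = atlas.label_layers[0].label_set
    nid = labelset.roots[0].id
    ws.select_ids(0, {nid})
    ws.send_selection_to_search()
    assert ws.search_inbox[-1] == {"keywords": [labelset.index[nid].name]}
    ws.send_location_to_search((2, 3, 4))
    loc = ws.search_inbox[-1]["location"]
    assert loc == tuple(float(v) for v in (2, 3, 4))  # identity geometry
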