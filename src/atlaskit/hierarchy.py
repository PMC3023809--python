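"""Hierarchical label sets: parsing, traversal, search, and graph layout.

A *label set* is a single-parent tree of labeled regions, each carrying an
integer id, a short abbreviation, a full name and an RGB display color.  An
atlas may attach several label sets to the same space (e.g. an anatomic and
a functional context).

Two on-disk formats are supported:

* **ILF dialect** — an XML document: root element ``<labelset name="...">``
  containing nested ``<label id=".." abbrev=".." name=".." color="R,G,B">``
  elements whose nesting encodes parentage.
* **OBO 1.2** — term stanzas with ``is_a`` edges, parsed through obonet.
  ``is_a`` must reduce to a tree: terms with several parents keep the
  lexically first parent and a warning records each dropped edge.

Layouts place every node deterministically: the radial layout puts each
generation on concentric circles, the linear layout puts each generation in
a column to the right of the previous one.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet
from lxml import etree

from .errors import StructureError, ValidationError

__all__ = [
    "LabelNode",
    "LabelSet",
    "GraphLayout",
    "parse_ilf",
    "write_ilf",
    "parse_obo",
    "descendants",
    "search_labels",
    "layout_radial",
    "layout_linear",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class LabelNode:
    """One labeled region: id, abbreviation, full name, RGB color, children."""

    id: int
    abbrev: str
    name: str
    color: tuple[int, int, int]
    children: list["LabelNode"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.id < 0:
            raise ValidationError(f"label id must be non-negative, got {self.id}")
        c = tuple(int(v) for v in self.color)
        if len(c) != 3 or any(not (0 <= v <= 255) for v in c):
            raise ValidationError(f"color must be an RGB triple of ints 0-255, got {self.color}")
        self.color = c


@dataclass
class LabelSet:
    """A named forest of :class:`LabelNode` with an id -> node index."""

    set_name: str
    roots: list[LabelNode]
    index: dict[int, LabelNode] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = self._build_index()

    def _build_index(self) -> dict[int, LabelNode]:
        index: dict[int, LabelNode] = {}
        stack = list(self.roots)
        while stack:
            node = stack.pop()
            if node.id in index:
                raise ValidationError(f"duplicate label id {node.id} in set {self.set_name!r}")
            index[node.id] = node
            stack.extend(node.children)
        return index

    def parent_map(self) -> dict[int, int | None]:
        parents: dict[int, int | None] = {r.id: None for r in self.roots}
        stack = list(self.roots)
        while stack:
            node = stack.pop()
            for ch in node.children:
                parents[ch.id] = node.id
                stack.append(ch)
        return parents

    def depth_map(self) -> dict[int, int]:
        depths: dict[int, int] = {}
        stack = [(r, 0) for r in self.roots]
        while stack:
            node, d = stack.pop()
            depths[node.id] = d
            stack.extend((ch, d + 1) for ch in node.children)
        return depths

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, label_id: int) -> bool:
        return label_id in self.index


@dataclass
class GraphLayout:
    """Node positions for a label-set drawing; one (x, y) per node id."""

    positions: dict[int, tuple[float, float]]
    style: str  # 'radial' or 'linear'


# ---------------------------------------------------------------------------
# ILF dialect
# ---------------------------------------------------------------------------

def _node_from_element(el) -> LabelNode:
    line = el.sourceline
    try:
        node_id = int(el.get("id"))
    except (TypeError, ValueError):
        raise ValidationError(f"line {line}: label element missing valid integer 'id'")
    color_attr = el.get("color", "")
    parts = color_attr.split(",")
    try:
        color = tuple(int(p.strip()) for p in parts)
        if len(color) != 3 or any(not (0 <= v <= 255) for v in color):
            raise ValueError
    except ValueError:
        raise ValidationError(
            f"line {line}: malformed color {color_attr!r} (expected 'R,G,B' with 0-255)"
        )
    node = LabelNode(
        id=node_id,
        abbrev=el.get("abbrev", ""),
        name=el.get("name", ""),
        color=color,
    )
    for child in el:
        if child.tag == "label":
            node.children.append(_node_from_element(child))
    return node


def parse_ilf(path: str | os.PathLike) -> LabelSet:
    """Parse an ILF-dialect XML file into a :class:`LabelSet`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ILF file not found: {path}")
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValidationError(f"malformed ILF XML in {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "labelset":
        raise ValidationError(f"{path}: root element must be <labelset>, got <{root.tag}>")
    roots = [_node_from_element(el) for el in root if el.tag == "label"]
    return LabelSet(set_name=root.get("name", path.stem), roots=roots)


def _element_from_node(node: LabelNode, parent) -> None:
    el = etree.SubElement(parent, "label")
    el.set("id", str(node.id))
    el.set("abbrev", node.abbrev)
    el.set("name", node.name)
    el.set("color", ",".join(str(c) for c in node.color))
    for ch in node.children:
        _element_from_node(ch, el)


def write_ilf(labelset: LabelSet, path: str | os.PathLike) -> Path:
    """Write a label set as ILF-dialect XML; round-trips with parse_ilf."""
    root = etree.Element("labelset")
    root.set("name", labelset.set_name)
    for node in labelset.roots:
        _element_from_node(node, root)
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="utf-8")
    return Path(path)


# ---------------------------------------------------------------------------
# OBO
# ---------------------------------------------------------------------------

_PALETTE_PRIMES = (97, 57, 31)


def _auto_color(i: int) -> tuple[int, int, int]:
    # distinct, deterministic pseudo-colors; avoid pure black (background-ish)
    return tuple((37 + i * p) % 255 for p in _PALETTE_PRIMES)


def parse_obo(path: str | os.PathLike, set_name: str | None = None) -> LabelSet:
    """Parse an OBO 1.2 ontology into a single-parent label tree.

    ``is_a`` edges define parentage (child ``is_a`` parent).  Terms with
    multiple parents keep only the lexically first parent; each dropped edge
    is recorded in ``LabelSet.warnings``.  Integer label ids come from an
    optional ``idmap: <term> <int>`` header line per term, otherwise from
    sequential assignment over lexically sorted term ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"OBO file not found: {path}")
    graph = obonet.read_obo(str(path))

    # cycle check on is_a (obonet edges run child -> parent)
    try:
        cycle = nx.find_cycle(graph, orientation="original")
        raise StructureError(
            "cyclic is_a relationship: " + " -> ".join(str(e[0]) for e in cycle)
        )
    except nx.NetworkXNoCycle:
        pass

    terms = sorted(graph.nodes)
    # optional explicit id map from header lines "idmap: TERM INT"
    id_map: dict[str, int] = {}
    for ln in path.read_text().splitlines():
        if ln.startswith("idmap:"):
            parts = ln.split(None, 2)[1:]
            if len(parts) == 2:
                id_map[parts[0]] = int(parts[1])
        if ln.startswith("[Term]"):
            break
    next_id = (max(id_map.values()) + 1) if id_map else 1
    for t in terms:
        if t not in id_map:
            id_map[t] = next_id
            next_id += 1

    warnings: list[str] = []
    chosen_parent: dict[str, str] = {}
    for t in terms:
        parents = sorted(v for _, v, k in graph.out_edges(t, keys=True) if k == "is_a")
        if parents:
            chosen_parent[t] = parents[0]
            for dropped in parents[1:]:
                warnings.append(f"dropped is_a edge {t} -> {dropped} (multiple parents)")

    nodes: dict[str, LabelNode] = {}
    for i, t in enumerate(terms):
        data = graph.nodes[t]
        nodes[t] = LabelNode(
            id=id_map[t],
            abbrev=t,
            name=data.get("name", t),
            color=_auto_color(i),
        )
    roots = []
    for t in terms:
        p = chosen_parent.get(t)
        if p is None:
            roots.append(nodes[t])
        else:
            nodes[p].children.append(nodes[t])

    ls = LabelSet(set_name=set_name or path.stem, roots=roots)
    ls.warnings = warnings
    return ls


# ---------------------------------------------------------------------------
# Traversal and search
# ---------------------------------------------------------------------------

def descendants(labelset: LabelSet, label_id: int) -> set[int]:
    """All ids at or below ``label_id`` (inclusive of the query node).

    Inclusive so that selecting a parent structure selects the structure
    itself along with every substructure.
    """
    if label_id not in labelset.index:
        raise KeyError(f"unknown label id {label_id} in set {labelset.set_name!r}")
    out: set[int] = set()
    stack = [labelset.index[label_id]]
    while stack:
        node = stack.pop()
        out.add(node.id)
        stack.extend(node.children)
    return out


def search_labels(labelset: LabelSet, pattern: str) -> set[int]:
    """Ids whose abbreviation or full name contains ``pattern``
    (case-insensitive plain substring)."""
    if not pattern:
        raise ValidationError("search pattern must be non-empty")
    pat = pattern.lower()
    return {
        node.id
        for node in labelset.index.values()
        if pat in node.abbrev.lower() or pat in node.name.lower()
    }


# ---------------------------------------------------------------------------
# Layouts
# ---------------------------------------------------------------------------

def _leaf_counts(labelset: LabelSet) -> dict[int, int]:
    counts: dict[int, int] = {}

    def rec(node: LabelNode) -> int:
        if not node.children:
            counts[node.id] = 1
            return 1
        n = sum(rec(ch) for ch in node.children)
        counts[node.id] = n
        return n

    for r in labelset.roots:
        rec(r)
    return counts


def layout_radial(labelset: LabelSet, ring_spacing: float = 1.0) -> GraphLayout:
    """Place each generation on concentric circles.

    Roots sit at the origin; a node at depth *g* sits at radius
    ``g * ring_spacing``.  Each child is assigned an angular sector nested
    within (and proportional by leaf count to) its parent's sector, and is
    drawn at the sector's bisector; ties break by child order in the file.
    """
    if not labelset.roots:
        raise ValidationError("cannot lay out an empty label set")
    counts = _leaf_counts(labelset)
    positions: dict[int, tuple[float, float]] = {}
    total_leaves = sum(counts[r.id] for r in labelset.roots)

    def place(node: LabelNode, depth: int, a0: float, a1: float) -> None:
        if depth == 0:
            positions[node.id] = (0.0, 0.0)
        else:
            mid = 0.5 * (a0 + a1)
            r = depth * ring_spacing
            positions[node.id] = (r * math.cos(mid), r * math.sin(mid))
        start = a0
        for ch in node.children:
            width = (a1 - a0) * counts[ch.id] / counts[node.id] if counts[node.id] else 0.0
            place(ch, depth + 1, start, start + width)
            start += width

    start = 0.0
    for r in labelset.roots:
        width = 2.0 * math.pi * counts[r.id] / total_leaves
        place(r, 0, start, start + width)
        start += width
    return GraphLayout(positions=positions, style="radial")


def layout_linear(labelset: LabelSet, column_spacing: float = 1.0) -> GraphLayout:
    """Place each generation in a column right of the previous generation.

    ``x = depth * column_spacing``; leaves get consecutive integer y values
    in depth-first order, internal nodes sit at the mean y of their children.
    """
    if not labelset.roots:
        raise ValidationError("cannot lay out an empty label set")
    positions: dict[int, tuple[float, float]] = {}
    next_leaf_y = 0

    def place(node: LabelNode, depth: int) -> float:
        nonlocal next_leaf_y
        x = depth * column_spacing
        if not node.children:
            y = float(next_leaf_y)
            next_leaf_y += 1
        else:
            ys = [place(ch, depth + 1) for ch in node.children]
            y = sum(ys) / len(ys)
        positions[node.id] = (x, y)
        return y

    for r in labelset.roots:
        place(r, 0)
    return GraphLayout(positions=positions, style="linear")
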