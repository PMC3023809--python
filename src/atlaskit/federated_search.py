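"""Federated search: one query fanned out to pluggable data sources.

A :class:`Query` carries free-text keywords and/or structured ``(field,
value)`` terms plus the list of sources to hit.  Each registered
:class:`DataSource` declares which search types it supports (``keyword``,
``query_term``) and what data types it returns; the engine routes each
source only the parts of the query it can handle, isolates per-source
failures, and merges everything into a :class:`ResultTable` grouped by
``(source, data_type)``.

Result records are immutable bags of annotations (text, numbers, URLs) with
optional thumbnail/payload locators.  The table supports view-level column
operations (sort, hide/show, reorder, expand/collapse groups) that never
alter record content, and any record can be placed in the global
:class:`Cart` shared by the other workspaces.

Three built-in source types keep the architecture testable offline: a
directory-of-images source (keyword match on filenames and sidecar
annotations), a delimited-table source (query-term match on named columns),
and an in-memory mock literature source.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import pandas as pd

from .errors import ConfigurationError, BoundsError, ValidationError

__all__ = [
    "Query",
    "DataSource",
    "ResultRecord",
    "ResultTable",
    "Cart",
    "SourceRegistry",
    "run_query",
    "sort_by",
    "set_visible",
    "reorder",
    "set_expanded",
    "visible_columns",
    "display_records",
    "DirectoryImageSource",
    "TableSource",
    "MockLiteratureSource",
    "query_from_atlas",
]

SEARCH_TYPES = {"keyword", "query_term"}


# ---------------------------------------------------------------------------
# Query and records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Query:
    """Keywords and/or (field, value) terms addressed to selected sources."""

    keywords: tuple[str, ...] = ()
    terms: tuple[tuple[str, str], ...] = ()
    selected_sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "keywords", tuple(self.keywords))
        object.__setattr__(self, "terms", tuple(tuple(t) for t in self.terms))
        object.__setattr__(self, "selected_sources", tuple(self.selected_sources))
        if not self.keywords and not self.terms:
            raise ValidationError("query needs at least one keyword or term")
        if not self.selected_sources:
            raise ValidationError("query needs at least one selected source")


@dataclass(frozen=True)
class ResultRecord:
    """One annotation record returned by a source; immutable."""

    source: str
    data_type: str
    annotations: tuple[tuple[str, object], ...]
    thumbnail_ref: str | None = None
    payload_ref: str | None = None

    def __post_init__(self) -> None:
        ann = tuple((str(k), v) for k, v in self.annotations)
        names = [k for k, _ in ann]
        if len(names) != len(set(names)):
            raise ValidationError(f"duplicate annotation names in record: {names}")
        object.__setattr__(self, "annotations", ann)

    @property
    def annotation_map(self) -> dict[str, object]:
        return dict(self.annotations)

    def get(self, name: str, default=None):
        return self.annotation_map.get(name, default)


@dataclass
class DataSource:
    """Service-provider contract for a searchable data source.

    ``execute`` must be a pure read: it receives a query already narrowed to
    the search types this source declares and returns result records.  The
    backing storage and access method are unconstrained.
    """

    name: str
    search_types: set[str]
    data_types: list[str]
    execute: Callable[[Query], list[ResultRecord]]

    def __post_init__(self) -> None:
        bad = set(self.search_types) - SEARCH_TYPES
        if bad:
            raise ValidationError(f"unknown search types {sorted(bad)} for source {self.name!r}")


class SourceRegistry:
    """Named registry of data sources."""

    def __init__(self) -> None:
        self._sources: dict[str, DataSource] = {}

    def register(self, source: DataSource) -> None:
        if source.name in self._sources:
            raise ConfigurationError(f"source {source.name!r} is already registered")
        self._sources[source.name] = source

    def get(self, name: str) -> DataSource:
        return self._sources[name]

    def names(self) -> list[str]:
        return sorted(self._sources)

    def __contains__(self, name: str) -> bool:
        return name in self._sources


# ---------------------------------------------------------------------------
# Result table
# ---------------------------------------------------------------------------

@dataclass
class ColumnState:
    """Per-group view state; never touches record content."""

    order: list[str]
    hidden: set[str] = field(default_factory=set)
    sort_key: str | None = None
    sort_ascending: bool = True
    expanded: bool = True
    display_order: list[int] = field(default_factory=list)  # record indices


@dataclass
class ResultTable:
    """Query results grouped by (source, data_type) plus per-source status."""

    groups: dict[tuple[str, str], list[ResultRecord]] = field(default_factory=dict)
    column_state: dict[tuple[str, str], ColumnState] = field(default_factory=dict)
    source_status: dict[str, str] = field(default_factory=dict)

    def all_records(self) -> list[ResultRecord]:
        return [r for recs in self.groups.values() for r in recs]


def _group_schema(records: list[ResultRecord]) -> list[str]:
    cols: list[str] = []
    for r in records:
        for k, _ in r.annotations:
            if k not in cols:
                cols.append(k)
    return cols


def run_query(query: Query, registry: SourceRegistry) -> ResultTable:
    """Fan a query out to its selected sources and merge the results.

    Each source receives only the search types it declares (keyword-only
    sources see keywords, term sources see terms).  A source that supports
    none of the query's populated parts is skipped with status
    ``"unsupported search type"``; a source that raises gets status
    ``failed: <message>`` without affecting any other group.  Groups are
    sorted by source name then data type, so the table is a deterministic
    function of the per-source result sets.
    """
    missing = [s for s in query.selected_sources if s not in registry]
    if missing:
        raise ConfigurationError(f"selected sources not registered: {missing}")

    table = ResultTable()
    per_source: dict[str, list[ResultRecord]] = {}
    for name in query.selected_sources:
        source = registry.get(name)
        kw = query.keywords if "keyword" in source.search_types else ()
        terms = query.terms if "query_term" in source.search_types else ()
        if not kw and not terms:
            table.source_status[name] = "unsupported search type"
            continue
        narrowed = Query(keywords=kw or (), terms=terms or (),
                         selected_sources=(name,)) if (kw or terms) else None
        try:
            records = list(source.execute(narrowed))
            table.source_status[name] = "ok"
            per_source[name] = records
        except Exception as exc:
            table.source_status[name] = f"failed: {exc}"

    for name in sorted(per_source):
        for rec in per_source[name]:
            table.groups.setdefault((rec.source, rec.data_type), []).append(rec)
    table.groups = dict(sorted(table.groups.items()))
    for key, recs in table.groups.items():
        table.column_state[key] = ColumnState(
            order=_group_schema(recs), display_order=list(range(len(recs)))
        )
    return table


# -- view operations --------------------------------------------------------

def _state(table: ResultTable, group: tuple[str, str]) -> ColumnState:
    if group not in table.groups:
        raise KeyError(f"no result group {group}; have {sorted(table.groups)}")
    return table.column_state[group]


def sort_by(table: ResultTable, group: tuple[str, str], column: str,
            ascending: bool = True) -> None:
    """Stable sort of a group's display order by an annotation column;
    records missing the column sort last regardless of direction."""
    st = _state(table, group)
    if column not in st.order:
        raise KeyError(f"unknown column {column!r} in group {group}")
    recs = table.groups[group]

    present = [i for i in st.display_order if recs[i].get(column) is not None]
    absent = [i for i in st.display_order if recs[i].get(column) is None]
    present.sort(key=lambda i: recs[i].get(column), reverse=not ascending)
    st.display_order = present + absent
    st.sort_key = column
    st.sort_ascending = ascending


def set_visible(table: ResultTable, group: tuple[str, str], column: str,
                visible: bool) -> None:
    st = _state(table, group)
    if column not in st.order:
        raise KeyError(f"unknown column {column!r} in group {group}")
    (st.hidden.discard if visible else st.hidden.add)(column)


def reorder(table: ResultTable, group: tuple[str, str], new_order: list[str]) -> None:
    st = _state(table, group)
    if sorted(new_order) != sorted(st.order):
        raise KeyError(
            f"new order must be a permutation of {st.order}, got {new_order}"
        )
    st.order = list(new_order)


def set_expanded(table: ResultTable, group: tuple[str, str], expanded: bool) -> None:
    _state(table, group).expanded = expanded


def visible_columns(table: ResultTable, group: tuple[str, str]) -> list[str]:
    st = _state(table, group)
    return [c for c in st.order if c not in st.hidden]


def display_records(table: ResultTable, group: tuple[str, str]) -> list[ResultRecord]:
    """The group's records in current display order (content untouched)."""
    st = _state(table, group)
    recs = table.groups[group]
    return [recs[i] for i in st.display_order]


# ---------------------------------------------------------------------------
# Cart
# ---------------------------------------------------------------------------

class Cart:
    """Global FIFO container carrying results between workspaces.

    Duplicates are allowed but flagged; items survive new queries.
    """

    def __init__(self) -> None:
        self._items: list[ResultRecord] = []

    def add(self, record: ResultRecord) -> bool:
        """Append a record; returns True if it duplicates an existing item."""
        duplicate = record in self._items
        self._items.append(record)
        return duplicate

    def remove(self, index: int) -> ResultRecord:
        if not (0 <= index < len(self._items)):
            raise BoundsError(f"cart index {index} out of range [0, {len(self._items)})")
        return self._items.pop(index)

    def list(self) -> list[ResultRecord]:
        return list(self._items)

    def __len__(self) -> int:
        return len(self._items)

    # -- persistence so CLI sessions can hand results across commands ------
    def save(self, path: str | os.PathLike) -> Path:
        doc = [
            {
                "source": r.source,
                "data_type": r.data_type,
                "annotations": [[k, v] for k, v in r.annotations],
                "thumbnail_ref": r.thumbnail_ref,
                "payload_ref": r.payload_ref,
            }
            for r in self._items
        ]
        Path(path).write_text(json.dumps(doc, indent=2))
        return Path(path)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "Cart":
        cart = cls()
        if Path(path).exists():
            for entry in json.loads(Path(path).read_text()):
                cart._items.append(ResultRecord(
                    source=entry["source"],
                    data_type=entry["data_type"],
                    annotations=tuple((k, v) for k, v in entry["annotations"]),
                    thumbnail_ref=entry.get("thumbnail_ref"),
                    payload_ref=entry.get("payload_ref"),
                ))
        return cart


# ---------------------------------------------------------------------------
# Built-in sources
# ---------------------------------------------------------------------------

def _keywords_match(keywords: Iterable[str], haystack: str) -> bool:
    # AND across keywords, case-insensitive substring
    hay = haystack.lower()
    return all(k.lower() in hay for k in keywords)


def DirectoryImageSource(name: str, path: str | os.PathLike,
                         data_type: str = "2D Image") -> DataSource:
    """A keyword source over a directory of images.

    Keywords match (AND, case-insensitive) against the filename plus the
    content of an optional ``<stem>.txt`` sidecar annotation file.  Records
    carry the file path as payload and thumbnail locator.
    """
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"image directory not found: {root}")

    def execute(query: Query) -> list[ResultRecord]:
        records = []
        exts = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}
        for f in sorted(root.iterdir()):
            if f.suffix.lower() not in exts:
                continue
            sidecar = f.with_suffix(".txt")
            extra = sidecar.read_text() if sidecar.exists() else ""
            if not _keywords_match(query.keywords, f.name + " " + extra):
                continue
            ann = [("filename", f.name)]
            if extra:
                ann.append(("description", extra.strip()))
            records.append(ResultRecord(
                source=name, data_type=data_type, annotations=tuple(ann),
                thumbnail_ref=str(f), payload_ref=str(f),
            ))
        return records

    return DataSource(name=name, search_types={"keyword"},
                      data_types=[data_type], execute=execute)


def TableSource(name: str, path: str | os.PathLike,
                data_type: str = "Table Row") -> DataSource:
    """A query-term source over a delimited table (CSV/TSV).

    Each term ``(field, value)`` filters on the named column
    (case-insensitive equality); terms combine with AND.  Every matching row
    becomes a record whose annotations are the row's cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table file not found: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")

    def execute(query: Query) -> list[ResultRecord]:
        sub = df
        for fld, value in query.terms:
            if fld not in sub.columns:
                raise KeyError(f"table source {name!r} has no column {fld!r}")
            sub = sub[sub[fld].str.lower() == str(value).lower()]
        return [
            ResultRecord(
                source=name, data_type=data_type,
                annotations=tuple((c, row[c]) for c in df.columns),
                payload_ref=f"{path}#row{idx}",
            )
            for idx, row in sub.iterrows()
        ]

    return DataSource(name=name, search_types={"query_term"},
                      data_types=[data_type], execute=execute)


def MockLiteratureSource(name: str, records: list[dict]) -> DataSource:
    """An in-memory keyword source of publication-like records (each a dict
    with at least ``title``; extra keys become annotations)."""

    def execute(query: Query) -> list[ResultRecord]:
        out = []
        for rec in records:
            hay = " ".join(str(v) for v in rec.values())
            if _keywords_match(query.keywords, hay):
                out.append(ResultRecord(
                    source=name, data_type="Publication",
                    annotations=tuple(rec.items()),
                ))
        return out

    return DataSource(name=name, search_types={"keyword"},
                      data_types=["Publication"], execute=execute)


# ---------------------------------------------------------------------------
# Atlas -> search handoff
# ---------------------------------------------------------------------------

def query_from_atlas(
    selected_names: Iterable[str] = (),
    location_world: Iterable[float] | None = None,
    selected_sources: Iterable[str] = (),
    extra_keywords: Iterable[str] = (),
    extra_terms: Iterable[tuple[str, str]] = (),
) -> Query:
    """Build a query from atlas context: selected structure names become
    keywords; a world location becomes a ``("location", "x,y,z")`` term."""
    keywords = tuple(selected_names) + tuple(extra_keywords)
    terms = tuple(tuple(t) for t in extra_terms)
    if location_world is not None:
        loc = ",".join(str(float(v)) for v in location_world)
        terms = terms + (("location", loc),)
    if not keywords and not terms:
        raise ValidationError("atlas handoff needs a selection or a location")
    return Query(keywords=keywords, terms=terms,
                 selected_sources=tuple(selected_sources) or ("*",))
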