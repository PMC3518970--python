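"""Hierarchical region nomenclature.

Meso-scale connectomes are defined over a rooted "is part" tree of named
brain regions.  A *view* of the hierarchy selects which subtrees are
collapsed; the leaves of the viewed tree, in depth-first document order,
give the canonical row/column order for every matrix the analysis
produces.  Collapsing a branch turns it into a leaf and hides its whole
subtree; connection records attached below a collapsed branch aggregate
up to it.

The document format is JSON: nested objects with ``id``, optional
``name``/``abbreviation``/``color``/``laterality_side``, and a
``children`` list.  Child order in the document is meaningful and is
never re-sorted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "Region",
    "RegionHierarchy",
    "HierarchyError",
    "CycleError",
    "MultipleRootsError",
    "DuplicateIdError",
    "UnknownRegionError",
    "load_hierarchy",
    "leaves_at_view",
    "subtree",
    "hierarchy_to_table",
    "hierarchy_to_graphml",
]


class HierarchyError(ValueError):
    """Base class for region-hierarchy validation failures."""


class CycleError(HierarchyError):
    """Parent links form a cycle."""


class MultipleRootsError(HierarchyError):
    """More than one region without a parent (or no root at all)."""


class DuplicateIdError(HierarchyError):
    """The same region id occurs twice."""


class UnknownRegionError(KeyError):
    """A region id was requested that the hierarchy does not contain."""


@dataclass(frozen=True)
class Region:
    """One named region of the nomenclature.

    ``level`` is 1 for the root and increases by one per "is part" step.
    ``laterality_side`` tags hemisphere membership for bilateral
    hierarchies built as two sibling subtrees under a common root.
    """

    id: str
    name: str = ""
    abbreviation: str = ""
    parent: str | None = None
    level: int = 1
    color: str | None = None
    laterality_side: str = "unpaired"


@dataclass
class RegionHierarchy:
    """Validated rooted tree of :class:`Region` objects.

    ``children`` preserves document order; depth-first traversal of it
    defines the canonical leaf sequence.
    """

    regions: dict[str, Region]
    root: str
    children: dict[str, list[str]] = field(default_factory=dict)

    def __contains__(self, region_id: str) -> bool:
        return region_id in self.regions

    def __len__(self) -> int:
        return len(self.regions)

    def region(self, region_id: str) -> Region:
        try:
            return self.regions[region_id]
        except KeyError:
            raise UnknownRegionError(region_id) from None

    def children_of(self, region_id: str) -> list[str]:
        self.region(region_id)
        return list(self.children.get(region_id, []))

    def is_leaf(self, region_id: str) -> bool:
        return not self.children.get(self.region(region_id).id)

    def leaves(self) -> list[str]:
        """All true leaves in depth-first document order."""
        return leaves_at_view(self, collapsed=frozenset())

    def depth(self) -> int:
        return max(r.level for r in self.regions.values())

    def walk(self) -> Iterator[str]:
        """Depth-first pre-order traversal of all region ids."""
        stack = [self.root]
        while stack:
            rid = stack.pop()
            yield rid
            stack.extend(reversed(self.children.get(rid, [])))


def _build(regions: Iterable[Region]) -> RegionHierarchy:
    by_id: dict[str, Region] = {}
    for r in regions:
        if r.id in by_id:
            raise DuplicateIdError(f"duplicate region id {r.id!r}")
        by_id[r.id] = r
    roots = [r.id for r in by_id.values() if r.parent is None]
    if len(roots) != 1:
        raise MultipleRootsError(
            f"hierarchy must have exactly one root, found {len(roots)}"
        )
    children: dict[str, list[str]] = {rid: [] for rid in by_id}
    for r in by_id.values():
        if r.parent is not None:
            if r.parent not in by_id:
                raise HierarchyError(
                    f"region {r.id!r} references missing parent {r.parent!r}"
                )
            children[r.parent].append(r.id)
    # reachability from the root doubles as the acyclicity check: with
    # exactly one parentless node, any cycle is unreachable from it
    seen: set[str] = set()
    stack = [roots[0]]
    while stack:
        rid = stack.pop()
        if rid in seen:
            raise CycleError(f"cycle detected at region {rid!r}")
        seen.add(rid)
        stack.extend(children[rid])
    if seen != set(by_id):
        raise CycleError(
            f"{len(by_id) - len(seen)} region(s) unreachable from the root "
            "(parent links form a cycle)"
        )
    for r in by_id.values():
        if r.parent is not None:
            expect = by_id[r.parent].level + 1
            if r.level != expect:
                raise HierarchyError(
                    f"region {r.id!r} has level {r.level}, expected {expect}"
                )
    return RegionHierarchy(regions=by_id, root=roots[0], children=children)


def _from_nested(doc: Mapping, parent: str | None, level: int, acc: list[Region]) -> None:
    rid = doc.get("id")
    if not isinstance(rid, str) or not rid:
        raise HierarchyError("every region object needs a non-empty string 'id'")
    acc.append(
        Region(
            id=rid,
            name=doc.get("name", rid),
            abbreviation=doc.get("abbreviation", rid),
            parent=parent,
            level=level,
            color=doc.get("color"),
            laterality_side=doc.get("laterality_side", "unpaired"),
        )
    )
    for child in doc.get("children", []):
        _from_nested(child, rid, level + 1, acc)


def load_hierarchy(source) -> RegionHierarchy:
    """Read and validate a hierarchy document.

    ``source`` may be a path to a JSON file, a JSON string, an already
    parsed nested mapping, or an iterable of :class:`Region`.  Raises a
    distinct :class:`HierarchyError` subclass for duplicate ids,
    multiple roots, missing parents and cycles.
    """
    if isinstance(source, RegionHierarchy):
        return _build(source.regions.values())
    if isinstance(source, Mapping):
        acc: list[Region] = []
        _from_nested(source, None, 1, acc)
        return _build(acc)
    if isinstance(source, (str, Path)):
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return load_hierarchy(json.loads(text))
    if hasattr(source, "read"):
        return load_hierarchy(json.load(source))
    return _build(source)


def leaves_at_view(h: RegionHierarchy, collapsed: Iterable[str] = ()) -> list[str]:
    """Leaves of the viewed tree in depth-first document order.

    A collapsed region is treated as a leaf: its subtree is hidden and
    the region itself appears in the list.  The returned order is the
    canonical matrix row/column order.
    """
    collapsed = set(collapsed)
    for rid in collapsed:
        if rid not in h:
            raise UnknownRegionError(rid)
    out: list[str] = []
    stack = [h.root]
    while stack:
        rid = stack.pop()
        kids = h.children.get(rid, [])
        if rid in collapsed or not kids:
            out.append(rid)
        else:
            stack.extend(reversed(kids))
    return out


def subtree(h: RegionHierarchy, region_id: str) -> set[str]:
    """The region plus all its descendants."""
    h.region(region_id)
    out: set[str] = set()
    stack = [region_id]
    while stack:
        rid = stack.pop()
        out.add(rid)
        stack.extend(h.children.get(rid, []))
    return out


def hierarchy_to_table(h: RegionHierarchy):
    """Tab-friendly id/parent/level table (one row per region)."""
    import pandas as pd

    rows = [
        {
            "id": rid,
            "parent": h.regions[rid].parent or "",
            "level": h.regions[rid].level,
            "name": h.regions[rid].name,
            "abbreviation": h.regions[rid].abbreviation,
        }
        for rid in h.walk()
    ]
    return pd.DataFrame(rows)


def hierarchy_to_graphml(h: RegionHierarchy, path) -> None:
    """Export the "is part" tree as GraphML (arcs parent -> child)."""
    import networkx as nx

    g = nx.DiGraph()
    for rid in h.walk():
        r = h.regions[rid]
        g.add_node(rid, name=r.name, abbreviation=r.abbreviation, level=r.level)
    for parent, kids in h.children.items():
        for kid in kids:
            g.add_edge(parent, kid)
    nx.write_graphml(g, path)
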