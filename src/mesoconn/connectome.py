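"""Weighted directed connectomes built from tract-tracing connection records.

A :class:`ConnectionRecord` is one literature-documented projection:
source region, target region, laterality (ipsilateral or contralateral),
an ordinal weight code 0..9 (0 = reported absent, 9 = strongest), and
tracer provenance.  Records are aggregated into a :class:`Connectome`, a
simple directed graph over the visible leaves of a region hierarchy:
arc weight is the maximum code over supporting records and ``n_studies``
counts them.  Self-projections and weight-0 ("documented absent") arcs
are excluded from the graph.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ontology import RegionHierarchy, UnknownRegionError, subtree

__all__ = [
    "ConnectionRecord",
    "Arc",
    "Connectome",
    "build_connectome",
    "condense",
    "remove_isolated",
    "adjacency_matrix",
    "connectome_from_adjacency",
    "extrinsic_io_counts",
    "read_records_csv",
    "write_records_csv",
    "connectome_to_graphml",
    "LEFT",
    "RIGHT",
]

LATERALITIES = ("ipsilateral", "contralateral")
TRANSPORTS = ("anterograde", "retrograde", "bidirectional")

#: node-id prefixes used when a bilateral graph is mirrored from records
LEFT = "left:"
RIGHT = "right:"


@dataclass(frozen=True)
class ConnectionRecord:
    """One documented projection between two regions."""

    source: str
    target: str
    laterality: str = "ipsilateral"
    weight_code: int = 1
    tracer: str = ""
    transport: str = "anterograde"
    case_id: str = ""
    reference: str = ""

    def __post_init__(self):
        if self.laterality not in LATERALITIES:
            raise ValueError(f"unknown laterality token {self.laterality!r}")
        if self.transport not in TRANSPORTS:
            raise ValueError(f"unknown transport token {self.transport!r}")
        if not 0 <= int(self.weight_code) <= 9:
            raise ValueError(f"weight code {self.weight_code} outside 0..9")


@dataclass
class Arc:
    weight: int
    n_studies: int = 1


@dataclass
class Connectome:
    """Simple weighted digraph over an ordered region list.

    ``arcs`` maps ``(source, target)`` to an :class:`Arc`; no self-loops,
    no parallel arcs.  Node order is the canonical matrix order.
    """

    nodes: list[str]
    arcs: dict[tuple[str, str], Arc] = field(default_factory=dict)

    def __post_init__(self):
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node ids")
        for (s, t) in self.arcs:
            if s == t:
                raise ValueError(f"self-loop {s!r}")
            if s not in node_set or t not in node_set:
                raise ValueError(f"arc endpoint outside node list: {s!r}->{t!r}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    def has_arc(self, s: str, t: str) -> bool:
        return (s, t) in self.arcs

    def successors(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {n: [] for n in self.nodes}
        for s, t in self.arcs:
            out[s].append(t)
        return out

    def predecessors(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {n: [] for n in self.nodes}
        for s, t in self.arcs:
            out[t].append(s)
        return out

    def out_degree(self) -> dict[str, int]:
        d = {n: 0 for n in self.nodes}
        for s, _ in self.arcs:
            d[s] += 1
        return d

    def in_degree(self) -> dict[str, int]:
        d = {n: 0 for n in self.nodes}
        for _, t in self.arcs:
            d[t] += 1
        return d

    def valency(self) -> dict[str, int]:
        """Degree all: in-degree plus out-degree."""
        do, di = self.out_degree(), self.in_degree()
        return {n: do[n] + di[n] for n in self.nodes}

    def subgraph(self, keep: Iterable[str]) -> "Connectome":
        keep_set = set(keep)
        nodes = [n for n in self.nodes if n in keep_set]
        arcs = {
            (s, t): replace_arc(a)
            for (s, t), a in self.arcs.items()
            if s in keep_set and t in keep_set
        }
        return Connectome(nodes=nodes, arcs=arcs)

    def copy(self) -> "Connectome":
        return Connectome(
            nodes=list(self.nodes),
            arcs={k: replace_arc(a) for k, a in self.arcs.items()},
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (s, t), a in self.arcs.items():
            g.add_edge(s, t, weight=a.weight, n_studies=a.n_studies)
        return g

    @classmethod
    def from_networkx(cls, g, node_order: Sequence[str] | None = None) -> "Connectome":
        nodes = list(node_order) if node_order is not None else list(g.nodes)
        arcs = {
            (s, t): Arc(int(d.get("weight", 1)), int(d.get("n_studies", 1)))
            for s, t, d in g.edges(data=True)
            if s != t
        }
        return cls(nodes=nodes, arcs=arcs)


def replace_arc(a: Arc) -> Arc:
    return Arc(weight=a.weight, n_studies=a.n_studies)


def _leaf_resolver(
    leaf_order: Sequence[str], hierarchy: RegionHierarchy | None
) -> dict[str, str]:
    """Map every region id to the visible leaf whose subtree contains it."""
    resolver: dict[str, str] = {}
    for leaf in leaf_order:
        members = subtree(hierarchy, leaf) if hierarchy is not None else {leaf}
        for rid in members:
            if rid in resolver:
                raise ValueError(
                    f"region {rid!r} lies under two visible leaves "
                    f"({resolver[rid]!r} and {leaf!r})"
                )
            resolver[rid] = leaf
    return resolver


def build_connectome(
    records: Iterable[ConnectionRecord],
    leaf_order: Sequence[str],
    side: str = "unilateral",
    hierarchy: RegionHierarchy | None = None,
) -> Connectome:
    """Aggregate connection records into a simple weighted digraph.

    Records attached below a visible leaf aggregate up to it (requires
    ``hierarchy``).  ``side="unilateral"`` keeps ipsilateral records only,
    on the plain leaf ids.  ``side="bilateral"`` mirrors the record set:
    every ipsilateral record appears on both hemispheres (node ids
    prefixed ``left:``/``right:``) and every contralateral record adds
    the two midline-crossing arcs.  Arc weight is the maximum code over
    supporting records; arcs whose maximum code is 0 (reported absent)
    and resolved self-projections are dropped.
    """
    if side not in ("unilateral", "bilateral"):
        raise ValueError(f"unknown side mode {side!r}")
    resolver = _leaf_resolver(leaf_order, hierarchy)

    if side == "unilateral":
        nodes = list(leaf_order)
    else:
        nodes = [LEFT + n for n in leaf_order] + [RIGHT + n for n in leaf_order]

    agg: dict[tuple[str, str], list[int]] = {}

    def _add(s: str, t: str, w: int) -> None:
        if s == t:
            return  # self-projection: excluded from graphs
        agg.setdefault((s, t), []).append(w)

    for rec in records:
        try:
            s = resolver[rec.source]
            t = resolver[rec.target]
        except KeyError as exc:
            raise UnknownRegionError(
                f"record region {exc.args[0]!r} not under any visible leaf"
            ) from None
        w = int(rec.weight_code)
        if side == "unilateral":
            if rec.laterality == "ipsilateral":
                _add(s, t, w)
        else:
            if rec.laterality == "ipsilateral":
                _add(LEFT + s, LEFT + t, w)
                _add(RIGHT + s, RIGHT + t, w)
            else:
                _add(LEFT + s, RIGHT + t, w)
                _add(RIGHT + s, LEFT + t, w)

    arcs = {
        key: Arc(weight=max(ws), n_studies=len(ws))
        for key, ws in agg.items()
        if max(ws) > 0
    }
    return Connectome(nodes=nodes, arcs=arcs)


def condense(c: Connectome) -> Connectome:
    """Keep only regions with at least one input *and* one output.

    Removal cascades: dropping a node can strip its neighbours of their
    last input or output, so removal iterates to a fixpoint.  Node order
    is preserved.  May return an empty connectome.
    """
    out = c.copy()
    while True:
        di, do = out.in_degree(), out.out_degree()
        keep = [n for n in out.nodes if di[n] >= 1 and do[n] >= 1]
        if len(keep) == len(out.nodes):
            return out
        out = out.subgraph(keep)


def remove_isolated(c: Connectome) -> Connectome:
    """Drop nodes with no arcs at all (total degree 0)."""
    val = c.valency()
    return c.subgraph([n for n in c.nodes if val[n] > 0])


def adjacency_matrix(c: Connectome, sentinel: int = -1) -> np.ndarray:
    """Square ordinal weight matrix; rows are sources, columns targets."""
    idx = {n: i for i, n in enumerate(c.nodes)}
    m = np.full((c.n_nodes, c.n_nodes), sentinel, dtype=int)
    for (s, t), a in c.arcs.items():
        m[idx[s], idx[t]] = a.weight
    np.fill_diagonal(m.reshape(m.shape) if m.size else m, sentinel)
    return m


def connectome_from_adjacency(
    m: np.ndarray, nodes: Sequence[str], sentinel: int = -1
) -> Connectome:
    """Inverse of :func:`adjacency_matrix` (n_studies reset to 1)."""
    m = np.asarray(m)
    if m.shape != (len(nodes), len(nodes)):
        raise ValueError("matrix shape does not match node list")
    arcs: dict[tuple[str, str], Arc] = {}
    for i, s in enumerate(nodes):
        for j, t in enumerate(nodes):
            if i != j and m[i, j] != sentinel:
                arcs[(s, t)] = Arc(weight=int(m[i, j]))
    return Connectome(nodes=list(nodes), arcs=arcs)


_IO_COLUMNS = ["Dic", "Dii", "Dis", "Doc", "Doi", "Dos",
               "Sic", "Sii", "Sis", "Soc", "Soi", "Sos"]


def extrinsic_io_counts(
    records: Iterable[ConnectionRecord],
    intrinsic: Iterable[str],
    hierarchy: RegionHierarchy,
):
    """Per-region extrinsic input/output tallies.

    For each intrinsic region the twelve counts split by direction
    (i = input, o = output), laterality (c = contralateral,
    i = ipsilateral, s = their sum) and attachment (D = records attached
    exactly at the region; S = records attached anywhere in its
    subtree).  A record is extrinsic when its other endpoint lies outside
    the union of the intrinsic regions' subtrees.  Returns a DataFrame
    indexed by region in the given order.
    """
    import pandas as pd

    intrinsic = list(intrinsic)
    subtrees = {r: subtree(hierarchy, r) for r in intrinsic}
    intrinsic_universe: set[str] = set().union(*subtrees.values()) if intrinsic else set()
    records = list(records)

    rows = []
    for r in intrinsic:
        counts = dict.fromkeys(_IO_COLUMNS, 0)
        members = subtrees[r]
        for rec in records:
            lat = "c" if rec.laterality == "contralateral" else "i"
            # inputs: record targets this region, source is extrinsic
            if rec.source not in intrinsic_universe:
                if rec.target == r:
                    counts[f"Di{lat}"] += 1
                if rec.target in members:
                    counts[f"Si{lat}"] += 1
            # outputs: record starts here, target is extrinsic
            if rec.target not in intrinsic_universe:
                if rec.source == r:
                    counts[f"Do{lat}"] += 1
                if rec.source in members:
                    counts[f"So{lat}"] += 1
        for d in ("Di", "Do", "Si", "So"):
            counts[d + "s"] = counts[d + "c"] + counts[d + "i"]
        rows.append(counts)
    return pd.DataFrame(rows, index=pd.Index(intrinsic, name="region"),
                        columns=_IO_COLUMNS)


_RECORD_FIELDS = ["source", "target", "laterality", "weight", "tracer",
                  "transport", "case", "reference"]


def read_records_csv(path, delimiter: str | None = None) -> list[ConnectionRecord]:
    """Read connection records from a delimited text file with header.

    Columns: source, target, laterality, weight, tracer, transport,
    case, reference.  Unknown laterality or transport tokens are
    rejected.  The delimiter is sniffed (comma or tab) unless given.
    """
    text = Path(path).read_text()
    if delimiter is None:
        delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.DictReader(text.splitlines(), delimiter=delimiter)
    out = []
    for row in reader:
        out.append(
            ConnectionRecord(
                source=row["source"],
                target=row["target"],
                laterality=row.get("laterality", "ipsilateral"),
                weight_code=int(row.get("weight", 1)),
                tracer=row.get("tracer", ""),
                transport=row.get("transport", "anterograde"),
                case_id=row.get("case", ""),
                reference=row.get("reference", ""),
            )
        )
    return out


def write_records_csv(records: Iterable[ConnectionRecord], path, delimiter=",") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(_RECORD_FIELDS)
        for r in records:
            w.writerow([r.source, r.target, r.laterality, r.weight_code,
                        r.tracer, r.transport, r.case_id, r.reference])


def connectome_to_graphml(c: Connectome, path) -> None:
    """GraphML export: directed, weight and n_studies as arc attributes."""
    import networkx as nx

    nx.write_graphml(c.to_networkx(), path)
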