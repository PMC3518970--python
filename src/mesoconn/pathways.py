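"""Constrained staged pathway reconstruction.

A stage specification is an ordered list of region sets; each stage
region is interpreted transhierarchically (it matches itself and any
ontology descendant).  A pathway is a chain with exactly one connectome
node per stage and a direct arc between consecutive nodes; the search is
exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .connectome import Connectome
from .ontology import RegionHierarchy, subtree

__all__ = ["StageSpec", "PathwayChain", "staged_paths", "pathways_table"]


@dataclass
class StageSpec:
    """Ordered stages, each a set of region ids (transhierarchical)."""

    stages: list[set[str]]

    def __post_init__(self):
        if len(self.stages) < 2:
            raise ValueError("a stage spec needs at least 2 stages")
        self.stages = [set(s) for s in self.stages]


@dataclass
class PathwayChain:
    nodes: list[str]
    weights: list[int]          # per hop
    n_studies: list[int]        # per hop
    reciprocal: list[bool]      # per hop: does the reverse arc exist?


def _resolve_stage(stage: set[str], c: Connectome,
                   h: RegionHierarchy | None) -> list[str]:
    members: set[str] = set()
    for rid in stage:
        members |= subtree(h, rid) if h is not None and rid in h else {rid}
    resolved = [n for n in c.nodes if n in members]
    if not resolved:
        raise ValueError(f"stage {sorted(stage)} resolves to no connectome node")
    return resolved


def staged_paths(
    c: Connectome,
    h: RegionHierarchy | None,
    spec: StageSpec | Sequence[Iterable[str]],
) -> list[PathwayChain]:
    """All arc chains visiting one node per stage, in stage order.

    Chains carry per-hop weight codes, supporting study counts and a
    flag marking hops whose reverse arc also exists.  Output order
    follows the connectome's node order stage by stage and is invariant
    to how regions are listed within a stage.
    """
    if not isinstance(spec, StageSpec):
        spec = StageSpec(stages=[set(s) for s in spec])
    stage_nodes = [_resolve_stage(s, c, h) for s in spec.stages]

    chains: list[PathwayChain] = []

    def _extend(prefix: list[str], depth: int) -> None:
        if depth == len(stage_nodes):
            arcs = [c.arcs[(a, b)] for a, b in zip(prefix, prefix[1:])]
            chains.append(PathwayChain(
                nodes=list(prefix),
                weights=[a.weight for a in arcs],
                n_studies=[a.n_studies for a in arcs],
                reciprocal=[c.has_arc(b, a) for a, b in zip(prefix, prefix[1:])],
            ))
            return
        for node in stage_nodes[depth]:
            if prefix and not c.has_arc(prefix[-1], node):
                continue
            _extend(prefix + [node], depth + 1)

    _extend([], 0)
    return chains


def pathways_table(chains: list[PathwayChain]):
    """One row per chain: node per stage, weight/studies/flag per hop."""
    import pandas as pd

    rows = []
    for ch in chains:
        row = {f"stage{i + 1}": n for i, n in enumerate(ch.nodes)}
        for i, (w, s, r) in enumerate(zip(ch.weights, ch.n_studies, ch.reciprocal)):
            row[f"hop{i + 1}_weight"] = w
            row[f"hop{i + 1}_studies"] = s
            row[f"hop{i + 1}_reciprocal"] = r
        rows.append(row)
    return pd.DataFrame(rows)
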