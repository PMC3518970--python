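"""Node- and arc-deletion vulnerability via harmonic closeness.

Closeness of a node is the mean inverse shortest directed distance to
every other node (harmonic form: unreachable pairs contribute 0, so the
measure survives the loss of strong connectivity that deletions cause).
The significance of deleting a node or an arc is the percent drop of the
network's mean closeness: positive values mean the deletion harmed the
network (paths lengthened or vanished); negative node values are
possible when removing a poorly connected node raises the mean over the
survivors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._graphops import all_pairs_distances, harmonic_closeness
from .connectome import Connectome
from .matrices import PairMatrix

__all__ = [
    "VulnerabilityReport",
    "mean_closeness",
    "node_significance",
    "edge_vulnerability_matrix",
]


@dataclass
class VulnerabilityReport:
    baseline_mean_closeness: float
    node_significance: dict[str, float]
    edge_matrix: PairMatrix


def _mean_closeness_idx(out_adj: list[list[int]]) -> float:
    dist = all_pairs_distances(out_adj)
    return float(harmonic_closeness(dist, axis=1).mean())


def mean_closeness(c: Connectome) -> float:
    """Network mean of out-going harmonic closeness."""
    from ._graphops import index_adjacency

    out_adj, _ = index_adjacency(c)
    return _mean_closeness_idx(out_adj)


def node_significance(c: Connectome) -> dict[str, float]:
    """Percent drop of mean closeness after deleting each node.

    The post-deletion mean is taken over the surviving nodes only (the
    removed region has no closeness).  Requires at least 3 nodes.
    """
    if c.n_nodes < 3:
        raise ValueError("node vulnerability needs at least 3 nodes")
    base = mean_closeness(c)
    if base == 0:
        raise ValueError("baseline mean closeness is 0; significance undefined")
    out = {}
    for r in c.nodes:
        after = mean_closeness(c.subgraph([n for n in c.nodes if n != r]))
        out[r] = 100 * (base - after) / base
    return out


def edge_vulnerability_matrix(c: Connectome) -> PairMatrix:
    """Percent drop of mean closeness after deleting each arc.

    The node set is unchanged; entries for absent arcs are NaN.
    """
    from ._graphops import index_adjacency

    base = mean_closeness(c)
    n = c.n_nodes
    m = np.full((n, n), np.nan)
    if base == 0:
        return PairMatrix(nodes=list(c.nodes), values=m, kind="edge_vulnerability")
    idx = {v: i for i, v in enumerate(c.nodes)}
    out_adj, _ = index_adjacency(c)
    for (s, t) in c.arcs:
        si, ti = idx[s], idx[t]
        out_adj[si].remove(ti)
        after = _mean_closeness_idx(out_adj)
        out_adj[si].append(ti)
        m[si, ti] = 100 * (base - after) / base
    return PairMatrix(nodes=list(c.nodes), values=m, kind="edge_vulnerability")


def vulnerability_report(c: Connectome) -> VulnerabilityReport:
    return VulnerabilityReport(
        baseline_mean_closeness=mean_closeness(c),
        node_significance=node_significance(c),
        edge_matrix=edge_vulnerability_matrix(c),
    )
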