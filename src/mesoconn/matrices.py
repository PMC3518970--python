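"""Pairwise node-by-node matrices: distance, communicability, matching.

All matrices share the connectome's canonical node order.  Distances
are unweighted shortest directed path lengths (``inf`` marks an
unreachable pair).  Communicability is the matrix exponential of the
binarized adjacency matrix — every walk between two regions counts,
down-weighted by the inverse factorial of its length.  The matching
index is the Jaccard overlap of two regions' neighbor sets (in, out or
combined), excluding the pair itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from ._graphops import all_pairs_distances, index_adjacency
from .connectome import Connectome

__all__ = [
    "PairMatrix",
    "distance_matrix",
    "communicability_matrix",
    "matching_matrix",
    "write_pair_matrix_tsv",
]


@dataclass
class PairMatrix:
    nodes: list[str]
    values: np.ndarray
    kind: str

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.nodes, columns=self.nodes)


def distance_matrix(c: Connectome) -> PairMatrix:
    """Smallest number of edges between regions; inf when unreachable."""
    out_adj, _ = index_adjacency(c)
    d = all_pairs_distances(out_adj).astype(float)
    d[d < 0] = np.inf
    return PairMatrix(nodes=list(c.nodes), values=d, kind="distance")


def communicability_matrix(c: Connectome) -> PairMatrix:
    """exp(A) of the binary adjacency matrix (weights ignored)."""
    n = c.n_nodes
    a = np.zeros((n, n))
    idx = {v: i for i, v in enumerate(c.nodes)}
    for s, t in c.arcs:
        a[idx[s], idx[t]] = 1.0
    return PairMatrix(nodes=list(c.nodes), values=expm(a), kind="communicability")


def matching_matrix(c: Connectome, mode: str = "all") -> PairMatrix:
    """Jaccard overlap of neighbor sets; the pair itself is excluded.

    ``mode`` selects in-, out- or combined neighbor sets.  An empty
    union scores 0; the diagonal is 1 by convention.
    """
    if mode not in ("in", "out", "all"):
        raise ValueError(f"unknown matching mode {mode!r}")
    out_adj, in_adj = index_adjacency(c)
    n = c.n_nodes
    if mode == "in":
        sets = [set(in_adj[i]) for i in range(n)]
    elif mode == "out":
        sets = [set(out_adj[i]) for i in range(n)]
    else:
        sets = [set(out_adj[i]) | set(in_adj[i]) for i in range(n)]
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a = sets[i] - {j}
            b = sets[j] - {i}
            union = a | b
            m[i, j] = m[j, i] = len(a & b) / len(union) if union else 0.0
    return PairMatrix(nodes=list(c.nodes), values=m, kind=f"matching_{mode}")


def write_pair_matrix_tsv(pm: PairMatrix, path) -> None:
    """Dense TSV with node labels; unreachable sentinel spelled 'inf'."""
    pm.as_frame().to_csv(path, sep="\t")
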