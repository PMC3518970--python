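"""Internal graph primitives shared across the metric modules.

Everything here works on integer-indexed adjacency lists (node order =
``Connectome.nodes``) so the hot loops (all-pairs BFS, SCC counting on
induced subsets, motif bit codes) avoid per-call networkx overhead.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from .connectome import Connectome


def index_adjacency(c: Connectome) -> tuple[list[list[int]], list[list[int]]]:
    """(out, in) adjacency lists over node indices in canonical order."""
    idx = {n: i for i, n in enumerate(c.nodes)}
    out: list[list[int]] = [[] for _ in c.nodes]
    inn: list[list[int]] = [[] for _ in c.nodes]
    for s, t in c.arcs:
        out[idx[s]].append(idx[t])
        inn[idx[t]].append(idx[s])
    return out, inn


def bitmask_adjacency(c: Connectome) -> tuple[list[int], list[int]]:
    """(out, in) neighbor sets as int bitmasks; bit j of out[i] = arc i->j."""
    idx = {n: i for i, n in enumerate(c.nodes)}
    out = [0] * c.n_nodes
    inn = [0] * c.n_nodes
    for s, t in c.arcs:
        out[idx[s]] |= 1 << idx[t]
        inn[idx[t]] |= 1 << idx[s]
    return out, inn


def all_pairs_distances(out_adj: list[list[int]]) -> np.ndarray:
    """Unweighted directed distances; -1 marks unreachable, diagonal 0."""
    n = len(out_adj)
    dist = np.full((n, n), -1, dtype=np.int64)
    for s in range(n):
        row = dist[s]
        row[s] = 0
        q = deque([s])
        while q:
            u = q.popleft()
            du = row[u]
            for v in out_adj[u]:
                if row[v] < 0:
                    row[v] = du + 1
                    q.append(v)
    return dist


def all_pairs_geodesics(
    out_adj: list[list[int]],
) -> tuple[np.ndarray, np.ndarray]:
    """Distances plus geodesic (shortest-path) counts between all pairs."""
    n = len(out_adj)
    dist = np.full((n, n), -1, dtype=np.int64)
    sigma = np.zeros((n, n), dtype=np.float64)
    for s in range(n):
        drow, srow = dist[s], sigma[s]
        drow[s] = 0
        srow[s] = 1.0
        q = deque([s])
        while q:
            u = q.popleft()
            du, su = drow[u], srow[u]
            for v in out_adj[u]:
                if drow[v] < 0:
                    drow[v] = du + 1
                    q.append(v)
                if drow[v] == du + 1:
                    srow[v] += su
    return dist, sigma


def harmonic_closeness(dist: np.ndarray, axis: int = 1) -> np.ndarray:
    """Mean inverse distance to (axis=1) or from (axis=0) the other nodes.

    Unreachable pairs contribute 0; normalization is 1/(n-1).
    """
    n = dist.shape[0]
    if n < 2:
        return np.zeros(n)
    with np.errstate(divide="ignore"):
        inv = np.where(dist > 0, 1.0 / np.where(dist > 0, dist, 1), 0.0)
    return inv.sum(axis=axis) / (n - 1)


def scc_count(out_adj: list[list[int]], members: list[int] | None = None) -> int:
    """Number of strongly connected components of the induced subgraph.

    Iterative Tarjan; ``members=None`` means the full node set.
    """
    if members is None:
        members = list(range(len(out_adj)))
    if not members:
        return 0
    member_set = set(members)
    index: dict[int, int] = {}
    lowlink: dict[int, int] = {}
    on_stack: set[int] = set()
    stack: list[int] = []
    counter = 0
    n_scc = 0
    for root in members:
        if root in index:
            continue
        work = [(root, iter([w for w in out_adj[root] if w in member_set]))]
        index[root] = lowlink[root] = counter
        counter += 1
        stack.append(root)
        on_stack.add(root)
        while work:
            v, it = work[-1]
            advanced = False
            for w in it:
                if w not in index:
                    index[w] = lowlink[w] = counter
                    counter += 1
                    stack.append(w)
                    on_stack.add(w)
                    work.append((w, iter([x for x in out_adj[w] if x in member_set])))
                    advanced = True
                    break
                elif w in on_stack:
                    if index[w] < lowlink[v]:
                        lowlink[v] = index[w]
            if advanced:
                continue
            work.pop()
            if work:
                parent = work[-1][0]
                if lowlink[v] < lowlink[parent]:
                    lowlink[parent] = lowlink[v]
            if lowlink[v] == index[v]:
                n_scc += 1
                while True:
                    w = stack.pop()
                    on_stack.discard(w)
                    if w == v:
                        break
    return n_scc
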