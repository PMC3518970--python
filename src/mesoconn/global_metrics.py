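"""Whole-network parameters of the condensed connectome.

Average valency 2E/N, line density 100·E/(N(N−1)), heterogeneity
(coefficient of variation of valency), mean shortest directed path
length over reachable ordered pairs, mean clustering of the underlying
undirected graph, mean degree centrality, small-worldness against a
size-matched Erdős–Rényi ensemble, the power-law fit delta error, and
directed Newman modularity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from ._graphops import all_pairs_distances, index_adjacency
from .connectome import Connectome
from .nulls import erdos_renyi

__all__ = [
    "GlobalMetrics",
    "global_summary",
    "small_worldness",
    "powerlaw_delta_error",
    "modularity_partition",
    "average_path_length",
    "average_clustering",
]


@dataclass
class GlobalMetrics:
    n_nodes: int
    n_arcs: int
    avg_valency: float | None
    line_density: float | None
    heterogeneity: float | None
    avg_path_length: float | None
    avg_cluster_coefficient: float | None
    avg_centrality: float | None
    small_worldness: float | None
    powerlaw_delta_error: float | None
    modularity_Q: float | None
    reachable_pair_fraction: float | None


def average_path_length(c: Connectome) -> tuple[float | None, float | None]:
    """(mean geodesic over reachable ordered pairs, reachable fraction).

    Unreachable ordered pairs are excluded from the mean; their
    complement is reported as the reachable fraction.  Undefined
    (None) for graphs with fewer than 2 nodes or no reachable pair.
    """
    n = c.n_nodes
    if n < 2:
        return None, None
    out_adj, _ = index_adjacency(c)
    dist = all_pairs_distances(out_adj)
    off = ~np.eye(n, dtype=bool)
    reach = (dist > 0) & off
    n_pairs = n * (n - 1)
    frac = reach.sum() / n_pairs
    if not reach.any():
        return None, 0.0
    return float(dist[reach].mean()), float(frac)


def average_clustering(c: Connectome) -> float:
    """Mean clustering coefficient of the underlying undirected graph."""
    g = c.to_networkx().to_undirected()
    if g.number_of_nodes() == 0:
        return 0.0
    return float(nx.average_clustering(g))


def small_worldness(c: Connectome, n_rand: int = 100, seed: int = 0) -> float | None:
    """S = (C / C_ER) / (L / L_ER) against n_rand size-matched ER graphs.

    Returns None when the ensemble clustering or any path length is
    undefined (e.g. near-empty graphs).
    """
    if c.n_nodes < 2 or c.n_arcs == 0:
        return None
    c_real = average_clustering(c)
    l_real, _ = average_path_length(c)
    cs, ls = [], []
    for r in range(n_rand):
        g = erdos_renyi(c.n_nodes, c.n_arcs, seed=(seed + 7919 * r) % (2**31 - 1))
        cs.append(average_clustering(g))
        lr, _ = average_path_length(g)
        if lr is not None:
            ls.append(lr)
    c_er = float(np.mean(cs)) if cs else 0.0
    l_er = float(np.mean(ls)) if ls else None
    if c_er == 0 or l_er in (None, 0) or l_real is None:
        return None
    return (c_real / c_er) / (l_real / l_er)


def powerlaw_delta_error(c: Connectome) -> float | None:
    """Mean deviation from a fitted power law, times 100.

    The valency histogram (zero-count bins excluded, valency 0 bins
    excluded from the log fit) is fit by P(k) ∝ k^(−γ) via least squares
    on log–log axes; the statistic is 100 times the mean absolute
    deviation between the empirical relative frequencies and the fit.
    Undefined (None) with fewer than 3 distinct positive valencies.
    """
    return delta_error_from_valencies(np.array(list(c.valency().values())))


def delta_error_from_valencies(vals: np.ndarray) -> float | None:
    """Power-law delta error of a raw valency sample (see above)."""
    vals = np.asarray(vals)
    if vals.size == 0:
        return None
    ks, counts = np.unique(vals[vals > 0], return_counts=True)
    if ks.size < 3:
        return None
    p = counts / vals.size
    slope, intercept = np.polyfit(np.log(ks), np.log(p), 1)
    fit = np.exp(intercept) * ks ** slope
    return float(100 * np.mean(np.abs(p - fit)))


def _directed_modularity(c: Connectome, partition: dict[str, int]) -> float:
    """Unweighted directed Newman modularity of a node->module map."""
    e = c.n_arcs
    if e == 0:
        return 0.0
    do, di = c.out_degree(), c.in_degree()
    q = 0.0
    modules = set(partition.values())
    for m in modules:
        members = [n for n in c.nodes if partition[n] == m]
        e_in = sum(1 for (s, t) in c.arcs if partition[s] == m and partition[t] == m)
        k_out = sum(do[n] for n in members)
        k_in = sum(di[n] for n in members)
        q += e_in / e - (k_out * k_in) / (e * e)
    return q


def modularity_partition(
    c: Connectome, seed: int = 0, restarts: int = 8
) -> tuple[dict[str, int], float]:
    """Heuristic maximization of unweighted directed Newman modularity.

    Louvain-style agglomeration with seeded deterministic restarts (the
    best partition over ``restarts`` runs is kept); falls back to the
    single-module partition (Q = 0) if the heuristic does worse.
    """
    if c.n_nodes == 0:
        raise ValueError("empty connectome")
    if c.n_arcs == 0:
        return {n: 0 for n in c.nodes}, 0.0
    g = c.to_networkx()
    best_q, best_p = -math.inf, None
    for r in range(max(1, restarts)):
        comms = nx.community.louvain_communities(
            g, weight=None, seed=(seed + 104729 * r) % (2**31 - 1))
        partition = {n: i for i, comm in enumerate(comms) for n in comm}
        q = _directed_modularity(c, partition)
        if q > best_q:
            best_q, best_p = q, partition
    if best_q < 0:
        return {n: 0 for n in c.nodes}, 0.0
    return best_p, best_q


def exhaustive_modularity(c: Connectome) -> tuple[dict[str, int], float]:
    """Exact best-partition modularity by set-partition enumeration (n <= 8)."""
    if c.n_nodes > 8:
        raise ValueError("exhaustive search limited to 8 nodes")

    def _partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for smaller in _partitions(rest):
            for i, block in enumerate(smaller):
                yield smaller[:i] + [block + [first]] + smaller[i + 1:]
            yield [[first]] + smaller

    best_q, best_p = -math.inf, None
    for blocks in _partitions(list(c.nodes)):
        partition = {n: i for i, block in enumerate(blocks) for n in block}
        q = _directed_modularity(c, partition)
        if q > best_q:
            best_q, best_p = q, partition
    return best_p, best_q


def global_summary(c: Connectome, n_rand: int = 100, seed: int = 0) -> GlobalMetrics:
    """All whole-network parameters in one bundle.

    ``n_rand`` sizes the ER ensemble behind small-worldness; ``seed``
    drives both that ensemble and the modularity heuristic.  Metrics
    that are undefined for the given graph come back as None rather
    than 0.
    """
    n, e = c.n_nodes, c.n_arcs
    if n < 1:
        raise ValueError("empty connectome")
    vals = np.array(list(c.valency().values()), dtype=float)
    avg_val = 2 * e / n
    density = 100 * e / (n * (n - 1)) if n > 1 else None
    het = float(vals.std() / vals.mean()) if vals.mean() > 0 else None
    apl, reach_frac = average_path_length(c)
    clust = average_clustering(c)
    centrality = avg_val / (2 * (n - 1)) if n > 1 else None
    _, q = modularity_partition(c, seed=seed) if e else ({}, 0.0)
    return GlobalMetrics(
        n_nodes=n,
        n_arcs=e,
        avg_valency=avg_val,
        line_density=density,
        heterogeneity=het,
        avg_path_length=apl,
        avg_cluster_coefficient=clust,
        avg_centrality=centrality,
        small_worldness=small_worldness(c, n_rand=n_rand, seed=seed) if n_rand else None,
        powerlaw_delta_error=powerlaw_delta_error(c),
        modularity_Q=q,
        reachable_pair_fraction=reach_frac,
    )
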