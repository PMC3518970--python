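"""Independent brute-force oracles used by the test suite.

Everything here goes through networkx or plain enumeration and stays
deliberately separate from the package's own code paths.
"""

from itertools import combinations, permutations

import networkx as nx
import numpy as np


def naive_motif_census(c, k, classes):
    """Classify every k-subset independently via networkx isomorphism."""
    reps = {}
    for mc in classes:
        g = nx.DiGraph()
        g.add_nodes_from(range(mc.k))
        code = mc.canonical_code
        bit = 0
        for i in range(k):
            for j in range(k):
                if i != j:
                    if code >> bit & 1:
                        g.add_edge(i, j)
                    bit += 1
        reps[mc.motif_id] = g
    g_full = c.to_networkx()
    counts = {mc.motif_id: 0 for mc in classes}
    for subset in combinations(c.nodes, k):
        sub = g_full.subgraph(subset)
        if sub.number_of_edges() == 0 or not nx.is_weakly_connected(sub):
            continue
        for mid, rep in reps.items():
            if nx.is_isomorphic(sub, rep):
                counts[mid] += 1
                break
    return counts


def shapley_by_permutations(c):
    """Exact Shapley values by full enumeration of arrival orders."""
    g = c.to_networkx()
    nodes = list(c.nodes)
    phi = dict.fromkeys(nodes, 0.0)
    n_orders = 0
    for order in permutations(nodes):
        n_orders += 1
        prev = 0
        members = []
        for v in order:
            members.append(v)
            cur = nx.number_strongly_connected_components(g.subgraph(members))
            phi[v] += cur - prev
            prev = cur
    return {v: phi[v] / n_orders for v in nodes}


def mean_harmonic_closeness_nx(g):
    """Mean over nodes of out-going harmonic closeness, 1/(n-1) normalized."""
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    total = 0.0
    for v in g.nodes:
        lengths = nx.single_source_shortest_path_length(g, v)
        total += sum(1.0 / d for u, d in lengths.items() if u != v) / (n - 1)
    return total / n


def node_significance_brute(c):
    g = c.to_networkx()
    base = mean_harmonic_closeness_nx(g)
    out = {}
    for v in c.nodes:
        h = g.copy()
        h.remove_node(v)
        out[v] = 100 * (base - mean_harmonic_closeness_nx(h)) / base
    return out


def edge_significance_brute(c):
    g = c.to_networkx()
    base = mean_harmonic_closeness_nx(g)
    out = {}
    for (s, t) in c.arcs:
        h = g.copy()
        h.remove_edge(s, t)
        out[(s, t)] = 100 * (base - mean_harmonic_closeness_nx(h)) / base
    return out


def stress_brute(c):
    """Stress centrality by explicit enumeration of all geodesics."""
    g = c.to_networkx()
    st = dict.fromkeys(c.nodes, 0)
    for s in c.nodes:
        for t in c.nodes:
            if s == t or not nx.has_path(g, s, t):
                continue
            for path in nx.all_shortest_paths(g, s, t):
                for v in path[1:-1]:
                    st[v] += 1
    return st


def exhaustive_modularity_nx(c):
    """Best directed Newman modularity over all set partitions (n <= 7)."""

    def _partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for smaller in _partitions(rest):
            for i, block in enumerate(smaller):
                yield smaller[:i] + [block + [first]] + smaller[i + 1:]
            yield [[first]] + smaller

    g = c.to_networkx()
    best = -np.inf
    for blocks in _partitions(list(c.nodes)):
        q = nx.community.modularity(g, [set(b) for b in blocks], weight=None)
        best = max(best, q)
    return best


def staged_chains_brute(c, stage_nodes):
    """All chains with one node per stage and arcs between consecutive."""
    from itertools import product

    chains = []
    for combo in product(*stage_nodes):
        if all(c.has_arc(a, b) for a, b in zip(combo, combo[1:])):
            chains.append(list(combo))
    return chains
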