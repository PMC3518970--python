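"""Per-node parameter table: degrees, centralities, Shapley rates, cycles.

The table mirrors the conventional local-parameter layout: degrees
(DGa/DGo/DGi), Katz status, eccentricities, directed and undirected
clustering variants, neighbor-degree statistics, locality, harmonic
closeness, betweenness and stress, eigenvector centrality, the Shapley
rate of a strongly-connected-component coalition game, within-module
degree z-scores, participation coefficients, radiality and centroid
values.

The Shapley game: coalition value v(S) = number of strongly connected
components of the subgraph induced by S (v(∅) = 0).  A node's Shapley
rate is its average marginal contribution over arrival orders; low or
negative rates mark nodes whose arrival fuses components — the
structurally important ones.  Rates always sum to v(full set), the SCC
count of the whole graph.
"""

from __future__ import annotations

import math
from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd

from ._graphops import (
    all_pairs_geodesics,
    harmonic_closeness,
    index_adjacency,
    scc_count,
)
from .connectome import Connectome
from .global_metrics import modularity_partition

__all__ = ["local_table", "shapley_rates", "cycle_counts", "LOCAL_COLUMNS"]

LOCAL_COLUMNS = [
    "DGa", "DGo", "DGi", "Katz", "Ecco", "Ecci", "CCo", "CCi", "CCa", "CC2",
    "ADG", "VC", "Loc", "Co", "Ci", "BC", "EC", "St", "Shapley",
    "Za", "Zo", "Zi", "PCa", "PCo", "PCi", "Ro", "Ri", "Ceno", "Ceni",
]


def _factorial_weights(n: int) -> list[float]:
    # w(s) = s!(n-1-s)!/n! -- weight of a coalition of size s in the
    # subset form of the Shapley value
    return [
        math.factorial(s) * math.factorial(n - 1 - s) / math.factorial(n)
        for s in range(n)
    ]


def shapley_rates(
    c: Connectome,
    mode: str = "monte_carlo",
    n_perms: int = 10_000,
    seed: int = 0,
) -> dict[str, float]:
    """Shapley value of every node in the SCC-count coalition game.

    ``mode="exact"`` (n <= 10) evaluates the subset-weighted sum over
    all coalitions; ``mode="monte_carlo"`` averages marginal
    contributions over ``n_perms`` random arrival orders, memoizing
    coalition values, deterministic under ``seed``.
    """
    n = c.n_nodes
    if n == 0:
        return {}
    out_adj, _ = index_adjacency(c)

    if mode == "exact":
        if n > 10:
            raise ValueError("exact mode limited to 10 nodes")
        v = np.zeros(1 << n)
        for mask in range(1, 1 << n):
            members = [i for i in range(n) if mask >> i & 1]
            v[mask] = scc_count(out_adj, members)
        w = _factorial_weights(n)
        phi = np.zeros(n)
        for i in range(n):
            bit = 1 << i
            for mask in range(1 << n):
                if mask & bit:
                    continue
                s = bin(mask).count("1")
                phi[i] += w[s] * (v[mask | bit] - v[mask])
        return {c.nodes[i]: float(phi[i]) for i in range(n)}

    if mode != "monte_carlo":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    phi = np.zeros(n)
    cache: dict[int, int] | None = {0: 0} if n <= 24 else None
    for _ in range(n_perms):
        order = rng.permutation(n)
        mask = 0
        members: list[int] = []
        prev = 0
        for i in order:
            members.append(int(i))
            mask |= 1 << int(i)
            if cache is not None:
                cur = cache.get(mask)
                if cur is None:
                    cur = scc_count(out_adj, members)
                    cache[mask] = cur
            else:
                cur = scc_count(out_adj, members)
            phi[i] += cur - prev
            prev = cur
    phi /= n_perms
    return {c.nodes[i]: float(phi[i]) for i in range(n)}


def cycle_counts(c: Connectome, region: str, length: int) -> int:
    """Distinct directed cycles of exactly ``length`` edges through a region."""
    if region not in c.nodes:
        raise KeyError(region)
    if length not in (2, 3):
        raise ValueError("cycle length must be 2 or 3")
    succ = c.successors()
    if length == 2:
        return sum(1 for u in succ[region] if c.has_arc(u, region))
    count = 0
    for u in succ[region]:
        if u == region:
            continue
        for w in succ[u]:
            if w not in (region, u) and c.has_arc(w, region):
                count += 1
    return count


def _directed_neighborhood_clustering(neigh: list[int], out_masks: list[int]) -> float:
    """Arc density among a neighbor set (0 when fewer than 2 neighbors)."""
    k = len(neigh)
    if k < 2:
        return 0.0
    arcs = 0
    for a in neigh:
        row = out_masks[a]
        for b in neigh:
            if a != b and row >> b & 1:
                arcs += 1
    return arcs / (k * (k - 1))


def local_table(
    c: Connectome,
    partition: dict[str, int] | None = None,
    shapley_mode: str = "auto",
    shapley_perms: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """The full per-node parameter table (one row per region).

    ``partition`` defaults to the seeded modularity partition; the
    Shapley column uses exact enumeration up to 10 nodes and Monte
    Carlo beyond (``shapley_mode="auto"``).
    """
    n = c.n_nodes
    if n == 0:
        raise ValueError("empty connectome")
    nodes = c.nodes
    idx = {v: i for i, v in enumerate(nodes)}
    out_adj, in_adj = index_adjacency(c)
    out_masks = [0] * n
    for i, nbrs in enumerate(out_adj):
        for j in nbrs:
            out_masks[i] |= 1 << j
    do = np.array([len(out_adj[i]) for i in range(n)])
    di = np.array([len(in_adj[i]) for i in range(n)])
    da = do + di
    und_nbrs = [sorted(set(out_adj[i]) | set(in_adj[i])) for i in range(n)]

    dist, sigma = all_pairs_geodesics(out_adj)
    finite = dist > 0

    # Katz status: column sums of (I - alpha*A)^-1 seen from the in-side,
    # alpha = 0.9 / spectral radius, unit exogenous contribution
    A = np.zeros((n, n))
    for i, nbrs in enumerate(out_adj):
        A[i, nbrs] = 1.0
    lam = float(np.max(np.abs(np.linalg.eigvals(A)))) if c.n_arcs else 0.0
    if lam > 0:
        katz = np.linalg.solve(np.eye(n) - (0.9 / lam) * A.T, np.ones(n))
    else:
        katz = np.ones(n)

    # eigenvector centrality on in-direction influence, max-normalized
    if c.n_arcs:
        eigvals, eigvecs = np.linalg.eig(A.T)
        lead = np.argmax(eigvals.real)
        ec = np.abs(eigvecs[:, lead].real)
        ec = ec / ec.max() if ec.max() > 0 else np.ones(n)
    else:
        ec = np.ones(n)

    ecc_out = np.array([dist[i][finite[i]].max() if finite[i].any() else 0
                        for i in range(n)])
    ecc_in = np.array([dist[:, i][finite[:, i]].max() if finite[:, i].any() else 0
                       for i in range(n)])

    und = c.to_networkx().to_undirected()
    cca = nx.clustering(und)

    # betweenness and stress by geodesic-count combination:
    # sigma_st(v) = sigma_sv * sigma_vt when d(s,t) = d(s,v) + d(v,t)
    bc = np.zeros(n)
    st = np.zeros(n)
    for v in range(n):
        for s in range(n):
            if s == v or not finite[s, v]:
                continue
            dsv = dist[s, v]
            for t in range(n):
                if t in (s, v) or not finite[v, t] or not finite[s, t]:
                    continue
                if dist[s, t] == dsv + dist[v, t]:
                    through = sigma[s, v] * sigma[v, t]
                    st[v] += through
                    bc[v] += through / sigma[s, t]

    co = harmonic_closeness(dist, axis=1)
    ci = harmonic_closeness(dist, axis=0)

    # radiality: mean reversed distance, diameter + 1 - d, over n-1
    diam = dist[finite].max() if finite.any() else 0
    ro = np.zeros(n)
    ri = np.zeros(n)
    if n > 1:
        rev = np.where(finite, diam + 1 - dist, 0)
        ro = rev.sum(axis=1) / (n - 1)
        ri = rev.sum(axis=0) / (n - 1)

    # centroid value: min over opponents of the closeness-dominance count
    big = 10 * (diam + 2)
    dall = np.where(dist >= 0, dist, big)
    ceno = np.zeros(n, dtype=int)
    ceni = np.zeros(n, dtype=int)
    for v in range(n):
        best_o, best_i = None, None
        for w in range(n):
            if w == v:
                continue
            others = [u for u in range(n) if u not in (v, w)]
            go = sum(1 for u in others if dall[v, u] < dall[w, u]) - sum(
                1 for u in others if dall[w, u] < dall[v, u])
            gi = sum(1 for u in others if dall[u, v] < dall[u, w]) - sum(
                1 for u in others if dall[u, w] < dall[u, v])
            best_o = go if best_o is None else min(best_o, go)
            best_i = gi if best_i is None else min(best_i, gi)
        ceno[v] = best_o if best_o is not None else 0
        ceni[v] = best_i if best_i is not None else 0

    if partition is None:
        partition, _ = modularity_partition(c, seed=seed)
    part_idx = np.array([partition[v] for v in nodes])

    def _module_z(deg_vec):
        z = np.zeros(n)
        for m in np.unique(part_idx):
            sel = part_idx == m
            within = np.zeros(sel.sum())
            members = np.where(sel)[0]
            for a, v in enumerate(members):
                within[a] = sum(
                    1 for u in (out_adj[v] if deg_vec is do else
                                in_adj[v] if deg_vec is di else und_all[v])
                    if part_idx[u] == m)
            mu, sd = within.mean(), within.std()
            z[members] = (within - mu) / sd if sd > 0 else 0.0
        return z

    und_all = [out_adj[i] + in_adj[i] for i in range(n)]  # multiset: degree-all links

    def _participation(neigh_lists, deg):
        pc = np.zeros(n)
        for v in range(n):
            if deg[v] == 0:
                continue
            per_mod: dict[int, int] = {}
            for u in neigh_lists[v]:
                per_mod[part_idx[u]] = per_mod.get(part_idx[u], 0) + 1
            pc[v] = 1 - sum((k / deg[v]) ** 2 for k in per_mod.values())
        return pc

    za, zo, zi = _module_z(None), _module_z(do), _module_z(di)
    pca = _participation(und_all, da)
    pco = _participation(out_adj, do)
    pci = _participation(in_adj, di)

    if shapley_mode == "auto":
        shapley_mode = "exact" if n <= 10 else "monte_carlo"
    shap = shapley_rates(c, mode=shapley_mode, n_perms=shapley_perms, seed=seed)

    rows = []
    for i, v in enumerate(nodes):
        neigh = und_nbrs[i]
        nb_deg = np.array([da[j] for j in neigh], dtype=float)
        adg = float(nb_deg.mean()) if neigh else 0.0
        vc = float(nb_deg.std() / nb_deg.mean()) if neigh and nb_deg.mean() > 0 else 0.0
        # locality: of all arcs touching the closed 1-neighborhood, the
        # fraction staying inside it
        hood = set(neigh) | {i}
        touching = inside = 0
        for (s, t) in c.arcs:
            si, ti = idx[s], idx[t]
            if si in hood or ti in hood:
                touching += 1
                if si in hood and ti in hood:
                    inside += 1
        loc = inside / touching if touching else 0.0
        ring2 = set()
        for j in neigh:
            ring2.update(und_nbrs[j])
        ring2 -= hood
        cc2 = float(np.mean([cca[nodes[j]] for j in ring2])) if ring2 else 0.0
        rows.append({
            "DGa": int(da[i]), "DGo": int(do[i]), "DGi": int(di[i]),
            "Katz": float(katz[i]),
            "Ecco": int(ecc_out[i]), "Ecci": int(ecc_in[i]),
            "CCo": _directed_neighborhood_clustering(out_adj[i], out_masks),
            "CCi": _directed_neighborhood_clustering(in_adj[i], out_masks),
            "CCa": float(cca[v]), "CC2": cc2,
            "ADG": adg, "VC": vc, "Loc": loc,
            "Co": float(co[i]), "Ci": float(ci[i]),
            "BC": float(bc[i]), "EC": float(ec[i]), "St": float(st[i]),
            "Shapley": shap[v],
            "Za": float(za[i]), "Zo": float(zo[i]), "Zi": float(zi[i]),
            "PCa": float(pca[i]), "PCo": float(pco[i]), "PCi": float(pci[i]),
            "Ro": float(ro[i]), "Ri": float(ri[i]),
            "Ceno": int(ceno[i]), "Ceni": int(ceni[i]),
        })
    return pd.DataFrame(rows, index=pd.Index(nodes, name="region"),
                        columns=LOCAL_COLUMNS)
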