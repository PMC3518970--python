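"""Random-network generators for baselines and motif significance.

Five kinds: Erdős–Rényi (uniform over simple digraphs with exactly n
nodes and e arcs), degree-preserving rewiring (double-arc swaps), and
directed adaptations of Watts–Strogatz, Barabási–Albert and the
ring-interpolation growth model of Ozik, Hunt & Ott.  The classic WS/BA
models are undirected; the directed readings used here are documented on
each generator.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import Arc, Connectome

__all__ = [
    "NullEnsembleSpec",
    "erdos_renyi",
    "rewire",
    "watts_strogatz_directed",
    "barabasi_albert_directed",
    "ozik_modified",
    "generate_null",
    "NULL_KINDS",
]

NULL_KINDS = ("erdos_renyi", "watts_strogatz", "barabasi_albert",
              "ozik_modified", "rewire")


@dataclass
class NullEnsembleSpec:
    """Which null ensemble to draw and how many replicates."""

    kind: str = "erdos_renyi"
    replicates: int = 1000
    seed: int = 0
    swap_multiplier: int = 10      # rewire
    p_rewire: float = 0.1          # watts_strogatz
    knobs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in NULL_KINDS:
            raise ValueError(f"unknown null kind {self.kind!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _nodes(n: int) -> list[str]:
    return [f"n{i:03d}" for i in range(n)]


def _check_e(n: int, e: int) -> None:
    if not 0 <= e <= n * (n - 1):
        raise ValueError(f"{e} arcs infeasible on {n} nodes")


def _from_pairs(n: int, pairs) -> Connectome:
    return Connectome(
        nodes=_nodes(n),
        arcs={(f"n{i:03d}", f"n{j:03d}"): Arc(weight=1) for i, j in pairs},
    )


def erdos_renyi(n: int, e: int, seed: int = 0) -> Connectome:
    """Uniformly random simple digraph with exactly n nodes and e arcs."""
    _check_e(n, e)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n * (n - 1), size=e, replace=False)
    pairs = []
    for c in chosen:
        i, r = divmod(int(c), n - 1)
        j = r if r < i else r + 1
        pairs.append((i, j))
    return _from_pairs(n, pairs)


def rewire(c: Connectome, swap_multiplier: int = 10, seed: int = 0,
           max_tries_factor: int = 100, n_swaps: int | None = None) -> Connectome:
    """Degree-preserving randomization by double-arc swaps.

    Repeatedly picks two arcs (a→b, c→d) and replaces them with
    (a→d, c→b), rejecting swaps that would create self-loops or
    duplicate arcs; every node keeps its exact in- and out-degree.
    Performs ``swap_multiplier * E`` successful swaps (or exactly
    ``n_swaps`` when given) or stops after ``max_tries_factor`` times
    that many attempts (saturated graphs with no legal swap come back as
    plain copies).
    """
    out = c.copy()
    e = out.n_arcs
    if e < 2:
        return out
    rng = np.random.default_rng(seed)
    arcs = list(out.arcs.keys())
    arc_set = set(arcs)
    target = swap_multiplier * e if n_swaps is None else n_swaps
    tries = 0
    done = 0
    max_tries = max_tries_factor * max(target, 1)
    while done < target and tries < max_tries:
        tries += 1
        i1, i2 = rng.integers(0, e, size=2)
        if i1 == i2:
            continue
        a, b = arcs[i1]
        cc, d = arcs[i2]
        if a == d or cc == b or b == d or a == cc:
            continue
        if (a, d) in arc_set or (cc, b) in arc_set:
            continue
        arc_set.discard((a, b))
        arc_set.discard((cc, d))
        arc_set.add((a, d))
        arc_set.add((cc, b))
        arcs[int(i1)] = (a, d)
        arcs[int(i2)] = (cc, b)
        done += 1
    weights = list(out.arcs.values())
    return Connectome(
        nodes=list(out.nodes),
        arcs={pair: Arc(weight=w.weight, n_studies=w.n_studies)
              for pair, w in zip(arcs, weights)},
    )


def watts_strogatz_directed(n: int, e: int, p_rewire: float = 0.1,
                            seed: int = 0) -> Connectome:
    """Directed small-world graph: ring lattice plus random re-targeting.

    Lattice arcs point both ways round the ring; offsets grow outward
    (±1, ±2, ...) and arcs are taken in round-robin order over nodes
    until exactly ``e`` arcs exist (the trim rule).  Each arc is then
    re-targeted with probability ``p_rewire`` to a uniformly random
    target, rejecting self-loops and duplicates.
    """
    _check_e(n, e)
    if not 0 <= p_rewire <= 1:
        raise ValueError("p_rewire outside [0, 1]")
    rng = np.random.default_rng(seed)
    pairs: list[tuple[int, int]] = []
    offset, sign = 1, 1
    while len(pairs) < e:
        if offset >= n:
            raise ValueError(f"{e} arcs infeasible for the ring construction")
        for i in range(n):
            if len(pairs) >= e:
                break
            pairs.append((i, (i + sign * offset) % n))
        if sign == 1:
            sign = -1
        else:
            sign, offset = 1, offset + 1
    arc_set = set(pairs)
    if p_rewire > 0:
        for k, (i, j) in enumerate(pairs):
            if rng.random() < p_rewire:
                for _ in range(4 * n):
                    t = int(rng.integers(0, n))
                    if t != i and (i, t) not in arc_set:
                        arc_set.discard((i, j))
                        arc_set.add((i, t))
                        pairs[k] = (i, t)
                        break
    return _from_pairs(n, pairs)


def barabasi_albert_directed(n: int, e: int, seed: int = 0) -> Connectome:
    """Directed preferential attachment with exact arc count.

    Starts from a small reciprocal seed clique; each new node adds arcs
    whose far endpoint is drawn preferentially by total (in+out) degree,
    alternating arc direction, until the global budget ``e`` is spent
    (the stop rule).  Leftover budget after growth is filled with
    preferentially chosen random arcs.
    """
    _check_e(n, e)
    rng = np.random.default_rng(seed)
    if n == 0 or e == 0:
        return _from_pairs(n, [])
    m = max(1, round(e / max(n, 1)))
    n0 = min(n, m + 1)
    arc_set: set[tuple[int, int]] = set()
    deg = np.zeros(n)
    for i in range(n0):
        for j in range(n0):
            if i != j and len(arc_set) < e:
                arc_set.add((i, j))
                deg[i] += 1
                deg[j] += 1

    def _pick(active: int) -> int:
        w = deg[:active].copy() + 1e-9
        w /= w.sum()
        return int(rng.choice(active, p=w))

    for v in range(n0, n):
        budget = min(m, e - len(arc_set))
        added = 0
        tries = 0
        while added < budget and tries < 100 * (budget + 1):
            tries += 1
            u = _pick(v)
            pair = (v, u) if added % 2 == 0 else (u, v)
            if pair[0] != pair[1] and pair not in arc_set:
                arc_set.add(pair)
                deg[u] += 1
                deg[v] += 1
                added += 1
    tries = 0
    while len(arc_set) < e and tries < 1000 * e:
        tries += 1
        u = _pick(n)
        v = _pick(n)
        if u != v and (u, v) not in arc_set:
            arc_set.add((u, v))
            deg[u] += 1
            deg[v] += 1
    return _from_pairs(n, arc_set)


def ozik_modified(n: int, e: int, seed: int = 0) -> Connectome:
    """Directed variant of the interpolating-growth small-world model.

    Nodes live on a ring; each new node is inserted at a random ring
    position and connects to its nearest ring neighbors on both sides,
    alternating arc direction outward, until its per-node budget is
    spent.  The documented reading of the construction: growth plus
    geographically local attachment, giving high clustering with a
    broadening degree distribution.  Arc budget handled as in the BA
    adaptation (stop rule, preferential fill).
    """
    _check_e(n, e)
    rng = np.random.default_rng(seed)
    if n == 0 or e == 0:
        return _from_pairs(n, [])
    m = max(1, round(e / max(n, 1)))
    ring: list[int] = [0]
    arc_set: set[tuple[int, int]] = set()
    for v in range(1, n):
        pos = int(rng.integers(0, len(ring)))
        ring.insert(pos + 1, v)
        budget = min(m, e - len(arc_set))
        added = 0
        step = 1
        L = len(ring)
        while added < budget and step < L:
            for side in (1, -1):
                if added >= budget:
                    break
                u = ring[(pos + 1 + side * step) % L]
                if u == v:
                    continue
                pair = (v, u) if added % 2 == 0 else (u, v)
                if pair not in arc_set:
                    arc_set.add(pair)
                    added += 1
            step += 1
    deg = np.zeros(n)
    for i, j in arc_set:
        deg[i] += 1
        deg[j] += 1
    tries = 0
    while len(arc_set) < e and tries < 1000 * e:
        tries += 1
        w = deg + 1e-9
        w /= w.sum()
        u, v = rng.choice(n, size=2, p=w)
        if u != v and (int(u), int(v)) not in arc_set:
            arc_set.add((int(u), int(v)))
            deg[u] += 1
            deg[v] += 1
    return _from_pairs(n, arc_set)


def generate_null(spec: NullEnsembleSpec, n: int, e: int,
                  template: Connectome | None = None, replicate: int = 0) -> Connectome:
    """Draw one replicate of the requested kind (seeded per replicate)."""
    seed = (spec.seed + 7919 * replicate) % (2**31 - 1)
    if spec.kind == "erdos_renyi":
        return erdos_renyi(n, e, seed)
    if spec.kind == "watts_strogatz":
        return watts_strogatz_directed(n, e, spec.p_rewire, seed)
    if spec.kind == "barabasi_albert":
        return barabasi_albert_directed(n, e, seed)
    if spec.kind == "ozik_modified":
        return ozik_modified(n, e, seed)
    if template is None:
        raise ValueError("rewire null needs the real connectome as template")
    return rewire(template, spec.swap_multiplier, seed)
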