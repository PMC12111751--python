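"""Independent naive re-implementation of the greedy dense-module search.

Used as the oracle in tests: every step recomputes the candidate set by
explicit per-node shortest-path distances and re-scores every candidate
module from scratch, sharing no code path with the package's
incremental implementation.
"""

from __future__ import annotations

import math
from collections import deque


def bfs_distance(adj: dict[str, set[str]], sources: set[str], target: str) -> int:
    """Shortest-path distance from any source to target (inf if unreachable)."""
    if target in sources:
        return 0
    seen = set(sources)
    queue = deque((s, 0) for s in sources)
    while queue:
        node, d = queue.popleft()
        for nb in adj[node]:
            if nb == target:
                return d + 1
            if nb not in seen:
                seen.add(nb)
                queue.append((nb, d + 1))
    return math.inf


def score_set(genes: list[str], weights: dict[str, float],
              edge_w: dict[tuple[str, str], float] | None, lam: float | None) -> float:
    k = len(genes)
    s = sum(weights[g] for g in genes)
    if lam is None:
        return s / math.sqrt(k)
    m, sw = 0, 0.0
    gs = set(genes)
    for (a, b), w in edge_w.items():
        if a in gs and b in gs:
            m += 1
            sw += w
    return (s + lam * sw) / math.sqrt(k + lam**2 * m)


def naive_search(edges: list[tuple[str, str]], weights: dict[str, float],
                 seed_gene: str, d: int = 2, r: float = 0.1,
                 edge_w: dict[tuple[str, str], float] | None = None,
                 lam: float | None = None) -> tuple[list[str], float]:
    """Grow one module from ``seed_gene``; returns (gene sequence, final score).

    In edge-weighted mode (``edge_w`` given) the graph is restricted to
    edges carrying a weight between weighted genes, mirroring the
    contract of the package implementation.
    """
    if edge_w is not None:
        edge_w = {tuple(sorted(e)): w for e, w in edge_w.items()}
        edges = [e for e in (tuple(sorted(e)) for e in edges)
                 if e in edge_w and e[0] in weights and e[1] in weights]
    adj: dict[str, set[str]] = {g: set() for g in weights}
    for a, b in edges:
        if a in weights and b in weights and a != b:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)

    members = [seed_gene]
    current = score_set(members, weights, edge_w, lam)
    while True:
        member_set = set(members)
        candidates = [g for g in weights
                      if g not in member_set
                      and bfs_distance(adj, member_set, g) <= d]
        best, best_score = None, -math.inf
        for c in sorted(candidates):
            sc = score_set(members + [c], weights, edge_w, lam)
            if sc > best_score:
                best, best_score = c, sc
        if best is None or not best_score > current * (1 + r):
            return members, current
        members.append(best)
        current = best_score


def random_trial_graph(rng, n_max: int = 12):
    """Random small weighted graph for oracle-equivalence trials."""
    n = int(rng.integers(3, n_max + 1))
    genes = [f"N{i:02d}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.35:
                edges.append((genes[i], genes[j]))
    # keep at least a spanning path so searches have room to grow
    for i in range(n - 1):
        edges.append((genes[i], genes[i + 1]))
    edges = sorted(set(tuple(sorted(e)) for e in edges))
    weights = {g: float(rng.normal(0.5, 1.5)) for g in genes}
    edge_w = {e: float(abs(rng.normal(1.0, 1.0))) for e in edges}
    return genes, edges, weights, edge_w
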