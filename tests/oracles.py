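"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — direct definitions, exhaustive
enumeration, dense linear algebra — and shares no code path with the
package.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


# -- pruning ---------------------------------------------------------------

def adjustcd_k1(edges: list[tuple[str, str]], u: str, v: str) -> float:
    """Round-1 reliability score from the definition, via raw set algebra."""
    nodes = sorted({a for e in edges for a in e})
    nbhd = {x: {x} for x in nodes}
    for a, b in edges:
        nbhd[a].add(b)
        nbhd[b].add(a)
    n_avg = sum(len(nbhd[x]) for x in nodes) / len(nodes)
    lam = {x: max(0.0, n_avg - len(nbhd[x])) for x in nodes}
    s = len(nbhd[u] & nbhd[v])
    return 2.0 * s / ((len(nbhd[u]) + lam[u]) + (len(nbhd[v]) + lam[v]))


def is_connected_sets(nodes: set[str], edges: list[tuple[str, str]]) -> bool:
    """Hand-rolled BFS connectivity check."""
    if not nodes:
        return True
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for a, b in edges:
        if a in adj and b in adj:
            adj[a].add(b)
            adj[b].add(a)
    start = next(iter(nodes))
    seen = {start}
    frontier = [start]
    while frontier:
        nxt = []
        for x in frontier:
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    nxt.append(y)
        frontier = nxt
    return seen == nodes


# -- ranking ---------------------------------------------------------------

def pagerank_linear_solve(
    nodes: list[str],
    weighted_edges: list[tuple[str, str, float]],
    damping: float = 0.85,
) -> dict[str, float]:
    """Exact damped-walk stationary distribution via a dense linear solve.

    Solves (I − d·Mᵀ) r = (1−d)/n · 1 with the same transition convention
    as the implementation (weight-proportional steps, isolated nodes
    teleport uniformly), which is the eigen-solution of the Google matrix.
    """
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    m = np.zeros((n, n))
    totals = {u: 0.0 for u in nodes}
    for a, b, w in weighted_edges:
        totals[a] += w
        totals[b] += w
    for a, b, w in weighted_edges:
        m[idx[a], idx[b]] += w / totals[a]
        m[idx[b], idx[a]] += w / totals[b]
    for u in nodes:
        if totals[u] == 0.0:
            m[idx[u], :] = 1.0 / n
    r = np.linalg.solve(np.eye(n) - damping * m.T, np.full(n, (1 - damping) / n))
    r = r / r.sum()
    return {u: float(r[idx[u]]) for u in nodes}


# -- evaluation ------------------------------------------------------------

def brute_omega(a: set, b: set) -> float:
    return len(a & b) ** 2 / (len(a) * len(b))


def brute_sn_ppv_acc(refs: list[set], preds: list[set]) -> tuple[float, float, float]:
    """Sn/PPV/Acc straight from the definitions with explicit loops."""
    sn_num = sum(max(len(r & p) for p in preds) for r in refs)
    sn = sn_num / sum(len(r) for r in refs)
    col_max = sum(max(len(r & p) for r in refs) for p in preds)
    col_tot = sum(len(r & p) for r in refs for p in preds)
    ppv = col_max / col_tot if col_tot > 0 else 0.0
    return sn, ppv, (sn * ppv) ** 0.5


def brute_mmr(refs: list[set], preds: list[set]) -> float:
    """Maximum matching ratio by exhaustive recursion over all matchings."""
    m = len(preds)

    def best(i: int, used: frozenset) -> float:
        if i == len(refs):
            return 0.0
        # leave reference i unmatched
        score = best(i + 1, used)
        for j in range(m):
            if j in used:
                continue
            w = brute_omega(refs[i], preds[j])
            if w > 0.0:
                score = max(score, w + best(i + 1, used | {j}))
        return score

    return best(0, frozenset()) / len(refs)


# -- merging ---------------------------------------------------------------

def brute_cohesiveness(
    weighted_edges: list[tuple[str, str, float]], members: set, p: float
) -> float:
    w_in = sum(w for a, b, w in weighted_edges if a in members and b in members)
    w_out = sum(w for a, b, w in weighted_edges if (a in members) != (b in members))
    denom = w_in + w_out + p
    return w_in / denom if denom > 0 else 0.0


# -- random instances ------------------------------------------------------

def random_complex_sets(
    rng: np.random.Generator, universe: int = 12, max_complexes: int = 6
) -> tuple[list[set], list[set]]:
    """A random reference/predicted pair over a small protein universe."""
    proteins = [f"p{i}" for i in range(universe)]

    def draw() -> list[set]:
        k = int(rng.integers(1, max_complexes + 1))
        out = []
        for _ in range(k):
            size = int(rng.integers(1, 6))
            out.append(set(rng.choice(proteins, size=size, replace=False)))
        return out

    return draw(), draw()


def random_edges(
    rng: np.random.Generator, n: int, p: float, weighted: bool = False
) -> list[tuple[str, str, float]]:
    nodes = [f"n{i:02d}" for i in range(n)]
    out = []
    for a, b in combinations(nodes, 2):
        if rng.random() < p:
            w = float(rng.uniform(0.2, 1.0)) if weighted else 1.0
            out.append((a, b, w))
    return out
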