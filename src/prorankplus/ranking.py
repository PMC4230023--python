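"""Protein importance ranking by a weighted PageRank-style random walk.

Proteins are ordered by the stationary distribution of a damped random walk
on the interaction graph: with probability ``d`` the walker follows an
interaction chosen proportionally to its weight, with probability ``1 − d``
it teleports to a uniformly random protein.  Isolated proteins teleport
uniformly.  For unweighted networks this reduces to the classical uniform
transition.  The resulting scores sum to one and are strictly positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .network import PPINetwork
from .pruning import ProteinClassification

__all__ = ["RankVector", "rank_proteins", "ordered_essentials"]


@dataclass
class RankVector:
    """Normalized importance score per protein."""

    scores: dict[str, float]
    damping: float = 0.85
    tolerance: float = 1e-9
    iterations_run: int = 0
    converged: bool = True

    def __getitem__(self, protein: str) -> float:
        return self.scores[protein]

    def __len__(self) -> int:
        return len(self.scores)

    def top(self, k: int) -> list[str]:
        """The ``k`` highest-scoring proteins, ties broken lexicographically."""
        return sorted(self.scores, key=lambda p: (-self.scores[p], p))[:k]


def rank_proteins(
    net: PPINetwork,
    damping: float = 0.85,
    tolerance: float = 1e-9,
    max_iter: int = 200,
) -> RankVector:
    """Power iteration for ``r = (1−d)/n + d·Mᵀr``.

    ``M`` is the row-stochastic transition matrix with
    ``M(u,v) = w(u,v) / Σ_x w(u,x)`` over neighbors; rows of isolated nodes
    are uniform (teleportation).  Iteration stops when the L1 change drops
    below ``tolerance``; non-convergence at ``max_iter`` emits a warning and
    returns the last iterate.  The result is normalized to sum to 1.
    """
    if not 0.0 < damping < 1.0:
        raise ValueError(f"damping must be in (0, 1), got {damping}")
    g = net.graph
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("cannot rank an empty network")

    nodes = sorted(g.nodes)
    index = {u: i for i, u in enumerate(nodes)}
    rows, cols, vals = [], [], []
    dangling = np.zeros(n, dtype=bool)
    for u in nodes:
        total = sum(d["weight"] for d in g[u].values())
        if total <= 0:
            dangling[index[u]] = True
            continue
        for v, d in g[u].items():
            rows.append(index[u])
            cols.append(index[v])
            vals.append(d["weight"] / total)
    m = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    mt = m.T.tocsr()

    r = np.full(n, 1.0 / n)
    teleport = (1.0 - damping) / n
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        r_new = teleport + damping * (mt @ r + r[dangling].sum() / n)
        delta = np.abs(r_new - r).sum()
        r = r_new
        if delta < tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"ranking did not converge in {max_iter} iterations "
            f"(last L1 change {delta:.3e})",
            stacklevel=2,
        )
    r = r / r.sum()
    return RankVector(
        scores={u: float(r[index[u]]) for u in nodes},
        damping=damping,
        tolerance=tolerance,
        iterations_run=iterations,
        converged=converged,
    )


def ordered_essentials(
    rank: RankVector, cls: ProteinClassification
) -> list[str]:
    """Essential proteins in decreasing rank order (lexicographic tie-break).

    The rank vector and the classification must cover the same node set.
    """
    if set(rank.scores) != set(cls.labels):
        raise ValueError("rank vector and classification cover different node sets")
    essentials = [p for p in rank.scores if cls.is_essential(p)]
    return sorted(essentials, key=lambda p: (-rank.scores[p], p))
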