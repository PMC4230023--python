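"""Interaction-reliability pruning and topological noise-protein filtering.

Stage 1 scores every interaction with an iterative, topology-based
reliability weight (an adjusted Czekanowski-Dice neighborhood similarity,
"AdjustCD") and discards interactions scoring below a threshold — 0.2 for
weighted networks, 0.45 for unweighted ones by default.  The AdjustCD score
is used only for the pruning decision; surviving edges keep their original
input weights.

Stage 2 classifies every protein of the pruned network as *essential* or as
one of three topological noise categories:

bridge
    the subgraph induced on the protein's neighbors is disconnected;
fjord
    that induced subgraph is connected but sparse (edge density below a
    threshold);
shore
    at least one neighbor is nearly isolated (degree at or below a
    threshold).

Only essential proteins later seed spoke-model complexes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean
from typing import Literal

import networkx as nx

from .network import PPINetwork

__all__ = [
    "PruningParams",
    "FilterParams",
    "ProteinClassification",
    "adjustcd_scores",
    "prune",
    "classify_proteins",
    "default_prune_threshold",
]

#: Pruning thresholds established experimentally for the two network kinds.
WEIGHTED_PRUNE_THRESHOLD = 0.2
UNWEIGHTED_PRUNE_THRESHOLD = 0.45

Label = Literal["essential", "bridge", "fjord", "shore"]
NOISE_LABELS: tuple[str, ...] = ("bridge", "fjord", "shore")


def default_prune_threshold(weighted: bool) -> float:
    return WEIGHTED_PRUNE_THRESHOLD if weighted else UNWEIGHTED_PRUNE_THRESHOLD


@dataclass
class PruningParams:
    """Parameters of the reliability-pruning stage.

    ``threshold`` — minimum AdjustCD score an interaction must reach to be
    kept (in [0, 1]).  ``iterations`` — number of AdjustCD refinement
    rounds; at round 1 the score is the smoothed fraction of shared
    neighbors, later rounds re-weight neighborhoods by the previous round's
    scores.
    """

    threshold: float = WEIGHTED_PRUNE_THRESHOLD
    iterations: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")
        if self.iterations < 1:
            raise ValueError(f"iterations must be >= 1, got {self.iterations}")


def adjustcd_scores(
    net: PPINetwork, params: PruningParams | None = None
) -> dict[tuple[str, str], float]:
    """Iterative topology-based reliability score for every edge.

    With self-inclusive neighborhoods ``N_u = {u} ∪ neighbors(u)`` the
    round-1 score of edge (u, v) is::

        score(u, v) = 2·|N_u ∩ N_v| / ((|N_u| + λ_u) + (|N_v| + λ_v))

    where ``λ_u = max(0, n_avg − |N_u|)`` smooths low-degree nodes against
    spuriously high similarity (``n_avg`` is the mean self-inclusive
    neighborhood size).  Later rounds replace the counts by sums of the
    previous round's scores over the same neighborhoods:
    ``D_k(u) = Σ_{x∈N_u} w_{k−1}(u,x)`` and
    ``S_k(u,v) = Σ_{x∈N_u∩N_v} (w_{k−1}(u,x) + w_{k−1}(v,x)) / 2``, with the
    self-score ``w(u,u)`` fixed at 1.

    Returns a dict keyed by sorted node pair.  Scores are symmetric and lie
    in [0, 1].
    """
    if params is None:
        params = PruningParams()
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("cannot score an empty network")

    nbhd = {u: set(g[u]) | {u} for u in g}
    n_avg = fmean(len(nbhd[u]) for u in g)
    lam = {u: max(0.0, n_avg - len(nbhd[u])) for u in g}

    def key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    # w holds the current score on every edge plus the fixed self-score 1.
    w: dict[tuple[str, str], float] = {(u, u): 1.0 for u in g}
    w.update({key(u, v): 1.0 for u, v in g.edges})

    scores: dict[tuple[str, str], float] = {}
    for _ in range(params.iterations):
        d = {u: sum(w[key(u, x)] for x in nbhd[u]) for u in g}
        scores = {}
        for u, v in g.edges:
            common = nbhd[u] & nbhd[v]
            s = sum(w[key(u, x)] + w[key(v, x)] for x in common) / 2.0
            denom = (d[u] + lam[u]) + (d[v] + lam[v])
            scores[key(u, v)] = 2.0 * s / denom if denom > 0 else 0.0
        w = {(u, u): 1.0 for u in g}
        w.update(scores)
    return scores


def prune(net: PPINetwork, params: PruningParams | None = None) -> PPINetwork:
    """Drop edges whose AdjustCD score falls below ``params.threshold``.

    Surviving edges keep their original input weights; nodes isolated by the
    pruning are retained in the graph.
    """
    if params is None:
        params = PruningParams(default_prune_threshold(net.is_weighted))
    scores = adjustcd_scores(net, params)
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    for u, v, w in net.graph.edges(data="weight", default=1.0):
        k = (u, v) if u <= v else (v, u)
        if scores[k] >= params.threshold:
            g.add_edge(u, v, weight=w)
    return PPINetwork(graph=g, is_weighted=net.is_weighted)


@dataclass
class FilterParams:
    """Cutoffs for the qualitative noise definitions.

    ``fjord_density`` — a protein is a fjord when its neighbors' induced
    subgraph has edge density below this value.  ``shore_degree`` — a
    protein is a shore when some neighbor has degree at or below this value.
    """

    fjord_density: float = 0.1
    shore_degree: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.fjord_density <= 1.0:
            raise ValueError("fjord_density must be in [0, 1]")
        if self.shore_degree < 0:
            raise ValueError("shore_degree must be >= 0")


@dataclass
class ProteinClassification:
    """Per-protein label: essential or a noise category (bridge/fjord/shore)."""

    labels: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, protein: str) -> str:
        return self.labels[protein]

    def is_essential(self, protein: str) -> bool:
        return self.labels.get(protein) == "essential"

    @property
    def essential_proteins(self) -> set[str]:
        return {p for p, l in self.labels.items() if l == "essential"}

    def counts(self) -> dict[str, int]:
        out = {"essential": 0, "bridge": 0, "fjord": 0, "shore": 0}
        for l in self.labels.values():
            out[l] += 1
        return out


def classify_proteins(
    net: PPINetwork, params: FilterParams | None = None
) -> ProteinClassification:
    """Label every node of the (pruned) network.

    For node ``p`` the induced subgraph on its neighbor set (excluding
    ``p``) decides the label, with precedence bridge > fjord > shore:
    disconnected → bridge; density below ``fjord_density`` → fjord; some
    neighbor of degree ≤ ``shore_degree`` → shore; otherwise essential.
    Nodes of degree ≤ 1 are labelled shore outright — their spoke complex
    could never reach three members.
    """
    if params is None:
        params = FilterParams()
    g = net.graph
    labels: dict[str, str] = {}
    for p in g:
        nbrs = list(g[p])
        if len(nbrs) <= 1:
            labels[p] = "shore"
            continue
        sub = g.subgraph(nbrs)
        if not nx.is_connected(sub):
            labels[p] = "bridge"
        elif nx.density(sub) < params.fjord_density:
            labels[p] = "fjord"
        elif any(g.degree(q) <= params.shore_degree for q in nbrs):
            labels[p] = "shore"
        else:
            labels[p] = "essential"
    return ProteinClassification(labels=labels)
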