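"""Planted-complex benchmark networks with known ground truth.

The generator embeds dense, optionally overlapping protein complexes in a
background of noise edges so the whole detection pipeline and the evaluator
can be exercised without any external dataset.  Each planted complex is an
Erdős–Rényi subgraph at within-complex density ``p_in`` (re-sampled until
connected); overlap is realised by letting a complex share one hub member
with its predecessor; every remaining node pair receives a background edge
with probability ``p_out``.  Real interactomes show exactly this overlap
structure — in curated yeast catalogs a large fraction of proteins belongs
to more than one complex — though the generator makes no attempt at
realistic degree distributions or bait–prey sampling artefacts.

Output is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from .network import Complex, ComplexSet, PPINetwork

__all__ = ["PlantedModel", "generate", "random_partition"]


@dataclass
class PlantedModel:
    """Description of a planted-complex network.

    ``overlap_fraction`` is the fraction of consecutive complex pairs that
    share one member.  ``weight_noise`` is the interval edge weights are
    drawn from (confidence-like scores); ``None`` yields an unweighted
    network.  ``n_background`` adds extra noise proteins belonging to no
    complex.
    """

    n_complexes: int = 10
    size_range: tuple[int, int] = (4, 8)
    p_in: float = 0.9
    p_out: float = 0.01
    overlap_fraction: float = 0.0
    weight_noise: tuple[float, float] | None = (0.5, 1.0)
    n_background: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if lo < 3 or hi < lo:
            raise ValueError("complex sizes must satisfy 3 <= min <= max")
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.n_complexes < 1:
            raise ValueError("need at least one complex")
        if self.weight_noise is not None:
            wlo, whi = self.weight_noise
            if not 0.0 < wlo <= whi:
                raise ValueError("weight interval must be positive and ordered")


def _sample_connected_er(
    rng: np.random.Generator, members: list[str], p_in: float, max_tries: int = 1000
) -> list[tuple[str, str]]:
    """Erdős–Rényi edges on ``members``, re-sampled until connected."""
    pairs = list(combinations(sorted(members), 2))
    for _ in range(max_tries):
        mask = rng.random(len(pairs)) < p_in
        edges = [e for e, keep in zip(pairs, mask) if keep]
        g = nx.Graph(edges)
        g.add_nodes_from(members)
        if nx.is_connected(g):
            return edges
    raise RuntimeError(
        f"could not draw a connected complex of size {len(members)} at p_in={p_in}"
    )


def generate(model: PlantedModel) -> tuple[PPINetwork, ComplexSet]:
    """Draw one network and its ground-truth complex catalog.

    Identical models (including the seed) produce identical output.
    """
    rng = np.random.default_rng(model.seed)
    lo, hi = model.size_range
    sizes = rng.integers(lo, hi + 1, size=model.n_complexes)

    next_id = 0

    def new_node() -> str:
        nonlocal next_id
        next_id += 1
        return f"P{next_id:05d}"

    n_shared = round(model.overlap_fraction * max(0, model.n_complexes - 1))
    memberships: list[list[str]] = []
    for i, size in enumerate(sizes):
        members: list[str] = []
        if 1 <= i <= n_shared:
            # hub member shared with the previous complex
            prev = memberships[i - 1]
            members.append(prev[int(rng.integers(len(prev)))])
        while len(members) < size:
            members.append(new_node())
        memberships.append(members)
    background = [new_node() for _ in range(model.n_background)]

    g = nx.Graph()
    for members in memberships:
        g.add_nodes_from(members)
    g.add_nodes_from(background)

    co_member: set[tuple[str, str]] = set()
    for members in memberships:
        for a, b in combinations(sorted(members), 2):
            co_member.add((a, b))
        for a, b in _sample_connected_er(rng, members, model.p_in):
            g.add_edge(a, b)

    all_nodes = sorted(g.nodes)
    for a, b in combinations(all_nodes, 2):
        if (a, b) in co_member:
            continue
        if rng.random() < model.p_out:
            g.add_edge(a, b)

    weighted = model.weight_noise is not None
    if weighted:
        wlo, whi = model.weight_noise
        for a, b in sorted(g.edges):
            g[a][b]["weight"] = float(rng.uniform(wlo, whi))
    else:
        nx.set_edge_attributes(g, 1.0, "weight")

    truth = ComplexSet([Complex(frozenset(m)) for m in memberships])
    return PPINetwork(graph=g, is_weighted=weighted), truth


def random_partition(
    nodes, sizes, seed: int = 0
) -> ComplexSet:
    """Baseline predictor: shuffle the proteins and cut them into complexes
    of the given sizes (truncating when proteins run out).  Used as the
    chance-level comparator for recovery experiments.
    """
    rng = np.random.default_rng(seed)
    pool = sorted(nodes)
    rng.shuffle(pool)
    out: list[Complex] = []
    start = 0
    for size in sizes:
        chunk = pool[start : start + size]
        if not chunk:
            break
        out.append(Complex(frozenset(chunk)))
        start += size
    return ComplexSet(out)
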