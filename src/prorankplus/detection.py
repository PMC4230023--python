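"""Spoke-model complex detection.

Each essential protein, visited in decreasing rank order, is pulled from the
network together with all of its direct interaction partners to form a
candidate complex (the spoke model).  A protein may belong to several
complexes — seeds that share many neighbors deliberately produce
overlapping candidates, which the merging stage later consolidates.
Candidates with fewer than three members are discarded, and exact duplicate
member-sets are removed keeping the earliest (highest-ranked seed).
"""

from __future__ import annotations

from .network import Complex, ComplexSet, PPINetwork
from .pruning import ProteinClassification
from .ranking import RankVector, ordered_essentials

__all__ = ["spoke_complex", "detect_complexes", "remove_duplicates", "MIN_COMPLEX_SIZE"]

#: Complexes below this size are never emitted.
MIN_COMPLEX_SIZE = 3


def spoke_complex(
    net: PPINetwork, seed: str, cls: ProteinClassification
) -> Complex:
    """Complex formed by ``seed`` and all of its neighbors.

    ``seed`` must be present in the network and classified essential.
    """
    if seed not in net.graph:
        raise ValueError(f"seed {seed!r} not in network")
    if not cls.is_essential(seed):
        raise ValueError(f"seed {seed!r} is not an essential protein")
    members = frozenset({seed} | set(net.graph[seed]))
    essential = frozenset(m for m in members if cls.is_essential(m))
    return Complex(members=members, seed=seed, essential_members=essential)


def detect_complexes(
    net: PPINetwork,
    rank: RankVector,
    cls: ProteinClassification,
    min_size: int = MIN_COMPLEX_SIZE,
) -> ComplexSet:
    """One spoke complex per essential protein, in descending rank order.

    Undersized complexes are dropped; among identical member-sets only the
    one seeded by the highest-ranked protein is kept.  The result may be
    empty when no protein is essential.
    """
    out: list[Complex] = []
    seen: set[frozenset[str]] = set()
    for seed in ordered_essentials(rank, cls):
        c = spoke_complex(net, seed, cls)
        if len(c) < min_size or c.members in seen:
            continue
        seen.add(c.members)
        out.append(c)
    return ComplexSet(out)


def remove_duplicates(cs: ComplexSet) -> ComplexSet:
    """Keep the first occurrence of each distinct member-set; idempotent."""
    out: list[Complex] = []
    seen: set[frozenset[str]] = set()
    for c in cs:
        if c.members in seen:
            continue
        seen.add(c.members)
        out.append(c)
    return ComplexSet(out)
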