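"""Merging by cohesiveness: consolidate highly-overlapping complexes.

Two detected complexes whose essential-protein overlap exceeds a merging
threshold (default 75%) are replaced by their union, which is then greedily
expanded: for every protein initially in the merged complex, each of its
network neighbors is admitted whenever adding it does not decrease the
cohesiveness

    cohesiveness(C) = w_in(C) / (w_in(C) + w_out(C) + p)

where ``w_in`` sums the weights of edges entirely inside C, ``w_out`` sums
the weights of edges leaving C, and ``p`` is a penalty for unobserved
interactions.  The procedure models a complex as a set of strongly
interconnected proteins that is well separated from the rest of the
network, without requiring it to be a dense subgraph.

Merging repeats in deterministic passes until no pair overlaps above the
threshold (or a pass cap is hit), then duplicates and undersized complexes
are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .detection import MIN_COMPLEX_SIZE, remove_duplicates
from .network import Complex, ComplexSet, PPINetwork
from .pruning import ProteinClassification

__all__ = [
    "MergeParams",
    "cohesiveness",
    "essential_overlap",
    "expand_by_cohesiveness",
    "merge_by_cohesiveness",
    "merge_all",
]


@dataclass
class MergeParams:
    """Knobs of the merge stage.

    ``threshold`` — minimum essential-protein overlap (strict) for two
    complexes to merge.  ``penalty`` — the cohesiveness penalty ``p``.
    ``overlap_mode`` — overlap denominator: ``"min"`` (containment; a small
    complex fully inside a larger one always merges) or ``"jaccard"``.
    ``max_passes`` — cap on merge passes before giving up with a warning.
    """

    threshold: float = 0.75
    penalty: float = 2.0
    overlap_mode: str = "min"
    max_passes: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must be in (0, 1]")
        if self.penalty < 0:
            raise ValueError("penalty must be nonnegative")
        if self.overlap_mode not in ("min", "jaccard"):
            raise ValueError(f"unknown overlap_mode {self.overlap_mode!r}")
        if self.max_passes < 1:
            raise ValueError("max_passes must be >= 1")


def cohesiveness(net: PPINetwork, members, penalty: float = 2.0) -> float:
    """``w_in / (w_in + w_out + p)`` for the protein set ``members``.

    ``w_in`` — total weight of edges with both endpoints in the set;
    ``w_out`` — total weight of edges with exactly one endpoint in it.
    Lies in [0, 1] for ``p ≥ 0``; defined as 0 for an edgeless set with
    ``p = 0``.
    """
    members = set(members)
    if not members:
        raise ValueError("cohesiveness of an empty set is undefined")
    g = net.graph
    missing = members - set(g)
    if missing:
        raise ValueError(f"proteins not in network: {sorted(missing)[:5]}")
    w_in = 0.0
    w_out = 0.0
    for u in members:
        for v, data in g[u].items():
            w = data["weight"]
            if v in members:
                if u < v:  # count internal edges once
                    w_in += w
            else:
                w_out += w
    denom = w_in + w_out + penalty
    return w_in / denom if denom > 0 else 0.0


def essential_overlap(c1: Complex, c2: Complex, mode: str = "min") -> float:
    """Fraction of shared essential proteins between two complexes.

    With ``mode="min"`` the denominator is the smaller essential set
    (containment overlap); with ``"jaccard"`` it is the union.  Returns 0
    when either complex has no essential members.
    """
    e1, e2 = c1.essential_members, c2.essential_members
    if not e1 or not e2:
        return 0.0
    inter = len(e1 & e2)
    if mode == "min":
        return inter / min(len(e1), len(e2))
    if mode == "jaccard":
        return inter / len(e1 | e2)
    raise ValueError(f"unknown overlap mode {mode!r}")


def expand_by_cohesiveness(
    net: PPINetwork, members, penalty: float = 2.0
) -> tuple[frozenset[str], list[float]]:
    """Greedy neighbor admission around a starting protein set.

    Scans the proteins *initially* in the set in lexicographic order, and
    each one's network neighbors in lexicographic order; a neighbor not yet
    in the set is admitted immediately whenever the cohesiveness of the
    enlarged set is greater than or equal to the current value (so the set
    grows during the scan and later candidates see the grown set).

    Returns the expanded set and the trajectory of accepted cohesiveness
    values (starting value first); the trajectory is non-decreasing by
    construction.
    """
    g = net.graph
    current = set(members)
    coh = cohesiveness(net, current, penalty)
    trajectory = [coh]
    for prot in sorted(members):
        for nb in sorted(g[prot]):
            if nb in current:
                continue
            cand = cohesiveness(net, current | {nb}, penalty)
            if cand >= coh:
                current.add(nb)
                coh = cand
                trajectory.append(cand)
    return frozenset(current), trajectory


def merge_by_cohesiveness(
    net: PPINetwork,
    c1: Complex,
    c2: Complex,
    cls: ProteinClassification,
    penalty: float = 2.0,
) -> Complex:
    """Union of two complexes, expanded while cohesiveness does not drop.

    The caller is responsible for checking the essential-overlap threshold.
    Essential members of the result are recomputed from ``cls``.
    """
    start = c1.members | c2.members
    expanded, _ = expand_by_cohesiveness(net, start, penalty)
    essential = frozenset(p for p in expanded if cls.is_essential(p))
    return Complex(members=expanded, seed=None, essential_members=essential)


def _pass_order(complexes: list[Complex]) -> list[Complex]:
    return sorted(complexes, key=lambda c: (-len(c.members), tuple(sorted(c.members))))


def merge_all(
    net: PPINetwork,
    cs: ComplexSet,
    cls: ProteinClassification,
    params: MergeParams | None = None,
    min_size: int = MIN_COMPLEX_SIZE,
) -> ComplexSet:
    """Merge overlapping complexes to a fixpoint.

    Each pass scans complex pairs in deterministic order (descending size,
    then lexicographic member list); the first pair whose essential overlap
    strictly exceeds ``params.threshold`` is replaced by its merged,
    expanded complex and the pass restarts.  Passes stop when none merges or
    ``params.max_passes`` is reached (warning).  Duplicates and complexes
    below ``min_size`` are removed from the result.
    """
    if params is None:
        params = MergeParams()
    work = list(cs)
    for _ in range(params.max_passes):
        work = _pass_order(work)
        merged = None
        for i in range(len(work)):
            for j in range(i + 1, len(work)):
                if essential_overlap(work[i], work[j], params.overlap_mode) > params.threshold:
                    merged = (i, j)
                    break
            if merged:
                break
        if merged is None:
            break
        i, j = merged
        new = merge_by_cohesiveness(net, work[i], work[j], cls, params.penalty)
        work = [c for k, c in enumerate(work) if k not in (i, j)]
        work.append(new)
    else:
        warnings.warn(
            f"merge pass cap ({params.max_passes}) reached before fixpoint",
            stacklevel=2,
        )
    kept = [c for c in work if len(c.members) >= min_size]
    return remove_duplicates(ComplexSet(kept))
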