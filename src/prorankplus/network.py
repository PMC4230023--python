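"""Core data types and file I/O for PPI networks and complex catalogs.

A protein-protein interaction (PPI) network is an undirected graph whose
vertices are proteins and whose edges are physical interactions, optionally
carrying a positive confidence weight.  A protein complex is simply a set of
member proteins; catalogs of complexes (MIPS/SGD style) are stored one
complex per line with whitespace-separated members.

Protein identifiers are opaque, case-sensitive strings; no symbol
normalisation is attempted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import networkx as nx

log = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "Complex",
    "ComplexSet",
    "load_network",
    "load_complexes",
    "write_complexes",
]


@dataclass
class PPINetwork:
    """Undirected, optionally weighted protein interaction network.

    Wraps a :class:`networkx.Graph`.  Invariants maintained by the
    constructors in this module:

    * no self-loops;
    * each unordered pair stored once, with a single positive weight;
    * unweighted networks carry weight 1.0 on every edge;
    * isolated nodes are permitted (they can never seed a complex).
    """

    graph: nx.Graph
    is_weighted: bool = False

    # -- convenience accessors -------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def neighbors(self, u: str) -> set[str]:
        return set(self.graph[u])

    def weight(self, u: str, v: str) -> float:
        return float(self.graph[u][v]["weight"])

    def degree(self, u: str) -> int:
        return int(self.graph.degree(u))

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for u, v, w in self.graph.edges(data="weight", default=1.0):
            yield u, v, float(w)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Union[tuple[str, str], tuple[str, str, float]]],
        weighted: bool = False,
        nodes: Iterable[str] = (),
    ) -> "PPINetwork":
        """Build a network from (u, v[, weight]) tuples.

        Self-loops are dropped; duplicate unordered pairs keep the maximum
        weight; extra ``nodes`` are added isolated.
        """
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for e in edges:
            u, v = e[0], e[1]
            w = float(e[2]) if (weighted and len(e) > 2) else 1.0
            if w <= 0:
                raise ValueError(f"nonpositive weight {w} on edge ({u}, {v})")
            g.add_node(u)
            g.add_node(v)
            if u == v:
                continue
            if g.has_edge(u, v):
                g[u][v]["weight"] = max(g[u][v]["weight"], w)
            else:
                g.add_edge(u, v, weight=w)
        return cls(graph=g, is_weighted=weighted)


@dataclass(frozen=True)
class Complex:
    """A protein complex: a non-empty set of members with optional provenance.

    ``seed`` is the spoke-model center the complex was pulled from (if any);
    ``essential_members`` is the subset classified as essential (non-noise)
    by the topological filter.
    """

    members: frozenset[str]
    seed: Optional[str] = None
    essential_members: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a complex must have at least one member")
        if self.seed is not None and self.seed not in self.members:
            raise ValueError(f"seed {self.seed!r} not among members")
        if not self.essential_members <= self.members:
            raise ValueError("essential_members must be a subset of members")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, protein: str) -> bool:
        return protein in self.members


@dataclass
class ComplexSet:
    """Ordered collection of complexes (duplicates allowed until filtered)."""

    complexes: list[Complex] = field(default_factory=list)

    def __iter__(self) -> Iterator[Complex]:
        return iter(self.complexes)

    def __len__(self) -> int:
        return len(self.complexes)

    def __getitem__(self, i: int) -> Complex:
        return self.complexes[i]

    def member_sets(self) -> list[frozenset[str]]:
        return [c.members for c in self.complexes]

    @classmethod
    def from_member_sets(cls, sets: Iterable[Iterable[str]]) -> "ComplexSet":
        return cls([Complex(frozenset(s)) for s in sets])


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def load_network(path: Union[str, Path], weighted: bool = False) -> PPINetwork:
    """Read a tab/whitespace-separated edge list.

    Columns are ``proteinA proteinB`` (unweighted) or
    ``proteinA proteinB weight`` (weighted); ``#``-prefixed lines are
    comments.  Self-interactions are dropped (count logged); duplicate
    unordered pairs collapse to the maximum weight.

    Raises :class:`ValueError` naming the offending line on malformed input,
    a missing weight column, or a nonpositive weight.
    """
    path = Path(path)
    best: dict[tuple[str, str], float] = {}
    nodes: set[str] = set()
    self_loops = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if weighted:
                if len(parts) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: weighted network requires 3 columns, "
                        f"got {len(parts)}"
                    )
                a, b, wtxt = parts[0], parts[1], parts[2]
                try:
                    w = float(wtxt)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: unparseable weight {wtxt!r}"
                    ) from exc
                if w <= 0:
                    raise ValueError(f"{path}:{lineno}: nonpositive weight {w}")
            else:
                if len(parts) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                    )
                a, b, w = parts[0], parts[1], 1.0
            nodes.add(a)
            nodes.add(b)
            if a == b:
                self_loops += 1
                continue
            key = (a, b) if a <= b else (b, a)
            prev = best.get(key)
            best[key] = w if prev is None else max(prev, w)
    if self_loops:
        log.info("dropped %d self-interaction line(s) from %s", self_loops, path)
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    for (a, b), w in best.items():
        g.add_edge(a, b, weight=w)
    return PPINetwork(graph=g, is_weighted=weighted)


def load_complexes(path: Union[str, Path]) -> ComplexSet:
    """Read a MIPS/SGD-style catalog: one complex per line, members
    whitespace-separated.  Blank lines are skipped; duplicate members within
    a line collapse.  An empty catalog raises :class:`ValueError`.
    """
    path = Path(path)
    out: list[Complex] = []
    with path.open() as fh:
        for raw in fh:
            members = frozenset(raw.split())
            if not members:
                continue
            out.append(Complex(members=members))
    if not out:
        raise ValueError(f"no complexes found in {path}")
    return ComplexSet(out)


def write_complexes(cs: ComplexSet, path: Union[str, Path]) -> None:
    """Write one complex per line, members sorted lexicographically.

    Output round-trips through :func:`load_complexes` to an equal list of
    member-sets.  Writing an empty set produces an empty file and a warning.
    """
    path = Path(path)
    if len(cs) == 0:
        warnings.warn(f"writing empty complex set to {path}", stacklevel=2)
    with path.open("w") as fh:
        for c in cs:
            fh.write(" ".join(sorted(c.members)) + "\n")
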