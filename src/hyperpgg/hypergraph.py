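"""Simple hypergraphs: container, validation, projections, degrees, and I/O.

A hypergraph ``H = (V, E)`` is a vertex set ``V = {0, ..., N-1}`` together
with a family ``E`` of hyperedges, each a set of at least two vertices. It is
*simple* when no hyperedge is contained in (or equal to) another. The *rank*
and *co-rank* are the maximum and minimum hyperedge cardinality; a hypergraph
with rank = co-rank = s is *s-uniform*.

The *2-section* is the graph on ``V`` in which two distinct vertices are
adjacent iff they share at least one hyperedge. The *m-degree* ``k_m(i)`` of
vertex ``i`` counts incident hyperedges of cardinality ``m``; the generalized
degree ``k(i)`` is the sum of the ``k_m(i)`` over ``m``.

Vertex ids are 0-based contiguous integers throughout, including in the
plain-text file format (one hyperedge per line, whitespace-separated ids,
``#`` comments).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import networkx as nx
import numpy as np

__all__ = [
    "Hypergraph",
    "HypergraphError",
    "MDegreeTable",
    "validate_simple",
    "simplify",
    "two_section",
    "m_degrees",
    "cardinality_fractions",
    "local_clustering",
    "read_hypergraph",
    "write_hypergraph",
    "graph_from_edgelist",
]


class HypergraphError(ValueError):
    """Malformed hypergraph, hyperedge, or hyperedge file."""


def _canonical_edge(edge: Iterable[int], n_vertices: int) -> Tuple[int, ...]:
    members = tuple(sorted(int(v) for v in edge))
    if len(members) < 2:
        raise HypergraphError(f"hyperedge {members} has cardinality < 2")
    if len(set(members)) != len(members):
        raise HypergraphError(f"hyperedge {members} repeats a vertex id")
    if members[0] < 0 or members[-1] >= n_vertices:
        raise HypergraphError(
            f"hyperedge {members} has a vertex id outside 0..{n_vertices - 1}"
        )
    return members


@dataclass(frozen=True)
class Hypergraph:
    """A hypergraph on vertices ``0..n_vertices-1``.

    Hyperedges are stored as sorted vertex-id tuples, which makes equality
    and subset tests canonical. Construction validates well-formedness
    (cardinality >= 2, distinct in-range ids, no repeated hyperedge) but not
    simplicity; use :func:`validate_simple` / :func:`simplify` for that.
    """

    n_vertices: int
    hyperedges: Tuple[Tuple[int, ...], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_vertices < 1:
            raise HypergraphError("n_vertices must be positive")
        canon = tuple(
            _canonical_edge(e, self.n_vertices) for e in self.hyperedges
        )
        if len(set(canon)) != len(canon):
            dup = [e for e, c in Counter(canon).items() if c > 1]
            raise HypergraphError(f"repeated hyperedge(s): {dup}")
        object.__setattr__(self, "hyperedges", canon)

    # -- basic descriptors -------------------------------------------------
    @property
    def n_hyperedges(self) -> int:
        return len(self.hyperedges)

    @property
    def rank(self) -> int:
        """Maximum hyperedge cardinality (m_max)."""
        if not self.hyperedges:
            raise HypergraphError("rank undefined: no hyperedges")
        return max(len(e) for e in self.hyperedges)

    @property
    def corank(self) -> int:
        """Minimum hyperedge cardinality (m_min)."""
        if not self.hyperedges:
            raise HypergraphError("co-rank undefined: no hyperedges")
        return min(len(e) for e in self.hyperedges)

    def is_uniform(self) -> bool:
        return self.n_hyperedges > 0 and self.rank == self.corank

    def edges_of_size(self, m: int) -> List[Tuple[int, ...]]:
        return [e for e in self.hyperedges if len(e) == m]

    @staticmethod
    def from_graph(graph: nx.Graph) -> "Hypergraph":
        """Wrap a simple graph as a 2-uniform hypergraph."""
        n = graph.number_of_nodes()
        return Hypergraph(n, tuple(tuple(sorted(e)) for e in graph.edges()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypergraph):
            return NotImplemented
        return self.n_vertices == other.n_vertices and set(
            self.hyperedges
        ) == set(other.hyperedges)

    def __hash__(self) -> int:
        return hash((self.n_vertices, frozenset(self.hyperedges)))


def validate_simple(
    H: Hypergraph,
) -> Tuple[bool, List[Tuple[Tuple[int, ...], Tuple[int, ...]]]]:
    """Check that no hyperedge is a subset of another.

    Returns ``(ok, violations)`` where each violation is a pair
    ``(contained, container)``. Only smaller-vs-larger cardinality pairs need
    testing (equal-size duplicates are excluded at construction).
    """
    by_size: Dict[int, List[Tuple[int, ...]]] = defaultdict(list)
    for e in H.hyperedges:
        by_size[len(e)].append(e)
    sizes = sorted(by_size)
    violations = []
    for i, m_small in enumerate(sizes):
        small_sets = [(e, frozenset(e)) for e in by_size[m_small]]
        for m_big in sizes[i + 1 :]:
            for big in by_size[m_big]:
                big_set = frozenset(big)
                for e, es in small_sets:
                    if es <= big_set:
                        violations.append((e, big))
    return (not violations), violations


def simplify(H: Hypergraph) -> Hypergraph:
    """Drop every hyperedge that is a subset of another (idempotent)."""
    _, violations = validate_simple(H)
    contained = {v[0] for v in violations}
    kept = tuple(e for e in H.hyperedges if e not in contained)
    return Hypergraph(H.n_vertices, kept)


def two_section(H: Hypergraph) -> nx.Graph:
    """Graph projection: i ~ j iff they share at least one hyperedge."""
    g = nx.Graph()
    g.add_nodes_from(range(H.n_vertices))
    for e in H.hyperedges:
        for a_idx in range(len(e)):
            for b_idx in range(a_idx + 1, len(e)):
                g.add_edge(e[a_idx], e[b_idx])
    return g


@dataclass(frozen=True)
class MDegreeTable:
    """Per-vertex m-degrees ``k_m(i)`` and generalized degree ``k(i)``."""

    by_size: Dict[int, np.ndarray]
    generalized: np.ndarray

    def k(self, i: int) -> int:
        return int(self.generalized[i])

    def km(self, m: int, i: int) -> int:
        arr = self.by_size.get(m)
        return int(arr[i]) if arr is not None else 0

    def mean_degrees(self) -> Dict[int, float]:
        """Mean m-degree <k_m> per cardinality."""
        return {m: float(arr.mean()) for m, arr in sorted(self.by_size.items())}


def m_degrees(H: Hypergraph) -> MDegreeTable:
    by_size: Dict[int, np.ndarray] = {}
    for e in H.hyperedges:
        m = len(e)
        if m not in by_size:
            by_size[m] = np.zeros(H.n_vertices, dtype=np.int64)
        by_size[m][list(e)] += 1
    generalized = (
        np.sum(list(by_size.values()), axis=0)
        if by_size
        else np.zeros(H.n_vertices, dtype=np.int64)
    )
    return MDegreeTable(by_size=by_size, generalized=generalized)


def cardinality_fractions(H: Hypergraph) -> Dict[int, float]:
    """Fractions p_m of hyperedges of each cardinality m (sum to 1)."""
    if H.n_hyperedges == 0:
        raise HypergraphError("cardinality fractions undefined: no hyperedges")
    counts = Counter(len(e) for e in H.hyperedges)
    total = H.n_hyperedges
    return {m: counts[m] / total for m in sorted(counts)}


def local_clustering(G: nx.Graph, i: int) -> float:
    """Watts–Strogatz local clustering of vertex ``i``; 0 when degree < 2.

    The 0-by-convention for low-degree vertices keeps comparisons total in
    the rewiring acceptance checks.
    """
    if i not in G:
        raise KeyError(f"vertex {i} not in graph")
    return float(nx.clustering(G, i))


# -- plain-text I/O --------------------------------------------------------

def write_hypergraph(H: Hypergraph, path) -> None:
    """One hyperedge per line, sorted 0-based ids; header records N."""
    with open(path, "w") as fh:
        fh.write(f"# vertices: {H.n_vertices}\n")
        for e in sorted(H.hyperedges, key=lambda t: (len(t), t)):
            fh.write(" ".join(str(v) for v in e) + "\n")


def read_hypergraph(path, require_simple: bool = True) -> Hypergraph:
    """Parse a hyperedge-list file; re-validates simplicity on read.

    Raises :class:`HypergraphError` with the offending line number for
    duplicate ids within a line, non-integer tokens, or (when
    ``require_simple``) subset violations.
    """
    edges: List[Tuple[int, ...]] = []
    declared_n = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if raw.lstrip().startswith("#"):
                stripped = raw.lstrip()[1:].strip()
                if stripped.startswith("vertices:"):
                    declared_n = int(stripped.split(":", 1)[1])
                continue
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                ids = [int(tok) for tok in line.split()]
            except ValueError as exc:
                raise HypergraphError(
                    f"{path}:{lineno}: non-integer token ({exc})"
                ) from None
            if len(ids) != len(set(ids)):
                raise HypergraphError(f"{path}:{lineno}: repeated vertex id")
            if len(ids) < 2:
                raise HypergraphError(
                    f"{path}:{lineno}: hyperedge needs >= 2 vertices"
                )
            if min(ids) < 0:
                raise HypergraphError(f"{path}:{lineno}: negative vertex id")
            edges.append(tuple(sorted(ids)))
    n = declared_n if declared_n is not None else (
        max((e[-1] for e in edges), default=-1) + 1
    )
    if n < 1:
        raise HypergraphError(f"{path}: empty hypergraph file, N unknown")
    H = Hypergraph(n, tuple(edges))
    if require_simple:
        ok, violations = validate_simple(H)
        if not ok:
            raise HypergraphError(
                f"{path}: not a simple hypergraph; first violation "
                f"{violations[0][0]} ⊆ {violations[0][1]}"
            )
    return H


def graph_from_edgelist(path) -> nx.Graph:
    """Read a two-column edge list (the 2-uniform file special case)."""
    H = read_hypergraph(path, require_simple=False)
    if H.n_hyperedges and H.rank > 2:
        raise HypergraphError(f"{path}: contains hyperedges of size > 2")
    return two_section(H)
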