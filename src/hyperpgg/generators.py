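"""Base-network models and the rank-3 clique-promotion algorithm.

Three base-network models are provided, all of them classic growing or
random-graph models:

* **Holme–Kim (HK)** — preferential attachment with triad formation. Each
  new vertex places one preferential-attachment (PA) link and then, for each
  of its remaining ``m - 1`` links, performs a triad-formation step with
  probability ``Pt`` (linking to a uniformly random not-yet-connected
  neighbor of the previous PA target), else a fresh PA step. The seed is a
  clique on ``m + 1`` vertices, so for ``Pt = 1`` a triad-formation step can
  never fail and every edge ends up inside at least one 3-clique.
* **Dorogovtsev–Mendes (DM)** — starting from a triangle, each new vertex
  attaches to both endpoints of a uniformly chosen existing edge; mean
  degree tends to 4 and triangles percolate the whole graph.
* **Erdős–Rényi (ER)** — G(N, M) with ``M = round(N <k> / 2)`` edges, which
  pins the mean degree exactly.

Promotion converts a uniformly sampled fraction ``p`` of the base graph's
3-cliques into triangular hyperedges, then removes every 2-edge contained in
a selected triangle. The result is a rank-3 simple hypergraph whose
2-section is exactly the base graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import networkx as nx
import numpy as np

from .hypergraph import Hypergraph

__all__ = [
    "GeneratorConfig",
    "PromotionConfig",
    "generate",
    "generate_hk",
    "generate_dm",
    "generate_er",
    "enumerate_3cliques",
    "promote_cliques",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings for one base-network model.

    ``model`` is one of ``"hk"``, ``"dm"``, ``"er"``. ``m`` and ``pt`` apply
    to HK (links per new vertex, triad-formation probability); ``mean_degree``
    applies to ER.
    """

    model: str
    n: int
    m: int = 3
    pt: float = 1.0
    mean_degree: float = 6.0
    seed: Optional[int] = None
    require_connected: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("hk", "dm", "er"):
            raise ValueError(f"unknown model {self.model!r}")
        if not (0.0 <= self.pt <= 1.0):
            raise ValueError("pt must lie in [0, 1]")
        if self.model == "hk" and not (self.n > self.m >= 1):
            raise ValueError("HK requires N > m >= 1")
        if self.model == "dm" and self.n < 3:
            raise ValueError("DM requires N >= 3")
        if self.model == "er" and not (0 <= self.mean_degree < self.n - 1):
            raise ValueError("ER requires 0 <= mean degree < N - 1")


@dataclass(frozen=True)
class PromotionConfig:
    """Fraction ``p`` of 3-cliques to promote to triangular hyperedges."""

    p: float
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("conversion fraction p must lie in [0, 1]")


def generate(cfg: GeneratorConfig) -> nx.Graph:
    """Dispatch to the configured base-network model."""
    if cfg.model == "hk":
        return generate_hk(cfg)
    if cfg.model == "dm":
        return generate_dm(cfg)
    return generate_er(cfg)


def generate_hk(cfg: GeneratorConfig) -> nx.Graph:
    """Holme–Kim growing network with triad formation.

    Seeded with a clique on ``m + 1`` vertices. Every new vertex adds ``m``
    links: one PA link, then ``m - 1`` triad-formation steps with
    probability ``pt`` each (falling back to PA only if no eligible neighbor
    of the previous PA target remains, which cannot occur for ``pt = 1``
    given the clique seed).
    """
    if cfg.model != "hk":
        raise ValueError("config is not for the HK model")
    if cfg.n <= cfg.m + 1:
        raise ValueError("HK requires N > m + 1")
    rng = np.random.default_rng(cfg.seed)
    m = cfg.m
    g = nx.complete_graph(m + 1)
    # PA sampling list: one entry per degree unit.
    repeated: List[int] = [v for v in range(m + 1) for _ in range(m)]

    for v in range(m + 1, cfg.n):
        targets: set = set()

        def pa_target() -> int:
            while True:
                w = repeated[rng.integers(len(repeated))]
                if w != v and w not in targets:
                    return w

        prev = pa_target()
        targets.add(prev)
        g.add_edge(v, prev)
        for _ in range(m - 1):
            t = None
            if rng.random() < cfg.pt:
                candidates = [
                    u for u in g.neighbors(prev) if u != v and u not in targets
                ]
                if candidates:
                    t = candidates[rng.integers(len(candidates))]
            if t is None:  # fresh PA step (also updates the TF anchor)
                t = pa_target()
                prev = t
            targets.add(t)
            g.add_edge(v, t)
        repeated.extend(targets)
        repeated.extend([v] * m)
    return g


def generate_dm(cfg: GeneratorConfig) -> nx.Graph:
    """Dorogovtsev–Mendes growing network (attach to a random edge)."""
    if cfg.model != "dm":
        raise ValueError("config is not for the DM model")
    rng = np.random.default_rng(cfg.seed)
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2)])
    edges: List[Tuple[int, int]] = [(0, 1), (1, 2), (0, 2)]
    for v in range(3, cfg.n):
        a, b = edges[rng.integers(len(edges))]
        g.add_edge(v, a)
        g.add_edge(v, b)
        edges.append((v, a))
        edges.append((v, b))
    return g


def generate_er(cfg: GeneratorConfig) -> nx.Graph:
    """Erdős–Rényi G(N, M) with M = round(N <k> / 2) uniform edges.

    With ``require_connected`` the draw is repeated until the graph is
    connected (uniform over connected G(N, M) graphs); isolated vertices
    would otherwise freeze under imitation dynamics, which assumes a
    single interacting population.
    """
    if cfg.model != "er":
        raise ValueError("config is not for the ER model")
    n_edges = round(cfg.n * cfg.mean_degree / 2)
    rng = np.random.default_rng(cfg.seed)
    for _ in range(1000):
        g = nx.gnm_random_graph(cfg.n, n_edges, seed=int(rng.integers(2**31)))
        if not cfg.require_connected or nx.is_connected(g):
            return g
    raise RuntimeError(
        "could not draw a connected G(N, M) graph; raise the mean degree"
    )


def enumerate_3cliques(G: nx.Graph) -> List[Tuple[int, int, int]]:
    """All unordered vertex triples forming a triangle, each listed once."""
    adj = {v: set(G.neighbors(v)) for v in G.nodes()}
    cliques: List[Tuple[int, int, int]] = []
    for u, v in G.edges():
        a, b = (u, v) if u < v else (v, u)
        for w in adj[a] & adj[b]:
            if w > b:
                cliques.append((a, b, w))
    cliques.sort()
    return cliques


def promote_cliques(G: nx.Graph, cfg: PromotionConfig) -> Hypergraph:
    """Promote a fraction ``p`` of 3-cliques to triangles; drop covered edges.

    ``round(p * n_cliques)`` cliques (banker's rounding) are sampled
    uniformly without replacement from the full clique list of the base
    graph, before any edge removal. A 2-edge survives iff it is covered by
    no selected triangle, so the 2-section of the result equals ``G``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = G.number_of_nodes()
    cliques = enumerate_3cliques(G)
    n_pick = round(cfg.p * len(cliques))
    if n_pick > 0:
        idx = rng.choice(len(cliques), size=n_pick, replace=False)
        picked = [cliques[i] for i in sorted(idx)]
    else:
        picked = []
    covered = set()
    for a, b, c in picked:
        covered.update({(a, b), (a, c), (b, c)})
    surviving = [
        tuple(sorted(e)) for e in G.edges() if tuple(sorted(e)) not in covered
    ]
    return Hypergraph(n, tuple(surviving) + tuple(picked))
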