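"""Null-model rewiring and topological-trap characterization.

Two degree-preserving edge-swap randomizations disentangle which structural
features sustain topological traps (local configurations that keep the
dynamics from absorbing into all-cooperate or all-defect):

* ``preserve_clustering`` — a swap is accepted only if it leaves the local
  clustering coefficient of every affected vertex unchanged (degrees are
  preserved by construction). Note the acceptance test covers all vertices
  whose triangle count a swap can touch, so the per-vertex clustering
  vector of the whole graph is invariant.
* ``preserve_3k`` — the two chosen vertices must have equal degree and so
  must the far endpoints of the two swapped edges; this preserves the joint
  degree distributions over edges P(k, k') and over two-paths P(k, k', k'')
  exactly.

A *bottleneck* trap is a bridge vertex gluing links/triangles between
groups of opposite strategy; its action is governed by the synergy values
at which a cooperator and a defector with given local configurations earn
identical payoffs (payoffs are linear in alpha, so thresholds come from a
linear solve). Because a triangle provides two redundant 2-section paths,
an edge lying in no 3-clique is the natural bottleneck candidate — graphs
with complete triangle percolation (e.g. Dorogovtsev–Mendes) have none.

The census utilities compare non-convergence counts (nNC per 100 runs)
between original and rewired structures, and correct the mean convergence
time for truncated runs: with nNC non-converged runs out of ``runs`` and
cap ``tmax``,

    t_C = runs * (t_mean - nNC * tmax / runs) / (runs - nNC).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .dynamics import SweepResult
from .generators import PromotionConfig, promote_cliques

__all__ = [
    "RewireConfig",
    "rewire_preserve_clustering",
    "rewire_preserve_3k",
    "corrected_convergence_time",
    "LocalConfiguration",
    "BottleneckResult",
    "bottleneck_threshold",
    "find_bottleneck_candidates",
    "trap_census",
    "two_path_degree_histogram",
    "edge_degree_histogram",
]


@dataclass(frozen=True)
class RewireConfig:
    """Rewiring settings: mode, number of ACCEPTED swaps, proposal cap, seed.

    ``n_steps`` counts accepted swaps; rejected proposals are retried
    without decrementing, up to ``max_proposals`` total attempts (None for
    20x ``n_steps``) so that a low acceptance rate terminates.
    """

    mode: str
    n_steps: int = 100_000
    seed: Optional[int] = None
    max_proposals: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode not in ("preserve_clustering", "preserve_3k"):
            raise ValueError("mode must be preserve_clustering or preserve_3k")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")


def _adjacency(G: nx.Graph) -> Dict[int, Set[int]]:
    return {v: set(G.neighbors(v)) for v in G.nodes()}


def _local_clustering(adj: Dict[int, Set[int]], v: int) -> float:
    nbrs = adj[v]
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = 0
    nbr_list = list(nbrs)
    for i, a in enumerate(nbr_list):
        adj_a = adj[a]
        for b in nbr_list[i + 1 :]:
            if b in adj_a:
                links += 1
    return 2.0 * links / (k * (k - 1))


def _swap_ok(adj, u, a, v, b) -> bool:
    """Validity of replacing edges (u,a),(v,b) by (u,b),(v,a)."""
    if len({u, a, v, b}) < 4:
        return False
    if b in adj[u] or a in adj[v]:
        return False
    return True


def _affected_vertices(adj, u, a, v, b) -> Set[int]:
    """Vertices whose triangle count the swap can change: the four endpoints
    plus the common neighbors of each old/new edge pair."""
    affected = {u, a, v, b}
    for x, y in ((u, a), (v, b), (u, b), (v, a)):
        affected |= adj[x] & adj[y]
    return affected


def rewire_preserve_clustering(G: nx.Graph, cfg: RewireConfig) -> nx.Graph:
    """Degree- and local-clustering-preserving randomization.

    Repeatedly picks two random vertices, one incident edge each, and swaps
    the far endpoints; the swap is kept only when the local clustering
    coefficient of every affected vertex is unchanged.
    """
    if cfg.mode != "preserve_clustering":
        raise ValueError("config mode mismatch")
    rng = np.random.default_rng(cfg.seed)
    adj = _adjacency(G)
    nodes = [v for v in G.nodes() if len(adj[v]) > 0]
    accepted = 0
    proposals = 0
    cap = cfg.max_proposals if cfg.max_proposals is not None else 20 * cfg.n_steps
    while accepted < cfg.n_steps and proposals < cap:
        proposals += 1
        u = nodes[rng.integers(len(nodes))]
        v = nodes[rng.integers(len(nodes))]
        if u == v:
            continue
        a = list(adj[u])[rng.integers(len(adj[u]))]
        b = list(adj[v])[rng.integers(len(adj[v]))]
        if not _swap_ok(adj, u, a, v, b):
            continue
        affected = _affected_vertices(adj, u, a, v, b)
        before = {x: _local_clustering(adj, x) for x in affected}
        adj[u].discard(a), adj[a].discard(u)
        adj[v].discard(b), adj[b].discard(v)
        adj[u].add(b), adj[b].add(u)
        adj[v].add(a), adj[a].add(v)
        if all(
            _local_clustering(adj, x) == before[x] for x in affected
        ):
            accepted += 1
        else:  # revert
            adj[u].discard(b), adj[b].discard(u)
            adj[v].discard(a), adj[a].discard(v)
            adj[u].add(a), adj[a].add(u)
            adj[v].add(b), adj[b].add(v)
    out = nx.Graph()
    out.add_nodes_from(G.nodes())
    for x, nbrs in adj.items():
        out.add_edges_from((x, y) for y in nbrs if y > x)
    return out


def rewire_preserve_3k(G: nx.Graph, cfg: RewireConfig) -> nx.Graph:
    """Randomization preserving degree correlations up to second order.

    Two vertices of equal degree are drawn; one incident edge each; if the
    far endpoints also have equal degree, the endpoints are exchanged. Each
    edge and each two-path keeps its degree labels, so P(k, k') and
    P(k, k', k'') are exactly invariant.
    """
    if cfg.mode != "preserve_3k":
        raise ValueError("config mode mismatch")
    rng = np.random.default_rng(cfg.seed)
    adj = _adjacency(G)
    nodes = [v for v in G.nodes() if len(adj[v]) > 0]
    degree_of = {v: len(adj[v]) for v in G.nodes()}
    by_degree: Dict[int, List[int]] = {}
    for v in nodes:
        by_degree.setdefault(degree_of[v], []).append(v)
    accepted = 0
    proposals = 0
    cap = cfg.max_proposals if cfg.max_proposals is not None else 20 * cfg.n_steps
    while accepted < cfg.n_steps and proposals < cap:
        proposals += 1
        u = nodes[rng.integers(len(nodes))]
        peers = by_degree[degree_of[u]]
        v = peers[rng.integers(len(peers))]
        if u == v:
            continue
        a = list(adj[u])[rng.integers(len(adj[u]))]
        b = list(adj[v])[rng.integers(len(adj[v]))]
        if degree_of[a] != degree_of[b]:
            continue
        if not _swap_ok(adj, u, a, v, b):
            continue
        adj[u].discard(a), adj[a].discard(u)
        adj[v].discard(b), adj[b].discard(v)
        adj[u].add(b), adj[b].add(u)
        adj[v].add(a), adj[a].add(v)
        accepted += 1
    out = nx.Graph()
    out.add_nodes_from(G.nodes())
    for x, nbrs in adj.items():
        out.add_edges_from((x, y) for y in nbrs if y > x)
    return out


def edge_degree_histogram(G: nx.Graph) -> Counter:
    """Histogram of unordered degree pairs over edges, P(k, k')."""
    deg = dict(G.degree())
    return Counter(
        tuple(sorted((deg[u], deg[v]))) for u, v in G.edges()
    )


def two_path_degree_histogram(G: nx.Graph) -> Counter:
    """Histogram of degree triples (k, k', k'') over paths of length two,
    keyed as (center degree, sorted end degrees)."""
    deg = dict(G.degree())
    hist: Counter = Counter()
    for center in G.nodes():
        nbrs = list(G.neighbors(center))
        for i, x in enumerate(nbrs):
            for y in nbrs[i + 1 :]:
                hist[(deg[center], tuple(sorted((deg[x], deg[y]))))] += 1
    return hist


def corrected_convergence_time(
    t_mean: float, n_nc: float, tmax: int, runs: int = 100
) -> float:
    """Mean convergence time over converged runs only.

    Inverts the mixture mean: non-converged runs contribute ``tmax`` each,
    so ``t_C = runs (t_mean - n_nc tmax / runs) / (runs - n_nc)``.
    """
    if not (0 <= n_nc <= runs):
        raise ValueError("n_nc must lie in [0, runs]")
    if n_nc == runs:
        raise ValueError("all runs non-converged: t_C undefined")
    if t_mean < n_nc * tmax / runs - 1e-9:
        raise ValueError("t_mean inconsistent with n_nc * tmax / runs")
    return runs * (t_mean - n_nc * tmax / runs) / (runs - n_nc)


# -- bottleneck thresholds -------------------------------------------------


@dataclass(frozen=True)
class LocalConfiguration:
    """Group memberships of one focal player: list of (m, nc) pairs, one per
    incident hyperedge, with nc the cooperating co-members in that group."""

    strategy: int  # 1 cooperator, 0 defector
    groups: Tuple[Tuple[int, int], ...]

    def payoff_line(self, b: float = 1.0) -> Tuple[float, float]:
        """Payoff as (intercept, slope) in alpha: f = A + B alpha."""
        A = -b * self.strategy * len(self.groups)
        B = 0.0
        for m, nc in self.groups:
            if m < 2 or not (0 <= nc <= m - 1):
                raise ValueError(f"invalid group ({m}, {nc})")
            B += b * (self.strategy + nc) / m
        return A, B


@dataclass(frozen=True)
class BottleneckResult:
    kind: str  # "crossing" | "parallel" | "always_equal"
    alpha_th: float = float("nan")


def bottleneck_threshold(
    cooperator: LocalConfiguration,
    defector: LocalConfiguration,
    b: float = 1.0,
) -> BottleneckResult:
    """Synergy at which the two focal players earn equal payoffs.

    Payoffs are linear in alpha, so the threshold is the crossing of two
    lines; parallel distinct lines yield no threshold, identical lines are
    flagged as always equal.
    """
    Ac, Bc = cooperator.payoff_line(b)
    Ad, Bd = defector.payoff_line(b)
    if np.isclose(Bc, Bd):
        if np.isclose(Ac, Ad):
            return BottleneckResult(kind="always_equal")
        return BottleneckResult(kind="parallel")
    return BottleneckResult(kind="crossing", alpha_th=(Ad - Ac) / (Bc - Bd))


def find_bottleneck_candidates(G: nx.Graph) -> List[Tuple[int, int]]:
    """Edges lying in no 3-clique — the non-redundant 2-section links where
    bottleneck traps can form. Empty for graphs with complete triangle
    percolation (e.g. any Dorogovtsev–Mendes network)."""
    adj = {v: set(G.neighbors(v)) for v in G.nodes()}
    out = []
    for u, v in G.edges():
        if not (adj[u] & adj[v]):
            out.append(tuple(sorted((u, v))))
    return sorted(out)


def trap_census(
    base_graph: nx.Graph,
    p: float,
    b: float,
    beta: float,
    r_grid: Sequence[float],
    runs_per_point: int = 100,
    c0: float = 0.5,
    tmax: int = 50_000,
    seed: int = 0,
    rewire_steps: int = 2_000,
    modes: Sequence[str] = ("original", "preserve_clustering", "preserve_3k"),
) -> pd.DataFrame:
    """Non-convergence census on a base graph and its rewired null models.

    For each structure, the base graph (possibly rewired) is promoted at the
    given ``p`` and swept over the ``r`` grid; reported per point are the
    mean final density, mean convergence time, corrected time ``t_C`` and
    ``nNC`` per 100 runs. A structure "has traps" when some runs fail to
    absorb by ``tmax``.
    """
    from .dynamics import (  # local import to avoid cycle at module load
        CompiledHypergraph,
        GameParams,
        random_initial_state,
        run,
    )

    rng_master = np.random.SeedSequence([int(seed), 424_243])
    children = rng_master.generate_state(4) % (2**31)
    rows = []
    for mode_idx, mode in enumerate(modes):
        if mode == "original":
            g = base_graph
        else:
            cfg = RewireConfig(
                mode=mode, n_steps=rewire_steps, seed=int(children[0])
            )
            g = (
                rewire_preserve_clustering(base_graph, cfg)
                if mode == "preserve_clustering"
                else rewire_preserve_3k(base_graph, cfg)
            )
        H = promote_cliques(g, PromotionConfig(p=p, seed=int(children[1])))
        comp = CompiledHypergraph(H)
        for r_idx, r in enumerate(sorted(r_grid)):
            params = GameParams(alpha=r * comp.alpha_cr, b=b, beta=beta)
            cs, ts, n_nc = [], [], 0
            for run_idx in range(runs_per_point):
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        [int(seed), mode_idx, r_idx, run_idx]
                    )
                )
                state0 = random_initial_state(comp.n, c0, rng)
                res = run(comp, state0, params, tmax, rng, record_trajectory=False)
                cs.append(res.c_final)
                ts.append(res.t_conv)
                n_nc += 0 if res.absorbed else 1
            nnc100 = 100.0 * n_nc / runs_per_point
            t_mean = float(np.mean(ts))
            tc = (
                corrected_convergence_time(t_mean, n_nc, tmax, runs_per_point)
                if n_nc < runs_per_point
                else float("nan")
            )
            rows.append(
                {
                    "structure": mode,
                    "r": r,
                    "mean_cinf": float(np.mean(cs)),
                    "mean_t": t_mean,
                    "t_c": tc,
                    "nnc_per100": nnc100,
                }
            )
    df = pd.DataFrame(rows)
    return df
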