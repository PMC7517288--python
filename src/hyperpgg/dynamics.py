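"""Public goods game (PGG) dynamics on simple hypergraphs.

Every vertex is a player with a binary strategy (1 = cooperate, 0 = defect).
In each round every player plays one PGG inside each incident hyperedge: a
cooperator pays a contribution ``b`` into the group pot, the pot is scaled
by the synergy factor ``alpha`` and split equally among the ``m`` group
members. With ``nc`` cooperating co-members (``q = nc / (m - 1)``), the
per-group payoff of a player with strategy ``sigma`` is

    f(sigma) = b * [ (alpha/m - 1) * sigma + (alpha * (m-1) / m) * q ]

and a player's round payoff is the sum over its incident hyperedges. Payoffs
are reset every round (no accumulation).

Strategy updating is synchronous smoothed imitation: each player draws one
neighbor uniformly at random in the 2-section and copies its strategy with
the Fermi probability ``F(f_j - f_i; beta) = 1 / (1 + exp(-beta (f_j -
f_i)))``. The states "all defect" and "all cooperate" are absorbing.

The module also implements the Monte Carlo sweep protocol and the structural
reciprocity measure ``r(p) = alpha_surv / alpha_cr``, where ``alpha_surv``
is the smallest synergy at which the mean asymptotic cooperator density
rises above zero and ``alpha_cr = sum_m m p_m`` is the well-mixed critical
synergy of the hypergraph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .generators import GeneratorConfig, PromotionConfig, generate, promote_cliques
from .hypergraph import Hypergraph, cardinality_fractions, two_section

__all__ = [
    "GameParams",
    "StrategyState",
    "RunResult",
    "SweepResult",
    "CompiledHypergraph",
    "hyperedge_payoff",
    "total_payoff",
    "fermi",
    "step",
    "run",
    "random_initial_state",
    "mc_experiment",
    "alpha_cr_from_fractions",
    "estimate_alpha_surv",
    "reciprocity_ratio",
]


@dataclass(frozen=True)
class GameParams:
    """Synergy factor alpha (> 1), contribution b (> 0), selection beta (> 0)."""

    alpha: float
    b: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not self.alpha > 1:
            raise ValueError("synergy factor alpha must exceed 1")
        if not self.b > 0:
            raise ValueError("contribution b must be positive")
        if not self.beta > 0:
            raise ValueError("selection strength beta must be positive")


@dataclass
class StrategyState:
    """Binary strategy vector sigma (1 = cooperate) and round index t."""

    sigma: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=np.int8)
        if not np.isin(self.sigma, (0, 1)).all():
            raise ValueError("strategies must be 0 or 1")

    @property
    def density(self) -> float:
        return float(self.sigma.mean())


@dataclass(frozen=True)
class RunResult:
    """Outcome of one trajectory: density series, absorption, final density."""

    trajectory: np.ndarray  # c(0), c(1), ..., c(t_conv)
    t_conv: int
    absorbed: bool
    c_final: float


@dataclass(frozen=True)
class SweepResult:
    """Per-grid-point averages of a Monte Carlo synergy sweep.

    ``table`` columns: ``r`` (alpha / alpha_cr), ``alpha`` (mean over
    hypergraph replicates), ``mean_cinf``, ``mean_t``, ``nnc_per100``.
    """

    table: pd.DataFrame
    alpha_cr: float  # mean over hypergraph replicates (Eq.-7 route)
    hypergraph_seeds: Tuple[int, ...]
    master_seed: int


def fermi(x, beta: float):
    """Fermi imitation probability 1 / (1 + exp(-beta x))."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-beta * x[pos]))
    ex = np.exp(beta * x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def hyperedge_payoff(sigma: int, nc: int, m: int, params: GameParams) -> float:
    """Per-group PGG payoff of a player with ``nc`` cooperating co-members."""
    if m < 2:
        raise ValueError("group size m must be >= 2")
    if not (0 <= nc <= m - 1):
        raise ValueError("nc must lie in 0..m-1")
    q = nc / (m - 1)
    a = params.alpha
    return params.b * ((a / m - 1.0) * sigma + (a * (m - 1) / m) * q)


class CompiledHypergraph:
    """Incidence arrays of a rank-<=3 hypergraph, prepared for fast sweeps.

    Splits hyperedges by cardinality into edge (M2 x 2) and triangle
    (M3 x 3) index arrays with sparse incidence matrices, and flattens the
    2-section adjacency into a CSR-style neighbor array for vectorized
    uniform neighbor draws.
    """

    def __init__(self, H: Hypergraph):
        if H.n_hyperedges and H.rank > 3:
            raise ValueError("dynamics are implemented for rank <= 3 only")
        self.hypergraph = H
        self.n = H.n_vertices
        e2 = np.array(H.edges_of_size(2), dtype=np.int64).reshape(-1, 2)
        e3 = np.array(H.edges_of_size(3), dtype=np.int64).reshape(-1, 3)
        self.e2, self.e3 = e2, e3
        self.B2 = self._incidence(e2)  # (n, M2)
        self.B3 = self._incidence(e3)  # (n, M3)
        self.k2 = np.asarray(self.B2.sum(axis=1)).ravel()
        self.k3 = np.asarray(self.B3.sum(axis=1)).ravel()

        g = two_section(H)
        deg = np.array([g.degree(v) for v in range(self.n)], dtype=np.int64)
        self.deg = deg
        self.offsets = np.concatenate(([0], np.cumsum(deg)))
        flat = np.empty(self.offsets[-1], dtype=np.int64)
        for v in range(self.n):
            flat[self.offsets[v] : self.offsets[v + 1]] = sorted(g.neighbors(v))
        self.neighbors_flat = flat
        self.has_isolated = bool((deg == 0).any())
        self.alpha_cr = alpha_cr_from_fractions(H)

    def _incidence(self, edges: np.ndarray) -> sp.csr_matrix:
        n_e = edges.shape[0]
        if n_e == 0:
            return sp.csr_matrix((self.n, 0))
        rows = edges.ravel()
        cols = np.repeat(np.arange(n_e), edges.shape[1])
        data = np.ones(rows.size)
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n, n_e))

    def payoffs(self, sigma: np.ndarray, params: GameParams) -> np.ndarray:
        """Round payoff vector f(i) summed over incident hyperedges."""
        a, b = params.alpha, params.b
        sig = sigma.astype(float)
        f = b * ((a / 2 - 1.0) * self.k2 + (a / 3 - 1.0) * self.k3) * sig
        if self.e2.size:
            nc2 = self.B2.T @ sig  # cooperators per edge (incl. self)
            f += b * (a / 2) * (self.B2 @ nc2 - self.k2 * sig)
        if self.e3.size:
            nc3 = self.B3.T @ sig
            f += b * (a / 3) * (self.B3 @ nc3 - self.k3 * sig)
        return f


def total_payoff(
    H: Hypergraph | CompiledHypergraph,
    state: StrategyState,
    params: GameParams,
) -> np.ndarray:
    """Payoff vector for the current strategies (reset every round)."""
    compiled = H if isinstance(H, CompiledHypergraph) else CompiledHypergraph(H)
    return compiled.payoffs(state.sigma, params)


def _advance(
    compiled: CompiledHypergraph,
    sigma: np.ndarray,
    params: GameParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """One synchronous imitation round; returns the next strategy vector.

    Two RNG arrays (neighbor picks, acceptance uniforms) are drawn every
    round regardless of outcome, so the stream advance is state-independent.
    """
    n = compiled.n
    f = compiled.payoffs(sigma, params)
    picks = rng.random(n)
    accept = rng.random(n)
    deg = compiled.deg
    active = deg > 0
    j = np.zeros(n, dtype=np.int64)
    j[active] = compiled.neighbors_flat[
        compiled.offsets[:-1][active]
        + (picks[active] * deg[active]).astype(np.int64)
    ]
    prob = fermi(f[j] - f, params.beta)
    flip = active & (sigma[j] != sigma) & (accept < prob)
    new_sigma = sigma.copy()
    new_sigma[flip] = sigma[j][flip]
    return new_sigma, int(flip.sum())


def _is_frozen(compiled: CompiledHypergraph, sigma: np.ndarray) -> bool:
    """True when no hyperedge is discordant, i.e. strategies are constant on
    every connected component: no future change is possible. On a connected
    2-section this coincides with c in {0, 1}."""
    if compiled.e2.size:
        if (sigma[compiled.e2[:, 0]] != sigma[compiled.e2[:, 1]]).any():
            return False
    if compiled.e3.size:
        s3 = sigma[compiled.e3].sum(axis=1)
        if ((s3 != 0) & (s3 != 3)).any():
            return False
    return True


def step(
    H: Hypergraph | CompiledHypergraph,
    state: StrategyState,
    params: GameParams,
    rng: np.random.Generator,
) -> StrategyState:
    """One synchronous round: every player imitates one uniform 2-section
    neighbor with Fermi probability of the payoff difference."""
    compiled = H if isinstance(H, CompiledHypergraph) else CompiledHypergraph(H)
    if compiled.has_isolated:
        warnings.warn(
            "isolated vertices present: their strategies are frozen",
            stacklevel=2,
        )
    sigma, _ = _advance(
        compiled, np.asarray(state.sigma, dtype=np.int8), params, rng
    )
    return StrategyState(sigma=sigma, t=state.t + 1)


def run(
    H: Hypergraph | CompiledHypergraph,
    state0: StrategyState,
    params: GameParams,
    tmax: int,
    rng: np.random.Generator,
    record_trajectory: bool = True,
) -> RunResult:
    """Iterate rounds until absorption (c in {0, 1}) or ``tmax`` rounds."""
    if tmax < 1:
        raise ValueError("tmax must be >= 1")
    compiled = H if isinstance(H, CompiledHypergraph) else CompiledHypergraph(H)
    sigma = np.asarray(state0.sigma, dtype=np.int8)
    n = compiled.n
    traj = [sigma.sum() / n] if record_trajectory else []
    s = int(sigma.sum())
    t = 0
    # A state is absorbing when no hyperedge is discordant; on a connected
    # structure that means c in {0, 1}, and on a disconnected one it also
    # covers frozen mixed states (e.g. isolated vertices).
    absorbed = s in (0, n) or _is_frozen(compiled, sigma)
    while not absorbed and t < tmax:
        sigma, n_flips = _advance(compiled, sigma, params, rng)
        t += 1
        s = int(sigma.sum())
        if record_trajectory:
            traj.append(s / n)
        absorbed = s in (0, n) or (
            n_flips == 0 and _is_frozen(compiled, sigma)
        )
    return RunResult(
        trajectory=np.array(traj if record_trajectory else [s / n]),
        t_conv=t,
        absorbed=absorbed,
        c_final=s / n,
    )


def random_initial_state(
    n: int, c0: float, rng: np.random.Generator
) -> StrategyState:
    """Exactly round(c0 * N) cooperators placed uniformly at random."""
    if not (0.0 <= c0 <= 1.0):
        raise ValueError("c0 must lie in [0, 1]")
    n_coop = round(c0 * n)
    sigma = np.zeros(n, dtype=np.int8)
    sigma[rng.permutation(n)[:n_coop]] = 1
    return StrategyState(sigma=sigma, t=0)


def alpha_cr_from_fractions(H: Hypergraph) -> float:
    """Well-mixed critical synergy alpha_cr = sum_m m p_m (mean cardinality)."""
    pm = cardinality_fractions(H)
    return sum(m * frac for m, frac in pm.items())


def _run_seed(master: int, h_idx: int, r_idx: int, run_idx: int) -> np.random.Generator:
    # Order-independent streams: every run's seed depends only on its indices.
    return np.random.default_rng(
        np.random.SeedSequence([master, h_idx, r_idx, run_idx])
    )


def mc_experiment(
    gen_cfg: GeneratorConfig,
    promo_cfg: PromotionConfig,
    b: float,
    beta: float,
    r_grid: Sequence[float],
    runs_per_point: int = 100,
    n_hypergraphs: int = 10,
    c0: float = 0.5,
    tmax: int = 20_000,
    seed: int = 0,
    stop_when_cinf_above: Optional[float] = None,
) -> SweepResult:
    """Monte Carlo sweep over the rescaled synergy grid ``r = alpha/alpha_cr``.

    For each hypergraph replicate (independent base network + promotion),
    each grid point runs ``runs_per_point`` trajectories from independent
    random initial conditions with exactly a fraction ``c0`` of cooperators.
    Asymptotic densities and convergence times are averaged within each
    hypergraph first, then across hypergraphs; non-converged runs count
    their last density and are tallied in ``nnc_per100``.

    ``stop_when_cinf_above`` truncates the ascending grid scan once the mean
    asymptotic density exceeds the given threshold (the survival onset),
    which leaves earlier grid points bit-identical to a full scan.
    """
    r_grid = sorted(float(r) for r in r_grid)
    ss = np.random.SeedSequence([int(seed), 979_323])
    h_seeds = [int(s) for s in ss.generate_state(2 * n_hypergraphs) % (2**31)]
    compiled: List[CompiledHypergraph] = []
    for h_idx in range(n_hypergraphs):
        g_cfg = GeneratorConfig(
            model=gen_cfg.model,
            n=gen_cfg.n,
            m=gen_cfg.m,
            pt=gen_cfg.pt,
            mean_degree=gen_cfg.mean_degree,
            seed=h_seeds[2 * h_idx],
            require_connected=gen_cfg.require_connected,
        )
        p_cfg = PromotionConfig(p=promo_cfg.p, seed=h_seeds[2 * h_idx + 1])
        compiled.append(CompiledHypergraph(promote_cliques(generate(g_cfg), p_cfg)))

    alpha_crs = np.array([c.alpha_cr for c in compiled])
    rows = []
    for r_idx, r in enumerate(r_grid):
        per_h_c, per_h_t, n_nc, n_runs = [], [], 0, 0
        for h_idx, comp in enumerate(compiled):
            alpha = r * comp.alpha_cr
            params = GameParams(alpha=alpha, b=b, beta=beta)
            cs, ts = [], []
            for run_idx in range(runs_per_point):
                rng = _run_seed(int(seed), h_idx, r_idx, run_idx)
                state0 = random_initial_state(comp.n, c0, rng)
                res = run(
                    comp, state0, params, tmax, rng, record_trajectory=False
                )
                cs.append(res.c_final)
                ts.append(res.t_conv)
                n_nc += 0 if res.absorbed else 1
                n_runs += 1
            per_h_c.append(np.mean(cs))
            per_h_t.append(np.mean(ts))
        mean_cinf = float(np.mean(per_h_c))
        rows.append(
            {
                "r": r,
                "alpha": float(r * alpha_crs.mean()),
                "mean_cinf": mean_cinf,
                "mean_t": float(np.mean(per_h_t)),
                "nnc_per100": 100.0 * n_nc / n_runs,
            }
        )
        if stop_when_cinf_above is not None and mean_cinf > stop_when_cinf_above:
            break
    return SweepResult(
        table=pd.DataFrame(rows),
        alpha_cr=float(alpha_crs.mean()),
        hypergraph_seeds=tuple(h_seeds),
        master_seed=int(seed),
    )


@dataclass(frozen=True)
class SurvivalOnset:
    """Location of the survival onset on a sweep grid (or absence thereof)."""

    found: bool
    r: float = float("nan")
    alpha: float = float("nan")


def estimate_alpha_surv(
    sweep: SweepResult, epsilon: Optional[float] = None, n_vertices: Optional[int] = None
) -> SurvivalOnset:
    """Smallest grid point whose mean asymptotic density exceeds ``epsilon``.

    The default threshold is half a player, 1/(2N), when ``n_vertices`` is
    given, else 1e-3.
    """
    if epsilon is None:
        epsilon = 1.0 / (2 * n_vertices) if n_vertices else 1e-3
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    hit = sweep.table[sweep.table["mean_cinf"] > epsilon]
    if hit.empty:
        return SurvivalOnset(found=False)
    row = hit.iloc[0]
    return SurvivalOnset(found=True, r=float(row["r"]), alpha=float(row["alpha"]))


def reciprocity_ratio(alpha_surv: float, H: Hypergraph) -> float:
    """Structural reciprocity r = alpha_surv / alpha_cr of the hypergraph."""
    return alpha_surv / alpha_cr_from_fractions(H)
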