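"""Closed-form layer: mean-field theory, hub invasion, isolated defectors.

Mean field
----------
Assuming every vertex carries the mean m-degree sequence ``<k_m>`` and
uncorrelated local states, the cooperator density obeys

    c(t+1) = c(t) + c(t) (1 - c(t)) [F(Δf) - F(-Δf)],
    Δf = b * sum_m (alpha/m - 1) <k_m>,

so besides the absorbing states the only stationary point is ``Δf = 0`` at

    alpha_cr = sum_m <k_m> / sum_m <k_m>/m = sum_m m p_m = <m>,

with ``p_m ∝ <k_m>/m`` the hyperedge-cardinality fractions. On a complete
m-uniform simple hypergraph of N vertices (the finite well-mixed structure)
the transition sits instead at ``alpha_cr^m = m (N-1) / (N-m)``.

Hub invasion
------------
A cooperator hub with m-degree sequence ``k_m^hub`` surrounded by average
vertices resists invasion above the threshold obtained by equating its
payoff to its defector neighbors' average payoff, which for s-uniform
hypergraphs reduces to

    r_hub = 1 / (1 + (s - 1) (q0_hub - qbar0_d * xi_s)),

with ``qbar0_d = c0 N/(N-1)``, ``q0_hub = qbar0_d - 1/(N-1)`` and
``xi_s = kbar_s / k_s^hub`` the neighborhood-to-hub degree ratio.

Isolated defectors
------------------
For a defector ``d`` with degree pair ``(k2(d), k3(d))`` completely
surrounded by equivalent cooperators, the payoff gap to a cooperator
neighbor ``j`` is linear in alpha:

    f(j) - f(d) = b alpha [k2(j) - k2(d)/2 + k3(j) - 2 k3(d)/3 - a(j)]
                  - b (k2(j) + k3(j)),

where ``a(j) = 1/2`` for a link neighbor and ``kappa_d(j)/3`` for a
triangle neighbor sharing ``kappa_d(j)`` triangles with ``d``. From this
follow the survive-and-invade probability and the degree/clustering
conditions under which the cooperator-defector competition sharpens as
alpha grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .dynamics import GameParams, fermi
from .hypergraph import Hypergraph, MDegreeTable, m_degrees, two_section

__all__ = [
    "MeanFieldSpec",
    "HubScenario",
    "DefectorScenario",
    "mean_field_step",
    "mean_field_trajectory",
    "alpha_cr_mean_field",
    "alpha_cr_finite",
    "hub_threshold",
    "r_hub",
    "identify_hubs",
    "xi_s",
    "defector_payoff_gap",
    "survive_and_invade_prob",
    "competition_conditions",
    "CompetitionReport",
    "kappa_from_clustering",
]


@dataclass(frozen=True)
class MeanFieldSpec:
    """Mean m-degrees <k_m> and game parameters of a mean-field population."""

    mean_degrees: Dict[int, float]
    params: GameParams

    def __post_init__(self) -> None:
        if not self.mean_degrees or all(
            v <= 0 for v in self.mean_degrees.values()
        ):
            raise ValueError("at least one mean m-degree must be positive")
        if any(v < 0 for v in self.mean_degrees.values()):
            raise ValueError("mean m-degrees must be non-negative")

    @property
    def delta_f(self) -> float:
        """Mean payoff advantage of cooperators, Δf = b Σ (α/m − 1)<k_m>."""
        a, b = self.params.alpha, self.params.b
        return b * sum(
            (a / m - 1.0) * km for m, km in self.mean_degrees.items()
        )


def mean_field_step(c: float, spec: MeanFieldSpec) -> float:
    """One master-equation update of the cooperator density."""
    if not (0.0 <= c <= 1.0):
        raise ValueError("density must lie in [0, 1]")
    df = spec.delta_f
    beta = spec.params.beta
    return c + c * (1.0 - c) * (fermi(df, beta) - fermi(-df, beta))


def mean_field_trajectory(
    c0: float,
    spec: MeanFieldSpec,
    tol: float = 1e-12,
    max_iter: int = 1_000_000,
) -> Tuple[float, int]:
    """Iterate the master equation to a fixed point; returns (c*, steps)."""
    c = c0
    for t in range(max_iter):
        c_next = min(1.0, max(0.0, mean_field_step(c, spec)))
        if abs(c_next - c) < tol:
            return c_next, t + 1
        c = c_next
    return c, max_iter


def alpha_cr_mean_field(spec_or_H) -> float:
    """Critical synergy <m> from mean m-degrees weighted by p_m ∝ <k_m>/m.

    Accepts a :class:`MeanFieldSpec`, a plain ``{m: <k_m>}`` mapping, or a
    :class:`Hypergraph` (whose mean degrees are then computed). Consistent
    with the hyperedge-count route ``sum_m m p_m``.
    """
    if isinstance(spec_or_H, MeanFieldSpec):
        kms = spec_or_H.mean_degrees
    elif isinstance(spec_or_H, Hypergraph):
        kms = m_degrees(spec_or_H).mean_degrees()
    else:
        kms = dict(spec_or_H)
    num = sum(km for km in kms.values())
    den = sum(km / m for m, km in kms.items())
    if den <= 0:
        raise ValueError("degenerate mean degrees")
    return num / den


def alpha_cr_finite(m: int, N: int) -> float:
    """Finite-size critical synergy m (N - 1) / (N - m) of the complete
    m-uniform simple hypergraph (strong-selection limit)."""
    if not (N > m >= 2):
        raise ValueError("need N > m >= 2")
    return m * (N - 1) / (N - m)


# -- cooperator hubs -------------------------------------------------------


@dataclass(frozen=True)
class HubScenario:
    """Hub m-degree sequence and neighborhood means for the invasion bound.

    ``k_hub`` maps cardinality m to the (mean) hub m-degree; ``k_bar`` maps
    m to the mean m-degree over the hubs' neighborhoods. ``c0`` is the
    initial cooperator fraction and ``N`` the population size.
    """

    k_hub: Dict[int, float]
    k_bar: Dict[int, float]
    c0: float
    N: int

    def __post_init__(self) -> None:
        if not (0.0 < self.c0 < 1.0):
            raise ValueError("c0 must lie in (0, 1)")
        if self.N < 3:
            raise ValueError("N must be >= 3")
        if any(v < 0 for v in self.k_hub.values()) or any(
            v < 0 for v in self.k_bar.values()
        ):
            raise ValueError("degrees must be non-negative")

    @property
    def qbar0_d(self) -> float:
        """Initial mean cooperating-neighbor fraction of defector neighbors."""
        return self.c0 * self.N / (self.N - 1)

    @property
    def q0_hub(self) -> float:
        """Initial mean cooperating-neighbor fraction of the hub itself."""
        return self.qbar0_d - 1.0 / (self.N - 1)


@dataclass(frozen=True)
class HubThreshold:
    finite: bool
    alpha_th: float = float("nan")


def hub_threshold(scn: HubScenario) -> HubThreshold:
    """Synergy above which a cooperator hub outperforms its defector
    neighbors on average (payoff-equality threshold).

    Solves f(hub as cooperator) = mean f(defector neighbor) at t = 0:

        alpha_th = sum_m k_m^hub /
                   sum_m [ k_m^hub/m
                           + (m-1)/m (q0_hub k_m^hub - qbar0_d kbar_m) ]
    """
    num = sum(scn.k_hub.values())
    den = 0.0
    for m, km in scn.k_hub.items():
        kbar = scn.k_bar.get(m, 0.0)
        den += km / m + (m - 1) / m * (scn.q0_hub * km - scn.qbar0_d * kbar)
    if den <= 0:
        return HubThreshold(finite=False)
    return HubThreshold(finite=True, alpha_th=num / den)


def r_hub(s: int, xi: float, c0: float, N: int) -> float:
    """Uniform-hypergraph reduction: r_hub = 1/(1 + (s-1)(q0_hub - qbar0_d xi)).

    This is alpha_th / alpha_cr for an s-uniform hypergraph with
    ``kbar_s = xi * k_s^hub``; it decreases monotonically in s.
    """
    if s < 2:
        raise ValueError("s must be >= 2")
    scn = HubScenario(k_hub={s: 1.0}, k_bar={s: xi}, c0=c0, N=N)
    den = 1.0 + (s - 1) * (scn.q0_hub - scn.qbar0_d * xi)
    if den <= 0:
        raise ValueError("no finite hub threshold for these parameters")
    return 1.0 / den


def identify_hubs(
    H: Hypergraph,
    percentile: float = 97.0,
    degree: str = "generalized",
) -> np.ndarray:
    """Vertices whose degree reaches the given percentile of the degree
    distribution. ``degree`` is ``"generalized"`` (sum of m-degrees) or
    ``"two_section"`` (degree in the graph projection)."""
    if degree == "generalized":
        d = m_degrees(H).generalized.astype(float)
    elif degree == "two_section":
        g = two_section(H)
        d = np.array([g.degree(v) for v in range(H.n_vertices)], dtype=float)
    else:
        raise ValueError("degree must be 'generalized' or 'two_section'")
    cutoff = np.percentile(d, percentile)
    hubs = np.flatnonzero(d >= cutoff)
    if hubs.size == 0:
        raise ValueError("empty hub set")
    return hubs


def xi_s(
    H: Hypergraph, hubs: Sequence[int], s: int
) -> Tuple[float, float, float]:
    """Neighborhood-to-hub s-degree ratio.

    Returns ``(k_s_hub, kbar_s, xi)``: the mean hub s-degree, the mean
    s-degree over hub neighborhoods (per hub, then over hubs), and their
    ratio ``xi = kbar_s / k_s_hub``.
    """
    table = m_degrees(H)
    ks = table.by_size.get(s)
    if ks is None:
        raise ValueError(f"hypergraph has no hyperedges of cardinality {s}")
    g = two_section(H)
    hubs = np.asarray(hubs)
    ks_hub = float(ks[hubs].mean())
    neigh_means = []
    for h in hubs:
        nbrs = list(g.neighbors(int(h)))
        if nbrs:
            neigh_means.append(ks[nbrs].mean())
    kbar_s = float(np.mean(neigh_means))
    if ks_hub <= 0:
        raise ValueError("hubs have zero s-degree")
    return ks_hub, kbar_s, kbar_s / ks_hub


# -- isolated defectors ----------------------------------------------------


@dataclass(frozen=True)
class DefectorScenario:
    """Isolated defector surrounded by equivalent cooperator neighbors.

    ``k2_d, k3_d`` are the defector's link- and triangle-degrees; ``k2_c,
    k3_c`` those of the (average) cooperator neighbor. ``kappa_d`` is the
    number of triangles a triangle-neighbor shares with the defector,
    ``kappa_c`` the analogous count among cooperators (used by the
    competition conditions). ``omega_c`` is the cooperator neighborhood
    size |Ω|; ``w`` the number of simultaneous invasions;
    ``neighbor_via`` selects the a(j) branch ('link' or 'triangle').
    """

    k2_d: float
    k3_d: float
    k2_c: float
    k3_c: float
    params: GameParams
    kappa_d: float = 0.0
    kappa_c: float = 0.0
    omega_c: float = 1.0
    w: int = 1
    neighbor_via: str = "link"

    def __post_init__(self) -> None:
        if self.neighbor_via not in ("link", "triangle"):
            raise ValueError("neighbor_via must be 'link' or 'triangle'")
        if self.neighbor_via == "triangle" and self.kappa_d <= 0:
            raise ValueError("triangle neighbors require kappa_d > 0")
        if self.k3_d > 0 and self.kappa_d <= 0:
            raise ValueError("k3_d > 0 requires kappa_d > 0")

    @property
    def a_j(self) -> float:
        """Shared-interaction correction a(j): 1/2 per link, kappa_d/3 per
        shared triangle."""
        return 0.5 if self.neighbor_via == "link" else self.kappa_d / 3.0

    @property
    def omega_d(self) -> float:
        """Defector neighborhood size |Ω(d)| = k2(d) + 2 k3(d)/kappa_d."""
        extra = 2.0 * self.k3_d / self.kappa_d if self.k3_d > 0 else 0.0
        return self.k2_d + extra


def defector_payoff_gap(scn: DefectorScenario) -> float:
    """Payoff gap f(j) - f(d) of a cooperator neighbor over the defector."""
    a, b = scn.params.alpha, scn.params.b
    slope = (
        scn.k2_c
        - scn.k2_d / 2.0
        + scn.k3_c
        - 2.0 * scn.k3_d / 3.0
        - scn.a_j
    )
    return b * (a * slope - (scn.k2_c + scn.k3_c))


def survive_and_invade_prob(scn: DefectorScenario) -> float:
    """Joint probability that the defector keeps its strategy this round and
    ``w`` of its cooperator neighbors simultaneously adopt defection.

    With all neighbors cooperators, the defector flips with probability
    ``p_d = F(f(c) - f(d))``; each targeted cooperator picks the defector
    among its |Ω| neighbors and flips with ``F(f(d) - f(c))``:

        (1 - p_d) * [ F(f(d) - f(c)) / |Ω| ]^w
    """
    if scn.w < 0 or scn.w > scn.omega_d:
        raise ValueError("need 0 <= w <= |Ω(d)|")
    if scn.omega_c <= 0:
        raise ValueError("cooperator neighborhood size must be positive")
    gap = defector_payoff_gap(scn)  # f(c) - f(d) seen from the neighbor j
    p_d = fermi(gap, scn.params.beta)
    p_invade_one = fermi(-gap, scn.params.beta) / scn.omega_c
    return float((1.0 - p_d) * p_invade_one**scn.w)


@dataclass(frozen=True)
class CompetitionReport:
    """Degree/clustering conditions for the defector-cooperator competition.

    ``general`` — does f(c) - f(d) decrease in alpha for the given mixed
    degrees; ``p0`` / ``p1`` — the pure-link and pure-triangle special
    cases (the latter rewritten through k3(σ) = k2(σ) kappa_σ / 2 in terms
    of p = 0 link-degrees); ``p0_implies_p1`` — whether kappa_d/kappa_c >
    3/4, the condition under which the link-case inequality implies the
    triangle-case one; ``k2_d_band`` — interval of k2(d) for which only the
    triangle case is competitive.
    """

    general: bool
    p0: bool
    p1: bool
    p0_implies_p1: bool
    k2_d_band: Tuple[float, float]


def competition_conditions(scn: DefectorScenario) -> CompetitionReport:
    omega_d = scn.omega_d
    if omega_d <= 0:
        raise ValueError("defector has no neighbors")
    lhs = (omega_d + 1.0) / omega_d * (scn.k2_d / 2.0 + 2.0 * scn.k3_d / 3.0)
    general = lhs > scn.k2_c + scn.k3_c
    p0 = scn.k2_d > 2.0 * scn.k2_c - 1.0
    if scn.kappa_d > 0:
        p1_lower = 1.5 * (scn.kappa_c / scn.kappa_d) * scn.k2_c - 1.0
        p1 = scn.k2_d > p1_lower
        p0_implies_p1 = (
            scn.kappa_c > 0 and scn.kappa_d / scn.kappa_c > 0.75
        )
    else:
        p1_lower = float("inf")
        p1 = False
        p0_implies_p1 = False
    band = (p1_lower, 2.0 * scn.k2_c - 1.0)
    return CompetitionReport(
        general=general,
        p0=p0,
        p1=p1,
        p0_implies_p1=p0_implies_p1,
        k2_d_band=band,
    )


def kappa_from_clustering(C: float, k2: float) -> float:
    """Shared-triangle count kappa = C (k2 - 1) from the local clustering
    coefficient and link-degree of the p = 0 base graph."""
    if not (0.0 <= C <= 1.0):
        raise ValueError("clustering coefficient must lie in [0, 1]")
    if k2 < 1:
        raise ValueError("k2 must be >= 1")
    return C * (k2 - 1.0)
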