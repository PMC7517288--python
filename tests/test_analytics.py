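"""Mean-field theory, hub invasion thresholds, isolated-defector analysis."""

import numpy as np
import pytest

from hyperpgg import (
    GameParams,
    Hypergraph,
    PromotionConfig,
    StrategyState,
    promote_cliques,
    total_payoff,
)
from hyperpgg import analytics as an
from hyperpgg.analytics import (
    DefectorScenario,
    HubScenario,
    MeanFieldSpec,
    alpha_cr_finite,
    alpha_cr_mean_field,
    competition_conditions,
    defector_payoff_gap,
    hub_threshold,
    identify_hubs,
    kappa_from_clustering,
    mean_field_step,
    mean_field_trajectory,
    r_hub,
    survive_and_invade_prob,
    xi_s,
)
from hyperpgg.dynamics import alpha_cr_from_fractions
from hyperpgg.generators import GeneratorConfig, generate_dm, generate_hk


class TestMeanField:
    def test_absorbing_fixed_points(self):
        spec = MeanFieldSpec({2: 3.0, 3: 2.0}, GameParams(2.0))
        assert mean_field_step(0.0, spec) == 0.0
        assert mean_field_step(1.0, spec) == 1.0

    def test_critical_synergy_leaves_density_unchanged(self):
        """At alpha = <m> the cooperator-defector payoff gap vanishes."""
        kms = {2: 4.0, 3: 4.0}
        spec = MeanFieldSpec(kms, GameParams(alpha_cr_mean_field(kms)))
        for c in (0.1, 0.5, 0.9):
            assert mean_field_step(c, spec) == pytest.approx(c)

    def test_supercritical_converges_to_full_cooperation(self):
        spec = MeanFieldSpec({3: 5.0}, GameParams(3.5, beta=1.0))
        c_star, _ = mean_field_trajectory(0.2, spec)
        assert c_star == pytest.approx(1.0, abs=1e-9)
        # and monotonically
        c = 0.2
        for _ in range(50):
            c_next = mean_field_step(c, spec)
            assert c_next >= c
            c = c_next

    @pytest.mark.parametrize("s", [2, 3, 4])
    def test_uniform_critical_synergy(self, s):
        assert alpha_cr_mean_field({s: 7.0}) == pytest.approx(s)

    def test_equal_mean_degrees_weighting(self):
        """<k2> = <k3> gives p_m proportional to (1/2, 1/3), alpha_cr = 2.4."""
        assert alpha_cr_mean_field({2: 5.0, 3: 5.0}) == pytest.approx(2.4)

    def test_two_route_consistency_on_generated_hypergraph(self):
        """Hyperedge-count and mean-degree routes agree to machine precision."""
        g = generate_hk(GeneratorConfig("hk", 200, 3, 1.0, seed=2))
        for p in (0.0, 0.4, 1.0):
            H = promote_cliques(g, PromotionConfig(p, seed=3))
            assert alpha_cr_mean_field(H) == pytest.approx(
                alpha_cr_from_fractions(H), rel=1e-12
            )


class TestFiniteSize:
    def test_values(self):
        assert alpha_cr_finite(3, 500) == pytest.approx(3 * 499 / 497)
        assert alpha_cr_finite(2, 3) == pytest.approx(4.0)

    def test_limit_and_monotonicity(self):
        assert alpha_cr_finite(3, 10**9) == pytest.approx(3.0, abs=1e-6)
        # the relative correction grows with m at fixed N
        ratios = [alpha_cr_finite(m, 100) / m for m in (2, 3, 4, 5)]
        assert all(a < b for a, b in zip(ratios, ratios[1:]))

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            alpha_cr_finite(3, 3)


class TestHubInvasion:
    def test_reduction_example(self):
        """s=2, N=501, c0=0.5, xi=0.5 gives r_hub = 1/1.2485."""
        assert r_hub(2, 0.5, 0.5, 501) == pytest.approx(1 / 1.2485, abs=1e-4)

    def test_threshold_reduces_to_uniform_formula(self):
        k = 12.0
        scn = HubScenario({3: k}, {3: 0.6 * k}, c0=0.5, N=500)
        th = hub_threshold(scn)
        assert th.finite
        assert th.alpha_th / 3 == pytest.approx(r_hub(3, 0.6, 0.5, 500))

    def test_unit_ratio_when_bracket_vanishes(self):
        """q0_hub = qbar0_d * xi makes the hub threshold equal alpha_cr."""
        N, c0 = 500, 0.5
        qbar = c0 * N / (N - 1)
        q0 = qbar - 1 / (N - 1)
        assert r_hub(4, q0 / qbar, c0, N) == pytest.approx(1.0)

    def test_monotone_decreasing_in_s(self):
        vals = [r_hub(s, 0.5, 0.5, 500) for s in range(2, 11)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_identify_hubs_star(self):
        star = Hypergraph(5, ((0, 1), (0, 2), (0, 3), (0, 4)))
        assert list(identify_hubs(star, 99.0)) == [0]

    def test_xi_is_one_on_regular_structure(self):
        cycle = Hypergraph(6, tuple((i, (i + 1) % 6) for i in range(6)))
        hubs = identify_hubs(cycle, 50.0)
        _, _, xi = xi_s(cycle, hubs, 2)
        assert xi == pytest.approx(1.0)

    def test_xi_gap_small_on_dm_hypergraphs(self):
        """xi_2 and xi_3 differ by only about 0.01 on DM structures."""
        gaps = []
        for s in range(3):
            g = generate_dm(GeneratorConfig("dm", 500, seed=30 + s))
            H = promote_cliques(g, PromotionConfig(0.5, seed=40 + s))
            hubs = identify_hubs(H, 97.0)
            _, _, x2 = xi_s(H, hubs, 2)
            _, _, x3 = xi_s(H, hubs, 3)
            gaps.append(abs(x2 - x3))
        assert np.mean(gaps) < 0.05


def _build_link_configuration(k2_d, k2_c):
    """Literal star-of-links: defector 0 linked to cooperator 1; both padded
    with extra cooperator neighbors to reach their target degrees."""
    edges = [(0, 1)]
    nxt = 2
    for _ in range(k2_d - 1):
        edges.append((0, nxt)); nxt += 1
    for _ in range(k2_c - 1):
        edges.append((1, nxt)); nxt += 1
    sigma = np.ones(nxt, dtype=int)
    sigma[0] = 0
    return Hypergraph(nxt, tuple(edges)), sigma


def _build_triangle_configuration(k3_d, k3_c, kappa):
    """Defector 0 in k3_d triangles, kappa of them shared with cooperator 1,
    who sits in k3_c triangles in total; everyone else cooperates."""
    tris = []
    nxt = 2
    for i in range(k3_d):
        if i < kappa:
            tris.append((0, 1, nxt)); nxt += 1
        else:
            tris.append((0, nxt, nxt + 1)); nxt += 2
    for _ in range(k3_c - kappa):
        tris.append((1, nxt, nxt + 1)); nxt += 2
    sigma = np.ones(nxt, dtype=int)
    sigma[0] = 0
    return Hypergraph(nxt, tuple(tris)), sigma


class TestDefectorGap:
    @pytest.mark.parametrize("k2_d,k2_c", [(3, 3), (8, 4), (2, 6)])
    def test_link_case_matches_payoff_simulation(self, k2_d, k2_c):
        params = GameParams(alpha=2.3, b=1.2, beta=1.0)
        H, sigma = _build_link_configuration(k2_d, k2_c)
        f = total_payoff(H, StrategyState(sigma), params)
        scn = DefectorScenario(
            k2_d=k2_d, k3_d=0, k2_c=k2_c, k3_c=0, params=params,
            neighbor_via="link",
        )
        assert defector_payoff_gap(scn) == pytest.approx(f[1] - f[0])

    @pytest.mark.parametrize("k3_d,k3_c,kappa", [(4, 3, 2), (7, 3, 1), (3, 5, 3)])
    def test_triangle_case_matches_payoff_simulation(self, k3_d, k3_c, kappa):
        params = GameParams(alpha=2.8, b=0.9, beta=1.0)
        H, sigma = _build_triangle_configuration(k3_d, k3_c, kappa)
        f = total_payoff(H, StrategyState(sigma), params)
        scn = DefectorScenario(
            k2_d=0, k3_d=k3_d, k2_c=0, k3_c=k3_c, params=params,
            kappa_d=kappa, neighbor_via="triangle",
        )
        assert defector_payoff_gap(scn) == pytest.approx(f[1] - f[0])

    def test_small_alpha_limit(self):
        """As alpha -> 1+ the gap tends to -b (k2(j) + k3(j)) from the
        cooperator's unreciprocated contributions."""
        params = GameParams(alpha=1.0 + 1e-9, b=1.0, beta=1.0)
        scn = DefectorScenario(
            k2_d=4, k3_d=0, k2_c=3, k3_c=0, params=params, neighbor_via="link"
        )
        slope = 3 - 4 / 2 - 0.5  # k2_c - k2_d/2 - a(j)
        assert defector_payoff_gap(scn) == pytest.approx(-3.0 + slope, abs=1e-6)

    def test_linearity_in_alpha(self):
        def gap(alpha):
            return defector_payoff_gap(
                DefectorScenario(
                    k2_d=5, k3_d=3, k2_c=4, k3_c=2, kappa_d=2.0,
                    params=GameParams(alpha=alpha, b=2.0, beta=1.0),
                    neighbor_via="triangle",
                )
            )

        slope = (4 - 5 / 2 + 2 - 2 * 3 / 3 - 2.0 / 3)  # * b
        assert gap(3.0) - gap(2.0) == pytest.approx(2.0 * slope)


class TestSurviveAndInvade:
    def test_w_zero_is_pure_survival(self):
        scn = DefectorScenario(
            k2_d=8, k3_d=0, k2_c=4, k3_c=0, omega_c=4, w=0,
            params=GameParams(2.0, 1.0, 1.0), neighbor_via="link",
        )
        gap = defector_payoff_gap(scn)
        assert survive_and_invade_prob(scn) == pytest.approx(
            1.0 - an.fermi(gap, 1.0)
        )

    def test_random_drift_limit(self):
        """beta -> 0: probability tends to (1/2) (1/(2 |Omega|))^w."""
        scn = DefectorScenario(
            k2_d=8, k3_d=0, k2_c=4, k3_c=0, omega_c=5, w=2,
            params=GameParams(2.0, 1.0, 1e-9), neighbor_via="link",
        )
        assert survive_and_invade_prob(scn) == pytest.approx(
            0.5 * (0.5 / 5) ** 2, rel=1e-6
        )

    def test_alpha_monotonicity_follows_competition_condition(self):
        """When the degree-heterogeneity condition holds, raising the synergy
        *increases* the defector's survive-and-invade probability — the
        counterintuitive regime behind the widened transition; when it fails,
        the probability decreases with alpha as one would expect."""
        for k2_c, expect_increasing in ((4, True), (12, False)):
            def prob(alpha):
                return survive_and_invade_prob(
                    DefectorScenario(
                        k2_d=8, k3_d=0, k2_c=k2_c, k3_c=0, omega_c=k2_c,
                        w=1, params=GameParams(alpha, 1.0, 1.0),
                        neighbor_via="link",
                    )
                )

            rep = competition_conditions(
                DefectorScenario(
                    k2_d=8, k3_d=0, k2_c=k2_c, k3_c=0, omega_c=k2_c,
                    params=GameParams(2.0, 1.0, 1.0), neighbor_via="link",
                )
            )
            assert rep.general is expect_increasing
            increasing = prob(3.0) > prob(2.5) > prob(2.0)
            assert increasing is expect_increasing

    def test_too_many_invasions_rejected(self):
        scn = DefectorScenario(
            k2_d=2, k3_d=0, k2_c=2, k3_c=0, omega_c=2, w=5,
            params=GameParams(2.0, 1.0, 1.0), neighbor_via="link",
        )
        with pytest.raises(ValueError):
            survive_and_invade_prob(scn)


class TestCompetitionConditions:
    def _scn(self, **kw):
        base = dict(
            k2_d=6, k3_d=0, k2_c=3, k3_c=0, kappa_d=1.0, kappa_c=1.0,
            params=GameParams(2.0, 1.0, 1.0), neighbor_via="link",
        )
        base.update(kw)
        return DefectorScenario(**base)

    def test_regular_structure_is_never_competitive(self):
        """Equal degrees everywhere: the cooperator's lead always grows
        with alpha."""
        rep = competition_conditions(
            self._scn(k2_d=4, k3_d=2, k2_c=4, k3_c=2, kappa_d=2.0, kappa_c=2.0)
        )
        assert not rep.general

    def test_pure_link_threshold(self):
        assert competition_conditions(self._scn(k2_d=6, k2_c=3)).p0
        assert not competition_conditions(self._scn(k2_d=5, k2_c=3)).p0

    def test_intermediate_degree_band(self):
        """k2(c) = 4 with kappa_c = kappa_d gives the band 5 < k2(d) <= 7."""
        rep = competition_conditions(self._scn(k2_c=4))
        low, high = rep.k2_d_band
        assert low == pytest.approx(5.0)
        assert high == pytest.approx(7.0)
        inside = competition_conditions(self._scn(k2_d=6, k2_c=4))
        assert inside.p1 and not inside.p0

    @pytest.mark.parametrize(
        "kappa_d,kappa_c,expect", [(0.8, 1.0, True), (0.7, 1.0, False)]
    )
    def test_link_implies_triangle_iff_kappa_ratio(self, kappa_d, kappa_c, expect):
        rep = competition_conditions(
            self._scn(kappa_d=kappa_d, kappa_c=kappa_c)
        )
        assert rep.p0_implies_p1 is expect


class TestKappaFromClustering:
    def test_values(self):
        assert kappa_from_clustering(0.0, 5) == 0.0
        assert kappa_from_clustering(1.0, 3) == 2.0

    def test_matches_direct_shared_triangle_count_on_k4(self):
        """In K4 every vertex has C = 1 and k2 = 3, and indeed shares
        exactly 2 triangles with each neighbor."""
        import networkx as nx

        g = nx.complete_graph(4)
        C = nx.clustering(g, 0)
        adj = {v: set(g.neighbors(v)) for v in g}
        shared = len(adj[0] & adj[1])  # triangles on the edge (0, 1)
        assert kappa_from_clustering(C, g.degree(0)) == pytest.approx(shared) == 2

    def test_dm_clustering_scales_inversely_with_degree(self):
        """DM networks have C(k2) ~ 1/k2, so kappa ~ (k2-1)/k2 * const."""
        import networkx as nx

        g = generate_dm(GeneratorConfig("dm", 2000, seed=8))
        clust = nx.clustering(g)
        deg = dict(g.degree())
        by_k = {}
        for v in g.nodes():
            by_k.setdefault(deg[v], []).append(clust[v])
        ks = sorted(k for k, vals in by_k.items() if len(vals) >= 5 and k >= 4)
        # fit C(k) ~ k^-gamma: gamma should be close to 1
        x = np.log([k for k in ks])
        y = np.log([np.mean(by_k[k]) for k in ks])
        gamma = -np.polyfit(x, y, 1)[0]
        assert gamma == pytest.approx(1.0, abs=0.15)
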