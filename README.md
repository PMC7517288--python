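# hyperpgg

Evolutionary dynamics of the **public goods game (PGG) on rank-3 simple
hypergraphs**: a simulator and analysis toolkit for studying how group
(higher-order) interactions shape the evolution of cooperation in structured
populations.

In a population where interactions are encoded by a hypergraph — vertex set
plus hyperedges of any size — each player either cooperates (contributes an
amount *b* per group) or defects. Every round, each group's pot is scaled by
a synergy factor α and split equally among its *m* members, giving a player
of strategy σ ∈ {0, 1} with *n<sub>c</sub>* cooperating co-members the
per-group payoff

    f(σ) = b [ (α/m − 1) σ + (α (m−1)/m) q ],    q = n_c / (m − 1),

summed over its incident hyperedges. Strategies are updated synchronously by
smoothed imitation: each player copies one uniformly drawn neighbor of the
2-section (graph projection) with the Fermi probability
F(Δf; β) = 1/(1 + e^(−βΔf)) of the payoff difference, with β the selection
strength. For a well-mixed population cooperation survives only above the
critical synergy α<sub>cr</sub> = Σ<sub>m</sub> m p<sub>m</sub> = ⟨m⟩; on a
structured population the survival threshold α<sub>surv</sub> can drop well
below it, and

    r(p) = α_surv(p) / α_cr(p)  <  1

quantifies this **structural reciprocity**. Hypergraphs are built by
promoting a fraction *p* of the 3-cliques of a clustered base network
(Holme–Kim, Dorogovtsev–Mendes, or Erdős–Rényi) into triangular hyperedges,
so *p* interpolates between pure pairwise (p = 0) and pure three-way (p = 1)
interactions while preserving the 2-section exactly.

The package implements, besides the simulator:

* a mean-field layer (master equation, α<sub>cr</sub> = ⟨m⟩, the finite-size
  threshold m(N−1)/(N−m) of complete m-uniform hypergraphs),
* an invasion analysis (cooperator-hub survival threshold and its uniform
  reduction r<sub>hub</sub> = 1/(1 + (s−1)(q₀<sup>hub</sup> − q̄₀<sup>(d)</sup>ξ<sub>s</sub>)),
  isolated-defector survive-and-invade probabilities, degree/clustering
  competition conditions),
* null-model randomizations (exact degree + local-clustering preserving, and
  exact 3K-distribution P(k,k′,k″) preserving) with a non-convergence census
  for characterizing **topological traps**, and
* bottleneck-trap thresholds from the linear-in-α payoff crossing of a
  cooperator/defector pair.

It is aimed at researchers in evolutionary game theory and higher-order
network science who want reproducible, seeded Monte Carlo sweeps and the
closed-form layer side by side.

## Worked example

```python
import numpy as np
from hyperpgg import (GeneratorConfig, PromotionConfig, promote_cliques,
                      generate_hk, alpha_cr_from_fractions)
from hyperpgg.dynamics import mc_experiment, estimate_alpha_surv

# A Holme-Kim scale-free, highly clustered base network (N=500, <k> ~ 6),
# with every 3-clique promoted to a triangular hyperedge (p = 1).
g = generate_hk(GeneratorConfig("hk", 500, 3, 1.0, seed=1))
H = promote_cliques(g, PromotionConfig(1.0, seed=2))
print(H.rank, H.corank, alpha_cr_from_fractions(H))
# 3 3 3.0              <- 3-uniform, well-mixed threshold alpha_cr = 3

sweep = mc_experiment(
    GeneratorConfig("hk", 500, 3, 1.0), PromotionConfig(1.0),
    b=1.0, beta=1.0, r_grid=np.arange(0.45, 1.001, 0.02),
    runs_per_point=25, n_hypergraphs=3, c0=0.5, tmax=10_000, seed=1,
    stop_when_cinf_above=1 / 1000,
)
print(sweep.table.tail(2).to_string(index=False))
#    r  alpha  mean_cinf     mean_t  nnc_per100
# 0.61   1.83    0.00000  16.773333         0.0
# 0.63   1.89    0.04728 477.986667         4.0
print(estimate_alpha_surv(sweep, n_vertices=500).r)   # 0.63
```

Reading: the mean asymptotic cooperator density stays at 0 up to r = 0.61
and first rises above half a player at r = 0.63, so cooperation on this
3-uniform hypergraph survives from 63% of the well-mixed critical synergy —
strong structural reciprocity (r < 1), and stronger than the ≈ 0.78–0.80
found for the same networks at p = 0.

The same sweeps are available from the shell:

```
hyperpgg generate --model hk --n 500 --m 3 --pt 1.0 --p 0.5 --seed 7 --out H.hyp
hyperpgg analyze --hypergraph H.hyp --report json
hyperpgg sweep --config sweep.yaml --out sweep.csv
hyperpgg rewire --mode 3k --steps 100000 --seed 3 --in g.hyp --out g_rw.hyp
hyperpgg traps --model dm --n 500 --p 1.0 --out census.csv
```

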