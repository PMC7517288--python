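# Methods

## Model

The population is a simple hypergraph H = (V, E): N vertices (players) and
hyperedges of cardinality 2 (links) or 3 (triangles) in the simulated
dynamics; the containers and generators accept any cardinality ≥ 2, but the
game engine is restricted to rank ≤ 3. Simplicity (no hyperedge contained in
another) is enforced so that a group interaction is never double-counted
through one of its sub-groups.

Each round every player plays one public goods game per incident hyperedge.
With contribution b, synergy α and n_c cooperating co-members in a group of
size m, the per-group payoff of a player with strategy σ is
b[(α/m − 1)σ + (α(m−1)/m)·n_c/(m−1)]; the round payoff is the sum over
incident hyperedges and is reset every round (no accumulation). The sum of
payoffs inside one group is b·n_c·(α − 1) — the game only redistributes and
scales contributions, which the test suite asserts exactly.

Updating is synchronous smoothed imitation on the 2-section: each player
draws one neighbor uniformly at random and adopts its strategy with the
Fermi probability F(Δf; β) = 1/(1 + e^(−βΔf)) of the payoff difference.
β → ∞ approaches best response; β ≪ 1 gives the replicator-like linear
regime F ≈ 1/2 + βΔf/4. A player whose drawn neighbor has the same strategy
cannot change; the two uniform draws per player are consumed every round
regardless, so the RNG stream advance is state-independent and runs are
reproducible and order-independent.

### Absorption

On a connected 2-section the only absorbing states are full defection
(c = 0) and full cooperation (c = 1). The runner uses the slightly more
general criterion "no hyperedge is discordant" (strategies constant on every
connected component): such a state can never change, so iterating it further
is pointless. This matters for Erdős–Rényi base networks, where G(N, M) at
⟨k⟩ = 6 carries ~N·e^(−⟨k⟩) isolated vertices whose strategy is frozen; a
run that is frozen but mixed is reported with its last density, like a
timed-out run. For the homogeneous-structure experiments the ER draw is
additionally conditioned on connectedness (rejection sampling, uniform over
connected G(N, M)), since the analysis assumes a single interacting
population; the generator's default remains the unconditioned ensemble.

## Hypergraph construction

Base networks:

* **Holme–Kim (HK)** — seed clique on m+1 vertices; each new vertex places
  one preferential-attachment (PA) link, then each of its remaining m−1
  links is, with probability Pt, a triad-formation link to a uniformly
  random not-yet-connected neighbor of the previous PA target (else a fresh
  PA link, which also re-anchors triad formation). With the clique seed and
  Pt = 1 a triad step never lacks a candidate, so every edge lies in a
  3-clique. Defaults N = 500, m = 3 (⟨k⟩ ≈ 6), Pt = 1 (maximum transitivity).
* **Dorogovtsev–Mendes (DM)** — seed triangle; each new vertex attaches to
  both endpoints of a uniformly chosen existing edge. ⟨k⟩ → 4, triangles
  percolate completely, and at full promotion k₃(i) = k₂(i) − 1 for every
  vertex (asserted in the tests). Default N = 500.
* **Erdős–Rényi (ER)** — G(N, M) with M = round(N⟨k⟩/2), pinning ⟨k⟩
  exactly; default ⟨k⟩ = 6 (a configuration choice matching the HK
  2-section, exposed in the config).

Promotion: round(p · #3-cliques) cliques (banker's rounding) are drawn
uniformly without replacement from the full clique list; each becomes a
triangular hyperedge, and every 2-edge covered by at least one selected
triangle is removed. The result is a rank-3 simple hypergraph whose
2-section equals the base graph exactly — a property-tested invariant — so p
interpolates between the 2-uniform (p = 0) and, on HK(Pt=1)/DM, the
3-uniform (p = 1) structure without touching who-interacts-with-whom.

## Monte Carlo protocol and r(p)

A sweep fixes (model, p, b, β, c0) and scans the rescaled synergy
r = α/α_cr, where α_cr = Σ_m m·p_m is computed per hypergraph replicate from
its hyperedge-cardinality fractions. Each grid point runs `runs_per_point`
trajectories from independent uniform initial conditions with exactly
round(c0·N) cooperators; densities and convergence times are averaged
within each hypergraph replicate first, then across replicates, and runs
not absorbed by tmax contribute their last density and are tallied as nNC
per 100 runs. The survival onset α_surv is the smallest grid point whose
mean asymptotic density exceeds ε = 1/(2N) (half a player; the
"grows above zero" reading made quantitative — configurable), and
r(p) = α_surv/α_cr. The onset is read from the replicate-averaged density
curve, matching how the sweep figures are drawn; per-replicate onsets can be
obtained by running single-replicate sweeps.

Reference scale is 10 hypergraph replicates × 100 runs per point with
tmax = 2×10⁴ and c0 = 0.5. The shipped tests use a reduced protocol —
N = 500, 3 replicates × 25 runs, grid step 0.02, tmax = 10⁴ — which
reproduces the reference endpoints within the ±0.05 tolerance used in the
checks while keeping each endpoint to seconds on one CPU. The onset
estimator is a first-exceedance statistic, so its seed-to-seed spread
shrinks with the number of runs per point; `scripts/acceptance.py`
therefore keeps the reference 10 × 100 replicate counts for the r(p)
endpoints (at tmax = 10⁴, which leaves the onsets unchanged) and the
reduced protocol for the convergence-time and non-convergence summaries. The grid scan may stop at the onset (`stop_when_cinf_above`); earlier
points are bit-identical to a full scan because every run's RNG stream is
derived from (master seed, replicate, grid index, run index) alone.

Seeds: one master seed spawns per-replicate generator/promotion seeds and
per-run streams via `numpy` SeedSequence; results are independent of
execution order and worker scheduling.

## Mean-field and invasion layer

* Master equation: c(t+1) = c + c(1−c)[F(Δf) − F(−Δf)] with
  Δf = b Σ_m (α/m − 1)⟨k_m⟩; fixed points at c ∈ {0, 1} and the balance
  α_cr = Σ⟨k_m⟩ / Σ⟨k_m⟩/m = Σ m p_m = ⟨m⟩ under the weighting
  p_m ∝ ⟨k_m⟩/m. The hyperedge-count and mean-degree routes agree to
  machine precision on generated hypergraphs (tested). Iteration stops at
  |Δc| < 1e−12 or 10⁶ steps.
* Finite-size correction: on the complete m-uniform simple hypergraph the
  strong-selection transition sits at α_cr^m = m(N−1)/(N−m) > m, with the
  relative shift growing in m; the simulator reproduces the N = 20, m = 3
  value ≈ 3.353 within grid resolution.
* Cooperator hubs: the survival threshold equates the t = 0 payoff of a
  cooperator hub (m-degree sequence k_m^hub, neighborhood means k̄_m) with
  its defector neighbors' average payoff, using q̄₀^(d) = c0·N/(N−1) and
  q₀^hub = q̄₀^(d) − 1/(N−1). For s-uniform structures this reduces to
  r_hub = 1/(1 + (s−1)(q₀^hub − q̄₀^(d)·ξ_s)) with ξ_s = k̄_s/k_s^hub,
  monotone decreasing in s. Hubs default to the top generalized-degree
  percentile band (97th–99th); 2-section degree is available as an option,
  since "degree" is ambiguous for hypergraphs. ξ_s uses the empirical
  neighborhood mean (per hub, then averaged) — an estimator choice; the
  s-independent treatment ξ = (ξ₂+ξ₃)/2 is available for uniform-rank
  comparisons.
* Isolated defectors: the payoff gap of a cooperator neighbor over a fully
  surrounded defector is linear in α with the shared-interaction correction
  a(j) = 1/2 (link) or κ_d/3 (κ_d shared triangles); the survive-and-invade
  probability combines defector survival with w simultaneous Fermi flips of
  its neighbors. The competition report evaluates the degree-heterogeneity
  condition under which this probability *rises* with α (the mechanism
  behind the widened transition region), its pure-link and pure-triangle
  specializations, the κ_d/κ_c > 3/4 implication between them, and the
  intermediate-degree band in which only the triangle case is competitive,
  using κ_σ = C(σ)(k₂(σ)−1) to express shared triangles through local
  clustering.

## Randomization and traps

Both null models are edge-swap Markov chains that preserve every vertex
degree by construction; `n_steps` counts accepted swaps (rejections are
retried), with a proposal cap (default 20× n_steps) so low acceptance rates
terminate.

* *Clustering-preserving*: a swap is accepted only if the local clustering
  coefficient of every affected vertex (the four endpoints and the common
  neighbors of the old and new edge pairs) is unchanged — hence the
  per-vertex clustering vector of the entire graph is exactly invariant.
  The acceptance test is deliberately stronger than checking the two
  sampled vertices alone, which would let third-party clustering drift.
* *3K-preserving*: the two sampled vertices must have equal degree and so
  must the two far endpoints; every edge and every two-path then keeps its
  degree labels, preserving P(k,k′) and P(k,k′,k″) exactly (asserted via
  histogram equality). The equal-degree test applies to the two initially
  chosen vertices, the literal reading of the procedure.

Trap characterization: a run is "trapped" when it reaches tmax unabsorbed.
The census re-promotes hypergraphs from the rewired base graph (same p,
fresh clique enumeration) and compares nNC per 100 and the corrected
convergence time t_C = runs·(t̄ − nNC·tmax/runs)/(runs − nNC) across
original, clustering-preserved and 3K-preserved structures. On DM-derived
hypergraphs the clustering-preserving null retains non-convergence in the
critical region while the 3K null removes it entirely — local clustering,
not second-order degree correlations, sustains these traps. Bottleneck
candidates are 2-section edges lying in no 3-clique (no redundant 2-path);
DM and HK(Pt=1) graphs have none, by complete triangle percolation. The
threshold of an explicit bottleneck configuration is the crossing of the
two linear-in-α payoffs of its cooperator and defector (parallel and
identical lines are flagged instead of solved).

## What the generators do and do not emulate

The synthetic base networks carry the features the analysis rests on:
power-law-like degree heterogeneity, high transitivity and triangle
percolation (HK, DM), or homogeneity with vanishing clustering (ER). They
do not emulate degree assortativity, community structure, weighted or
temporal interactions, or group sizes above 3 — so passing tests support
claims about heterogeneity and clustering effects, not about assortative or
modular real networks, for which a weaker reciprocity gain is expected.

## Numerical choices and limitations

* Payoffs are float64 sums of per-size sparse matvecs; no tolerance enters
  the dynamics itself. Fermi evaluation is overflow-safe on both tails.
* ε for the onset (1/(2N)), the mean-field stopping rule, and the
  approximate-equality tolerance in the bottleneck line solver (numpy
  `isclose`) are the only thresholds; all are configurable arguments.
* Local clustering of degree < 2 vertices is 0 by convention, keeping
  rewiring acceptance checks total.
* The dynamics module rejects rank > 3 hypergraphs; the containers,
  promotion algorithm and analytics formulas are written for general rank
  but are exercised only at rank ≤ 3.
* Reduced-scale sweeps bias the onset estimate slightly upward relative to
  the reference protocol (rarer survival events go unseen with fewer runs);
  the effect is largest under weak selection and stays within the ±0.05
  band at the shipped scale.
* The trap census is statistical (non-convergence counts), not a structural
  enumeration of trap topologies; state-recurrence detection beyond the
  tmax criterion is out of scope.
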