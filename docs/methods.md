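# Methods

## Game model

Agents occupy the nodes of an undirected, connected, simple graph and play
the weak Prisoner's Dilemma with every neighbor: payoff matrix R = 1 for
mutual cooperation, P = 0 for mutual defection, T = 1 + r for defecting
against a cooperator, S = 0 for the exploited cooperator.  The cost-to-
benefit ratio r (default 0.95) is the only free payoff parameter; the
implementation accepts any T > R ≥ P ≥ S, so the weak-dilemma boundary case
P = S is admitted deliberately.  A node's payoff `P_x` in a generation is
the sum over its neighbors of these pairwise payoffs.

Three synchronous update rules are implemented.  One generation updates all
sites simultaneously from the payoffs and strategies of the current
generation (the scheduler is applied uniformly to all three rules):

* **recolonize** (death–birth competition): neighbor y invades site x with
  probability `W_{x←y} = (P_y − P_x)/(D·d_>)` if `P_y > P_x` and 0
  otherwise, where `D = T − S` and `d_> = max(d_x, d_y)`; this bound makes
  W a genuine probability for any reachable payoff state.  The occupant
  retains the site with the product `Π_l (1 − W_{x←l})`; otherwise one
  neighbor wins with relative probability `W_{x←y}/Σ_l W_{x←l}`.  Equal
  payoffs give W = 0 (the continuous limit of the upper branch; the rule's
  two branches are defined only for strict inequality).
* **fermi**: every node acts once per generation as a learner, draws one
  neighbor uniformly as model, and imitates with probability
  `1/(1 + exp((P_learner − P_model)/k))`, noise amplitude k = 0.1 by
  default.  (An alternative reading — drawing both roles per pair — exists;
  the per-focal-learner reading was fixed because it gives every node
  exactly one revision opportunity per generation, matching the synchronous
  scheduler of the other rules.)
* **unconditional imitation**: copy the neighbor with the largest payoff
  iff it strictly exceeds one's own; ties among equally best neighbors are
  broken uniformly at random, so the rule is deterministic exactly when all
  argmaxes are unique.

Homogeneous strategy states are absorbing under all three rules; the
evaluator exploits this by filling the remaining averaging window with the
constant frequency once homogeneity is reached (provably identical output,
large speedup on structures that fixate).

## Equilibrium evaluation

A cooperation-level sample starts from a uniform random half/half strategy
assignment, discards `⌈t·N⌉` transient generations and averages the
cooperation frequency over the next `⌈a·N⌉` generations.  Mode-A uses
(t, a) = (1, 0.1), Mode-B (10, 1); both are exposed, and an absolute-count
variant (e.g. 22000 + 2000 generations) is available for long-run
protocols.  Windows are disjoint and consecutive; the recorded frequency is
the one after each averaging-window update.  Because samples fluctuate
(more strongly on smaller graphs), `multi_sample_evaluate` aggregates
independent samples into a running (sum, num, avg) record — the object the
optimizer's bookkeeping is built on.

The game loop is JIT-compiled (numba) over a CSR adjacency; one Mode-A
sample on a 200-node BA network costs ~2 ms, which sets the scale for
everything below.

## Network generators

`generate_ba(n, m_attach)` grows a Barabási–Albert network from an
`m_attach`-clique seed, each newcomer attaching `m_attach` preferential
edges (repeated-endpoints method).  The clique seed makes the saturated
case n = m_attach + 1 the complete graph.  `generate_hk` shares the same
growth routine and adds the Holme–Kim triad step: after each preferential
edge, with probability `p_triad` the next edge closes a triangle through a
neighbor of the previous target (falling back to preferential attachment
when impossible), so `p_triad = 0` reduces exactly to the BA generator and
larger `p_triad` yields higher clustering at the same degree distribution.
The mean attachment count is not dictated by the optimization problem;
the default used throughout the harness is `m_attach = 2` (mean degree ≈ 4),
configurable.

## Degree-preserving rewiring

Two move types conserve the degree sequence exactly:

* **simple edge swapping** (initialization and mutation): two edges (a,b),
  (c,d) with four distinct endpoints are replaced by (a,c), (b,d) when
  neither new edge exists; 100 draw attempts bound the search so
  swap-saturated graphs (e.g. complete graphs) terminate with a no-op flag.
* **edge switching** (local search): around a hub u with neighbors i, j
  (all of degree ≥ 2, i and j non-adjacent), edges (j,k) and (i,m) are
  replaced by (j,i) and (k,m), all five nodes distinct and both new edges
  absent.  Sampling order: hub fixed by the operator's node pass (uniform
  for the free-standing function), (i, j) uniform over qualifying neighbor
  pairs, k and m uniform over qualifying incident edges, 1000 attempts
  before reporting failure — failure is a normal outcome (e.g. stars admit
  no valid tuple).

All rewiring operators return new graphs, so a rejected proposal needs no
rollback.  Moves that would disconnect the graph are rejected wherever the
population invariant requires connectivity.

## The restoration list

Each of the 2·GS working slots (GS parents, GS offspring) owns a pyramid of
at most `max_levels` records, sorted by avg descending (stable on ties, for
determinism under fixed seeds).  The pyramid geometry is one record per
level — the simplest shape in which upper records outrank lower ones.

* **insertion**: append when vacant; otherwise evict the worst-avg record
  whose avg is smaller and num not larger than the incomer's (exactly one
  eviction); if none qualifies the backup is refused.  The `≤` on num is
  the chosen reading of "smaller avg and num": strict on avg, non-strict on
  num, so a better-estimated equal-effort solution can displace a worse one.
* **mutation**: a refused better-avg solution may still replace the level-m
  record with probability `alpha^(max_levels − m)` (m counted from the
  top), making upper records exponentially harder to displace; alpha = 0
  protects every record.  Candidate levels are tried bottom-up and at most
  one replacement fires.
* **information update**: when the working solution that a record backs up
  is re-sampled, the record's (sum, num) are overwritten in place and the
  pyramid re-sorted; the stored graph is never touched.

Two comparison strategies handle unequal sampling counts: inside the
population, only avg matters; against a record, a three-way verdict
(record-wins / current-wins / neither) drives the operator's branches
below.

## The multilevel evolutionary operator

Given a working solution with avg `a`, the operator resets its aggregate to
one sample (sum = a, num = 1, no backup linked) and makes one pass over
nodes in identifier order and each node's incident edges in neighbor order
(a deterministic iteration under a fixed seed).  Each visit attempts an
edge switch with probability `min(1, β·d_i/Σd)` (β = 20), so hubs — whose
wiring matters most — are adjusted more often; the clamp guards small test
graphs where `β·d_i` exceeds Σd.  An attempted switch yields G′, evaluated
with the variant's first-evaluation sampling count, and:

* **rejected** (G′ disconnected, or avg_G′ ≤ avg_G): the working solution
  is re-evaluated once more, its aggregate updated, and its backup — if it
  is itself a restored record — synchronized.  This is the mechanism that
  concentrates sampling effort on retained structures.  Exact ties are
  routed here deliberately: a no-information proposal should not reset the
  aggregate.  Disconnected proposals skip the evaluation of G′ (the
  cooperation level of a disconnected graph is not defined here) but still
  trigger the re-sample of G.
* **accepted, avg_G above the pyramid top** (or pyramid empty): G is backed
  up (insertion, then mutation rule), and G′ adopted with a fresh
  one-sample aggregate.
* **accepted, but pyramid top above avg_G′**: the working solution is
  replaced by a copy of the top record, which stays linked as its own
  backup — the restoration that undoes an earlier wrong filtering.
  Restoration does not clear the pyramid and the record keeps its (sum,
  num).
* **accepted otherwise**: G′ adopted with a fresh aggregate.

## The EA loop and variants

The outer loop is a (μ + λ) memetic EA: GS = 6 solutions are derived from
the input structure by `2N` connectivity-checked swap attempts and
evaluated; each generation draws GS parent pairs by roulette (probability
`avg_i/Σ avg_j`, uniform when all avg are 0), recombines, mutates each
child by one accepted swap, evaluates it, applies the multilevel operator
to all 2·GS solutions (each against its own pyramid), and keeps the best GS
by avg (stable ranking).  gen_max = 30 by default.

Crossover is a degree-preserving intersection-plus-repair recombination
designed for this package: with probability Pc = 0.8 the child keeps the
parents' common edges, fills degree deficits preferentially from the
symmetric difference, pairs residual stubs randomly, and retries up to 20
times for connectivity before falling back to a copy of the fitter parent.
Identical parents reproduce exactly.

Variants: `lv1` (max_levels = 1, alpha = 0), `lv5` (5, 0.5), `lv10`
(10, 0.5), `lv1-M` (as lv1 but every newly created structure's *first*
evaluation averages s = 5 independent samples).  The sampling count s
applies to initial structures, offspring, and each G′ inside the operator,
while rejection re-samples stay single; a rejected attempt therefore costs
s + 1 simulator calls instead of 2, which is what makes the multi-sampling
variant roughly three times as expensive as lv1 at matched configurations —
the package's audited evaluation counters reproduce that ratio.

`run_ea_cluster` swaps the fitness for the clustering coefficient
(deterministic, single evaluation), drops the restoration list, and uses a
canonical accept-if-better local search over the same proposals;
gen_max = 120 by default, where its trajectory has essentially converged.

One master seed drives everything through spawned numpy generators and
derived kernel seeds (all < 2^31), so any run is bit-reproducible.

## Synthetic data and what the tests show

All inputs are generated: BA/HK networks from the generators above and
hand-built gadgets (triangle, K4 minus an edge, cycles, the edge-switching
figure gadget, two joined squares).  The generators emulate the degree
heterogeneity and (for HK) tunable clustering of scale-free populations;
they do not emulate degree correlations, community structure, or any
empirical contact network, so passing tests demonstrate the optimizer's
behavior on idealized scale-free structures, not on real-world topologies.

The noise-robustness of the memory is tested on a surrogate objective —
true score = clustering coefficient, observed with Gaussian noise
(σ = 0.05) — because there the *true* quality of the output is computable
exactly; lv5 matching or beating lv1 on the true score in a majority of
paired runs is the desk-scale analogue of the restoration list resisting
noise-induced selection errors.

## Study sizes

The package's studies run at reduced scale, chosen so the full suite and
the acceptance script complete comfortably on a single CPU: structures of
200–800 nodes (vs 500–1000), 10 EA generations (vs 30), post-hoc scoring
with 200 independent evaluations (vs 5000), distribution studies with 200
evaluations per condition.  Full-scale settings remain available through
configuration (`gen_max`, `posthoc_samples`, sizes).  Scaled in this way,
the qualitative contrasts are all reproduced: smaller populations fluctuate
more, Mode-A and Mode-B agree in the mean, multi-sampling shrinks spread,
lv5 improves structures, and lv1-M costs ≈ 3× lv1.

## Numerical choices and limitations

* Ties: exact-tie proposals re-sample rather than reset (above); equal-avg
  records keep insertion order; equal-payoff neighbors are never imitated
  under strict-inequality rules.
* Degree-1 nodes have clustering 0 (the formula's d(d−1)/2 denominator
  vanishes; the standard convention keeps the mean defined).
* The recolonize takeover weight can reach exactly 1 (e.g. a zero-payoff
  cooperator beside a saturated defector); the retention product then
  vanishes and takeover is certain — handled without special-casing.
* Selection intensity of roulette selection degenerates when all avg are
  equal or zero; the uniform fallback keeps the loop well defined on
  all-defect populations.
* The evaluation-count accounting audits simulator invocations only;
  clustering-coefficient calls in the baseline are counted by the same
  counter but are orders of magnitude cheaper, so counts are comparable
  only within an objective.
* Known limitations: no asynchronous schedules, no directed/weighted/
  multilayer graphs, no coevolutionary link adaptation; the crossover is a
  documented stand-in rather than a published recombination operator.
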