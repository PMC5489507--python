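"""Multilevel evolutionary optimization of network structure.

``run_mlea`` optimizes the equilibrium cooperation level of a Prisoner's
Dilemma population structure by degree-preserving rewiring.  The loop is a
memetic EA: roulette parent selection, degree-preserving crossover,
double-edge-swap mutation, then a *multilevel evolutionary operator* — a
hill-climbing local search over edge switches whose working solution is
re-sampled on every rejected move (so retained structures accumulate
evaluations and their noisy fitness sharpens, while abandoned ones are
sampled no further) and which backs solutions up into, or restores them
from, a per-slot restoration-list pyramid.  ``run_ea_cluster`` is the
comparison baseline: the same EA skeleton with a deterministic objective
(the clustering coefficient) and a canonical accept-if-better local search.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from . import netstruct
from .memory import RestorationList, Solution
from .pdgame import (EvaluationMode, MODE_A, PayoffParams, UpdateRule,
                     multi_sample_evaluate)

__all__ = [
    "MlEAConfig",
    "OptimizationResult",
    "CooperationEvaluator",
    "ClusteringEvaluator",
    "variant_config",
    "initialize_population",
    "roulette_select",
    "crossover",
    "multilevel_operator",
    "run_mlea",
    "run_ea_cluster",
    "VARIANTS",
]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class MlEAConfig:
    """Tunables of the optimizer.

    GS
        population size (= Omega; one restoration-list pyramid per parent
        slot and per offspring slot, 2*GS in total).
    gen_max
        EA generations.
    Pc
        crossover rate; with probability 1-Pc a child is a parent copy.
    alpha
        mutation-rule base of the restoration list: a level-m record is
        displaced by a better failed-insertion solution with probability
        alpha**(max_levels - m).  alpha = 0 protects every record.
    beta
        probability scale of the local search: an edge of node i is
        adjusted with probability min(1, beta * d_i / sum_j d_j).
    max_levels
        pyramid capacity (the "lv" in variant names).
    init_samples
        evaluation samplings for every newly created structure's first
        evaluation (1 for lv variants, 5 for the multi-sampling lv1-M).
    init_swap_attempts / mutation_swap_attempts
        double-edge-swap attempts used to derive the initial population
        from the input structure and to mutate offspring (None = 2N).
    """

    GS: int = 6
    gen_max: int = 30
    Pc: float = 0.8
    alpha: float = 0.5
    beta: float = 20.0
    max_levels: int = 5
    init_samples: int = 1
    rule: UpdateRule = field(default_factory=UpdateRule.recolonize)
    mode: EvaluationMode = MODE_A
    r: float = 0.95
    seed: int = 0
    init_swap_attempts: int | None = None
    mutation_swap_attempts: int = 1

    def __post_init__(self):
        if self.GS < 2:
            raise ValueError("GS must be >= 2")
        if self.gen_max < 1:
            raise ValueError("gen_max must be >= 1")
        if not 0.0 <= self.Pc <= 1.0:
            raise ValueError("Pc must be in [0, 1]")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.max_levels < 1:
            raise ValueError("max_levels must be >= 1")
        if self.init_samples < 1:
            raise ValueError("init_samples must be >= 1")

    @property
    def payoffs(self) -> PayoffParams:
        return PayoffParams.from_ratio(self.r)


VARIANTS = {
    "lv1": dict(max_levels=1, alpha=0.0, init_samples=1),
    "lv1-M": dict(max_levels=1, alpha=0.0, init_samples=5),
    "lv5": dict(max_levels=5, alpha=0.5, init_samples=1),
    "lv10": dict(max_levels=10, alpha=0.5, init_samples=1),
}


def variant_config(name: str, **overrides) -> MlEAConfig:
    """Named optimizer variants: lv1 / lv1-M / lv5 / lv10."""
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; choose from "
                         f"{sorted(VARIANTS)}")
    params = dict(VARIANTS[name])
    params.update(overrides)
    return MlEAConfig(**params)


@dataclass
class OptimizationResult:
    """Outcome of one optimization run."""

    best: Solution
    trajectory: list[float]
    n_evaluations: int
    seed: int
    variant: str = ""

    def to_dict(self) -> dict:
        return {
            "best_avg": self.best.avg,
            "best_num": self.best.num,
            "trajectory": list(self.trajectory),
            "n_evaluations": self.n_evaluations,
            "seed": self.seed,
            "variant": self.variant,
        }


# ---------------------------------------------------------------------------
# evaluators (fitness with an audited call counter)

class CooperationEvaluator:
    """Noisy fitness: equilibrium cooperation level of a structure.

    ``count`` audits the exact number of single simulator invocations
    (multi-sample calls count once per sample).
    """

    deterministic = False

    def __init__(self, rule: UpdateRule, pp: PayoffParams,
                 mode: EvaluationMode):
        self.rule = rule
        self.pp = pp
        self.mode = mode
        self.count = 0

    def evaluate(self, graph: nx.Graph, rng: np.random.Generator,
                 n_samples: int = 1) -> tuple[float, int]:
        est = multi_sample_evaluate(graph, n_samples, self.rule, self.pp,
                                    self.mode, rng)
        self.count += est.num
        return est.sum, est.num


class ClusteringEvaluator:
    """Deterministic fitness: the clustering coefficient (baseline
    objective).  n_samples is irrelevant; every call is a single count."""

    deterministic = True

    def __init__(self):
        self.count = 0

    def evaluate(self, graph: nx.Graph, rng: np.random.Generator,
                 n_samples: int = 1) -> tuple[float, int]:
        self.count += 1
        return netstruct.clustering_coefficient(graph), 1


# ---------------------------------------------------------------------------
# EA building blocks

def initialize_population(g0: nx.Graph, config: MlEAConfig,
                          rng: np.random.Generator,
                          evaluator=None) -> list[Solution]:
    """GS degree-preserving variants of g0 (connectivity-checked double-edge
    swaps), each evaluated with ``init_samples`` samplings."""
    netstruct.validate_graph(g0, require_connected=True)
    if evaluator is None:
        evaluator = CooperationEvaluator(config.rule, config.payoffs,
                                         config.mode)
    attempts = (config.init_swap_attempts
                if config.init_swap_attempts is not None
                else 2 * g0.number_of_nodes())
    n_samples = 1 if evaluator.deterministic else config.init_samples
    population = []
    for _ in range(config.GS):
        g = netstruct.simple_edge_swapping(g0, rng, attempts,
                                           require_connected=True)
        total, num = evaluator.evaluate(g, rng, n_samples)
        population.append(Solution(graph=g, sum=total, num=num))
    return population


def roulette_select(population: list[Solution],
                    rng: np.random.Generator) -> tuple[Solution, Solution]:
    """Fitness-proportionate parent pair: each parent drawn with probability
    avg_i / sum_j avg_j (uniform fallback when every avg is 0)."""
    if not population:
        raise ValueError("population is empty")
    avgs = np.array([sol.avg for sol in population])
    total = avgs.sum()
    probs = avgs / total if total > 0 else None
    ia, ib = rng.choice(len(population), size=2, p=probs)
    return population[int(ia)], population[int(ib)]


def _repair_child(common: set, sym_diff: list, target_deg: np.ndarray,
                  n: int, rng: np.random.Generator) -> nx.Graph | None:
    child = nx.Graph()
    child.add_nodes_from(range(n))
    child.add_edges_from(common)
    deficit = target_deg - np.array([child.degree(v) for v in range(n)])
    order = rng.permutation(len(sym_diff))
    for idx in order:
        u, v = sym_diff[idx]
        if deficit[u] > 0 and deficit[v] > 0 and not child.has_edge(u, v):
            child.add_edge(u, v)
            deficit[u] -= 1
            deficit[v] -= 1
    stubs = [v for v in range(n) for _ in range(deficit[v])]
    for _ in range(20):  # random stub pairing, avoiding loops/duplicates
        if not stubs:
            break
        perm = rng.permutation(len(stubs))
        shuffled = [stubs[i] for i in perm]
        leftover = []
        for a, b in zip(shuffled[::2], shuffled[1::2]):
            if a != b and not child.has_edge(a, b):
                child.add_edge(a, b)
            else:
                leftover.extend((a, b))
        if len(shuffled) % 2:
            leftover.append(shuffled[-1])
        if len(leftover) == len(stubs):
            return None  # stuck
        stubs = leftover
    if stubs:
        return None
    return child


def crossover(pa: Solution, pb: Solution, config: MlEAConfig,
              rng: np.random.Generator) -> nx.Graph:
    """Degree-preserving recombination: with probability Pc, keep the
    intersection of the parent edge sets, fill degree deficits preferentially
    from the symmetric difference, pair residual stubs randomly, and retry
    up to 20 times until the child is connected — falling back to a copy of
    the fitter parent.  With probability 1 - Pc, return a parent copy."""
    deg_a = netstruct.degree_sequence(pa.graph)
    if deg_a != netstruct.degree_sequence(pb.graph):
        raise ValueError("parents must share one degree sequence")
    fitter = pa if pa.avg >= pb.avg else pb
    if rng.random() >= config.Pc:
        parent = pa if rng.random() < 0.5 else pb
        return parent.graph.copy()
    edges_a = {tuple(sorted(e)) for e in pa.graph.edges()}
    edges_b = {tuple(sorted(e)) for e in pb.graph.edges()}
    common = edges_a & edges_b
    sym_diff = sorted(edges_a ^ edges_b)
    n = pa.graph.number_of_nodes()
    target_deg = np.array([pa.graph.degree(v) for v in range(n)])
    for _ in range(20):
        child = _repair_child(common, sym_diff, target_deg, n, rng)
        if child is not None and nx.is_connected(child):
            return child
    return fitter.graph.copy()


# ---------------------------------------------------------------------------
# local search operators

def _attempt_probability(beta: float, degree: int, degree_total: int) -> float:
    return min(1.0, beta * degree / degree_total)


def multilevel_operator(sol: Solution, pyramid_index: int,
                        rlist: RestorationList, config: MlEAConfig,
                        evaluator, rng: np.random.Generator) -> Solution:
    """The multilevel evolutionary operator (hill climbing with restoration).

    The working solution starts from ``sol``'s graph with its aggregate reset
    to one sample (sum = avg, num = 1) and no backup linked.  One pass visits
    every node in identifier order and each of its incident edges in neighbor
    order; each visit attempts an edge switch with probability
    min(1, beta*d_i/sum_d).  A switch producing G':

    * **rejected** (G' disconnected, or avg_G' <= avg_G): the working
      solution is re-evaluated once and its aggregate updated — retained
      structures are thereby sampled ever more — and its backup, if linked,
      is synchronized;
    * **accepted** with avg_G > top-of-pyramid: the working solution is
      backed up (insertion rule, then mutation rule), and G' adopted with a
      fresh aggregate;
    * **accepted** but top-of-pyramid > avg_G' > avg_G: the working solution
      is replaced by a copy of the pyramid's top record, which stays linked
      as its own backup;
    * **accepted** otherwise: G' adopted with a fresh aggregate.

    Returns the final working solution; ``sol`` itself is not mutated.
    """
    pyramid = rlist[pyramid_index]
    pyramid.linked = None
    current = Solution(graph=sol.graph.copy(), sum=sol.avg, num=1)
    degree_total = 2 * current.graph.number_of_edges()
    n_samples = 1 if evaluator.deterministic else config.init_samples

    for node in sorted(current.graph.nodes()):
        d_i = current.graph.degree(node)
        p_attempt = _attempt_probability(config.beta, d_i, degree_total)
        neighbors = sorted(current.graph.neighbors(node))
        for _ in neighbors:
            if rng.random() >= p_attempt:
                continue
            proposal = netstruct.node_select(current.graph, rng, hub=node)
            if proposal is None:
                continue
            adjusted = netstruct.edge_switch(current.graph, proposal)
            if not nx.is_connected(adjusted):
                rejected, adj_sol = True, None
            else:
                total, num = evaluator.evaluate(adjusted, rng, n_samples)
                adj_sol = Solution(graph=adjusted, sum=total, num=num)
                rejected = adj_sol.avg <= current.avg
            if rejected:
                extra, _ = evaluator.evaluate(current.graph, rng, 1)
                current.add_sample(extra)
                if pyramid.linked is not None:
                    pyramid.synchronize(current.sum, current.num)
                continue
            top = pyramid.top()
            if top is None or current.avg > top.avg:
                pyramid.backup(current.copy(), config.alpha, rng)
                pyramid.sort()
                current = adj_sol
                pyramid.linked = None
            elif top.avg > adj_sol.avg:
                restored = rlist.restore_top(pyramid_index)
                pyramid.linked = pyramid.top()
                current = restored
            else:
                current = adj_sol
                pyramid.linked = None
    return current


def canonical_local_search(sol: Solution, config: MlEAConfig, evaluator,
                           rng: np.random.Generator) -> Solution:
    """Accept-if-better hill climbing over the same edge-switch proposals,
    with no memory and no re-sampling (the EA_cluster baseline operator)."""
    current = sol.copy()
    degree_total = 2 * current.graph.number_of_edges()
    for node in sorted(current.graph.nodes()):
        d_i = current.graph.degree(node)
        p_attempt = _attempt_probability(config.beta, d_i, degree_total)
        neighbors = sorted(current.graph.neighbors(node))
        for _ in neighbors:
            if rng.random() >= p_attempt:
                continue
            proposal = netstruct.node_select(current.graph, rng, hub=node)
            if proposal is None:
                continue
            adjusted = netstruct.edge_switch(current.graph, proposal)
            if not nx.is_connected(adjusted):
                continue
            total, num = evaluator.evaluate(adjusted, rng, 1)
            if total / num > current.avg:
                current = Solution(graph=adjusted, sum=total, num=num)
    return current


# ---------------------------------------------------------------------------
# full runs

def _mutate_offspring(g: nx.Graph, config: MlEAConfig,
                      rng: np.random.Generator) -> nx.Graph:
    return netstruct.simple_edge_swapping(
        g, rng, config.mutation_swap_attempts, require_connected=True)


def _run_ea(g0: nx.Graph, config: MlEAConfig, evaluator, use_memory: bool,
            variant: str) -> OptimizationResult:
    rng = np.random.default_rng(config.seed)
    n_samples = 1 if evaluator.deterministic else config.init_samples
    population = initialize_population(g0, config, rng, evaluator)
    rlist = RestorationList(2 * config.GS, config.max_levels)
    trajectory = [max(sol.avg for sol in population)]
    for _ in range(config.gen_max):
        offspring = []
        for _ in range(config.GS):
            pa, pb = roulette_select(population, rng)
            child = crossover(pa, pb, config, rng)
            child = _mutate_offspring(child, config, rng)
            total, num = evaluator.evaluate(child, rng, n_samples)
            offspring.append(Solution(graph=child, sum=total, num=num))
        pool = population + offspring
        if use_memory:
            refined = [multilevel_operator(sol, slot, rlist, config,
                                           evaluator, rng)
                       for slot, sol in enumerate(pool)]
        else:
            refined = [canonical_local_search(sol, config, evaluator, rng)
                       for sol in pool]
        refined.sort(key=lambda sol: -sol.avg)  # stable: Strategy 1 ranking
        population = refined[:config.GS]
        trajectory.append(population[0].avg)
    best = population[0]
    return OptimizationResult(best=best, trajectory=trajectory,
                              n_evaluations=evaluator.count,
                              seed=config.seed, variant=variant)


def run_mlea(g0: nx.Graph, config: MlEAConfig, evaluator=None,
             variant: str = "") -> OptimizationResult:
    """Optimize g0's equilibrium cooperation level (or any injected fitness)
    with the multilevel EA.  Degree sequence and connectivity of every
    candidate match g0's throughout."""
    if evaluator is None:
        evaluator = CooperationEvaluator(config.rule, config.payoffs,
                                         config.mode)
    return _run_ea(g0, config, evaluator, use_memory=True, variant=variant)


def run_ea_cluster(g0: nx.Graph, config: MlEAConfig | None = None,
                   **overrides) -> OptimizationResult:
    """Baseline: optimize the clustering coefficient with the canonical EA
    (deterministic fitness, single evaluations, accept-if-better local
    search); 120 generations by default."""
    if config is None:
        overrides.setdefault("gen_max", 120)
        overrides.setdefault("init_samples", 1)
        config = MlEAConfig(**overrides)
    else:
        config = replace(config, init_samples=1)
    return _run_ea(g0, config, ClusteringEvaluator(), use_memory=False,
                   variant="ea-cluster")
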