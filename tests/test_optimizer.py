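"""The multilevel EA: building blocks, operator branch behavior, full runs,
and the clustering baseline."""

import math

import networkx as nx
import numpy as np
import pytest

from coopnet import netstruct
from coopnet.memory import RestorationList, Solution
from coopnet.netstruct import clustering_coefficient, degree_sequence
from coopnet.optimizer import (ClusteringEvaluator, MlEAConfig, crossover,
                               initialize_population, multilevel_operator,
                               roulette_select, run_ea_cluster, run_mlea,
                               variant_config)


class ConstantEvaluator:
    """Every structure scores the same — the local search has no signal."""

    deterministic = False

    def __init__(self, value=0.5):
        self.value = value
        self.count = 0

    def evaluate(self, graph, rng, n_samples=1):
        self.count += n_samples
        return self.value * n_samples, n_samples


class NoisyClusteringEvaluator:
    """True score = clustering coefficient, observed with Gaussian noise —
    a deterministic-truth surrogate for the noisy cooperation fitness."""

    deterministic = False

    def __init__(self, sigma, seed):
        self.sigma = sigma
        self.rng = np.random.default_rng(seed)
        self.count = 0

    def evaluate(self, graph, rng, n_samples=1):
        self.count += n_samples
        true = clustering_coefficient(graph)
        total = sum(true + self.rng.normal(0.0, self.sigma)
                    for _ in range(n_samples))
        return total, n_samples


@pytest.fixture(scope="module")
def g60():
    return netstruct.generate_ba(60, 2, np.random.default_rng(17))


class TestConfig:
    def test_paper_defaults(self):
        cfg = MlEAConfig()
        assert (cfg.GS, cfg.gen_max, cfg.beta, cfg.r) == (6, 30, 20.0, 0.95)

    def test_variants(self):
        assert variant_config("lv1").max_levels == 1
        assert variant_config("lv1").alpha == 0.0
        assert variant_config("lv1-M").init_samples == 5
        assert variant_config("lv5").max_levels == 5
        assert variant_config("lv10").max_levels == 10
        with pytest.raises(ValueError):
            variant_config("lv2")

    @pytest.mark.parametrize("kwargs", [
        dict(GS=1), dict(Pc=1.5), dict(alpha=-0.1), dict(beta=0),
        dict(max_levels=0), dict(init_samples=0)])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            MlEAConfig(**kwargs)


class TestInitializePopulation:
    def test_members_are_valid_variants(self, g60, rng):
        cfg = MlEAConfig(GS=4, init_samples=5, seed=0)
        pop = initialize_population(g60, cfg, rng, ConstantEvaluator())
        assert len(pop) == 4
        for sol in pop:
            assert degree_sequence(sol.graph) == degree_sequence(g60)
            assert nx.is_connected(sol.graph)
            assert sol.num == 5

    def test_disconnected_input_rejected(self, rng):
        g = nx.Graph([(0, 1), (2, 3)])
        with pytest.raises(ValueError):
            initialize_population(g, MlEAConfig(), rng, ConstantEvaluator())


class TestRouletteSelect:
    def test_fitness_proportionate(self, rng):
        pop = [Solution(nx.path_graph(3), sum=1.0, num=1),
               Solution(nx.path_graph(3), sum=3.0, num=1)]
        picks = sum(roulette_select(pop, rng)[0] is pop[1]
                    for _ in range(20000))
        se = math.sqrt(0.75 * 0.25 / 20000)
        assert abs(picks / 20000 - 0.75) < 3 * se

    def test_all_zero_fitness_uniform_fallback(self, rng):
        pop = [Solution(nx.path_graph(3), sum=0.0, num=1) for _ in range(4)]
        counts = np.zeros(4)
        for _ in range(4000):
            pa, _ = roulette_select(pop, rng)
            counts[pop.index(pa)] += 1
        assert (counts > 700).all()


class TestCrossover:
    def test_identical_parents_reproduce_exactly(self, g60, rng):
        pa = Solution(g60.copy(), sum=0.5, num=1)
        pb = Solution(g60.copy(), sum=0.4, num=1)
        child = crossover(pa, pb, MlEAConfig(Pc=1.0), rng)
        assert set(map(frozenset, child.edges())) == \
            set(map(frozenset, g60.edges()))

    def test_common_edges_kept_degrees_conserved(self, rng):
        g = netstruct.generate_ba(20, 2, rng)
        # second parent differs by a few swaps
        other = netstruct.simple_edge_swapping(g, rng, 4)
        pa = Solution(g, sum=0.5, num=1)
        pb = Solution(other, sum=0.4, num=1)
        common = set(map(frozenset, g.edges())) & \
            set(map(frozenset, other.edges()))
        for seed in range(100):
            child = crossover(pa, pb, MlEAConfig(Pc=1.0),
                              np.random.default_rng(seed))
            assert degree_sequence(child) == degree_sequence(g)
            assert common <= set(map(frozenset, child.edges()))

    def test_mismatched_degree_sequences_rejected(self, rng):
        pa = Solution(nx.cycle_graph(6), sum=0.5, num=1)
        pb = Solution(nx.star_graph(5), sum=0.5, num=1)
        with pytest.raises(ValueError):
            crossover(pa, pb, MlEAConfig(), rng)

    def test_pc_zero_returns_parent_copy(self, g60, rng):
        pa = Solution(g60.copy(), sum=0.5, num=1)
        pb = Solution(netstruct.simple_edge_swapping(g60, rng, 10),
                      sum=0.4, num=1)
        child = crossover(pa, pb, MlEAConfig(Pc=0.0), rng)
        assert set(map(frozenset, child.edges())) in (
            set(map(frozenset, pa.graph.edges())),
            set(map(frozenset, pb.graph.edges())))


class TestMultilevelOperator:
    def test_constant_fitness_is_a_fixed_point(self, g60, rng):
        """With no fitness signal every proposal ties and is re-sampled:
        the graph never changes and the sampling count strictly grows."""
        evaluator = ConstantEvaluator()
        cfg = MlEAConfig(seed=0)
        rlist = RestorationList(2, cfg.max_levels)
        sol = Solution(g60.copy(), sum=0.5, num=1)
        out = multilevel_operator(sol, 0, rlist, cfg, evaluator, rng)
        assert set(map(frozenset, out.graph.edges())) == \
            set(map(frozenset, g60.edges()))
        assert out.num > 1
        assert out.avg == pytest.approx(0.5)

    def test_hill_climbs_on_noise_free_objective(self, rng):
        g = netstruct.generate_hk(80, 2, 0.5, np.random.default_rng(5))
        evaluator = ClusteringEvaluator()
        cfg = MlEAConfig(seed=0)
        rlist = RestorationList(2, cfg.max_levels)
        start = clustering_coefficient(g)
        sol = Solution(g, sum=start, num=1)
        out = multilevel_operator(sol, 0, rlist, cfg, evaluator, rng)
        assert out.avg >= start
        assert degree_sequence(out.graph) == degree_sequence(g)
        assert nx.is_connected(out.graph)

    def test_restoration_returns_pyramid_top(self, g60, rng):
        """When the pyramid's top outruns both the working solution and its
        adjusted variant, the operator falls back to the stored record."""
        cfg = MlEAConfig(seed=0, beta=1000.0)  # attempt every edge
        rlist = RestorationList(1, cfg.max_levels)
        elite = Solution(g60.copy(), sum=3 * 0.99, num=3)
        rlist.insert_record(0, elite)
        elite_edges = set(map(frozenset, elite.graph.edges()))

        class KeyedEvaluator:
            """Scores the elite structure 0.99 and everything else 0.2."""
            deterministic = False
            count = 0

            def evaluate(self, graph, rng_, n_samples=1):
                self.count += n_samples
                edges = set(map(frozenset, graph.edges()))
                value = 0.99 if edges == elite_edges else 0.2
                return value * n_samples, n_samples

        sol = Solution(netstruct.simple_edge_swapping(
            g60, rng, 10), sum=0.1, num=1)
        out = multilevel_operator(sol, 0, rlist, cfg, KeyedEvaluator(), rng)
        # 0.1 < 0.2 < 0.99: restoration fires on the first accepted switch
        # and the restored elite survives every later rejected proposal
        assert out.avg == pytest.approx(0.99)
        assert set(map(frozenset, out.graph.edges())) == elite_edges


class TestNoiseRobustness:
    def test_memory_depth_beats_single_level_under_noise(self):
        """With noisy observations of a deterministic truth, the deeper
        restoration list (lv5) recovers a final true score at least as good
        as lv1's in a majority of paired runs — the defense against
        selection errors caused by evaluation noise."""
        g0 = netstruct.generate_hk(50, 2, 0.5, np.random.default_rng(2))
        wins = 0
        n_pairs = 10
        for seed in range(n_pairs):
            finals = {}
            for name in ("lv1", "lv5"):
                cfg = variant_config(name, GS=3, gen_max=2, seed=seed)
                res = run_mlea(g0, cfg,
                               evaluator=NoisyClusteringEvaluator(
                                   0.05, seed=1000 + seed))
                finals[name] = clustering_coefficient(res.best.graph)
            wins += finals["lv5"] >= finals["lv1"]
        assert wins > n_pairs / 2


class TestRunMlea:
    def test_structure_invariants_and_audited_counter(self, g60):
        evaluator = ConstantEvaluator()
        cfg = MlEAConfig(GS=3, gen_max=2, seed=11)
        res = run_mlea(g60, cfg, evaluator=evaluator)
        assert degree_sequence(res.best.graph) == degree_sequence(g60)
        assert nx.is_connected(res.best.graph)
        assert res.n_evaluations == evaluator.count
        assert len(res.trajectory) == cfg.gen_max + 1

    def test_multisampling_costs_more_evaluations(self, g60):
        counts = {}
        for name in ("lv1", "lv1-M"):
            res = run_mlea(g60, variant_config(name, gen_max=2, seed=4),
                           variant=name)
            counts[name] = res.n_evaluations
        assert counts["lv1-M"] > counts["lv1"]

    def test_deterministic_under_master_seed(self, g60):
        runs = [run_mlea(g60, variant_config("lv5", gen_max=1, seed=21))
                for _ in range(2)]
        assert runs[0].trajectory == runs[1].trajectory
        assert runs[0].n_evaluations == runs[1].n_evaluations
        assert set(map(frozenset, runs[0].best.graph.edges())) == \
            set(map(frozenset, runs[1].best.graph.edges()))


class TestRunEaCluster:
    def test_improves_clustering_monotonically(self):
        g0 = netstruct.generate_hk(100, 2, 0.5, np.random.default_rng(9))
        res = run_ea_cluster(g0, gen_max=3, seed=1)
        traj = res.trajectory
        assert all(b >= a - 1e-12 for a, b in zip(traj, traj[1:]))
        assert res.best.avg > clustering_coefficient(g0)
        assert degree_sequence(res.best.graph) == degree_sequence(g0)
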