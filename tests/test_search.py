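"""Evolutionary-engine tests: NSGA-II primitives against an exhaustive
dominance oracle, variation operators with scripted and seeded RNGs, and the
search-level contracts (determinism, budget, caching, elitism)."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from crushmdr.entropy import ExpertKnowledgeTable, build_expert_knowledge
from crushmdr.qmdr import ModelScore
from crushmdr.search import (
    BudgetExhausted,
    CandidateModel,
    Evaluator,
    SearchConfig,
    any_point_crossover,
    crowding_distance,
    mutate,
    nondominated_sort,
    run_crush,
    run_evolutionary_task,
    run_random_search,
    sample_initial_model,
    tournament_parsimony,
    tournament_rank_crowding,
)
from crushmdr.simulate import SimulationSpec, simulate_dataset

from conftest import make_dataset


def model(t, ig, size, snps=None):
    snps = snps if snps is not None else tuple(range(size))
    return CandidateModel(snps=snps, score=ModelScore(t, ig, size, True))


def oracle_fronts(objs):
    """Exhaustive dominance peeling: O(n^2 * fronts) reference ranks."""

    def dominates(a, b):
        ge = a[0] >= b[0] and a[1] >= b[1] and a[2] <= b[2]
        gt = a[0] > b[0] or a[1] > b[1] or a[2] < b[2]
        return ge and gt

    ranks = {}
    remaining = set(range(len(objs)))
    rank = 0
    while remaining:
        front = {
            i
            for i in remaining
            if not any(dominates(objs[j], objs[i]) for j in remaining if j != i)
        }
        for i in front:
            ranks[i] = rank
        remaining -= front
        rank += 1
    return [ranks[i] for i in range(len(objs))]


class ScriptedRNG:
    """Stand-in RNG returning pre-recorded integer draws."""

    def __init__(self, integers):
        self._ints = list(integers)

    def integers(self, low, high=None, size=None):
        return self._ints.pop(0)


class TestNondominatedSort:
    def test_clear_dominance(self):
        m1 = model(3, 0.2, 2)
        m2 = model(2, 0.1, 3)
        ranks = nondominated_sort([m1, m2])
        assert ranks.tolist() == [0, 1]

    def test_single_model_rank_zero(self):
        assert nondominated_sort([model(1, 0.1, 2)]).tolist() == [0]

    def test_mutually_nondominated(self):
        m1 = model(3, 0.1, 2)
        m2 = model(2, 0.5, 2, snps=(5, 6))
        assert nondominated_sort([m1, m2]).tolist() == [0, 0]

    def test_equal_objectives_share_rank(self):
        m1 = model(1.0, 0.1, 2, snps=(0, 1))
        m2 = model(1.0, 0.1, 2, snps=(2, 3))
        assert nondominated_sort([m1, m2]).tolist() == [0, 0]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        models = [
            model(
                float(rng.choice([0.5, 1.0, 2.0, 3.0])),
                float(rng.choice([0.0, 0.1, 0.2])),
                int(rng.integers(1, 5)),
                snps=tuple(range(100 + 10 * i, 100 + 10 * i + 2)),
            )
            for i in range(n)
        ]
        ranks = nondominated_sort(models)
        objs = [
            (m.score.t_statistic, m.score.mean_interaction_info, m.score.size)
            for m in models
        ]
        assert ranks.tolist() == oracle_fronts(objs)

    def test_unscored_model_errors(self):
        with pytest.raises(ValueError):
            nondominated_sort([CandidateModel(snps=(0,))])


class TestCrowdingDistance:
    def test_two_models_all_infinite(self):
        front = [model(1, 0.1, 2), model(2, 0.2, 3)]
        assert np.isinf(crowding_distance(front)).all()

    def test_evenly_spaced_middle_is_three(self):
        front = [
            model(1.0, 0.1, 3),
            model(2.0, 0.2, 2, snps=(7, 8)),
            model(3.0, 0.3, 1, snps=(9,)),
        ]
        dist = crowding_distance(front)
        assert np.isinf(dist[0]) and np.isinf(dist[2])
        assert dist[1] == pytest.approx(3.0)

    def test_identical_interior_zero(self):
        front = [
            model(1.0, 0.1, 2, snps=(0, 1)),
            model(1.0, 0.1, 2, snps=(2, 3)),
            model(1.0, 0.1, 2, snps=(4, 5)),
        ]
        dist = crowding_distance(front)
        assert sorted(np.isinf(dist)) == [False, True, True]
        assert dist[~np.isinf(dist)].sum() == 0.0

    def test_empty_front_errors(self):
        with pytest.raises(ValueError):
            crowding_distance([])


class TestTournaments:
    def _ranked_pop(self):
        pop = [
            model(3, 0.3, 2, snps=(0, 1)),
            model(2, 0.2, 2, snps=(2, 3)),
            model(1, 0.1, 3, snps=(4, 5, 6)),
        ]
        nondominated_sort(pop)
        for m, c in zip(pop, (np.inf, 1.0, 0.5)):
            m.crowding = c
        return pop

    def test_rank_wins(self):
        pop = self._ranked_pop()
        pop[0].pareto_rank, pop[1].pareto_rank, pop[2].pareto_rank = 0, 1, 2
        rng = np.random.default_rng(0)
        for _ in range(20):
            winner = tournament_rank_crowding(pop, 3, rng)
            assert winner.pareto_rank == min(
                m.pareto_rank for m in pop
            ) or winner in pop

    def test_crowding_breaks_rank_ties(self):
        pop = self._ranked_pop()
        for m in pop:
            m.pareto_rank = 0
        rng = np.random.default_rng(1)
        # entrants drawn with replacement; whenever the inf-crowding model
        # is in the tournament it must win
        for _ in range(50):
            winner = tournament_rank_crowding(pop, len(pop) * 4, rng)
            assert winner is pop[0]

    def test_full_tie_uniform(self):
        pop = [
            model(1.0, 0.1, 2, snps=(2 * i, 2 * i + 1)) for i in range(3)
        ]
        for m in pop:
            m.pareto_rank, m.crowding = 0, 1.0
        rng = np.random.default_rng(2)
        counts = np.zeros(3)
        for _ in range(10000):
            winner = tournament_rank_crowding(pop, 3, rng)
            counts[pop.index(winner)] += 1
        assert sps.chisquare(counts).pvalue > 0.001

    def test_parsimony_always_minimal(self):
        pop = [
            model(1, 0.1, 2, snps=(0, 1)),
            model(5, 0.5, 3, snps=(2, 3, 4)),
            model(9, 0.9, 5, snps=tuple(range(10, 15))),
        ]
        rng = np.random.default_rng(3)
        for _ in range(200):
            winner = tournament_parsimony(pop, 6, rng)
            entr_min = min(len(m.snps) for m in pop)
            assert len(winner.snps) >= entr_min  # winner from entrants only
        # with all models entered, the size-2 model always wins
        for _ in range(50):
            assert tournament_parsimony(pop, 50, rng) is pop[0]


class TestCrossover:
    def test_identical_parents_reproduce(self):
        p = CandidateModel(snps=(3, 7, 9))
        c1, c2 = any_point_crossover(p, p, np.random.default_rng(0))
        # cuts may differ, but content stays within the parent set
        assert set(c1.snps) <= {3, 7, 9}
        assert set(c2.snps) <= {3, 7, 9}
        c1, c2 = any_point_crossover(p, p, ScriptedRNG([2, 2]))
        assert c1.snps == (3, 7, 9)
        assert c2.snps == (3, 7, 9)

    def test_fixed_cut_trace(self):
        a = CandidateModel(snps=(1, 2))
        b = CandidateModel(snps=(3, 4))
        c1, c2 = any_point_crossover(a, b, ScriptedRNG([1, 1]))
        assert c1.snps == (1, 4)
        assert c2.snps == (3, 2)

    def test_children_can_outgrow_parents(self):
        a = CandidateModel(snps=(1, 2, 3))
        b = CandidateModel(snps=(2, 5))
        lengths = set()
        for ca in range(4):
            for cb in range(3):
                c1, c2 = any_point_crossover(a, b, ScriptedRNG([ca, cb, 0, 0]))
                lengths.add(len(c1.snps))
                lengths.add(len(c2.snps))
                for c in (c1, c2):
                    assert len(set(c.snps)) == len(c.snps)
        assert 4 in lengths  # e.g. cuts (3,1): [1,2,3]+[5]

    def test_truncation_at_max_size(self):
        a = CandidateModel(snps=tuple(range(8)))
        b = CandidateModel(snps=tuple(range(8, 16)))
        c1, _ = any_point_crossover(
            a, b, ScriptedRNG([8, 0, 0]), max_model_size=10
        )
        assert len(c1.snps) == 10


class TestMutate:
    def test_rate_zero_identity(self):
        m = CandidateModel(snps=(1, 5, 9))
        out = mutate(m, 20, 0.0, np.random.default_rng(0))
        assert out.snps == m.snps

    def test_rate_one_all_replaced(self):
        m = CandidateModel(snps=(1, 5, 9))
        rng = np.random.default_rng(1)
        for _ in range(50):
            out = mutate(m, 20, 1.0, rng)
            assert all(a != b for a, b in zip(out.snps, m.snps))
            assert len(set(out.snps)) == 3

    def test_empirical_rate(self):
        m = CandidateModel(snps=(0, 1, 2, 3, 4))
        rng = np.random.default_rng(2)
        rate = 0.1
        trials = 20000
        flips = 0
        for _ in range(trials):
            out = mutate(m, 50, rate, rng)
            flips += sum(a != b for a, b in zip(out.snps, m.snps))
        p_hat = flips / (trials * 5)
        se = np.sqrt(rate * (1 - rate) / (trials * 5))
        assert abs(p_hat - rate) < 3 * se


class TestSampleInitialModel:
    def _ek(self, n):
        gain = np.zeros((n, n))
        bp = np.array([(i + 1) % n for i in range(n)])
        return ExpertKnowledgeTable(
            gain=gain, best_partner=bp, class_vector=np.zeros(2, dtype=int)
        )

    def test_collapsed_range_single_snp(self):
        cfg = SearchConfig(init_size_center=1, init_size_delta=0)
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = sample_initial_model(self._ek(10), 10, cfg, rng)
            assert len(m.snps) == 1

    def test_forced_expert_knowledge_path(self):
        cfg = SearchConfig(
            init_size_center=2, init_size_delta=0, ek_seed_prob=1.0
        )
        ek = self._ek(10)
        rng = np.random.default_rng(1)
        for _ in range(100):
            m = sample_initial_model(ek, 10, cfg, rng)
            assert m.snps[1] == ek.best_partner[m.snps[0]]

    def test_size_distribution_uniform_one_to_five(self):
        cfg = SearchConfig()  # defaults: 3 +/- 2
        ek = self._ek(50)
        rng = np.random.default_rng(2)
        sizes = np.array(
            [
                len(sample_initial_model(ek, 50, cfg, rng).snps)
                for _ in range(10000)
            ]
        )
        counts = np.bincount(sizes, minlength=6)[1:6]
        assert (counts > 0).all()
        assert sps.chisquare(counts).pvalue > 0.001


def _tiny_sim(seed=3, n=200, m=30):
    return simulate_dataset(
        SimulationSpec(
            n_genes=1, maf=0.4, heritability=0.2, trait_sd=0.0,
            n_samples=n, n_total_snps=m, seed=seed,
        )
    )


def _tiny_config(**kw):
    base = dict(
        steady_state_pop=40, task_pop=15, task_generations=4,
        n_tasks_per_round=2, evaluation_budget=800, seed=0,
    )
    base.update(kw)
    return SearchConfig(**base)


class TestEvaluator:
    def test_cache_hits_are_free(self):
        sim = _tiny_sim()
        ek = build_expert_knowledge(sim.dataset)
        ev = Evaluator(sim.dataset, ek, budget=10)
        s1 = ev.score((1, 2))
        assert ev.evaluations == 1
        s2 = ev.score((2, 1))  # same set, different order
        assert s2 is s1
        assert ev.evaluations == 1

    def test_budget_exhaustion(self):
        sim = _tiny_sim()
        ek = build_expert_knowledge(sim.dataset)
        ev = Evaluator(sim.dataset, ek, budget=2)
        ev.score((0,))
        ev.score((1,))
        with pytest.raises(BudgetExhausted):
            ev.score((2,))
        assert ev.score((0,)) is not None  # cached models still retrievable

    def test_archive_mutually_nondominated(self):
        sim = _tiny_sim()
        ek = build_expert_knowledge(sim.dataset)
        ev = Evaluator(sim.dataset, ek, budget=200)
        rng = np.random.default_rng(0)
        cfg = SearchConfig()
        while not ev.exhausted():
            m = sample_initial_model(ek, sim.dataset.n_snps, cfg, rng)
            try:
                ev.score(m.snps)
            except BudgetExhausted:
                break
        archive = ev.archive_models()
        ranks = nondominated_sort(archive)
        assert (ranks == 0).all()


class TestEvolutionaryTask:
    def _seed_pop(self, ev, ek, n_snps, k=10):
        rng = np.random.default_rng(5)
        cfg = SearchConfig()
        pop = []
        while len(pop) < k:
            m = sample_initial_model(ek, n_snps, cfg, rng)
            m.score = ev.score(m.snps)
            pop.append(m)
        return pop

    def test_zero_generations_returns_seed_pop(self):
        sim = _tiny_sim()
        ek = build_expert_knowledge(sim.dataset)
        ev = Evaluator(sim.dataset, ek, budget=500)
        pop = self._seed_pop(ev, ek, sim.dataset.n_snps)
        cfg = _tiny_config(task_generations=1)
        cfg.task_generations = 0
        out, partial = run_evolutionary_task(
            pop, ev, cfg, np.random.default_rng(0)
        )
        assert [m.snps for m in out] == [m.snps for m in pop]
        assert not partial

    def test_evaluations_equal_cache_misses(self):
        sim = _tiny_sim()
        ek = build_expert_knowledge(sim.dataset)
        ev = Evaluator(sim.dataset, ek, budget=5000)
        pop = self._seed_pop(ev, ek, sim.dataset.n_snps)
        run_evolutionary_task(
            pop, ev, _tiny_config(), np.random.default_rng(1)
        )
        assert ev.evaluations == len(ev.cache)

    def test_best_t_monotone_under_elitism(self, strong_sim):
        ds = strong_sim.dataset
        ek = build_expert_knowledge(ds)
        ev = Evaluator(ds, ek, budget=3000)
        pop = self._seed_pop(ev, ek, ds.n_snps, k=15)
        cfg = _tiny_config(task_generations=1, task_pop=15)
        best = max(m.score.t_statistic for m in pop)
        rng = np.random.default_rng(2)
        for _ in range(8):
            pop, _ = run_evolutionary_task(pop, ev, cfg, rng)
            new_best = max(m.score.t_statistic for m in pop)
            assert new_best >= best - 1e-12
            best = new_best


class TestRunCrush:
    def test_deterministic_from_seed(self):
        sim = _tiny_sim()
        cfg = _tiny_config(seed=123)
        r1 = run_crush(sim.dataset, cfg)
        r2 = run_crush(sim.dataset, _tiny_config(seed=123))
        assert [m.key for m in r1.pareto_front] == [
            m.key for m in r2.pareto_front
        ]
        assert r1.archive_size == r2.archive_size
        assert r1.history == r2.history

    def test_budget_and_model_invariants(self):
        sim = _tiny_sim()
        cfg = _tiny_config(evaluation_budget=600)
        res = run_crush(sim.dataset, cfg)
        assert res.archive_size <= 600
        assert res.pareto_front
        for m in res.pareto_front:
            assert 1 <= len(m.snps) <= cfg.max_model_size
            assert len(set(m.snps)) == len(m.snps)
        ranks = nondominated_sort(res.pareto_front)
        assert (ranks == 0).all()

    def test_finds_planted_pair_noiseless(self):
        sim = _tiny_sim(seed=8)
        res = run_crush(sim.dataset, _tiny_config(evaluation_budget=1500))
        assert set(sim.truth.functional_snp_ids) <= res.front_snp_ids()

    def test_invalid_config_rejected_before_evaluation(self):
        sim = _tiny_sim()
        with pytest.raises(ValueError):
            run_crush(sim.dataset, _tiny_config(ek_seed_prob=1.5))
        with pytest.raises(ValueError):
            run_crush(
                sim.dataset,
                _tiny_config(evaluation_budget=10, steady_state_pop=40),
            )


class TestRandomSearch:
    def test_budget_one_front_is_single_model(self):
        sim = _tiny_sim()
        ek = build_expert_knowledge(sim.dataset)
        res = run_random_search(
            sim.dataset, ek, 1, SearchConfig(seed=0),
            np.random.default_rng(0),
        )
        assert res.archive_size == 1
        assert len(res.pareto_front) == 1

    def test_deterministic(self):
        sim = _tiny_sim()
        ek = build_expert_knowledge(sim.dataset)
        runs = [
            run_random_search(
                sim.dataset, ek, 300, SearchConfig(seed=4),
                np.random.default_rng(99),
            )
            for _ in range(2)
        ]
        assert [m.key for m in runs[0].pareto_front] == [
            m.key for m in runs[1].pareto_front
        ]


class TestConfig:
    def test_mutation_rate_by_dataset_size(self):
        cfg = SearchConfig()
        assert cfg.resolve_mutation_rate(100) == 0.05
        assert cfg.resolve_mutation_rate(1000) == 0.005
        assert SearchConfig(per_snp_mutation_rate=0.2).resolve_mutation_rate(
            100
        ) == 0.2

    def test_from_file_yaml_and_kv(self, tmp_path):
        y = tmp_path / "c.yaml"
        y.write_text("evaluation_budget: 1234\ntask_pop: 7\n")
        cfg = SearchConfig.from_file(y)
        assert cfg.evaluation_budget == 1234 and cfg.task_pop == 7
        kv = tmp_path / "c.cfg"
        kv.write_text("evaluation_budget = 99\nseed = 3\n")
        cfg2 = SearchConfig.from_file(kv)
        assert cfg2.evaluation_budget == 99 and cfg2.seed == 3
        bad = tmp_path / "bad.yaml"
        bad.write_text("not_a_key: 1\n")
        with pytest.raises(ValueError):
            SearchConfig.from_file(bad)
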