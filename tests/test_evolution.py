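import itertools
import random
from dataclasses import replace

import pytest

from dysmod import (
    EAParameters,
    Individual,
    ScoredNetwork,
    crossover,
    evaluate,
    evolve,
    initialise_population,
    is_connected_subset,
    mutate,
    run_size_sweep,
    sample_connected_subnetwork,
    tournament_select,
)

FAST = dict(generations=10, population_size=20)


class TestSampling:
    def test_size_one(self, lfr_net, rng):
        s = sample_connected_subnetwork(lfr_net, 1, rng)
        assert len(s) == 1

    def test_full_vertex_set(self, triangle, rng):
        s = sample_connected_subnetwork(triangle, 3, rng)
        assert s == triangle.ids("abc")

    def test_samples_always_connected(self, lfr_net, rng):
        for _ in range(300):
            s = sample_connected_subnetwork(lfr_net, 10, rng)
            assert len(s) == 10
            assert is_connected_subset(lfr_net, s)

    def test_oversized_request_errors(self, triangle, rng):
        with pytest.raises(ValueError):
            sample_connected_subnetwork(triangle, 4, rng)

    def test_respects_allowed_set(self, path3, rng):
        allowed = path3.ids(["a", "b"])
        for _ in range(20):
            s = sample_connected_subnetwork(path3, 2, rng, allowed=allowed)
            assert s == allowed


class TestInitialisation:
    def test_overlap_contract(self, lfr_net, rng):
        params = EAParameters(subnetwork_size=8, population_size=50)
        pop = initialise_population(lfr_net, params, rng)
        assert len(pop) == 50
        for ind in pop:
            ind.validate(lfr_net, 8)

    def test_disjoint_forced_split(self, bridged_triangles, rng):
        # with sizes 3+3 on bridged triangles, the only disjoint connected
        # splits avoiding the bridge node are the two triangles themselves
        # or one triangle plus a bridge-including set
        params = EAParameters(subnetwork_size=3, mode="disjoint", population_size=30)
        pop = initialise_population(bridged_triangles, params, rng)
        for ind in pop:
            ind.validate(bridged_triangles, 3, 3)

    def test_disjoint_oversized_errors(self, triangle, rng):
        params = EAParameters(subnetwork_size=2, mode="disjoint", population_size=5)
        with pytest.raises(ValueError):
            initialise_population(triangle, params, rng)


class TestMutation:
    def test_rate_zero_is_identity(self, lfr_net, rng):
        params = EAParameters(mutation_rate=0.0, subnetwork_size=5)
        ind = Individual.from_set(sample_connected_subnetwork(lfr_net, 5, rng))
        assert mutate(lfr_net, ind, params, rng) is ind

    def test_path_pair_enumeration(self, path3):
        # on path a-b-c from {a,b}: the only admissible swap outcomes are
        # {a,b} (unchanged) or {b,c}; always connected, always size 2
        params = EAParameters(mutation_rate=1.0, subnetwork_size=2)
        seen = set()
        for seed in range(40):
            rng = random.Random(seed)
            ind = Individual.from_set(path3.ids(["a", "b"]))
            out = mutate(path3, ind, params, rng)
            assert len(out.s1) == 2
            assert is_connected_subset(path3, out.s1)
            seen.add(frozenset(path3.labels_of(out.s1)))
        assert seen <= {frozenset("ab"), frozenset("bc")}
        assert frozenset("bc") in seen

    def test_star_two_set_both_removable(self, rng):
        net = ScoredNetwork([("hub", "x"), ("hub", "y"), ("hub", "z")])
        params = EAParameters(mutation_rate=1.0, subnetwork_size=2)
        for seed in range(30):
            ind = Individual.from_set(net.ids(["hub", "x"]))
            out = mutate(net, ind, params, random.Random(seed))
            assert len(out.s1) == 2
            assert is_connected_subset(net, out.s1)

    def test_disjoint_sets_stay_disjoint(self, small_benchmark, rng):
        net = small_benchmark.network
        params = EAParameters(mutation_rate=1.0, subnetwork_size=6, mode="disjoint")
        pop = initialise_population(net, replace(params, population_size=20), rng)
        for ind in pop:
            out = mutate(net, ind, params, rng)
            out.validate(net, 6, 6)


class TestCrossover:
    def test_disjoint_parents_unchanged(self, rng):
        net = ScoredNetwork([("a", "b"), ("b", "c"), ("c", "d")])
        params = EAParameters(crossover_rate=1.0, subnetwork_size=2)
        p1 = Individual.from_set(net.ids(["a", "b"]))
        p2 = Individual.from_set(net.ids(["c", "d"]))
        assert crossover(net, p1, p2, params, rng) == (p1, p2)

    def test_rate_zero_is_identity(self, path3, rng):
        params = EAParameters(crossover_rate=0.0, subnetwork_size=2)
        p1 = Individual.from_set(path3.ids(["a", "b"]))
        p2 = Individual.from_set(path3.ids(["b", "c"]))
        assert crossover(path3, p1, p2, params, rng) == (p1, p2)

    def test_children_are_connected_subsets_of_merge(self, path3):
        params = EAParameters(crossover_rate=1.0, subnetwork_size=2)
        p1 = Individual.from_set(path3.ids(["a", "b"]))
        p2 = Individual.from_set(path3.ids(["b", "c"]))
        outcomes = set()
        for seed in range(40):
            c1, c2 = crossover(path3, p1, p2, params, random.Random(seed))
            for c in (c1, c2):
                assert len(c.s1) == 2
                assert is_connected_subset(path3, c.s1)
                outcomes.add(frozenset(path3.labels_of(c.s1)))
        assert outcomes == {frozenset("ab"), frozenset("bc")}


class TestSelection:
    def test_lower_f_bar_wins(self, two_cliques, rng):
        params = EAParameters(subnetwork_size=4, population_size=20)
        good = Individual.from_set(two_cliques.ids("abcd"))
        bad = Individual.from_set(two_cliques.ids("efgh"))
        pop = [good, bad]
        fits = [evaluate(two_cliques, ind) for ind in pop]
        pool = tournament_select(pop, fits, params, rng)
        assert pool.count(good) > pool.count(bad)

    def test_identical_population(self, two_cliques, rng):
        params = EAParameters(subnetwork_size=4, population_size=10)
        ind = Individual.from_set(two_cliques.ids("abcd"))
        pop = [ind] * 4
        fits = [evaluate(two_cliques, i) for i in pop]
        assert all(p == ind for p in tournament_select(pop, fits, params, rng))


class TestEvolve:
    def test_finds_scored_clique(self, two_cliques):
        # exhaustive enumeration over connected 4-subsets confirms {a,b,c,d}
        # is the unique global optimum: z = 6 under both conditions, <C> = 1
        best_f = max(
            evaluate(two_cliques, Individual.from_set(frozenset(sub))).F
            for sub in itertools.combinations(range(two_cliques.n_nodes), 4)
            if is_connected_subset(two_cliques, frozenset(sub))
        )
        params = EAParameters(subnetwork_size=4, generations=30, population_size=50, seed=1)
        res = evolve(two_cliques, params)
        assert two_cliques.labels_of(res.best.s1) == ["a", "b", "c", "d"]
        assert res.best_fitness.F == pytest.approx(best_f)

    def test_zero_generations_returns_initial_best(self, lfr_net):
        params = EAParameters(subnetwork_size=5, generations=0, seed=3, population_size=30)
        res = evolve(lfr_net, params)
        assert len(res.history) == 1
        res.best.validate(lfr_net, 5)

    def test_no_variation_keeps_initial_best(self, lfr_net):
        base = EAParameters(
            subnetwork_size=5, seed=9, population_size=30,
            mutation_rate=0.0, crossover_rate=0.0, generations=10,
        )
        res = evolve(lfr_net, base)
        res0 = evolve(lfr_net, replace(base, generations=0))
        assert res.best_fitness.F_bar == pytest.approx(res0.best_fitness.F_bar)

    def test_history_non_increasing(self, lfr_net):
        params = EAParameters(subnetwork_size=6, seed=4, **FAST)
        res = evolve(lfr_net, params)
        assert all(a >= b for a, b in zip(res.history, res.history[1:]))

    def test_deterministic_from_seed(self, lfr_net):
        params = EAParameters(subnetwork_size=6, seed=11, **FAST)
        r1, r2 = evolve(lfr_net, params), evolve(lfr_net, params)
        assert r1.best == r2.best
        assert r1.history == r2.history
        assert r1.population_final == r2.population_final

    def test_every_generation_valid(self, small_benchmark):
        net = small_benchmark.network
        params = EAParameters(subnetwork_size=6, mode="disjoint", seed=2, **FAST)
        res = evolve(net, params)
        for ind in res.population_final:
            ind.validate(net, 6, 6)


class TestSizeSweep:
    def test_result_count(self, lfr_net):
        params = EAParameters(seed=5, **FAST)
        results = run_size_sweep(lfr_net, [4, 6], 3, params)
        assert len(results) == 6
        assert sorted({len(r.best.s1) for r in results}) == [4, 6]

    def test_single_run(self, lfr_net):
        params = EAParameters(seed=5, **FAST)
        assert len(run_size_sweep(lfr_net, [4], 1, params)) == 1

    def test_sweep_deterministic(self, lfr_net):
        params = EAParameters(seed=5, **FAST)
        a = run_size_sweep(lfr_net, [4, 5], 2, params)
        b = run_size_sweep(lfr_net, [4, 5], 2, params)
        assert [r.best for r in a] == [r.best for r in b]

    def test_empty_sizes_error(self, lfr_net):
        with pytest.raises(ValueError):
            run_size_sweep(lfr_net, [], 1, EAParameters(**FAST))
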