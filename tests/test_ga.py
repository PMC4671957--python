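import numpy as np
import pytest

import emgafit as eg
from emgafit.ga import (
    GAConfig,
    Genotype,
    crossover_child,
    diversity_child,
    mutate_rotation,
    mutate_translation,
    mutation_rate,
    next_generation,
    run_ga,
    seed_population,
    tournament_select,
)

from conftest import cheap_context, random_genotype


class TestMutationSchedule:
    def test_endpoints_and_midpoint(self):
        cfg = GAConfig(generations=100)
        assert mutation_rate(1, cfg) == pytest.approx(0.2)
        assert mutation_rate(100, cfg) == pytest.approx(0.01)
        assert mutation_rate(50, cfg) == pytest.approx(0.2 + (49 / 99) * (0.01 - 0.2))

    def test_single_generation(self):
        cfg = GAConfig(generations=1)
        assert mutation_rate(1, cfg) == pytest.approx(0.2)


class TestSeedPopulation:
    def test_population_size_and_split(self, small_quats, rng):
        ctx = cheap_context(quats=small_quats)
        cfg = GAConfig(population_size=160, seed=0)
        comps = [object()] * 3
        pop = seed_population(ctx.points, comps, small_quats, cfg, rng,
                              ctx.map_center, ctx.mutation_range)
        assert len(pop) == 160
        # undisplaced half sits exactly on feature points
        on_points = 0
        for g in pop:
            dists = np.linalg.norm(
                g.translations[:, None, :] - (ctx.points.points - ctx.map_center)[None],
                axis=-1,
            ).min(axis=1)
            if np.all(dists < 1e-9):
                on_points += 1
        assert on_points >= 80  # 80 undisplaced (a displaced one can land on a point only with probability 0)

    def test_single_feature_point(self, small_quats, rng):
        pts = eg.PointSet([[5.0, 5.0, 5.0]])
        cfg = GAConfig(population_size=10)
        pop = seed_population(pts, [object()] * 2, small_quats, cfg, rng,
                              np.zeros(3), mutation_range=0.0)
        for g in pop:
            assert np.allclose(g.translations, [5.0, 5.0, 5.0])

    def test_rotation_indices_valid_and_reproducible(self, small_quats):
        ctx = cheap_context(quats=small_quats)
        cfg = GAConfig(population_size=30, seed=0)
        pops = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            pops.append(seed_population(ctx.points, [object()] * 3, small_quats,
                                        cfg, rng, ctx.map_center, ctx.mutation_range))
        for a, b in zip(*pops):
            assert np.array_equal(a.translations, b.translations)
            assert np.array_equal(a.rotation_indices, b.rotation_indices)
            assert np.all((a.rotation_indices >= 0) & (a.rotation_indices < small_quats.size))


class TestTournament:
    def evaluated(self, fitnesses, quats, rng):
        pop = []
        for f in fitnesses:
            g = random_genotype(2, quats, rng)
            g.fitness = eg.FitnessBreakdown(mi=f / 2, ps=0.0, n=2)
            pop.append(g)
        return pop

    def test_two_member_population_deterministic(self, small_quats, rng):
        pop = self.evaluated([5.0, 3.0], small_quats, rng)
        for _ in range(20):
            assert tournament_select(pop, 2, rng) is pop[0]

    def test_winner_at_least_as_fit_as_any_loser(self, small_quats, rng):
        pop = self.evaluated(list(range(10)), small_quats, rng)
        for _ in range(100):
            winner = tournament_select(pop, 2, rng)
            assert winner.fitness.f >= min(g.fitness.f for g in pop)

    def test_selection_probability_matches_rank_formula(self, small_quats, rng):
        """P(rank r wins; 0 = best) = 2(N−1−r) / (N(N−1)) for size-2
        tournaments drawn without replacement."""
        N = 160
        pop = self.evaluated(list(range(N, 0, -1)), small_quats, rng)
        counts = np.zeros(N)
        trials = 10_000
        for _ in range(trials):
            winner = tournament_select(pop, 2, rng)
            counts[pop.index(winner)] += 1
        freq = counts / trials
        expected = 2 * (N - 1 - np.arange(N)) / (N * (N - 1))
        # 4-sigma binomial envelope per rank
        se = np.sqrt(expected * (1 - expected) / trials)
        assert np.all(np.abs(freq - expected) < 4 * se + 1e-12)
        # monotone decrease on the smoothed empirical counts
        assert freq[:20].mean() > freq[70:90].mean() > freq[-20:].mean()


class TestMutations:
    def test_translation_bounded(self, rng):
        for _ in range(200):
            v = mutate_translation(np.zeros(3), 6.5, rng)
            assert np.linalg.norm(v) <= 6.5 + 1e-12

    def test_rotation_uniform(self, rng):
        n_quats, draws = 50, 10_000
        counts = np.bincount(
            [mutate_rotation(n_quats, rng) for _ in range(draws)], minlength=n_quats
        )
        p = 1 / n_quats
        se = np.sqrt(draws * p * (1 - p))
        assert np.all(np.abs(counts - draws * p) < 4 * se)


class TestCrossover:
    def make_parents(self, quats, rng):
        a = random_genotype(3, quats, rng)
        b = random_genotype(3, quats, rng)
        a.fitness = eg.FitnessBreakdown(mi=1.0, ps=0.0, n=3)
        b.fitness = eg.FitnessBreakdown(mi=0.5, ps=0.0, n=3)
        return a, b

    def test_no_crossover_copies_fitter_parent(self, small_quats, rng):
        ctx = cheap_context(quats=small_quats)
        a, b = self.make_parents(small_quats, rng)
        cfg = GAConfig(crossover_prob=0.0, mutation_initial=0.0, mutation_final=0.0)
        child = crossover_child((a, b), cfg, 1, rng, ctx)
        assert np.array_equal(child.translations, a.translations)
        assert np.array_equal(child.rotation_indices, a.rotation_indices)

    def test_full_crossover_copies_other_parent(self, small_quats, rng):
        ctx = cheap_context(quats=small_quats)
        a, b = self.make_parents(small_quats, rng)
        cfg = GAConfig(crossover_prob=1.0, mutation_initial=0.0, mutation_final=0.0)
        child = crossover_child((a, b), cfg, 1, rng, ctx)
        assert np.array_equal(child.translations, b.translations)
        assert np.array_equal(child.rotation_indices, b.rotation_indices)

    def test_mismatched_gene_counts_rejected(self, small_quats, rng):
        ctx = cheap_context(quats=small_quats)
        a = random_genotype(3, small_quats, rng)
        b = random_genotype(2, small_quats, rng)
        a.fitness = b.fitness = eg.FitnessBreakdown(mi=0.0, ps=0.0, n=3)
        with pytest.raises(ValueError, match="gene counts"):
            crossover_child((a, b), GAConfig(), 1, rng, ctx)


class TestDiversity:
    def test_swap_preserves_gene_multiset(self, small_quats, rng):
        ctx = cheap_context(quats=small_quats)
        g = random_genotype(4, small_quats, rng)
        cfg = GAConfig(diversity_mutation_rate=0.0)
        child = diversity_child(g, cfg, rng, ctx)
        pairs = lambda x: sorted(
            (tuple(t), int(r)) for t, r in zip(x.translations, x.rotation_indices)
        )
        assert pairs(child) == pairs(g)

    def test_two_component_swap_deterministic(self, small_quats, rng):
        ctx = cheap_context(quats=small_quats)
        g = random_genotype(2, small_quats, rng)
        cfg = GAConfig(diversity_mutation_rate=0.0)
        child = diversity_child(g, cfg, rng, ctx)
        assert np.array_equal(child.translations, g.translations[::-1])
        assert np.array_equal(child.rotation_indices, g.rotation_indices[::-1])

    def test_single_component_falls_back_to_mutation_copy(self, small_quats, rng):
        ctx = cheap_context(quats=small_quats)
        g = random_genotype(1, small_quats, rng)
        cfg = GAConfig(diversity_mutation_rate=0.0)
        child = diversity_child(g, cfg, rng, ctx)
        assert np.array_equal(child.translations, g.translations)


class TestNextGeneration:
    def seeded_pop(self, ctx, cfg, rng):
        pop = seed_population(ctx.points, [object()] * 3, ctx.quats, cfg, rng,
                              ctx.map_center, ctx.mutation_range)
        for g in pop:
            g.fitness = ctx.evaluate(g)
        return pop

    def test_child_mix_and_merge_pool_at_160(self):
        cfg = GAConfig(population_size=160)
        assert cfg.n_crossover_children == 144
        assert cfg.n_diversity_children == 16
        # merged pool is parents + children = 2N
        assert cfg.population_size + cfg.n_crossover_children + cfg.n_diversity_children == 320

    def test_survivor_count_and_elitism(self, small_quats, rng):
        ctx = cheap_context(quats=small_quats)
        cfg = GAConfig(population_size=40, generations=10)
        pop = self.seeded_pop(ctx, cfg, rng)
        best0 = max(g.fitness.f for g in pop)
        for gen in range(1, 6):
            pop = next_generation(pop, cfg, gen, ctx, rng)
            assert len(pop) == 40
            best1 = max(g.fitness.f for g in pop)
            assert best1 >= best0
            best0 = best1

    def test_no_novel_genes_without_crossover_or_mutation(self, small_quats, rng):
        """With crossover and mutation off, children only copy parent gene
        values, and the elitist merge keeps the incumbent best."""
        ctx = cheap_context(quats=small_quats)
        cfg = GAConfig(population_size=20, generations=5, crossover_prob=0.0,
                       mutation_initial=0.0, mutation_final=0.0,
                       diversity_fraction=0.0)
        pop = self.seeded_pop(ctx, cfg, rng)
        parent_genes = {
            (tuple(map(tuple, g.translations)), tuple(g.rotation_indices)) for g in pop
        }
        best_before = max(pop, key=lambda g: g.fitness.f)
        new = next_generation(pop, cfg, 1, ctx, rng)
        for g in new:
            key = (tuple(map(tuple, g.translations)), tuple(g.rotation_indices))
            assert key in parent_genes
        assert max(new, key=lambda g: g.fitness.f).fitness.f == best_before.fitness.f


class TestRunGA:
    def test_trace_length_monotone_and_selection_pressure(self, small_quats):
        ctx = cheap_context(quats=small_quats)
        cfg = GAConfig(population_size=20, generations=15, seed=4,
                       quaternion_count=small_quats.size)
        best, trace = run_ga(None, [object()] * 3, ctx.points, cfg, run_seed=0, ctx=ctx)
        assert len(trace) == 15
        assert np.all(np.diff(trace.best) >= 0)
        assert trace.mean[-1] >= trace.mean[0]
        assert best.fitness.f == trace.best[-1]

    def test_reproducible_gene_lists(self, small_quats):
        ctx = cheap_context(quats=small_quats)
        cfg = GAConfig(population_size=12, generations=6, seed=7,
                       quaternion_count=small_quats.size)
        runs = [run_ga(None, [object()] * 3, ctx.points, cfg, run_seed=3, ctx=ctx)
                for _ in range(2)]
        a, b = runs[0][0], runs[1][0]
        assert np.array_equal(a.translations, b.translations)
        assert np.array_equal(a.rotation_indices, b.rotation_indices)


class TestEnsemble:
    def test_ranked_output(self, toy_assembly):
        cfg = GAConfig(population_size=10, generations=3, n_runs=3, seed=2)
        res = eg.run_ensemble(toy_assembly.target_map, toy_assembly.components,
                              toy_assembly.centroids, cfg)
        assert len(res.genotypes) == 3
        f = [g.fitness.f for g in res.genotypes]
        assert f == sorted(f, reverse=True)

    def test_bp_rank_against_reference(self, toy_assembly):
        cfg = GAConfig(population_size=10, generations=3, n_runs=3, seed=2)
        res = eg.run_ensemble(toy_assembly.target_map, toy_assembly.components,
                              toy_assembly.centroids, cfg,
                              reference=toy_assembly.native)
        assert 1 <= res.bp_rank <= 3
        assert res.bp_rmsd >= 0
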