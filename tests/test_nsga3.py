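"""NSGA-III internals: reference directions, nondominated sorting,
normalization/association, niching, SBX, polynomial mutation and the
evolution loop contracts."""

from math import comb

import numpy as np
import pytest
from scipy.stats import binomtest

from privhar import EvolutionConfig, das_dennis_directions, evolve, nondominated_sort
from privhar.nsga3 import (
    Individual,
    environmental_selection,
    niching_select,
    normalize_and_associate,
    normalize_objectives,
    polynomial_mutation,
    sbx_crossover,
)

from oracles import oracle_das_dennis, oracle_nondominated_sort, oracle_ray_association


class TestDasDennis:
    def test_study_setting_yields_45(self):
        assert len(das_dennis_directions(3, 8)) == 45

    def test_two_objective_single_partition(self):
        dirs = das_dennis_directions(2, 1).directions
        assert {tuple(d) for d in dirs} == {(0.0, 1.0), (1.0, 0.0)}

    def test_three_objective_two_partitions(self):
        dirs = das_dennis_directions(3, 2).directions
        assert len(dirs) == 6
        assert {tuple(d) for d in dirs} == oracle_das_dennis(3, 2)

    @pytest.mark.parametrize("M", [2, 3, 4])
    @pytest.mark.parametrize("p", [1, 2, 3, 4, 5, 6])
    def test_matches_lattice_enumeration(self, M, p):
        ref = das_dennis_directions(M, p)
        assert len(ref) == comb(M + p - 1, p)
        assert {tuple(d) for d in ref.directions} == oracle_das_dennis(M, p)
        np.testing.assert_allclose(ref.directions.sum(axis=1), 1.0, atol=1e-12)


class TestNondominatedSort:
    def test_single_point(self):
        assert [f.tolist() for f in nondominated_sort(np.array([[1.0, 2.0]]))] == [[0]]

    def test_strict_dominance(self):
        fronts = nondominated_sort(np.array([[0, 0, 0], [1, 1, 1]], float))
        assert [f.tolist() for f in fronts] == [[0], [1]]

    def test_matches_peeling_oracle(self, rng):
        pts = rng.random((50, 3))
        fronts = nondominated_sort(pts)
        expected = oracle_nondominated_sort(pts)
        assert [sorted(f.tolist()) for f in fronts] == expected
        # fronts partition the input
        assert sorted(i for f in fronts for i in f) == list(range(50))


class TestNormalizeAndAssociate:
    def test_ideal_point_translation(self, rng):
        pool = rng.random((30, 3)) + 5.0
        ideal, scale = normalize_objectives(pool)
        np.testing.assert_allclose(ideal, pool.min(axis=0))
        assert np.all(scale > 0)

    def test_member_on_reference_ray(self):
        ref = das_dennis_directions(3, 2)
        pool = np.vstack([np.eye(3), [[0.4, 0.4, 0.2]]])
        member = 0.3 * np.array([[0.5, 0.5, 0.0]])
        niche, dist = normalize_and_associate(member, pool, ref)
        assert dist[0] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(
            ref.directions[niche[0]], [0.5, 0.5, 0.0], atol=1e-12
        )

    def test_matches_ray_distance_oracle(self, rng):
        ref = das_dennis_directions(3, 4)
        pool = rng.random((20, 3))
        ideal, scale = normalize_objectives(pool)
        niche, dist = normalize_and_associate(pool, pool, ref)
        for i in range(20):
            normalized = (pool[i] - ideal) / scale
            j, d = oracle_ray_association(normalized, ref.directions)
            assert niche[i] == j
            assert dist[i] == pytest.approx(d, rel=1e-9, abs=1e-12)

    def test_degenerate_identical_objectives(self):
        pool = np.ones((5, 3))
        niche, dist = normalize_and_associate(pool, pool, das_dennis_directions(3, 2))
        assert len(niche) == 5
        assert np.all(np.isfinite(dist))


class TestNiching:
    def test_whole_front_when_slots_match(self, rng):
        counts = np.zeros(3, dtype=int)
        selected = niching_select(
            np.array([4, 7, 9]), 3, counts,
            niche_of=np.array([0, 1, 2]), dist_of=np.array([0.1, 0.2, 0.3]),
            rng=np.random.default_rng(0),
        )
        assert sorted(selected) == [4, 7, 9]

    def test_single_candidate(self):
        counts = np.zeros(1, dtype=int)
        got = niching_select(
            np.array([3]), 1, counts, np.array([0]), np.array([0.5]),
            np.random.default_rng(0),
        )
        assert got == [3]
        assert counts[0] == 1

    def test_empty_niche_prefers_closest(self):
        counts = np.zeros(1, dtype=int)
        got = niching_select(
            np.array([1, 2, 3]), 1, counts, np.array([0, 0, 0]),
            np.array([0.9, 0.1, 0.5]), np.random.default_rng(0),
        )
        assert got == [2]

    def test_reproducible_given_seed(self, rng):
        front = np.arange(20)
        niche_of = rng.integers(0, 5, 20)
        dist_of = rng.random(20)
        a = niching_select(front, 10, np.zeros(5, int), niche_of, dist_of,
                           np.random.default_rng(42))
        b = niching_select(front, 10, np.zeros(5, int), niche_of, dist_of,
                           np.random.default_rng(42))
        assert a == b


class TestVariationOperators:
    def test_sbx_prob_zero_copies_parents(self, rng):
        a, b = rng.random(62), rng.random(62)
        c1, c2 = sbx_crossover(a, b, eta=30, prob=0.0, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(c1, a)
        np.testing.assert_array_equal(c2, b)

    def test_sbx_identical_parents_unchanged(self, rng):
        a = rng.random(62)
        c1, c2 = sbx_crossover(a, a.copy(), eta=30, prob=1.0,
                               rng=np.random.default_rng(0))
        np.testing.assert_allclose(c1, a, atol=1e-12)
        np.testing.assert_allclose(c2, a, atol=1e-12)

    def test_sbx_preserves_parent_mean_before_clipping(self):
        """SBX children straddle the parents symmetrically: per gene,
        c1 + c2 == p1 + p2 exactly (checked over 10^4 pairs, unclipped)."""
        rng = np.random.default_rng(7)
        for _ in range(10_000):
            a, b = rng.random(8), rng.random(8)
            c1, c2 = sbx_crossover(a, b, eta=15, prob=1.0, rng=rng, bounds=None)
            np.testing.assert_allclose(c1 + c2, a + b, rtol=1e-9, atol=1e-9)

    def test_sbx_respects_bounds(self, rng):
        gen = np.random.default_rng(3)
        for _ in range(200):
            a, b = rng.random(10), rng.random(10)
            c1, c2 = sbx_crossover(a, b, eta=2, prob=1.0, rng=gen, bounds=(0.0, 1.0))
            for c in (c1, c2):
                assert np.all(c >= 0.0) and np.all(c <= 1.0)

    def test_pm_prob_zero_is_identity(self, rng):
        x = rng.random(62)
        np.testing.assert_array_equal(
            polynomial_mutation(x, eta=20, prob=0.0, rng=np.random.default_rng(0)), x
        )

    def test_pm_outputs_within_bounds(self):
        rng = np.random.default_rng(11)
        x = np.linspace(0.01, 0.99, 10)
        for _ in range(10_000):
            y = polynomial_mutation(x, eta=20, prob=1.0, rng=rng, bounds=(0.0, 1.0))
            assert np.all(y >= 0.0) and np.all(y <= 1.0)

    def test_pm_symmetric_at_interval_midpoint(self):
        """For a gene at the midpoint of its bounds, the polynomial-mutation
        perturbation is symmetric about zero (two-sided sign test)."""
        rng = np.random.default_rng(5)
        x = np.full(100, 0.5)
        deltas = []
        for _ in range(1000):
            y = polynomial_mutation(x, eta=20, prob=1.0, rng=rng, bounds=(0.0, 1.0))
            deltas.extend((y - x).tolist())
        deltas = np.asarray(deltas)
        deltas = deltas[deltas != 0.0]
        pos = int((deltas > 0).sum())
        assert binomtest(pos, len(deltas), 0.5).pvalue > 1e-3


def _sphere_fitness(genome):
    """3-objective DTLZ2: the Pareto front is the unit-sphere octant."""
    g = float(np.sum((genome[2:] - 0.5) ** 2))
    t1, t2 = genome[0] * np.pi / 2, genome[1] * np.pi / 2
    return np.array(
        [
            (1 + g) * np.cos(t1) * np.cos(t2),
            (1 + g) * np.cos(t1) * np.sin(t2),
            (1 + g) * np.sin(t1),
        ]
    )


class TestEvolve:
    def _config(self, **kw):
        base = dict(population_size=12, n_offspring=6, p=3, M=3, generations=3,
                    n_genes=7, seed=0)
        base.update(kw)
        return EvolutionConfig(**base)

    def test_fitness_call_counts(self):
        calls = []

        def fitness(g):
            calls.append(1)
            return _sphere_fitness(g)

        history = evolve(self._config(generations=0), fitness)
        assert len(calls) == 12
        assert len(history) == 1
        evolve(self._config(generations=4), lambda g: (calls.append(1), _sphere_fitness(g))[1])
        assert len(calls) == 12 + 12 + 4 * 6

    def test_population_size_invariant_and_evaluated(self):
        history = evolve(self._config(), _sphere_fitness)
        for pop in history:
            assert len(pop) == 12
            assert all(ind.evaluated for ind in pop.individuals)
            assert all(ind.rank is not None for ind in pop.individuals)

    def test_full_run_reproducible(self):
        h1 = evolve(self._config(), _sphere_fitness)
        h2 = evolve(self._config(), _sphere_fitness)
        np.testing.assert_array_equal(h1[-1].genomes(), h2[-1].genomes())
        np.testing.assert_array_equal(h1[-1].objectives(), h2[-1].objectives())

    def test_fitness_error_aborts_run(self):
        def broken(genome):
            raise RuntimeError("inductor blew up")

        with pytest.raises(RuntimeError, match="inductor blew up"):
            evolve(self._config(), broken)

    def test_refuses_more_directions_than_population(self):
        with pytest.raises(ValueError, match="reference directions"):
            EvolutionConfig(population_size=10, p=8, M=3)

    def test_environmental_selection_respects_fronts(self, rng):
        individuals = [
            Individual(genome=rng.random(4), objectives=rng.random(3))
            for _ in range(40)
        ]
        ref = das_dennis_directions(3, 3)
        survivors = environmental_selection(individuals, 20, ref, np.random.default_rng(0))
        assert len(survivors) == 20
        max_kept = max(ind.rank for ind in survivors)
        kept_ids = {id(ind) for ind in survivors}
        for ind in individuals:
            if ind.rank is not None and ind.rank < max_kept:
                assert id(ind) in kept_ids

    def test_dtlz2_front_distance_shrinks(self):
        cfg = self._config(generations=25, seed=3)
        history = evolve(cfg, _sphere_fitness)

        def front_distance(pop):
            F = np.vstack([ind.objectives for ind in pop.front(0)])
            return np.abs(np.linalg.norm(F, axis=1) - 1.0).mean()

        assert front_distance(history[-1]) < front_distance(history[1])
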