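"""Placement-optimizer contracts: the LOPO objective against an independent
oracle, cardinality conservation of the GA operators, selection sampling
distributions, and greedy/exhaustive search behavior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score

from gaitstrain import (
    Chromosome,
    GAConfig,
    PrecomputedLOPO,
    balanced_crossover,
    exhaustive_select,
    forward_select,
    ga_select,
    interchange_mutation,
    lopo_linear_objective,
    random_placement_instance,
    roulette_select,
)


def _tiny_instance(n_candidates=6, n_participants=3, frames=50, seed=0):
    return random_placement_instance(
        n_candidates, n_participants=n_participants, n_frames=frames, seed=seed
    )


class TestLopoObjective:
    def test_exact_linear_recovery_gives_unit_fitness(self):
        # hip angles ARE a linear map of the selected strains, no noise
        rng = np.random.default_rng(0)
        coef = rng.normal(0, 1, (3, 3))
        strains, angles = [], []
        for _ in range(3):
            s = rng.normal(0, 1, (40, 3))
            strains.append(s)
            angles.append(s @ coef.T + np.array([10.0, 2.0, -1.0]))
        res = lopo_linear_objective(strains, angles, [0, 1, 2])
        assert res.fitness == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_fitness_near_zero(self):
        rng = np.random.default_rng(1)
        strains = [rng.normal(0, 1, (4000, 2)) for _ in range(3)]
        angles = [rng.normal(0, 5, (4000, 3)) for _ in range(3)]
        res = lopo_linear_objective(strains, angles, [0, 1])
        assert abs(res.fitness) < 0.05

    def test_matches_sklearn_oracle(self):
        # independent route: sklearn LinearRegression + r2_score per fold
        strains, angles = _tiny_instance(n_candidates=4, frames=50, seed=3)
        subset = [0, 2]
        res = lopo_linear_objective(strains, angles, subset)
        fold_means = []
        for held in range(3):
            x_tr = np.vstack([strains[p][:, subset] for p in range(3) if p != held])
            y_tr = np.vstack([angles[p] for p in range(3) if p != held])
            model = LinearRegression().fit(x_tr, y_tr)
            pred = model.predict(strains[held][:, subset])
            fold_means.append(
                np.mean([r2_score(angles[held][:, j], pred[:, j]) for j in range(3)])
            )
        assert res.fitness == pytest.approx(np.mean(fold_means), abs=1e-9)

    def test_precomputed_equivalent_to_direct(self):
        strains, angles = _tiny_instance(n_candidates=8, seed=5)
        obj = PrecomputedLOPO(strains, angles)
        for subset in ([0], [1, 4], [2, 3, 7], list(range(8))):
            direct = lopo_linear_objective(strains, angles, subset)
            fast = obj.evaluate(subset)
            assert fast.fitness == pytest.approx(direct.fitness, abs=1e-9)
            np.testing.assert_allclose(fast.per_fold_r2, direct.per_fold_r2,
                                       atol=1e-9)
            np.testing.assert_allclose(fast.per_plane_r2, direct.per_plane_r2,
                                       atol=1e-9)

    def test_empty_subset_rejected(self):
        strains, angles = _tiny_instance()
        with pytest.raises(ValueError):
            lopo_linear_objective(strains, angles, [])


class TestForwardSelect:
    def test_first_step_is_singleton_argmax(self):
        strains, angles = _tiny_instance(n_candidates=7, seed=2)
        obj = PrecomputedLOPO(strains, angles)
        trace = forward_select(7, obj, 3)
        singles = [obj([j]) for j in range(7)]
        assert trace[0][0] == (int(np.argmax(singles)),)
        assert trace[0][1] == pytest.approx(max(singles))

    def test_subsets_nested(self):
        strains, angles = _tiny_instance(n_candidates=7, seed=4)
        obj = PrecomputedLOPO(strains, angles)
        trace = forward_select(7, obj, 4)
        for (small, _), (big, _) in zip(trace, trace[1:]):
            assert set(small) <= set(big)

    def test_greedy_trace_matches_stepwise_bruteforce(self):
        strains, angles = _tiny_instance(n_candidates=10, seed=6)
        obj = PrecomputedLOPO(strains, angles)
        trace = forward_select(10, obj, 3)
        selected = []
        for k in range(3):
            best_j, best_f = None, -np.inf
            for j in range(10):
                if j in selected:
                    continue
                f = obj(selected + [j])
                if f > best_f:
                    best_j, best_f = j, f
            selected.append(best_j)
            assert trace[k][0] == tuple(sorted(selected))
            assert trace[k][1] == pytest.approx(best_f, abs=1e-12)


class TestBalancedCrossover:
    def test_identical_parents_unchanged(self, rng):
        p = Chromosome(np.array([1, 0, 1, 0, 1, 0], dtype=np.int8))
        a, b = balanced_crossover(p, p, rng)
        np.testing.assert_array_equal(a.genes, p.genes)
        np.testing.assert_array_equal(b.genes, p.genes)

    def test_no_valid_point_returns_parents(self, rng):
        a = Chromosome(np.array([1, 1, 0, 0, 0, 0], dtype=np.int8))
        b = Chromosome(np.array([0, 0, 0, 0, 1, 1], dtype=np.int8))
        ca, cb = balanced_crossover(a, b, rng)
        np.testing.assert_array_equal(ca.genes, a.genes)
        np.testing.assert_array_equal(cb.genes, b.genes)

    def test_children_conserve_cardinality_over_enumerated_points(self, rng):
        # every valid cut point yields cardinality-k children (oracle:
        # exhaustive prefix ones-count enumeration)
        a = Chromosome(np.array([1, 0, 1, 0, 0, 0], dtype=np.int8))
        b = Chromosome(np.array([0, 1, 1, 0, 0, 0], dtype=np.int8))
        ca_ones = np.cumsum(a.genes)
        cb_ones = np.cumsum(b.genes)
        valid = [p for p in range(1, 6) if ca_ones[p - 1] == cb_ones[p - 1]]
        assert valid  # the instance admits interior points
        for point in valid:
            ga = np.concatenate([a.genes[:point], b.genes[point:]])
            gb = np.concatenate([b.genes[:point], a.genes[point:]])
            assert ga.sum() == 2 and gb.sum() == 2
        for _ in range(50):
            ca, cb = balanced_crossover(a, b, rng)
            assert ca.cardinality == 2 and cb.cardinality == 2

    def test_cardinality_mismatch_rejected(self, rng):
        a = Chromosome(np.array([1, 1, 0, 0], dtype=np.int8))
        b = Chromosome(np.array([1, 0, 0, 0], dtype=np.int8))
        with pytest.raises(ValueError):
            balanced_crossover(a, b, rng)

    @given(st.integers(0, 2**31 - 1), st.integers(2, 9))
    @settings(max_examples=60, deadline=None)
    def test_crossover_conserves_cardinality_property(self, seed, k):
        rng = np.random.default_rng(seed)
        length = 12
        a = Chromosome.random(length, k, rng)
        b = Chromosome.random(length, k, rng)
        ca, cb = balanced_crossover(a, b, rng)
        assert ca.cardinality == k and cb.cardinality == k
        assert ca.length == length and cb.length == length


class TestInterchangeMutation:
    def test_single_swap_reachability(self):
        base = Chromosome(np.array([1, 1, 0, 0], dtype=np.int8))
        expected = {(1, 0, 1, 0), (1, 0, 0, 1), (0, 1, 1, 0), (0, 1, 0, 1)}
        seen = set()
        rng = np.random.default_rng(0)
        for _ in range(300):
            m = interchange_mutation(base, rng)
            assert m.cardinality == 2
            seen.add(tuple(int(g) for g in m.genes))
        assert seen == expected

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_cardinality_conserved_property(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 10))
        chrom = Chromosome.random(10, k, rng)
        assert interchange_mutation(chrom, rng).cardinality == k

    def test_degenerate_chromosome_noop_with_warning(self, rng):
        allones = Chromosome(np.ones(5, dtype=np.int8))
        with pytest.warns(UserWarning):
            out = interchange_mutation(allones, rng)
        np.testing.assert_array_equal(out.genes, allones.genes)

    def test_swap_distribution_uniform(self):
        # k * (L - k) = 8 equally likely outcomes; chi-square at 10,000 draws
        base = Chromosome(np.array([1, 1, 0, 0, 0, 0], dtype=np.int8))
        rng = np.random.default_rng(99)
        counts: dict[tuple, int] = {}
        n = 10_000
        for _ in range(n):
            m = interchange_mutation(base, rng)
            key = tuple(int(g) for g in m.genes)
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 8
        chi2 = sum((c - n / 8) ** 2 / (n / 8) for c in counts.values())
        assert chi2 < stats.chi2.ppf(0.999, df=7)


class TestRouletteSelect:
    def _pop(self, n):
        return [Chromosome.from_subset([i], n) for i in range(n)]

    def test_dominant_fitness_dominates_selection(self, rng):
        pop = self._pop(2)
        picks = roulette_select(pop, np.array([1.0, 0.0]), 1000, rng)
        frac_first = np.mean([p.subset == (0,) for p in picks])
        assert frac_first > 0.99

    def test_equal_fitness_uniform(self):
        pop = self._pop(4)
        rng = np.random.default_rng(3)
        picks = roulette_select(pop, np.zeros(4), 10_000, rng)
        counts = np.array([sum(p.subset == (i,) for p in picks) for i in range(4)])
        chi2 = ((counts - 2500.0) ** 2 / 2500.0).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=3)

    def test_frequencies_proportional_to_fitness(self):
        pop = self._pop(3)
        f = np.array([0.2, 0.3, 0.5])
        rng = np.random.default_rng(11)
        n = 10_000
        picks = roulette_select(pop, f, n, rng)
        counts = np.array([sum(p.subset == (i,) for p in picks) for i in range(3)])
        # shifted-by-min probabilities: (eps, 0.1, 0.3)/sum
        shifted = f - f.min() + 1e-6
        probs = shifted / shifted.sum()
        for c, p in zip(counts, probs):
            se = np.sqrt(n * p * (1 - p))
            assert abs(c - n * p) < 4.5 * se + 1.0


class TestGASelect:
    def test_finds_exhaustive_optimum_small_instance(self):
        strains, angles = _tiny_instance(n_candidates=10, seed=8)
        obj = PrecomputedLOPO(strains, angles)
        _, opt = exhaustive_select(10, obj, 2)
        hits = 0
        for seed in range(10):
            _, fit, _ = ga_select(10, obj, 2, GAConfig(seed=seed))
            hits += abs(fit - opt) < 1e-9
        assert hits >= 9

    def test_symmetric_candidates_flat_history(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, (60, 1))
        strains = [np.tile(base + i, (1, 6)) for i in range(3)]
        angles = [np.column_stack([base + i, base + i, base + i]) for i in range(3)]
        obj = PrecomputedLOPO(strains, angles)
        _, _, hist = ga_select(6, obj, 2, GAConfig(seed=1, generations=20,
                                                   stagnation_limit=5))
        assert np.ptp(hist.best_fitness) < 1e-9

    def test_cardinality_constant_across_generations(self):
        strains, angles = _tiny_instance(n_candidates=9, seed=9)
        obj = PrecomputedLOPO(strains, angles)
        _, _, hist = ga_select(9, obj, 3, GAConfig(seed=5, generations=25),
                               record_populations=True)
        for pop in hist.populations:
            assert all(ch.cardinality == 3 for ch in pop)

    def test_best_fitness_nondecreasing(self):
        strains, angles = _tiny_instance(n_candidates=9, seed=10)
        obj = PrecomputedLOPO(strains, angles)
        _, _, hist = ga_select(9, obj, 3, GAConfig(seed=6))
        best = hist.best_fitness
        assert all(b >= a - 1e-12 for a, b in zip(best, best[1:]))

    @pytest.mark.parametrize("k", [0, 9])
    def test_degenerate_k_rejected(self, k):
        strains, angles = _tiny_instance(n_candidates=9, seed=1)
        obj = PrecomputedLOPO(strains, angles)
        with pytest.raises(ValueError):
            ga_select(9, obj, k, GAConfig(seed=0))
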