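"""Binary grey wolf operators, wrapper fitness and the optimizer loop."""

import numpy as np
import pytest

from cbbgwo.bgwo import (BinarySolution, CentroidClassifier, FitnessConfig,
                         WrapperFitness, bstep, crossover, cstep,
                         leader_candidate, optimize, update_coefficients)


class TestCoefficients:
    def test_schedule_endpoints(self, rng):
        x = np.zeros(4)
        c0 = update_coefficients(0, 10, x, x, rng)
        assert c0.a == 2.0
        cT = update_coefficients(10, 10, x, x, rng)
        assert cT.a == 0.0
        assert np.allclose(cT.A, 0.0)

    def test_coincident_positions_zero_distance(self, rng):
        x = np.ones(6)
        coef = update_coefficients(3, 10, x, x, rng)
        # D = |C*x - x| = |C - 1| which is 0 when C = 1; check the bound
        assert np.allclose(coef.D, np.abs(coef.C - 1.0))
        zeros = np.zeros(6)
        coef0 = update_coefficients(3, 10, zeros, zeros, rng)
        assert np.allclose(coef0.D, 0.0)

    def test_a_bounds_A(self, rng):
        coef = update_coefficients(2, 8, np.ones(100), np.zeros(100), rng)
        assert np.all(np.abs(coef.A) <= coef.a + 1e-12)
        assert np.all(coef.C >= 0) and np.all(coef.C <= 2)
        assert np.all(coef.D >= 0)

    def test_invalid_schedule(self, rng):
        with pytest.raises(ValueError):
            update_coefficients(0, 0, np.ones(2), np.ones(2), rng)


class TestTransfer:
    def test_sigmoid_midpoint_exact(self):
        assert cstep(1.0, 0.5) == 0.5
        assert cstep(0.5, 1.0) == 0.5

    def test_value_at_zero(self):
        assert cstep(0.0, 1.0) == pytest.approx(1 / (1 + np.e ** 5),
                                                rel=1e-12)

    def test_saturation_and_monotonicity(self):
        grid = np.linspace(-3, 3, 101)
        vals = cstep(grid, 1.0)
        assert np.all(np.diff(vals) > 0)  # strictly increasing in A*D
        assert cstep(1e3, 1.0) == pytest.approx(1.0)
        assert 0 < cstep(-2.0, 3.0) < 1

    def test_bstep_threshold(self):
        assert bstep(0.9, 0.5) == 1
        assert bstep(0.1, 0.5) == 0
        assert bstep(0.5, 0.5) == 1  # cstep >= rand

    def test_bstep_is_bernoulli_with_cstep_probability(self, rng):
        p = 0.37
        n = 10 ** 5
        bits = bstep(np.full(n, p), rng.random(n))
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(bits.mean() - p) < 3 * sigma


class TestLeaderCandidate:
    def test_or_truth_table(self):
        leader = np.array([0, 0, 1, 1])
        steps = np.array([0, 1, 0, 1])
        assert list(leader_candidate(leader, steps)) == [0, 1, 1, 1]

    def test_equals_elementwise_or_on_random_vectors(self, rng):
        a = rng.integers(0, 2, 500)
        b = rng.integers(0, 2, 500)
        assert np.array_equal(leader_candidate(a, b),
                              np.logical_or(a, b).astype(int))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            leader_candidate(np.ones(3), np.ones(4))


class TestCrossover:
    def test_unanimity(self, rng):
        x = rng.integers(0, 2, 50)
        assert np.array_equal(crossover(x, x, x, rng), x)

    def test_support_property(self, rng):
        x1 = rng.integers(0, 2, 200)
        x2 = rng.integers(0, 2, 200)
        x3 = rng.integers(0, 2, 200)
        out = crossover(x1, x2, x3, rng)
        assert np.all((out == x1) | (out == x2) | (out == x3))

    def test_source_fractions_near_one_third(self, rng):
        d = 30_000
        out = crossover(np.ones(d, dtype=int), np.zeros(d, dtype=int),
                        np.zeros(d, dtype=int), rng)
        p = 1 / 3
        sigma = np.sqrt(p * (1 - p) / d)
        assert abs(out.mean() - p) < 3 * sigma

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            crossover(np.ones(3), np.ones(3), np.ones(4), rng)


def _separable_block(n_per_class=12, d=6, informative=2, seed=0):
    """Deterministically separable two-class block on the first columns."""
    rng = np.random.default_rng(seed)
    X = rng.random((2 * n_per_class, d)) * 0.05
    y = np.array(["a"] * n_per_class + ["b"] * n_per_class)
    X[:n_per_class, :informative] += 1.0
    return X, y


class TestFitness:
    def test_all_zero_bits_returns_lambda(self):
        X, y = _separable_block()
        config = FitnessConfig(lambda_weight=0.9, cv_folds=2)
        objective = WrapperFitness(X, y, config)
        assert objective(np.zeros(6, dtype=bool)) == 0.9
        assert objective.flagged_empty == 1

    def test_separable_data_leaves_only_sparsity_term(self):
        X, y = _separable_block()
        config = FitnessConfig(lambda_weight=0.99, cv_folds=3)
        objective = WrapperFitness(X, y, config)
        bits = np.array([True, True] + [False] * 4)
        assert objective(bits) == pytest.approx(0.01 * 2 / 6, abs=1e-12)

    def test_noise_feature_costs_exactly_the_sparsity_increment(self):
        X, y = _separable_block()
        objective = WrapperFitness(X, y, FitnessConfig(cv_folds=3))
        perfect = np.array([True, True] + [False] * 4)
        with_noise = perfect.copy()
        with_noise[5] = True
        delta = objective(with_noise) - objective(perfect)
        assert delta == pytest.approx(0.01 / 6, abs=1e-12)

    def test_deterministic_given_seed(self, rng):
        X, y = _separable_block(seed=3)
        config = FitnessConfig(seed=5)
        f1 = WrapperFitness(X, y, config)
        f2 = WrapperFitness(X, y, config)
        bits = rng.random(6) < 0.5
        bits[0] = True
        assert f1(bits) == f2(bits)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FitnessConfig(lambda_weight=0.0)
        with pytest.raises(ValueError):
            FitnessConfig(cv_folds=1)
        with pytest.raises(ValueError):
            WrapperFitness(np.ones((4, 2)),
                           np.array(["a", "b", "c", "d"]))


class TestCentroidClassifier:
    def test_matches_explicit_distances(self, rng):
        X = rng.random((20, 4))
        y = rng.integers(0, 3, 20).astype(str)
        clf = CentroidClassifier().fit(X, y)
        classes = np.unique(y)
        centroids = np.array([X[y == c].mean(axis=0) for c in classes])
        Xt = rng.random((7, 4))
        expected = classes[np.argmin(
            ((Xt[:, None, :] - centroids[None]) ** 2).sum(-1), axis=1)]
        assert np.array_equal(clf.predict(Xt), expected)


class TestOptimize:
    def test_single_bit_search(self):
        alpha, _ = optimize(d=1, fitness_fn=lambda b: 0.0 if b[0] else 1.0,
                            pop_size=3, n_iterations=5, seed=0)
        assert list(alpha.bits) == [True]
        assert alpha.fitness == 0.0

    def test_popcount_minimisation_reaches_repaired_optimum(self):
        alpha, trace = optimize(d=8, fitness_fn=lambda b: float(b.sum()),
                                pop_size=10, n_iterations=50, seed=123)
        assert alpha.n_selected == 1  # repair forbids the empty set
        frame = trace.to_frame()
        assert (np.diff(frame["alpha_fitness"]) <= 0).all()

    def test_alpha_fitness_non_increasing(self, rng):
        weights = rng.random(12)
        alpha, trace = optimize(
            d=12, fitness_fn=lambda b: float(weights[b].sum()),
            pop_size=6, n_iterations=20, seed=7)
        fit = trace.to_frame()["alpha_fitness"].to_numpy()
        assert (np.diff(fit) <= 1e-15).all()
        assert alpha.fitness == fit[-1]

    def test_seed_determinism_and_sensitivity(self):
        fn = lambda b: float(b.sum())  # noqa: E731
        a1, t1 = optimize(8, fn, pop_size=5, n_iterations=10, seed=42)
        a2, t2 = optimize(8, fn, pop_size=5, n_iterations=10, seed=42)
        assert np.array_equal(a1.bits, a2.bits)
        assert t1.to_frame().equals(t2.to_frame())
        weights = np.linspace(0.1, 1.7, 8)
        wfn = lambda b: float(weights[b].sum())  # noqa: E731
        traces = [optimize(8, wfn, pop_size=5, n_iterations=10, seed=s)[1]
                  .to_frame().to_numpy().tolist() for s in (1, 2)]
        assert traces[0] != traces[1]

    def test_population_guard(self):
        with pytest.raises(ValueError):
            optimize(4, lambda b: 0.0, pop_size=2)
        with pytest.raises(ValueError):
            optimize(0, lambda b: 0.0)

    def test_binary_solution_counts_bits(self):
        sol = BinarySolution(bits=np.array([1, 0, 1, 1]), fitness=0.5)
        assert sol.n_selected == 3
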