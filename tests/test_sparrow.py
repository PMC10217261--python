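"""Sparrow search and the envelope-entropy fitness."""

import numpy as np
import pytest

from ecgdenoise import (SSAConfig, ssa_minimize, envelope_entropy, vmd_fitness,
                        optimize_vmd_params, VMD_PARAM_BOUNDS, Signal,
                        gen_test_signal, add_noise_at_snr, vmd_decompose,
                        VMDParams)


class TestEnvelopeEntropy:
    def test_pure_tone_is_maximal(self):
        n = 512
        tone = np.cos(2 * np.pi * 16 * np.arange(n) / n)  # bin-aligned: flat envelope
        assert envelope_entropy(tone) == pytest.approx(np.log(n), abs=1e-9)

    def test_impulse_is_near_degenerate(self):
        # the analytic-signal envelope of an impulse is concentrated but not a
        # perfect delta (the discrete Hilbert kernel has sidelobes), so the
        # entropy is far below the flat-envelope maximum without being zero
        n = 512
        imp = np.zeros(n)
        imp[n // 2] = 1.0
        assert envelope_entropy(imp) < 0.6 * np.log(n)

    def test_amplitude_modulation_lowers_entropy(self):
        n = 1024
        k = np.arange(n)
        carrier = np.cos(2 * np.pi * 64 * k / n)
        am = (1 + 0.8 * np.cos(2 * np.pi * 4 * k / n)) * carrier
        assert envelope_entropy(am) < envelope_entropy(carrier)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            envelope_entropy(np.zeros(64))
        with pytest.raises(ValueError):
            envelope_entropy(np.array([1.0, 2.0]))


class TestVmdFitness:
    def test_single_mode_equals_its_entropy(self, eq1_small):
        ms = vmd_decompose(eq1_small, VMDParams(K=1, alpha=2000))
        assert vmd_fitness(eq1_small, 1, 2000) == pytest.approx(
            envelope_entropy(ms.modes[0]))

    def test_finite_positive_over_search_box(self, eq1_small):
        for K in (2, 8, 15):
            for alpha in (500, 2750, 5000):
                f = vmd_fitness(eq1_small, K, alpha)
                assert np.isfinite(f) and f > 0

    def test_noise_raises_minimum_entropy(self):
        t = np.arange(1500) / 500.0
        clean = Signal(np.sin(2 * np.pi * 25 * t), 500.0)
        noisy = add_noise_at_snr(clean, 10.0, seed=3)
        assert vmd_fitness(clean, 2, 2000) <= vmd_fitness(noisy, 2, 2000)


def sphere(x):
    return float(x @ x)


class TestSsaMinimize:
    def test_sphere_quick(self):
        for seed in range(5):
            cfg = SSAConfig(bounds=((-5, 5), (-5, 5)), pop_size=30,
                            max_iter=100, seed=seed)
            r = ssa_minimize(sphere, cfg)
            assert r.best_fitness < 1e-2
            assert np.all(np.diff(r.convergence) <= 0)
            assert r.best_fitness == r.convergence[-1]
            assert np.all((r.best_position >= -5) & (r.best_position <= 5))

    def test_constant_objective(self):
        cfg = SSAConfig(bounds=((0, 1),), pop_size=5, max_iter=10, seed=0)
        r = ssa_minimize(lambda x: 3.5, cfg)
        assert r.best_fitness == 3.5
        assert np.all(r.convergence == 3.5)

    def test_quadratic_minimizer_located(self):
        cfg = SSAConfig(bounds=((0, 10),), pop_size=30, max_iter=100, seed=3)
        r = ssa_minimize(lambda x: float((x[0] - 3.0) ** 2), cfg)
        assert abs(r.best_position[0] - 3.0) < 0.05

    def test_integer_dims_rounded(self):
        cfg = SSAConfig(bounds=((0, 10), (0, 10)), pop_size=10, max_iter=20,
                        integer_dims=frozenset({1}), seed=2)
        r = ssa_minimize(lambda x: float((x[0] - 3.3) ** 2 + (x[1] - 6.6) ** 2), cfg)
        assert r.best_position[1] == round(r.best_position[1])
        assert r.best_position[1] == 7

    def test_nan_objective_rejected(self):
        cfg = SSAConfig(bounds=((0, 1),), pop_size=4, max_iter=3, seed=0)
        with pytest.raises(ValueError, match="non-finite"):
            ssa_minimize(lambda x: float("nan"), cfg)

    def test_same_seed_identical_result(self):
        cfg = SSAConfig(bounds=((-2, 2), (-2, 2)), pop_size=12, max_iter=30, seed=9)
        a = ssa_minimize(sphere, cfg)
        b = ssa_minimize(sphere, cfg)
        assert np.array_equal(a.best_position, b.best_position)
        assert np.array_equal(a.convergence, b.convergence)
        assert a.evaluations == b.evaluations


def _pso_reference(fn, bounds, pop, iters, seed):
    """Plain global-best PSO used as an independent sanity yardstick."""
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    d = lo.size
    x = lo + rng.random((pop, d)) * (hi - lo)
    v = np.zeros((pop, d))
    f = np.array([fn(p) for p in x])
    pbest, pbest_f = x.copy(), f.copy()
    g = int(np.argmin(f))
    gbest, gbest_f = x[g].copy(), f[g]
    for _ in range(iters):
        r1, r2 = rng.random((pop, d)), rng.random((pop, d))
        v = 0.7 * v + 1.5 * r1 * (pbest - x) + 1.5 * r2 * (gbest - x)
        x = np.clip(x + v, lo, hi)
        f = np.array([fn(p) for p in x])
        improved = f < pbest_f
        pbest[improved], pbest_f[improved] = x[improved], f[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest, gbest_f = pbest[g].copy(), pbest_f[g]
    return gbest_f


BENCH_FUNCTIONS = {
    "sphere": lambda x: float(x @ x),
    "rastrigin": lambda x: float(10 * x.size + np.sum(x**2 - 10 * np.cos(2 * np.pi * x))),
    "rosenbrock": lambda x: float(100 * (x[1] - x[0] ** 2) ** 2 + (1 - x[0]) ** 2),
    "ackley": lambda x: float(-20 * np.exp(-0.2 * np.sqrt(np.mean(x ** 2)))
                              - np.exp(np.mean(np.cos(2 * np.pi * x))) + 20 + np.e),
    "griewank": lambda x: float(1 + np.sum(x ** 2) / 4000
                                - np.prod(np.cos(x / np.sqrt(np.arange(1, x.size + 1))))),
}


@pytest.mark.parametrize("name", sorted(BENCH_FUNCTIONS))
def test_ssa_within_tenfold_of_pso(name):
    """Sanity (not superiority): SSA's median best on standard 2-D test
    functions is within 10x of a reference PSO at an equal budget."""
    fn = BENCH_FUNCTIONS[name]
    bounds = ((-5, 5), (-5, 5))
    ssa_best, pso_best = [], []
    for seed in range(20):
        cfg = SSAConfig(bounds=bounds, pop_size=30, max_iter=100, seed=seed)
        ssa_best.append(ssa_minimize(fn, cfg).best_fitness)
        pso_best.append(_pso_reference(fn, bounds, 30, 100, seed))
    floor = 1e-6  # below this both have numerically found the optimum
    assert np.median(ssa_best) <= max(10 * np.median(pso_best), floor)


class TestOptimizeVmdParams:
    def test_result_within_bounds(self, eq1_small):
        cfg = SSAConfig(bounds=VMD_PARAM_BOUNDS, pop_size=8, max_iter=4,
                        integer_dims=frozenset({0, 1}), seed=0)
        K, alpha, result = optimize_vmd_params(eq1_small, cfg)
        assert 2 <= K <= 15 and 500 <= alpha <= 5000
        assert result.convergence.size == 4
        assert np.all(np.diff(result.convergence) <= 0)

    def test_matches_coarse_grid_oracle(self, eq1_small):
        # brute force over the integer grid is the independent optimum
        grid_best = min(vmd_fitness(eq1_small, K, a)
                        for K in range(2, 16) for a in range(500, 5001, 500))
        cfg = SSAConfig(bounds=VMD_PARAM_BOUNDS, pop_size=30, max_iter=15,
                        integer_dims=frozenset({0, 1}), seed=1)
        _, _, result = optimize_vmd_params(eq1_small, cfg)
        assert result.best_fitness <= grid_best + 0.05
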