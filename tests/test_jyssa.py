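import math

import numpy as np
import pytest

from moldseed import JyssaConfig, optimize
from moldseed.jyssa import (
    Population,
    elite_reverse,
    follower_update,
    init_population,
    producer_update,
    scout_update,
)


def sphere(x):
    return float(np.sum(x * x))


def _pop(X, f, lower=-10.0, upper=10.0):
    X = np.asarray(X, dtype=float)
    f = np.asarray(f, dtype=float)
    i_best, i_worst = int(np.argmin(f)), int(np.argmax(f))
    return Population(
        X=X.copy(), f=f.copy(),
        xbest=X[i_best].copy(), fg=float(f[i_best]),
        xworst=X[i_worst].copy(), fw=float(f[i_worst]),
    )


def _cfg(**kw):
    defaults = dict(lower=[-10.0], upper=[10.0], pop_size=4, max_iter=10,
                    producer_fraction=0.25, rng_seed=0)
    defaults.update(kw)
    return JyssaConfig(**defaults)


class TestConfigValidation:
    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            JyssaConfig(lower=[1.0], upper=[1.0])

    def test_scout_fraction_range(self):
        with pytest.raises(ValueError):
            JyssaConfig(lower=[0.0], upper=[1.0], scout_fraction=0.5)
        JyssaConfig(lower=[0.0], upper=[1.0], scout_fraction=0.10)
        JyssaConfig(lower=[0.0], upper=[1.0], scout_fraction=0.20)

    def test_safety_threshold_range(self):
        with pytest.raises(ValueError):
            JyssaConfig(lower=[0.0], upper=[1.0], safety_threshold=0.4)


class TestInitPopulation:
    def test_in_box_and_role_counts(self):
        cfg = JyssaConfig(lower=[0.0, 0.0], upper=[1.0, 1.0], pop_size=30,
                          producer_fraction=0.2, rng_seed=1)
        pop = init_population(cfg, sphere)
        assert np.all(pop.X >= 0.0) and np.all(pop.X <= 1.0)
        assert np.all(np.isfinite(pop.f))
        assert int(np.sum(pop.roles == "producer")) == round(0.2 * 30)

    def test_constant_fitness_unchanged_by_elite_step(self):
        cfg = JyssaConfig(lower=[0.0, 0.0], upper=[1.0, 1.0], pop_size=20, rng_seed=2)
        rng_a = np.random.default_rng(99)
        rng_b = np.random.default_rng(99)
        pop_plain = init_population(
            JyssaConfig(lower=[0.0, 0.0], upper=[1.0, 1.0], pop_size=20,
                        rng_seed=2, elite_reverse_enabled=False),
            lambda x: 1.0, rng=rng_a)
        pop_elite = init_population(cfg, lambda x: 1.0, rng=rng_b)
        np.testing.assert_array_equal(pop_plain.X, pop_elite.X)

    def test_opposition_improves_mean_initial_fitness(self):
        corner = np.array([5.0, 5.0])
        fn = lambda x: float(np.sum((x - corner) ** 2))
        diffs = []
        for seed in range(50):
            kw = dict(lower=[-5.0, -5.0], upper=[5.0, 5.0], pop_size=20, rng_seed=seed)
            with_elite = init_population(JyssaConfig(**kw), fn)
            plain = init_population(
                JyssaConfig(**kw, elite_reverse_enabled=False), fn)
            diffs.append(plain.f.mean() - with_elite.f.mean())
        assert np.mean(diffs) >= 0.0


class TestProducerUpdate:
    def test_alarm_branch_zero_noise_is_identity(self, stub_rng_cls):
        cfg = _cfg(safety_threshold=0.8)
        pop = _pop([[2.0], [3.0], [-4.0], [5.0]], [1, 2, 3, 4])
        rng = stub_rng_cls(uniforms=[0.95], normals=[0.0])  # R2 >= ST, Q = 0
        before = pop.X.copy()
        producer_update(pop, cfg, rng)
        np.testing.assert_array_equal(pop.X, before)

    def test_safe_branch_contracts_magnitude(self, stub_rng_cls):
        cfg = _cfg()
        pop = _pop([[2.0], [3.0], [-4.0], [5.0]], [1, 2, 3, 4])
        rng = stub_rng_cls(uniforms=[0.1, 0.5])  # R2 < ST, alpha = 0.5
        producer_update(pop, cfg, rng)
        assert abs(pop.X[0, 0]) < 2.0

    def test_hand_computed_update(self, stub_rng_cls):
        # producer rank 1, alpha = 0.5, max_iter = 10:
        # x' = x * exp(-1 / (0.5 * 10)) = 2 * exp(-0.2)
        cfg = _cfg()
        pop = _pop([[2.0], [3.0], [-4.0], [5.0]], [1, 2, 3, 4])
        rng = stub_rng_cls(uniforms=[0.1, 0.5])
        producer_update(pop, cfg, rng)
        assert pop.X[0, 0] == pytest.approx(2.0 * math.exp(-0.2), abs=1e-12)
        # non-producers untouched
        np.testing.assert_array_equal(pop.X[1:], [[3.0], [-4.0], [5.0]])


class TestFollowerUpdate:
    def test_d1_plunder_reflection(self, stub_rng_cls):
        cfg = _cfg()
        pop = _pop([[0.0], [2.0], [4.0], [6.0]], [1, 2, 3, 4])
        # sign queue: 0 -> A = -1; normals for starving ranks 3 and 4
        rng = stub_rng_cls(normals=[0.5, -0.2], signs=[0])
        follower_update(pop, cfg, rng, xp=np.array([0.0]))
        assert pop.X[1, 0] == pytest.approx(0.0 - abs(2.0 - 0.0))   # xp - |x - xp|
        assert pop.X[2, 0] == pytest.approx(0.5 * math.exp((6.0 - 4.0) / 9.0))
        assert pop.X[3, 0] == pytest.approx(-0.2 * math.exp(0.0))

    def test_follower_at_xp_stays(self, stub_rng_cls):
        cfg = _cfg()
        pop = _pop([[1.0], [1.0], [4.0], [6.0]], [1, 2, 3, 4])
        rng = stub_rng_cls(normals=[0.0, 0.0], signs=[1])
        follower_update(pop, cfg, rng, xp=np.array([1.0]))
        assert pop.X[1, 0] == pytest.approx(1.0)

    def test_hand_computed_d2(self, stub_rng_cls):
        cfg = JyssaConfig(lower=[-10.0, -10.0], upper=[10.0, 10.0], pop_size=6,
                          max_iter=10, producer_fraction=0.2, rng_seed=0)
        X = [[0.0, 0.0], [1.0, 3.0], [2.0, -1.0], [4.0, 4.0], [5.0, -5.0], [6.0, 6.0]]
        pop = _pop(X, [1, 2, 3, 4, 5, 6])
        xp = np.array([0.5, -0.5])
        # ranks 2, 3 plunder (signs per dim), ranks 4-6 starve (one normal each)
        rng = stub_rng_cls(normals=[0.3, -0.4, 0.1], signs=[1, 0, 0, 1])
        follower_update(pop, cfg, rng, xp=xp)
        # rank 2 (row 1): A = (+1, -1); step = (|1-0.5| - |3+0.5|) / 2 = -1.5
        np.testing.assert_allclose(pop.X[1], xp + (-1.5), atol=1e-12)
        # rank 3 (row 2): A = (-1, +1); step = (-|2-0.5| + |-1+0.5|) / 2 = -0.5
        np.testing.assert_allclose(pop.X[2], xp + (-0.5), atol=1e-12)
        # rank 4 (row 3): Q = 0.3, xworst = (6, 6)
        expected = 0.3 * np.exp((np.array([6.0, 6.0]) - np.array([4.0, 4.0])) / 16.0)
        np.testing.assert_allclose(pop.X[3], expected, atol=1e-12)


class TestScoutUpdate:
    def test_at_worst_with_best_fitness_unchanged(self, stub_rng_cls):
        cfg = _cfg(scout_fraction=0.20)
        # row 0 is both the global best fitness AND sits at the worst position
        pop = _pop([[6.0], [2.0], [4.0], [6.0]], [1, 2, 3, 4])
        pop.xworst = np.array([6.0])
        rng = stub_rng_cls(choices=[0], uniforms=[0.75])
        scout_update(pop, cfg, rng)
        assert pop.X[0, 0] == pytest.approx(6.0)

    def test_at_best_position_stays(self, stub_rng_cls):
        cfg = _cfg(scout_fraction=0.20)
        pop = _pop([[1.0], [3.0], [4.0], [6.0]], [1, 2, 3, 4])
        pop.X[2] = pop.xbest.copy()   # scout at the best position, fi > fg
        rng = stub_rng_cls(choices=[2], normals=[1.7])
        scout_update(pop, cfg, rng)
        np.testing.assert_allclose(pop.X[2], pop.xbest)

    def test_hand_computed_step_toward_best(self, stub_rng_cls):
        cfg = _cfg(scout_fraction=0.20, beta_mean=1.0)
        pop = _pop([[1.0], [3.0], [4.0], [6.0]], [1, 2, 3, 4])
        rng = stub_rng_cls(choices=[1], normals=[0.5])  # beta = 1.0 + 0.5
        scout_update(pop, cfg, rng)
        assert pop.X[1, 0] == pytest.approx(1.0 + 1.5 * abs(3.0 - 1.0))


class TestEliteReverse:
    def test_single_elite_degenerate_box_no_change(self, stub_rng_cls):
        cfg = _cfg()
        pop = _pop([[3.0], [5.0], [7.0], [9.0]], [9, 25, 49, 81])
        rng = stub_rng_cls(uniforms=[0.2, 0.5])
        elite_reverse(pop, cfg, sphere, rng)
        assert pop.X[0, 0] == pytest.approx(3.0)
        assert pop.fg == pytest.approx(9.0)

    def test_greedy_acceptance_never_raises_fg(self):
        cfg = JyssaConfig(lower=[-5.0], upper=[5.0], pop_size=10,
                          elite_fraction=0.3, rng_seed=0)
        rng = np.random.default_rng(0)
        for trial in range(20):
            X = rng.uniform(-5, 5, (10, 1))
            f = np.array([abs(x[0]) for x in X])
            pop = _pop(X, f, lower=-5.0, upper=5.0)
            fg_before = pop.fg
            elite_reverse(pop, cfg, lambda x: abs(float(x[0])), rng)
            assert pop.fg <= fg_before

    def test_ablation_on_shifted_sphere(self):
        finals = {True: [], False: []}
        for seed in range(15):
            shift = np.random.default_rng(500 + seed).uniform(-3, 3, 2)
            fn = lambda x, c=shift: float(np.sum((x - c) ** 2))
            for flag in (True, False):
                cfg = JyssaConfig(lower=[-5.0, -5.0], upper=[5.0, 5.0],
                                  pop_size=20, max_iter=30, rng_seed=seed,
                                  elite_reverse_enabled=flag, patience=1000)
                finals[flag].append(optimize(fn, cfg).fun)
        assert np.mean(finals[True]) <= np.mean(finals[False])


class TestOptimize:
    def test_sphere_convergence(self):
        ok = 0
        for seed in range(10):
            cfg = JyssaConfig(lower=[-10.0, -10.0], upper=[10.0, 10.0],
                              pop_size=30, max_iter=100, rng_seed=seed)
            ok += optimize(sphere, cfg).fun <= 1e-3
        assert ok >= 9

    def test_constant_fitness_flat_history(self):
        cfg = JyssaConfig(lower=[0.0, 0.0], upper=[1.0, 1.0], pop_size=10,
                          max_iter=30, rng_seed=0, patience=1000)
        result = optimize(lambda x: 7.0, cfg)
        assert np.all(result.history == 7.0)

    def test_history_monotone_non_increasing(self):
        cfg = JyssaConfig(lower=[-5.0, -5.0], upper=[5.0, 5.0], pop_size=20,
                          max_iter=50, rng_seed=3)
        history = optimize(sphere, cfg).history
        assert np.all(np.diff(history) <= 0)

    def test_bitwise_reproducibility(self):
        cfg = JyssaConfig(lower=[-5.0, -5.0], upper=[5.0, 5.0], pop_size=15,
                          max_iter=40, rng_seed=11)
        r1, r2 = optimize(sphere, cfg), optimize(sphere, cfg)
        np.testing.assert_array_equal(r1.history, r2.history)
        np.testing.assert_array_equal(r1.x, r2.x)

    def test_positions_stay_in_bounds(self):
        lo, hi = np.array([-2.0, -3.0]), np.array([2.0, 3.0])
        seen = []
        fn = lambda x: (seen.append(x.copy()), float(np.sum(x**2)))[1]
        cfg = JyssaConfig(lower=lo, upper=hi, pop_size=10, max_iter=20, rng_seed=5)
        optimize(fn, cfg)
        all_x = np.array(seen)
        assert np.all(all_x >= lo - 1e-12) and np.all(all_x <= hi + 1e-12)

    def test_non_finite_fitness_reports_position(self):
        def bad(x):
            return float("nan") if x[0] > 0 else float(np.sum(x**2))
        cfg = JyssaConfig(lower=[-1.0, -1.0], upper=[1.0, 1.0], pop_size=10,
                          max_iter=5, rng_seed=0)
        with pytest.raises(ValueError, match="position"):
            optimize(bad, cfg)

    def test_discrete_lattice_matches_grid_search(self):
        ok = 0
        for seed in range(10):
            r = np.random.default_rng(1000 + seed)
            i0, j0 = r.integers(0, 20, 2)

            def fn(x, i0=i0, j0=j0):
                i = int(np.clip(round(x[0]), 0, 19))
                j = int(np.clip(round(x[1]), 0, 19))
                return float((i - i0) ** 2 + (j - j0) ** 2)

            # brute-force oracle over all 400 cells
            grid = [(fn([i, j]), (i, j)) for i in range(20) for j in range(20)]
            best_cell = min(grid)[1]
            cfg = JyssaConfig(lower=[0.0, 0.0], upper=[19.0, 19.0],
                              pop_size=30, max_iter=100, rng_seed=seed)
            result = optimize(fn, cfg)
            ok += (round(result.x[0]), round(result.x[1])) == best_cell
        assert ok >= 9
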