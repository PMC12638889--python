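"""Unit and property tests for the COOT/ICOOT movement operators and loops."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cootseg.optimizer import (
    Bounds,
    OptimizerConfig,
    chain_movement,
    compute_b,
    follow_leader,
    init_population,
    leader_movement,
    levy_perturb,
    levy_sigma,
    levy_step,
    levy_step_from_draws,
    opposite,
    quasi_opposite,
    random_movement,
    run_coot,
    run_icoot,
    select_leader_index,
)
from cootseg.synthetic import test_function

B01 = Bounds(lb=0.0, ub=255.0, dim=1)


class TestBoundsAndConfig:
    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            Bounds(lb=0.0, ub=0.0, dim=1)
        with pytest.raises(ValueError):
            Bounds(lb=0.0, ub=1.0, dim=0)

    def test_clip_clamps_to_nearest_bound(self):
        b = Bounds(lb=[0.0, -1.0], ub=[1.0, 1.0], dim=2)
        assert np.allclose(b.clip(np.array([2.0, -3.0])), [1.0, -1.0])

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_agents": 1},
            {"max_iter": 0},
            {"beta": 0.0},
            {"beta": 2.5},
            {"p_follow": 1.5},
            {"jumping_rate": -0.1},
            {"mode": "other"},
            {"leader_fraction": 0.99, "n_agents": 2},  # leaders would be >= N
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            OptimizerConfig(**kwargs)


class TestMovementOperators:
    @pytest.mark.parametrize(
        "ic,imax,expected", [(0, 100, 1.0), (100, 100, 0.0), (50, 100, 0.5)]
    )
    def test_damping_factor(self, ic, imax, expected):
        assert compute_b(ic, imax) == pytest.approx(expected)

    def test_damping_factor_invalid(self):
        with pytest.raises(ValueError):
            compute_b(0, 0)
        with pytest.raises(ValueError):
            compute_b(5, 4)

    @pytest.mark.parametrize(
        "pos,b,r,r1,expected",
        [
            ([10.0], 0.0, [100.0], 1.0, [10.0]),  # zero step
            ([10.0], 1.0, [100.0], 1.0, [100.0]),  # full step lands on R
            ([0.0], 0.5, [100.0], 1.0, [50.0]),
        ],
    )
    def test_random_movement_fixed_draws(self, pos, b, r, r1, expected):
        out = random_movement(np.array(pos), b, B01, np.array(r), r1)
        assert np.allclose(out, expected)

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([2.0, 4.0], [6.0, 8.0], [4.0, 6.0]),
            ([3.0], [3.0], [3.0]),
            ([0.0], [255.0], [127.5]),
        ],
    )
    def test_chain_movement(self, a, b, expected):
        assert np.allclose(chain_movement(np.array(a), np.array(b)), expected)

    def test_chain_movement_dim_mismatch(self):
        with pytest.raises(ValueError):
            chain_movement(np.zeros(2), np.zeros(3))

    @pytest.mark.parametrize("j,nl,expected", [(5, 3, 3), (3, 3, 1), (0, 4, 1)])
    def test_leader_label(self, j, nl, expected):
        assert select_leader_index(j, nl) == expected

    def test_leader_label_invalid(self):
        with pytest.raises(ValueError):
            select_leader_index(0, 0)

    @pytest.mark.parametrize(
        "r2,r3,leader,coot,expected",
        [
            (0.5, 0.0, 10.0, 4.0, 16.0),  # 2L - C
            (0.0, 0.3, 10.0, 4.0, 10.0),  # leader exactly
            (0.7, 0.25, 10.0, 4.0, 10.0),  # cos(pi/2) = 0
        ],
    )
    def test_follow_leader_fixed_draws(self, r2, r3, leader, coot, expected):
        out = follow_leader(np.array([coot]), np.array([leader]), r2, r3, B01)
        assert np.allclose(out, expected)

    @pytest.mark.parametrize(
        "r5,b,r4,r3,g,l,expected_preclip",
        [
            (0.3, 1.0, 1.0, 0.0, 10.0, 4.0, 16.0),
            (0.7, 1.0, 1.0, 0.0, 10.0, 4.0, -4.0),
            (0.3, 1.0, 0.0, 0.9, 10.0, 4.0, 10.0),  # R4=0 -> gBest exactly
        ],
    )
    def test_leader_movement_fixed_draws(self, r5, b, r4, r3, g, l, expected_preclip):
        out = leader_movement(np.array([l]), np.array([g]), b, r3, r4, r5, B01)
        assert np.allclose(out, np.clip(expected_preclip, 0.0, 255.0))


class TestLevy:
    def test_sigma_closed_form_beta_one(self):
        assert levy_sigma(1.0) == pytest.approx(1.0, abs=1e-12)

    def test_sigma_matches_gamma_oracle(self):
        # independent evaluation through math.lgamma
        beta = 1.5
        num = math.exp(math.lgamma(1 + beta)) * math.sin(math.pi * beta / 2)
        den = math.exp(math.lgamma((1 + beta) / 2)) * beta * 2 ** ((beta - 1) / 2)
        expected = (num / den) ** (1 / beta)
        assert levy_sigma(beta) == pytest.approx(expected, abs=1e-12)
        assert levy_sigma(beta) == pytest.approx(0.6966, abs=1e-4)

    def test_sigma_invalid_beta(self):
        with pytest.raises(ValueError):
            levy_sigma(0.0)

    def test_step_from_fixed_draws(self):
        assert np.allclose(levy_step_from_draws(np.zeros(3), np.ones(3)), 0.0)
        out = levy_step_from_draws(np.ones(2), np.ones(2), beta=1.5)
        assert np.allclose(out, 0.01 * levy_sigma(1.5))

    def test_heavy_tail(self, rng):
        steps = np.concatenate([levy_step(1000, 1.5, rng) for _ in range(100)])
        a = np.abs(steps)
        m, s = steps.mean(), steps.std()
        kurtosis = np.mean(((steps - m) / s) ** 4) - 3.0
        assert kurtosis > 10
        assert a.max() > 50 * np.median(a)

    def test_perturb_modes(self, rng):
        b = Bounds(lb=-1.0, ub=1.0, dim=2)
        x = np.array([0.1, -0.2])
        assert np.allclose(levy_perturb(x, 0.0, 1.5, b, rng), x)  # alpha = 0
        out = levy_perturb(x, 1.0, 1.5, b, rng, mode="multiplicative")
        assert b.contains(out)
        with pytest.raises(ValueError):
            levy_perturb(x, 1.0, 1.5, b, rng, mode="bogus")


class TestOpposition:
    @pytest.mark.parametrize(
        "lb,ub,x,expected", [(0, 255, 200, 55), (2, 10, 2, 10), (0, 10, 5, 5)]
    )
    def test_opposite_examples(self, lb, ub, x, expected):
        b = Bounds(lb=float(lb), ub=float(ub), dim=1)
        assert np.allclose(opposite(np.array([float(x)]), b), expected)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=255.0, allow_nan=False))
    def test_opposite_is_involution(self, x):
        b = Bounds(lb=0.0, ub=255.0, dim=1)
        xx = np.array([x])
        assert np.allclose(opposite(opposite(xx, b), b), xx, atol=1e-12)

    def test_quasi_opposite_fixed_draw(self):
        b = Bounds(lb=0.0, ub=1.0, dim=1)
        out = quasi_opposite(np.array([0.2]), b, np.array([0.0]))
        assert np.allclose(out, 0.5)
        # degenerate: x at the centre collapses the interval
        out = quasi_opposite(np.array([0.5]), b, np.array([0.7]))
        assert np.allclose(out, 0.5)

    def test_quasi_opposite_containment(self, rng):
        b = Bounds(lb=0.0, ub=1.0, dim=1)
        x = np.array([0.2])
        draws = rng.random((100_000, 1))
        outs = np.array([quasi_opposite(x, b, u)[0] for u in draws[:2000]])
        # vectorised equivalent for the full 1e5 sweep
        lo, hi = 0.5, 0.8
        vals = lo + draws[:, 0] * (hi - lo)
        assert outs.min() >= lo - 1e-12 and outs.max() <= hi + 1e-12
        assert vals.min() >= lo and vals.max() <= hi


class TestRuns:
    def test_init_population_sampling_law(self):
        cfg = OptimizerConfig(n_agents=100, seed=7)
        b = Bounds(lb=0.0, ub=255.0, dim=3)
        pop = init_population(cfg, b)
        assert pop.positions.shape == (100, 3)
        assert pop.positions.min() >= 0.0 and pop.positions.max() <= 255.0
        assert abs(pop.positions.mean() - 127.5) < 10.0
        assert pop.n_leaders == 10

    def test_init_population_leaders_ranked_first(self):
        cfg = OptimizerConfig(n_agents=20, seed=3, mode="minimize")
        b = Bounds(lb=-10.0, ub=10.0, dim=4)
        pop = init_population(cfg, b, objective=test_function("sphere", 4))
        assert np.all(np.diff(pop.fitness) >= 0)

    def test_coot_finds_sphere_optimum(self):
        cfg = OptimizerConfig(n_agents=30, max_iter=300, seed=1, mode="minimize")
        res = run_coot(test_function("sphere", 2), Bounds(-100.0, 100.0, 2), cfg)
        assert res.best_fitness <= 1e-4
        assert len(res.trace) == 300

    def test_single_iteration_trace(self):
        cfg = OptimizerConfig(n_agents=5, max_iter=1, seed=0, mode="minimize")
        res = run_coot(test_function("sphere", 2), Bounds(-1.0, 1.0, 2), cfg)
        assert res.trace.shape == (1,)

    @pytest.mark.parametrize("runner", [run_coot, run_icoot])
    def test_determinism(self, runner):
        cfg = OptimizerConfig(n_agents=15, max_iter=40, seed=11, mode="minimize")
        b = Bounds(-5.12, 5.12, 4)
        f = test_function("rastrigin", 4)
        r1, r2 = runner(f, b, cfg), runner(f, b, cfg)
        assert np.array_equal(r1.trace, r2.trace)
        assert np.array_equal(r1.best_position, r2.best_position)
        assert r1.best_fitness == r2.best_fitness

    @pytest.mark.parametrize("mode", ["minimize", "maximize"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_trace_is_monotone(self, mode, seed):
        f = test_function("rastrigin", 3)
        obj = f if mode == "minimize" else (lambda x: -f(x))
        cfg = OptimizerConfig(n_agents=12, max_iter=60, seed=seed, mode=mode)
        res = run_icoot(obj, Bounds(-5.12, 5.12, 3), cfg)
        diffs = np.diff(res.trace)
        assert np.all(diffs >= 0) if mode == "maximize" else np.all(diffs <= 0)

    def test_icoot_reduces_to_coot_without_extras(self):
        cfg = OptimizerConfig(
            n_agents=20, max_iter=50, seed=3, mode="minimize",
            p_levy=0.0, jumping_rate=0.0,
        )
        f = test_function("rosenbrock", 5)
        b = Bounds(-5.0, 10.0, 5)
        a, c = run_coot(f, b, cfg), run_icoot(f, b, cfg)
        assert np.array_equal(a.trace, c.trace)
        assert np.array_equal(a.best_position, c.best_position)

    def test_icoot_sphere_high_dim_reliability(self):
        hits = 0
        for seed in range(20):
            cfg = OptimizerConfig(n_agents=30, max_iter=1000, seed=seed, mode="minimize")
            res = run_icoot(test_function("sphere", 10), Bounds(-100.0, 100.0, 10), cfg)
            assert res.best_fitness >= 0.0
            if res.best_fitness <= 1e-2:
                hits += 1
        assert hits >= 18  # >= 90% of runs

    def test_non_finite_objective_raises_with_context(self):
        cfg = OptimizerConfig(n_agents=5, max_iter=2, seed=0, mode="minimize")
        with pytest.raises(ValueError, match="non-finite"):
            run_coot(lambda x: float("nan"), Bounds(0.0, 1.0, 2), cfg)

    def test_boundary_containment_of_best(self):
        cfg = OptimizerConfig(n_agents=10, max_iter=30, seed=5, mode="minimize")
        b = Bounds(-0.5, 0.5, 3)
        res = run_icoot(test_function("sphere", 3), b, cfg)
        assert b.contains(res.best_position)
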