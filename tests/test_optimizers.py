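import json
import math
from pathlib import Path

import numpy as np
import pytest

from msfs.optimizers import (
    ALGORITHMS,
    SCAConfig,
    SHOConfig,
    _brownian_move,
    _predation_failure,
    _predation_success,
    _sca_move,
    _spiral_move,
    breeding_update,
    initialize_population,
    levy_step,
    mantegna_sigma,
    movement_update,
    optimize,
    predation_update,
    sca_position_update,
    sho_optimize,
    shosca_optimize,
)
from msfs.synthetic_data import sphere_objective

PILOT = json.loads((Path(__file__).parent / "fixtures" / "sphere_pilot.json").read_text())


class _FakeRng:
    """Deterministic generator stub feeding prescribed draws to operators."""

    def __init__(self, normals=(), uniforms=()):
        self._normals = list(normals)
        self._uniforms = list(uniforms)

    def standard_normal(self, size=None):
        if size is None:
            return self._normals.pop(0)
        return np.full(size, self._normals.pop(0))

    def random(self, size=None):
        if size is None:
            return self._uniforms.pop(0)
        return np.full(size, self._uniforms.pop(0))

    def permutation(self, n):
        return np.arange(n)


class TestInitialization:
    def test_population_shape_bounds_and_seed(self):
        a = initialize_population(10, 286, np.random.default_rng(1))
        b = initialize_population(10, 286, np.random.default_rng(1))
        assert a.shape == (10, 286)
        assert a.min() >= 0.0 and a.max() <= 1.0
        np.testing.assert_array_equal(a, b)

    def test_tiny_population_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            initialize_population(3, 5, np.random.default_rng(0))

    def test_collapsed_bounds_give_constant_population(self):
        pop = initialize_population(4, 3, np.random.default_rng(0), lb=0.3, ub=0.3)
        np.testing.assert_allclose(pop, 0.3)


class TestLevy:
    def test_sigma_values_for_default_exponent(self):
        assert mantegna_sigma(1.5) == pytest.approx(0.6966, abs=2e-4)
        assert mantegna_sigma(1.5, literal=True) == pytest.approx(0.5813, abs=2e-4)

    def test_zero_numerator_draw_gives_zero_step(self):
        assert levy_step(SHOConfig(), _FakeRng(normals=[0.0, 1.3])) == 0.0

    def test_step_linear_in_scale(self):
        s1 = levy_step(SHOConfig(s=0.01), _FakeRng(normals=[0.7, -1.1]))
        s2 = levy_step(SHOConfig(s=0.02), _FakeRng(normals=[0.7, -1.1]))
        assert s2 == pytest.approx(2 * s1)

    def test_tiny_denominator_is_floored(self):
        step = levy_step(SHOConfig(), _FakeRng(normals=[1.0, 0.0]))
        assert math.isfinite(step)


class TestMovementKernels:
    def test_spiral_collapses_without_levy_step(self):
        x = np.array([0.2, 0.8])
        np.testing.assert_array_equal(_spiral_move(x, np.array([0.5, 0.5]), 0.0, 1, 1, 1), x)

    def test_brownian_collapses_without_drift_draw(self):
        x = np.array([0.3])
        np.testing.assert_array_equal(
            _brownian_move(x, np.array([0.9]), 0.0, 0.05, np.array([0.4])), x
        )

    def test_brownian_hand_value_one_dimensional(self):
        beta = 1.0 / math.sqrt(2 * math.pi)  # normal density at 0
        out = _brownian_move(np.array([0.2]), np.array([0.8]), 1.0, 0.05, np.array([beta]))
        assert out[0] == pytest.approx(0.19762, abs=5e-6)

    def test_movement_update_stays_in_bounds(self):
        rng = np.random.default_rng(8)
        elite = np.full(6, 0.5)
        for _ in range(200):
            out = movement_update(rng.random(6), elite, SHOConfig(), rng)
            assert out.min() >= 0.0 and out.max() <= 1.0


class TestPredation:
    def test_success_branch_at_start_returns_elite(self):
        elite = np.array([0.4, 0.9])
        np.testing.assert_allclose(_predation_success(np.array([0.1, 0.2]), elite, 1.0, 0.0), elite)

    def test_success_branch_at_end_proposes_origin(self):
        out = _predation_success(np.array([0.1, 0.2]), np.array([0.4, 0.9]), 0.0, 0.7)
        np.testing.assert_allclose(out, 0.0)

    def test_failure_branch_at_end_keeps_position(self):
        x1 = np.array([0.3, 0.6])
        np.testing.assert_allclose(_predation_failure(x1, np.array([0.9, 0.9]), 0.0, 0.0), x1)

    def test_zero_horizon_rejected(self):
        with pytest.raises(ValueError, match="T"):
            predation_update(np.zeros(2), np.zeros(2), 0, 0, SHOConfig(), np.random.default_rng(0))

    def test_update_respects_bounds(self):
        rng = np.random.default_rng(9)
        for t in (0, 25, 50):
            out = predation_update(rng.random(5), rng.random(5), t, 50, SHOConfig(), rng)
            assert out.min() >= 0.0 and out.max() <= 1.0


class TestSCAUpdate:
    def test_sine_branch_hand_value(self):
        out = _sca_move(
            np.array([0.4]), np.array([0.6]), 1.0,
            np.array([math.pi / 2]), np.array([1.0]), np.array([0.0]),
        )
        assert out[0] == pytest.approx(0.6)

    def test_final_iteration_amplitude_vanishes(self):
        x = np.random.default_rng(2).random(7)
        out = sca_position_update(x, np.full(7, 0.5), 50, 50, SCAConfig(), np.random.default_rng(0))
        np.testing.assert_allclose(out, x)

    def test_update_respects_bounds(self):
        rng = np.random.default_rng(10)
        for t in (0, 10, 49):
            out = sca_position_update(rng.random(6), rng.random(6), t, 50, SCAConfig(), rng)
            assert out.min() >= 0.0 and out.max() <= 1.0


class TestBreeding:
    def test_offspring_count_and_convex_hull(self):
        rng = np.random.default_rng(4)
        pop = rng.random((7, 5))
        fitness = rng.random(7)
        kids = breeding_update(pop, fitness, rng)
        assert kids.shape == (3, 5)
        assert kids.min() >= pop.min() - 1e-12 and kids.max() <= pop.max() + 1e-12

    def test_unit_mixing_weight_returns_father(self):
        pop = np.array([[0.1] * 3, [0.2] * 3, [0.7] * 3, [0.9] * 3])
        fitness = np.array([1.0, 2.0, 3.0, 4.0])
        kids = breeding_update(pop, fitness, _FakeRng(uniforms=[1.0]))
        np.testing.assert_allclose(kids, pop[:2])  # fathers = best ceil(P/2)

    def test_zero_mixing_weight_returns_mother(self):
        pop = np.array([[0.1] * 3, [0.2] * 3, [0.7] * 3, [0.9] * 3])
        kids = breeding_update(pop, np.array([1.0, 2.0, 3.0, 4.0]), _FakeRng(uniforms=[0.0]))
        np.testing.assert_allclose(kids, pop[2:])

    def test_unevaluated_population_rejected(self):
        with pytest.raises(RuntimeError, match="fitness"):
            breeding_update(np.zeros((4, 2)), np.array([0.1, np.nan, 0.2, 0.3]),
                            np.random.default_rng(0))


class TestEngine:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_trace_non_increasing_and_positions_legal(self, algorithm):
        checked = sphere_objective(6)

        def objective(x):
            assert np.all(x >= 0.0) and np.all(x <= 1.0)
            return checked(x)

        res = optimize(algorithm, objective, P=8, dim=6, T=20, rng=3)
        assert res.trace.shape == (20,)
        assert np.all(np.diff(res.trace) <= 0)
        assert res.trace[-1] == res.best_fitness

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_bitwise_reproducible_from_seed(self, algorithm):
        a = optimize(algorithm, sphere_objective(5), P=6, dim=5, T=15, rng=11)
        b = optimize(algorithm, sphere_objective(5), P=6, dim=5, T=15, rng=11)
        np.testing.assert_array_equal(a.trace, b.trace)
        np.testing.assert_array_equal(a.best_position, b.best_position)

    def test_zero_iterations_returns_best_of_initial_population(self):
        calls = []

        def objective(x):
            calls.append(x.copy())
            return float(np.sum(x))

        res = sho_optimize(objective, P=5, dim=3, T=0, rng=1)
        assert len(calls) == 5 and res.evaluations == 5
        assert res.best_fitness == pytest.approx(min(float(np.sum(c)) for c in calls))
        assert res.trace.size == 0

    def test_evaluation_budget_matches_protocol(self):
        res = sho_optimize(sphere_objective(4), P=6, dim=4, T=10, rng=0)
        assert res.evaluations == 6 + 10 * (6 + 3)  # init + per-iter agents + offspring

    def test_constant_objective_is_harmless(self):
        res = shosca_optimize(lambda x: 1.0, P=5, dim=3, T=10, rng=0)
        np.testing.assert_allclose(res.trace, 1.0)

    def test_non_finite_objective_is_reported(self):
        with pytest.raises(RuntimeError, match="non-finite"):
            sho_optimize(lambda x: float("nan"), P=4, dim=2, T=2, rng=0)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            shosca_optimize(sphere_objective(3), P=4, dim=3, T=2, variant="bogus", rng=0)

    def test_single_iteration_preserves_population_size(self):
        res = shosca_optimize(sphere_objective(4), P=7, dim=4, T=1, rng=5)
        assert res.best_position.shape == (4,)
        assert res.evaluations == 7 + 7 + 3  # init + updated + offspring


class TestSphereCompetence:
    """Convergence levels pinned by the committed one-shot pilot."""

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_final_fitness_within_pilot_bound(self, algorithm):
        bound = PILOT["bounds"][algorithm]
        finals = [
            optimize(algorithm, sphere_objective(10), P=10, dim=10, T=50, rng=s).best_fitness
            for s in PILOT["seeds"]
        ]
        assert sum(f <= bound for f in finals) >= 9

    def test_hybrid_dominates_plain_sho_on_sphere(self):
        obj = sphere_objective(10)
        sho = np.mean([sho_optimize(obj, T=50, rng=s).best_fitness for s in range(10)])
        hybrid = np.mean(
            [shosca_optimize(obj, T=50, rng=s).best_fitness for s in range(10)]
        )
        assert hybrid <= sho
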