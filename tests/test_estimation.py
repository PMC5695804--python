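"""Training objectives, optimizers, Pareto machinery, and AIC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from complement_rom import (
    Condition,
    Trajectory,
    aic_score,
    default_objectives,
    dops_minimize,
    pareto_anneal,
    pareto_rank,
    random_parameter_control,
    scale_measurements,
)
from complement_rom.estimation import (
    DegenerateScalingError,
    MeasurementTable,
    TrainingObjective,
    objective,
)
from complement_rom.synthetic import SyntheticProtocol, generate


class TestScaleMeasurements:
    def test_simple_series(self):
        assert scale_measurements([1.0, 3.0, 5.0]) == pytest.approx([0, 0.5, 1])

    def test_two_points(self):
        assert scale_measurements([0.0, 10.0]) == pytest.approx([0.0, 1.0])

    def test_affine_invariance(self):
        base = np.array([2.0, 7.0, 4.0, 9.0])
        assert scale_measurements(3.5 * base + 11.0) == pytest.approx(
            scale_measurements(base)
        )

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateScalingError):
            scale_measurements([4.0, 4.0, 4.0])


def _table(times, values, dose=1.0, species="C3a"):
    import pandas as pd

    return MeasurementTable(
        pd.DataFrame(
            {
                "condition": f"zymosan_{dose:g}",
                "dose_mg_ml": dose,
                "species": species,
                "time": times,
                "value": values,
                "units": "nM",
            }
        )
    )


def _traj(times, values, species="C3a"):
    return Trajectory(np.asarray(times), np.asarray(values)[:, None],
                      (species,), Condition(initiator_dose=1.0))


class TestObjective:
    def test_perfect_fit_is_zero(self, model, nominal):
        data = generate(model, nominal, SyntheticProtocol(sigma=0.0))
        obj = TrainingObjective("O2", 1.0)
        assert objective(nominal, model, data, obj) == pytest.approx(0.0, abs=1e-8)

    def test_scale_term_isolates_amplitude_error(self):
        times = [1.0, 2.0, 3.0]
        measured = [10.0, 20.0, 40.0]
        doubled = _traj(times, [20.0, 40.0, 80.0])
        obj = TrainingObjective("O2", 1.0, species=("C3a",))
        value = objective(None, None, _table(times, measured), obj, traj=doubled)
        # identical shape: only the scale term remains, ((40-80)/40)^2 = 1
        assert value == pytest.approx(1.0)

    def test_hand_computed_toy(self):
        # measurements [2, 6, 4] -> scaled [0, 1, 0.5]
        # simulation   [1, 2, 5] -> scaled [0, 0.25, 1]
        # shape term: 0 + 0.75^2 + 0.5^2 = 0.8125
        # scale term: ((6 - 5)/6)^2 = 1/36
        times = [0.0, 1.0, 2.0]
        value = objective(
            None, None, _table(times, [2.0, 6.0, 4.0]),
            TrainingObjective("O1", 1.0, species=("C3a",)),
            traj=_traj(times, [1.0, 2.0, 5.0]),
        )
        assert value == pytest.approx(0.8125 + 1.0 / 36.0)

    def test_unit_change_only_moves_scale_term(self):
        times = [0.0, 1.0, 2.0]
        measured = np.array([2.0, 6.0, 4.0])
        sim = [1.0, 2.0, 5.0]
        obj = TrainingObjective("O1", 1.0, species=("C3a",))
        a = objective(None, None, _table(times, measured), obj,
                      traj=_traj(times, sim))
        b = objective(None, None, _table(times, measured * 1000.0), obj,
                      traj=_traj(times, sim))
        # shape term (0.8125) is unit-invariant; scale term changes
        assert abs((a - 0.8125) - 1.0 / 36.0) < 1e-12
        assert b - 0.8125 == pytest.approx(((6000 - 5) / 6000) ** 2)


class TestDopsMinimize:
    BOUNDS = np.array([[-5.0, 5.0]] * 5)

    @staticmethod
    def sphere(x):
        return float(np.sum(x**2))

    def test_sphere_smoke_oracle(self):
        result = dops_minimize(self.sphere, self.BOUNDS, budget=2000, seed=7,
                               x0=np.full(5, 4.0))
        assert result.fun < 1e-2

    def test_budget_one_returns_single_sample(self):
        result = dops_minimize(self.sphere, self.BOUNDS, budget=1, seed=0)
        assert result.n_eval == 1
        assert np.allclose(result.x, 0.0)  # center of bounds

    def test_deterministic_under_seed(self):
        a = dops_minimize(self.sphere, self.BOUNDS, budget=500, seed=3)
        b = dops_minimize(self.sphere, self.BOUNDS, budget=500, seed=3)
        assert a.fun == b.fun and np.array_equal(a.x, b.x)

    def test_respects_bounds(self):
        seen = []

        def spy(x):
            seen.append(x.copy())
            return self.sphere(x)

        bounds = np.array([[1.0, 2.0]] * 3)
        dops_minimize(spy, bounds, budget=300, seed=1)
        arr = np.stack(seen)
        assert arr.min() >= 1.0 and arr.max() <= 2.0

    def test_invalid_budget(self):
        with pytest.raises(ValueError):
            dops_minimize(self.sphere, self.BOUNDS, budget=0, seed=0)


class TestParetoRank:
    def test_strict_domination(self):
        assert pareto_rank([(1, 2), (2, 3)]).tolist() == [0, 1]

    def test_trade_off_both_on_front(self):
        assert pareto_rank([(1, 3), (3, 1)]).tolist() == [0, 0]

    def test_three_layers(self):
        ranks = pareto_rank([(0, 0), (1, 1), (2, 2), (0, 3)])
        # (0,0) dominates everything; (1,1) and (0,3) trade off in layer 1
        assert ranks.tolist() == [0, 1, 2, 1]

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(42)
        F = rng.random((20, 2))
        ranks = pareto_rank(F)

        def dominates(a, b):
            return np.all(a <= b) and np.any(a < b)

        remaining = set(range(20))
        layer = 0
        while remaining:
            front = {
                i for i in remaining
                if not any(dominates(F[j], F[i]) for j in remaining if j != i)
            }
            for i in front:
                assert ranks[i] == layer
            remaining -= front
            layer += 1

    @given(st.lists(st.tuples(st.floats(0, 1), st.floats(0, 1)),
                    min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_rank_zero_mutually_nondominated(self, vectors):
        F = np.asarray(vectors)
        ranks = pareto_rank(F)
        front = np.flatnonzero(ranks == 0)
        assert front.size >= 1
        for i in front:
            for j in front:
                if i != j:
                    assert not (np.all(F[j] <= F[i]) and np.any(F[j] < F[i]))


class TestParetoAnneal:
    @staticmethod
    def bowls(x):
        """Two 1-D quadratic bowls with minima at -1 and +1."""
        return np.array([(x[0] - 1.0) ** 2, (x[0] + 1.0) ** 2])

    def test_front_spans_between_single_objective_optima(self):
        xs, F, _ = pareto_anneal(self.bowls, np.array([[-3.0, 3.0]]),
                                 x0=np.array([0.0]), iterations=800, seed=5)
        ranks = pareto_rank(F)
        front = np.stack(xs)[ranks == 0, 0]
        # the true Pareto set is the segment [-1, 1]
        assert front.min() < -0.5 and front.max() > 0.5
        assert np.all(front > -1.2) and np.all(front < 1.2)

    def test_deterministic_under_seed(self):
        a = pareto_anneal(self.bowls, np.array([[-3.0, 3.0]]),
                          x0=np.array([0.0]), iterations=200, seed=9)
        b = pareto_anneal(self.bowls, np.array([[-3.0, 3.0]]),
                          x0=np.array([0.0]), iterations=200, seed=9)
        assert np.array_equal(np.stack(a[0]), np.stack(b[0]))
        assert np.array_equal(a[1], b[1])

    def test_zero_temperature_limit_rejects_dominated(self):
        # with T -> 0 and every neighbor strictly dominated by the start,
        # the Metropolis channel closes and nothing is accepted
        calls = {"n": 0}

        def worsening(x):
            calls["n"] += 1
            return (np.array([1.0, 2.0]) if calls["n"] == 1
                    else np.array([2.0, 3.0]))

        xs, F, n_accepted = pareto_anneal(
            worsening, np.array([[-1.0, 1.0]]), x0=np.array([0.0]),
            iterations=100, seed=0, t0=1e-300,
        )
        assert n_accepted == 0
        assert len(xs) == 1

    def test_archive_ranks_satisfy_layered_definition(self):
        rng = np.random.default_rng(1)

        def noisy(x):
            return np.array([x[0] ** 2 + 0.1 * rng.random(),
                             (x[0] - 2) ** 2 + 0.1 * rng.random()])

        xs, F, _ = pareto_anneal(noisy, np.array([[-1.0, 3.0]]),
                                 x0=np.array([1.0]), iterations=300, seed=2)
        ranks = pareto_rank(F)
        brute = pareto_rank(np.asarray(F))
        assert np.array_equal(ranks, brute)
        front = np.flatnonzero(ranks == 0)
        for i in front:
            assert not any(
                np.all(F[j] <= F[i]) and np.any(F[j] < F[i])
                for j in range(len(F)) if j != i
            )


class TestAic:
    def test_parameter_penalty_is_additive(self):
        base = aic_score(28, 50, residual=3.0, scale=10.0)
        assert aic_score(56, 50, residual=3.0, scale=10.0) == pytest.approx(
            base + 2 * 28
        )

    def test_log_identity_in_residual(self):
        base = aic_score(28, 50, residual=3.0, scale=10.0)
        scaled = aic_score(28, 50, residual=3.0 * np.e, scale=10.0)
        assert scaled == pytest.approx(base + 50)

    def test_zero_residual_floored(self):
        assert aic_score(28, 50, residual=0.0, scale=10.0, floor=-999.0) == -999.0


class TestRandomParameterControl:
    def test_draws_within_bounds(self, nominal):
        for p in random_parameter_control(nominal, 50, seed=1):
            lo, hi = p.bounds[:, 0], p.bounds[:, 1]
            assert np.all(p.values >= lo) and np.all(p.values <= hi)

    def test_deterministic(self, nominal):
        a = random_parameter_control(nominal, 5, seed=4)
        b = random_parameter_control(nominal, 5, seed=4)
        for x, y in zip(a, b):
            assert np.array_equal(x.values, y.values)

    def test_log_uniform_median_near_bound_midpoint(self):
        from complement_rom.reaction_core import ParameterSet

        template = ParameterSet(("k",), np.array([3.0]),
                                np.array([[1.0, 10.0]]))
        draws = random_parameter_control(template, 1000, seed=0)
        logs = np.log10([p["k"] for p in draws])
        assert abs(np.median(logs) - 0.5) < 0.2
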