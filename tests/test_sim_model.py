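"""Simulation model: ranges, regimes, shift protocol, window arithmetic."""

import numpy as np
import pytest

from ptda.sim_model import (DEFAULT_T, TRANSIENT, DynamicsLabel, ModelParams,
                            ModelState, ShiftProtocol, VARIABLES, add_noise,
                            classify_dynamics, make_validation_set,
                            run_is_complex, simulate_run, step_model,
                            write_run_csv, _core_step, _observe)

LO = np.array([-1.0, -1.0, 0.0, 0.0, -1.0])
HI = np.array([1.0, 1.0, 1.0, 1.0, 1.0])


class TestStepModel:
    def test_pure_map_is_deterministic(self):
        s = ModelState(0.2, -0.1, 0.5, 0.4, 0.3)
        p = ModelParams(0.3, 0.6, 0.7, 0.2)
        a, b = step_model(s, p), step_model(s, p)
        assert a == b

    def test_rejects_nonfinite_state(self):
        with pytest.raises(ValueError):
            ModelState(np.nan, 0, 0.5, 0.5, 0)

    def test_parameters_confined_to_unit_interval(self):
        with pytest.raises(ValueError):
            ModelParams(1.2, 0.5, 0.5, 0.5)

    def test_low_trait_dynamics_converge_to_fixed_point(self):
        p = ModelParams(0.1, 0.1, 0.1, 0.1)
        u = np.full(5, 0.4)
        for _ in range(2000):
            u = _core_step(u, p.as_array())
        x = _observe(u, p.as_array())
        x_next = _observe(_core_step(u, p.as_array()), p.as_array())
        assert np.max(np.abs(x_next - x)) < 1e-10

    def test_range_conservation_over_long_ensemble(self):
        """100 random starts, 10^5 iterations: no variable leaves its range."""
        rng = np.random.default_rng(0)
        u = rng.uniform(0.0, 1.0, (5, 100))
        params = rng.uniform(0.0, 1.0, 4)
        for _ in range(100_000):
            u = _core_step(u, params)
        obs = _observe(u, params)
        assert np.all(obs >= LO[:, None] - 1e-12)
        assert np.all(obs <= HI[:, None] + 1e-12)


class TestSimulateRun:
    def test_same_seed_gives_identical_trajectories(self):
        proto = ShiftProtocol(rng_seed=5)
        a = simulate_run(5, proto)
        b = simulate_run(5, proto)
        assert np.array_equal(a.trajectories, b.trajectories)

    def test_shift_respects_minimum_change(self):
        for seed in range(40):
            run = simulate_run(seed, ShiftProtocol())
            delta = run.params_after.as_array() - run.params_before.as_array()
            assert np.all(np.abs(delta) >= 0.05)
            assert np.all(run.params_after.as_array() <= 1.0)
            assert np.all(run.params_after.as_array() >= 0.0)

    def test_signed_protocol_draws_both_directions(self):
        signs = set()
        for seed in range(30):
            run = simulate_run(seed, ShiftProtocol(direction="signed"))
            delta = run.params_after.as_array() - run.params_before.as_array()
            signs.update(np.sign(delta).tolist())
        assert signs == {-1.0, 1.0}

    def test_ramp_parameter_path_is_piecewise_linear(self):
        ramp = 30
        run = simulate_run(3, ShiftProtocol(ramp_length=ramp))
        path = run.param_path
        s = run.protocol.shift_time
        # flat before, flat after, exactly `ramp` equal increments between
        assert np.all(path[: s] == path[0])
        assert np.all(path[s + ramp:] == path[-1])
        inc = np.diff(path[s - 1: s + ramp], axis=0)
        assert np.allclose(inc, inc[0])
        assert inc.shape[0] == ramp

    def test_instantaneous_shift_first_affects_next_sample(self):
        run = simulate_run(3, ShiftProtocol())
        s = run.protocol.shift_time
        assert np.all(run.param_path[s - 1] == run.params_before.as_array())
        assert np.all(run.param_path[s] == run.params_after.as_array())

    def test_trajectories_within_declared_ranges(self):
        run = simulate_run(11, ShiftProtocol())
        assert np.all(run.trajectories >= LO - 1e-12)
        assert np.all(run.trajectories <= HI + 1e-12)


class TestClassifyDynamics:
    @pytest.mark.parametrize("period", [1, 2, 4, 8, 16])
    def test_constructed_cycles_classified_exactly(self, rng, period):
        cell = rng.uniform(0, 1, period)
        x = np.tile(cell, 200 // period + 1)[:200]
        label = classify_dynamics(x)
        if period == 1:
            assert label == DynamicsLabel("fixed")
        else:
            assert label == DynamicsLabel("periodic", period)

    def test_pendular_series_is_a_two_cycle(self):
        x = np.tile([0.2, 0.8], 50)
        assert classify_dynamics(x) == DynamicsLabel("periodic", 2)

    def test_chaotic_logistic_orbit_is_not_periodic(self):
        x = [0.2]
        for _ in range(299):
            x.append(4.0 * x[-1] * (1 - x[-1]))
        assert classify_dynamics(np.array(x)).kind == "chaotic"

    def test_sixteen_cycle_passes_the_complexity_filter(self, rng):
        cell = rng.uniform(0, 1, 16)
        x = np.tile(cell, 10)
        assert classify_dynamics(x).is_complex

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            classify_dynamics(np.zeros(40))


class TestValidationSet:
    def test_window_count_and_shape(self, small_transition_windows):
        assert len(small_transition_windows) == 6
        for w in small_transition_windows:
            assert w.data.shape == (100, 5)
            assert w.true_tp == 50

    def test_windows_indices_match_protocol(self):
        """tp 50 -> adjusted [100, 200]; tp 80 -> adjusted [70, 170]."""
        wins50 = make_validation_set(2, tp_position=50, seed=7)
        wins80 = make_validation_set(2, tp_position=80, seed=7)
        for w50, w80 in zip(wins50, wins80):
            run = simulate_run(w50.run_seed, ShiftProtocol(rng_seed=w50.run_seed))
            adj = run.adjusted
            assert np.array_equal(w50.data, adj[100:200])
            assert np.array_equal(w80.data, adj[70:170])

    def test_null_windows_lie_before_the_shift(self, small_null_windows):
        for w in small_null_windows:
            run = simulate_run(w.run_seed, ShiftProtocol(rng_seed=w.run_seed))
            assert np.array_equal(w.data, run.adjusted[:100])
            assert w.true_tp is None

    def test_only_complex_runs_are_kept(self, small_transition_windows):
        for w in small_transition_windows:
            run = simulate_run(w.run_seed, ShiftProtocol(rng_seed=w.run_seed))
            assert run_is_complex(run)

    def test_reproducible_and_csv_roundtrip(self, tmp_path):
        a = make_validation_set(2, tp_position=50, seed=3)
        b = make_validation_set(2, tp_position=50, seed=3)
        for wa, wb in zip(a, b):
            assert np.array_equal(wa.data, wb.data)
        run = simulate_run(a[0].run_seed, ShiftProtocol(rng_seed=a[0].run_seed))
        write_run_csv(run, tmp_path / "run.csv")
        write_run_csv(run, tmp_path / "run2.csv")
        assert (tmp_path / "run.csv").read_bytes() == \
            (tmp_path / "run2.csv").read_bytes()
        loaded = np.loadtxt(tmp_path / "run.csv", delimiter=",", skiprows=1)
        assert np.allclose(loaded, run.trajectories, atol=1e-12)

    def test_impossible_window_arithmetic_raises(self):
        with pytest.raises(ValueError):
            make_validation_set(1, tp_position=160, seed=0)


class TestAddNoise:
    def test_zero_noise_is_identity(self, rng):
        x = rng.standard_normal(100)
        assert np.array_equal(add_noise(x, 0.0, 1), x)

    @pytest.mark.parametrize("pct, ratio", [(100, 1.0), (50, 0.5)])
    def test_noise_variance_matches_requested_fraction(self, pct, ratio):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(10_000)
        noisy = add_noise(x, pct, 123)
        got = np.var(noisy - x, ddof=1) / np.var(x, ddof=1)
        assert got == pytest.approx(ratio, rel=0.06)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            add_noise(np.zeros(10), -1.0)
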