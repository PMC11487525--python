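"""Integration of the driven and autonomous reservoir equations."""

import dataclasses

import numpy as np
import pytest

from rcswitching import (OrbitSpec, RCParams, ReservoirRealization,
                         integrate_closed_loop, integrate_open_loop,
                         open_loop_derivative, project)
from rcswitching.dynamics import (PlanarTrajectory, StateTrajectory,
                                  read_trajectory_csv, sample_half_steps,
                                  write_trajectory_csv)
from rcswitching.training import TrainConfig, TrainedRC


def decoupled_realization(n=8, seed=0):
    """A realization with M = 0 (spectral radius 0): pure input-driven decay."""
    real = ReservoirRealization.generate(n_nodes=n, connection_prob=0.5,
                                         spectral_radius=0.3, seed=seed)
    return real.with_spectral_radius(0.0)


def zero_input(t):
    t = np.asarray(t, dtype=float)
    return np.zeros(t.shape + (2,))


class TestOpenLoopDerivative:
    def test_pure_decay_when_uncoupled(self, rng):
        real = decoupled_realization()
        params = RCParams(sigma=0.0)
        r0 = rng.normal(size=8)
        np.testing.assert_allclose(
            open_loop_derivative(r0, np.zeros(2), real, params),
            -params.gamma * r0)

    def test_origin_is_fixed_point_without_drive(self):
        real = decoupled_realization()
        params = RCParams()
        out = open_loop_derivative(np.zeros(8), np.zeros(2), real, params)
        np.testing.assert_array_equal(out, np.zeros(8))

    def test_driven_fixed_point_matches_tanh(self):
        # with M = 0 and constant input, r* = tanh(sigma W_in u) is stationary
        real = decoupled_realization()
        params = RCParams()
        u = np.array([3.0, -2.0])
        r_star = np.tanh(params.sigma * real.input_weights @ u)
        out = open_loop_derivative(r_star, u, real, params)
        np.testing.assert_allclose(out, np.zeros(8), atol=1e-15)

    def test_dimension_mismatch(self):
        real = decoupled_realization()
        with pytest.raises(ValueError):
            open_loop_derivative(np.zeros(5), np.zeros(2), real, RCParams())


class TestIntegrateOpenLoop:
    def test_linear_decay_closed_form(self, rng):
        real = decoupled_realization()
        params = RCParams(sigma=0.0)
        r0 = rng.normal(size=8)
        traj = integrate_open_loop(real, params, zero_input, r0=r0,
                                   n_steps=200)
        exact = r0 * np.exp(-params.gamma * traj.times[-1])
        assert np.max(np.abs(traj.states[-1] - exact)) < 1e-9

    def test_zero_steps_returns_initial_state(self):
        real = decoupled_realization()
        traj = integrate_open_loop(real, RCParams(), zero_input,
                                   r0=np.ones(8), n_steps=0)
        assert len(traj) == 1
        np.testing.assert_array_equal(traj.states[0], np.ones(8))

    def test_short_input_series_rejected(self):
        real = decoupled_realization()
        series = np.zeros((5, 2))
        with pytest.raises(ValueError, match="too short"):
            integrate_open_loop(real, RCParams(), series, n_steps=10)

    def test_deterministic_repeatability(self, rng):
        real = ReservoirRealization.generate(n_nodes=20, connection_prob=0.2,
                                             spectral_radius=0.5, seed=3)
        orbit = OrbitSpec(x_center=8.0)
        r0 = rng.normal(size=20) * 0.1
        a = integrate_open_loop(real, RCParams(), orbit, r0=r0, n_steps=300)
        b = integrate_open_loop(real, RCParams(), orbit, r0=r0, n_steps=300)
        np.testing.assert_array_equal(a.states, b.states)

    def test_kernel_matches_numpy_reference(self, rng):
        """Compiled RK4 equals a plain-NumPy RK4 built on the reference RHS."""
        real = ReservoirRealization.generate(n_nodes=6, connection_prob=0.5,
                                             spectral_radius=0.4, seed=5)
        params = RCParams()
        orbit = OrbitSpec(x_center=6.5)
        r0 = rng.normal(size=6) * 0.2
        n_steps = 50
        traj = integrate_open_loop(real, params, orbit, r0=r0,
                                   n_steps=n_steps)
        tau = params.tau
        u = sample_half_steps(orbit, 0.0, n_steps, tau)
        r = r0.copy()
        for k in range(n_steps):
            f = lambda s, uu: open_loop_derivative(s, uu, real, params)
            k1 = f(r, u[2 * k])
            k2 = f(r + 0.5 * tau * k1, u[2 * k + 1])
            k3 = f(r + 0.5 * tau * k2, u[2 * k + 1])
            k4 = f(r + tau * k3, u[2 * k + 2])
            r = r + (tau / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
        np.testing.assert_allclose(traj.states[-1], r, atol=1e-13)


class TestClosedLoop:
    def test_zero_readout_decays_to_origin(self, rng):
        real = decoupled_realization()
        params = RCParams()
        trained = TrainedRC(realization=real, params=params,
                            readout=np.zeros((2, 16)),
                            end_state_A=np.zeros(8), end_state_B=np.zeros(8),
                            train_config=TrainConfig(t_listen=1, t_train=2,
                                                     tau=params.tau))
        r0 = rng.uniform(-1, 1, size=8)
        traj = integrate_closed_loop(trained, r0, n_steps=300)
        exact = r0 * np.exp(-params.gamma * traj.times[-1])
        assert np.max(np.abs(traj.states[-1] - exact)) < 1e-9

    def test_states_eventually_inside_unit_box(self, trained_rc, rng):
        r0 = rng.uniform(-1, 1, size=100)
        traj = integrate_closed_loop(trained_rc, r0, n_steps=300)
        late = traj.states[traj.times >= 10 / trained_rc.params.gamma]
        assert np.max(np.abs(late)) <= 1 + 1e-6


class TestProject:
    def test_zero_state_maps_to_origin(self, rng):
        readout = rng.normal(size=(2, 20))
        np.testing.assert_array_equal(project(readout, np.zeros(10)),
                                      np.zeros(2))

    def test_selector_readout_returns_leading_components(self, rng):
        n = 10
        readout = np.zeros((2, 2 * n))
        readout[0, 0] = 1.0
        readout[1, 1] = 1.0
        r = rng.normal(size=n)
        np.testing.assert_allclose(project(readout, r), r[:2])

    def test_training_targets_reproduced(self, trained_rc, task8,
                                         scaled_train_config, params):
        from rcswitching import harvest
        x, y, _ = harvest(trained_rc.realization, params, task8.orbit_A,
                          scaled_train_config)
        resid = np.mean((trained_rc.readout @ x - y) ** 2)
        assert resid < 1e-2


class TestRK4Convergence:
    def test_fourth_order_on_linear_benchmark(self):
        real = decoupled_realization(n=4)
        r0 = np.ones(4)
        t_end = 1.0
        errors, taus = [], [0.04, 0.02, 0.01, 0.005]
        for tau in taus:
            params = RCParams(sigma=0.0, tau=tau)
            n_steps = int(round(t_end / tau))
            traj = integrate_open_loop(real, params, zero_input, r0=r0,
                                       n_steps=n_steps)
            exact = r0 * np.exp(-params.gamma * t_end)
            errors.append(np.max(np.abs(traj.states[-1] - exact)))
        slope = np.polyfit(np.log(taus), np.log(errors), 1)[0]
        assert 3.8 <= slope <= 4.2

    def test_halving_tau_reduces_error_sixteenfold(self):
        real = decoupled_realization(n=4)
        r0 = np.ones(4)
        errs = []
        for tau in (0.02, 0.01):
            params = RCParams(sigma=0.0, tau=tau)
            traj = integrate_open_loop(real, params, zero_input, r0=r0,
                                       n_steps=int(round(1.0 / tau)))
            errs.append(np.max(np.abs(traj.states[-1]
                                      - r0 * np.exp(-params.gamma))))
        assert errs[0] / errs[1] == pytest.approx(16, rel=0.3)


class TestTrajectoryContainers:
    def test_non_uniform_times_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            StateTrajectory(times=[0.0, 0.1, 0.3], states=np.zeros((3, 2)))

    def test_csv_round_trip_planar(self, tmp_path):
        traj = PlanarTrajectory(times=np.arange(4) * 0.01,
                                points=np.arange(8.0).reshape(4, 2))
        path = tmp_path / "traj.csv"
        write_trajectory_csv(traj, path)
        back = read_trajectory_csv(path)
        assert isinstance(back, PlanarTrajectory)
        np.testing.assert_allclose(back.points, traj.points)

    def test_csv_round_trip_states(self, tmp_path, rng):
        traj = StateTrajectory(times=np.arange(5) * 0.01,
                               states=rng.normal(size=(5, 3)))
        path = tmp_path / "traj.csv"
        write_trajectory_csv(traj, path)
        back = read_trajectory_csv(path)
        assert isinstance(back, StateTrajectory)
        np.testing.assert_allclose(back.states, traj.states, rtol=1e-15)

    def test_npz_round_trip_exact(self, tmp_path, rng):
        from rcswitching.dynamics import (load_trajectory_npz,
                                          save_trajectory_npz)
        traj = StateTrajectory(times=np.arange(5) * 0.01,
                               states=rng.normal(size=(5, 3)))
        path = tmp_path / "traj.npz"
        save_trajectory_npz(traj, path)
        back = load_trajectory_npz(path)
        np.testing.assert_array_equal(back.states, traj.states)


class TestRCParams:
    @pytest.mark.parametrize("kwargs", [
        {"gamma": 0.0}, {"sigma": -0.1}, {"tau": 0.0},
        {"gamma": 10.0, "tau": 0.2},  # tau * gamma >= 1
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RCParams(**kwargs)
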