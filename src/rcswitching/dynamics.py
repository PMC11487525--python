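"""Integration of the driven (open-loop) and autonomous (closed-loop) reservoir.

Open loop:   dr/dt = gamma * (-r + tanh(M r + sigma W_in u(t)))
Closed loop: dr/dt = gamma * (-r + tanh(M r + sigma W_in W_out q(r)))

Both are integrated with fixed-step classical 4th-order Runge-Kutta at step
``tau`` (0.01 by default).  The driving signal is analytic, so the middle RK4
stages are fed exact values at t + tau/2; callers may pass a callable u(t), an
orbit specification, or a pre-sampled array at tau/2 resolution.

Because tanh is bounded, each component satisfies dr_i/dt < 0 whenever
r_i > 1 (and > 0 whenever r_i < -1), making the box [-1, 1]^N globally
attracting for any readout: the closed loop can never diverge.  A guard in the
kernel still aborts if |r_i| ever exceeds 10, which would indicate a bug.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from . import _kernels

__all__ = [
    "RCParams",
    "StateTrajectory",
    "PlanarTrajectory",
    "DivergenceError",
    "open_loop_derivative",
    "integrate_open_loop",
    "integrate_closed_loop",
    "closed_loop_projection",
    "project",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

DEFAULT_GAMMA = 10.0
DEFAULT_SIGMA = 0.1
DEFAULT_TAU = 0.01


class DivergenceError(RuntimeError):
    """Closed-loop state left the theoretically attracting region."""


@dataclasses.dataclass(frozen=True)
class RCParams:
    """Reservoir dynamics parameters.

    gamma : decay rate (1/time); sets the reservoir's intrinsic timescale.
    sigma : input strength multiplying W_in u.
    tau   : RK4 step (time).  tau * gamma < 1 guards explicit-step stability.
    """

    gamma: float = DEFAULT_GAMMA
    sigma: float = DEFAULT_SIGMA
    tau: float = DEFAULT_TAU

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.tau * self.gamma >= 1:
            raise ValueError("require tau * gamma < 1 for stable stepping")


@dataclasses.dataclass
class StateTrajectory:
    """Uniformly sampled reservoir states; states[k] is the N-vector at
    times[k]."""

    times: np.ndarray
    states: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if len(self.times) != len(self.states):
            raise ValueError("times and states length mismatch")
        if len(self.times) > 2:
            dt = np.diff(self.times)
            if np.max(np.abs(dt - dt[0])) > 1e-12:
                raise ValueError("times must be uniformly spaced")

    def __len__(self):
        return len(self.times)


@dataclasses.dataclass
class PlanarTrajectory:
    """A trajectory in the two-dimensional projected (prediction) space."""

    times: np.ndarray
    points: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        if len(self.times) != len(self.points):
            raise ValueError("times and points length mismatch")
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def __len__(self):
        return len(self.times)


def open_loop_derivative(state, input_value, realization, params) -> np.ndarray:
    """Right-hand side gamma*(-r + tanh(M r + sigma W_in u)), in plain NumPy.

    This is the reference formula the compiled kernel must agree with.
    """
    r = np.asarray(state, dtype=float)
    u = np.asarray(input_value, dtype=float)
    if r.shape != (realization.n_nodes,):
        raise ValueError("state dimension mismatch")
    if u.shape != (realization.input_dim,):
        raise ValueError("input dimension mismatch")
    drive = realization.adjacency @ r + params.sigma * (
        realization.input_weights @ u)
    return params.gamma * (-r + np.tanh(drive))


def sample_half_steps(input_series, t0: float, n_steps: int, tau: float,
                      input_dim: int = 2) -> np.ndarray:
    """Sample the driving signal at tau/2 spacing over [t0, t0 + n_steps*tau].

    ``input_series`` may be a callable u(t) (scalar or vectorized), an object
    with an ``evaluate(t)`` method (an orbit spec), or an array already at
    tau/2 resolution with at least 2*n_steps + 1 rows.
    """
    m = 2 * n_steps + 1
    if isinstance(input_series, np.ndarray):
        if input_series.shape[0] < m:
            raise ValueError(
                f"input series too short: need {m} half-step samples, "
                f"got {input_series.shape[0]}")
        return np.ascontiguousarray(input_series[:m], dtype=float)
    t = t0 + 0.5 * tau * np.arange(m)
    if hasattr(input_series, "evaluate"):
        return np.ascontiguousarray(input_series.evaluate(t), dtype=float)
    out = np.asarray(input_series(t), dtype=float)
    if out.shape == (m, input_dim):
        return np.ascontiguousarray(out)
    # non-vectorized callable
    return np.stack([np.asarray(input_series(tk), dtype=float) for tk in t])


def integrate_open_loop(realization, params: RCParams, input_series,
                        r0=None, n_steps: int = 0,
                        t0: float = 0.0) -> StateTrajectory:
    """RK4-integrate the driven reservoir for n_steps from r0 (default 0)."""
    n = realization.n_nodes
    if r0 is None:
        r0 = np.zeros(n)
    r0 = np.ascontiguousarray(r0, dtype=float)
    if r0.shape != (n,):
        raise ValueError("r0 dimension mismatch")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    u_half = sample_half_steps(input_series, t0, n_steps, params.tau,
                               realization.input_dim)
    indptr, indices, data, wc, wv = realization.csr_parts()
    states = _kernels.rk4_open(indptr, indices, data, wc, wv,
                               params.gamma, params.sigma, params.tau,
                               u_half, r0)
    times = t0 + params.tau * np.arange(n_steps + 1)
    return StateTrajectory(times=times, states=states)


def _run_closed(trained_rc, r0, n_steps: int, record_states: bool,
                t0: float = 0.0):
    real = trained_rc.realization
    params = trained_rc.params
    r0 = np.ascontiguousarray(r0, dtype=float)
    if r0.shape != (real.n_nodes,):
        raise ValueError("initial state dimension mismatch")
    wlin, wsq = trained_rc.readout_blocks()
    indptr, indices, data, wc, wv = real.csr_parts()
    states, proj, final, status = _kernels.rk4_closed(
        indptr, indices, data, wc, wv, params.gamma, params.sigma,
        params.tau, wlin, wsq, r0, n_steps, record_states)
    if status >= 0:
        raise DivergenceError(
            f"closed-loop state exceeded |r_i| = {_kernels.DIVERGENCE_BOUND} "
            f"at step {status} (t = {t0 + status * params.tau:.4f}); this "
            "should be impossible for a tanh reservoir and indicates a bug")
    times = t0 + params.tau * np.arange(n_steps + 1)
    return states, proj, final, times


def integrate_closed_loop(trained_rc, r0, n_steps: int,
                          t0: float = 0.0) -> StateTrajectory:
    """Autonomous trajectory of the trained reservoir from r0."""
    states, _proj, _final, times = _run_closed(trained_rc, r0, n_steps,
                                               True, t0)
    return StateTrajectory(times=times, states=states)


def closed_loop_projection(trained_rc, r0, n_steps: int, t0: float = 0.0):
    """Projected prediction u(t) = W_out q(r(t)) of the autonomous run.

    Returns (PlanarTrajectory, final_state).  Storing only the projection
    keeps long runs (switching statistics) cheap in memory.
    """
    _states, proj, final, times = _run_closed(trained_rc, r0, n_steps,
                                              False, t0)
    return PlanarTrajectory(times=times, points=proj), final


def project(readout: np.ndarray, state) -> np.ndarray:
    """Map a reservoir state to the prediction space: u = W_out q(r).

    A readout with 2N columns uses quadratic features [r; r^2]; one with N
    columns is a linear-only readout.
    """
    from .training import feature_vector
    r = np.asarray(state, dtype=float)
    n = r.shape[-1]
    if readout.shape[1] == 2 * n:
        q = feature_vector(r, "quadratic")
    elif readout.shape[1] == n:
        q = feature_vector(r, "linear")
    else:
        raise ValueError("readout width matches neither N nor 2N")
    return q @ readout.T if q.ndim > 1 else readout @ q


# -- trajectory serialization ---------------------------------------------

def write_trajectory_csv(traj, path) -> None:
    """Columnar text round-trip: t,x,y for planar; t,r_1..r_N for states."""
    import pandas as pd
    path = Path(path)
    if isinstance(traj, PlanarTrajectory):
        df = pd.DataFrame({"t": traj.times, "x": traj.x, "y": traj.y})
    else:
        cols = {f"r_{i + 1}": traj.states[:, i]
                for i in range(traj.states.shape[1])}
        df = pd.DataFrame({"t": traj.times, **cols})
    df.to_csv(path, index=False, float_format="%.17g")


def read_trajectory_csv(path):
    import pandas as pd
    df = pd.read_csv(path)
    if list(df.columns[1:]) == ["x", "y"]:
        return PlanarTrajectory(times=df["t"].to_numpy(),
                                points=df[["x", "y"]].to_numpy())
    return StateTrajectory(times=df["t"].to_numpy(),
                           states=df.iloc[:, 1:].to_numpy())


def save_trajectory_npz(traj, path) -> None:
    """Binary archive for long runs; exact round-trip."""
    if isinstance(traj, PlanarTrajectory):
        np.savez(Path(path), kind="planar", times=traj.times,
                 points=traj.points)
    else:
        np.savez(Path(path), kind="state", times=traj.times,
                 states=traj.states)


def load_trajectory_npz(path):
    with np.load(Path(path)) as f:
        if str(f["kind"]) == "planar":
            return PlanarTrajectory(times=f["times"], points=f["points"])
        return StateTrajectory(times=f["times"], states=f["states"])
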