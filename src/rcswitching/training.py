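"""Readout training: state harvesting and ridge regression.

The open-loop reservoir is driven with each orbit's signal from the zero
state.  States before ``t_listen`` (the listening stage / washout) are
discarded; states from ``t_listen`` to ``t_train`` are mapped through the
feature map q(r) = [r; r^2] and collected as columns of X, with the driving
signal values as target columns Y.  Appending the elementwise squares breaks
the odd symmetry of the tanh flow and thereby suppresses "mirror attractors"
(spurious symmetry-image reconstructions).

The readout solves the ridge problem

    W_out = Y X^T (X X^T + beta I)^{-1}

via a symmetric positive-definite (Cholesky) factorization — never an
explicit inverse.  For the two-orbit task, X and Y concatenate the per-orbit
blocks column-wise; the adjacency, input weights, and all training parameters
are identical for both drives.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import scipy.linalg

from .dynamics import RCParams, integrate_open_loop, sample_half_steps
from .network import ReservoirRealization

__all__ = [
    "TrainConfig",
    "TrainedRC",
    "quad_features",
    "feature_vector",
    "harvest",
    "ridge_readout",
    "train_seeing_double",
    "echo_state_gap",
]

DEFAULT_T_LISTEN = 50.0
DEFAULT_T_TRAIN = 550.0
DEFAULT_RIDGE = 1e-4

#: components of the end-of-training state must satisfy |r_i| <= 1 + this
BOUNDEDNESS_TOL = 1e-6


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Listening/training windows and the ridge parameter.

    t_listen : washout duration; states before it never enter the regression.
    t_train  : end of the training stage (t_train > t_listen).
    ridge_param : Tikhonov parameter beta of the readout solve.
    tau      : sampling/integration step; must equal the dynamics tau.
    """

    t_listen: float = DEFAULT_T_LISTEN
    t_train: float = DEFAULT_T_TRAIN
    ridge_param: float = DEFAULT_RIDGE
    tau: float = 0.01

    def __post_init__(self):
        if self.t_listen < 0:
            raise ValueError("t_listen must be >= 0")
        if self.t_train <= self.t_listen:
            raise ValueError("t_train must exceed t_listen")
        if self.ridge_param < 0:
            raise ValueError("ridge_param must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")

    def check_columns(self, n_nodes: int) -> None:
        """The regression must be overdetermined: >= 2N training columns."""
        cols = (self.t_train - self.t_listen) / self.tau
        if cols < 2 * n_nodes:
            raise ValueError(
                f"training window supplies {cols:.0f} columns; need at least "
                f"2N = {2 * n_nodes} for a conditioned regression")


def feature_vector(state: np.ndarray, kind: str = "quadratic") -> np.ndarray:
    """q(r): [r; r^2] for 'quadratic', r itself for 'linear'.

    Accepts a single state (N,) or a batch (..., N); the feature axis is
    last.
    """
    r = np.asarray(state, dtype=float)
    if kind == "linear":
        return r
    if kind == "quadratic":
        return np.concatenate([r, r * r], axis=-1)
    raise ValueError(f"unknown feature kind {kind!r}")


def quad_features(state: np.ndarray) -> np.ndarray:
    """Quadratic feature map q(r) = [r; r^2] (elementwise square).

    The squares make the map non-odd — q(-r) != -q(r) for r != 0 — which is
    what prevents mirror attractors in the closed loop.
    """
    return feature_vector(state, "quadratic")


def harvest(realization: ReservoirRealization, params: RCParams,
            input_series, train_config: TrainConfig,
            feature_kind: str = "quadratic"):
    """Drive the reservoir from r(0) = 0 and collect regression blocks.

    Returns (X, Y, end_state): X has a q(r(t)) column and Y a u(t) column for
    every t = t_listen, t_listen + tau, ..., t_train; end_state is
    r(t_train), the closed-loop initialization for this orbit.
    """
    if abs(train_config.tau - params.tau) > 1e-15:
        raise ValueError("train_config.tau must equal the dynamics tau")
    train_config.check_columns(realization.n_nodes)
    tau = params.tau
    n_total = int(round(train_config.t_train / tau))
    i_listen = int(round(train_config.t_listen / tau))
    u_half = sample_half_steps(input_series, 0.0, n_total, tau,
                               realization.input_dim)
    traj = integrate_open_loop(realization, params, u_half, r0=None,
                               n_steps=n_total)
    states = traj.states[i_listen:]
    features = feature_vector(states, feature_kind).T
    targets = u_half[2 * i_listen::2].T.copy()
    end_state = traj.states[-1].copy()
    return features, targets, end_state


def ridge_readout(features_concat: np.ndarray, targets_concat: np.ndarray,
                  ridge_param: float) -> np.ndarray:
    """Solve W_out = Y X^T (X X^T + beta I)^{-1} by Cholesky.

    X is features (n_features x T), Y is targets (D x T).
    """
    x = np.asarray(features_concat, dtype=float)
    y = np.asarray(targets_concat, dtype=float)
    if x.shape[1] != y.shape[1]:
        raise ValueError("features and targets must share the column count")
    gram = x @ x.T
    gram[np.diag_indices_from(gram)] += ridge_param
    try:
        cho = scipy.linalg.cho_factor(gram, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError(
            "X X^T + beta I is not positive definite (singular Gram matrix); "
            "use a ridge parameter beta > 0") from exc
    # W = Y X^T A^{-1}  <=>  A W^T = X Y^T  (A symmetric)
    wt = scipy.linalg.cho_solve(cho, x @ y.T)
    return wt.T


@dataclasses.dataclass
class TrainedRC:
    """A reservoir realization together with its trained readout.

    ``end_state_A`` / ``end_state_B`` are the reservoir states at the end of
    the two training drives, r^(C_A)(t_train) and r^(C_B)(t_train) — the
    canonical initial conditions for reconstructing each orbit in closed
    loop.
    """

    realization: ReservoirRealization
    params: RCParams
    readout: np.ndarray
    end_state_A: np.ndarray
    end_state_B: np.ndarray
    train_config: TrainConfig
    feature_kind: str = "quadratic"

    def __post_init__(self):
        self.readout = np.ascontiguousarray(self.readout, dtype=float)

    def readout_blocks(self):
        """(W_lin, W_sq): D x N blocks acting on r and r^2 respectively."""
        n = self.realization.n_nodes
        if self.feature_kind == "linear":
            wlin = self.readout
            wsq = np.zeros_like(wlin)
        else:
            wlin = np.ascontiguousarray(self.readout[:, :n])
            wsq = np.ascontiguousarray(self.readout[:, n:])
        return wlin, wsq

    def validate(self) -> None:
        if not np.isfinite(self.readout).all():
            raise ValueError("readout contains non-finite entries")
        for name, s in (("end_state_A", self.end_state_A),
                        ("end_state_B", self.end_state_B)):
            if not np.isfinite(s).all():
                raise ValueError(f"{name} contains non-finite entries")
            if np.max(np.abs(s)) > 1.0 + BOUNDEDNESS_TOL:
                raise ValueError(f"{name} violates the boundedness invariant")

    def save(self, path) -> None:
        real = self.realization
        with open(Path(path), "wb") as fh:  # keep the exact filename
            self._savez(fh, real)

    def _savez(self, fh, real) -> None:
        np.savez(fh,
                 base_adjacency_matrix=real.base_adjacency_matrix,
                 input_weights=real.input_weights,
                 n_nodes=real.n_nodes, input_dim=real.input_dim,
                 connection_prob=real.connection_prob,
                 spectral_radius=real.spectral_radius, seed=real.seed,
                 gamma=self.params.gamma, sigma=self.params.sigma,
                 tau=self.params.tau,
                 readout=self.readout, end_state_A=self.end_state_A,
                 end_state_B=self.end_state_B,
                 t_listen=self.train_config.t_listen,
                 t_train=self.train_config.t_train,
                 ridge_param=self.train_config.ridge_param,
                 feature_kind=self.feature_kind)

    @classmethod
    def load(cls, path) -> "TrainedRC":
        with np.load(Path(path)) as f:
            real = ReservoirRealization(
                base_adjacency_matrix=f["base_adjacency_matrix"],
                input_weights=f["input_weights"],
                n_nodes=int(f["n_nodes"]), input_dim=int(f["input_dim"]),
                connection_prob=float(f["connection_prob"]),
                spectral_radius=float(f["spectral_radius"]),
                seed=int(f["seed"]))
            params = RCParams(gamma=float(f["gamma"]),
                              sigma=float(f["sigma"]), tau=float(f["tau"]))
            config = TrainConfig(t_listen=float(f["t_listen"]),
                                 t_train=float(f["t_train"]),
                                 ridge_param=float(f["ridge_param"]),
                                 tau=float(f["tau"]))
            return cls(realization=real, params=params,
                       readout=f["readout"],
                       end_state_A=f["end_state_A"],
                       end_state_B=f["end_state_B"],
                       train_config=config,
                       feature_kind=str(f["feature_kind"]))


def train_seeing_double(realization: ReservoirRealization, params: RCParams,
                        orbit_A, orbit_B, train_config: TrainConfig,
                        feature_kind: str = "quadratic") -> TrainedRC:
    """Harvest both orbit drives, concatenate, and solve the ridge readout.

    Both harvests start from the zero state and use the identical
    realization, dynamics parameters, and training windows; only the driving
    signal differs.
    """
    xa, ya, end_a = harvest(realization, params, orbit_A, train_config,
                            feature_kind)
    xb, yb, end_b = harvest(realization, params, orbit_B, train_config,
                            feature_kind)
    features = np.concatenate([xa, xb], axis=1)
    targets = np.concatenate([ya, yb], axis=1)
    readout = ridge_readout(features, targets, train_config.ridge_param)
    trained = TrainedRC(realization=realization, params=params,
                        readout=readout, end_state_A=end_a, end_state_B=end_b,
                        train_config=train_config, feature_kind=feature_kind)
    trained.validate()
    return trained


def echo_state_gap(realization: ReservoirRealization, params: RCParams,
                   input_series, t_listen: float, rng=None) -> float:
    """Max-norm distance at t_listen between the zero start and a random
    start of the listening stage.

    A small gap certifies the echo-state (fading-memory) property: by the end
    of the washout, the state is determined by the input history alone.
    """
    rng = np.random.default_rng(rng)
    n_steps = int(round(t_listen / params.tau))
    u_half = sample_half_steps(input_series, 0.0, n_steps, params.tau,
                               realization.input_dim)
    a = integrate_open_loop(realization, params, u_half, r0=None,
                            n_steps=n_steps)
    r0 = rng.uniform(-1.0, 1.0, size=realization.n_nodes)
    b = integrate_open_loop(realization, params, u_half, r0=r0,
                            n_steps=n_steps)
    return float(np.max(np.abs(a.states[-1] - b.states[-1])))
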