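"""Random reservoir construction: adjacency matrix M and input matrix W_in.

The reservoir is an Erdos-Renyi-style sparse random matrix: each entry is
independently nonzero with probability ``connection_prob`` and nonzero values
are uniform on [-1, 1].  The base draw is then rescaled so that its spectral
radius (magnitude of the dominant eigenvalue) equals a target ``rho``.  The
input matrix assigns each neuron exactly one input component, with a uniform
[-1, 1] weight, so every neuron is driven by a single coordinate of the
two-dimensional signal.

A :class:`ReservoirRealization` stores the *base* (pre-rescaling) matrix plus
its generation parameters, and derives the rescaled adjacency on demand.  This
makes a spectral-radius sweep exact: every ``rho`` along a continuation uses
the same random draw, rescaled, never redrawn.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

__all__ = [
    "SpectralRescaleError",
    "measure_spectral_radius",
    "make_adjacency",
    "make_input_weights",
    "ReservoirRealization",
]

#: base matrices with spectral radius below this are treated as nilpotent
_NILPOTENT_TOL = 1e-12


class SpectralRescaleError(ValueError):
    """The base matrix has spectral radius 0, so no rescaling can reach a
    positive target; redraw with a different seed."""


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def measure_spectral_radius(matrix: np.ndarray) -> float:
    """Magnitude of the largest eigenvalue of a square matrix."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {matrix.shape}")
    return float(np.max(np.abs(np.linalg.eigvals(matrix))))


def base_adjacency(n_nodes: int, connection_prob: float, seed) -> np.ndarray:
    """Draw the pre-rescaling sparse random matrix.

    Draw order (fixed for reproducibility): an N x N uniform block for the
    Bernoulli mask, then an N x N uniform [-1, 1] block for the values.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if not 0.0 < connection_prob <= 1.0:
        raise ValueError("connection_prob must lie in (0, 1]")
    rng = _rng(seed)
    mask = rng.random((n_nodes, n_nodes)) < connection_prob
    values = rng.uniform(-1.0, 1.0, size=(n_nodes, n_nodes))
    return np.where(mask, values, 0.0)


def make_adjacency(n_nodes: int, connection_prob: float,
                   spectral_radius: float, seed) -> np.ndarray:
    """Sparse random adjacency rescaled to the target spectral radius.

    A target of 0 returns the zero matrix (the limit of the rescaling), so
    parameter sweeps do not crash at the degenerate endpoint.
    """
    if spectral_radius < 0:
        raise ValueError("spectral_radius must be >= 0")
    base = base_adjacency(n_nodes, connection_prob, seed)
    return rescale_adjacency(base, spectral_radius)


def rescale_adjacency(base: np.ndarray, spectral_radius: float) -> np.ndarray:
    """Rescale a base matrix to a target spectral radius."""
    if spectral_radius == 0.0:
        return np.zeros_like(base)
    base_sr = measure_spectral_radius(base)
    if base_sr < _NILPOTENT_TOL:
        raise SpectralRescaleError(
            "base matrix has spectral radius 0 (nilpotent draw); rescaling to "
            f"{spectral_radius} is undefined — redraw with a new seed")
    return base * (spectral_radius / base_sr)


def make_input_weights(n_nodes: int, input_dim: int, seed) -> np.ndarray:
    """Input matrix with exactly one uniform [-1, 1] entry per row.

    Draw order: N column indices, then N uniform values.
    """
    if n_nodes < 1 or input_dim < 1:
        raise ValueError("n_nodes and input_dim must be >= 1")
    rng = _rng(seed)
    cols = rng.integers(0, input_dim, size=n_nodes)
    vals = rng.uniform(-1.0, 1.0, size=n_nodes)
    win = np.zeros((n_nodes, input_dim))
    win[np.arange(n_nodes), cols] = vals
    return win


@dataclasses.dataclass
class ReservoirRealization:
    """One fixed random reservoir structure plus its generation parameters.

    ``base_adjacency_matrix`` is the pre-rescaling draw; ``adjacency`` derives
    the matrix at the current ``spectral_radius`` from it.  Sub-seeds for the
    adjacency and input draws are spawned from ``seed`` via
    ``np.random.SeedSequence``, so regeneration is bit-identical and the two
    matrices are independent of one another's sizes.
    """

    base_adjacency_matrix: np.ndarray
    input_weights: np.ndarray
    n_nodes: int
    input_dim: int
    connection_prob: float
    spectral_radius: float
    seed: int

    def __post_init__(self):
        self._adjacency_cache: np.ndarray | None = None
        self._csr_cache = None

    # -- construction -----------------------------------------------------

    @classmethod
    def generate(cls, n_nodes: int = 100, connection_prob: float = 0.04,
                 spectral_radius: float = 0.7, input_dim: int = 2,
                 seed: int = 0) -> "ReservoirRealization":
        ss_adj, ss_win = np.random.SeedSequence(seed).spawn(2)
        base = base_adjacency(n_nodes, connection_prob,
                              np.random.default_rng(ss_adj))
        if spectral_radius > 0:
            # fail fast on a (vanishingly unlikely) nilpotent draw
            rescale_adjacency(base, spectral_radius)
        win = make_input_weights(n_nodes, input_dim,
                                 np.random.default_rng(ss_win))
        return cls(base_adjacency_matrix=base, input_weights=win,
                   n_nodes=n_nodes, input_dim=input_dim,
                   connection_prob=connection_prob,
                   spectral_radius=spectral_radius, seed=seed)

    def with_spectral_radius(self, rho: float) -> "ReservoirRealization":
        """Same random draw, different target spectral radius."""
        if rho < 0:
            raise ValueError("spectral_radius must be >= 0")
        return dataclasses.replace(self, spectral_radius=rho)

    # -- derived views ----------------------------------------------------

    @property
    def adjacency(self) -> np.ndarray:
        if self._adjacency_cache is None:
            self._adjacency_cache = rescale_adjacency(
                self.base_adjacency_matrix, self.spectral_radius)
        return self._adjacency_cache

    def csr_parts(self):
        """(indptr, indices, data) of the rescaled adjacency, plus the
        one-nonzero-per-row input matrix as (columns, values) arrays."""
        if self._csr_cache is None:
            from scipy.sparse import csr_matrix
            csr = csr_matrix(self.adjacency)
            win = self.input_weights
            cols = np.abs(win).argmax(axis=1).astype(np.int64)
            vals = win[np.arange(self.n_nodes), cols]
            self._csr_cache = (csr.indptr.astype(np.int64),
                               csr.indices.astype(np.int64),
                               csr.data.astype(np.float64), cols, vals)
        return self._csr_cache

    # -- validation -------------------------------------------------------

    def validate(self, check_regeneration: bool = True) -> None:
        """Assert every structural invariant; raises ValueError on failure."""
        base = self.base_adjacency_matrix
        win = self.input_weights
        if base.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("adjacency shape mismatch")
        if win.shape != (self.n_nodes, self.input_dim):
            raise ValueError("input weight shape mismatch")
        nz = base[base != 0.0]
        if nz.size and (np.abs(nz) > 1.0).any():
            raise ValueError("base adjacency nonzeros outside [-1, 1]")
        if self.spectral_radius > 0:
            sr = measure_spectral_radius(self.adjacency)
            if abs(sr - self.spectral_radius) > 1e-8:
                raise ValueError(
                    f"rescaled spectral radius {sr} != {self.spectral_radius}")
        counts = (win != 0.0).sum(axis=1)
        if not (counts == 1).all():
            raise ValueError("input weight rows must have exactly one nonzero")
        row_vals = win[win != 0.0]
        if (np.abs(row_vals) > 1.0).any():
            raise ValueError("input weights outside [-1, 1]")
        if check_regeneration:
            other = ReservoirRealization.generate(
                self.n_nodes, self.connection_prob, self.spectral_radius,
                self.input_dim, self.seed)
            if not (np.array_equal(base, other.base_adjacency_matrix)
                    and np.array_equal(win, other.input_weights)):
                raise ValueError("seeded regeneration is not bit-identical")

    # -- serialization ----------------------------------------------------

    def save(self, path) -> None:
        """One-archive serialization; round-trips bit-exactly."""
        with open(Path(path), "wb") as fh:  # keep the exact filename
            np.savez(fh,
                     base_adjacency_matrix=self.base_adjacency_matrix,
                     input_weights=self.input_weights,
                     n_nodes=self.n_nodes, input_dim=self.input_dim,
                     connection_prob=self.connection_prob,
                     spectral_radius=self.spectral_radius, seed=self.seed)

    @classmethod
    def load(cls, path) -> "ReservoirRealization":
        with np.load(Path(path)) as f:
            return cls(base_adjacency_matrix=f["base_adjacency_matrix"],
                       input_weights=f["input_weights"],
                       n_nodes=int(f["n_nodes"]),
                       input_dim=int(f["input_dim"]),
                       connection_prob=float(f["connection_prob"]),
                       spectral_radius=float(f["spectral_radius"]),
                       seed=int(f["seed"]))
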