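"""Attractor continuation in the spectral radius.

Starting from a spectral radius where both orbits are reconstructed, rho is
decreased in small steps (0.001 in the full protocol).  At every rho the
*same* base random matrix is rescaled and the readout retrained with the
identical input sequences, so rho is the only quantity that changes.  Each
reconstructed attractor ("branch") is then tracked by integrating the closed
loop from the branch's final state at the previous rho for a fixed window,
collecting the local maxima x_m of the projected x variable after a transient
discard, and classifying what the state settled onto.  When a branch's orbit
is lost the sweep keeps following whatever attractor the carried state
approaches — fixed point, the surviving orbit, or the switching attractor —
which is exactly the data behind a bifurcation (x_m vs rho) diagram.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .dynamics import DivergenceError, PlanarTrajectory, \
    closed_loop_projection
from .switching import RelayThresholds, relay_transitions
from .training import train_seeing_double

__all__ = [
    "ContinuationPoint",
    "ContinuationTable",
    "local_maxima",
    "classify_attractor",
    "continuation_sweep",
    "basin_probe",
]

logger = logging.getLogger(__name__)

DEFAULT_T_TRACK = 200.0
DEFAULT_DISCARD = 0.5
#: late-time displacement below this fraction of the orbit radius -> fixed point
FIXED_POINT_TOL = 1e-3
#: a branch left its orbit after this many consecutive off-label windows
BRANCH_DEBOUNCE = 2

LABELS = ("orbit_A", "orbit_B", "switching", "fixed_point", "other")


def local_maxima(series, discard_fraction: float = 0.0) -> np.ndarray:
    """Values v_k with v_{k-1} < v_k >= v_{k+1} (plateau starts count once).

    The first ``discard_fraction`` of the series is dropped as transient.
    """
    s = np.asarray(series, dtype=float)
    k0 = int(len(s) * discard_fraction)
    s = s[k0:]
    if len(s) < 3:
        raise ValueError("series too short after transient discard")
    mid = s[1:-1]
    mask = (s[:-2] < mid) & (mid >= s[2:])
    return mid[mask]


def classify_attractor(planar_traj: PlanarTrajectory, task_pair,
                       relay_thresholds: RelayThresholds = RelayThresholds()
                       ) -> str:
    """Label what the (post-transient) projected trajectory settled onto.

    fixed_point : late-time displacement below 1e-3 * b over the last
                  quarter window;
    orbit_A/B   : zero relay transitions and the mean x sign matches the
                  orbit's center;
    switching   : at least two relay transitions in each direction;
    other       : anything else (single crossings, drifting transients).
    """
    pts = planar_traj.points
    b = task_pair.radius
    tail = pts[-max(len(pts) // 4, 2):]
    if np.max(np.hypot(tail[:, 0] - tail[-1, 0],
                       tail[:, 1] - tail[-1, 1])) < FIXED_POINT_TOL * b:
        return "fixed_point"
    trans = relay_transitions(planar_traj.x, planar_traj.times,
                              relay_thresholds, low_state="B", high_state="A")
    states = trans.states
    n_to_a = states.count("A")
    n_to_b = states.count("B")
    if n_to_a >= 2 and n_to_b >= 2:
        return "switching"
    if len(trans) == 0:
        mean_x = float(np.mean(planar_traj.x))
        sign_a = np.sign(task_pair.orbit_A.x_center)
        if mean_x * sign_a > 0:
            return "orbit_A"
        if mean_x * sign_a < 0:
            return "orbit_B"
    return "other"


@dataclasses.dataclass
class ContinuationPoint:
    """One tracked branch at one rho."""

    rho: float
    branch_id: str
    xm_values: np.ndarray
    attractor_label: str
    carried_state: np.ndarray
    on_original_orbit: bool = True


@dataclasses.dataclass
class ContinuationTable:
    """All (rho, branch) records of a sweep, finest rho first."""

    points: list
    diagnostics: dict = dataclasses.field(default_factory=dict)

    def validate(self) -> None:
        last_rho: dict = {}
        for p in self.points:
            if p.branch_id in last_rho and p.rho >= last_rho[p.branch_id]:
                raise ValueError("rho must strictly decrease within a branch")
            last_rho[p.branch_id] = p.rho
            if p.attractor_label == "fixed_point" and len(p.xm_values):
                raise ValueError("fixed points must carry no local maxima")

    def to_frame(self):
        """Long-format DataFrame: one row per x_m value."""
        import pandas as pd
        rows = []
        for p in self.points:
            if len(p.xm_values):
                for xm in p.xm_values:
                    rows.append({"rho": p.rho, "branch_id": p.branch_id,
                                 "xm": float(xm),
                                 "label": p.attractor_label})
            else:
                rows.append({"rho": p.rho, "branch_id": p.branch_id,
                             "xm": np.nan, "label": p.attractor_label})
        return pd.DataFrame(rows, columns=["rho", "branch_id", "xm", "label"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    def branch_labels(self, branch_id: str):
        return [(p.rho, p.attractor_label) for p in self.points
                if p.branch_id == branch_id]


def _rho_grid(rho_start: float, rho_end: float, rho_step: float) -> np.ndarray:
    if rho_end <= 0 or rho_start < rho_end:
        raise ValueError("require rho_start >= rho_end > 0")
    if rho_step <= 0:
        raise ValueError("rho_step must be > 0")
    if rho_start == rho_end:
        return np.array([rho_start])
    ratio = (rho_start - rho_end) / rho_step
    if ratio < 1.0 - 1e-9:
        raise ValueError("rho_step exceeds the sweep range")
    n = (int(round(ratio)) if abs(ratio - round(ratio)) < 1e-6
         else int(np.floor(ratio)))
    return rho_start - rho_step * np.arange(n + 1)


def continuation_sweep(base_realization, params, task_pair,
                       rho_start: float = 0.7, rho_end: float = 0.1,
                       rho_step: float = 0.001,
                       t_track: float = DEFAULT_T_TRACK,
                       train_config=None,
                       thresholds: RelayThresholds = RelayThresholds(),
                       discard_fraction: float = DEFAULT_DISCARD,
                       feature_kind: str = "quadratic") -> ContinuationTable:
    """Downward rho sweep tracking both reconstructed orbits.

    At each rho: rescale the base matrix, retrain, integrate each live
    branch from its carried state for ``t_track``, record x_m after
    discarding the first ``discard_fraction`` of the window, classify, and
    carry the final state forward.  At the first rho the branches start from
    the end-of-training states.  (Run with ``rho_start < rho_end`` swapped
    grids externally to continue upward, e.g. to follow a fixed-point branch
    back up.)
    """
    from .training import TrainConfig
    if train_config is None:
        train_config = TrainConfig(tau=params.tau)
    grid = _rho_grid(rho_start, rho_end, rho_step)
    n_steps = int(round(t_track / params.tau))
    points: list = []
    diagnostics: dict = {"failed_rhos": []}
    branches = {
        "A": {"state": None, "alive": True, "off_count": 0, "on": True,
              "orbit_label": "orbit_A"},
        "B": {"state": None, "alive": True, "off_count": 0, "on": True,
              "orbit_label": "orbit_B"},
    }
    for rho in grid:
        real = base_realization.with_spectral_radius(float(rho))
        try:
            trained = train_seeing_double(real, params, task_pair.orbit_A,
                                          task_pair.orbit_B, train_config,
                                          feature_kind)
        except Exception as exc:  # noqa: BLE001 - sweep must survive
            logger.warning("training failed at rho=%.4f: %s", rho, exc)
            diagnostics["failed_rhos"].append(float(rho))
            continue
        for bid, br in branches.items():
            if not br["alive"]:
                continue
            r0 = br["state"]
            if r0 is None:
                r0 = (trained.end_state_A if bid == "A"
                      else trained.end_state_B)
            try:
                traj, final = closed_loop_projection(trained, r0, n_steps)
            except DivergenceError as exc:
                logger.warning("branch %s died at rho=%.4f: %s",
                               bid, rho, exc)
                br["alive"] = False
                continue
            k0 = int(len(traj) * discard_fraction)
            tail = PlanarTrajectory(times=traj.times[k0:],
                                    points=traj.points[k0:])
            label = classify_attractor(tail, task_pair, thresholds)
            xm = (np.array([]) if label == "fixed_point"
                  else local_maxima(tail.x))
            if label != br["orbit_label"]:
                br["off_count"] += 1
                if br["off_count"] >= BRANCH_DEBOUNCE:
                    br["on"] = False
            else:
                br["off_count"] = 0
                br["on"] = True
            br["state"] = final
            points.append(ContinuationPoint(
                rho=float(rho), branch_id=bid, xm_values=xm,
                attractor_label=label, carried_state=final,
                on_original_orbit=br["on"]))
        if not any(br["alive"] for br in branches.values()):
            diagnostics["all_branches_dead_at"] = float(rho)
            break
    table = ContinuationTable(points=points, diagnostics=diagnostics)
    table.validate()
    return table


def basin_probe(trained_rc, k: int, t_horizon: float, task_pair,
                thresholds: RelayThresholds = RelayThresholds(),
                discard_fraction: float = DEFAULT_DISCARD,
                seed: int = 0) -> list:
    """Classify the attractors reached from k uniform starts in [-1, 1]^N.

    A scan for untrained attractors: every label other than the two orbits
    (or switching/fixed point already on record) is worth inspecting.
    """
    rng = np.random.default_rng(seed)
    n_steps = int(round(t_horizon / trained_rc.params.tau))
    labels = []
    for _ in range(k):
        r0 = rng.uniform(-1.0, 1.0, size=trained_rc.realization.n_nodes)
        traj, _ = closed_loop_projection(trained_rc, r0, n_steps)
        k0 = int(len(traj) * discard_fraction)
        tail = PlanarTrajectory(times=traj.times[k0:], points=traj.points[k0:])
        labels.append(classify_attractor(tail, task_pair, thresholds))
    return labels
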