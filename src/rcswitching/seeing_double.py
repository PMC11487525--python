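"""The seeing-double task: two circular orbits of opposite rotation.

The driving signal is u(t) = (b_x cos t + x_cen, b_y sin t), a circle of
radius b = |b_x| = |b_y| centered at (x_cen, 0).  The task pairs a
counter-clockwise orbit C_A (b_x = b_y = b, center +x_cen) with its y-axis
mirror image C_B (b_x = -b, b_y = b, center -x_cen), which is traversed
clockwise.  Shrinking |x_cen| moves the circles together: they touch when
|x_cen| = b and overlap for 0 < |x_cen| < b, which is what makes the task
hard — overlapping training data force the reservoir to disambiguate
identical input points by their history.

This module also scores closed-loop reconstructions: a trained reservoir is
*multifunctional* when, initialized from the end-of-training state of each
drive, it reproduces both circles (small radial error about the correct
center, correct rotation direction).
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np

from .dynamics import PlanarTrajectory, closed_loop_projection

__all__ = [
    "OrbitSpec",
    "TaskPair",
    "OverlapClass",
    "orbit_signal",
    "overlap_class",
    "radial_error",
    "rotation_direction",
    "multifunctionality_check",
    "MultifunctionalityReport",
]

DEFAULT_RADIUS = 5.0
DEFAULT_VERDICT_TOL = 0.05      # radial error threshold, fraction of b
DEFAULT_VERDICT_HORIZON = 500.0  # closed-loop test duration (time units)
DEFAULT_DISCARD_FRACTION = 0.5   # transient discarded before scoring
ROTATION_TOL_PER_POINT = 1e-9    # |cross sum| below tol*count -> indeterminate


@dataclasses.dataclass(frozen=True)
class OrbitSpec:
    """One circular orbit: center (x_center, 0), signed radii (bx, by).

    The signs of bx, by encode the rotation direction: bx = by > 0 is
    counter-clockwise, bx = -by < 0 is clockwise.
    """

    x_center: float
    bx: float = DEFAULT_RADIUS
    by: float = DEFAULT_RADIUS

    def __post_init__(self):
        if abs(self.bx) != abs(self.by) or self.bx == 0:
            raise ValueError("require |bx| = |by| = b > 0 (a circle)")

    @property
    def radius(self) -> float:
        return abs(self.bx)

    @property
    def center(self) -> np.ndarray:
        return np.array([self.x_center, 0.0])

    @property
    def direction(self) -> int:
        """+1 counter-clockwise, -1 clockwise."""
        return 1 if self.bx * self.by > 0 else -1

    def evaluate(self, t) -> np.ndarray:
        """u(t) = (bx cos t + x_center, by sin t); t scalar or array."""
        t = np.asarray(t, dtype=float)
        out = np.stack([self.bx * np.cos(t) + self.x_center,
                        self.by * np.sin(t)], axis=-1)
        return out

    # alias so OrbitSpec can stand in for a generic input series
    __call__ = evaluate


@dataclasses.dataclass(frozen=True)
class TaskPair:
    """The two orbits of one seeing-double instance (B mirrors A in x)."""

    orbit_A: OrbitSpec
    orbit_B: OrbitSpec

    def __post_init__(self):
        a, b = self.orbit_A, self.orbit_B
        if not (b.x_center == -a.x_center and b.bx == -a.bx and b.by == a.by):
            raise ValueError("orbit_B must be the y-axis mirror of orbit_A")

    @classmethod
    def seeing_double(cls, x_cen: float,
                      radius: float = DEFAULT_RADIUS) -> "TaskPair":
        return cls(orbit_A=OrbitSpec(x_center=x_cen, bx=radius, by=radius),
                   orbit_B=OrbitSpec(x_center=-x_cen, bx=-radius, by=radius))

    @property
    def x_cen(self) -> float:
        return self.orbit_A.x_center

    @property
    def radius(self) -> float:
        return self.orbit_A.radius


def orbit_signal(spec: OrbitSpec, t_start: float, n_samples: int,
                 tau: float) -> PlanarTrajectory:
    """Sample the orbit at t_start + k*tau for k = 0 .. n_samples-1."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    t = t_start + tau * np.arange(n_samples)
    return PlanarTrajectory(times=t, points=spec.evaluate(t))


class OverlapClass(str, enum.Enum):
    DISJOINT = "disjoint"
    TOUCHING = "touching"
    OVERLAPPING = "overlapping"
    IDENTICAL = "identical"


def overlap_class(x_cen_magnitude: float,
                  b: float = DEFAULT_RADIUS) -> OverlapClass:
    """Geometric relation of the two circles at center offset +-x_cen."""
    if x_cen_magnitude < 0 or b < 0:
        raise ValueError("inputs must be >= 0")
    if x_cen_magnitude == 0:
        return OverlapClass.IDENTICAL
    if x_cen_magnitude > b:
        return OverlapClass.DISJOINT
    if x_cen_magnitude == b:
        return OverlapClass.TOUCHING
    return OverlapClass.OVERLAPPING


def radial_error(traj: PlanarTrajectory, spec: OrbitSpec,
                 discard_fraction: float = DEFAULT_DISCARD_FRACTION) -> float:
    """Mean relative deviation of distance-to-center from the orbit radius.

    The first ``discard_fraction`` of the trajectory is dropped as transient.
    0 for a perfect reconstruction; 1.0 for a trajectory sitting at the
    center.
    """
    k0 = int(len(traj) * discard_fraction)
    pts = traj.points[k0:]
    if len(pts) == 0:
        raise ValueError("no points remain after transient discard")
    dist = np.hypot(pts[:, 0] - spec.x_center, pts[:, 1])
    return float(np.mean(np.abs(dist - spec.radius)) / spec.radius)


def rotation_direction(traj, center) -> int:
    """Net sense of rotation about ``center``: +1 CCW, -1 CW, 0 indeterminate.

    Sign of the summed cross products of successive center-relative
    displacements; magnitudes below a per-point tolerance count as
    indeterminate (e.g. a fixed point).
    """
    pts = traj.points if hasattr(traj, "points") else np.asarray(traj, float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    rel = pts - np.asarray(center, dtype=float)
    cross = rel[:-1, 0] * rel[1:, 1] - rel[:-1, 1] * rel[1:, 0]
    total = float(np.sum(cross))
    if abs(total) < ROTATION_TOL_PER_POINT * len(pts):
        return 0
    return 1 if total > 0 else -1


@dataclasses.dataclass
class MultifunctionalityReport:
    """Verdict plus per-orbit diagnostics of the closed-loop test."""

    verdict: str                      # multifunctional | partial | failed
    diagnostics: dict                 # per-orbit radial error / direction

    def __bool__(self):
        return self.verdict == "multifunctional"


def _score_orbit(traj: PlanarTrajectory, spec: OrbitSpec, tol: float,
                 discard_fraction: float) -> dict:
    err = radial_error(traj, spec, discard_fraction)
    k0 = int(len(traj) * discard_fraction)
    tail = PlanarTrajectory(times=traj.times[k0:], points=traj.points[k0:])
    direction = rotation_direction(tail, spec.center)
    ok = bool(err < tol and direction == spec.direction)
    return {"radial_error": err, "rotation_direction": direction,
            "expected_direction": spec.direction, "reconstructed": ok}


def multifunctionality_check(trained_rc, task_pair: TaskPair,
                             horizon: float = DEFAULT_VERDICT_HORIZON,
                             tol: float = DEFAULT_VERDICT_TOL,
                             discard_fraction: float =
                             DEFAULT_DISCARD_FRACTION
                             ) -> MultifunctionalityReport:
    """Run the closed loop from both end-of-training states and score it.

    multifunctional: both orbits reconstructed (radial error < tol about the
    correct center, correct rotation sense) after transient discard.
    partial: exactly one reconstructed (e.g. both initializations fall onto
    the same surviving orbit).  failed: neither (switching or otherwise).
    """
    n_steps = int(round(horizon / trained_rc.params.tau))
    diagnostics = {}
    n_ok = 0
    for name, r0, spec in (("orbit_A", trained_rc.end_state_A,
                            task_pair.orbit_A),
                           ("orbit_B", trained_rc.end_state_B,
                            task_pair.orbit_B)):
        traj, _ = closed_loop_projection(trained_rc, r0, n_steps)
        diag = _score_orbit(traj, spec, tol, discard_fraction)
        diagnostics[name] = diag
        n_ok += diag["reconstructed"]
    verdict = {2: "multifunctional", 1: "partial", 0: "failed"}[n_ok]
    return MultifunctionalityReport(verdict=verdict, diagnostics=diagnostics)
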