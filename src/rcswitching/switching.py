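"""Metastable-state transition detection and switching statistics.

When the trained reservoir fails to reconstruct both orbits, its projected
state wanders between the two regions of the prediction plane where the
orbits used to live — metastable states we monitor through the projected x
coordinate.  Transitions are detected with a *non-ideal relay*: two
thresholds alpha < beta, where the detector enters the low state only when x
drops below alpha and the high state only when x rises above beta.  Samples
inside the (alpha, beta) band never change the state, which suppresses the
false alarms a single threshold would produce when a trajectory briefly dips
across the midline.

Residence times (durations of completed stays in each state) are summarized
as probability densities on log-spaced bins, and escape times measure how
long a trajectory launched on a just-destabilized orbit takes to leave it.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .dynamics import closed_loop_projection
from .training import train_seeing_double

__all__ = [
    "RelayThresholds",
    "TransitionSequence",
    "ResidenceHistogram",
    "relay_transitions",
    "residence_durations",
    "log_binned_density",
    "residence_histogram",
    "collect_switchings",
    "escape_time",
    "escape_time_sweep",
    "winding_counts",
]

DEFAULT_ALPHA = -2.0
DEFAULT_BETA = 2.0
DEFAULT_BINS = 100


@dataclasses.dataclass(frozen=True)
class RelayThresholds:
    """Hysteresis band of the non-ideal relay: enter the low state below
    ``alpha``, the high state above ``beta``; strictly-inside samples are
    inert.  Exact threshold hits do not trigger (strict inequalities)."""

    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA

    def __post_init__(self):
        if not self.alpha < self.beta:
            raise ValueError("require alpha < beta")


@dataclasses.dataclass
class TransitionSequence:
    """Alternating state entries detected by the relay.

    ``entries`` is an ordered list of (time, entered_state); the first
    threshold crossing sets ``initial_state`` and is not itself an entry.
    ``complete`` is set by :func:`collect_switchings` when a requested
    transition count was reached (None when not applicable).
    """

    entries: list
    initial_state: str = "undetermined"
    complete: bool | None = None

    def __post_init__(self):
        prev_t, prev_s = -np.inf, self.initial_state
        for t, s in self.entries:
            if t <= prev_t:
                raise ValueError("transition times must strictly increase")
            if s == prev_s:
                raise ValueError("entered states must strictly alternate")
            prev_t, prev_s = t, s

    def __len__(self):
        return len(self.entries)

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.entries])

    @property
    def states(self) -> list:
        return [s for _, s in self.entries]


class _Relay:
    """Incremental non-ideal relay; feeding chunks is equivalent to feeding
    the concatenated series (the carried state makes the detector causal)."""

    def __init__(self, thresholds: RelayThresholds, low_state: str = "A",
                 high_state: str = "B", state: str | None = None):
        self.thr = thresholds
        self.low = low_state
        self.high = high_state
        self.state = state  # None = undetermined
        self.initial_state = state if state is not None else "undetermined"
        self.entries: list = []

    def feed(self, x_series, times) -> None:
        x = np.asarray(x_series, dtype=float)
        t = np.asarray(times, dtype=float)
        if x.shape != t.shape:
            raise ValueError("series and times must have the same length")
        a, b = self.thr.alpha, self.thr.beta
        for xi, ti in zip(x, t):
            if xi < a and self.state != self.low:
                if self.state is None:
                    self.initial_state = self.low
                else:
                    self.entries.append((float(ti), self.low))
                self.state = self.low
            elif xi > b and self.state != self.high:
                if self.state is None:
                    self.initial_state = self.high
                else:
                    self.entries.append((float(ti), self.high))
                self.state = self.high

    def result(self, complete: bool | None = None) -> TransitionSequence:
        return TransitionSequence(entries=list(self.entries),
                                  initial_state=self.initial_state,
                                  complete=complete)


def relay_transitions(x_series, times,
                      thresholds: RelayThresholds = RelayThresholds(),
                      low_state: str = "A", high_state: str = "B",
                      initial_state: str | None = None) -> TransitionSequence:
    """Detect metastable-state transitions in a scalar series.

    By default the low state (x < alpha) is labelled "A" and the high state
    (x > beta) "B"; when monitoring the projected x coordinate of the
    seeing-double task, pass ``low_state="B", high_state="A"`` so the labels
    match the orbit centered at -x_cen (low) and +x_cen (high).
    """
    relay = _Relay(thresholds, low_state, high_state, initial_state)
    relay.feed(x_series, times)
    return relay.result()


def residence_durations(transitions: TransitionSequence):
    """Durations of completed stays, split by state.

    The open-ended stays before the first and after the last transition are
    excluded; fewer than two transitions therefore yield empty lists.
    Returns ``{state: [durations...]}`` for the two states seen.
    """
    out: dict = {}
    entries = transitions.entries
    for (t0, s0), (t1, _s1) in zip(entries[:-1], entries[1:]):
        out.setdefault(s0, []).append(t1 - t0)
    return out


def log_binned_density(durations, n_bins: int = DEFAULT_BINS):
    """Probability density of durations on geometrically spaced bins.

    Bin limits are the min and max of the data; the density integrates to 1
    (sum of density * bin width).  Returns (bin_edges, density).
    """
    d = np.asarray(durations, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if d.size < 2 or (d <= 0).any():
        raise ValueError("need at least 2 positive durations")
    lo, hi = float(d.min()), float(d.max())
    if lo == hi:
        raise ValueError("all durations equal: log-spaced binning degenerate")
    edges = np.geomspace(lo, hi, n_bins + 1)
    edges[0], edges[-1] = lo, hi  # guard rounding at the data limits
    counts, edges = np.histogram(d, bins=edges)
    widths = np.diff(edges)
    density = counts / (d.size * widths)
    return edges, density


@dataclasses.dataclass
class ResidenceHistogram:
    """Residence-time densities of both metastable states on shared
    log-spaced bins (limits: combined min/max of the two samples)."""

    bin_edges: np.ndarray
    density_A: np.ndarray
    density_B: np.ndarray

    def validate(self) -> None:
        widths = np.diff(self.bin_edges)
        for name, dens in (("A", self.density_A), ("B", self.density_B)):
            if (dens < 0).any():
                raise ValueError(f"negative density for state {name}")
            total = float(np.sum(dens * widths))
            if dens.any() and abs(total - 1.0) > 1e-12:
                raise ValueError(
                    f"density for state {name} integrates to {total}, not 1")


def residence_histogram(durations_A, durations_B,
                        n_bins: int = DEFAULT_BINS) -> ResidenceHistogram:
    da = np.asarray(durations_A, dtype=float)
    db = np.asarray(durations_B, dtype=float)
    both = np.concatenate([da, db])
    if both.size < 2 or (both <= 0).any():
        raise ValueError("need at least 2 positive durations")
    lo, hi = float(both.min()), float(both.max())
    if lo == hi:
        raise ValueError("all durations equal: log-spaced binning degenerate")
    edges = np.geomspace(lo, hi, n_bins + 1)
    edges[0], edges[-1] = lo, hi
    widths = np.diff(edges)
    out = []
    for d in (da, db):
        counts, _ = np.histogram(d, bins=edges)
        dens = (counts / (d.size * widths)) if d.size else np.zeros(n_bins)
        out.append(dens)
    hist = ResidenceHistogram(bin_edges=edges, density_A=out[0],
                              density_B=out[1])
    hist.validate()
    return hist


def collect_switchings(trained_rc, r0, target_count: int,
                       thresholds: RelayThresholds = RelayThresholds(),
                       max_time: float = 1e5, chunk_time: float = 1000.0,
                       low_state: str = "B", high_state: str = "A"):
    """Integrate the closed loop in chunks until ``target_count`` transitions.

    Returns (TransitionSequence, final_state).  ``complete`` on the sequence
    flags whether the target was reached before ``max_time``; a
    non-switching (multifunctional) reservoir simply runs out the clock with
    zero transitions.
    """
    tau = trained_rc.params.tau
    relay = _Relay(thresholds, low_state, high_state)
    state = np.asarray(r0, dtype=float)
    t0 = 0.0
    first = True
    while t0 < max_time and len(relay.entries) < target_count:
        n_steps = int(round(min(chunk_time, max_time - t0) / tau))
        if n_steps == 0:
            break
        traj, state = closed_loop_projection(trained_rc, state, n_steps,
                                             t0=t0)
        # the chunk's first sample repeats the previous chunk's last
        sl = slice(None) if first else slice(1, None)
        relay.feed(traj.x[sl], traj.times[sl])
        first = False
        t0 += n_steps * tau
    return relay.result(complete=len(relay.entries) >= target_count), state


def escape_time(x_series, times,
                thresholds: RelayThresholds = RelayThresholds(),
                start_state: str = "A", low_state: str = "A",
                high_state: str = "B"):
    """Time from times[0] to the first transition out of ``start_state``.

    The relay is primed in ``start_state`` (the metastable state of the
    initialization), so the first entry into the opposite state is the
    escape.  Returns None when the series never escapes.
    """
    relay = _Relay(thresholds, low_state, high_state, state=start_state)
    relay.feed(x_series, times)
    for t, s in relay.entries:
        if s != start_state:
            return float(t - times[0])
    return None


def escape_time_sweep(base_realization, params, task_pair, rho_grid,
                      train_config,
                      thresholds: RelayThresholds = RelayThresholds(),
                      max_time: float = 500.0,
                      feature_kind: str = "quadratic"):
    """Escape time from the orbit-A initialization across a rho grid.

    Retrains at every rho (same base matrix, rescaled; same input
    sequences), integrates from r^(C_A)(t_train), and records the first
    relay departure from the high (A) state.  Returns a DataFrame with
    columns (rho, t_esc, escaped).
    """
    import pandas as pd
    rows = []
    n_steps = int(round(max_time / params.tau))
    for rho in np.asarray(rho_grid, dtype=float):
        real = base_realization.with_spectral_radius(float(rho))
        trained = train_seeing_double(real, params, task_pair.orbit_A,
                                      task_pair.orbit_B, train_config,
                                      feature_kind)
        traj, _ = closed_loop_projection(trained, trained.end_state_A,
                                         n_steps)
        t_esc = escape_time(traj.x, traj.times, thresholds,
                            start_state="A", low_state="B", high_state="A")
        rows.append({"rho": float(rho),
                     "t_esc": np.nan if t_esc is None else t_esc,
                     "escaped": t_esc is not None})
    return pd.DataFrame(rows)


def winding_counts(traj, transitions: TransitionSequence, task_pair):
    """Revolutions completed during each completed stay.

    Tags every completed stay with the number of loops the projected
    trajectory makes about the resident orbit's center (total winding angle
    divided by 2 pi, rounded — threshold crossings cut into loops, so a
    near-complete revolution counts as one) — the basis for stratifying
    residence-time branches by loop count.  Returns a list of
    (entered_state, duration, loops) tuples aligned with
    :func:`residence_durations`.
    """
    centers = {"A": task_pair.orbit_A.center, "B": task_pair.orbit_B.center}
    times = traj.times
    out = []
    for (t0, s0), (t1, _s1) in zip(transitions.entries[:-1],
                                   transitions.entries[1:]):
        k0, k1 = np.searchsorted(times, [t0, t1])
        seg = traj.points[k0:k1 + 1] - centers[s0]
        if len(seg) < 2:
            out.append((s0, t1 - t0, 0))
            continue
        ang = np.arctan2(seg[:, 1], seg[:, 0])
        total = np.abs(np.unwrap(ang)[-1] - np.unwrap(ang)[0])
        out.append((s0, t1 - t0, int(round(total / (2 * np.pi)))))
    return out
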