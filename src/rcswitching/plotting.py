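"""Optional plotting helpers (matplotlib): bifurcation panels and portraits.

Excluded from the computational pipeline; import fails gracefully when
matplotlib is not installed.
"""

from __future__ import annotations

import numpy as np


def _mpl():
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "plotting requires matplotlib (install the 'plot' extra)"
        ) from exc
    return plt


def plot_bifurcation(frame, ax=None, branch_colors=None):
    """Scatter the local maxima x_m against rho, one color per branch.

    ``frame`` is the long-format continuation table (columns rho,
    branch_id, xm, label) as produced by ``ContinuationTable.to_frame``.
    """
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    colors = branch_colors or {"A": "tab:blue", "B": "tab:orange"}
    for bid, sub in frame.dropna(subset=["xm"]).groupby("branch_id"):
        ax.plot(sub["rho"], sub["xm"], ".", ms=2,
                color=colors.get(bid, "k"), label=f"branch {bid}")
    ax.set_xlabel(r"spectral radius $\rho$")
    ax.set_ylabel(r"local maxima $x_m$")
    ax.invert_xaxis()
    ax.legend(markerscale=6)
    return ax


def plot_projection(traj, task_pair=None, ax=None):
    """Phase portrait of a projected trajectory, with the target circles."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.plot(traj.x, traj.y, lw=0.5, color="k")
    if task_pair is not None:
        t = np.linspace(0, 2 * np.pi, 200)
        for spec, c in ((task_pair.orbit_A, "tab:blue"),
                        (task_pair.orbit_B, "tab:orange")):
            ax.plot(spec.x_center + spec.radius * np.cos(t),
                    spec.radius * np.sin(t), "--", color=c)
    ax.set_aspect("equal")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    return ax
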