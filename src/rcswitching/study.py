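"""Experiment orchestration: the full multi-x_cen study.

For every center offset in the configuration, :func:`run_study` runs the
spectral-radius continuation, records the multifunctionality verdict at each
rho, and — wherever the switching label occurs — collects transition
statistics at the first switching rho.  All outputs are deterministic given
the configured seed; every file gets a JSON sidecar with the package version,
seed, and a configuration hash.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from .config import ExperimentConfig, write_config
from .continuation import continuation_sweep
from .dynamics import RCParams
from .network import ReservoirRealization
from .seeing_double import TaskPair, multifunctionality_check
from .switching import (RelayThresholds, collect_switchings,
                        residence_durations, residence_histogram)
from .training import TrainConfig, train_seeing_double

__all__ = ["run_study"]

logger = logging.getLogger(__name__)


def _sidecar(config: ExperimentConfig, extra: dict | None = None) -> dict:
    from . import __version__
    meta = {"version": __version__, "seed": config.network.seed,
            "config_hash": config.config_hash(),
            "config": config.model_dump()}
    if extra:
        meta.update(extra)
    return meta


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_study(config: ExperimentConfig, outdir=None) -> Path:
    """Run continuation + verdicts (+ switching statistics) per x_cen.

    Returns the artifact directory.  Failures in one stage are logged and
    the remaining stages continue.
    """
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_config(config, outdir / "config.yaml")
    _write_json(_sidecar(config), outdir / "study.json")

    params = RCParams(gamma=config.dynamics.gamma,
                      sigma=config.dynamics.sigma, tau=config.dynamics.tau)
    train_config = TrainConfig(t_listen=config.training.t_listen,
                               t_train=config.training.t_train,
                               ridge_param=config.training.ridge_param,
                               tau=config.dynamics.tau)
    thresholds = RelayThresholds(alpha=config.relay.alpha,
                                 beta=config.relay.beta)
    base = ReservoirRealization.generate(
        n_nodes=config.network.n_nodes,
        connection_prob=config.network.connection_prob,
        spectral_radius=config.continuation.rho_start,
        input_dim=2, seed=config.network.seed)

    for x_cen in config.task.x_cen_values:
        tag = f"xcen_{x_cen:g}"
        subdir = outdir / tag
        subdir.mkdir(exist_ok=True)
        task = TaskPair.seeing_double(x_cen, config.task.radius)
        logger.info("continuation sweep for x_cen=%g", x_cen)
        try:
            table = continuation_sweep(
                base, params, task,
                rho_start=config.continuation.rho_start,
                rho_end=config.continuation.rho_end,
                rho_step=config.continuation.rho_step,
                t_track=config.continuation.t_track,
                train_config=train_config, thresholds=thresholds)
        except Exception as exc:  # noqa: BLE001 - continue remaining stages
            logger.error("continuation failed for %s: %s", tag, exc)
            _write_json(_sidecar(config, {"error": str(exc)}),
                        subdir / "error.json")
            continue
        table.write_csv(subdir / "continuation.csv")
        _write_json(_sidecar(config, {"x_cen": x_cen,
                                      "diagnostics": table.diagnostics}),
                    subdir / "continuation.json")

        verdicts = _verdicts_along_grid(base, params, task, train_config,
                                        config)
        _write_json(_sidecar(config, {"x_cen": x_cen,
                                      "verdicts": verdicts}),
                    subdir / "verdicts.json")

        switch_rhos = sorted({p.rho for p in table.points
                              if p.attractor_label == "switching"},
                             reverse=True)
        if switch_rhos:
            _switching_stats(base, params, task, train_config, thresholds,
                             switch_rhos[0], config, subdir)
    return outdir


def _verdicts_along_grid(base, params, task, train_config, config) -> list:
    """Multifunctionality verdict from fresh end-of-training states at every
    rho of the continuation grid."""
    cont = config.continuation
    n = int(np.floor((cont.rho_start - cont.rho_end) / cont.rho_step
                     + 1e-9)) + 1
    grid = cont.rho_start - cont.rho_step * np.arange(n)
    out = []
    for rho in grid:
        real = base.with_spectral_radius(float(rho))
        try:
            trained = train_seeing_double(real, params, task.orbit_A,
                                          task.orbit_B, train_config)
            report = multifunctionality_check(
                trained, task, horizon=config.verdict.horizon,
                tol=config.verdict.tol,
                discard_fraction=config.verdict.discard_fraction)
            out.append({"rho": float(rho), "verdict": report.verdict,
                        "diagnostics": report.diagnostics})
        except Exception as exc:  # noqa: BLE001
            out.append({"rho": float(rho), "verdict": "error",
                        "error": str(exc)})
    return out


def _switching_stats(base, params, task, train_config, thresholds, rho,
                     config, subdir: Path) -> None:
    import pandas as pd
    logger.info("switching statistics at rho=%.4f", rho)
    real = base.with_spectral_radius(float(rho))
    trained = train_seeing_double(real, params, task.orbit_A, task.orbit_B,
                                  train_config)
    transitions, _ = collect_switchings(
        trained, trained.end_state_A, config.switching.target_count,
        thresholds, max_time=config.switching.max_time)
    pd.DataFrame(transitions.entries,
                 columns=["time", "entered_state"]).to_csv(
        subdir / "transitions.csv", index=False, float_format="%.17g")
    durations = residence_durations(transitions)
    meta = {"rho": rho, "n_transitions": len(transitions),
            "complete": transitions.complete}
    try:
        hist = residence_histogram(durations.get("A", []),
                                   durations.get("B", []),
                                   config.switching.n_bins)
        edges = hist.bin_edges
        pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                      "density_A": hist.density_A,
                      "density_B": hist.density_B}).to_csv(
            subdir / "residence_histogram.csv", index=False,
            float_format="%.17g")
    except ValueError as exc:
        meta["histogram_error"] = str(exc)
    _write_json(_sidecar(config, meta), subdir / "switching.json")
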