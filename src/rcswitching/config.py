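"""Experiment configuration: schema, validation, YAML round-trip.

A single :class:`ExperimentConfig` describes a full study: network draw,
dynamics parameters, training windows, the list of center offsets x_cen, the
continuation grid, relay thresholds, and switching-collection limits.
Unknown keys are rejected and every cross-field invariant (alpha < beta,
t_train > t_listen, ...) is checked before any computation runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["ExperimentConfig", "load_config", "write_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NetworkSection(_Strict):
    n_nodes: int = Field(100, ge=1)
    connection_prob: float = Field(0.04, gt=0.0, le=1.0)
    seed: int = 0


class DynamicsSection(_Strict):
    gamma: float = Field(10.0, gt=0.0)
    sigma: float = Field(0.1, ge=0.0)
    tau: float = Field(0.01, gt=0.0)

    @model_validator(mode="after")
    def _stability(self):
        if self.tau * self.gamma >= 1:
            raise ValueError("require tau * gamma < 1")
        return self


class TrainingSection(_Strict):
    t_listen: float = Field(50.0, ge=0.0)
    t_train: float = Field(550.0, gt=0.0)
    ridge_param: float = Field(1e-4, ge=0.0)

    @model_validator(mode="after")
    def _windows(self):
        if self.t_train <= self.t_listen:
            raise ValueError("t_train must exceed t_listen")
        return self


class TaskSection(_Strict):
    x_cen_values: list[float] = Field(
        default_factory=lambda: [8.0, 6.5, 5.0, 3.5, 2.0])
    radius: float = Field(5.0, gt=0.0)


class ContinuationSection(_Strict):
    rho_start: float = Field(0.7, gt=0.0)
    rho_end: float = Field(0.1, gt=0.0)
    rho_step: float = Field(0.001, gt=0.0)
    t_track: float = Field(200.0, gt=0.0)

    @model_validator(mode="after")
    def _range(self):
        if self.rho_start < self.rho_end:
            raise ValueError("rho_start must be >= rho_end")
        if (self.rho_start > self.rho_end
                and self.rho_step > self.rho_start - self.rho_end):
            raise ValueError("rho_step exceeds the sweep range")
        return self


class VerdictSection(_Strict):
    horizon: float = Field(500.0, gt=0.0)
    tol: float = Field(0.05, gt=0.0)
    discard_fraction: float = Field(0.5, ge=0.0, lt=1.0)


class RelaySection(_Strict):
    alpha: float = -2.0
    beta: float = 2.0

    @model_validator(mode="after")
    def _ordered(self):
        if self.alpha >= self.beta:
            raise ValueError("require alpha < beta")
        return self


class SwitchingSection(_Strict):
    target_count: int = Field(10000, ge=1)
    max_time: float = Field(3e5, gt=0.0)
    n_bins: int = Field(100, ge=2)


class ExperimentConfig(_Strict):
    network: NetworkSection = NetworkSection()
    dynamics: DynamicsSection = DynamicsSection()
    training: TrainingSection = TrainingSection()
    task: TaskSection = TaskSection()
    continuation: ContinuationSection = ContinuationSection()
    verdict: VerdictSection = VerdictSection()
    relay: RelaySection = RelaySection()
    switching: SwitchingSection = SwitchingSection()
    output_dir: str = "rcswitching-study"

    @model_validator(mode="after")
    def _train_window_vs_tau(self):
        cols = (self.training.t_train
                - self.training.t_listen) / self.dynamics.tau
        if cols < 2 * self.network.n_nodes:
            raise ValueError("training window too short: need >= 2N columns")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment configuration."""
    with open(Path(path)) as fh:
        raw = yaml.safe_load(fh) or {}
    return ExperimentConfig.model_validate(raw)


def write_config(config: ExperimentConfig, path) -> None:
    with open(Path(path), "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
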