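"""Flat YAML experiment configuration with strict key checking."""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .neural_coding import (
    ACTIVATION_KINDS,
    ActivationSpec,
    CodingLayer,
    ThresholdSpec,
    sample_sensory_weights,
)
from .plasticity import LearningParams
from .task_model import TaskGeometry, default_geometry

__all__ = ["ExperimentConfig", "load_config", "config_hash"]

_DEFAULT_POSTURES = (-math.pi / 4, 0.0, math.pi / 4)


@dataclass
class ExperimentConfig:
    """Every tunable of the simulator, one flat namespace.

    The YAML file uses the same key names (``lambda`` maps to ``lam``).
    Unknown keys in a file are rejected before any computation.
    """

    # task geometry
    K: int = 8
    target_start_angle: float = 0.0
    posture_angles: tuple = _DEFAULT_POSTURES
    n_muscles: int = 5
    muscle_base_angles: tuple | None = None
    posture_rotations: tuple | None = None
    # coding layer
    n_neurons: int = 2000
    theta: float = 3.0
    theta_heterogeneity_sd: float = 0.0
    activation: str = "threshold_linear"
    beta: float = 1.0
    weight_seed: int | None = None
    # learning
    eta: float = 0.4
    lam: float = 0.0
    n_trials: int = 20_000
    adaptable: tuple = ("W",)
    convergence_window: tuple | None = None
    train_seed: int | None = None
    # experiment orchestration
    seed: int = 0
    runs: int = 10
    theta_grid: tuple | None = None  # None = 18 points from -3 to 3.8
    generalization_targets: int = 500
    generalization_spacing: str = "random"
    modulation_margin: float = 0.005
    w_init_sd: float | None = None  # comparison nets; None = 1/sqrt(N)
    j_init_sd: float = 0.1  # comparison nets; 0 is a silent fixed point

    def __post_init__(self):
        if self.activation not in ACTIVATION_KINDS:
            raise ValueError(
                f"unknown activation {self.activation!r}; choose from {ACTIVATION_KINDS}"
            )

    # ---- construction of model objects -------------------------------------

    def geometry(self) -> TaskGeometry:
        return default_geometry(
            K=self.K,
            target_start_angle=self.target_start_angle,
            posture_angles=self.posture_angles,
            n_muscles=self.n_muscles,
            muscle_base_angles=self.muscle_base_angles,
            posture_rotations=self.posture_rotations,
        )

    def coding(self, weight_seed=None, theta_seed: int | None = None) -> CodingLayer:
        if weight_seed is None:
            weight_seed = self.weight_seed if self.weight_seed is not None else self.seed
        weights = sample_sensory_weights(self.n_neurons, weight_seed)
        thresholds = ThresholdSpec(
            base=self.theta,
            heterogeneity_sd=self.theta_heterogeneity_sd,
            seed=theta_seed if theta_seed is not None else self.seed,
        )
        return CodingLayer(weights, thresholds, ActivationSpec(self.activation, self.beta))

    def learning_params(self) -> LearningParams:
        window = self.convergence_window
        return LearningParams(
            eta=self.eta,
            lam=self.lam,
            n_trials=self.n_trials,
            adaptable=tuple(self.adaptable),
            convergence_window=tuple(window) if window is not None else None,
        )

    def resolved_theta_grid(self) -> np.ndarray:
        if self.theta_grid is not None:
            return np.asarray(self.theta_grid, dtype=float)
        return np.linspace(-3.0, 3.8, 18)

    # ---- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            key = "lambda" if f.name == "lam" else f.name
            value = getattr(self, f.name)
            if isinstance(value, tuple):
                value = list(value)
            elif isinstance(value, np.ndarray):
                value = value.tolist()
            out[key] = value
        return out


_FIELD_NAMES = {("lambda" if f.name == "lam" else f.name) for f in fields(ExperimentConfig)}


def load_config(source: str | Path | dict | None, **overrides) -> ExperimentConfig:
    """Build a config from a YAML file (or dict), rejecting unknown keys."""
    data: dict = {}
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {source} must hold a flat mapping")
        data.update(loaded)
    elif isinstance(source, dict):
        data.update(source)
    elif source is not None:
        raise TypeError(f"cannot load config from {type(source)}")
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "lambda" in data:
        data["lam"] = data.pop("lambda")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return ExperimentConfig(**data)


def config_hash(config: ExperimentConfig) -> str:
    """Stable short hash of the effective configuration."""
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
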