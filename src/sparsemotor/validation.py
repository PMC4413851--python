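"""Independent oracles and tiny deterministic fixtures for testing.

The finite-difference gradient here is deliberately naive — it never calls
the analytic gradient code it is used to check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .neural_coding import (
    ActivationSpec,
    CodingLayer,
    ThresholdSpec,
    sample_sensory_weights,
)
from .plasticity import LearningParams
from .task_model import TaskGeometry, default_geometry

__all__ = [
    "OracleFailureError",
    "Fixture",
    "finite_difference_gradient",
    "make_fixture",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("tiny-sparse", "tiny-dense")


class OracleFailureError(RuntimeError):
    """The oracle itself hit a non-finite value and cannot judge anything."""


@dataclass(frozen=True)
class Fixture:
    """A frozen tiny network instance, fully determined by its seeds."""

    name: str
    geometry: TaskGeometry
    coding: CodingLayer
    params: LearningParams
    weight_seed: int
    train_seed: int
    expected_sparseness: float

    def to_config(self) -> dict:
        """Flat config dict from which the fixture can be rebuilt."""
        g = self.geometry
        return {
            "K": g.targets.K,
            "target_start_angle": float(g.targets.angles[0]),
            "posture_angles": [float(a) for a in g.postures.angles],
            "n_muscles": g.muscles.n_muscles,
            "n_neurons": self.coding.n_neurons,
            "theta": self.coding.thresholds.base,
            "theta_heterogeneity_sd": self.coding.thresholds.heterogeneity_sd,
            "activation": self.coding.activation.kind,
            "beta": self.coding.activation.beta,
            "weight_seed": self.weight_seed,
            "eta": self.params.eta,
            "lambda": self.params.lam,
            "n_trials": self.params.n_trials,
            "train_seed": self.train_seed,
        }


def finite_difference_gradient(cost, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central-difference gradient estimate of ``cost`` at ``x``, entry by entry."""
    if h <= 0:
        raise ValueError("step h must be positive")
    x = np.asarray(x, dtype=float)
    grad = np.empty_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = x.copy()
        xm = x.copy()
        xp[idx] += h
        xm[idx] -= h
        cp, cm = cost(xp), cost(xm)
        if not (np.isfinite(cp) and np.isfinite(cm)):
            raise OracleFailureError(f"non-finite cost at perturbed entry {idx}")
        grad[idx] = (cp - cm) / (2.0 * h)
    return grad


def _tiny_geometry() -> TaskGeometry:
    # 2 targets, a single midrange posture, 2 muscles
    return default_geometry(
        K=2, posture_angles=[0.0], n_muscles=2, posture_rotations=[0.0]
    )


def make_fixture(name: str) -> Fixture:
    """Frozen tiny instances: N=6, K=2, one posture.

    ``tiny-sparse`` places the homogeneous threshold between the 3rd and 4th
    largest per-neuron pre-activation maxima so that exactly half the neurons
    are never active; ``tiny-dense`` uses theta = -10 so all are active.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    weight_seed, train_seed, n = 20150429, 648, 6
    geometry = _tiny_geometry()
    weights = sample_sensory_weights(n, weight_seed)
    if name == "tiny-dense":
        theta, expected = -10.0, 0.0
    else:
        # per-neuron best pre-activation over the conditions, thresholds at 0
        maxima = np.max(
            [weights.J_v @ v + weights.J_p @ p for v, p in geometry.conditions()],
            axis=0,
        )
        top = np.sort(maxima)[::-1]
        theta = float((top[2] + top[3]) / 2.0)  # 3 of 6 neurons stay silent
        expected = 0.5
    coding = CodingLayer(weights, ThresholdSpec(theta), ActivationSpec())
    params = LearningParams(n_trials=500)
    return Fixture(
        name=name,
        geometry=geometry,
        coding=coding,
        params=params,
        weight_seed=weight_seed,
        train_seed=train_seed,
        expected_sparseness=expected,
    )
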