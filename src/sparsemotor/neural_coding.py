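"""Population coding layer: rectified activations at fixed metabolic cost.

Each neuron i receives a visual target vector v and a proprioceptive
posture vector p through fixed random weights and fires

    u_i = J_v[i] . v + J_p[i] . p - theta_i
    r_i = rectified nonlinearity of u_i            (see ActivationSpec)
    A   = r / ||r||                                (so that A^T A = 1)

The unit-norm constraint pins the squared-summed activity (the metabolic
cost) at 1 for every presented input, so the threshold theta controls how
many neurons participate without changing how much total activity is spent.
If no neuron crosses threshold the population is silent and A = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SensoryWeights",
    "ThresholdSpec",
    "ActivationSpec",
    "ActivityVector",
    "CodingLayer",
    "sample_sensory_weights",
    "compute_activity",
    "activity_table",
    "sparseness",
    "ACTIVATION_KINDS",
]

ACTIVATION_KINDS = ("threshold_linear", "tanh_rectified", "sigmoid")

_UNIT_TOL = 1e-6
_NORM_TOL = 1e-10


@dataclass(frozen=True)
class SensoryWeights:
    """Fixed random input weights, one row per neuron."""

    J_v: np.ndarray  # (N, 2)
    J_p: np.ndarray  # (N, 2)
    seed: int | None = None

    @property
    def n_neurons(self) -> int:
        return self.J_v.shape[0]


@dataclass(frozen=True)
class ThresholdSpec:
    """Per-neuron thresholds theta_i = base + xi_i, xi_i ~ N(0, sd^2)."""

    base: float
    heterogeneity_sd: float = 0.0
    seed: int | None = None

    def resolve(self, n_neurons: int) -> np.ndarray:
        """Materialize the per-neuron threshold vector."""
        if self.heterogeneity_sd == 0.0:
            return np.full(n_neurons, self.base, dtype=float)
        rng = np.random.default_rng(self.seed)
        return self.base + self.heterogeneity_sd * rng.standard_normal(n_neurons)

    def with_base(self, base: float) -> "ThresholdSpec":
        """Same heterogeneity draw, shifted to a new base (for theta sweeps)."""
        return ThresholdSpec(base=base, heterogeneity_sd=self.heterogeneity_sd, seed=self.seed)


@dataclass(frozen=True)
class ActivationSpec:
    """Choice of rectified nonlinearity.

    ``threshold_linear`` ignores beta. ``tanh_rectified`` fires
    [tanh(beta * u)]_+ and ``sigmoid`` fires [logistic(beta * u) - 1/2]_+,
    both zero at and below threshold like the threshold-linear case.
    """

    kind: str = "threshold_linear"
    beta: float = 1.0

    def __post_init__(self):
        if self.kind not in ACTIVATION_KINDS:
            raise ValueError(
                f"unknown activation kind {self.kind!r}; choose from {ACTIVATION_KINDS}"
            )


@dataclass(frozen=True)
class ActivityVector:
    """Normalized population response to one (target, posture) input."""

    values: np.ndarray  # (N,) nonnegative; unit norm unless silent
    active_mask: np.ndarray  # (N,) bool, values > 0
    is_silent: bool


@dataclass(frozen=True)
class CodingLayer:
    """Sensory weights + thresholds + activation, with thresholds resolved."""

    weights: SensoryWeights
    thresholds: ThresholdSpec
    activation: ActivationSpec = field(default_factory=ActivationSpec)

    @property
    def n_neurons(self) -> int:
        return self.weights.n_neurons

    def theta_values(self) -> np.ndarray:
        return self.thresholds.resolve(self.n_neurons)

    def with_theta(self, base: float) -> "CodingLayer":
        return CodingLayer(
            weights=self.weights,
            thresholds=self.thresholds.with_base(base),
            activation=self.activation,
        )


def sample_sensory_weights(N: int, seed: int | np.random.SeedSequence) -> SensoryWeights:
    """Two N x 2 matrices of iid standard-Gaussian entries."""
    if N < 1:
        raise ValueError(f"need at least one neuron, got N={N}")
    rng = np.random.default_rng(seed)
    J_v = rng.standard_normal((N, 2))
    J_p = rng.standard_normal((N, 2))
    seed_int = seed if isinstance(seed, int) else None
    return SensoryWeights(J_v=J_v, J_p=J_p, seed=seed_int)


def _check_unit(vec: np.ndarray, name: str) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (2,):
        raise ValueError(f"{name} must be a 2-vector, got shape {vec.shape}")
    if abs(vec @ vec - 1.0) > _UNIT_TOL:
        raise ValueError(f"{name} must be a unit vector, got norm {np.sqrt(vec @ vec)}")
    return vec


def raw_response(u: np.ndarray, activation: ActivationSpec) -> np.ndarray:
    """Rectified nonlinearity applied to pre-activations u."""
    if activation.kind == "threshold_linear":
        return np.maximum(u, 0.0)
    if activation.kind == "tanh_rectified":
        return np.maximum(np.tanh(activation.beta * u), 0.0)
    # logistic, shifted to vanish at u = 0 and rectified
    return np.maximum(1.0 / (1.0 + np.exp(-activation.beta * u)) - 0.5, 0.0)


def _normalize(r: np.ndarray) -> ActivityVector:
    norm = np.linalg.norm(r)
    if norm == 0.0:
        return ActivityVector(values=r, active_mask=r > 0, is_silent=True)
    values = r / norm
    return ActivityVector(values=values, active_mask=values > 0, is_silent=False)


def compute_activity(
    v: np.ndarray,
    p: np.ndarray,
    weights: SensoryWeights,
    thresholds: ThresholdSpec | np.ndarray,
    activation: ActivationSpec = ActivationSpec(),
) -> ActivityVector:
    """Population response to one input, normalized to unit squared cost."""
    v = _check_unit(v, "target vector")
    p = _check_unit(p, "posture vector")
    theta = (
        thresholds.resolve(weights.n_neurons)
        if isinstance(thresholds, ThresholdSpec)
        else np.asarray(thresholds, dtype=float)
    )
    if theta.shape != (weights.n_neurons,):
        raise ValueError(
            f"threshold vector shape {theta.shape} does not match N={weights.n_neurons}"
        )
    u = weights.J_v @ v + weights.J_p @ p - theta
    return _normalize(raw_response(u, activation))


def activity_table(
    coding: CodingLayer,
    conditions,
) -> np.ndarray:
    """N x C matrix of normalized activities over (target, posture) pairs.

    Columns of all-zero indicate silent conditions. Vectorized equivalent of
    calling :func:`compute_activity` per condition.
    """
    conditions = list(conditions)
    if not conditions:
        raise ValueError("need at least one (target, posture) condition")
    V = np.stack([np.asarray(v, dtype=float) for v, _ in conditions])  # (C, 2)
    P = np.stack([np.asarray(p, dtype=float) for _, p in conditions])  # (C, 2)
    theta = coding.theta_values()
    U = coding.weights.J_v @ V.T + coding.weights.J_p @ P.T - theta[:, None]  # (N, C)
    R = raw_response(U, coding.activation)
    norms = np.linalg.norm(R, axis=0)
    safe = np.where(norms == 0.0, 1.0, norms)
    return R / safe[None, :]


def sparseness(
    coding: CodingLayer,
    conditions,
) -> float:
    """Fraction of neurons whose activity is zero across every condition."""
    table = activity_table(coding, conditions)
    never_active = np.all(table <= 0.0, axis=1)
    return float(never_active.sum()) / coding.n_neurons
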