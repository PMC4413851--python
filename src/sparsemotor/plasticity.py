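"""Gradient learning of the sensorimotor map.

Per trial the cost is

    C = 1/2 ||v - P [W A]_+||^2 + lambda/2 ||M||^2

with M = [W A]_+ the rectified muscle drive. The neuron-to-muscle update is
the (sub)gradient step

    dW = eta * (P_+^T e - lambda * M) A^T

where P_+ zeroes the columns of inactive muscles (subgradient 0 at the
rectification kink) and e = v - P M. For the comparison networks the same
cost is differentiated through the activation nonlinearity and the
unit-norm normalization to update the sensory weights J_v, J_p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .neural_coding import (
    ActivationSpec,
    ActivityVector,
    CodingLayer,
    activity_table,
    raw_response,
)
from .task_model import TaskGeometry, make_trial_schedule

__all__ = [
    "MuscleMap",
    "LearningParams",
    "TrainResult",
    "UnsupportedConfigurationError",
    "muscle_activity",
    "masked_projection",
    "update_W",
    "update_J",
    "train",
    "converged_error",
    "trial_cost",
]

logger = logging.getLogger(__name__)


class UnsupportedConfigurationError(ValueError):
    """Raised for adaptable-weight / activation combinations that make no sense."""


@dataclass
class MuscleMap:
    """Adaptable neuron-to-muscle connectivity, N_M x N, zero-initialized."""

    W: np.ndarray

    @classmethod
    def zeros(cls, n_muscles: int, n_neurons: int) -> "MuscleMap":
        return cls(W=np.zeros((n_muscles, n_neurons)))

    @classmethod
    def gaussian(
        cls, n_muscles: int, n_neurons: int, sd: float, seed
    ) -> "MuscleMap":
        rng = np.random.default_rng(seed)
        return cls(W=sd * rng.standard_normal((n_muscles, n_neurons)))


@dataclass(frozen=True)
class LearningParams:
    eta: float = 0.4
    lam: float = 0.0
    n_trials: int = 20_000
    adaptable: tuple[str, ...] = ("W",)
    # 1-based inclusive (start, end) trial window; None = final 10% of trials
    convergence_window: tuple[int, int] | None = None

    def __post_init__(self):
        if self.eta < 0:
            raise ValueError("learning rate eta must be nonnegative")
        if self.lam < 0:
            raise ValueError("regularization lambda must be nonnegative")
        unknown = set(self.adaptable) - {"W", "J"}
        if unknown:
            raise ValueError(f"unknown adaptable weights: {sorted(unknown)}")

    def window_for(self, n_trials: int) -> tuple[int, int]:
        if self.convergence_window is not None:
            return self.convergence_window
        start = int(0.9 * n_trials) + 1
        return (min(start, n_trials), n_trials)


@dataclass
class TrainResult:
    """Full squared-error trace plus final weights."""

    errors: np.ndarray  # (T,) squared movement error per trial
    W: np.ndarray
    J_v: np.ndarray
    J_p: np.ndarray
    seed: int
    converged_error: float
    window: tuple[int, int]


def _activity_values(A) -> tuple[np.ndarray, bool]:
    if isinstance(A, ActivityVector):
        return A.values, A.is_silent
    A = np.asarray(A, dtype=float)
    return A, not np.any(A > 0)


def muscle_activity(W: np.ndarray, A) -> tuple[np.ndarray, np.ndarray]:
    """Rectified muscle drive M = [W A]_+ and the active-muscle mask."""
    values, _ = _activity_values(A)
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[1] != values.shape[0]:
        raise ValueError(
            f"W shape {W.shape} incompatible with activity length {values.shape}"
        )
    drive = W @ values
    M = np.maximum(drive, 0.0)
    return M, drive > 0


def masked_projection(P: np.ndarray, active_muscles: np.ndarray) -> np.ndarray:
    """Copy of P with columns of inactive muscles zeroed."""
    P = np.asarray(P, dtype=float)
    mask = np.asarray(active_muscles, dtype=bool)
    if mask.shape != (P.shape[1],):
        raise ValueError(f"mask length {mask.shape} does not match P columns {P.shape}")
    return P * mask[None, :]


def update_W(
    W: np.ndarray,
    e: np.ndarray,
    A,
    P_plus: np.ndarray,
    params: LearningParams,
) -> np.ndarray:
    """One gradient step of the neuron-to-muscle weights; silent trials are no-ops."""
    values, silent = _activity_values(A)
    W = np.asarray(W, dtype=float)
    if silent:
        return W.copy()
    e = np.asarray(e, dtype=float)
    P_plus = np.asarray(P_plus, dtype=float)
    if P_plus.shape != (e.shape[0], W.shape[0]):
        raise ValueError(
            f"masked projection {P_plus.shape} incompatible with W {W.shape}"
        )
    M = np.maximum(W @ values, 0.0)
    h = P_plus.T @ e - params.lam * M
    return W + params.eta * np.outer(h, values)


def _forward(J_v, J_p, W, v, p, P, theta, activation, lam):
    """Full forward pass; returns intermediates needed by the gradients."""
    u = J_v @ v + J_p @ p - theta
    z_raw = raw_response(u, activation)
    norm = np.linalg.norm(z_raw)
    if norm == 0.0:
        return None  # silent population
    A = z_raw / norm
    drive = W @ A
    M = np.maximum(drive, 0.0)
    x = P @ M
    e = v - x
    cost = 0.5 * (e @ e) + 0.5 * lam * (M @ M)
    return u, z_raw, norm, A, drive, M, e, cost


def trial_cost(J_v, J_p, W, v, p, P, theta, activation, lam=0.0) -> float:
    """Scalar trial cost; silent populations incur the no-movement cost."""
    fwd = _forward(J_v, J_p, W, v, p, P, theta, activation, lam)
    if fwd is None:
        return 0.5 * float(v @ v)
    return float(fwd[-1])


def _coding_gradients(J_v, J_p, W, v, p, P, theta, activation, lam):
    """Gradients of the trial cost w.r.t. J_v, J_p (and W), chain-ruled
    through the rectified activation and the unit-norm normalization."""
    fwd = _forward(J_v, J_p, W, v, p, P, theta, activation, lam)
    if fwd is None:
        return None
    u, z_raw, norm, A, drive, M, e, cost = fwd
    dC_dM = -(P.T @ e) + lam * M
    dC_ddrive = dC_dM * (drive >= 0)  # subgradient 1 at the kink (see train)
    dC_dA = W.T @ dC_ddrive
    # A = z_raw / ||z_raw||: projector through the normalization
    dC_dz = (dC_dA - A * (A @ dC_dA)) / norm
    if activation.kind == "threshold_linear":
        dz_du = (u > 0).astype(float)
    elif activation.kind == "tanh_rectified":
        t = np.tanh(activation.beta * u)
        dz_du = activation.beta * (1.0 - t * t) * (t > 0)
    else:  # sigmoid
        s = 1.0 / (1.0 + np.exp(-activation.beta * u))
        dz_du = activation.beta * s * (1.0 - s) * (s > 0.5)
    dC_du = dC_dz * dz_du
    dJ_v = np.outer(dC_du, v)
    dJ_p = np.outer(dC_du, p)
    dW = np.outer(dC_ddrive, A)
    return dJ_v, dJ_p, dW, e, cost


def update_J(
    J_v: np.ndarray,
    J_p: np.ndarray,
    W: np.ndarray,
    v: np.ndarray,
    p: np.ndarray,
    P: np.ndarray,
    theta: np.ndarray,
    activation: ActivationSpec,
    params: LearningParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One gradient step of the sensory weights (comparison networks only)."""
    if activation.kind != "tanh_rectified":
        raise UnsupportedConfigurationError(
            "sensory-weight learning is defined only for the tanh_rectified "
            f"comparison networks, not {activation.kind!r}"
        )
    grads = _coding_gradients(J_v, J_p, W, v, p, P, theta, activation, params.lam)
    if grads is None:
        return J_v.copy(), J_p.copy()
    dJ_v, dJ_p, _, _, _ = grads
    return J_v - params.eta * dJ_v, J_p - params.eta * dJ_p


def converged_error(result: TrainResult | np.ndarray, window: tuple[int, int]) -> float:
    """Mean squared error over a 1-based inclusive trial window."""
    errors = result.errors if isinstance(result, TrainResult) else np.asarray(result)
    start, end = window
    if not (1 <= start <= end <= errors.shape[0]):
        raise ValueError(
            f"window {window} invalid for a trace of {errors.shape[0]} trials"
        )
    return float(np.mean(errors[start - 1 : end]))


def train(
    geometry: TaskGeometry,
    coding: CodingLayer,
    muscle_map: MuscleMap | None = None,
    params: LearningParams = LearningParams(),
    seed: int = 0,
) -> TrainResult:
    """Run the full trial loop and return the error trace and final weights.

    Each trial: draw (target, posture), compute the population activity,
    the rectified muscle drive, the executed movement and its error, then
    take a gradient step on every adaptable weight block. Silent trials
    record the no-movement error and trigger no update.
    """
    adapt_W = "W" in params.adaptable
    adapt_J = "J" in params.adaptable
    if adapt_J and coding.activation.kind != "tanh_rectified":
        raise UnsupportedConfigurationError(
            "adaptable J requires the tanh_rectified activation"
        )
    K = geometry.targets.K
    n_postures = geometry.postures.count
    n_muscles = geometry.muscles.n_muscles
    N = coding.n_neurons
    if muscle_map is None:
        muscle_map = MuscleMap.zeros(n_muscles, N)
    W = np.array(muscle_map.W, dtype=float, copy=True)
    if W.shape != (n_muscles, N):
        raise ValueError(f"W shape {W.shape} != ({n_muscles}, {N})")

    schedule = make_trial_schedule(params.n_trials, K, n_postures, seed)
    targets = geometry.targets.vectors
    postures = geometry.postures.vectors
    projections = geometry.muscles.projections
    theta = coding.theta_values()
    eta, lam = params.eta, params.lam
    errors = np.empty(params.n_trials)

    J_v = np.array(coding.weights.J_v, dtype=float, copy=True)
    J_p = np.array(coding.weights.J_p, dtype=float, copy=True)

    if not adapt_J:
        # Activity only depends on the (target, posture) condition: precompute.
        table = activity_table(coding, geometry.conditions())  # (N, C)
        silent = ~np.any(table > 0, axis=0)
        A_cols = np.ascontiguousarray(table.T)  # (C, N)
        cond = schedule.posture_idx * K + schedule.target_idx
        for t in range(params.n_trials):
            c = cond[t]
            v = targets[schedule.target_idx[t]]
            if silent[c]:
                errors[t] = v @ v
                continue
            A = A_cols[c]
            P = projections[schedule.posture_idx[t]]
            drive = W @ A
            M = np.maximum(drive, 0.0)
            e = v - P @ M
            errors[t] = e @ e
            if adapt_W and eta != 0.0:
                # subgradient 1 at the muscle-rectification kink, otherwise the
                # all-zero initial W is a fixed point and learning never starts
                h = (P.T @ e) * (drive >= 0) - lam * M
                W += eta * h[:, None] * A[None, :]
            if (t + 1) % 1000 == 0:
                logger.info("trial %d/%d error %.3e", t + 1, params.n_trials, errors[t])
    else:
        for t in range(params.n_trials):
            v = targets[schedule.target_idx[t]]
            P = projections[schedule.posture_idx[t]]
            p = postures[schedule.posture_idx[t]]
            grads = _coding_gradients(
                J_v, J_p, W, v, p, P, theta, coding.activation, lam
            )
            if grads is None:
                errors[t] = v @ v
                continue
            dJ_v, dJ_p, dW, e, _ = grads
            errors[t] = e @ e
            J_v -= eta * dJ_v
            J_p -= eta * dJ_p
            if adapt_W:
                W -= eta * dW
            if (t + 1) % 1000 == 0:
                logger.info("trial %d/%d error %.3e", t + 1, params.n_trials, errors[t])

    window = params.window_for(params.n_trials)
    return TrainResult(
        errors=errors,
        W=W,
        J_v=J_v,
        J_p=J_p,
        seed=seed,
        converged_error=converged_error(errors, window),
        window=window,
    )
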