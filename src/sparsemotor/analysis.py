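"""Experiment-level analyses of the trained networks.

Covers the threshold sweep (error and sparseness as a function of theta),
PCA of the condition-wise activity covariance, generalization to novel
targets with frozen weights, and classification of per-neuron tuning as
additively versus multiplicatively modulated by posture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neural_coding import (
    ActivationSpec,
    CodingLayer,
    ThresholdSpec,
    activity_table,
    sample_sensory_weights,
    sparseness,
)
from .plasticity import LearningParams, MuscleMap, train
from .task_model import TaskGeometry

__all__ = [
    "SweepResult",
    "ActivityPatternMatrix",
    "SpectrumResult",
    "TuningMatrix",
    "ModulationFit",
    "theta_sweep",
    "build_pattern_matrix",
    "pca_contributions",
    "generalization_error",
    "tuning_matrix",
    "modulation_fit",
    "modulation_census",
]


@dataclass(frozen=True)
class SweepResult:
    """Per-theta converged error (mean/sd across runs) and sparseness."""

    thetas: np.ndarray  # (n_theta,) sorted ascending
    mean_error: np.ndarray  # (n_theta,)
    sd_error: np.ndarray  # (n_theta,)
    sparseness: np.ndarray  # (n_theta,) mean across runs
    per_run_error: np.ndarray  # (n_runs, n_theta)
    per_run_sparseness: np.ndarray  # (n_runs, n_theta)
    shared_J: bool = True

    @property
    def argmin_theta(self) -> float:
        """Grid point minimizing the across-run mean converged error."""
        return float(self.thetas[int(np.argmin(self.mean_error))])


@dataclass(frozen=True)
class ActivityPatternMatrix:
    """N neurons x C conditions activity table with condition labels."""

    values: np.ndarray
    labels: tuple[str, ...]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SpectrumResult:
    """Eigenvalue spectrum of the condition-wise activity covariance."""

    eigenvalues: np.ndarray  # non-increasing, nonnegative within tolerance
    contributions: np.ndarray  # percent, sums to 100 unless degenerate
    degenerate: bool = False

    def n_nonzero(self, rel_tol: float = 1e-10) -> int:
        """Eigenvalues above rel_tol times the largest one."""
        if self.degenerate or self.eigenvalues.size == 0:
            return 0
        return int(np.sum(self.eigenvalues > rel_tol * self.eigenvalues[0]))


@dataclass(frozen=True)
class TuningMatrix:
    """One neuron's activity over all targets (rows) and postures (columns)."""

    neuron: int
    values: np.ndarray  # (K, n_postures)
    target_angles: np.ndarray
    posture_labels: tuple[str, ...]


@dataclass(frozen=True)
class ModulationFit:
    """Additive f(v)+g(p) versus multiplicative f(v)g(p) tuning fit."""

    r2_additive: float
    r2_multiplicative: float
    label: str  # additive | multiplicative | flat | ambiguous


def theta_sweep(
    thetas,
    n_runs: int,
    geometry: TaskGeometry,
    n_neurons: int = 2000,
    activation: ActivationSpec = ActivationSpec(),
    heterogeneity_sd: float = 0.0,
    params: LearningParams = LearningParams(),
    seed: int = 0,
) -> SweepResult:
    """Train one network per (run, theta); J and the trial schedule are drawn
    once per run and shared across the whole theta grid, so differences along
    the grid reflect the threshold alone."""
    thetas = np.sort(np.asarray(thetas, dtype=float))
    if thetas.size == 0:
        raise ValueError("theta grid must be non-empty")
    if n_runs < 1:
        raise ValueError("need at least one run")
    conditions = geometry.conditions()
    n_muscles = geometry.muscles.n_muscles
    run_seeds = np.random.SeedSequence(seed).spawn(n_runs)
    errs = np.empty((n_runs, thetas.size))
    sps = np.empty((n_runs, thetas.size))
    for r, run_ss in enumerate(run_seeds):
        w_ss, th_ss, tr_ss = run_ss.spawn(3)
        weights = sample_sensory_weights(n_neurons, w_ss)
        th_seed = int(th_ss.generate_state(1)[0])
        train_seed = int(tr_ss.generate_state(1)[0])
        base_spec = ThresholdSpec(0.0, heterogeneity_sd, th_seed)
        for j, theta in enumerate(thetas):
            coding = CodingLayer(weights, base_spec.with_base(theta), activation)
            result = train(
                geometry,
                coding,
                MuscleMap.zeros(n_muscles, n_neurons),
                params,
                seed=train_seed,
            )
            errs[r, j] = result.converged_error
            sps[r, j] = sparseness(coding, conditions)
    return SweepResult(
        thetas=thetas,
        mean_error=errs.mean(axis=0),
        sd_error=errs.std(axis=0),
        sparseness=sps.mean(axis=0),
        per_run_error=errs,
        per_run_sparseness=sps,
        shared_J=True,
    )


def build_pattern_matrix(
    coding: CodingLayer, geometry: TaskGeometry
) -> ActivityPatternMatrix:
    """Activities over all (target, posture) conditions (posture-major order)."""
    table = activity_table(coding, geometry.conditions())
    return ActivityPatternMatrix(
        values=table, labels=tuple(geometry.condition_labels())
    )


def pca_contributions(patterns: ActivityPatternMatrix | np.ndarray) -> SpectrumResult:
    """Eigen-spectrum of the covariance of activities over conditions.

    Conditions are treated as observations and neurons as variables; the
    covariance is centered over conditions. Computed through the SVD of the
    centered pattern matrix, which is equivalent to eigendecomposing the
    N x N covariance but avoids forming it.
    """
    X = patterns.values if isinstance(patterns, ActivityPatternMatrix) else np.asarray(patterns)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need an N x C pattern matrix with at least 2 conditions")
    C = X.shape[1]
    centered = X - X.mean(axis=1, keepdims=True)
    s = np.linalg.svd(centered, compute_uv=False)
    eigenvalues = s**2 / (C - 1)
    total = eigenvalues.sum()
    if total <= 0.0:
        return SpectrumResult(
            eigenvalues=eigenvalues,
            contributions=np.zeros_like(eigenvalues),
            degenerate=True,
        )
    return SpectrumResult(
        eigenvalues=eigenvalues,
        contributions=eigenvalues / total * 100.0,
        degenerate=False,
    )


def generalization_error(
    W: np.ndarray,
    coding: CodingLayer,
    geometry: TaskGeometry,
    L: int = 500,
    seed: int = 0,
    spacing: str = "random",
) -> float:
    """Mean squared movement error on L novel targets x all postures, W frozen.

    Novel target angles are uniform on [0, 2*pi) (``spacing='random'``) or
    evenly spaced (``spacing='even'``).
    """
    if L < 1:
        raise ValueError("need at least one novel target")
    if spacing == "random":
        angles = np.random.default_rng(seed).uniform(0.0, 2.0 * np.pi, size=L)
    elif spacing == "even":
        angles = 2.0 * np.pi * np.arange(L) / L
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    targets = np.column_stack([np.cos(angles), np.sin(angles)])
    postures = geometry.postures.vectors
    conditions = [
        (targets[l], postures[kp])
        for kp in range(geometry.postures.count)
        for l in range(L)
    ]
    table = activity_table(coding, conditions)  # (N, n_postures * L)
    W = np.asarray(W, dtype=float)
    total = 0.0
    for kp in range(geometry.postures.count):
        A_block = table[:, kp * L : (kp + 1) * L]  # (N, L)
        M = np.maximum(W @ A_block, 0.0)  # (N_M, L)
        x = geometry.muscles.projections[kp] @ M  # (2, L)
        e = targets.T - x
        total += float(np.sum(e * e))
    return total / (L * geometry.postures.count)


def _reshape_tuning(row: np.ndarray, K: int, n_postures: int) -> np.ndarray:
    # condition order is posture-major: c = kp * K + k
    return row.reshape(n_postures, K).T


def tuning_matrix(
    neuron: int, coding: CodingLayer, geometry: TaskGeometry
) -> TuningMatrix:
    """K x n_postures activity table of one neuron over all conditions."""
    if not 0 <= neuron < coding.n_neurons:
        raise ValueError(f"neuron index {neuron} outside [0, {coding.n_neurons})")
    table = activity_table(coding, geometry.conditions())
    values = _reshape_tuning(table[neuron], geometry.targets.K, geometry.postures.count)
    return TuningMatrix(
        neuron=neuron,
        values=values,
        target_angles=geometry.targets.angles,
        posture_labels=geometry.postures.labels,
    )


def _rank1_nonnegative(T: np.ndarray, n_iter: int = 100, tol: float = 1e-10):
    """Best nonnegative rank-1 approximation f g^T by alternating least squares."""
    f = np.maximum(T.mean(axis=1), 0.0)
    if not np.any(f > 0):
        f = np.ones(T.shape[0])
    prev = np.inf
    g = np.zeros(T.shape[1])
    for _ in range(n_iter):
        denom = f @ f
        if denom == 0.0:
            break
        g = np.maximum(T.T @ f / denom, 0.0)
        denom = g @ g
        if denom == 0.0:
            break
        f = np.maximum(T @ g / denom, 0.0)
        resid = float(np.sum((T - np.outer(f, g)) ** 2))
        if abs(prev - resid) <= tol * max(prev, 1.0):
            break
        prev = resid
    return f, g


def modulation_fit(
    t: TuningMatrix | np.ndarray,
    margin: float = 0.005,
    flat_tol: float = 1e-6,
) -> ModulationFit:
    """Classify a tuning table as additive, multiplicative, flat, or ambiguous.

    Additive: least-squares fit of f(v_k) + g(p_kp) (row + column means).
    Multiplicative: best nonnegative rank-1 fit f(v_k) * g(p_kp). The label
    goes to the model with the higher R^2 by at least ``margin``.
    """
    T = t.values if isinstance(t, TuningMatrix) else np.asarray(t, dtype=float)
    if T.ndim != 2:
        raise ValueError("tuning table must be 2-D (targets x postures)")
    grand = T.mean()
    ss_tot = float(np.sum((T - grand) ** 2))
    if T.max(initial=0.0) <= flat_tol or ss_tot <= flat_tol**2:
        return ModulationFit(0.0, 0.0, "flat")
    additive = T.mean(axis=1, keepdims=True) + T.mean(axis=0, keepdims=True) - grand
    r2_add = 1.0 - float(np.sum((T - additive) ** 2)) / ss_tot
    f, g = _rank1_nonnegative(T)
    r2_mul = 1.0 - float(np.sum((T - np.outer(f, g)) ** 2)) / ss_tot
    if r2_mul > r2_add + margin:
        label = "multiplicative"
    elif r2_add > r2_mul + margin:
        label = "additive"
    else:
        label = "ambiguous"
    return ModulationFit(r2_additive=r2_add, r2_multiplicative=r2_mul, label=label)


def modulation_census(
    coding: CodingLayer,
    geometry: TaskGeometry,
    margin: float = 0.005,
    flat_tol: float = 1e-6,
) -> dict[str, int]:
    """Count modulation labels over all neurons active in some condition."""
    table = activity_table(coding, geometry.conditions())
    K, n_postures = geometry.targets.K, geometry.postures.count
    counts = {"additive": 0, "multiplicative": 0, "flat": 0, "ambiguous": 0}
    for i in range(coding.n_neurons):
        if not np.any(table[i] > flat_tol):
            continue  # never-active neurons are excluded, not counted as flat
        fit = modulation_fit(
            _reshape_tuning(table[i], K, n_postures), margin=margin, flat_tol=flat_tol
        )
        counts[fit.label] += 1
    return counts
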