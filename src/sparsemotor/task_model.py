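"""Wrist-movement task geometry: targets, postures, muscles, trials.

Targets are unit vectors on a screen circle, postures are unit vectors
encoding forearm rotation, and each posture carries a 2 x N_M projection
matrix mapping muscle activity to screen movement via posture-dependent
pulling directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TargetSet",
    "PostureSet",
    "MuscleGeometry",
    "TrialSchedule",
    "TaskGeometry",
    "make_target_set",
    "make_posture_set",
    "build_muscle_geometry",
    "make_trial_schedule",
    "sample_trial",
    "execute_and_error",
    "DEFAULT_POSTURE_ANGLES",
    "DEFAULT_POSTURE_LABELS",
]

DEFAULT_POSTURE_ANGLES = (-np.pi / 4, 0.0, np.pi / 4)
DEFAULT_POSTURE_LABELS = ("pronation", "midrange", "supination")


def _unit_vectors(angles: np.ndarray) -> np.ndarray:
    return np.column_stack([np.cos(angles), np.sin(angles)])


@dataclass(frozen=True)
class TargetSet:
    """K visual targets on the unit circle."""

    angles: np.ndarray  # (K,) radians
    vectors: np.ndarray  # (K, 2) unit vectors

    @property
    def K(self) -> int:
        return len(self.angles)


@dataclass(frozen=True)
class PostureSet:
    """Forearm postures as unit vectors with human-readable labels."""

    angles: np.ndarray  # (n_postures,) radians
    vectors: np.ndarray  # (n_postures, 2)
    labels: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.angles)


@dataclass(frozen=True)
class MuscleGeometry:
    """Posture-dependent muscle pulling directions and projections.

    ``projections[kp]`` is the 2 x N_M matrix whose i-th column is
    (cos(phi[i, kp]), sin(phi[i, kp])).
    """

    pulling_angles: np.ndarray  # (n_postures, N_M)
    projections: np.ndarray  # (n_postures, 2, N_M)

    @property
    def n_muscles(self) -> int:
        return self.pulling_angles.shape[1]

    @property
    def n_postures(self) -> int:
        return self.pulling_angles.shape[0]


@dataclass(frozen=True)
class TrialSchedule:
    """Precomputed uniform random (target, posture) indices, 0-based."""

    n_trials: int
    seed: int
    target_idx: np.ndarray  # (T,) in [0, K)
    posture_idx: np.ndarray  # (T,) in [0, n_postures)


@dataclass(frozen=True)
class TaskGeometry:
    """Bundle of everything the training loop needs about the task."""

    targets: TargetSet
    postures: PostureSet
    muscles: MuscleGeometry

    def __post_init__(self):
        if self.muscles.n_postures != self.postures.count:
            raise ValueError(
                "muscle geometry defines projections for "
                f"{self.muscles.n_postures} postures but the posture set "
                f"has {self.postures.count}"
            )

    @property
    def n_conditions(self) -> int:
        return self.targets.K * self.postures.count

    def condition_labels(self) -> list[str]:
        """Labels 'targetIndex_postureIndex' (1-based), posture-major order."""
        return [
            f"{k + 1}_{kp + 1}"
            for kp in range(self.postures.count)
            for k in range(self.targets.K)
        ]

    def conditions(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """All (target vector, posture vector) pairs, matching labels order."""
        return [
            (self.targets.vectors[k], self.postures.vectors[kp])
            for kp in range(self.postures.count)
            for k in range(self.targets.K)
        ]


def make_target_set(K: int, start_angle: float = 0.0) -> TargetSet:
    """K unit-vector targets evenly spaced from ``start_angle``."""
    if K < 1:
        raise ValueError(f"need at least one target, got K={K}")
    angles = start_angle + 2.0 * np.pi * np.arange(K) / K
    return TargetSet(angles=angles, vectors=_unit_vectors(angles))


def make_posture_set(
    angles=DEFAULT_POSTURE_ANGLES,
    labels: tuple[str, ...] | None = None,
) -> PostureSet:
    """Postures at the given angles; defaults to pronation/midrange/supination."""
    angles = np.asarray(angles, dtype=float)
    if angles.ndim != 1 or angles.size < 1:
        raise ValueError("posture angles must be a non-empty 1-D sequence")
    if labels is None:
        if angles.size == len(DEFAULT_POSTURE_LABELS):
            labels = DEFAULT_POSTURE_LABELS
        else:
            labels = tuple(f"posture{i + 1}" for i in range(angles.size))
    if len(labels) != angles.size:
        raise ValueError("one label per posture angle required")
    return PostureSet(angles=angles, vectors=_unit_vectors(angles), labels=tuple(labels))


def build_muscle_geometry(
    n_muscles: int = 5,
    base_angles=None,
    posture_rotations=DEFAULT_POSTURE_ANGLES,
) -> MuscleGeometry:
    """Pulling directions phi[i, kp] = base_angles[i] + posture_rotations[kp].

    Default base angles are evenly spaced over the full circle; each posture
    rigidly rotates the whole set.
    """
    if n_muscles < 1:
        raise ValueError(f"need at least one muscle, got {n_muscles}")
    if base_angles is None:
        base_angles = 2.0 * np.pi * np.arange(n_muscles) / n_muscles
    base_angles = np.asarray(base_angles, dtype=float)
    if base_angles.size != n_muscles:
        raise ValueError(
            f"{n_muscles} muscles but {base_angles.size} base angles given"
        )
    rotations = np.asarray(posture_rotations, dtype=float)
    if rotations.ndim != 1 or rotations.size < 1:
        raise ValueError("posture_rotations must be a non-empty 1-D sequence")
    phi = rotations[:, None] + base_angles[None, :]  # (n_postures, N_M)
    projections = np.stack([np.cos(phi), np.sin(phi)], axis=1)
    return MuscleGeometry(pulling_angles=phi, projections=projections)


def make_trial_schedule(
    n_trials: int, K: int, n_postures: int, seed: int | np.random.SeedSequence
) -> TrialSchedule:
    """Uniform independent (target, posture) draws, reproducible from seed."""
    if n_trials < 1:
        raise ValueError(f"need at least one trial, got {n_trials}")
    rng = np.random.default_rng(seed)
    target_idx = rng.integers(0, K, size=n_trials)
    posture_idx = rng.integers(0, n_postures, size=n_trials)
    seed_int = seed if isinstance(seed, int) else -1
    return TrialSchedule(
        n_trials=n_trials, seed=seed_int, target_idx=target_idx, posture_idx=posture_idx
    )


def sample_trial(schedule: TrialSchedule, t: int) -> tuple[int, int]:
    """The 1-based (k, k') pair of trial t (1-based, per the task convention)."""
    if not 1 <= t <= schedule.n_trials:
        raise ValueError(f"trial index {t} outside [1, {schedule.n_trials}]")
    return int(schedule.target_idx[t - 1]) + 1, int(schedule.posture_idx[t - 1]) + 1


def execute_and_error(
    P: np.ndarray, M: np.ndarray, v: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Movement x = P @ M and error e = v - x."""
    P = np.asarray(P, dtype=float)
    M = np.asarray(M, dtype=float)
    v = np.asarray(v, dtype=float)
    if P.ndim != 2 or P.shape[0] != 2:
        raise ValueError(f"projection must be 2 x N_M, got shape {P.shape}")
    if M.shape != (P.shape[1],):
        raise ValueError(
            f"muscle vector of length {M.shape} incompatible with projection {P.shape}"
        )
    if v.shape != (2,):
        raise ValueError(f"target must be a 2-vector, got shape {v.shape}")
    x = P @ M
    return x, v - x


def default_geometry(
    K: int = 8,
    target_start_angle: float = 0.0,
    posture_angles=DEFAULT_POSTURE_ANGLES,
    n_muscles: int = 5,
    muscle_base_angles=None,
    posture_rotations=None,
) -> TaskGeometry:
    """Assemble the standard 8-target, 3-posture, 5-muscle task."""
    postures = make_posture_set(posture_angles)
    if posture_rotations is None:
        posture_rotations = postures.angles
    return TaskGeometry(
        targets=make_target_set(K, target_start_angle),
        postures=postures,
        muscles=build_muscle_geometry(n_muscles, muscle_base_angles, posture_rotations),
    )
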