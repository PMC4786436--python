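"""Kinematic posture models: synergy (PCA) and individual-digit descriptions.

A grasping posture is summarized by 24 hand joint angles (wrist excluded).
Postural synergies are the principal components of the posture-by-joint
matrix after averaging repetitions and removing the grand-mean posture:
each observed posture is then a linear combination of a small number of
synergies.  The individual-digit model is the somatotopic alternative —
one aggregate displacement per digit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DIGITS = ("thumb", "index", "middle", "ring", "little")

#: Default 24-DoF convention (a documented convention, configurable): the
#: thumb carries 6 DoF including carpometacarpal rotation, index/middle 4
#: each, ring/little 5 each (their CMC flexion captures the palmar arch).
DEFAULT_JOINT_LABELS: tuple[str, ...] = (
    "thumb_CMC_flex", "thumb_CMC_abd", "thumb_CMC_rot",
    "thumb_MCP_flex", "thumb_MCP_abd", "thumb_IP_flex",
    "index_MCP_flex", "index_MCP_abd", "index_PIP_flex", "index_DIP_flex",
    "middle_MCP_flex", "middle_MCP_abd", "middle_PIP_flex", "middle_DIP_flex",
    "ring_CMC_flex", "ring_MCP_flex", "ring_MCP_abd",
    "ring_PIP_flex", "ring_DIP_flex",
    "little_CMC_flex", "little_MCP_flex", "little_MCP_abd",
    "little_PIP_flex", "little_DIP_flex",
)

DEFAULT_DIGIT_MAP: dict[str, str] = {
    label: label.split("_", 1)[0] for label in DEFAULT_JOINT_LABELS
}


class ConfigError(ValueError):
    """Invalid configuration (bad mapping, out-of-range parameter)."""


@dataclass
class PostureSet:
    """Per-subject joint-angle data: postures x repetitions x joints (degrees)."""

    angles: np.ndarray
    joint_labels: tuple[str, ...] = DEFAULT_JOINT_LABELS
    digit_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_DIGIT_MAP))
    posture_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 3:
            raise ValueError("angles must be postures x reps x joints")
        if self.angles.shape[2] != len(self.joint_labels):
            raise ValueError(
                f"{self.angles.shape[2]} joint columns but "
                f"{len(self.joint_labels)} labels"
            )
        if not np.all(np.isfinite(self.angles)):
            bad = np.unique(np.nonzero(~np.isfinite(self.angles))[0])
            raise ValueError(f"non-finite angles for postures {bad.tolist()}")
        missing = [j for j in self.joint_labels if j not in self.digit_map]
        if missing:
            raise ConfigError(f"joints not assigned to a digit: {missing}")
        if self.posture_labels is None:
            self.posture_labels = tuple(
                f"object{i:02d}" for i in range(self.angles.shape[0])
            )

    @property
    def n_postures(self) -> int:
        return self.angles.shape[0]

    @property
    def n_reps(self) -> int:
        return self.angles.shape[1]

    @property
    def n_joints(self) -> int:
        return self.angles.shape[2]


@dataclass
class SynergyModel:
    """PCA posture model: mean posture, loadings (k x joints), weights, variance."""

    mean_posture: np.ndarray
    loadings: np.ndarray
    weights: np.ndarray
    variance_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.mean_posture = np.asarray(self.mean_posture, dtype=float)
        self.loadings = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        self.variance_fraction = np.asarray(self.variance_fraction, dtype=float)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


@dataclass
class DigitModel:
    """Somatotopic posture model: aggregate angular displacement per digit."""

    displacements: np.ndarray
    digits: tuple[str, ...] = DIGITS

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.shape[1] != len(self.digits):
            raise ValueError("one displacement column per digit required")


def average_repetitions(ps: PostureSet) -> np.ndarray:
    """Mean posture per object across repetitions, shape (postures, joints)."""
    if ps.n_reps < 1:
        raise ValueError("at least one repetition per posture required")
    return ps.angles.mean(axis=1)


def center_postures(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove the grand-mean posture; returns (centered matrix, mean posture)."""
    mat = np.asarray(mat, dtype=float)
    if mat.shape[0] < 2:
        raise ValueError("need at least two postures to center")
    mean_posture = mat.mean(axis=0)
    return mat - mean_posture, mean_posture


def _fix_signs(loadings: np.ndarray, weights: np.ndarray) -> None:
    # PCA sign is arbitrary; make the largest-|value| loading entry positive
    # so identical inputs always give identical models.
    for i in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] *= -1.0
            weights[:, i] *= -1.0


def extract_kinematic_synergies(mat: np.ndarray, k: int) -> SynergyModel:
    """Fit the k-synergy PCA model to a postures x joints matrix.

    Computed by SVD of the centered matrix.  Loadings are unit-norm rows
    ordered by explained variance; ``variance_fraction[i]`` is the share of
    total (centered) variance carried by component i.
    """
    mat = np.asarray(mat, dtype=float)
    n, p = mat.shape
    k_max = min(n - 1, p)
    if not 1 <= k <= k_max:
        raise ValueError(f"k={k} out of range [1, {k_max}] for a {n}x{p} matrix")
    centered, mean_posture = center_postures(mat)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = np.sum(s**2)
    loadings = vt[:k].copy()
    weights = (u[:, :k] * s[:k]).copy()
    _fix_signs(loadings, weights)
    variance_fraction = s[:k] ** 2 / total if total > 0 else np.zeros(k)
    return SynergyModel(mean_posture, loadings, weights, variance_fraction)


def compute_digit_model(
    mat: np.ndarray,
    joint_labels: tuple[str, ...] = DEFAULT_JOINT_LABELS,
    digit_map: dict[str, str] | None = None,
    mode: str = "sum",
) -> DigitModel:
    """Aggregate joint angles per digit for each posture.

    ``mode="sum"`` (default) sums the joint angles within each digit;
    ``mode="mean"`` averages them instead.
    """
    mat = np.asarray(mat, dtype=float)
    if digit_map is None:
        digit_map = DEFAULT_DIGIT_MAP
    if mat.shape[1] != len(joint_labels):
        raise ValueError("column count does not match joint labels")
    unmapped = [j for j in joint_labels if j not in digit_map]
    if unmapped:
        raise ConfigError(f"joints not assigned to a digit: {unmapped}")
    if mode not in ("sum", "mean"):
        raise ValueError("mode must be 'sum' or 'mean'")
    out = np.zeros((mat.shape[0], len(DIGITS)))
    for d, digit in enumerate(DIGITS):
        cols = [i for i, j in enumerate(joint_labels) if digit_map[j] == digit]
        if not cols:
            continue
        block = mat[:, cols]
        out[:, d] = block.sum(axis=1) if mode == "sum" else block.mean(axis=1)
    return DigitModel(out)


def project_postures(model: SynergyModel, new_mat: np.ndarray) -> np.ndarray:
    """Project postures into the fitted synergy space: (X - mean) @ loadings.T."""
    new_mat = np.atleast_2d(np.asarray(new_mat, dtype=float))
    if new_mat.shape[1] != model.mean_posture.shape[0]:
        raise ValueError(
            f"joint count {new_mat.shape[1]} does not match model "
            f"({model.mean_posture.shape[0]})"
        )
    return (new_mat - model.mean_posture) @ model.loadings.T


def reconstruct_postures(model: SynergyModel, weights: np.ndarray | None = None) -> np.ndarray:
    """Invert the synergy projection: weights @ loadings + mean posture."""
    w = model.weights if weights is None else np.atleast_2d(weights)
    return w @ model.loadings + model.mean_posture
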