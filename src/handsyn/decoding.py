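"""Reconstruction of full hand postures (24 joint angles) from voxel patterns.

Voxel patterns are reduced to five principal components within a task ROI
and a leave-one-stimulus-out multiple regression maps those components onto
the 24 joint angles, reconstructing the held-out posture each time.
Fidelity is quantified subject-wise and posture-wise by R^2 (squared
Pearson correlation) and by the rank-accuracy statistic against the
originally recorded postures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import VoxelPatternSet
from .representation import zscore_patterns
from .validation import _average_rank_of_true, rank_to_percentage


@dataclass
class ReconstructionResult:
    """Reconstructed posture matrix and its fidelity statistics."""

    reconstructed: np.ndarray  # postures x joints
    r2_subject: float
    r2_per_posture: np.ndarray
    rank_accuracy: float | None = None
    p_value: float | None = None
    null_distribution: np.ndarray | None = None


def reduce_fmri(
    vp: VoxelPatternSet, mask: np.ndarray, k: int = 5
) -> np.ndarray:
    """Reduce masked, z-normalized voxel patterns to k principal components.

    Returns the postures x k component-score matrix.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != vp.n_voxels:
        raise ValueError("mask length does not match voxel count")
    if not mask.any():
        raise ValueError("empty voxel mask")
    if k > vp.n_postures - 1:
        raise ValueError(f"k={k} too large for {vp.n_postures} postures")
    data = zscore_patterns(vp.responses[mask].T)  # postures x voxels
    centered = data - data.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    return u[:, :k] * s[:k]


def _squared_pearson(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.ravel(a), np.ravel(b)
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def decode_postures(fmri_pcs: np.ndarray, postures: np.ndarray) -> ReconstructionResult:
    """Leave-one-stimulus-out regression from fMRI components to joint angles.

    For each stimulus, 24 per-joint ordinary least-squares regressions are
    fitted on the remaining stimuli and used to predict the held-out row.
    R^2 is reported subject-wise (vectorized matrices) and posture-wise
    (per row), both as squared Pearson correlations.
    """
    fmri_pcs = np.asarray(fmri_pcs, dtype=float)
    postures = np.asarray(postures, dtype=float)
    n, k = fmri_pcs.shape
    if postures.shape[0] != n:
        raise ValueError("posture rows must match fMRI rows")
    recon = np.empty_like(postures)
    for i in range(n):
        keep = np.arange(n) != i
        x = np.column_stack([fmri_pcs[keep], np.ones(n - 1)])
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise np.linalg.LinAlgError("rank-deficient training design")
        coef, *_ = np.linalg.lstsq(x, postures[keep], rcond=None)
        recon[i] = np.concatenate([fmri_pcs[i], [1.0]]) @ coef
    r2_subject = _squared_pearson(recon, postures)
    r2_rows = np.array(
        [_squared_pearson(recon[i], postures[i]) for i in range(n)]
    )
    return ReconstructionResult(recon, r2_subject, r2_rows)


def decode_rank_accuracy(
    result: ReconstructionResult,
    originals: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
) -> ReconstructionResult:
    """Rank each reconstructed posture against the recorded postures.

    Each reconstructed row is ranked by Euclidean distance among all
    original rows; ranks map to 0-100 scores.  The permutation null
    shuffles the original posture labels (one permutation per iteration);
    p is the one-sided (r+1)/(n+1) rank of the observed mean accuracy.
    """
    originals = np.asarray(originals, dtype=float)
    recon = result.reconstructed
    n = originals.shape[0]
    if recon.shape != originals.shape:
        raise ValueError("reconstructed and original shapes differ")
    # pct[i, j]: score earned if original j were labelled as posture i's truth
    pct = np.empty((n, n))
    for i in range(n):
        dists = np.linalg.norm(originals - recon[i], axis=1)
        for j in range(n):
            pct[i, j] = rank_to_percentage(_average_rank_of_true(dists, j), n)
    observed = float(np.mean(pct[np.arange(n), np.arange(n)]))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for it in range(n_perm):
        perm = rng.permutation(n)
        null[it] = np.mean(pct[np.arange(n), perm])
    p = (np.sum(null >= observed) + 1.0) / (n_perm + 1.0)
    return ReconstructionResult(
        recon, result.r2_subject, result.r2_per_posture, observed, float(p), null
    )


def decode_via_synergies(
    fmri_pcs: np.ndarray, synergy_weights: np.ndarray, loadings: np.ndarray,
    mean_posture: np.ndarray,
) -> ReconstructionResult:
    """Variant: regress onto synergy weights first, then expand to angles.

    The leave-one-out regression predicts the 5 synergy weights of the
    held-out stimulus, which are then mapped through the synergy loadings
    and the mean posture to joint angles.
    """
    inner = decode_postures(fmri_pcs, np.asarray(synergy_weights, dtype=float))
    recon = inner.reconstructed @ np.asarray(loadings) + np.asarray(mean_posture)
    target = np.asarray(synergy_weights) @ np.asarray(loadings) + np.asarray(mean_posture)
    r2_subject = _squared_pearson(recon, target)
    r2_rows = np.array(
        [_squared_pearson(recon[i], target[i]) for i in range(recon.shape[0])]
    )
    return ReconstructionResult(recon, r2_subject, r2_rows)
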