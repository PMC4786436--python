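"""Voxelwise encoding of posture models with leave-two-out cross-validation.

A linear encoding model predicts each voxel's response to a grasping
movement as a linear combination of the movement's five synergy weights.
The procedure runs one fold per unordered pair of stimuli (190 folds for
20 stimuli): train ordinary least squares on the remaining 18, keep the
best-responding voxels (stage 1: mean training response; stage 2: training
R^2), prune small isolated clusters on the voxel grid, predict the two
held-out patterns and assign them to the observed patterns by correlation
distance.  Chance accuracy is 50%.  A recruitment map counts, per voxel,
fold-wise selection-and-success events (0 to 380 for 20 stimuli).
Significance comes from re-running the procedure with the training weights
shuffled within each column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

_CONNECTIVITY = {"face": 1, "edge": 2, "vertex": 3}


@dataclass
class VoxelPatternSet:
    """Voxel responses (t-score-like) per posture plus integer grid coordinates."""

    responses: np.ndarray  # voxels x postures
    coords: np.ndarray  # voxels x 3, integer grid positions
    posture_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        self.coords = np.asarray(self.coords)
        if self.responses.shape[0] != self.coords.shape[0]:
            raise ValueError("responses and coords row counts differ")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("non-finite voxel responses")
        uniq = np.unique(self.coords, axis=0)
        if uniq.shape[0] != self.coords.shape[0]:
            raise ValueError("duplicate voxel coordinates")
        if self.posture_labels is None:
            self.posture_labels = tuple(
                f"object{i:02d}" for i in range(self.responses.shape[1])
            )

    @property
    def n_voxels(self) -> int:
        return self.responses.shape[0]

    @property
    def n_postures(self) -> int:
        return self.responses.shape[1]


@dataclass
class EncodingConfig:
    """Thresholds of the encoding procedure.

    Defaults follow the whole-brain protocol: 5000 voxels by mean training
    response, 1000 by training R^2, minimum cluster size 50 under
    face-adjacency.  Stage counts are clamped (with a warning) to the number
    of available voxels so the procedure also runs on small synthetic grids.
    """

    n_select_stage1: int = 5000
    n_select_stage2: int = 1000
    cluster_min_size: int = 50
    connectivity: str = "face"
    include_intercept: bool = True
    n_perm: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.connectivity not in _CONNECTIVITY:
            raise ValueError("connectivity must be face, edge or vertex")
        if not 1 <= self.n_select_stage2 <= self.n_select_stage1:
            raise ValueError("require 1 <= n_select_stage2 <= n_select_stage1")

    def clamped(self, n_voxels: int) -> "EncodingConfig":
        s1 = min(self.n_select_stage1, n_voxels)
        s2 = min(self.n_select_stage2, s1)
        if (s1, s2) != (self.n_select_stage1, self.n_select_stage2):
            logger.info(
                "stage counts clamped to (%d, %d) for %d voxels", s1, s2, n_voxels
            )
        return EncodingConfig(
            s1, s2, self.cluster_min_size, self.connectivity,
            self.include_intercept, self.n_perm, self.seed,
        )


@dataclass
class EncodingResult:
    """Overall accuracy, per-pair outcomes, recruitment map and diagnostics."""

    overall_accuracy: float
    pair_outcomes: np.ndarray  # n x n, percent correct per pair, NaN diagonal
    recruitment: np.ndarray  # per-voxel integer score, 0..2*n_folds
    per_fold: list[dict] = field(default_factory=list)
    null_distribution: np.ndarray | None = None
    p_value: float | None = None


def enumerate_folds(n_stimuli: int) -> list[tuple[list[int], tuple[int, int]]]:
    """All leave-two-out folds: (training ids, held-out pair)."""
    if n_stimuli < 3:
        raise ValueError("need at least three stimuli")
    folds = []
    for pair in combinations(range(n_stimuli), 2):
        train = [i for i in range(n_stimuli) if i not in pair]
        folds.append((train, pair))
    return folds


def select_voxels_stage1(
    vp: VoxelPatternSet, train_ids: list[int], n_select: int
) -> np.ndarray:
    """Indices of the voxels with the best mean response over the training
    stimuli; ties broken by voxel index (stable sort)."""
    mean_resp = vp.responses[:, train_ids].mean(axis=1)
    order = np.argsort(-mean_resp, kind="stable")
    return np.sort(order[: min(n_select, vp.n_voxels)])


def fit_encoding_regression(
    weights: np.ndarray,
    patterns: np.ndarray,
    include_intercept: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel ordinary least squares of training patterns on synergy weights.

    Returns (coefficients, R^2): coefficients has one column per voxel and
    one row per predictor (intercept last when included); R^2 is the training
    coefficient of determination per voxel.
    """
    weights = np.asarray(weights, dtype=float)
    patterns = np.asarray(patterns, dtype=float)
    n = weights.shape[0]
    if patterns.shape[0] != n:
        raise ValueError("weights and patterns row counts differ")
    x = np.column_stack([weights, np.ones(n)]) if include_intercept else weights
    if n < x.shape[1] + 1:
        raise ValueError(f"need at least {x.shape[1] + 1} training stimuli")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        corr = np.corrcoef(x.T)
        pairs = [
            (i, j)
            for i in range(x.shape[1])
            for j in range(i + 1, x.shape[1])
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} of {x.shape[1]}); "
            f"collinear column pairs: {pairs}"
        )
    coef, *_ = np.linalg.lstsq(x, patterns, rcond=None)
    fitted = x @ coef
    sse = np.sum((patterns - fitted) ** 2, axis=0)
    sst = np.sum((patterns - patterns.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sst > 0, 1.0 - sse / np.where(sst > 0, sst, 1.0), 0.0)
    return coef, r2


def cluster_prune(
    coords: np.ndarray,
    selected: np.ndarray,
    min_size: int,
    connectivity: str = "face",
) -> np.ndarray:
    """Drop selected voxels in connected components smaller than ``min_size``.

    Components are computed on the integer grid among the selected voxels
    only, under face (6), edge (18) or vertex (26) adjacency.
    """
    if len(selected) == 0:
        return selected
    pts = np.asarray(coords)[selected]
    origin = pts.min(axis=0)
    shape = tuple((pts.max(axis=0) - origin + 1).astype(int))
    vol = np.zeros(shape, dtype=bool)
    ijk = (pts - origin).astype(int)
    vol[tuple(ijk.T)] = True
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    labels, n_lab = ndimage.label(vol, structure=structure)
    if n_lab == 0:
        return np.array([], dtype=int)
    sizes = np.bincount(labels.ravel())
    voxel_labels = labels[tuple(ijk.T)]
    keep = sizes[voxel_labels] >= min_size
    return np.asarray(selected)[keep]


def pairwise_decode(predicted: np.ndarray, observed: np.ndarray) -> int:
    """Assign each predicted pattern to the closer observed pattern by
    correlation distance; return the number (0, 1 or 2) predicted correctly."""
    predicted = np.atleast_2d(predicted)
    observed = np.atleast_2d(observed)
    if predicted.shape[1] < 2:
        raise ValueError("patterns need at least two voxels")

    def cdist(a: np.ndarray, b: np.ndarray) -> float:
        sa, sb = np.std(a), np.std(b)
        if sa == 0 or sb == 0:
            logger.warning("zero-variance pattern in pairwise decoding")
            return 2.0  # maximal correlation distance
        return 1.0 - float(np.corrcoef(a, b)[0, 1])

    correct = 0
    for i in range(2):
        d_same = cdist(predicted[i], observed[i])
        d_other = cdist(predicted[i], observed[1 - i])
        if d_same < d_other:
            correct += 1
    return correct


def _encode_one_fold(
    vp: VoxelPatternSet,
    weights: np.ndarray,
    train: list[int],
    pair: tuple[int, int],
    cfg: EncodingConfig,
    stage1: np.ndarray,
    train_weights: np.ndarray | None = None,
) -> tuple[int, np.ndarray]:
    """One leave-two-out fold; returns (correct count, final voxel indices)."""
    w_train = weights[train] if train_weights is None else train_weights
    patterns_train = vp.responses[stage1][:, train].T
    coef, r2 = fit_encoding_regression(w_train, patterns_train, cfg.include_intercept)
    order = np.argsort(-r2, kind="stable")
    stage2 = stage1[np.sort(order[: cfg.n_select_stage2])]
    final = cluster_prune(vp.coords, stage2, cfg.cluster_min_size, cfg.connectivity)
    if len(final) < 2:
        # no cluster reaches the size threshold; decode within the unpruned
        # stage-2 selection rather than forfeiting the fold
        logger.warning(
            "fold %s: no cluster of >= %d voxels; using unpruned stage-2 set",
            pair, cfg.cluster_min_size,
        )
        final = stage2
    # refit restricted to the surviving voxels (cheap: subset of columns)
    keep_cols = np.searchsorted(stage1, final)
    coef_f = coef[:, keep_cols]
    w_test = weights[list(pair)]
    x_test = (
        np.column_stack([w_test, np.ones(2)]) if cfg.include_intercept else w_test
    )
    predicted = x_test @ coef_f
    observed = vp.responses[final][:, list(pair)].T
    return pairwise_decode(predicted, observed), final


def run_encoding(
    vp: VoxelPatternSet, model_weights: np.ndarray, cfg: EncodingConfig
) -> EncodingResult:
    """Full leave-two-out encoding procedure.

    Overall accuracy is the percentage of held-out patterns assigned
    correctly over all folds.  The recruitment score of a voxel increments
    by one for each correctly predicted held-out pattern in folds where the
    voxel survived selection and pruning (maximum 2 per fold).
    """
    model_weights = np.asarray(model_weights, dtype=float)
    if model_weights.shape[0] != vp.n_postures:
        raise ValueError("weight rows must match posture count")
    cfg = cfg.clamped(vp.n_voxels)
    folds = enumerate_folds(vp.n_postures)
    recruitment = np.zeros(vp.n_voxels, dtype=int)
    n = vp.n_postures
    pair_outcomes = np.full((n, n), np.nan)
    per_fold = []
    total_correct = 0
    for train, pair in folds:
        stage1 = select_voxels_stage1(vp, train, cfg.n_select_stage1)
        correct, final = _encode_one_fold(vp, model_weights, train, pair, cfg, stage1)
        total_correct += correct
        recruitment[final] += correct
        pair_outcomes[pair[0], pair[1]] = pair_outcomes[pair[1], pair[0]] = 50.0 * correct
        per_fold.append({"pair": pair, "correct": correct, "n_voxels": len(final)})
    overall = 100.0 * total_correct / (2 * len(folds))
    return EncodingResult(overall, pair_outcomes, recruitment, per_fold)


def permutation_null_encoding(
    vp: VoxelPatternSet,
    model_weights: np.ndarray,
    cfg: EncodingConfig,
    observed: EncodingResult | None = None,
    with_replacement: bool = False,
) -> EncodingResult:
    """Permutation null for the encoding accuracy.

    Each iteration re-runs every fold with the 18 training weights shuffled
    independently within each column (preserving per-column variance) and
    tests on the untouched held-out pair.  The default shuffle is a
    within-column permutation; ``with_replacement=True`` draws each entry
    independently from the column instead.
    """
    model_weights = np.asarray(model_weights, dtype=float)
    cfg = cfg.clamped(vp.n_voxels)
    if observed is None:
        observed = run_encoding(vp, model_weights, cfg)
    rng = np.random.default_rng(cfg.seed)
    folds = enumerate_folds(vp.n_postures)
    # stage 1 does not depend on the weights: precompute per fold
    stage1_cache = [
        select_voxels_stage1(vp, train, cfg.n_select_stage1) for train, _ in folds
    ]
    n_train = vp.n_postures - 2
    k = model_weights.shape[1]
    null = np.empty(cfg.n_perm)
    for it in range(cfg.n_perm):
        total = 0
        for f, (train, pair) in enumerate(folds):
            w = model_weights[train]
            if with_replacement:
                idx = rng.integers(0, n_train, size=(n_train, k))
            else:
                idx = np.argsort(rng.random((n_train, k)), axis=0)
            shuffled = w[idx, np.arange(k)[np.newaxis, :]]
            correct, _ = _encode_one_fold(
                vp, model_weights, train, pair, cfg, stage1_cache[f], shuffled
            )
            total += correct
        null[it] = 100.0 * total / (2 * len(folds))
    p = (np.sum(null >= observed.overall_accuracy) + 1.0) / (cfg.n_perm + 1.0)
    return EncodingResult(
        observed.overall_accuracy,
        observed.pair_outcomes,
        observed.recruitment,
        observed.per_fold,
        null,
        float(p),
    )


def group_probability_map(
    subject_recruitments: list[np.ndarray], min_subjects: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Across-subject overlap of binarized recruitment maps.

    Returns (overlap counts, thresholded mask keeping voxels recruited in at
    least ``min_subjects`` subjects).
    """
    shapes = {np.asarray(m).shape for m in subject_recruitments}
    if len(shapes) != 1:
        raise ValueError("recruitment maps are not on a common voxel grid")
    stack = np.stack([np.asarray(m) > 0 for m in subject_recruitments])
    overlap = stack.sum(axis=0)
    return overlap, overlap >= min_subjects


def pair_accuracy_heatmap(results: list[EncodingResult]) -> np.ndarray:
    """Mean per-pair decoding accuracy across subjects (symmetric, % units)."""
    mats = np.stack([r.pair_outcomes for r in results])
    return np.nanmean(mats, axis=0)
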