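"""Rank-accuracy discrimination of posture models with leave-one-repetition-out
cross-validation and permutation inference.

For every (posture, repetition) fold the left-out repetition of that posture
is the *probe*; leaving the same repetition index out for every posture, the
remaining repetitions are averaged per posture to form the *test set* (so
all test items are averages of equally many repetitions).
PCA is fitted to the test set, the probe is transformed with the fitted
parameters (including the test-set mean), and the probe is ranked against
all test items by Euclidean distance in component space.  The rank of the
true posture maps to a 0-100 score whose expectation under exchangeable
labels is 50, regardless of the number of postures.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .kinematics import extract_kinematic_synergies, project_postures

logger = logging.getLogger(__name__)


@dataclass
class RankAccuracyResult:
    """Per-gesture and mean rank accuracies, optional permutation null and p."""

    per_gesture_accuracy: np.ndarray
    mean_accuracy: float
    null_distribution: np.ndarray | None = None
    p_value: float | None = None


def rank_to_percentage(rank: float, n: int) -> float:
    """Map a rank in a sorted list of n candidates onto a 0-100 accuracy.

    Rank 1 (smallest distance) gives 100; the worst rank gives 0; a
    uniformly random rank averages to 50 for any n >= 2.
    """
    if n < 2:
        raise ValueError("need at least two candidates")
    if not 1 <= rank <= n:
        raise ValueError(f"rank {rank} outside [1, {n}]")
    return 100.0 * (n - rank) / (n - 1)


def _average_rank_of_true(distances: np.ndarray, true_idx: int) -> float:
    """1-based rank of the true item, ties broken by average rank."""
    d_true = distances[true_idx]
    less = np.sum(distances < d_true)
    equal = np.sum(distances == d_true)
    return less + (equal + 1) / 2.0


def _fold_rank_percentages(data: np.ndarray, k: int) -> np.ndarray:
    """For every (posture, rep) fold, the rank-percentage each test item would
    earn if it were labelled as the probe's true posture.

    Column ``true`` of row (p, r) is the observed score for that fold; the
    remaining columns support label-shuffling nulls, because the distances do
    not depend on the labels.
    """
    data = np.asarray(data, dtype=float)
    n_post, n_reps, n_dim = data.shape
    if n_reps < 2:
        raise ValueError("need at least two repetitions")
    out = np.empty((n_post * n_reps, n_post))
    rep_sums = data.sum(axis=1)
    for r in range(n_reps):
        # leave repetition r out for every posture: each test item is the
        # average of the remaining repetitions, so all items are exchangeable
        # under the null and chance is exactly 50%
        test = (rep_sums - data[:, r, :]) / (n_reps - 1)
        model = extract_kinematic_synergies(test, k)
        test_scores = project_postures(model, test)
        probe_scores = project_postures(model, data[:, r, :])
        for p in range(n_post):
            dists = np.linalg.norm(test_scores - probe_scores[p], axis=1)
            order_rank = np.empty(n_post)
            for c in range(n_post):
                order_rank[c] = rank_to_percentage(
                    _average_rank_of_true(dists, c), n_post
                )
            # roll so that column 0 is the true posture of this fold
            out[p * n_reps + r] = np.concatenate([order_rank[p:], order_rank[:p]])
    return out


def rank_accuracy(data: np.ndarray, k: int) -> RankAccuracyResult:
    """Leave-one-repetition-out rank accuracy of a postures x reps x dims table.

    Scores are averaged across repetitions within each posture and then
    across postures.
    """
    data = np.asarray(data, dtype=float)
    n_post, n_reps, _ = data.shape
    pct = _fold_rank_percentages(data, k)[:, 0].reshape(n_post, n_reps)
    per_gesture = pct.mean(axis=1)
    return RankAccuracyResult(per_gesture, float(per_gesture.mean()))


def permutation_null_rank(
    data: np.ndarray,
    k: int,
    n_iter: int = 10000,
    seed: int | None = None,
) -> RankAccuracyResult:
    """Rank accuracy with a label-shuffling permutation null.

    In each iteration, each fold's test-set labels are shuffled before
    ranking.  Distances are label-invariant, so a shuffled fold scores the
    rank percentage of a uniformly drawn test item; the null is built from
    these draws and the p-value is the one-sided (r+1)/(n+1) rank of the
    observed mean accuracy.
    """
    if n_iter < 100:
        warnings.warn(f"n_iter={n_iter} is small; the p-value resolution is 1/{n_iter + 1}")
    data = np.asarray(data, dtype=float)
    n_post, n_reps, _ = data.shape
    pct = _fold_rank_percentages(data, k)
    per_gesture = pct[:, 0].reshape(n_post, n_reps).mean(axis=1)
    observed = float(per_gesture.mean())
    rng = np.random.default_rng(seed)
    # one independent label shuffle per fold per iteration
    idx = rng.integers(0, n_post, size=(n_iter, pct.shape[0]))
    null = pct[np.arange(pct.shape[0])[np.newaxis, :], idx].mean(axis=1)
    p = (np.sum(null >= observed) + 1.0) / (n_iter + 1.0)
    return RankAccuracyResult(per_gesture, observed, null, float(p))


def accuracy_vs_components(
    data: np.ndarray, k_range: list[int] | range
) -> list[tuple[int, float]]:
    """Mean rank accuracy for each number of retained components."""
    return [(int(k), rank_accuracy(data, k).mean_accuracy) for k in k_range]


def compare_models_group(
    accuracies_a: np.ndarray, accuracies_b: np.ndarray
) -> dict[str, float]:
    """Convenience wrapper: Wilcoxon signed-rank test between per-subject
    accuracy vectors of two models (for group-level model comparisons)."""
    from scipy.stats import wilcoxon

    stat, p = wilcoxon(accuracies_a, accuracies_b)
    return {"statistic": float(stat), "p_value": float(p)}
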