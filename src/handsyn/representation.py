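"""Representational similarity analysis, MDS, noise ceiling, cortical
synergy mapping, the topography C statistic, and cross-subject synergy
stability clustering.

Representational similarity (RS) matrices hold the pairwise distances
between stimulus representations — of voxel patterns reduced to five
principal components, or of the behavioral posture models.  Second-order
Pearson correlations between RS matrices (over the off-diagonal upper
triangle) compare what different data modalities encode; the Mantel test
assesses them by permuting stimulus labels.  The topography C parameter
correlates pairwise voxel distances in anatomical space with distances in
synergy-fit feature space: large C means voxels with similar tuning are
spatially close.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .encoding import VoxelPatternSet

logger = logging.getLogger(__name__)


@dataclass
class RSMatrix:
    """Symmetric zero-diagonal matrix of pairwise stimulus distances."""

    distances: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-10):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(d < -1e-12):
            raise ValueError("distances must be nonnegative")
        self.distances = d
        if self.labels is None:
            self.labels = tuple(f"object{i:02d}" for i in range(d.shape[0]))

    @property
    def n_items(self) -> int:
        return self.distances.shape[0]

    def upper(self) -> np.ndarray:
        """Vectorized upper triangle, diagonal excluded."""
        iu = np.triu_indices(self.n_items, k=1)
        return self.distances[iu]


def define_roi(
    responses: np.ndarray, rest_baseline: float = 0.0, q: float = 0.05
) -> np.ndarray:
    """Voxel mask from a per-voxel t-test of mean activity against rest,
    corrected for false discovery rate (Benjamini-Hochberg at level q)."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    responses = np.asarray(responses, dtype=float)
    t, p = stats.ttest_1samp(responses, popmean=rest_baseline, axis=1)
    p = np.where(np.isnan(p), 1.0, p)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def zscore_patterns(data: np.ndarray) -> np.ndarray:
    """Global z-scoring: subtract the grand mean of the array and divide by
    its standard deviation (normalization across all voxels and stimuli)."""
    data = np.asarray(data, dtype=float)
    sd = data.std()
    if sd == 0:
        raise ValueError("zero-variance data cannot be z-scored")
    return (data - data.mean()) / sd


def compute_rs(
    items: np.ndarray,
    reduce_to: int | None = None,
    zscore: bool = False,
    labels: tuple[str, ...] | None = None,
) -> RSMatrix:
    """Pairwise Euclidean distances between stimulus representations.

    Optionally z-normalizes the table globally and reduces its columns to
    the top ``reduce_to`` principal components first.
    """
    items = np.asarray(items, dtype=float)
    n = items.shape[0]
    if n < 3:
        raise ValueError("need at least three items")
    if zscore:
        items = zscore_patterns(items)
    if reduce_to is not None:
        if reduce_to > min(n - 1, items.shape[1]):
            raise ValueError(f"reduce_to={reduce_to} too large for {items.shape}")
        centered = items - items.mean(axis=0)
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        items = u[:, :reduce_to] * s[:reduce_to]
    return RSMatrix(squareform(pdist(items, metric="euclidean")), labels)


def rs_correlation(a: RSMatrix, b: RSMatrix) -> float:
    """Second-order Pearson correlation of two RS matrices over the
    vectorized off-diagonal upper triangle."""
    if a.n_items != b.n_items:
        raise ValueError("RS matrices have different sizes")
    if a.labels != b.labels:
        raise ValueError("RS matrices have different label orders")
    ua, ub = a.upper(), b.upper()
    if np.std(ua) == 0 or np.std(ub) == 0:
        raise ValueError("zero-variance RS matrix; correlation undefined")
    return float(np.corrcoef(ua, ub)[0, 1])


def mantel_test(
    a: RSMatrix, b: RSMatrix, n_iter: int = 10000, seed: int | None = None
) -> tuple[float, float]:
    """Mantel test: observed RS correlation and a one-sided permutation p.

    The null randomizes the stimulus labels of one matrix (simultaneous
    row/column permutation); p uses the (r+1)/(n+1) estimator.
    """
    observed = rs_correlation(a, b)
    rng = np.random.default_rng(seed)
    n = a.n_items
    iu = np.triu_indices(n, k=1)
    ua = a.upper()
    ua = (ua - ua.mean()) / ua.std()
    db = b.distances
    null = np.empty(n_iter)
    for i in range(n_iter):
        perm = rng.permutation(n)
        ub = db[np.ix_(perm, perm)][iu]
        ub = (ub - ub.mean()) / ub.std()
        null[i] = np.mean(ua * ub)
    p = (np.sum(null >= observed) + 1.0) / (n_iter + 1.0)
    return observed, float(p)


def noise_ceiling(subject_rs: list[RSMatrix]) -> tuple[float, float]:
    """Bounds on the attainable RS correlation given between-subject noise.

    The upper bound correlates each subject's RS with the group mean RS
    including that subject; the lower bound uses the leave-one-subject-out
    mean instead.
    """
    if len(subject_rs) < 3:
        raise ValueError("need at least three subjects")
    mats = np.stack([s.distances for s in subject_rs])
    n_sub = mats.shape[0]
    labels = subject_rs[0].labels
    mean_all = mats.mean(axis=0)
    upper_vals, lower_vals = [], []
    for i in range(n_sub):
        subj = subject_rs[i]
        upper_vals.append(rs_correlation(subj, RSMatrix(mean_all, labels)))
        loo = (mats.sum(axis=0) - mats[i]) / (n_sub - 1)
        lower_vals.append(rs_correlation(subj, RSMatrix(loo, labels)))
    return float(np.mean(lower_vals)), float(np.mean(upper_vals))


def mds_embed(
    rs: RSMatrix,
    dims: int = 2,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Metric-stress MDS by iterative majorization (SMACOF).

    Returns (configuration, final raw stress, per-iteration stress trace).
    The stress trace is nonincreasing by the majorization property.
    """
    n = rs.n_items
    if not 1 <= dims < n:
        raise ValueError("dims must be in [1, n_items)")
    d = rs.distances
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, dims))
    trace = []
    stress_prev = np.inf
    for _ in range(max_iter):
        dist = squareform(pdist(x))
        stress = 0.5 * np.sum((d - dist) ** 2) / 2.0
        trace.append(stress)
        if stress_prev - stress < tol * max(stress_prev, 1e-30):
            break
        stress_prev = stress
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, d / dist, 0.0)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x = b @ x / n
    else:
        logger.warning("MDS did not converge in %d iterations", max_iter)
    return x, float(trace[-1]), np.asarray(trace)


def procrustes_align(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Align y to x by translation, rotation and uniform scaling.

    Returns the aligned copy of y and the disparity (sum of squared
    differences after standardizing x, as in the classical Procrustes
    statistic).
    """
    from scipy.spatial import procrustes

    mtx1, mtx2, disparity = procrustes(x, y)
    # re-express the aligned y on the scale of the original x
    x = np.asarray(x, dtype=float)
    norm_x = np.linalg.norm(x - x.mean(axis=0))
    aligned = mtx2 * norm_x + x.mean(axis=0)
    return aligned, float(disparity)


def per_synergy_voxel_fit(
    vp: VoxelPatternSet, single_synergy_weights: np.ndarray
) -> np.ndarray:
    """Per-voxel squared Pearson correlation between the voxel's responses
    across postures and one synergy's weight vector."""
    w = np.asarray(single_synergy_weights, dtype=float).ravel()
    if w.shape[0] != vp.n_postures:
        raise ValueError("weight length must match posture count")
    resp = vp.responses
    wc = w - w.mean()
    rc = resp - resp.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.sum(rc**2, axis=1) * np.sum(wc**2))
    num = rc @ wc
    r2 = np.zeros(vp.n_voxels)
    ok = denom > 0
    if not np.all(ok):
        logger.warning("%d zero-variance voxels got R^2 = 0", np.sum(~ok))
    r2[ok] = (num[ok] / denom[ok]) ** 2
    return r2


@dataclass
class TopographyInput:
    """Voxel coordinates paired with per-synergy goodness of fit."""

    coords: np.ndarray
    synergy_fit: np.ndarray  # voxels x n_synergies R^2

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.synergy_fit = np.atleast_2d(np.asarray(self.synergy_fit, dtype=float))
        if self.coords.shape[0] != self.synergy_fit.shape[0]:
            raise ValueError("coords and synergy_fit rows differ")
        if np.any(self.synergy_fit < -1e-12) or np.any(self.synergy_fit > 1 + 1e-12):
            raise ValueError("R^2 values must lie in [0, 1]")


def _standardized_upper(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("degenerate constant dimension in distance space")
    return pdist(x, metric="seuclidean", V=sd**2 * x.shape[0] / (x.shape[0] - 1))


def topography_c(t: TopographyInput) -> float:
    """Topography index: Pearson correlation between pairwise standardized
    Euclidean distances in anatomical (map) space and in synergy-fit
    (feature) space."""
    if t.coords.shape[0] < 3:
        raise ValueError("need at least three voxels")
    dm = _standardized_upper(t.coords)
    df = _standardized_upper(t.synergy_fit)
    if dm.std() == 0 or df.std() == 0:
        raise ValueError("degenerate constant space")
    return float(np.corrcoef(dm, df)[0, 1])


def topography_permutation(
    t: TopographyInput,
    mode: str = "voxel-shuffle",
    subject_fits: list[np.ndarray] | None = None,
    n_iter: int = 10000,
    seed: int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Permutation test for the topography index.

    ``voxel-shuffle`` permutes feature rows across voxels, breaking any
    map-feature coupling.  ``subject-shuffle`` rebuilds the group feature
    space by averaging subject maps after randomly permuting each subject's
    synergy columns (random subject combinations); it requires per-subject
    synergy-fit maps.
    """
    if mode not in ("voxel-shuffle", "subject-shuffle"):
        raise ValueError("mode must be voxel-shuffle or subject-shuffle")
    if mode == "subject-shuffle" and subject_fits is None:
        raise ValueError("subject-shuffle requires per-subject synergy fits")
    observed = topography_c(t)
    rng = np.random.default_rng(seed)
    dm = _standardized_upper(t.coords)
    dm = (dm - dm.mean()) / dm.std()
    n_vox = t.coords.shape[0]
    k = t.synergy_fit.shape[1]
    null = np.empty(n_iter)
    for i in range(n_iter):
        if mode == "voxel-shuffle":
            feat = t.synergy_fit[rng.permutation(n_vox)]
        else:
            acc = np.zeros((n_vox, k))
            for sf in subject_fits:  # type: ignore[union-attr]
                acc += np.asarray(sf)[:, rng.permutation(k)]
            feat = acc / len(subject_fits)  # type: ignore[arg-type]
        df = _standardized_upper(feat)
        sd = df.std()
        if sd == 0:
            null[i] = 0.0
            continue
        df = (df - df.mean()) / sd
        null[i] = np.mean(dm * df)
    p = (np.sum(null >= observed) + 1.0) / (n_iter + 1.0)
    return observed, float(p), null


def align_synergy_signs(
    subject_weights: list[np.ndarray], reference: int = 0
) -> list[np.ndarray]:
    """Resolve per-subject PCA sign ambiguity by correlating each subject's
    synergy weight vectors with the reference subject's and flipping
    negative matches."""
    ref = np.asarray(subject_weights[reference], dtype=float)
    out = []
    for w in subject_weights:
        w = np.asarray(w, dtype=float).copy()
        for c in range(w.shape[1]):
            r = np.corrcoef(w[:, c], ref[:, c])[0, 1]
            if r < 0:
                w[:, c] *= -1.0
        out.append(w)
    return out


def synergy_stability_clustering(
    vectors: np.ndarray,
    subject_ids: np.ndarray,
    n_classes: int = 3,
    max_iter: int = 100,
    seed: int | None = None,
) -> tuple[np.ndarray, float]:
    """Cannot-link-constrained k-means over per-subject synergy weight vectors.

    No two vectors from the same subject may share a class.  Each subject's
    vectors are assigned to distinct classes by an exact minimum-cost
    matching against the current centroids (Hungarian algorithm), which
    also yields balanced classes when every subject contributes
    ``n_classes`` vectors.  Returns (assignments, final objective).
    """
    vectors = np.asarray(vectors, dtype=float)
    subject_ids = np.asarray(subject_ids)
    subjects = np.unique(subject_ids)
    for s in subjects:
        if np.sum(subject_ids == s) > n_classes:
            raise ValueError(
                f"subject {s} has more vectors than classes; "
                "cannot-link constraints are infeasible"
            )
    rng = np.random.default_rng(seed)
    # initialize centroids from one random subject's own vectors
    s0 = subjects[rng.integers(len(subjects))]
    own = vectors[subject_ids == s0]
    centroids = own[:n_classes].copy()
    if centroids.shape[0] < n_classes:
        extra = vectors[rng.choice(len(vectors), n_classes - len(centroids), replace=False)]
        centroids = np.vstack([centroids, extra])
    assign = np.full(len(vectors), -1, dtype=int)
    prev_obj = np.inf
    for _ in range(max_iter):
        for s in subjects:
            idx = np.flatnonzero(subject_ids == s)
            cost = np.linalg.norm(
                vectors[idx][:, np.newaxis, :] - centroids[np.newaxis, :, :], axis=2
            ) ** 2
            rows, cols = linear_sum_assignment(cost)
            assign[idx[rows]] = cols
        obj = 0.0
        for c in range(n_classes):
            members = vectors[assign == c]
            if len(members):
                centroids[c] = members.mean(axis=0)
                obj += float(np.sum((members - centroids[c]) ** 2))
        if prev_obj - obj < 1e-12:
            break
        prev_obj = obj
    return assign, obj
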