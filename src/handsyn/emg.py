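"""Surface-EMG preprocessing, time-domain feature pool, and muscle-synergy model.

Five muscle channels (FDS, EDC, FDI, APB, ADM roles) recorded during each
grasp are resampled to 1 kHz, band-pass and notch filtered, and summarized
by a pool of 82 per-channel features (410 over 5 channels): 22 primary
time-domain features on the whole 2500-sample window plus second-order
statistics (median, MAD, skewness, kurtosis) of the amplitude-type features
tracked over sliding sub-windows.  PCA on the standardized pool gives the
5-dimensional muscle-synergy model, with component scores averaged across
repetitions of each movement.

The exact composition of the feature pool is a registry-driven convention
of this package (the set of standard EMG gesture-recognition features);
the registry is configurable and its composition is recorded in the
FeatureMatrix metadata.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal, stats

CHANNEL_ROLES = ("FDS", "EDC", "FDI", "APB", "ADM")

#: Second-order statistics applied to sliding-window traces of primary features.
SECOND_ORDER_STATS = ("median", "mad", "skewness", "kurtosis")


class FeatureError(ValueError):
    """Raised when a trial cannot be featurized (non-finite samples, too short)."""


def _spread(x: np.ndarray) -> bool:
    # guard near-constant data: higher moments are numerically meaningless
    return np.std(x) > 1e-10 * (np.abs(np.mean(x)) + 1.0)


def _safe_skew(x: np.ndarray) -> float:
    return float(stats.skew(x)) if _spread(x) else 0.0


def _safe_kurt(x: np.ndarray) -> float:
    return float(stats.kurtosis(x)) if _spread(x) else 0.0


def _ar_coefficients(x: np.ndarray, order: int = 4) -> np.ndarray:
    """Least-squares autoregressive coefficients; zeros for degenerate input."""
    if np.std(x) == 0 or len(x) <= order + 1:
        return np.zeros(order)
    y = x[order:]
    design = np.column_stack([x[order - i - 1 : len(x) - i - 1] for i in range(order)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef


def _zero_crossings(x: np.ndarray) -> float:
    s = np.sign(x)
    s = s[s != 0]
    return float(np.sum(s[1:] != s[:-1])) if len(s) > 1 else 0.0


def _slope_sign_changes(x: np.ndarray) -> float:
    d = np.diff(x)
    s = np.sign(d)
    s = s[s != 0]
    return float(np.sum(s[1:] != s[:-1])) if len(s) > 1 else 0.0


@dataclass(frozen=True)
class FeatureDef:
    """One primary feature: name, how it scales with amplitude, whether its
    sliding-window trace feeds the second-order statistics."""

    name: str
    scaling: str  # linear | quadratic | invariant | other
    windowed: bool


# 22 primary time-domain features. The first 16 are amplitude-type statistics;
# the 15 flagged `windowed` also generate 4 second-order features each
# (15 x 4 = 60), for 82 per channel in total.
PRIMARY_FEATURES: tuple[FeatureDef, ...] = (
    FeatureDef("mav", "linear", True),       # mean absolute value
    FeatureDef("rms", "linear", True),
    FeatureDef("var", "quadratic", True),
    FeatureDef("std", "linear", True),
    FeatureDef("wl", "linear", True),        # waveform length
    FeatureDef("zc", "invariant", True),     # zero crossings (zero threshold)
    FeatureDef("ssc", "invariant", True),    # slope sign changes
    FeatureDef("wamp", "other", True),       # Willison amplitude
    FeatureDef("iemg", "linear", True),      # integrated EMG
    FeatureDef("ssi", "quadratic", True),    # simple square integral
    FeatureDef("logdet", "other", True),     # log detector
    FeatureDef("damv", "linear", True),      # mean absolute derivative
    FeatureDef("dasdv", "linear", True),     # RMS of the derivative
    FeatureDef("myop", "other", True),       # myopulse percentage rate
    FeatureDef("mfl", "other", True),        # maximum fractal length
    FeatureDef("peak", "linear", False),
    FeatureDef("skewness", "invariant", False),
    FeatureDef("kurtosis", "invariant", False),
    FeatureDef("ar1", "invariant", False),
    FeatureDef("ar2", "invariant", False),
    FeatureDef("ar3", "invariant", False),
    FeatureDef("ar4", "invariant", False),
)

WAMP_THRESHOLD = 0.05
MYOP_THRESHOLD = 0.016
LOGDET_EPS = 1e-12


def _primary_vector(x: np.ndarray) -> dict[str, float]:
    d = np.diff(x)
    ar = _ar_coefficients(x)
    n = len(x)
    return {
        "mav": float(np.mean(np.abs(x))),
        "rms": float(np.sqrt(np.mean(x**2))),
        "var": float(np.var(x)),
        "std": float(np.std(x)),
        "wl": float(np.sum(np.abs(d))),
        "zc": _zero_crossings(x),
        "ssc": _slope_sign_changes(x),
        "wamp": float(np.sum(np.abs(d) > WAMP_THRESHOLD)),
        "iemg": float(np.sum(np.abs(x))),
        "ssi": float(np.sum(x**2)),
        "logdet": float(np.exp(np.mean(np.log(np.abs(x) + LOGDET_EPS)))),
        "damv": float(np.mean(np.abs(d))) if len(d) else 0.0,
        "dasdv": float(np.sqrt(np.mean(d**2))) if len(d) else 0.0,
        "myop": float(np.mean(np.abs(x) > MYOP_THRESHOLD)),
        "mfl": float(np.log10(np.sqrt(np.sum(d**2)) + LOGDET_EPS)),
        "peak": float(np.max(np.abs(x))) if n else 0.0,
        "skewness": _safe_skew(x),
        "kurtosis": _safe_kurt(x),
        "ar1": float(ar[0]),
        "ar2": float(ar[1]),
        "ar3": float(ar[2]),
        "ar4": float(ar[3]),
    }


def feature_names(registry: tuple[FeatureDef, ...] = PRIMARY_FEATURES) -> list[str]:
    """Ordered per-channel feature names: primaries then second-order stats."""
    names = [f.name for f in registry]
    for f in registry:
        if f.windowed:
            names.extend(f"{f.name}_{s}" for s in SECOND_ORDER_STATS)
    return names


@dataclass
class EMGTrial:
    """One preprocessed trial: channels x samples at a fixed sampling rate."""

    samples: np.ndarray
    fs: float
    posture_id: int
    rep_id: int

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))


@dataclass
class FeatureMatrix:
    """Trial-level feature table plus the registry that produced it."""

    values: np.ndarray
    names: list[str]
    posture_ids: np.ndarray
    rep_ids: np.ndarray
    registry: tuple[FeatureDef, ...] = PRIMARY_FEATURES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.posture_ids = np.asarray(self.posture_ids, dtype=int)
        self.rep_ids = np.asarray(self.rep_ids, dtype=int)
        if self.values.shape[1] != len(self.names):
            raise ValueError("feature column count does not match names")


@dataclass
class MuscleModel:
    """5-dimensional muscle-synergy model (movement scores, PCA loadings)."""

    weights: np.ndarray
    loadings: np.ndarray
    variance_fraction: np.ndarray
    column_mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    column_sd: np.ndarray = field(default=None)  # type: ignore[assignment]


def preprocess_trial(
    raw: np.ndarray,
    fs_in: float,
    posture_id: int = 0,
    rep_id: int = 0,
    fs_out: float = 1000.0,
    band: tuple[float, float] = (30.0, 495.0),
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
    min_samples: int = 2500,
) -> EMGTrial:
    """Resample to 1 kHz and apply zero-phase band-pass and notch filters.

    The high-pass edge is 30 Hz; the low-pass edge is capped at 0.99 of the
    output Nyquist (495 Hz at 1 kHz), since a 1000 Hz edge is not realizable
    after resampling to 1 kHz.
    """
    if fs_in < fs_out:
        raise ValueError(f"input sampling rate {fs_in} below output rate {fs_out}")
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    frac = Fraction(int(round(fs_out)), int(round(fs_in)))
    x = signal.resample_poly(raw, frac.numerator, frac.denominator, axis=1)
    if x.shape[1] < min_samples:
        raise ValueError(
            f"trial has {x.shape[1]} samples after resampling; "
            f"at least {min_samples} required"
        )
    nyq = fs_out / 2.0
    hi = min(band[1], 0.99 * nyq)
    sos = signal.butter(4, [band[0], hi], btype="bandpass", fs=fs_out, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=1)
    b, a = signal.iirnotch(notch_hz, notch_q, fs=fs_out)
    x = signal.filtfilt(b, a, x, axis=1)
    return EMGTrial(x, fs_out, posture_id, rep_id)


def _sliding_windows(x: np.ndarray, width: int, step: int) -> np.ndarray:
    n = (len(x) - width) // step + 1
    if n < 2:
        return x[np.newaxis, :]
    return np.stack([x[i * step : i * step + width] for i in range(n)])


def extract_channel_features(
    x: np.ndarray,
    registry: tuple[FeatureDef, ...] = PRIMARY_FEATURES,
    window: int = 2500,
    sub_window: int = 250,
    sub_overlap: float = 0.5,
) -> np.ndarray:
    """82 time-domain features for one channel of a preprocessed trial.

    Primary features are computed on the first ``window`` samples; second-order
    features are the median, MAD, skewness and kurtosis of each windowed
    primary feature tracked over ``sub_window``-sample windows with
    ``sub_overlap`` fractional overlap.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise FeatureError("non-finite samples in trial")
    if len(x) < window:
        raise FeatureError(f"trial has {len(x)} samples; window of {window} required")
    x = x[:window]
    primaries = _primary_vector(x)
    out = [primaries[f.name] for f in registry]
    step = max(1, int(round(sub_window * (1.0 - sub_overlap))))
    wins = _sliding_windows(x, sub_window, step)
    traces = {f.name: [] for f in registry if f.windowed}
    for w in wins:
        pv = _primary_vector(w)
        for name in traces:
            traces[name].append(pv[name])
    for f in registry:
        if not f.windowed:
            continue
        tr = np.asarray(traces[f.name])
        out.extend(
            [
                float(np.median(tr)),
                float(np.median(np.abs(tr - np.median(tr)))),
                _safe_skew(tr),
                _safe_kurt(tr),
            ]
        )
    return np.asarray(out)


def extract_features(
    trials: list[EMGTrial],
    registry: tuple[FeatureDef, ...] = PRIMARY_FEATURES,
    window: int = 2500,
) -> FeatureMatrix:
    """Featurize a collection of trials into a trials x (channels*82) matrix."""
    per_channel = feature_names(registry)
    rows, pids, rids = [], [], []
    names = [
        f"ch{c + 1}_{name}"
        for c in range(trials[0].samples.shape[0])
        for name in per_channel
    ]
    for t in trials:
        try:
            row = np.concatenate(
                [
                    extract_channel_features(t.samples[c], registry, window)
                    for c in range(t.samples.shape[0])
                ]
            )
        except FeatureError as e:
            raise FeatureError(
                f"trial posture={t.posture_id} rep={t.rep_id}: {e}"
            ) from e
        rows.append(row)
        pids.append(t.posture_id)
        rids.append(t.rep_id)
    return FeatureMatrix(np.asarray(rows), names, np.asarray(pids), np.asarray(rids), registry)


def build_muscle_model(
    features: FeatureMatrix,
    n_reps: int,
    n_components: int = 5,
    standardize: bool = True,
) -> MuscleModel:
    """PCA on the pooled feature table, then average scores over repetitions.

    Columns are z-scored before PCA by default (the features span wildly
    different scales).  PCA runs across all trials; the per-trial component
    scores are then averaged across the repetitions of each movement,
    yielding the movements x components weight matrix.
    """
    postures = np.unique(features.posture_ids)
    missing = [
        (int(p), r)
        for p in postures
        for r in range(n_reps)
        if not np.any((features.posture_ids == p) & (features.rep_ids == r))
    ]
    if missing:
        raise ValueError(f"missing trials (posture, rep): {missing}")
    x = features.values
    mu = x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        sd = np.ones(x.shape[1])
    z = (x - mu) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    loadings = vt[:n_components].copy()
    scores = (u[:, :n_components] * s[:n_components]).copy()
    # deterministic sign: largest-|value| loading entry positive
    for i in range(n_components):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] *= -1.0
            scores[:, i] *= -1.0
    total = np.sum(s**2)
    weights = np.zeros((len(postures), n_components))
    for i, p in enumerate(postures):
        weights[i] = scores[features.posture_ids == p].mean(axis=0)
    return MuscleModel(
        weights=weights,
        loadings=loadings,
        variance_fraction=s[:n_components] ** 2 / total if total > 0 else np.zeros(n_components),
        column_mean=mu,
        column_sd=sd,
    )
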