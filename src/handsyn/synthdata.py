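"""Synthetic kinematic, EMG and voxel-pattern data with the generative
structure the downstream analyses assume.

The generator emulates the study design: 20 grasp-to-use postures described
by 24 hand joint angles, each repeated 5 times; surface EMG from 5 muscles
at 2 kHz over 6 repetitions; and per-posture voxel response patterns on an
integer 3-D grid.  Postures are built from a small number of latent
synergies (an orthonormal basis with prescribed variance fractions) plus
repetition noise; EMG envelopes are linear in latent muscle weights; voxel
responses are linear in synergy weights through spatially smooth coefficient
maps, with a configurable fraction of pure-noise voxels.

Everything is driven by a single seed: identical configurations give
bit-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, signal

from .emg import EMGTrial
from .encoding import VoxelPatternSet
from .kinematics import DEFAULT_JOINT_LABELS, PostureSet

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class InvalidConfigError(ValueError):
    """Raised for configurations that violate the generator's invariants."""


@dataclass(frozen=True)
class SynthConfig:
    """Study-design constants and noise levels of the synthetic generator.

    The defaults are the study conditions: 20 postures x 5 repetitions x 24
    joints with three latent synergies carrying (0.5, 0.3, 0.1) of the total
    posture variance (about 20 deg overall spread) and repetition noise
    sized so the remaining ~10% is noise after averaging; 5 EMG channels at
    2 kHz with 2.5 s trials (2500 samples after resampling to 1 kHz) over 6
    repetitions; a 20x20x20 voxel grid with unit signal standard deviation,
    half-informative coefficient maps smoothed to 4-voxel FWHM, and additive
    response noise of 0.5.
    """

    n_postures: int = 20
    n_reps: int = 5
    n_joints: int = 24
    n_latent: int = 3
    latent_variance_fractions: tuple[float, ...] = (0.5, 0.3, 0.1)
    total_variance: float = 400.0  # deg^2, summed across joints
    rep_noise_sd: float = 2.89  # deg per joint; ~10% of total after averaging
    mean_angle: float = 30.0
    mean_angle_sd: float = 12.0
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    n_voxels: int | None = None
    voxel_noise_sd: float = 0.5
    noise_smoothness_fwhm: float = 2.0  # response noise is spatially smooth,
    # as after standard Gaussian smoothing (4 mm FWHM at 2 mm voxels)
    signal_sd: float = 1.0
    task_activation: float = 1.0  # mean response offset of informative voxels
    smoothness_fwhm: float = 4.0
    zero_coef_fraction: float = 0.5
    emg_channels: int = 5
    emg_fs: float = 2000.0
    emg_reps: int = 6
    trial_samples: int = 5000  # raw samples per trial (2.5 s at emg_fs)
    emg_band: tuple[float, float] = (30.0, 450.0)
    emg_baseline: float = 1.0
    emg_modulation: float = 0.5
    emg_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_postures": self.n_postures,
            "n_reps": self.n_reps,
            "n_joints": self.n_joints,
            "n_latent": self.n_latent,
            "emg_channels": self.emg_channels,
            "emg_reps": self.emg_reps,
            "trial_samples": self.trial_samples,
        }
        for name, v in counts.items():
            if v < 1:
                raise InvalidConfigError(f"{name} must be >= 1, got {v}")
        fr = np.asarray(self.latent_variance_fractions, dtype=float)
        if len(fr) != self.n_latent:
            raise InvalidConfigError("one variance fraction per latent component")
        if np.any(fr < 0) or fr.sum() > 1.0 + 1e-12:
            raise InvalidConfigError("variance fractions must be >= 0 and sum <= 1")
        if np.any(np.diff(fr) > 1e-12):
            raise InvalidConfigError("variance fractions must be nonincreasing")
        if self.n_latent > min(self.n_postures - 1, self.n_joints):
            raise InvalidConfigError(
                "n_latent exceeds min(n_postures - 1, n_joints)"
            )
        if self.emg_fs <= 0:
            raise InvalidConfigError("emg_fs must be positive")
        if self.n_voxels is not None and self.n_voxels > int(np.prod(self.grid_shape)):
            raise InvalidConfigError("n_voxels exceeds grid capacity")
        if not 0.0 <= self.zero_coef_fraction <= 1.0:
            raise InvalidConfigError("zero_coef_fraction must be in [0, 1]")


def _rng(cfg: SynthConfig, stream: str) -> np.random.Generator:
    # independent, reproducible stream per data modality (crc32 is stable
    # across processes, unlike Python's randomized str hash)
    key = zlib.crc32(stream.encode()) % (2**31)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(key,))
    )


def latent_posture_weights(cfg: SynthConfig) -> np.ndarray:
    """Latent synergy weights per posture with exact per-component variance."""
    rng = _rng(cfg, "posture")
    w = rng.standard_normal((cfg.n_postures, cfg.n_latent))
    w -= w.mean(axis=0)
    # orthogonalize columns, then scale each to its exact variance budget
    q, _ = np.linalg.qr(w)
    fr = np.asarray(cfg.latent_variance_fractions)
    target_sd = np.sqrt(fr * cfg.total_variance)
    q = q / q.std(axis=0)
    return q * target_sd


def latent_loadings(cfg: SynthConfig) -> np.ndarray:
    """Random orthonormal latent basis (QR of a seeded Gaussian matrix)."""
    rng = _rng(cfg, "loadings")
    g = rng.standard_normal((cfg.n_joints, cfg.n_latent))
    q, r = np.linalg.qr(g)
    q *= np.sign(np.diag(r))[np.newaxis, :]
    return q.T  # n_latent x n_joints


def generate_posture_set(cfg: SynthConfig) -> PostureSet:
    """Postures x reps x joints angle array: mean + latent structure + noise."""
    rng = _rng(cfg, "posture_noise")
    if cfg.n_joints == len(DEFAULT_JOINT_LABELS):
        labels = DEFAULT_JOINT_LABELS
        digit_map = None
    else:
        labels = tuple(f"joint{i:02d}" for i in range(cfg.n_joints))
        digit_map = {j: "thumb" for j in labels}
    mean = cfg.mean_angle + cfg.mean_angle_sd * _rng(cfg, "mean").standard_normal(
        cfg.n_joints
    )
    w = latent_posture_weights(cfg)
    loadings = latent_loadings(cfg)
    clean = mean + w @ loadings  # postures x joints
    angles = (
        clean[:, np.newaxis, :]
        + cfg.rep_noise_sd
        * rng.standard_normal((cfg.n_postures, cfg.n_reps, cfg.n_joints))
    )
    kwargs = {"joint_labels": labels}
    if digit_map is not None:
        kwargs["digit_map"] = digit_map
    return PostureSet(angles, **kwargs)


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    x = rng.standard_normal(n)
    hi = min(band[1], 0.99 * fs / 2.0)
    sos = signal.butter(4, [band[0], hi], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    sd = np.std(y)
    return y / sd if sd > 0 else y


def generate_emg_trials(
    muscle_weights: np.ndarray, cfg: SynthConfig
) -> list[EMGTrial]:
    """Raw EMG trials: band-limited carriers amplitude-modulated per posture.

    For each trial and channel, a 30-450 Hz Gaussian carrier is scaled by a
    channel-specific affine function of that posture's latent muscle weights
    (rectified at a small positive floor) and corrupted by additive Gaussian
    noise.  Output trials are at the raw sampling rate ``emg_fs``.
    """
    muscle_weights = np.asarray(muscle_weights, dtype=float)
    if not np.all(np.isfinite(muscle_weights)):
        raise ValueError("muscle weights must be finite")
    if cfg.emg_fs <= 0:
        raise InvalidConfigError("emg_fs must be positive")
    n_post, k = muscle_weights.shape
    rng = _rng(cfg, "emg")
    col_sd = muscle_weights.std(axis=0)
    col_sd = np.where(col_sd > 0, col_sd, 1.0)
    w_norm = (muscle_weights - muscle_weights.mean(axis=0)) / col_sd
    # channel-specific modulation directions in latent space
    mix = rng.standard_normal((cfg.emg_channels, k))
    mix /= np.linalg.norm(mix, axis=1, keepdims=True)
    trials = []
    for p in range(n_post):
        gains = cfg.emg_baseline + cfg.emg_modulation * (mix @ w_norm[p])
        gains = np.maximum(gains, 0.05 * cfg.emg_baseline)
        for r in range(cfg.emg_reps):
            x = np.empty((cfg.emg_channels, cfg.trial_samples))
            for c in range(cfg.emg_channels):
                carrier = _bandlimited_noise(
                    rng, cfg.trial_samples, cfg.emg_fs, cfg.emg_band
                )
                x[c] = gains[c] * carrier + cfg.emg_noise_sd * rng.standard_normal(
                    cfg.trial_samples
                )
            trials.append(EMGTrial(x, cfg.emg_fs, posture_id=p, rep_id=r))
    return trials


def coefficient_maps(cfg: SynthConfig, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Smooth per-voxel coefficient maps over the grid.

    Returns (coords, coef) where coef is voxels x components.  Each map is a
    Gaussian random field smoothed to ``smoothness_fwhm`` (reflect boundary)
    and standardized across voxels; a ``zero_coef_fraction`` of voxels is
    zeroed to act as pure-noise voxels.
    """
    rng = _rng(cfg, "voxel_coef")
    shape = cfg.grid_shape
    sigma = cfg.smoothness_fwhm * _FWHM_TO_SIGMA
    fields = []
    for _ in range(n_components):
        f = rng.standard_normal(shape)
        if sigma > 0:
            f = ndimage.gaussian_filter(f, sigma=sigma, mode="reflect")
        f = (f - f.mean()) / f.std()
        fields.append(f.ravel())
    coef = np.column_stack(fields)
    coords = np.argwhere(np.ones(shape, dtype=bool))
    n_total = coords.shape[0]
    n_vox = cfg.n_voxels if cfg.n_voxels is not None else n_total
    if n_vox < n_total:
        keep = np.sort(rng.choice(n_total, size=n_vox, replace=False))
        coords, coef = coords[keep], coef[keep]
    if cfg.zero_coef_fraction > 0:
        # informative voxels form spatially contiguous blobs, as in real
        # activation maps: zero out the region below a quantile of a
        # smoothed support field rather than scattering nulls at random
        support = rng.standard_normal(shape)
        if sigma > 0:
            support = ndimage.gaussian_filter(support, sigma=sigma, mode="reflect")
        support = support.ravel()
        if n_vox < n_total:
            support = support[keep]
        thr = np.quantile(support, cfg.zero_coef_fraction)
        coef[support < thr] = 0.0
    return coords, coef


def generate_voxel_patterns(
    synergy_weights: np.ndarray, cfg: SynthConfig
) -> VoxelPatternSet:
    """Voxel responses linear in synergy weights plus Gaussian noise.

    Coefficient maps are globally rescaled per component so an informative
    voxel's signal has standard deviation ``signal_sd`` across postures in
    expectation, whatever the scale of the supplied weights.
    """
    synergy_weights = np.asarray(synergy_weights, dtype=float)
    if not np.all(np.isfinite(synergy_weights)):
        raise ValueError("synergy weights must be finite")
    n_post, k = synergy_weights.shape
    coords, coef = coefficient_maps(cfg, k)
    w_sd = synergy_weights.std(axis=0)
    w_sd = np.where(w_sd > 0, w_sd, 1.0)
    scale = cfg.signal_sd / (np.sqrt(k) * w_sd)
    coef = coef * scale[np.newaxis, :]
    rng = _rng(cfg, "voxel_noise")
    responses = coef @ synergy_weights.T
    # task-engaged voxels respond above rest on average (t-score-like offset)
    informative = ~np.all(coef == 0, axis=1)
    responses[informative] += cfg.task_activation
    if cfg.voxel_noise_sd > 0:
        shape = cfg.grid_shape
        n_total = int(np.prod(shape))
        sigma = cfg.noise_smoothness_fwhm * _FWHM_TO_SIGMA
        noise = np.empty((n_total, n_post))
        for p in range(n_post):
            f = rng.standard_normal(shape)
            if sigma > 0:
                f = ndimage.gaussian_filter(f, sigma=sigma, mode="reflect")
                f /= f.std()
            noise[:, p] = f.ravel()
        if coords.shape[0] < n_total:
            flat = np.ravel_multi_index(coords.T, shape)
            noise = noise[flat]
        responses = responses + cfg.voxel_noise_sd * noise
    return VoxelPatternSet(responses, coords)


def with_seed(cfg: SynthConfig, seed: int) -> SynthConfig:
    """A copy of the configuration with a different seed."""
    return replace(cfg, seed=seed)
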