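"""Delimited-text and NIfTI readers/writers for the pipeline's data objects.

Matrices travel as tab-separated text with headers; volumetric maps can be
written as NIfTI (one 3-D volume per posture, or a single score volume).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .emg import EMGTrial
from .encoding import VoxelPatternSet
from .kinematics import DEFAULT_JOINT_LABELS, PostureSet, SynergyModel


def write_posture_set(ps: PostureSet, path: str | Path) -> None:
    """Tidy delimited text: posture_id, rep, one column per joint label."""
    rows = []
    for p in range(ps.n_postures):
        for r in range(ps.n_reps):
            rows.append([p, r, *ps.angles[p, r]])
    df = pd.DataFrame(rows, columns=["posture_id", "rep", *ps.joint_labels])
    df.to_csv(path, sep="\t", index=False)


def read_posture_set(path: str | Path) -> PostureSet:
    df = pd.read_csv(path, sep="\t")
    joints = [c for c in df.columns if c not in ("posture_id", "rep")]
    postures = np.sort(df["posture_id"].unique())
    reps = np.sort(df["rep"].unique())
    angles = np.empty((len(postures), len(reps), len(joints)))
    for i, p in enumerate(postures):
        for j, r in enumerate(reps):
            row = df[(df["posture_id"] == p) & (df["rep"] == r)]
            if len(row) != 1:
                raise ValueError(f"missing or duplicated trial posture={p} rep={r}")
            angles[i, j] = row[joints].to_numpy()[0]
    kwargs = {}
    if tuple(joints) != DEFAULT_JOINT_LABELS:
        kwargs = {
            "joint_labels": tuple(joints),
            "digit_map": {j: j.split("_", 1)[0] for j in joints},
        }
    return PostureSet(angles, **kwargs)


def write_emg_trial(trial: EMGTrial, path: str | Path) -> None:
    """One file per trial: sample index plus one column per channel."""
    n_ch, n = trial.samples.shape
    df = pd.DataFrame(
        {"sample": np.arange(n)}
        | {f"ch{c + 1}": trial.samples[c] for c in range(n_ch)}
    )
    df.to_csv(path, sep="\t", index=False)


def read_emg_trial(path: str | Path, fs: float, posture_id: int, rep_id: int) -> EMGTrial:
    df = pd.read_csv(path, sep="\t")
    chans = [c for c in df.columns if c.startswith("ch")]
    return EMGTrial(df[chans].to_numpy().T, fs, posture_id, rep_id)


def write_voxel_patterns(vp: VoxelPatternSet, path: str | Path) -> None:
    """Delimited text: x, y, z then one response column per posture."""
    cols = {"x": vp.coords[:, 0], "y": vp.coords[:, 1], "z": vp.coords[:, 2]}
    for i, lab in enumerate(vp.posture_labels):
        cols[lab] = vp.responses[:, i]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_voxel_patterns(path: str | Path) -> VoxelPatternSet:
    df = pd.read_csv(path, sep="\t")
    coords = df[["x", "y", "z"]].to_numpy(dtype=int)
    labels = [c for c in df.columns if c not in ("x", "y", "z")]
    return VoxelPatternSet(df[labels].to_numpy(), coords, tuple(labels))


def write_voxel_patterns_nifti(vp: VoxelPatternSet, path: str | Path) -> None:
    """4-D NIfTI volume (grid x postures); empty grid cells are NaN."""
    import nibabel as nib

    shape = tuple(vp.coords.max(axis=0).astype(int) + 1)
    vol = np.full(shape + (vp.n_postures,), np.nan)
    vol[tuple(vp.coords.astype(int).T)] = vp.responses
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


def write_score_map_nifti(
    scores: np.ndarray, coords: np.ndarray, path: str | Path
) -> None:
    """Single 3-D NIfTI volume of per-voxel scores (recruitment, overlap)."""
    import nibabel as nib

    coords = np.asarray(coords, dtype=int)
    shape = tuple(coords.max(axis=0) + 1)
    vol = np.zeros(shape)
    vol[tuple(coords.T)] = scores
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


def write_synergy_model(model: SynergyModel, prefix: str | Path) -> None:
    """Loadings and weights as delimited text plus JSON metadata."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".loadings.tsv"), model.loadings, delimiter="\t")
    np.savetxt(prefix.with_suffix(".weights.tsv"), model.weights, delimiter="\t")
    meta = {
        "mean_posture": model.mean_posture.tolist(),
        "variance_fraction": model.variance_fraction.tolist(),
        "n_components": model.n_components,
    }
    prefix.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def read_matrix(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t")


def write_matrix(mat: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(mat), delimiter="\t")
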