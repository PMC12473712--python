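"""Manifest and recording I/O, modality assembly, resampling, normalization.

File dialects
-------------
Pose CSV      header ``t,px,py,pz,qw,qx,qy,qz`` — seconds, metres, unit
              quaternions (w-first).  Sampling must be uniform (1e-6 s jitter
              tolerance); quaternions within 1e-3 of unit norm are
              re-normalized, anything further is rejected.
IMU CSV       header ``t,acc_x,acc_y,acc_z,gyr_x,gyr_y,gyr_z`` — m/s², rad/s.
Manifest CSV  header ``subject_id,day,trial,device,path`` with paths relative
              to the manifest's directory.

Modalities
----------
Each channel set is a 3-channel view of a trial: ``POS`` raw world positions,
``EULER`` intrinsic Z-Y-X Euler angles (left wrapped — the discontinuities
are the phenomenon under study, so no unwrapping), ``ACC``/``GYRO`` the
transformed body-frame signals with an optional low-pass cutoff.  Channel
sets are resampled by linear interpolation to the layout's length and stacked
(one ``length x 3k`` array) or kept as separate branch arrays, then z-scored
per channel with statistics fit on the training day only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import quatmath as qm
from .imugen import PoseRecording, transform_recording

__all__ = [
    "MANIFEST_COLUMNS",
    "ModalityConfig",
    "FeatureTensorSet",
    "read_manifest",
    "write_manifest",
    "manifest_from_rows",
    "read_pose_csv",
    "write_pose_csv",
    "write_imu_csv",
    "resample_channels",
    "assemble_features",
]

MANIFEST_COLUMNS = ["subject_id", "day", "trial", "device", "path"]
POSE_COLUMNS = ["t", "px", "py", "pz", "qw", "qx", "qy", "qz"]
IMU_COLUMNS = ["t", "acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"]
CHANNEL_SETS = ("POS", "EULER", "ACC", "GYRO")


@dataclass(frozen=True)
class ModalityConfig:
    """Which 3-channel sets feed the classifier, and in what layout.

    ``stacked`` concatenates all sets along the channel axis into one
    ``stacked_length x 3k`` array (the single-input CNNs); ``branched`` keeps
    one ``branch_length x 3`` array per set (the multi-input CNN, max 2 sets).
    """

    channel_sets: tuple[str, ...]
    lowpass_cutoff: float | None = None
    layout: str = "stacked"
    stacked_length: int = 128
    branch_length: int = 100

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel_sets", tuple(s.upper() for s in self.channel_sets))
        unknown = set(self.channel_sets) - set(CHANNEL_SETS)
        if unknown:
            raise ValueError(f"unknown channel sets: {sorted(unknown)}")
        if self.layout not in ("stacked", "branched"):
            raise ValueError("layout must be 'stacked' or 'branched'")
        if self.layout == "branched" and not 1 <= len(self.channel_sets) <= 2:
            raise ValueError("branched layout takes 1-2 channel sets")
        if not self.channel_sets:
            raise ValueError("at least one channel set required")

    @property
    def label(self) -> str:
        tag = "+".join(self.channel_sets)
        if self.lowpass_cutoff is not None:
            tag += f":{self.lowpass_cutoff:g}"
        return tag

    @classmethod
    def parse(cls, text: str, **kwargs) -> "ModalityConfig":
        """Parse e.g. ``"acc+gyro:6"`` → sets (ACC, GYRO), cutoff 6 Hz."""
        cutoff = None
        if ":" in text:
            text, cut = text.split(":", 1)
            cutoff = None if cut.lower() == "none" else float(cut)
        return cls(tuple(text.split("+")), lowpass_cutoff=cutoff, **kwargs)


@dataclass
class FeatureTensorSet:
    """Assembled per-trial feature arrays with labels and day groups.

    ``arrays`` is a list with one entry per branch; the stacked layout uses a
    single entry of shape ``(n_trials, length, 3k)``.  ``labels`` are integer
    class indices into ``class_names``; ``groups`` are day numbers.
    """

    arrays: list[np.ndarray]
    labels: np.ndarray
    groups: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        n = len(self.labels)
        for a in self.arrays:
            if len(a) != n:
                raise ValueError("feature arrays and labels must share length")
            if not np.isfinite(a).all():
                raise ValueError("features contain non-finite values")

    def subset(self, mask: np.ndarray) -> "FeatureTensorSet":
        return FeatureTensorSet(
            [a[mask] for a in self.arrays],
            self.labels[mask],
            self.groups[mask],
            self.class_names,
        )


# ---------------------------------------------------------------------------
# CSV dialects


def write_pose_csv(path: str | Path, rec: PoseRecording) -> None:
    df = pd.DataFrame(
        np.column_stack([rec.times, rec.positions, rec.orientations]),
        columns=POSE_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_pose_csv(path: str | Path) -> PoseRecording:
    df = pd.read_csv(path)
    missing = [c for c in POSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: pose CSV missing columns {missing}")
    t = df["t"].to_numpy(float)
    if len(t) < 3:
        raise ValueError(f"{path}: fewer than 3 samples")
    dts = np.diff(t)
    if np.any(np.abs(dts - dts[0]) > 1e-6):
        raise ValueError(
            f"{path}: non-uniform timestamps (max jitter "
            f"{np.max(np.abs(dts - dts[0])):.3g} s); resample before loading"
        )
    if dts[0] <= 0:
        raise ValueError(f"{path}: non-increasing timestamps")
    quats = df[["qw", "qx", "qy", "qz"]].to_numpy(float)
    norms = qm.norm(quats)
    if np.any(np.abs(norms - 1.0) > 1e-3):
        raise ValueError(
            f"{path}: non-unit quaternion (norm deviates by "
            f"{np.max(np.abs(norms - 1.0)):.3g}, tolerance 1e-3)"
        )
    quats = quats / norms[:, None]
    return PoseRecording(
        df[["px", "py", "pz"]].to_numpy(float), quats, 1.0 / float(dts[0])
    )


def write_imu_csv(path: str | Path, times: np.ndarray, acc: np.ndarray, gyr: np.ndarray) -> None:
    df = pd.DataFrame(np.column_stack([times, acc, gyr]), columns=IMU_COLUMNS)
    df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# Manifests


def manifest_from_rows(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    _validate_manifest(df)
    return df


def _validate_manifest(df: pd.DataFrame) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    key = df[["subject_id", "day", "trial", "device"]]
    if key.duplicated().any():
        dupes = key[key.duplicated()].head(3).to_dict("records")
        raise ValueError(f"duplicate (subject, day, trial, device) rows: {dupes}")


def write_manifest(path: str | Path, manifest: pd.DataFrame) -> None:
    _validate_manifest(manifest)
    manifest.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _validate_manifest(df)
    base = path.parent
    for rel in df["path"]:
        if not (base / rel).exists():
            raise FileNotFoundError(f"manifest entry does not resolve: {base / rel}")
    df.attrs["base_dir"] = str(base)
    return df


def load_miller_corpus(path: str | Path):  # pragma: no cover - adapter stub
    """Adapter stub for the open VR-basketball corpus's native layout.

    The external corpus (41 subjects x 10 trials x 2 days x 3 devices) ships
    in its own directory structure; converting it means writing one pose CSV
    per right-controller trial and a manifest with the device as label.  This
    package does not bundle or download that data — implement the conversion
    here if you have a local copy, then use :func:`read_manifest` as usual.
    """
    raise NotImplementedError(
        "external corpus adapter not implemented; convert recordings to the "
        "pose CSV dialect and build a manifest with manifest_from_rows()"
    )


# ---------------------------------------------------------------------------
# Resampling and feature assembly


def resample_channels(series: np.ndarray, target: int) -> np.ndarray:
    """Linear interpolation of an (N, C) array onto ``target`` uniform samples
    spanning the same time range.  Endpoints are preserved exactly."""
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n < 2:
        raise ValueError("need at least 2 samples to resample")
    if target < 2:
        raise ValueError("target length must be >= 2")
    src = np.linspace(0.0, 1.0, n)
    dst = np.linspace(0.0, 1.0, target)
    return np.stack([np.interp(dst, src, series[:, c]) for c in range(series.shape[1])], axis=1)


def _trial_channels(
    rec: PoseRecording,
    channel_set: str,
    cutoff: float | None,
    add_gravity: bool,
    filter_order: int,
) -> np.ndarray:
    if channel_set == "POS":
        return rec.positions
    if channel_set == "EULER":
        # wrapped on purpose: the discontinuity is what this modality exhibits
        return qm.quat_to_euler(rec.orientations)
    kin = transform_recording(rec, cutoff, order=filter_order, add_gravity=add_gravity)
    if channel_set == "ACC":
        return kin.acceleration
    if channel_set == "GYRO":
        return kin.angular_velocity
    raise ValueError(f"unknown channel set {channel_set!r}")


def assemble_features(
    manifest: pd.DataFrame,
    modality: ModalityConfig,
    *,
    base_dir: str | Path | None = None,
    train_day: int = 1,
    add_gravity: bool = False,
    filter_order: int = 4,
    normalize: bool = True,
    recordings: dict[str, PoseRecording] | None = None,
) -> FeatureTensorSet:
    """Build classifier-ready feature tensors for every manifest row.

    Loads each recording (or takes it from ``recordings`` keyed by path),
    derives the configured channel sets, resamples to the layout length,
    and z-scores per channel using **training-day statistics only** so no
    test-day information leaks into normalization.
    """
    if base_dir is None:
        base_dir = manifest.attrs.get("base_dir", ".")
    base = Path(base_dir)

    per_set: dict[str, list[np.ndarray]] = {s: [] for s in modality.channel_sets}
    length = (
        modality.stacked_length if modality.layout == "stacked" else modality.branch_length
    )
    for rel in manifest["path"]:
        rec = recordings[rel] if recordings is not None else read_pose_csv(base / rel)
        for s in modality.channel_sets:
            raw = _trial_channels(
                rec, s, modality.lowpass_cutoff, add_gravity, filter_order
            )
            per_set[s].append(resample_channels(raw, length))

    branches = [np.stack(per_set[s]) for s in modality.channel_sets]
    if modality.layout == "stacked":
        branches = [np.concatenate(branches, axis=2)]

    class_names = sorted(manifest["subject_id"].astype(str).unique())
    label_of = {c: i for i, c in enumerate(class_names)}
    labels = manifest["subject_id"].astype(str).map(label_of).to_numpy()
    groups = manifest["day"].to_numpy(int)

    if normalize:
        train_mask = groups == train_day
        if not train_mask.any():
            raise ValueError(f"no rows for training day {train_day}")
        normed = []
        for x in branches:
            mu = x[train_mask].mean(axis=(0, 1), keepdims=True)
            sd = x[train_mask].std(axis=(0, 1), keepdims=True)
            sd = np.where(sd < 1e-12, 1.0, sd)
            normed.append((x - mu) / sd)
        branches = normed

    return FeatureTensorSet(branches, labels, groups, class_names)
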