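"""Shared fixtures: seeded smooth orientation streams and in-memory corpora."""

import numpy as np
import pytest

from pose2imu import quatmath as qm
from pose2imu.datasets_io import manifest_from_rows
from pose2imu.synthetic import SyntheticConfig, draw_subjects, generate_trial


def smooth_orientations(rng: np.random.Generator, n: int = 180, fs: float = 60.0):
    """A smooth random unit-quaternion stream: low-frequency rotation-vector
    Fourier series turned into quaternions (no sign flips, bounded rates)."""
    t = np.arange(n) / fs
    rotvec = np.zeros((n, 3))
    for _ in range(3):
        freq = rng.uniform(0.2, 1.5)
        amp = rng.uniform(0.2, 1.0, size=3)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        rotvec += amp * np.sin(2 * np.pi * freq * t[:, None] + phase)
    angle = np.linalg.norm(rotvec, axis=1)
    axis = np.where(
        angle[:, None] > 1e-12,
        rotvec / np.maximum(angle, 1e-12)[:, None],
        np.array([1.0, 0.0, 0.0]),
    )
    return qm.from_axis_angle(axis, angle)


def smooth_recording(rng: np.random.Generator, n: int = 180, fs: float = 60.0):
    """A smooth random pose recording (for invariance/property tests)."""
    from pose2imu.imugen import PoseRecording

    t = np.arange(n) / fs
    pos = np.zeros((n, 3))
    for _ in range(3):
        freq = rng.uniform(0.2, 1.5)
        amp = rng.uniform(0.05, 0.5, size=3)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        pos += amp * np.sin(2 * np.pi * freq * t[:, None] + phase)
    return PoseRecording(pos, smooth_orientations(rng, n, fs), fs)


def in_memory_corpus(n_subjects=5, trials_per_day=6, n_days=2, seed=0, **cfg_kwargs):
    """Generate a corpus without touching disk: (manifest, recordings dict)."""
    cfg = SyntheticConfig(
        n_subjects=n_subjects,
        trials_per_day=trials_per_day,
        n_days=n_days,
        seed=seed,
        **cfg_kwargs,
    )
    subjects = draw_subjects(n_subjects, seed)
    recordings, rows = {}, []
    for i, params in enumerate(subjects):
        for day in range(1, n_days + 1):
            for trial in range(trials_per_day):
                rel = f"S{i:03d}_d{day}_t{trial:02d}.csv"
                recordings[rel] = generate_trial(params, day, trial, cfg, subject_key=i)
                rows.append(
                    {
                        "subject_id": f"S{i:03d}",
                        "day": day,
                        "trial": trial,
                        "device": "synthetic",
                        "path": rel,
                    }
                )
    return manifest_from_rows(rows), recordings


@pytest.fixture(scope="session")
def small_corpus():
    """5 subjects x 6 trials x 2 days, default noise/drift (session-cached)."""
    return in_memory_corpus(seed=42)
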