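# pose2imu

Behavioral biometrics from VR hand-controller motion, via **modality
transformation**: the 6-DoF pose stream a tracked controller produces —
world-frame position `p(t)` and unit-quaternion orientation `o(t)` — is
converted algebraically into the body-frame signals an inertial measurement
unit attached to the controller would report,

    v(t) = vec( o*(t) ⊗ p'(t)  ⊗ o(t) )        velocity            [m/s]
    a(t) = vec( o*(t) ⊗ p''(t) ⊗ o(t) )        acceleration        [m/s²]
    ω(t) = 2 M(o(t)) o'(t) = 2 vec(o*(t) ⊗ o'(t))   angular rate   [rad/s]

with `⊗` the Hamilton product, `*` the conjugate, `'` the forward difference,
and `M(o)` the 3×4 quaternion-rate matrix.  Orientation expressed as Euler
angles is discontinuous (the ±180° yaw wrap), which hurts convolutional
classifiers; the derived accelerometer/gyroscope channels are smooth and —
crucially — invariant to where the subject stands and faces, so they
generalize across recording sessions.  The package is for researchers in
motion-based user identification who want this transform, the accompanying
CNN identification pipeline, and a controllable synthetic corpus to exercise
it end to end without any data download.

What's inside (`src/pose2imu/`):

| module | contents |
|---|---|
| `quatmath` | w-first Hamilton-convention quaternion algebra, intrinsic Z-Y-X Euler conversions |
| `imugen` | the pose→IMU transform, sign-continuity correction, zero-phase Butterworth conditioning |
| `synthetic` | seeded generator of subject-distinct VR throw gestures (41×10×2 by default) with day drift, placement changes, and guaranteed Euler-wrap discontinuities |
| `datasets_io` | pose/IMU/manifest CSV dialects, resampling to model input shapes, leakage-free per-channel z-scoring |
| `nn` / `models` | numpy 1-D CNN engine; vanilla, attention, and multi-input (equal-kernel two-branch) architectures; Adam training loop |
| `evaluation` | cross-day split, macro F1, One-vs-Rest AUC/FAR/FRR (argmax-based), repetition-averaged experiment grid |
| `cli` | `pose2imu simulate / transform / train / compare / evaluate` |

See `docs/methods.md` for the model, conventions and design choices.

## Worked example

Generate a small synthetic corpus, transform one trial, and run a cross-day
identification cell:

```python
import numpy as np
from pose2imu import (
    SyntheticConfig, draw_subjects, generate_trial, transform_recording,
    ModalityConfig, assemble_features, TrainConfig, quatmath as qm,
)
from pose2imu.datasets_io import manifest_from_rows
from pose2imu.evaluation import evaluate_cell

cfg = SyntheticConfig(n_subjects=10, trials_per_day=10, n_days=2, seed=2027)
subjects = draw_subjects(cfg.n_subjects, cfg.seed)

rec = generate_trial(subjects[0], day=1, trial=0, cfg=cfg, subject_key=0)
yaw = qm.quat_to_euler(rec.orientations)[:, 0]
kin = transform_recording(rec, cutoff=6.0)
print(f"max consecutive yaw jump: {np.abs(np.diff(yaw)).max():.2f} rad")
print(f"max consecutive gyro step: {np.abs(np.diff(kin.angular_velocity, axis=0)).max():.2f} rad/s")

recordings, rows = {}, []
for i, params in enumerate(subjects):
    for day in (1, 2):
        for trial in range(cfg.trials_per_day):
            key = f"S{i:03d}_d{day}_t{trial:02d}"
            recordings[key] = generate_trial(params, day, trial, cfg, subject_key=i)
            rows.append({"subject_id": f"S{i:03d}", "day": day, "trial": trial,
                         "device": "synthetic", "path": key})
manifest = manifest_from_rows(rows)

features = assemble_features(
    manifest, ModalityConfig.parse("acc+gyro:6", layout="branched"),
    recordings=recordings,
)
report = evaluate_cell(features, "multi_input_cnn",
                       TrainConfig(epochs=60, repetitions=3), master_seed=511)
m = report.mean
print(f"cross-day macro F1 {m['f1']:.3f}, OvR AUC {m['auc']:.3f}, "
      f"FAR {m['far']:.4f}, FRR {m['frr']:.4f}")
```

Output:

```
max consecutive yaw jump: 6.24 rad
max consecutive gyro step: 0.26 rad/s
cross-day macro F1 0.533, OvR AUC 0.881, FAR 0.0422, FRR 0.3800
```

The first two lines are the phenomenon in miniature: the Euler yaw channel
jumps by ≈2π where the orientation crosses the ±180° boundary, while the
gyroscope derived from the *same* rotation stays smooth.  The last line is
cross-day identification of 10 subjects (chance F1 = 0.1) from transformed
ACC+GYRO signals with a 6 Hz low-pass, averaged over 3 seeded training
repetitions.  Note FAR = FRR/9 exactly: with balanced test sets and
argmax decisions, the One-vs-Rest identity `FAR = FRR/(K−1)` holds by
construction.

The same experiment from the shell:

```bash
pose2imu simulate --subjects 10 --trials 10 --days 2 --seed 2027 --out corpus/
pose2imu transform --manifest corpus/manifest.csv --out imu/ --lowpass 6
pose2imu train --manifest corpus/manifest.csv --modality acc+gyro:6 \
    --model multi_input_cnn --epochs 60 --reps 3 --seed 511 --out run.json
pose2imu compare --manifest corpus/manifest.csv --reps 3 --epochs 60 \
    --seed 1 --out grid.csv
```

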