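"""I/O dialects, resampling, feature assembly and leakage-free normalization."""

import numpy as np
import pandas as pd
import pytest

from pose2imu import quatmath as qm
from pose2imu.datasets_io import (
    ModalityConfig,
    assemble_features,
    manifest_from_rows,
    read_manifest,
    read_pose_csv,
    resample_channels,
    write_manifest,
    write_pose_csv,
)
from pose2imu.imugen import PoseRecording
from pose2imu.synthetic import SyntheticConfig, draw_subjects, generate_trial

from conftest import in_memory_corpus


def tiny_recording(n=20, fs=50.0, seed=0):
    rng = np.random.default_rng(seed)
    q = qm.random_unit_quaternions(n, rng)
    return PoseRecording(rng.standard_normal((n, 3)), q, fs)


class TestPoseCsv:
    def test_round_trip(self, tmp_path):
        rec = tiny_recording()
        path = tmp_path / "trial.csv"
        write_pose_csv(path, rec)
        back = read_pose_csv(path)
        np.testing.assert_allclose(back.positions, rec.positions, atol=1e-8)
        np.testing.assert_allclose(back.orientations, rec.orientations, atol=1e-8)
        assert abs(back.sample_rate - rec.sample_rate) < 1e-6

    def test_rejects_non_unit_quaternion(self, tmp_path):
        rec = tiny_recording()
        df = pd.read_csv((lambda p: (write_pose_csv(p, rec), p)[1])(tmp_path / "x.csv"))
        df.loc[3, ["qw", "qx", "qy", "qz"]] = [0.5, 0.0, 0.0, 0.0]
        df.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(ValueError, match="non-unit quaternion"):
            read_pose_csv(tmp_path / "bad.csv")

    def test_rejects_missing_column(self, tmp_path):
        rec = tiny_recording()
        write_pose_csv(tmp_path / "x.csv", rec)
        df = pd.read_csv(tmp_path / "x.csv").drop(columns=["qz"])
        df.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(ValueError, match=r"missing columns \['qz'\]"):
            read_pose_csv(tmp_path / "bad.csv")

    def test_rejects_uneven_sampling(self, tmp_path):
        rec = tiny_recording()
        write_pose_csv(tmp_path / "x.csv", rec)
        df = pd.read_csv(tmp_path / "x.csv")
        df.loc[5, "t"] += 0.003
        df.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(ValueError, match="non-uniform timestamps"):
            read_pose_csv(tmp_path / "bad.csv")


class TestManifest:
    def test_round_trip(self, tmp_path):
        rows = [
            {"subject_id": "S0", "day": 1, "trial": 0, "device": "d", "path": "a.csv"},
            {"subject_id": "S0", "day": 2, "trial": 0, "device": "d", "path": "b.csv"},
        ]
        manifest = manifest_from_rows(rows)
        for rel in manifest["path"]:
            write_pose_csv(tmp_path / rel, tiny_recording())
        write_manifest(tmp_path / "manifest.csv", manifest)
        back = read_manifest(tmp_path / "manifest.csv")
        pd.testing.assert_frame_equal(back, manifest)
        assert back.attrs["base_dir"] == str(tmp_path)

    def test_rejects_duplicate_keys(self):
        row = {"subject_id": "S0", "day": 1, "trial": 0, "device": "d", "path": "a.csv"}
        with pytest.raises(ValueError, match="duplicate"):
            manifest_from_rows([row, dict(row, path="b.csv")])

    def test_rejects_dangling_paths(self, tmp_path):
        manifest = manifest_from_rows(
            [{"subject_id": "S0", "day": 1, "trial": 0, "device": "d", "path": "no.csv"}]
        )
        write_manifest(tmp_path / "manifest.csv", manifest)
        with pytest.raises(FileNotFoundError, match="no.csv"):
            read_manifest(tmp_path / "manifest.csv")


class TestResampling:
    def test_constant_and_linear_fixed_points(self):
        const = np.full((135, 2), 3.5)
        np.testing.assert_array_equal(resample_channels(const, 50), np.full((50, 2), 3.5))
        ramp = np.linspace(0, 1, 135)[:, None]
        out = resample_channels(ramp, 128)
        np.testing.assert_allclose(out, np.linspace(0, 1, 128)[:, None], atol=1e-12)
        assert out[0, 0] == 0.0 and out[-1, 0] == 1.0

    def test_sinusoid_interpolation_error(self):
        # linear-interp error bound h^2 |f''| / 8 = (2pi*2)^2 / (8 * 224^2)
        # ~ 3.9e-4 for a 2 Hz sinusoid spanning 1 s on 225 samples
        t_src = np.linspace(0, 1, 225)
        x = np.sin(2 * np.pi * 2.0 * t_src)[:, None]
        out = resample_channels(x, 128)
        t_dst = np.linspace(0, 1, 128)
        np.testing.assert_allclose(out[:, 0], np.sin(2 * np.pi * 2.0 * t_dst), atol=1e-3)

    def test_rejects_degenerate_sizes(self):
        with pytest.raises(ValueError):
            resample_channels(np.zeros((1, 3)), 10)
        with pytest.raises(ValueError):
            resample_channels(np.zeros((10, 3)), 1)


class TestModalityConfig:
    def test_parse_and_label(self):
        m = ModalityConfig.parse("acc+gyro:6", layout="branched")
        assert m.channel_sets == ("ACC", "GYRO") and m.lowpass_cutoff == 6.0
        assert m.label == "ACC+GYRO:6"
        assert ModalityConfig.parse("pos+euler").lowpass_cutoff is None

    def test_branched_limited_to_two_sets(self):
        with pytest.raises(ValueError, match="1-2 channel sets"):
            ModalityConfig(("POS", "EULER", "ACC"), layout="branched")
        with pytest.raises(ValueError, match="unknown channel sets"):
            ModalityConfig(("XYZ",))


class TestAssembleFeatures:
    @pytest.fixture(scope="class")
    def corpus(self):
        return in_memory_corpus(n_subjects=3, trials_per_day=2, seed=1)

    def test_stacked_pos_euler_shape(self, corpus):
        manifest, recs = corpus
        feats = assemble_features(
            manifest, ModalityConfig(("POS", "EULER")), recordings=recs
        )
        assert len(feats.arrays) == 1
        assert feats.arrays[0].shape == (12, 128, 6)

    def test_branched_acc_gyro_pair(self, corpus):
        manifest, recs = corpus
        feats = assemble_features(
            manifest,
            ModalityConfig(("ACC", "GYRO"), lowpass_cutoff=6.0, layout="branched"),
            recordings=recs,
        )
        assert [a.shape for a in feats.arrays] == [(12, 100, 3), (12, 100, 3)]

    def test_training_day_zscore_contract(self, corpus):
        manifest, recs = corpus
        feats = assemble_features(
            manifest, ModalityConfig(("POS", "EULER")), recordings=recs, train_day=1
        )
        train = feats.arrays[0][feats.groups == 1]
        np.testing.assert_allclose(train.mean(axis=(0, 1)), 0.0, atol=1e-9)
        np.testing.assert_allclose(train.std(axis=(0, 1)), 1.0, atol=1e-6)

    def test_no_leakage_from_test_day(self, corpus):
        manifest, recs = corpus
        feats = assemble_features(
            manifest, ModalityConfig(("POS",)), recordings=recs, train_day=1
        )
        # corrupt every day-2 recording; day-1 features must be untouched
        perturbed = {
            rel: (
                rec
                if day == 1
                else PoseRecording(
                    rec.positions + 100.0, rec.orientations, rec.sample_rate
                )
            )
            for (rel, rec), day in zip(recs.items(), manifest["day"])
        }
        feats2 = assemble_features(
            manifest, ModalityConfig(("POS",)), recordings=perturbed, train_day=1
        )
        d1 = feats.groups == 1
        np.testing.assert_array_equal(feats.arrays[0][d1], feats2.arrays[0][d1])

    def test_deterministic(self, corpus):
        manifest, recs = corpus
        mod = ModalityConfig(("ACC", "GYRO"), lowpass_cutoff=3.0)
        a = assemble_features(manifest, mod, recordings=recs)
        b = assemble_features(manifest, mod, recordings=recs)
        np.testing.assert_array_equal(a.arrays[0], b.arrays[0])
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_euler_channels_keep_the_wrap(self):
        # assembled EULER features must preserve the discontinuity (no unwrap)
        cfg = SyntheticConfig(n_subjects=1, seed=3, trial_noise_pos=0.0,
                              trial_noise_angle=0.0, day_drift_scale=0.0)
        rec = generate_trial(draw_subjects(1, 3)[0], 1, 0, cfg)
        manifest = manifest_from_rows(
            [{"subject_id": "S0", "day": d, "trial": 0, "device": "x", "path": f"p{d}"}
             for d in (1, 2)]
        )
        feats = assemble_features(
            manifest, ModalityConfig(("EULER",)), normalize=False,
            recordings={"p1": rec, "p2": rec},
        )
        yaw = feats.arrays[0][0, :, 0]
        assert np.abs(np.diff(yaw)).max() > np.pi
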