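"""Landmark displacement, biosignal downsampling, padding, outlier flags
and the five dataset configurations."""

import numpy as np
import pytest
from scipy import stats

from adafnn.preprocessing import (
    BioSignalRecording,
    DatasetConfiguration,
    LandmarkFrameSeries,
    assemble_configuration,
    downsample_moving_average,
    landmark_displacement_series,
    pad_trials,
    read_biosignal_file,
    read_landmark_file,
    tukey_outlier_flags,
)


class TestLandmarkDisplacement:
    def test_static_landmarks_give_zero(self):
        coords = np.tile([[2.0, 3.0]], (5, 4, 1))
        d = landmark_displacement_series(LandmarkFrameSeries(coords))
        assert d.shape == (4, 4)
        np.testing.assert_array_equal(d, 0.0)

    def test_three_four_five_triangle(self):
        coords = np.array([[[0.0, 0.0]], [[3.0, 4.0]]])
        d = landmark_displacement_series(LandmarkFrameSeries(coords))
        assert d[0, 0] == pytest.approx(5.0)

    def test_frame_order_reversal_preserves_distances(self, rng):
        coords = rng.normal(size=(10, 3, 2))
        d1 = landmark_displacement_series(LandmarkFrameSeries(coords))
        d2 = landmark_displacement_series(LandmarkFrameSeries(coords[::-1]))
        np.testing.assert_allclose(d1, d2[::-1])

    def test_rigid_translation_constant_across_landmarks(self, rng):
        base = rng.normal(size=(1, 6, 2))
        shifts = np.cumsum(rng.normal(size=(8, 1, 2)), axis=0)
        coords = base + shifts
        d = landmark_displacement_series(LandmarkFrameSeries(coords))
        # every landmark moves identically at each step
        assert np.allclose(d, d[:, :1])

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            LandmarkFrameSeries(np.zeros((1, 4, 2)))


class TestDownsampleMovingAverage:
    def test_first_window_mean_of_one_to_ten(self):
        x = np.arange(1.0, 11.0)
        assert downsample_moving_average(x, 10) == pytest.approx([5.5])

    def test_constant_signal_unchanged(self):
        x = np.full((40, 2), 3.7)
        out = downsample_moving_average(x, 10)
        np.testing.assert_allclose(out, 3.7)

    def test_windows_are_consecutive_blocks(self):
        y = np.arange(1.0, 21.0)
        out = downsample_moving_average(y, 10)
        assert out[0] == pytest.approx(np.mean(y[:10]))
        assert out[1] == pytest.approx(np.mean(y[10:20]))

    def test_leftover_samples_dropped(self):
        x = np.arange(25.0)
        assert downsample_moving_average(x, 10).shape == (2,)

    def test_mean_conservation(self, rng):
        x = rng.normal(size=47)
        out = downsample_moving_average(x, 10)
        assert out.mean() == pytest.approx(x[:40].mean())

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            downsample_moving_average(np.ones(5), 10)

    def test_repeat_upscale_round_trip(self, rng):
        vals = rng.normal(size=12)
        raw = np.repeat(vals, 10)
        np.testing.assert_allclose(downsample_moving_average(raw, 10), vals)


class TestPadTrials:
    def test_full_length_trial_unchanged(self, rng):
        tr = rng.normal(size=(20, 3))
        values, mask = pad_trials([tr], 20)
        np.testing.assert_array_equal(values[0], tr)
        assert mask.all()

    def test_reference_padding_arithmetic(self):
        # longest recording 5282 frames, standardized length 5300
        tr = np.ones((5282, 1))
        values, mask = pad_trials([tr], 5300)
        assert (~mask[0]).sum() == 18
        assert values[0, 5282:].sum() == 0.0

    def test_padded_region_is_zero_per_channel(self, rng):
        tr = rng.normal(size=(7, 4))
        values, mask = pad_trials([tr], 12)
        np.testing.assert_array_equal(values[0, 7:], 0.0)
        assert mask[0, :7].all() and not mask[0, 7:].any()

    def test_overlong_trial_rejected(self):
        with pytest.raises(ValueError):
            pad_trials([np.ones((30, 2))], 20)


class TestTukeyOutlierFlags:
    def test_constant_series_has_no_flags(self):
        assert not tukey_outlier_flags(np.full(10, 2.0)).any()

    def test_gross_outlier_flagged(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8, 1000.0])
        flags = tukey_outlier_flags(x)
        # verify against explicitly computed type-7 fences
        q1, q3 = np.quantile(x, [0.25, 0.75])
        expected = (x > q3 + 1.5 * (q3 - q1)) | (x < q1 - 1.5 * (q3 - q1))
        np.testing.assert_array_equal(flags, expected)
        assert flags[-1] and not flags[:-1].any()

    def test_normal_sample_flag_rate(self):
        # Tukey fences flag ~0.7% of a standard normal population
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10000)
        rate = tukey_outlier_flags(x).mean()
        assert 0.003 < rate < 0.012

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            tukey_outlier_flags([1.0, 2.0, 3.0])


class TestAssembleConfiguration:
    @pytest.fixture
    def modalities(self, rng):
        n, J = 6, 30
        facial = rng.normal(size=(n, J, 8))
        bio = rng.normal(size=(n, J, 2))
        labels = np.array([0, 0, 1, 1, 2, 2])
        return facial, bio, labels

    @pytest.mark.parametrize("cid,sel,expected_F", [
        ("facial_only", None, 8),
        ("bio_only", None, 2),
        ("full_fusion", None, 10),
        ("selected_facial", (1, 3, 5), 3),
        ("selected_facial_plus_bio", (0, 2), 4),
    ])
    def test_channel_counts(self, modalities, cid, sel, expected_F):
        facial, bio, labels = modalities
        ts = assemble_configuration(facial, bio,
                                    DatasetConfiguration(cid, sel), labels)
        assert ts.F == expected_F

    def test_channel_order_facial_then_bio(self, modalities):
        facial, bio, labels = modalities
        ts = assemble_configuration(
            facial, bio, DatasetConfiguration("full_fusion"), labels)
        np.testing.assert_array_equal(ts.values[:, :, :8], facial)
        np.testing.assert_array_equal(ts.values[:, :, 8:], bio)
        assert ts.channel_names[-2:] == ["ecg", "eda"]

    def test_bio_only_ignores_facial(self, modalities):
        _, bio, labels = modalities
        ts = assemble_configuration(None, bio,
                                    DatasetConfiguration("bio_only"), labels)
        np.testing.assert_array_equal(ts.values, bio)

    def test_shape_mismatch_rejected(self, modalities, rng):
        facial, bio, labels = modalities
        with pytest.raises(ValueError):
            assemble_configuration(facial[:, :20], bio,
                                   DatasetConfiguration("full_fusion"), labels)

    def test_selected_index_out_of_range(self, modalities):
        facial, bio, labels = modalities
        with pytest.raises(ValueError):
            assemble_configuration(
                facial, bio,
                DatasetConfiguration("selected_facial", (99,)), labels)

    def test_selected_config_requires_indices(self):
        with pytest.raises(ValueError):
            DatasetConfiguration("selected_facial")


class TestRawReaders:
    def test_biosignal_round_trip(self, tmp_path, rng):
        data = rng.normal(size=(60, 2))
        path = tmp_path / "bio.tsv"
        np.savetxt(path, data, delimiter="\t", header="ecg\teda", comments="")
        rec = read_biosignal_file(path)
        np.testing.assert_allclose(rec.samples, data)

    def test_landmark_long_format_round_trip(self, tmp_path, rng):
        T, L = 5, 3
        coords = rng.normal(size=(T, L, 2))
        rows = []
        for t in range(T):
            for l in range(L):
                rows.append([t, l, coords[t, l, 0], coords[t, l, 1]])
        path = tmp_path / "face.tsv"
        np.savetxt(path, rows, delimiter="\t",
                   header="frame\tlandmark_id\tx\ty", comments="")
        series = read_landmark_file(path)
        np.testing.assert_allclose(series.coords, coords)

    def test_biosignal_wrong_columns_rejected(self, tmp_path, rng):
        path = tmp_path / "bad.tsv"
        np.savetxt(path, rng.normal(size=(30, 3)), delimiter="\t")
        with pytest.raises(ValueError):
            read_biosignal_file(path)
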