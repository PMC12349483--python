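"""The synthetic trial generator: determinism, prevalence, signal shape,
and the raw-stream round trip through preprocessing."""

import numpy as np
import pytest

from adafnn.preprocessing import (
    downsample_moving_average,
    landmark_displacement_series,
    pad_trials,
    LandmarkFrameSeries,
)
from adafnn.synthetic import (
    Bump,
    SyntheticSpec,
    generate_raw_streams,
    generate_trials,
    localization_mass_fraction,
    multimodal_spec,
    write_raw_streams,
)


class TestGenerateTrials:
    def test_same_seed_identical_tensor(self):
        spec = SyntheticSpec(n_per_class=(10, 8, 6), J=50, F=3, seed=5)
        ts1, _ = generate_trials(spec)
        ts2, _ = generate_trials(spec)
        np.testing.assert_array_equal(ts1.values, ts2.values)
        np.testing.assert_array_equal(ts1.labels, ts2.labels)

    def test_prevalence_matches_spec_exactly(self):
        spec = SyntheticSpec(n_per_class=(11, 7, 5), J=30, F=2,
                             informative_channels=(0,), seed=1)
        ts, _ = generate_trials(spec)
        np.testing.assert_array_equal(ts.class_counts(), [11, 7, 5])

    def test_class_mean_converges_to_bump_sum(self):
        # law of large numbers on the class-conditional mean curve
        n = 2000
        spec = SyntheticSpec(n_per_class=(n, 1, 1), J=80, F=1,
                             informative_channels=(0,), noise_sd=0.5,
                             pad_prob=0.0, seed=2)
        ts, _ = generate_trials(spec)
        t = ts.grid.points
        bump = 1.0 * np.exp(-0.5 * ((t - 0.2) / 0.04) ** 2)
        mean_curve = ts.values[ts.labels == 0, :, 0].mean(axis=0)
        assert np.max(np.abs(mean_curve - bump)) < 3 * 0.5 / np.sqrt(n) * 4

    def test_noninformative_channels_are_pure_noise(self):
        spec = SyntheticSpec(n_per_class=(300, 300, 300), J=60, F=2,
                             informative_channels=(0,), noise_sd=0.5,
                             pad_prob=0.0, seed=3)
        ts, _ = generate_trials(spec)
        noise = ts.values[:, :, 1]
        assert abs(noise.mean()) < 0.01
        assert noise.std() == pytest.approx(0.5, abs=0.01)

    def test_zero_amplitude_removes_class_signal(self):
        bumps = {c: (Bump(0.5, 0.05, 0.0),) for c in range(3)}
        spec = SyntheticSpec(n_per_class=(40, 30, 20), J=40, F=2,
                             class_bumps=bumps, informative_channels=(0, 1),
                             pad_prob=0.0, seed=4)
        ts, _ = generate_trials(spec)
        means = [ts.values[ts.labels == c].mean() for c in range(3)]
        assert np.ptp(means) < 0.05

    def test_padding_masks_match_zeroed_tails(self):
        spec = SyntheticSpec(n_per_class=(30, 20, 15), J=50, F=2,
                             informative_channels=(0,), pad_prob=1.0,
                             pad_fraction_range=(0.05, 0.1), seed=6)
        ts, _ = generate_trials(spec)
        assert (~ts.pad_mask).any()
        assert np.all(ts.values[~ts.pad_mask] == 0.0)

    def test_ground_truth_windows_cover_bump_centers(self):
        _, truth = generate_trials(SyntheticSpec(seed=0))
        for ch in truth["informative_channels"]:
            for (lo, hi), center in zip(truth["windows"][ch], (0.2, 0.5, 0.8)):
                assert lo < center < hi


class TestLocalizationScore:
    def test_flat_basis_scores_window_length(self):
        spec = SyntheticSpec(seed=0)
        ts, truth = generate_trials(spec)
        bases = np.ones((spec.F, 2, spec.J))
        total_window = sum(hi - lo for lo, hi
                           in truth["windows"][0])
        score = localization_mass_fraction(bases, ts.grid, truth)
        assert score == pytest.approx(total_window, abs=0.02)

    def test_in_window_bump_scores_near_one(self):
        spec = SyntheticSpec(seed=0)
        ts, truth = generate_trials(spec)
        t = ts.grid.points
        bump = np.exp(-0.5 * ((t - 0.5) / 0.01) ** 2)
        bases = np.tile(bump, (spec.F, 2, 1))
        assert localization_mass_fraction(bases, ts.grid, truth) > 0.95


class TestMultimodalDesign:
    def test_fused_spec_contains_both_modalities(self):
        spec = multimodal_spec("fused")
        assert spec.F == 8
        assert set(spec.informative_channels) == {0, 1, 2, 6, 7}

    def test_single_modality_specs(self):
        assert multimodal_spec("facial").F == 6
        assert multimodal_spec("bio").F == 2
        with pytest.raises(ValueError):
            multimodal_spec("audio")

    def test_facial_merges_classes_one_and_two(self):
        spec = multimodal_spec("facial", n_per_class=(200, 200, 200))
        ts, _ = generate_trials(spec)
        m1 = ts.values[ts.labels == 1, :, 0].mean(axis=0)
        m2 = ts.values[ts.labels == 2, :, 0].mean(axis=0)
        m0 = ts.values[ts.labels == 0, :, 0].mean(axis=0)
        assert np.max(np.abs(m1 - m2)) < 0.15       # same facial signature
        assert np.max(np.abs(m0 - m1)) > 0.4        # class 0 differs


class TestRawStreams:
    @pytest.fixture
    def small_raw_spec(self):
        return SyntheticSpec(n_per_class=(4, 3, 2), J=30, F=4,
                             informative_channels=(0, 1), pad_prob=0.5,
                             pad_fraction_range=(0.05, 0.2), seed=9)

    def test_constant_coordinates_give_zero_displacement(self):
        coords = np.tile([[1.0, 2.0]], (10, 2, 1))
        d = landmark_displacement_series(LandmarkFrameSeries(coords))
        np.testing.assert_array_equal(d, 0.0)

    def test_blockwise_constant_bio_inverts_exactly(self, small_raw_spec):
        streams, target = generate_raw_streams(small_raw_spec)
        s = streams[0]
        J_obs = s["bio"].shape[0] // 10
        down = downsample_moving_average(s["bio"], 10)
        np.testing.assert_allclose(down, target.values[0, :J_obs, 2:])

    def test_full_round_trip_reproduces_target_tensor(self, small_raw_spec):
        streams, target = generate_raw_streams(small_raw_spec)
        J = small_raw_spec.J
        rebuilt = np.zeros_like(target.values)
        for i, s in enumerate(streams):
            disp = landmark_displacement_series(LandmarkFrameSeries(s["coords"]))
            bio = downsample_moving_average(s["bio"], 10)
            (facial_padded, mask) = pad_trials([disp], J)
            (bio_padded, _) = pad_trials([bio], J)
            rebuilt[i] = np.concatenate([facial_padded[0], bio_padded[0]], axis=1)
        np.testing.assert_allclose(rebuilt, target.values, atol=1e-9)

    def test_write_raw_streams_files_exist(self, small_raw_spec, tmp_path):
        streams, _ = generate_raw_streams(small_raw_spec)
        write_raw_streams(streams, tmp_path)
        assert (tmp_path / "manifest.json").exists()
        assert (tmp_path / "facial_0000.tsv").exists()
        assert (tmp_path / "bio_0008.tsv").exists()
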