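import numpy as np
import pandas as pd
import pytest

import stutterkit as sk
from stutterkit.acoustic import (
    CLASSIC_NAMES,
    FoldAwareScaler,
    SyntheticEmbedder,
    classic_frame_features,
    classic_segment_matrix,
    delta_features,
    frame_signal,
    normalize_amplitude,
    reduce_segment,
    segment_acoustic_vector,
)
from stutterkit.corpus import FeatureTable, Fold


class TestNormalizeAmplitude:
    @pytest.mark.parametrize("peak", [0.5, 2.0, 1e-3])
    def test_peak_scaled_to_one(self, peak):
        x = peak * np.sin(np.linspace(0, 20, 400))
        assert np.max(np.abs(normalize_amplitude(x))) == pytest.approx(1.0)

    def test_silence_unchanged_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            out = normalize_amplitude(np.zeros(100))
        assert not out.any()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_amplitude(np.array([]))


class TestFraming:
    def test_one_second_at_16k_gives_98_frames(self):
        frames = frame_signal(np.zeros(16000), 16000)
        assert frames.shape == (98, 400)  # floor((16000-400)/160)+1

    def test_exactly_one_window(self):
        assert frame_signal(np.zeros(400), 16000).shape == (1, 400)

    def test_short_input_zero_padded(self):
        with pytest.warns(UserWarning, match="pad"):
            frames = frame_signal(np.ones(384), 16000)
        assert frames.shape == (1, 400)
        assert frames[0, -1] == 0.0

    def test_overlap_must_be_smaller_than_window(self):
        with pytest.raises(ValueError):
            frame_signal(np.zeros(1000), 16000, win_s=0.01, overlap_s=0.02)

    def test_hop_is_window_minus_overlap(self):
        x = np.arange(16000, dtype=float)
        frames = frame_signal(x, 16000)
        assert frames[1, 0] == 160.0  # 10 ms hop at 16 kHz


class TestClassicFeatures:
    def test_32_columns_total(self):
        mat = classic_segment_matrix(np.random.default_rng(0).standard_normal(8000),
                                     16000)
        assert mat.shape[1] == 32
        assert len(CLASSIC_NAMES) == 32

    def test_constant_frame_has_zero_zcr(self):
        feats = classic_frame_features(np.full((1, 400), 0.3), 16000)
        assert feats[0, 0] == 0.0

    def test_alternating_frame_has_unit_zcr(self):
        frame = 0.5 * (-1.0) ** np.arange(400)
        feats = classic_frame_features(frame[None, :], 16000)
        assert feats[0, 0] == 1.0

    def test_white_noise_entropy_near_flat_spectrum_limit(self):
        from stutterkit.acoustic import N_ENTROPY_BANDS

        rng = np.random.default_rng(42)
        frames = rng.standard_normal((50, 400))
        feats = classic_frame_features(frames, 16000)
        assert feats[:, 1].mean() == pytest.approx(np.log2(N_ENTROPY_BANDS),
                                                   rel=0.02)

    def test_pure_tone_entropy_well_below_noise_entropy(self):
        t = np.arange(400) / 16000
        tone = np.sin(2 * np.pi * 1000 * t)[None, :]
        noise = np.random.default_rng(0).standard_normal((1, 400))
        assert classic_frame_features(tone, 16000)[0, 1] \
            < 0.5 * classic_frame_features(noise, 16000)[0, 1]

    def test_deterministic(self):
        x = np.random.default_rng(3).standard_normal(4000)
        a = classic_segment_matrix(x, 16000)
        b = classic_segment_matrix(x.copy(), 16000)
        np.testing.assert_array_equal(a, b)


class TestDeltas:
    def test_constant_trajectory_zero_delta(self):
        assert not delta_features(np.full((20, 16), 3.0)).any()

    def test_linear_ramp_interior_deltas_equal_slope(self):
        slope = 0.7
        mat = slope * np.arange(30)[:, None] * np.ones((1, 4))
        deltas = delta_features(mat)
        np.testing.assert_allclose(deltas[2:-2], slope, atol=1e-12)

    def test_single_frame_gives_zeros(self):
        out = delta_features(np.ones((1, 16)))
        assert out.shape == (1, 16) and not out.any()


class TestReduceSegment:
    def test_single_varying_column_recovers_basis_vector(self):
        mat = np.zeros((40, 5))
        mat[:, 2] = np.sin(np.linspace(0, 7, 40))
        loading = reduce_segment(mat)
        np.testing.assert_allclose(np.abs(loading), [0, 0, 1, 0, 0], atol=1e-12)
        assert loading[2] > 0  # sign fixed positive at the dominant element

    def test_unit_norm_for_multiframe(self):
        mat = np.random.default_rng(1).standard_normal((30, 8))
        assert np.linalg.norm(reduce_segment(mat)) == pytest.approx(1.0)

    def test_matches_covariance_eigendecomposition(self):
        mat = np.random.default_rng(7).standard_normal((50, 5))
        centred = mat - mat.mean(0)
        w, v = np.linalg.eigh(centred.T @ centred / len(mat))
        top = v[:, np.argmax(w)]
        top *= np.sign(top[np.argmax(np.abs(top))])
        np.testing.assert_allclose(reduce_segment(mat), top, atol=1e-8)

    def test_single_frame_returns_raw_values(self):
        row = np.array([[1.5, -2.0, 0.3]])
        np.testing.assert_array_equal(reduce_segment(row), row[0])


class TestAcousticVector:
    def test_1056_columns_with_default_embedder(self):
        x = np.random.default_rng(0).standard_normal(8000)
        vec, names = segment_acoustic_vector(x, 16000, SyntheticEmbedder())
        assert vec.shape == (1056,)
        assert len(names) == 1056
        assert names[:3] == ["ac_zcr", "ac_spectral_entropy", "ac_log_energy"]

    def test_embedder_deterministic_and_fixed_width(self):
        emb = SyntheticEmbedder(seed=9)
        x = np.random.default_rng(2).standard_normal(6400)
        a, b = emb.transform(x, 16000), emb.transform(x.copy(), 16000)
        np.testing.assert_array_equal(a, b)
        assert a.shape[1] == emb.output_dimension == 1024


def make_table(values, folds):
    idx = pd.Index([f"s{i}" for i in range(len(values))], name="segment_id")
    return FeatureTable(
        pd.DataFrame(values, index=idx, columns=["a", "b"]),
        pd.Series(folds, index=idx),
    )


class TestFoldAwareScaler:
    def test_fit_fold_values_standardised(self):
        table = make_table([[1, 5], [2, 5], [3, 5], [10, 0]],
                           ["TRAIN", "TRAIN", "VALIDATION", "TEST"])
        scaled = FoldAwareScaler().fit(table).transform(table)
        fit_part = scaled.values.iloc[:3]["a"]
        assert fit_part.mean() == pytest.approx(0.0)
        assert fit_part.std(ddof=0) == pytest.approx(1.0)

    def test_constant_column_centred_and_flagged(self):
        table = make_table([[1, 5], [2, 5], [3, 5], [4, 7]],
                           ["TRAIN", "TRAIN", "VALIDATION", "TEST"])
        scaler = FoldAwareScaler().fit(table)
        assert scaler.constant_columns_ == ["b"]
        scaled = scaler.transform(table)
        assert scaled.values["b"].iloc[0] == pytest.approx(0.0)
        assert scaled.values["b"].iloc[3] == pytest.approx(2.0)

    def test_test_rows_use_fit_parameters_only(self):
        table = make_table([[1, 1], [3, 2], [2, 3], [7, 4]],
                           ["TRAIN", "TRAIN", "VALIDATION", "TEST"])
        scaler = FoldAwareScaler().fit(table)
        scaled = scaler.transform(table)
        mu, sd = scaler.mean_["a"], scaler.scale_["a"]
        assert scaled.values["a"].iloc[3] == pytest.approx((7 - mu) / sd)

    def test_refuses_to_fit_on_test(self):
        table = make_table([[1, 1], [2, 2]], ["TEST", "TEST"])
        with pytest.raises(ValueError, match="TEST"):
            FoldAwareScaler(fit_folds=(Fold.TEST,)).fit(table)
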