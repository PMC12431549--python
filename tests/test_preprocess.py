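"""Preprocessing stages: resampling, baseline removal, denoising,
z-scoring, segmentation, labeling, encoding."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings, strategies as st

from ecglite.containers import BeatAnnotation, EcgRecord
from ecglite.preprocess import (
    REJECT,
    PreprocessConfig,
    denoise_window,
    encode_labels,
    label_window_mitbih,
    remove_baseline,
    resample_to_target,
    run_preprocessing,
    segment_record,
    zscore,
)
from ecglite.synthetic import NORMAL_BEAT, SynthConfig, synth_beat, synth_record

CFG = PreprocessConfig()


def _tone(freq, fs=128.0, seconds=60.0):
    t = np.arange(int(fs * seconds)) / fs
    return np.sin(2 * np.pi * freq * t), t


class TestResample:
    def test_already_at_target_is_identity(self):
        rec = EcgRecord("p", 128.0, np.arange(1000, dtype=float))
        assert resample_to_target(rec, 128.0) is rec

    def test_360hz_record_length_and_annotation_scaling(self):
        ann = [BeatAnnotation(360, "N")]
        rec = EcgRecord("p", 360.0, np.random.default_rng(0).normal(size=3600), ann)
        out = resample_to_target(rec, 128.0)
        assert len(out.signal) == 1280  # 3600 * 128 / 360
        assert out.annotations[0].index == 128
        assert out.fs == 128.0

    def test_tone_is_preserved_through_resampling(self):
        x, _ = _tone(5.0, fs=360.0, seconds=10.0)
        rec = EcgRecord("p", 360.0, x)
        out = resample_to_target(rec, 128.0)
        # interior amplitude preserved (edges show filter transients)
        mid = out.signal[200:-200]
        assert abs(mid.max() - 1.0) < 0.02


class TestRemoveBaseline:
    def test_dc_is_rejected(self):
        y = remove_baseline(np.full(4000, 5.0), 128.0, CFG)
        assert np.max(np.abs(y)) < 1e-6
        assert len(y) == 4000

    def test_sub_cutoff_tone_strongly_attenuated(self):
        x, _ = _tone(0.05)  # cutoff/10
        y = remove_baseline(x, 128.0, CFG)
        steady = y[len(y) // 4: -len(y) // 4]
        assert np.max(np.abs(steady)) < 1e-3

    def test_passband_tone_passes_within_one_percent(self):
        x, _ = _tone(5.0)
        y = remove_baseline(x, 128.0, CFG)
        steady = y[len(y) // 4: -len(y) // 4]
        assert abs(np.max(np.abs(steady)) - 1.0) < 0.01

    def test_attenuation_exceeds_60db_at_cutoff_over_ten(self):
        x, _ = _tone(0.05, seconds=120.0)
        y = remove_baseline(x, 128.0, CFG)
        steady = y[len(y) // 3: -len(y) // 3]
        ratio = np.max(np.abs(steady))
        assert 20 * np.log10(1.0 / ratio) > 60.0

    def test_single_pass_mode_and_short_signal_error(self):
        x, _ = _tone(5.0)
        y = remove_baseline(x, 128.0, PreprocessConfig(zero_phase=False))
        assert len(y) == len(x)
        with pytest.raises(ValueError, match="too short"):
            remove_baseline(np.zeros(10), 128.0, CFG)


class TestDenoise:
    @pytest.mark.parametrize("n", [512, 700, 1000, 1024])
    def test_threshold_zero_is_perfect_reconstruction(self, n, rng):
        w = rng.normal(size=n)
        out = denoise_window(w, PreprocessConfig(threshold_factor=0.0))
        np.testing.assert_allclose(out, w, atol=1e-8)

    def test_surviving_detail_coefficients_respect_threshold(self, rng):
        """Dual route: re-apply the stated rule with pywt directly and compare."""
        w = rng.normal(size=1000)
        wavelet = pywt.Wavelet("sym4")
        level = pywt.dwt_max_level(1000, wavelet)
        assert level == 7  # floor(log2(1000 / (8 - 1)))
        coeffs = pywt.wavedec(w, wavelet, level=level)
        expected = [coeffs[0]]
        for d in coeffs[1:]:
            tau = 0.04 * np.max(np.abs(d))
            kept = np.where(np.abs(d) >= tau, d, 0.0)
            assert np.all((kept == 0) | (np.abs(kept) >= tau))
            expected.append(kept)
        oracle = pywt.waverec(expected, wavelet)[:1000]
        np.testing.assert_allclose(denoise_window(w, CFG), oracle, atol=1e-10)

    def test_denoising_reduces_rmse_to_clean_beat(self, rng):
        clean = np.tile(synth_beat(NORMAL_BEAT, rr_s=0.85, fs=128.0), 10)[:1000]
        noisy = clean + rng.normal(0.0, 0.05, size=clean.shape)
        den = denoise_window(noisy, CFG)
        rmse_before = np.sqrt(np.mean((noisy - clean) ** 2))
        rmse_after = np.sqrt(np.mean((den - clean) ** 2))
        assert rmse_after < rmse_before

    def test_window_shorter_than_support_rejected(self):
        with pytest.raises(ValueError, match="support"):
            denoise_window(np.zeros(4), CFG)


class TestZscore:
    def test_hand_computed_three_point_example(self):
        out = zscore(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out, [-1.22474487, 0.0, 1.22474487], atol=1e-8)
        assert abs(out.mean()) < 1e-9
        assert abs(out.std() - 1.0) < 1e-9

    def test_constant_window_maps_to_zeros(self):
        np.testing.assert_array_equal(zscore(np.full(100, 3.3)), np.zeros(100))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_idempotent_and_standardized(self, seed):
        w = np.random.default_rng(seed).normal(2.0, 5.0, size=200)
        z = zscore(w)
        assert abs(z.mean()) < 1e-9 and abs(z.std() - 1.0) < 1e-9
        np.testing.assert_allclose(zscore(z), z, atol=1e-9)


class TestSegmentation:
    def _rec(self, n, annotations=()):
        return EcgRecord("p", 128.0, np.arange(n, dtype=float), list(annotations))

    def test_counts_and_starts(self):
        assert [s for s, _ in segment_record(self._rec(2500), CFG)] == [0, 1000]
        assert segment_record(self._rec(999), CFG) == []

    def test_noise_marked_window_excluded(self):
        rec = self._rec(3000, [BeatAnnotation(1500, "NOISE")])
        assert [s for s, _ in segment_record(rec, CFG)] == [0, 2000]

    def test_window_count_is_floor_of_usable_length(self):
        rec = self._rec(5432)
        assert len(segment_record(rec, CFG)) == 5

    def test_majority_label_and_tiebreaks(self):
        anns = [BeatAnnotation(i, s) for i, s in [(10, "N"), (20, "N"), (30, "V")]]
        assert label_window_mitbih((0, 1000), anns) == "N"
        anns = [BeatAnnotation(10, "N"), BeatAnnotation(20, "V")]
        assert label_window_mitbih((0, 1000), anns) == "V"
        anns = [BeatAnnotation(10, "L"), BeatAnnotation(20, "V")]
        assert label_window_mitbih((0, 1000), anns) == "L"

    def test_reject_on_other_or_empty(self):
        anns = [BeatAnnotation(10, "N"), BeatAnnotation(20, "OTHER")]
        assert label_window_mitbih((0, 1000), anns) == REJECT
        assert label_window_mitbih((0, 1000), []) == REJECT
        # beats outside the span do not count
        assert label_window_mitbih((0, 5), [BeatAnnotation(10, "N")]) == REJECT


class TestEncodeLabels:
    def test_multiclass_vectors_length_five(self):
        onehot, order = encode_labels(["N", "V"], "multiclass")
        assert order == ("N", "L", "R", "A", "V")
        np.testing.assert_array_equal(onehot[0], [1, 0, 0, 0, 0])
        np.testing.assert_array_equal(onehot[1], [0, 0, 0, 0, 1])

    def test_binary_grouping_of_segment_codes(self):
        onehot, order = encode_labels([0.0, 1.0, 2.0, 3.0], "binary")
        assert order == ("Normal", "Arrhythmia")
        np.testing.assert_array_equal(onehot[0], [1, 0])
        for row in onehot[1:]:
            np.testing.assert_array_equal(row, [0, 1])

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            encode_labels(["X"], "multiclass")
        with pytest.raises(ValueError, match="unknown"):
            encode_labels([7.0], "binary")


class TestRunPreprocessing:
    def test_windows_are_standardized_and_onehot(self, small_binary_ws):
        ws = small_binary_ws
        assert ws.windows.shape[1] == 1000
        assert np.all(np.abs(ws.windows.mean(axis=1)) < 1e-6)
        assert np.all(np.abs(ws.windows.std(axis=1) - 1.0) < 1e-6)
        assert np.all(ws.labels_onehot.sum(axis=1) == 1)

    def test_all_noise_record_contributes_no_windows(self):
        cfg = SynthConfig(duration_s=30.0, n_noise_markers=200)
        noisy = synth_record("NSR", cfg, seed=2, patient_id="noisy")
        clean = synth_record("NSR", SynthConfig(duration_s=30.0), seed=3,
                             patient_id="clean")
        ws = run_preprocessing([noisy, clean], CFG, mode="multiclass")
        assert set(ws.patient_ids) == {"clean"}

    def test_30min_clean_record_yields_230_windows(self):
        rec = synth_record("NSR", SynthConfig(duration_s=1800.0), seed=4)
        ws = run_preprocessing([rec], CFG, mode="multiclass")
        assert len(ws) == 230

    def test_window_duration_prints_781_seconds(self):
        assert round(CFG.window_duration_s, 2) == 7.81
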