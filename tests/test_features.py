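"""Cepstral extractors against hand-built oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import snorescreen as ss
from snorescreen.errors import DegenerateFrameError, ParameterError
from snorescreen.features import _dct_matrix, log_mel_energies

from conftest import (
    SR,
    oracle_lpc,
    oracle_lpcc,
    oracle_mel_filterbank,
    oracle_mfcc,
    random_stable_lpc_model,
)


class TestMelScale:
    def test_thousand_hz_is_thousand_mel(self):
        assert ss.hz_to_mel(1000.0) == pytest.approx(1000.0, rel=1e-3)

    def test_zero_maps_to_zero(self):
        assert ss.hz_to_mel(0.0) == 0.0

    def test_inverse(self):
        f = np.linspace(0, 8000, 33)
        np.testing.assert_allclose(ss.mel_to_hz(ss.hz_to_mel(f)), f, atol=1e-8)


@pytest.fixture(scope="module")
def fb():
    return ss.build_mel_filterbank(ss.FeatureConfig(), SR, 512)


class TestMelFilterbank:
    def test_shape_and_nonnegativity(self, fb):
        assert fb.weights.shape == (40, 257)
        assert np.all(fb.weights >= 0)
        assert np.all(fb.weights <= 1.0 + 1e-12)

    def test_triangles_have_single_peak(self, fb):
        for row in fb.weights:
            support = np.flatnonzero(row)
            peak = np.argmax(row)
            # rises up to the peak, falls after it
            assert np.all(np.diff(row[support[0]: peak + 1]) >= -1e-12)
            assert np.all(np.diff(row[peak: support[-1] + 1]) <= 1e-12)

    def test_centers_strictly_increasing(self, fb):
        assert np.all(np.diff(fb.centers_hz) > 0)

    def test_matches_pointwise_construction(self, fb):
        np.testing.assert_allclose(fb.weights, oracle_mel_filterbank(), atol=1e-10)

    def test_bad_band_edges_rejected(self):
        with pytest.raises(ParameterError):
            ss.build_mel_filterbank(
                ss.FeatureConfig(f_min=5000.0, f_max=1000.0), SR, 512
            )


class TestLogMelEnergies:
    def test_zero_spectrum_floors(self):
        fb = ss.build_mel_filterbank(ss.FeatureConfig(), SR, 512)
        out = log_mel_energies(np.zeros((3, 257)), fb, 1e-10)
        np.testing.assert_allclose(out, np.log(1e-10))

    def test_doubling_adds_ln2(self, rng):
        fb = ss.build_mel_filterbank(ss.FeatureConfig(), SR, 512)
        spec = rng.uniform(0.5, 1.0, (2, 257))
        base = log_mel_energies(spec, fb)
        np.testing.assert_allclose(log_mel_energies(2 * spec, fb) - base,
                                   np.log(2), atol=1e-10)

    def test_single_filter_spectrum(self):
        fb = ss.build_mel_filterbank(ss.FeatureConfig(), SR, 512)
        spec = fb.weights[10][None, :]
        e = np.exp(log_mel_energies(spec, fb))[0]
        assert e[10] == pytest.approx(np.sum(fb.weights[10] ** 2))
        assert np.argmax(e) == 10


class TestMFCC:
    def test_three_second_clip_shape(self, three_second_clip):
        assert ss.mfcc(three_second_clip.audio).shape == (298, 40)

    def test_silence_has_no_cepstral_content(self):
        sig = ss.AudioSignal(np.zeros(48000), SR)
        mat = ss.mfcc(sig).values
        np.testing.assert_allclose(mat - mat[0], 0.0, atol=1e-9)  # frames identical
        np.testing.assert_allclose(mat, 0.0, atol=1e-9)           # DCT of a constant

    def test_gain_invariance_of_nonzero_coefficients(self, short_two_tone):
        base = ss.mfcc(short_two_tone).values
        louder = ss.AudioSignal(short_two_tone.samples * 3.0, SR)
        np.testing.assert_allclose(ss.mfcc(louder).values, base, atol=1e-6)

    def test_matches_independent_reference_chain(self, short_two_tone):
        ref = oracle_mfcc(short_two_tone.samples)
        got = ss.mfcc(short_two_tone).values
        assert got.shape == ref.shape
        np.testing.assert_allclose(got, ref, atol=1e-4)


class TestLPC:
    def test_recovers_ar1_coefficient(self, rng):
        x = np.zeros(48000)
        e = rng.standard_normal(48000)
        for n in range(1, 48000):
            x[n] = 0.9 * x[n - 1] + e[n]
        model = ss.lpc(x, 1)
        assert model.coeffs[0] == pytest.approx(0.9, abs=0.02)

    def test_white_noise_is_unpredictable(self, rng):
        model = ss.lpc(rng.standard_normal(48000), 12)
        assert np.all(np.abs(model.coeffs) < 0.1)

    def test_order_one_closed_form(self, rng):
        frame = rng.standard_normal(480)
        r0 = frame @ frame
        r1 = frame[:-1] @ frame[1:]
        assert ss.lpc(frame, 1).coeffs[0] == pytest.approx(r1 / r0, rel=1e-12)

    def test_matches_toeplitz_solve(self, rng):
        frame = rng.standard_normal(480)
        model = ss.lpc(frame, 8)
        np.testing.assert_allclose(model.coeffs, oracle_lpc(frame, 8), atol=1e-8)

    def test_all_zero_frame_rejected(self):
        with pytest.raises(DegenerateFrameError):
            ss.lpc(np.zeros(480), 4)

    def test_order_at_least_frame_length_rejected(self):
        with pytest.raises(ParameterError):
            ss.lpc(np.ones(10), 10)

    def test_minimum_phase_on_random_frames(self, rng):
        # autocorrelation method must always give a stable all-pole filter
        for _ in range(200):
            frame = rng.standard_normal(120) * rng.uniform(1e-4, 10)
            poles = ss.lpc(frame, 12).poles()
            assert np.all(np.abs(poles) < 1.0)

    def test_prediction_error_nonincreasing_in_order(self, rng):
        frame = np.sin(np.arange(480) * 0.11) + 0.1 * rng.standard_normal(480)
        errs = [ss.lpc(frame, p).prediction_error for p in (1, 2, 4, 8, 12)]
        assert np.all(np.diff(errs) <= 1e-9)


class TestLPCC:
    def test_order_one_hand_values(self):
        model = ss.LPCModel(coeffs=np.array([0.8]), order=1, gain=1.0,
                            prediction_error=1.0)
        c = ss.lpcc(model, 3)
        assert c[0] == pytest.approx(0.8)
        assert c[1] == pytest.approx(0.8**2 / 2)
        # c(3) = (1 - 1/3) a1 c(2) by the n > p branch
        assert c[2] == pytest.approx((2 / 3) * 0.8 * c[1])

    def test_zero_model_gives_zero_cepstrum(self):
        model = ss.LPCModel(coeffs=np.zeros(5), order=5, gain=1.0,
                            prediction_error=1.0)
        assert not np.any(ss.lpcc(model, 12))

    @given(order=st.integers(1, 5), n_coeffs=st.integers(1, 20),
           seed=st.integers(0, 10_000))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_plain_python_recursion(self, order, n_coeffs, seed):
        model = random_stable_lpc_model(np.random.default_rng(seed), order)
        np.testing.assert_allclose(
            ss.lpcc(model, n_coeffs), oracle_lpcc(model.coeffs, n_coeffs),
            atol=1e-12,
        )


class TestFeatureMatrices:
    def test_lpcc_features_shape(self, three_second_clip):
        assert ss.lpcc_features(three_second_clip.audio).shape == (298, 40)

    def test_lpcc_features_silence_all_zero(self):
        sig = ss.AudioSignal(np.zeros(48000), SR)
        assert not np.any(ss.lpcc_features(sig).values)

    def test_lpcc_features_match_frame_by_frame_composition(self, short_two_tone):
        from snorescreen.signal import preprocess

        got = ss.lpcc_features(short_two_tone).values
        frames = preprocess(short_two_tone)
        for i in (0, 10, 40):
            expected = ss.lpcc(ss.lpc(frames.frames[i], 12), 40)
            np.testing.assert_allclose(got[i], expected, atol=1e-12)

    def test_lpmfcc_shape(self, three_second_clip):
        assert ss.lpmfcc(three_second_clip.audio).shape == (298, 40)

    def test_lpmfcc_silence_near_zero(self):
        sig = ss.AudioSignal(np.zeros(48000), SR)
        np.testing.assert_allclose(ss.lpmfcc(sig).values, 0.0, atol=1e-9)

    def test_lpmfcc_matches_explicit_chain(self, short_two_tone):
        from snorescreen.signal import preprocess

        config = ss.FeatureConfig()
        got = ss.lpmfcc(short_two_tone).values
        frames = preprocess(short_two_tone)
        H = oracle_mel_filterbank()
        m = np.arange(40)
        for i in (0, 17, 33):
            a = ss.lpc(frames.frames[i], 12).coeffs
            spec = np.abs(np.fft.rfft(a, 512)) ** 2
            z = np.log(np.maximum(spec @ H.T, config.log_floor))
            expected = [np.sum(z * np.cos(np.pi * n * (m + 0.5) / 40))
                        for n in range(1, 41)]
            np.testing.assert_allclose(got[i], expected, atol=1e-10)

    def test_all_extractors_finite_on_noise(self, rng):
        sig = ss.AudioSignal(rng.standard_normal(16000) * 1e-6, SR)
        for kind in ("mfcc", "lpcc", "lpmfcc"):
            assert np.all(np.isfinite(ss.extract(sig, kind).values))

    def test_extract_unknown_kind(self, three_second_clip):
        with pytest.raises(ParameterError):
            ss.extract(three_second_clip.audio, "plp")


class TestDCTMatrix:
    def test_rows_are_orthogonal_cosines(self):
        D = _dct_matrix(40, 40)
        # row n=1..39 each sums (almost) to zero over the filter index
        np.testing.assert_allclose(D.sum(axis=1)[:39], 0.0, atol=1e-10)


class TestArchive:
    def test_roundtrip(self, tmp_path, rng):
        mats = [
            ss.FeatureMatrix(rng.standard_normal((10, 4)), "mfcc", ss.FrameParams())
            for _ in range(3)
        ]
        ss.save_feature_archive(tmp_path / "f.npz", mats, [0, 1, 1])
        back, labels = ss.load_feature_archive(tmp_path / "f.npz")
        assert len(back) == 3
        assert back[0].feature_kind == "mfcc"
        np.testing.assert_array_equal(labels, [0, 1, 1])
        for a, b in zip(mats, back):
            np.testing.assert_array_equal(a.values, b.values)
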