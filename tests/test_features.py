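"""Multiscale feature extraction: counts, naming, oracles and guards."""

import numpy as np
import pytest
from scipy.fft import dct

from arslab.exceptions import ValidationError
from arslab.features import (
    DEFAULT_WINDOWS_MS,
    FEATURE_BASE_NAMES,
    MELODIC_NAMES,
    MFCC_NAMES,
    SPECTRAL_NAMES,
    _moving_average,
    extract_feature_vector,
    extract_frame_block,
    extract_melodic_features,
    extract_mfcc_features,
    extract_spectral_features,
    feature_names,
    pitch_curve,
    summarize_statistics,
)
from arslab.synth import synth_wheeze
from arslab.tf import STFTConfig, TFImage, mel_filterbank, stft_spectrogram


def _image(values, freqs=None, rate=4000.0):
    values = np.asarray(values, dtype=float)
    if freqs is None:
        freqs = np.linspace(0, rate / 2, values.shape[0])
    return TFImage(values, np.asarray(freqs, float), np.arange(values.shape[1], dtype=float), "linear", rate)


class TestCounts:
    def test_channel_count_laws(self):
        assert len(SPECTRAL_NAMES) == 25
        assert len(MFCC_NAMES) == 26
        assert len(MELODIC_NAMES) == 30
        assert len(FEATURE_BASE_NAMES) == 81

    def test_vector_length_2430(self):
        wave = synth_wheeze(2.0, 300.0, 4000.0, seed=0)
        vec = extract_feature_vector(wave)
        assert vec.shape == (2430,)
        assert np.all(np.isfinite(vec))

    def test_single_window_gives_405(self):
        wave = synth_wheeze(2.0, 300.0, 4000.0, seed=0)
        vec = extract_feature_vector(wave, windows_ms=(32,))
        assert vec.shape == (405,)

    def test_name_scheme(self):
        names = feature_names()
        assert len(names) == 2430
        assert len(set(names)) == 2430
        assert names.count("std_melinharm250ms_32") == 1
        assert "median_melvoicing_16" in names
        assert "min_specbright4ratio_32" in names
        assert "std_melinharmHF1s_16" in names


class TestSpectral:
    def test_point_mass_spectrum(self):
        """Single occupied bin at 500 Hz: centroid 500, spread 0, flatness ~ 0."""
        freqs = np.fft.rfftfreq(512, d=1 / 4000)
        S = np.zeros((freqs.size, 3))
        S[np.argmin(np.abs(freqs - 500.0))] = 1.0
        feats = extract_spectral_features(_image(S, freqs))
        centroid, spread = feats[0], feats[1]
        flatness = feats[SPECTRAL_NAMES.index("specflatness")]
        assert np.allclose(centroid, freqs[np.argmin(np.abs(freqs - 500.0))])
        assert np.allclose(spread, 0.0)
        assert np.all(flatness < 1e-6)

    def test_flat_spectrum_flatness_and_entropy_maximal(self):
        S = np.ones((257, 4))
        feats = extract_spectral_features(_image(S))
        assert np.allclose(feats[SPECTRAL_NAMES.index("specflatness")], 1.0)
        assert np.allclose(feats[SPECTRAL_NAMES.index("specentropy")], 1.0)

    def test_flux_median_suppresses_spike(self):
        """Small-sequence oracle: a single spiked frame inflates raw flux but
        the median-filtered flux stays at the background level."""
        rng = np.random.default_rng(0)
        base = np.abs(rng.uniform(0.9, 1.1, size=(50, 9)))
        S = base.copy()
        S[:, 4] += 30.0
        feats = extract_spectral_features(_image(S))
        flux = feats[SPECTRAL_NAMES.index("specflux")]
        flux_med = feats[SPECTRAL_NAMES.index("specfluxmedian")]
        assert flux.max() > 10 * flux_med.max()

    def test_silence_yields_finite_zeros(self):
        feats = extract_spectral_features(_image(np.zeros((257, 5))))
        assert np.all(np.isfinite(feats))
        assert np.all(feats == 0)

    def test_scale_invariant_channels(self):
        rng = np.random.default_rng(1)
        S = np.abs(rng.standard_normal((257, 11))) + 0.01
        a = extract_spectral_features(_image(S))
        b = extract_spectral_features(_image(S * 37.5))
        for name in (
            "speccentroid",
            "specspread",
            "specflatness",
            "specbright4ratio",
            "specrolloff95",
            "specrolloffOutRatio",
        ):
            i = SPECTRAL_NAMES.index(name)
            assert np.allclose(a[i], b[i]), name

    def test_brightness_ratio_bounded(self):
        rng = np.random.default_rng(2)
        S = np.abs(rng.standard_normal((257, 20)))
        feats = extract_spectral_features(_image(S))
        b4 = feats[SPECTRAL_NAMES.index("specbright4ratio")]
        assert np.all((0 <= b4) & (b4 <= 1))

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            extract_spectral_features(_image(np.empty((0, 0))))


class TestMFCC:
    def test_row_count(self):
        wave = np.random.default_rng(3).standard_normal(8000)
        spec = stft_spectrogram(wave, STFTConfig(window_kind="hamming"), 4000)
        assert extract_mfcc_features(spec).shape[0] == 26

    def test_constant_spectrogram_zero_deltas(self):
        S = np.tile(np.abs(np.random.default_rng(4).standard_normal(257))[:, None], (1, 10))
        out = extract_mfcc_features(_image(S))
        assert np.allclose(out[13:], 0.0)

    def test_matches_dense_matrix_oracle(self):
        """Independent oracle: explicit log -> DCT-II matrix multiplication."""
        wave = synth_wheeze(2.0, 350.0, 4000.0, seed=5)
        spec = stft_spectrogram(wave, STFTConfig(window_kind="hamming"), 4000)
        ours = extract_mfcc_features(spec)[:13]
        fb = mel_filterbank(64, spec.freqs)
        logE = np.log(fb @ spec.values + 1e-10)
        n = 64
        k = np.arange(n)
        D = np.cos(np.pi * np.outer(np.arange(n), (2 * k + 1)) / (2 * n))
        D *= np.sqrt(2.0 / n)
        D[0] /= np.sqrt(2.0)
        oracle = (D @ logE)[1:14]
        assert np.allclose(ours, oracle, atol=1e-8)


class TestMelodic:
    def test_row_count(self):
        wave = synth_wheeze(2.0, 300.0, 4000.0, seed=6)
        out = extract_melodic_features(wave, STFTConfig(window_kind="hamming"), 4000)
        assert out.shape[0] == 30

    def test_pitch_recovery_within_two_percent(self):
        for f0 in (150.0, 440.0, 880.0):
            wave = synth_wheeze(1.0, f0, 4000.0, seed=7)
            pitch, voicing, _ = pitch_curve(wave, STFTConfig(window_kind="hamming", window_ms=64))
            voiced = pitch[pitch > 0]
            assert voiced.size > 0
            assert abs(np.median(voiced) - f0) / f0 < 0.02

    def test_silence_unvoiced(self):
        pitch, voicing, inharm = pitch_curve(np.zeros(8000), STFTConfig(window_kind="hamming"))
        assert np.all(pitch == 0)
        assert np.all(voicing < 0.05)
        assert np.all(inharm == 0)

    def test_inharmonic_pair_scores_higher_than_pure_tone(self):
        t = np.arange(8000) / 4000
        harmonic = synth_wheeze(2.0, 440.0, 4000.0, seed=8)
        pair = np.sin(2 * np.pi * 440 * t) + np.sin(2 * np.pi * 527 * t)
        cfg = STFTConfig(window_kind="hamming", window_ms=64)
        _, _, ih_h = pitch_curve(harmonic, cfg)
        p, _, ih_p = pitch_curve(pair, cfg)
        assert np.median(ih_p[p > 0]) > np.median(ih_h[ih_h >= 0])

    def test_constant_curve_smoothing_identity(self):
        x = np.full(100, 3.3)
        assert np.allclose(_moving_average(x, 7), x)

    def test_impulse_smoothing_plateau(self):
        """Convolution arithmetic oracle: w-frame average of a unit impulse
        has an interior plateau of height 1/w."""
        x = np.zeros(101)
        x[50] = 1.0
        out = _moving_average(x, 9)
        assert np.isclose(out[50], 1 / 9)
        assert np.isclose(out.sum(), 1.0)

    def test_window_too_short_for_ceiling_rejected(self):
        with pytest.raises(ValidationError):
            pitch_curve(np.zeros(4000), STFTConfig(window_kind="hamming", window_ms=32), f_max=10.0)


class TestSummary:
    def test_constant_channel(self):
        block = np.full((1, 6), 4.2)
        out = summarize_statistics(block)
        assert np.allclose(out, [4.2, 0.0, 4.2, 4.2, 4.2])

    def test_forced_arithmetic(self):
        out = summarize_statistics(np.array([[1.0, 2.0, 3.0, 4.0]]))
        mean, std, median, lo, hi = out
        assert (mean, median, lo, hi) == (2.5, 2.5, 1.0, 4.0)
        assert np.isclose(std, np.std([1, 2, 3, 4], ddof=1))

    def test_frame_permutation_invariance(self):
        rng = np.random.default_rng(9)
        block = rng.standard_normal((81, 17))
        perm = block[:, rng.permutation(17)]
        assert np.allclose(summarize_statistics(block), summarize_statistics(perm))

    def test_empty_block_rejected(self):
        with pytest.raises(ValidationError):
            summarize_statistics(np.empty((81, 0)))


class TestRobustness:
    @pytest.mark.parametrize(
        "wave",
        [
            np.zeros(8000),  # silence
            np.eye(1, 8000, 4000).ravel(),  # single impulse
            np.sign(np.sin(2 * np.pi * 100 * np.arange(8000) / 4000)),  # clipped
        ],
        ids=["silence", "impulse", "clipped"],
    )
    def test_no_nan_inf_on_degenerate_excerpts(self, wave):
        vec = extract_feature_vector(wave, windows_ms=(16, 128))
        assert np.all(np.isfinite(vec))

    def test_deterministic(self):
        wave = synth_wheeze(2.0, 500.0, 4000.0, seed=10)
        assert np.array_equal(
            extract_feature_vector(wave, windows_ms=(32,)),
            extract_feature_vector(wave, windows_ms=(32,)),
        )

    def test_feature_frame_header(self):
        from arslab.features import features_to_frame

        wave = synth_wheeze(2.0, 500.0, 4000.0, seed=10)
        vec = extract_feature_vector(wave, windows_ms=(32,))
        frame = features_to_frame([vec], windows_ms=(32,))
        assert list(frame.columns) == feature_names((32,))
        assert frame.shape == (1, 405)
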