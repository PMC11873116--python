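"""Spectral features: framing, Levinson-Durbin, LAR, LPCC, MFCC, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.fft import dct as scipy_dct
from scipy.linalg import solve_toeplitz
from scipy.signal import lfilter

from vowelpd.acoustic import assemble_phonation_features
from vowelpd.errors import DegenerateInputError, TooShortError
from vowelpd.preprocess import Waveform
from vowelpd.spectral import (
    SpectralCoefficients,
    coefficient_track,
    combine_features,
    frame_signal,
    lar_to_parcor,
    levinson_durbin,
    lpc_to_cepstrum,
    mfcc_frame,
    parcor_to_lar,
    summarize_coefficients,
)
from vowelpd.synth import VowelSpec, synthesize_vowel


def _stable_ar(rng, p=10, max_radius=0.92):
    """Random stable AR(p) polynomial from bounded-radius pole pairs."""
    poly = np.array([1.0])
    n_pairs = p // 2
    for _ in range(n_pairs):
        r = rng.uniform(0.3, max_radius)
        theta = rng.uniform(0.1, np.pi - 0.1)
        pair = np.array([1.0, -2 * r * np.cos(theta), r * r])
        poly = np.convolve(poly, pair)
    if p % 2:
        poly = np.convolve(poly, np.array([1.0, -rng.uniform(-0.8, 0.8)]))
    return -poly[1:]  # A(z) = 1 - sum a_k z^-k


def _ar_autocorrelation(a, n_lags, rng, n=30000):
    x = lfilter([1.0], np.concatenate([[1.0], -a]), rng.standard_normal(n))[5000:]
    return np.correlate(x, x, "full")[len(x) - 1 : len(x) + n_lags] / len(x)


class TestFrameSignal:
    def test_printed_frame_counts(self):
        """3.3 s and 6.8 s at 8 kHz give 205 and 424 analysis windows."""
        for n, expected in [(26400, 205), (54400, 424), (256, 1)]:
            w = Waveform(samples=np.full(n, 0.3), fs=8000)
            assert frame_signal(w).frames.shape == (expected, 256)

    def test_too_short_rejected(self):
        with pytest.raises(TooShortError):
            frame_signal(Waveform(samples=np.full(100, 0.3), fs=8000))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=256, max_value=60000),
        win=st.sampled_from([128, 256, 512]),
    )
    def test_count_matches_naive_loop(self, n, win):
        """Closed-form frame count equals a step-by-step enumeration."""
        if n < win:
            return
        w = Waveform(samples=np.full(n, 0.3), fs=8000)
        hop = win // 2
        got = frame_signal(w, win=win).frames.shape[0]
        naive = 0
        start = 0
        while start + win <= n:
            naive += 1
            start += hop
        assert got == naive


class TestLevinsonDurbin:
    def test_white_noise_case(self):
        a, k, err = levinson_durbin(np.array([1.0] + [0.0] * 10), 10)
        assert np.all(a == 0.0)
        assert err == 1.0

    def test_order_one_closed_form(self):
        a, k, err = levinson_durbin(np.array([1.0, 0.5]), 1)
        assert a[0] == pytest.approx(0.5)
        assert k[0] == pytest.approx(0.5)
        assert err == pytest.approx(0.75)

    def test_matches_dense_toeplitz_solve(self):
        """100 random stable AR(10) systems agree with the direct solve."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            a_true = _stable_ar(rng)
            r = _ar_autocorrelation(a_true, 10, rng)
            a_ld, k, err = levinson_durbin(r, 10)
            a_direct = solve_toeplitz(r[:10], r[1:11])
            worst = max(worst, float(np.max(np.abs(a_ld - a_direct))))
            assert np.all(np.abs(k) < 1.0)
            assert err >= 0.0
        assert worst < 1e-8

    def test_nonpositive_r0_rejected(self):
        with pytest.raises(ValueError):
            levinson_durbin(np.array([0.0] * 11), 10)


class TestLogAreaRatio:
    def test_closed_forms(self):
        assert parcor_to_lar(np.array([0.0]))[0] == 0.0
        assert parcor_to_lar(np.array([0.5]))[0] == pytest.approx(np.log(3.0))

    def test_antisymmetry_and_roundtrip(self):
        k = np.linspace(-0.95, 0.95, 39)
        g = parcor_to_lar(k)
        np.testing.assert_allclose(parcor_to_lar(-k), -g, atol=1e-12)
        np.testing.assert_allclose(lar_to_parcor(g), k, atol=1e-12)

    def test_unstable_k_rejected(self):
        with pytest.raises(ValueError):
            parcor_to_lar(np.array([1.0]))


class TestLPCC:
    def test_zero_model(self):
        assert np.all(lpc_to_cepstrum(np.zeros(10)) == 0.0)

    def test_ar1_closed_form(self):
        """Cepstrum of 1/(1 - alpha z^-1) is alpha^n / n."""
        alpha = 0.6
        c = lpc_to_cepstrum(np.array([alpha] + [0.0] * 9), 10)
        expected = np.array([alpha ** n / n for n in range(1, 11)])
        np.testing.assert_allclose(c, expected, atol=1e-12)

    def test_matches_fft_cepstrum(self):
        """Recursion equals the FFT real-cepstrum of 1/A on 100 models."""
        rng = np.random.default_rng(7)
        nfft = 1 << 14
        worst = 0.0
        for _ in range(100):
            a = _stable_ar(rng)
            c_rec = lpc_to_cepstrum(a, 10)
            spectrum = np.fft.fft(np.concatenate([[1.0], -a]), nfft)
            real_cep = np.fft.ifft(np.log(1.0 / np.abs(spectrum))).real
            c_fft = 2.0 * real_cep[1:11]  # minimum phase: c_n = 2 c_real,n
            worst = max(worst, float(np.max(np.abs(c_rec - c_fft))))
        assert worst < 1e-6


def _mfcc_reference(frame, fs, n_coef=10, n_filters=26):
    """Straight-line filterbank + DCT evaluation (independent oracle)."""
    n = len(frame)
    nfft = 1 << int(np.ceil(np.log2(n)))
    windowed = frame * np.hanning(n)
    power = np.abs(np.fft.rfft(windowed, nfft)) ** 2
    bins = np.fft.rfftfreq(nfft, d=1.0 / fs)
    mel = lambda f: 2595.0 * np.log10(1.0 + f / 700.0)  # noqa: E731
    imel = lambda m: 700.0 * (10.0 ** (m / 2595.0) - 1.0)  # noqa: E731
    edges = imel(np.linspace(0.0, mel(fs / 2.0), n_filters + 2))
    energies = np.zeros(n_filters)
    for i in range(n_filters):
        lo, center, hi = edges[i], edges[i + 1], edges[i + 2]
        for b, f in enumerate(bins):
            if lo <= f <= center:
                wgt = (f - lo) / (center - lo)
            elif center < f <= hi:
                wgt = (hi - f) / (hi - center)
            else:
                wgt = 0.0
            energies[i] += wgt * power[b]
    log_e = np.log(np.maximum(energies, 1e-12))
    coefs = scipy_dct(log_e, type=2, norm="ortho")
    return coefs[1 : n_coef + 1]


class TestMFCC:
    def test_gain_separation(self):
        """A global gain only moves c0; retained coefficients are equal."""
        rng = np.random.default_rng(0)
        frame = rng.standard_normal(256) * 0.1 + np.sin(
            2 * np.pi * 300 * np.arange(256) / 8000
        )
        a = mfcc_frame(frame, 8000)
        b = mfcc_frame(frame * 0.25, 8000)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_distinct_tones_distinct_vectors(self):
        t = np.arange(256) / 8000
        a = mfcc_frame(np.sin(2 * np.pi * 1000 * t), 8000)
        b = mfcc_frame(np.sin(2 * np.pi * 2000 * t), 8000)
        assert np.linalg.norm(a - b) > 0.1

    def test_matches_straight_line_oracle(self):
        spec = VowelSpec(duration=1.5, f0=150.0, hnr_db=25.0)
        w = synthesize_vowel(spec, 8000, 11)
        for start in (2000, 5000, 8000):
            frame = w.samples[start : start + 256]
            np.testing.assert_allclose(
                mfcc_frame(frame, 8000), _mfcc_reference(frame, 8000), atol=1e-9
            )

    def test_silent_frame_finite(self):
        out = mfcc_frame(np.zeros(256), 8000)
        assert np.all(np.isfinite(out))


class TestSummaries:
    def test_constant_track_zero_variance(self):
        track = SpectralCoefficients(kind="lpc", matrix=np.full((8, 10), 0.3))
        s = summarize_coefficients(track, "s1")
        np.testing.assert_allclose(s.var_vec, 0.0, atol=1e-15)

    def test_two_frame_sample_variance(self):
        track = SpectralCoefficients(
            kind="lpc", matrix=np.vstack([np.zeros(10), np.full(10, 2.0)])
        )
        s = summarize_coefficients(track, "s1")
        np.testing.assert_allclose(s.mean_vec, 1.0)
        np.testing.assert_allclose(s.var_vec, 2.0)  # sample variance, ddof=1

    def test_single_frame_rejected(self):
        track = SpectralCoefficients(kind="lpc", matrix=np.zeros((1, 10)))
        with pytest.raises(DegenerateInputError):
            summarize_coefficients(track, "s1")

    def test_tremor_raises_coefficient_variance(self):
        """Unsteady phonation shows up as larger track variance."""
        steady = VowelSpec(duration=2.0, f0=150.0, jitter_pct=0.2,
                           shimmer_pct=1.0, tremor_depth=0.0, hnr_db=25.0)
        shaky = VowelSpec(duration=2.0, f0=150.0, jitter_pct=2.5,
                          shimmer_pct=8.0, tremor_depth=0.03, hnr_db=12.0)
        norms = {}
        for name, spec in [("steady", steady), ("shaky", shaky)]:
            vals = []
            for seed in (1, 2, 3):
                w = synthesize_vowel(spec, 8000, seed)
                s = summarize_coefficients(coefficient_track(w, "mfcc"), "x")
                vals.append(np.linalg.norm(s.var_vec))
            norms[name] = np.mean(vals)
        assert norms["shaky"] > norms["steady"]


class TestCombine:
    def test_combined_length_33(self, clean_vowel):
        pf = assemble_phonation_features(clean_vowel)
        s = summarize_coefficients(coefficient_track(clean_vowel, "mfcc"), "s1")
        v = combine_features(s, pf, "s1", "var")
        assert len(v.values) == 33
        assert len(v.names) == 33

    def test_subject_mismatch_rejected(self, clean_vowel):
        pf = assemble_phonation_features(clean_vowel)
        s = summarize_coefficients(coefficient_track(clean_vowel, "mfcc"), "s1")
        with pytest.raises(ValueError):
            combine_features(s, pf, "other", "var")

    def test_ordering_stable(self, clean_vowel):
        pf = assemble_phonation_features(clean_vowel)
        s = summarize_coefficients(coefficient_track(clean_vowel, "lpcc"), "s1")
        v1 = combine_features(s, pf, "s1", "mean")
        v2 = combine_features(s, pf, "s1", "mean")
        assert v1.names == v2.names
        np.testing.assert_array_equal(v1.values, v2.values)
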