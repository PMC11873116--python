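"""Windowed linear-prediction spectral features: LPC, LAR, LPCC, MFCC.

The voiced segment is analyzed in sliding windows of 256 samples (32 ms
at 8 kHz) with 50% overlap.  Each window is fit with an autoregressive
model of order 10 by the autocorrelation (Yule-Walker) method solved with
the Levinson-Durbin recursion, yielding:

- *LPC*  — the predictor coefficients a_1..a_10 in the convention
  A(z) = 1 - sum_k a_k z^{-k};
- *LAR*  — log-area ratios g_i = ln((1 + k_i) / (1 - k_i)) of the
  reflection (partial-correlation) coefficients k_i;
- *LPCC* — cepstral coefficients from the standard LPC-to-cepstrum
  recursion;
- *MFCC* — mel-frequency cepstral coefficients (Hann window, 26-filter
  triangular mel bank, orthonormal DCT-II, c0 excluded).

Per recording, the mean and sample variance of each of the 10
coefficients across windows summarize the track; either summary can be
concatenated with the 23-entry phonation vector into a 33-entry combined
feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct

from vowelpd._frames import frame_view
from vowelpd.acoustic import PhonationFeatures
from vowelpd.errors import DegenerateInputError, TooShortError
from vowelpd.preprocess import Waveform
from vowelpd.spectrogram import mel_filterbank

AR_ORDER = 10
FRAME_WIN = 256
FRAME_OVERLAP = 0.5
N_MFCC_FILTERS = 26
_LOG_FLOOR = 1e-12

KINDS = ("lpc", "lar", "lpcc", "mfcc")


@dataclass(frozen=True)
class FrameMatrix:
    """Contiguous raw-sample analysis windows (no taper, no padding)."""

    frames: np.ndarray  # (n_frames, win)
    win: int
    hop: int
    fs: int


@dataclass(frozen=True)
class SpectralCoefficients:
    """Per-frame coefficient track of one kind."""

    kind: str
    matrix: np.ndarray  # (n_frames, p)
    p: int = AR_ORDER


@dataclass(frozen=True)
class SpectralSummary:
    """Per-recording mean and sample variance of each coefficient."""

    kind: str
    mean_vec: np.ndarray
    var_vec: np.ndarray
    subject_id: str


@dataclass(frozen=True)
class CombinedFeatureVector:
    """Spectral summary (10) concatenated with phonation features (23)."""

    values: np.ndarray  # length 33
    names: tuple[str, ...]
    subject_id: str
    spectral_kind: str
    spectral_stat: str


def frame_signal(
    w: Waveform, win: int = FRAME_WIN, overlap: float = FRAME_OVERLAP
) -> FrameMatrix:
    """Slice the waveform into raw-sample windows.

    Frame count is ``floor((n - win) / hop) + 1`` with
    ``hop = round(win * (1 - overlap))``; no padding and no taper (the AR
    fit uses the biased autocorrelation of the raw frame).
    """
    n = len(w.samples)
    if n < win:
        raise TooShortError(f"need at least {win} samples, got {n}")
    hop = int(round(win * (1.0 - overlap)))
    return FrameMatrix(
        frames=np.ascontiguousarray(frame_view(w.samples, win, hop)),
        win=win,
        hop=hop,
        fs=w.fs,
    )


def levinson_durbin(
    r: np.ndarray, p: int = AR_ORDER
) -> tuple[np.ndarray, np.ndarray, float]:
    """Solve the order-``p`` Yule-Walker system by Levinson-Durbin.

    ``r`` holds autocorrelation lags 0..p (at least).  Returns
    ``(a, k, err)``: predictor coefficients a_1..a_p in the convention
    A(z) = 1 - sum a_k z^{-k}, reflection coefficients k_1..k_p, and the
    final prediction-error power (non-negative, non-increasing in p).
    For a valid autocorrelation sequence all |k_i| < 1.
    """
    r = np.asarray(r, dtype=np.float64)
    if len(r) < p + 1:
        raise ValueError(f"need lags 0..{p}, got {len(r)} values")
    if r[0] <= 0:
        raise ValueError("r[0] must be positive")
    a = np.zeros(p)
    k = np.zeros(p)
    err = float(r[0])
    for i in range(p):
        acc = r[i + 1] - np.dot(a[:i], r[i:0:-1])
        ki = acc / err
        k[i] = ki
        a_new = a.copy()
        a_new[i] = ki
        a_new[:i] = a[:i] - ki * a[i - 1 :: -1][:i]
        a = a_new
        err *= 1.0 - ki * ki
        if err <= 0:
            err = max(err, 0.0)
            break
    return a, k, err


def parcor_to_lar(k: np.ndarray) -> np.ndarray:
    """Log-area ratios g_i = ln((1 + k_i) / (1 - k_i)); requires |k| < 1."""
    k = np.asarray(k, dtype=np.float64)
    if np.any(np.abs(k) >= 1.0):
        raise ValueError("reflection coefficients must satisfy |k| < 1")
    return np.log((1.0 + k) / (1.0 - k))


def lar_to_parcor(g: np.ndarray) -> np.ndarray:
    """Inverse mapping: k_i = tanh(g_i / 2)."""
    return np.tanh(np.asarray(g, dtype=np.float64) / 2.0)


def lpc_to_cepstrum(a: np.ndarray, p: int | None = None) -> np.ndarray:
    """Cepstrum of the all-pole model 1/A(z) by the standard recursion.

    With A(z) = 1 - sum a_k z^{-k}:
    c_1 = a_1;  c_n = a_n + sum_{k=1}^{n-1} (k/n) c_k a_{n-k}.
    """
    a = np.asarray(a, dtype=np.float64)
    if p is None:
        p = len(a)
    c = np.zeros(p)
    for n in range(1, p + 1):
        acc = a[n - 1] if n <= len(a) else 0.0
        for kk in range(1, n):
            a_nk = a[n - kk - 1] if n - kk <= len(a) else 0.0
            acc += (kk / n) * c[kk - 1] * a_nk
        c[n - 1] = acc
    return c


def mfcc_frame(
    frame: np.ndarray,
    fs: float,
    n_coef: int = AR_ORDER,
    n_filters: int = N_MFCC_FILTERS,
) -> np.ndarray:
    """MFCC of one frame: Hann window, mel filterbank, log, DCT-II.

    The power spectrum is pooled by ``n_filters`` triangular mel filters
    over 0..fs/2, log-compressed (floored for silent frames) and passed
    through the orthonormal type-II DCT; coefficients 1..n_coef are
    returned (c0, the overall log gain, is excluded).
    """
    frame = np.asarray(frame, dtype=np.float64)
    if len(frame) < 64:
        raise ValueError(f"frame too short for MFCC: {len(frame)} samples")
    nfft = 1 << int(np.ceil(np.log2(len(frame))))
    windowed = frame * np.hanning(len(frame))
    power = np.abs(np.fft.rfft(windowed, nfft)) ** 2
    fb = mel_filterbank(n_filters, nfft, fs)
    log_e = np.log(np.maximum(fb @ power, _LOG_FLOOR))
    coefs = dct(log_e, type=2, norm="ortho")
    return coefs[1 : n_coef + 1]


def _frame_lpc(frame: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Biased-autocorrelation AR fit of one frame; zeros when silent."""
    n = len(frame)
    r = np.correlate(frame, frame, mode="full")[n - 1 : n + p] / n
    if r[0] <= 0:
        return np.zeros(p), np.zeros(p)
    a, k, _ = levinson_durbin(r, p)
    return a, k


def coefficient_track(
    w: Waveform, kind: str, p: int = AR_ORDER, win: int = FRAME_WIN
) -> SpectralCoefficients:
    """Per-frame coefficients of one kind over the sliding-window analysis."""
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}, got {kind!r}")
    fm = frame_signal(w, win=win)
    rows = np.zeros((len(fm.frames), p))
    for i, frame in enumerate(fm.frames):
        if kind == "mfcc":
            rows[i] = mfcc_frame(frame, fm.fs, n_coef=p)
            continue
        a, k = _frame_lpc(frame, p)
        if kind == "lpc":
            rows[i] = a
        elif kind == "lar":
            rows[i] = parcor_to_lar(np.clip(k, -1 + 1e-9, 1 - 1e-9))
        else:  # lpcc
            rows[i] = lpc_to_cepstrum(a, p)
    return SpectralCoefficients(kind=kind, matrix=rows, p=p)


def summarize_coefficients(
    track: SpectralCoefficients, subject_id: str
) -> SpectralSummary:
    """Element-wise mean and sample variance across frames (needs >= 2)."""
    if len(track.matrix) < 2:
        raise DegenerateInputError("variance undefined with fewer than 2 frames")
    return SpectralSummary(
        kind=track.kind,
        mean_vec=track.matrix.mean(axis=0),
        var_vec=track.matrix.var(axis=0, ddof=1),
        subject_id=subject_id,
    )


def combine_features(
    s: SpectralSummary, pmf: PhonationFeatures, subject_id: str, stat: str = "var"
) -> CombinedFeatureVector:
    """Concatenate one spectral summary vector with the phonation vector.

    ``stat`` selects the mean or variance side of the summary; the result
    has length 10 + 23 = 33 with stable, documented ordering.
    """
    if s.subject_id != subject_id:
        raise ValueError(
            f"subject mismatch: summary {s.subject_id!r} vs {subject_id!r}"
        )
    if stat not in ("mean", "var"):
        raise ValueError("stat must be 'mean' or 'var'")
    spec_vec = s.mean_vec if stat == "mean" else s.var_vec
    spec_names = tuple(f"{s.kind}_{stat}_{i + 1}" for i in range(len(spec_vec)))
    values = np.concatenate([spec_vec, pmf.to_array()])
    return CombinedFeatureVector(
        values=values,
        names=spec_names + PhonationFeatures.names,
        subject_id=subject_id,
        spectral_kind=s.kind,
        spectral_stat=stat,
    )
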