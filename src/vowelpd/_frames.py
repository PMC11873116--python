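"""Shared short-time analysis helpers (framing, energy, periodicity).

These are internal building blocks used by the preprocessing stage (silence
trimming, voiced-segment selection) and the acoustic-feature stage (pitch
tracking, HNR).  Frames are contiguous strided views over the raw samples.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_UPSAMPLE = 4  # lag-domain oversampling of the autocorrelation
_PEAK_MARGIN = 0.02  # octave guard: prefer the shortest lag within this margin


def frame_view(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    """Return a (n_frames, win) read-only view with no padding.

    Frame count is ``floor((n - win) / hop) + 1``; requires ``n >= win``.
    """
    if len(x) < win:
        raise ValueError(f"signal length {len(x)} shorter than window {win}")
    return sliding_window_view(x, win)[::hop]


def short_time_energy(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    """Per-frame energy (sum of squares) over a sliding window."""
    frames = frame_view(np.asarray(x, dtype=np.float64), win, hop)
    return np.einsum("ij,ij->i", frames, frames)


def nacf_peak(
    frame: np.ndarray,
    fs: float,
    fmin: float,
    fmax: float,
) -> tuple[float, float]:
    """Normalized-autocorrelation pitch candidate for one frame.

    Returns ``(f0_hz, strength)`` where ``strength`` is the height of the
    normalized-autocorrelation peak in [0, 1]; ``(0, 0)`` when no valid
    lag exists.  Two details matter for unbiased estimates:

    - the raw autocorrelation is trigonometrically interpolated (zero-
      padded spectrum) to 4x lag resolution, because the peak of a
      wide-band voiced frame is only a few samples wide and integer-lag
      sampling underestimates its height at non-integer periods;
    - among local maxima within a small margin of the global maximum the
      *shortest* lag wins, which suppresses octave errors (a perfectly
      periodic frame scores equally at T, 2T, 3T, ...).

    The normalization divides by the geometric mean of the energies of
    the two lag-shifted sub-frames, so a periodic frame scores 1
    regardless of frame length (no window-taper decay bias).
    """
    x = np.asarray(frame, dtype=np.float64)
    x = x - x.mean()
    n = len(x)
    lmin = max(2, int(np.floor(fs / fmax)))
    lmax = int(np.ceil(fs / fmin))
    if lmax >= n - 1:
        lmax = n - 2
    if lmax <= lmin + 1:
        return 0.0, 0.0

    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    # zero-padded inverse transform = sinc-interpolated linear autocorrelation
    fine = np.fft.irfft(spec * np.conj(spec), _UPSAMPLE * nfft) * _UPSAMPLE

    # energy normalization terms at integer lags, linearly interpolated
    csq = np.concatenate([[0.0], np.cumsum(x * x)])
    int_lags = np.arange(0, lmax + 2)
    e_head = csq[n - int_lags]
    e_tail = csq[n] - csq[int_lags]
    denom_int = np.sqrt(e_head * e_tail)

    j0 = _UPSAMPLE * lmin - 1
    j1 = _UPSAMPLE * lmax + 1
    fine_lags = np.arange(j0, j1 + 1) / _UPSAMPLE
    denom = np.interp(fine_lags, int_lags, denom_int)
    with np.errstate(divide="ignore", invalid="ignore"):
        ncc = np.where(denom > 0, fine[j0 : j1 + 1] / denom, 0.0)
    if not np.isfinite(ncc).any():
        return 0.0, 0.0

    # local maxima in the interior of the search range
    interior = np.arange(1, len(ncc) - 1)
    is_peak = (ncc[interior] >= ncc[interior - 1]) & (ncc[interior] > ncc[interior + 1])
    peaks = interior[is_peak]
    if len(peaks) == 0:
        return 0.0, 0.0
    best_val = float(ncc[peaks].max())
    candidates = peaks[ncc[peaks] >= best_val - _PEAK_MARGIN]
    i = int(candidates[0])  # shortest lag within the margin

    y0, y1, y2 = ncc[i - 1], ncc[i], ncc[i + 1]
    d = y0 - 2.0 * y1 + y2
    if d < 0:
        delta = float(np.clip(0.5 * (y0 - y2) / d, -0.5, 0.5))
    else:
        delta = 0.0
    lag = fine_lags[i] + delta / _UPSAMPLE
    strength = float(np.clip(y1 - 0.25 * (y0 - y2) * delta, 0.0, 1.0))
    f0 = fs / lag
    if not (fmin <= f0 <= fmax):
        return 0.0, 0.0
    return float(f0), strength
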