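"""Linear- and mel-scale spectrogram matrices and fixed-size images.

Two recipes are implemented, matched to the study conditions they model:

- *linear*: Hann window of 1024 samples, 75% overlap, 1024-point FFT, no
  padding; values are ``10*log10(|S| / max|S|)`` so the global maximum is
  0 dB.
- *mel*: Hann window of 512 samples, 90% overlap (hop = floor(51.2) = 51,
  a dialect choice that reproduces the 260-frame count for a 1.5 s clip
  at 8820 Hz), 1024-point FFT, 256 triangular mel filters spanning
  0..fs/2, log energies normalized so the maximum is 0; frames are
  center-padded (reflect) giving ``floor(n / hop) + 1`` windows.

Images are rendered deterministically at 600x600 pixels, 24-bit color,
with a fixed perceptually-uniform colormap over the [-80, 0] value range.
PNG is the default output (lossless and bit-reproducible); JPEG at
quality 95 is available for compatibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image

from vowelpd.errors import DegenerateInputError, TooShortError
from vowelpd.preprocess import Waveform

LINEAR_WIN = 1024
LINEAR_HOP = 256  # 75% overlap
MEL_WIN = 512
MEL_HOP = 51  # floor(512 * 0.10)
NFFT = 1024
N_MEL_FILTERS = 256
IMAGE_SIZE = 600
VALUE_RANGE = (-80.0, 0.0)
DEFAULT_COLORMAP = "magma"
_LOG_FLOOR = 1e-10


def hz_to_mel(f):
    """Perceptual mel scale: mel = 2595 * log10(1 + f / 700)."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    return 2595.0 * np.log10(1.0 + f / 700.0)


def mel_to_hz(m):
    """Inverse of :func:`hz_to_mel`."""
    m = np.asarray(m, dtype=np.float64)
    if np.any(m < 0):
        raise ValueError("mel value must be non-negative")
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, nfft: int, fs: float) -> np.ndarray:
    """Triangular mel filterbank, shape (n_filters, nfft // 2 + 1).

    Filter centers are equally spaced on the mel scale between 0 and
    fs/2; each filter ramps linearly (in Hz) between its neighbors.
    """
    mel_points = np.linspace(0.0, float(hz_to_mel(fs / 2.0)), n_filters + 2)
    hz_points = mel_to_hz(mel_points)
    bins = np.fft.rfftfreq(nfft, d=1.0 / fs)
    fb = np.zeros((n_filters, len(bins)))
    for i in range(n_filters):
        lo, center, hi = hz_points[i], hz_points[i + 1], hz_points[i + 2]
        up = (bins - lo) / max(center - lo, 1e-12)
        down = (hi - bins) / max(hi - center, 1e-12)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


@dataclass(frozen=True)
class SpectrogramMatrix:
    """Max-normalized time x frequency log-energy grid."""

    values: np.ndarray  # (n_frames, n_bins), max = 0
    times: np.ndarray  # frame-center seconds
    freqs: np.ndarray  # Hz (linear) or mel-band center Hz (mel)
    scale: str  # "linear" | "mel"


@dataclass(frozen=True)
class SpectrogramImage:
    """Deterministic 600x600, 24-bit rendering of a spectrogram matrix."""

    pixels: np.ndarray  # (600, 600, 3) uint8
    colormap: str
    subject_id: str
    scale: str


def stft_magnitude(
    w: Waveform, win: int = LINEAR_WIN, hop: int = LINEAR_HOP, nfft: int = NFFT
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw Hann-windowed STFT magnitudes with no padding.

    Frame count is ``floor((n - win) / hop) + 1``.  Returns
    ``(magnitudes, times, freqs)`` before any normalization, so Parseval
    bookkeeping against windowed time-domain power is possible.
    """
    n = len(w.samples)
    if n < win:
        raise TooShortError(f"need at least {win} samples, got {n}")
    window = np.hanning(win)
    n_frames = (n - win) // hop + 1
    starts = np.arange(n_frames) * hop
    frames = np.stack([w.samples[s : s + win] for s in starts]) * window
    mags = np.abs(np.fft.rfft(frames, nfft, axis=1))
    times = (starts + win / 2) / w.fs
    freqs = np.fft.rfftfreq(nfft, d=1.0 / w.fs)
    return mags, times, freqs


def linear_spectrogram(w: Waveform) -> SpectrogramMatrix:
    """Linear-scale spectrogram: 10*log10(|S| / max|S|), global max 0 dB."""
    mags, times, freqs = stft_magnitude(w)
    peak = float(mags.max())
    if peak <= 0:
        raise DegenerateInputError("silent input: zero spectrogram")
    values = 10.0 * np.log10(np.maximum(mags, _LOG_FLOOR * peak) / peak)
    return SpectrogramMatrix(values=values, times=times, freqs=freqs, scale="linear")


def mel_spectrogram(w: Waveform) -> SpectrogramMatrix:
    """Mel-scale spectrogram, log energies normalized to a maximum of 0."""
    n = len(w.samples)
    if n < MEL_WIN:
        raise TooShortError(f"need at least {MEL_WIN} samples, got {n}")
    pad = MEL_WIN // 2
    x = np.pad(w.samples, pad, mode="reflect")
    window = np.hanning(MEL_WIN)
    n_frames = n // MEL_HOP + 1
    starts = np.arange(n_frames) * MEL_HOP
    frames = np.stack([x[s : s + MEL_WIN] for s in starts]) * window
    power = np.abs(np.fft.rfft(frames, NFFT, axis=1)) ** 2
    fb = mel_filterbank(N_MEL_FILTERS, NFFT, w.fs)
    mel_energy = power @ fb.T
    log_mel = np.log(np.maximum(mel_energy, _LOG_FLOOR))
    values = log_mel - log_mel.max()
    times = starts * 1.0 / w.fs
    centers = mel_to_hz(
        np.linspace(0.0, float(hz_to_mel(w.fs / 2.0)), N_MEL_FILTERS + 2)[1:-1]
    )
    return SpectrogramMatrix(values=values, times=times, freqs=centers, scale="mel")


def render_spectrogram_image(
    m: SpectrogramMatrix,
    colormap: str = DEFAULT_COLORMAP,
    subject_id: str = "",
    value_range: tuple[float, float] = VALUE_RANGE,
) -> SpectrogramImage:
    """Render a matrix to a 600x600, 24-bit image (frequency up, time right).

    The value -> color mapping is fixed: values are clipped to
    ``value_range``, scaled to [0, 1] and passed through ``colormap``;
    the grid is bilinearly resampled to 600x600.  Identical matrices
    produce identical pixel buffers.
    """
    if m.values.size == 0:
        raise DegenerateInputError("empty spectrogram matrix")
    lo, hi = value_range
    norm = np.clip((m.values - lo) / (hi - lo), 0.0, 1.0)
    cmap = colormaps[colormap]
    rgba = cmap(norm.T[::-1])  # freq rows, low at bottom
    rgb8 = (rgba[..., :3] * 255.0).round().astype(np.uint8)
    img = Image.fromarray(rgb8, mode="RGB").resize(
        (IMAGE_SIZE, IMAGE_SIZE), resample=Image.BILINEAR
    )
    return SpectrogramImage(
        pixels=np.asarray(img, dtype=np.uint8),
        colormap=colormap,
        subject_id=subject_id,
        scale=m.scale,
    )


def save_image(
    image: SpectrogramImage, path: str | Path, jpeg_quality: int | None = None
) -> Path:
    """Write PNG (default, lossless) or JPEG when the path ends in .jpg."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = Image.fromarray(image.pixels, mode="RGB")
    if path.suffix.lower() in (".jpg", ".jpeg"):
        img.save(path, format="JPEG", quality=jpeg_quality or 95)
    else:
        img.save(path, format="PNG")
    return path


def average_spectrogram_difference(
    group_a: list[SpectrogramMatrix], group_b: list[SpectrogramMatrix]
) -> SpectrogramMatrix:
    """Element-wise group-mean difference map (A minus B).

    All matrices must share shape and scale; used to visualize where the
    PD group's average energy distribution departs from controls (e.g. an
    F0-band shift).
    """
    if not group_a or not group_b:
        raise DegenerateInputError("both groups must be non-empty")
    ref = group_a[0]
    for m in group_a + group_b:
        if m.values.shape != ref.values.shape or m.scale != ref.scale:
            raise ValueError("all matrices must share shape and scale")
    mean_a = np.mean([m.values for m in group_a], axis=0)
    mean_b = np.mean([m.values for m in group_b], axis=0)
    return SpectrogramMatrix(
        values=mean_a - mean_b, times=ref.times, freqs=ref.freqs, scale=ref.scale
    )
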