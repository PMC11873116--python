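"""Recording preprocessing: normalize, decimate, trim, select, clip.

The stages mirror how field studies condition sustained-vowel recordings
before feature extraction: amplitudes are rescaled to [-1, 1], wide-band
smartphone recordings are decimated toward telephone-band rates, leading
and trailing silence is trimmed with a short-time-energy gate, the longest
continuous voiced stretch is selected when phonation was interrupted, and
a fixed-length 1.5 s segment centered on the midpoint feeds the
spectrogram path.  Recordings shorter than 1.5 s after trimming are
excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import filtfilt, firwin

from vowelpd._frames import frame_view, nacf_peak, short_time_energy
from vowelpd.errors import (
    DegenerateInputError,
    ConfigError,
    FormatError,
    TooShortError,
)

CLIP_SECONDS = 1.5
"""Fixed analysis-segment length in seconds for spectrogram generation."""

#: short-time energy gate defaults: 25 ms window, 10 ms hop, -20 dB threshold
ENERGY_WIN_S = 0.025
ENERGY_HOP_S = 0.010
ENERGY_REL_THRESHOLD = 0.01

#: voicing decision: normalized-autocorrelation peak above this value within
#: the 60-500 Hz pitch range, with frame energy above the silence gate
VOICING_THRESHOLD = 0.45
VOICING_FMIN = 60.0
VOICING_FMAX = 500.0
VOICING_WIN_S = 0.040


@dataclass(frozen=True)
class Waveform:
    """Mono audio samples in [-1, 1] with their sampling rate.

    ``provenance`` is free text carried through the pipeline (source file,
    synthesis parameters, processing applied).
    """

    samples: np.ndarray
    fs: int
    provenance: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or len(samples) < 1:
            raise FormatError("waveform must be a non-empty 1-D sample array")
        if self.fs <= 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        peak = float(np.max(np.abs(samples)))
        if peak > 1.0 + 1e-9:
            raise FormatError(f"samples exceed [-1, 1] (max |x| = {peak:.4g})")

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return len(self.samples) / self.fs

    def with_samples(self, samples: np.ndarray, note: str = "") -> "Waveform":
        prov = f"{self.provenance}; {note}" if note else self.provenance
        return Waveform(samples=samples, fs=self.fs, provenance=prov)


@dataclass(frozen=True)
class TrimResult:
    """Outcome of silence trimming: the retained waveform and boundaries."""

    waveform: Waveform
    start_s: float
    end_s: float
    voiced_segments: list[tuple[float, float]] = field(default_factory=list)


def read_wav(path: str | Path) -> Waveform:
    """Read a mono PCM WAV file into a float waveform in [-1, 1].

    Integer PCM is scaled by the type's full-scale value; float WAVs are
    passed through (and must already lie in [-1, 1]).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        fs, data = wavfile.read(str(path))
    except Exception as exc:  # noqa: BLE001 - normalize into FormatError
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim != 1:
        raise FormatError(f"{path}: expected mono audio, got shape {data.shape}")
    if data.size == 0:
        raise FormatError(f"{path}: empty audio stream")
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = np.asarray(data, dtype=np.float64)
    else:
        raise FormatError(f"{path}: unsupported sample encoding {data.dtype}")
    samples = np.clip(samples, -1.0, 1.0)
    return Waveform(samples=samples, fs=int(fs), provenance=str(path))


def write_wav(w: Waveform, path: str | Path) -> Path:
    """Write a waveform as RIFF WAV, PCM 16-bit mono (round-to-nearest)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pcm = np.round(np.clip(w.samples, -1.0, 1.0) * 32767.0).astype(np.int16)
    wavfile.write(str(path), int(w.fs), pcm)
    return path


def normalize_amplitude(w: Waveform) -> Waveform:
    """Rescale so the absolute peak equals 1 (shape preserved)."""
    peak = float(np.max(np.abs(w.samples)))
    if peak == 0.0:
        raise DegenerateInputError("cannot normalize an all-zero waveform")
    return w.with_samples(w.samples / peak, "normalized")


def decimate(w: Waveform, factor: int) -> Waveform:
    """Integer-factor downsampling with a zero-phase anti-alias FIR.

    The low-pass cutoff sits at 0.45 of the output rate; the Hamming FIR is
    applied forward-backward (zero phase) so stopband attenuation is doubled,
    comfortably beyond 60 dB alias suppression.
    """
    if factor < 1 or int(factor) != factor:
        raise ConfigError(f"decimation factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return w
    if w.fs % factor != 0:
        raise ConfigError(
            f"factor {factor} does not divide the sampling rate {w.fs} evenly"
        )
    new_fs = w.fs // factor
    numtaps = 120 * factor + 1
    if len(w.samples) <= 3 * numtaps:
        raise TooShortError("recording too short for anti-alias filtering")
    taps = firwin(numtaps, 0.45 * new_fs, fs=w.fs)
    filtered = filtfilt(taps, [1.0], w.samples)
    out = np.clip(filtered[::factor], -1.0, 1.0)
    return Waveform(
        samples=out,
        fs=new_fs,
        provenance=f"{w.provenance}; decimated x{factor}",
    )


def trim_silence(
    w: Waveform,
    win_s: float = ENERGY_WIN_S,
    hop_s: float = ENERGY_HOP_S,
    rel_threshold: float = ENERGY_REL_THRESHOLD,
) -> TrimResult:
    """Trim leading/trailing silence with a short-time energy gate.

    Retains the span between the first and last analysis frame whose energy
    exceeds ``rel_threshold`` times the maximum frame energy.  Raises
    :class:`DegenerateInputError` when no frame passes (pure silence).
    """
    win = max(1, int(round(win_s * w.fs)))
    hop = max(1, int(round(hop_s * w.fs)))
    if len(w.samples) < win:
        raise DegenerateInputError(
            f"input ({w.duration:.3f} s) shorter than the energy window"
        )
    energy = short_time_energy(w.samples, win, hop)
    emax = float(energy.max())
    if emax <= 0.0:
        raise DegenerateInputError("pure silence: no frame exceeds the energy gate")
    above = energy > rel_threshold * emax
    if not above.any():
        raise DegenerateInputError("pure silence: no frame exceeds the energy gate")
    idx = np.flatnonzero(above)
    start = idx[0] * hop
    # a passing final frame extends to the signal edge: the gate must not
    # shave samples the analysis window simply could not cover
    if idx[-1] == len(energy) - 1:
        end = len(w.samples)
    else:
        end = min(idx[-1] * hop + win, len(w.samples))
    segments = _runs_to_segments(above, win, hop, w.fs)
    return TrimResult(
        waveform=w.with_samples(w.samples[start:end], "trimmed"),
        start_s=start / w.fs,
        end_s=end / w.fs,
        voiced_segments=segments,
    )


def _runs_to_segments(
    mask: np.ndarray, win: int, hop: int, fs: int
) -> list[tuple[float, float]]:
    """Contiguous True runs of a frame mask as (start_s, end_s) intervals."""
    segments: list[tuple[float, float]] = []
    run_start = None
    for i, flag in enumerate(mask):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            segments.append((run_start * hop / fs, ((i - 1) * hop + win) / fs))
            run_start = None
    if run_start is not None:
        segments.append((run_start * hop / fs, ((len(mask) - 1) * hop + win) / fs))
    return segments


def voicing_mask(
    w: Waveform,
    win_s: float = VOICING_WIN_S,
    hop_s: float = ENERGY_HOP_S,
    threshold: float = VOICING_THRESHOLD,
) -> np.ndarray:
    """Per-frame voiced/unvoiced decision.

    A frame is voiced when its normalized autocorrelation peak within the
    60-500 Hz pitch range exceeds ``threshold`` and its energy is above the
    silence gate (relative to the loudest frame).
    """
    win = int(round(win_s * w.fs))
    hop = int(round(hop_s * w.fs))
    if len(w.samples) < win:
        raise DegenerateInputError("input shorter than the voicing analysis window")
    frames = frame_view(w.samples, win, hop)
    energy = np.einsum("ij,ij->i", frames, frames)
    egate = ENERGY_REL_THRESHOLD * float(energy.max())
    mask = np.zeros(len(frames), dtype=bool)
    for i, frame in enumerate(frames):
        if energy[i] <= egate:
            continue
        _, strength = nacf_peak(frame, w.fs, VOICING_FMIN, VOICING_FMAX)
        mask[i] = strength > threshold
    return mask


#: unvoiced gaps up to this long are bridged inside one voiced segment:
#: transient distortions and momentary aperiodicity do not end a phonation,
#: while a genuine pause between repeated attempts (>= several hundred ms)
#: still separates segments
VOICED_MAX_GAP_S = 0.25


def longest_voiced_segment(
    w: Waveform,
    win_s: float = VOICING_WIN_S,
    hop_s: float = ENERGY_HOP_S,
    max_gap_s: float = VOICED_MAX_GAP_S,
) -> Waveform:
    """Return the longest contiguous run of voiced frames as a waveform.

    Sustained-vowel takes are sometimes interrupted (breaths, repeated
    attempts); analysis proceeds on the longest uninterrupted phonation.
    Unvoiced gaps shorter than ``max_gap_s`` are treated as part of the
    surrounding phonation.
    """
    mask = voicing_mask(w, win_s=win_s, hop_s=hop_s)
    if not mask.any():
        raise DegenerateInputError("no voiced frame found")
    hop_frames = int(round(hop_s * w.fs))
    max_gap = int(round(max_gap_s * w.fs / hop_frames))
    voiced_pos = np.flatnonzero(mask)
    for a, b in zip(voiced_pos[:-1], voiced_pos[1:]):
        if 1 < b - a <= max_gap + 1:
            mask[a:b] = True
    win = int(round(win_s * w.fs))
    hop = int(round(hop_s * w.fs))
    best_len, best_start = 0, 0
    run_start = None
    for i, flag in enumerate(np.append(mask, False)):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    start = best_start * hop
    if best_start + best_len == len(mask):  # run reaches the final frame
        end = len(w.samples)
    else:
        end = min((best_start + best_len - 1) * hop + win, len(w.samples))
    return w.with_samples(w.samples[start:end], "longest-voiced")


def center_clip(w: Waveform, clip_s: float = CLIP_SECONDS) -> Waveform:
    """Extract exactly ``round(clip_s * fs)`` samples centered on the midpoint.

    Raises :class:`TooShortError` when the input is shorter than ``clip_s``;
    such recordings are excluded from spectrogram analysis.
    """
    n_out = int(round(clip_s * w.fs))
    n = len(w.samples)
    if n < n_out:
        raise TooShortError(
            f"recording ({n / w.fs:.3f} s) shorter than the {clip_s} s clip"
        )
    start = (n - n_out) // 2
    return w.with_samples(w.samples[start : start + n_out], f"clip {clip_s}s")


@dataclass(frozen=True)
class PreprocessResult:
    """Conditioned views of one recording.

    ``voiced`` is the full longest voiced segment (used for phonation and
    spectral features); ``clip`` is its central 1.5 s (used for
    spectrograms).
    """

    voiced: Waveform
    clip: Waveform
    trim: TrimResult


def preprocess_recording(
    w: Waveform,
    decimate_factor: int | None = None,
    clip_s: float = CLIP_SECONDS,
) -> PreprocessResult:
    """Run the fixed preprocessing chain on one recording.

    Order: normalize -> (decimate, smartphone recordings only) -> trim
    silence -> longest voiced segment -> center 1.5 s clip.  Re-running the
    chain on its own clip output reproduces the clip.
    """
    w = normalize_amplitude(w)
    if decimate_factor is not None and decimate_factor > 1:
        w = decimate(w, decimate_factor)
    trim = trim_silence(w)
    voiced = longest_voiced_segment(trim.waveform)
    clip = center_clip(voiced, clip_s=clip_s)
    return PreprocessResult(voiced=voiced, clip=clip, trim=trim)
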