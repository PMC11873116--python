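"""Phonation (acoustic) features of a sustained vowel.

One 23-entry feature vector summarizes each recording:

==============================  =============================================
entries                         meaning
==============================  =============================================
f0_mean, f0_sd                  fundamental-frequency level and stability (Hz)
f1..f4 mean and SD (8)          first four formant frequencies (Hz)
hnr_db                          harmonics-to-noise ratio (dB)
jitter x 5                      local %, local absolute (s), RAP %, PPQ5 %,
                                DDP % — cycle-length perturbation measures
shimmer x 6                     local %, local dB, APQ3 %, APQ5 %, APQ11 %,
                                DDA % — cycle-amplitude perturbation measures
unvoiced_fraction               fraction of analysis frames without voicing
==============================  =============================================

Jitter/shimmer follow the standard voice-report definitions computed on
this module's own glottal cycle sequence (peak-picking guided by the
frame-wise pitch track).  DDP = 3*RAP and DDA = 3*APQ3 hold exactly by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from vowelpd._frames import frame_view, nacf_peak
from vowelpd.errors import DegenerateInputError, InsufficientCyclesError
from vowelpd.preprocess import ENERGY_REL_THRESHOLD, Waveform

PITCH_FMIN = 60.0
PITCH_FMAX = 500.0
PITCH_HOP_S = 0.010
VOICING_THRESHOLD = 0.45
HNR_CAP_DB = 40.0
MIN_CYCLES = 12  # APQ11 needs 11-cycle windows


@dataclass(frozen=True)
class PitchTrack:
    """Frame-wise F0 estimates; 0 Hz marks unvoiced frames."""

    times: np.ndarray  # frame-center times, s
    f0: np.ndarray  # Hz, 0 where unvoiced
    strength: np.ndarray  # normalized-autocorrelation peak height

    @property
    def voiced(self) -> np.ndarray:
        return self.f0 > 0

    @property
    def unvoiced_fraction(self) -> float:
        return float(np.mean(~self.voiced))


@dataclass(frozen=True)
class CycleSequence:
    """Glottal cycle marks with per-cycle periods and peak amplitudes."""

    boundaries_s: np.ndarray  # cycle marks t_0..t_N
    periods_s: np.ndarray  # T_i = t_i - t_{i-1}, length N
    amplitudes: np.ndarray  # per-cycle peak amplitude, length N

    def __post_init__(self) -> None:
        if len(self.periods_s) != len(self.amplitudes):
            raise ValueError("periods and amplitudes must have equal length")
        if np.any(self.periods_s <= 0):
            raise ValueError("cycle periods must be positive")


_FEATURE_NAMES = (
    "f0_mean",
    "f0_sd",
    "f1_mean",
    "f1_sd",
    "f2_mean",
    "f2_sd",
    "f3_mean",
    "f3_sd",
    "f4_mean",
    "f4_sd",
    "hnr_db",
    "jitter_local_pct",
    "jitter_local_abs_s",
    "jitter_rap_pct",
    "jitter_ppq5_pct",
    "jitter_ddp_pct",
    "shimmer_local_pct",
    "shimmer_local_db",
    "shimmer_apq3_pct",
    "shimmer_apq5_pct",
    "shimmer_apq11_pct",
    "shimmer_dda_pct",
    "unvoiced_fraction",
)


@dataclass(frozen=True)
class PhonationFeatures:
    """The 23-entry phonation feature vector (fixed, documented order)."""

    f0_mean: float
    f0_sd: float
    f1_mean: float
    f1_sd: float
    f2_mean: float
    f2_sd: float
    f3_mean: float
    f3_sd: float
    f4_mean: float
    f4_sd: float
    hnr_db: float
    jitter_local_pct: float
    jitter_local_abs_s: float
    jitter_rap_pct: float
    jitter_ppq5_pct: float
    jitter_ddp_pct: float
    shimmer_local_pct: float
    shimmer_local_db: float
    shimmer_apq3_pct: float
    shimmer_apq5_pct: float
    shimmer_apq11_pct: float
    shimmer_dda_pct: float
    unvoiced_fraction: float
    partial: bool = False  # True when the formant stage flagged sparse frames

    names = _FEATURE_NAMES

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _FEATURE_NAMES], dtype=np.float64)

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in _FEATURE_NAMES}


def track_pitch(
    w: Waveform,
    fmin: float = PITCH_FMIN,
    fmax: float = PITCH_FMAX,
    hop_s: float = PITCH_HOP_S,
    voicing_threshold: float = VOICING_THRESHOLD,
) -> PitchTrack:
    """Frame-based normalized-autocorrelation pitch tracking.

    The analysis window spans three periods of the lowest tracked pitch;
    frames whose autocorrelation peak falls below ``voicing_threshold``
    (or whose energy is below the silence gate) are reported as unvoiced
    (F0 = 0).
    """
    win = int(round(3.0 / fmin * w.fs))
    hop = max(1, int(round(hop_s * w.fs)))
    if len(w.samples) < win:
        raise DegenerateInputError(
            f"need at least {3.0 / fmin:.3f} s for pitch tracking"
        )
    frames = frame_view(w.samples, win, hop)
    energy = np.einsum("ij,ij->i", frames, frames)
    egate = ENERGY_REL_THRESHOLD * float(energy.max())
    times = (np.arange(len(frames)) * hop + win / 2) / w.fs
    f0 = np.zeros(len(frames))
    strength = np.zeros(len(frames))
    for i, frame in enumerate(frames):
        if energy[i] <= egate:
            continue
        hz, s = nacf_peak(frame, w.fs, fmin, fmax)
        strength[i] = s
        if s > voicing_threshold:
            f0[i] = hz
    # octave correction: isolated halving/doubling errors are snapped back
    # to the track median (sustained vowels have near-constant F0)
    voiced = f0 > 0
    if voiced.any():
        med = float(np.median(f0[voiced]))
        for i in np.flatnonzero(voiced):
            if abs(2.0 * f0[i] - med) < 0.15 * med:
                f0[i] *= 2.0
            elif abs(0.5 * f0[i] - med) < 0.15 * med:
                f0[i] *= 0.5
            if not (fmin <= f0[i] <= fmax):
                f0[i] = med
    return PitchTrack(times=times, f0=f0, strength=strength)


def extract_cycles(w: Waveform, pt: PitchTrack) -> CycleSequence:
    """Mark glottal cycles by waveform matching guided by the pitch track.

    Each cycle's period is the normalized-cross-correlation lag (with
    parabolic sub-sample refinement) between the current cycle's waveform
    and the signal one expected period later, searched over [0.8, 1.25]
    of the locally tracked period.  Template matching repeats exactly on
    a perfectly periodic signal, so the measured jitter floor is
    essentially zero.  Per-cycle amplitudes are the interpolated waveform
    maxima within each cycle.  Raises :class:`InsufficientCyclesError`
    with fewer than 12 cycles.
    """
    voiced_idx = np.flatnonzero(pt.voiced)
    if len(voiced_idx) < 5:
        raise DegenerateInputError("need at least 5 voiced frames")
    x = w.samples
    fs = w.fs
    vt = pt.times[voiced_idx]
    vf = pt.f0[voiced_idx]
    t_med = fs / float(np.median(vf))

    def local_period_samples(pos: float) -> float:
        # clamp to the median: residual track outliers must not make the
        # search window skip (or split) a cycle
        t_loc = fs / float(np.interp(pos / fs, vt, vf))
        return float(np.clip(t_loc, 0.75 * t_med, 1.33 * t_med))

    # frames are centered, so the voiced region really extends half an
    # analysis window beyond the first/last voiced frame centers
    half_win = float(pt.times[0])
    t_start = max(vt[0] - half_win, 0.0)
    t_end = min(vt[-1] + half_win, len(x) / fs)
    i0 = int(t_start * fs)
    period0 = int(round(local_period_samples(i0)))
    seg = x[i0 : i0 + 2 * period0]
    if len(seg) < 3:
        raise DegenerateInputError("voiced region too short for cycle marking")
    cur = float(i0 + int(np.argmax(seg)))

    marks: list[float] = [cur]
    periods: list[float] = []
    while cur / fs < t_end:
        T = local_period_samples(cur)
        L = int(round(0.9 * T))
        r0 = int(round(cur))
        lo = int(np.floor(0.8 * T))
        hi = int(np.ceil(1.25 * T))
        if r0 + hi + L >= len(x):
            # near the signal edge: shrink the template to mark the last
            # cycles instead of discarding them
            L = len(x) - r0 - hi - 1
            if L < int(0.4 * T):
                break
        if L < 4:
            break
        template = x[r0 : r0 + L]
        seg = x[r0 + lo : r0 + hi + L]
        cc = np.correlate(seg, template, mode="valid")
        csq = np.concatenate([[0.0], np.cumsum(seg * seg)])
        e_seg = csq[L:] - csq[: len(cc)]
        e_t = float(np.dot(template, template))
        if e_t <= 0:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            ncc = np.where(e_seg > 0, cc / np.sqrt(e_t * e_seg), 0.0)
        k = int(np.argmax(ncc))
        delta = 0.0
        if 1 <= k < len(ncc) - 1:
            y0, y1, y2 = ncc[k - 1], ncc[k], ncc[k + 1]
            d = y0 - 2 * y1 + y2
            if d < 0:
                delta = float(np.clip(0.5 * (y0 - y2) / d, -0.5, 0.5))
        tau = lo + k + delta
        periods.append(tau / fs)
        cur += tau
        marks.append(cur)

    if len(periods) < MIN_CYCLES:
        raise InsufficientCyclesError(
            f"found {len(periods)} cycles; perturbation quotients need "
            f">= {MIN_CYCLES}"
        )

    # per-cycle amplitudes: interpolated waveform maximum within the cycle
    amps = []
    for a, b in zip(marks[:-1], marks[1:]):
        ia, ib = int(round(a)), min(int(round(b)) + 1, len(x))
        k = ia + int(np.argmax(x[ia:ib]))
        if 1 <= k < len(x) - 1:
            y0, y1, y2 = x[k - 1], x[k], x[k + 1]
            d = y0 - 2 * y1 + y2
            if d < 0:
                dd = float(np.clip(0.5 * (y0 - y2) / d, -0.5, 0.5))
                amps.append(y1 - 0.25 * (y0 - y2) * dd)
                continue
        amps.append(float(x[k]))
    amplitudes = np.asarray(amps)

    boundaries = np.asarray(marks) / fs
    periods = np.asarray(periods)
    keep = amplitudes > 0
    if not keep.all():
        periods, amplitudes = periods[keep], amplitudes[keep]
        boundaries = boundaries[np.concatenate([[True], keep])]
    if len(periods) < MIN_CYCLES:
        raise InsufficientCyclesError(
            f"found {len(periods)} usable cycles; need >= {MIN_CYCLES}"
        )
    return CycleSequence(
        boundaries_s=boundaries, periods_s=periods, amplitudes=amplitudes
    )


def _window_quotient(values: np.ndarray, q: int) -> float:
    """mean |v_i - mean(q-point window centered on i)| / mean(v)."""
    h = q // 2
    n = len(values)
    devs = [
        abs(values[i] - values[i - h : i + h + 1].mean())
        for i in range(h, n - h)
    ]
    return float(np.mean(devs) / values.mean())


def jitter_metrics(c: CycleSequence) -> dict[str, float]:
    """Five standard jitter measures of the cycle-period sequence."""
    T = c.periods_s
    if len(T) < MIN_CYCLES:
        raise InsufficientCyclesError(f"need >= {MIN_CYCLES} cycles, got {len(T)}")
    mean_T = float(T.mean())
    abs_dT = np.abs(np.diff(T))
    local_abs = float(abs_dT.mean())
    rap = _window_quotient(T, 3) * 100.0
    ppq5 = _window_quotient(T, 5) * 100.0
    return {
        "jitter_local_pct": local_abs / mean_T * 100.0,
        "jitter_local_abs_s": local_abs,
        "jitter_rap_pct": rap,
        "jitter_ppq5_pct": ppq5,
        "jitter_ddp_pct": 3.0 * rap,
    }


def shimmer_metrics(c: CycleSequence) -> dict[str, float]:
    """Six standard shimmer measures of the cycle-amplitude sequence."""
    A = c.amplitudes
    if len(A) < MIN_CYCLES:
        raise InsufficientCyclesError(f"need >= {MIN_CYCLES} cycles, got {len(A)}")
    if np.any(A <= 0):
        raise DegenerateInputError("non-positive cycle amplitude")
    mean_A = float(A.mean())
    abs_dA = np.abs(np.diff(A))
    apq3 = _window_quotient(A, 3) * 100.0
    return {
        "shimmer_local_pct": float(abs_dA.mean()) / mean_A * 100.0,
        "shimmer_local_db": float(np.mean(np.abs(20.0 * np.log10(A[1:] / A[:-1])))),
        "shimmer_apq3_pct": apq3,
        "shimmer_apq5_pct": _window_quotient(A, 5) * 100.0,
        "shimmer_apq11_pct": _window_quotient(A, 11) * 100.0,
        "shimmer_dda_pct": 3.0 * apq3,
    }


def harmonics_to_noise_ratio(w: Waveform, pt: PitchTrack) -> float:
    """Mean frame-wise HNR in dB, capped at +40.

    Per voiced frame, with ``r`` the normalized autocorrelation at the
    pitch lag, HNR = 10*log10(r / (1 - r)): ``r`` estimates the periodic
    fraction of the frame's power.
    """
    if not pt.voiced.any():
        raise DegenerateInputError("no voiced frames")
    r = pt.strength[pt.voiced]
    r = np.clip(r, 1e-6, 1.0 - 1e-6)
    hnr = 10.0 * np.log10(r / (1.0 - r))
    return float(np.minimum(hnr, HNR_CAP_DB).mean())


def formant_summary(
    w: Waveform,
    n_formants: int = 4,
    frame_s: float = 0.050,
    hop_s: float = 0.025,
    preemphasis: float = 0.97,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Frame-wise LPC-root formant estimates: means, SDs, partial flag.

    Each frame is pre-emphasized, Hamming-windowed and fit with an LPC
    model of order ``2 + fs/1000``; roots with 90 Hz < f < fs/2 - 50 Hz
    and bandwidth < 400 Hz are formant candidates, assigned ascending.
    Returns ``(means, sds, partial)`` where ``partial`` is True when more
    than half the frames yielded fewer than ``n_formants`` candidates.
    """
    from vowelpd.spectral import levinson_durbin  # shared recursion

    x = lfilter([1.0, -preemphasis], [1.0], w.samples)
    win = int(round(frame_s * w.fs))
    hop = int(round(hop_s * w.fs))
    if len(x) < win:
        raise DegenerateInputError("input shorter than one formant frame")
    frames = frame_view(x, win, hop) * np.hamming(win)
    order = int(round(w.fs / 1000.0)) + 2
    per_frame: list[np.ndarray] = []
    n_sparse = 0
    for frame in frames:
        r = np.correlate(frame, frame, mode="full")[win - 1 : win + order] / win
        if r[0] <= 0:
            n_sparse += 1
            continue
        try:
            a, _, _ = levinson_durbin(r, order)
        except ValueError:
            n_sparse += 1
            continue
        poly = np.concatenate([[1.0], -a])
        roots = np.roots(poly)
        roots = roots[np.imag(roots) > 0]
        freqs = np.angle(roots) * w.fs / (2.0 * np.pi)
        bws = -(w.fs / np.pi) * np.log(np.abs(roots))
        ok = (freqs > 90.0) & (freqs < w.fs / 2.0 - 50.0) & (bws < 400.0)
        cand = np.sort(freqs[ok])
        if len(cand) < n_formants:
            n_sparse += 1
            continue
        per_frame.append(cand[:n_formants])
    partial = n_sparse > len(frames) / 2
    if not per_frame:
        return (
            np.full(n_formants, np.nan),
            np.full(n_formants, np.nan),
            True,
        )
    mat = np.vstack(per_frame)
    return mat.mean(axis=0), mat.std(axis=0, ddof=1 if len(mat) > 1 else 0), partial


def assemble_phonation_features(w: Waveform) -> PhonationFeatures:
    """Compute the full 23-entry phonation vector for one voiced segment."""
    pt = track_pitch(w)
    voiced_f0 = pt.f0[pt.voiced]
    if len(voiced_f0) < 5:
        raise DegenerateInputError("too few voiced frames for phonation features")
    cycles = extract_cycles(w, pt)
    jit = jitter_metrics(cycles)
    shim = shimmer_metrics(cycles)
    hnr = harmonics_to_noise_ratio(w, pt)
    fmeans, fsds, partial = formant_summary(w)
    return PhonationFeatures(
        f0_mean=float(voiced_f0.mean()),
        f0_sd=float(voiced_f0.std(ddof=1)) if len(voiced_f0) > 1 else 0.0,
        f1_mean=float(fmeans[0]),
        f1_sd=float(fsds[0]),
        f2_mean=float(fmeans[1]),
        f2_sd=float(fsds[1]),
        f3_mean=float(fmeans[2]),
        f3_sd=float(fsds[2]),
        f4_mean=float(fmeans[3]),
        f4_sd=float(fsds[3]),
        hnr_db=hnr,
        unvoiced_fraction=pt.unvoiced_fraction,
        partial=partial,
        **jit,
        **shim,
    )


def features_to_frame(rows: dict[str, PhonationFeatures]):
    """One CSV-ready row per subject_id, columns in the documented order."""
    import pandas as pd

    data = {sid: f.to_dict() for sid, f in rows.items()}
    frame = pd.DataFrame.from_dict(data, orient="index", columns=list(_FEATURE_NAMES))
    frame.index.name = "subject_id"
    return frame
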