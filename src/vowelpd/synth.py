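"""Synthetic sustained-vowel cohorts with controlled dysphonia.

The generator follows the classical source-filter view of phonation: a
glottal pulse train (band-limited impulses with a -12 dB/octave spectral
tilt) drives a cascade of second-order formant resonators, with aspiration
noise added at a prescribed harmonics-to-noise ratio.  Dysphonic voice
quality is injected at the source:

- *jitter* — i.i.d. Gaussian cycle-length perturbation, calibrated so the
  standard "local" jitter estimator recovers the requested percentage in
  expectation (for i.i.d. Gaussian perturbation, E|eta_i - eta_{i-1}| =
  2*sigma/sqrt(pi), hence sigma = (pct/100) * sqrt(pi)/2);
- *shimmer* — the analogous per-cycle amplitude perturbation;
- *tremor* — slow sinusoidal F0 modulation ("ripples" of the harmonic
  lines across time);
- *distortions* — transient F0/amplitude deviation events, emulating the
  short subtle distortions and severe aperiodic stretches seen in
  Parkinsonian phonation.

Two channel conditions are modeled: a telephone line (0.3-3.4 kHz
band-pass, 8 kHz sampling) and a smartphone capture (full band at
44.1 kHz), both quantized to 16-bit words.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import filtfilt, firwin, lfilter, resample_poly

from vowelpd.errors import InvalidSpecError
from vowelpd.preprocess import Waveform, write_wav

#: Gaussian-sigma per unit of target local jitter/shimmer percentage:
#: E|eta_i - eta_{i-1}| = 2*sigma/sqrt(pi)  =>  sigma = pct/100 * sqrt(pi)/2.
PERTURBATION_CALIBRATION = math.sqrt(math.pi) / 2.0

#: default /a/ formants as (center Hz, bandwidth Hz)
DEFAULT_FORMANTS: tuple[tuple[float, float], ...] = (
    (700.0, 130.0),
    (1220.0, 70.0),
    (2600.0, 160.0),
    (3500.0, 200.0),
)

_PULSE_HALF_WIDTH = 40  # samples on each side of a band-limited pulse
_TILT_CORNER_HZ = 100.0  # one-pole corner; two poles give -12 dB/octave


@dataclass(frozen=True)
class VowelSpec:
    """Ground-truth parameters of one synthetic sustained /a/."""

    duration: float = 3.0
    f0: float = 120.0
    jitter_pct: float = 0.5
    shimmer_pct: float = 3.0
    tremor_rate: float = 5.0
    tremor_depth: float = 0.0
    hnr_db: float = 25.0
    formants: tuple[tuple[float, float], ...] = DEFAULT_FORMANTS
    distortion_rate: float = 0.0
    distortion_duration: float = 0.15

    def __post_init__(self) -> None:
        if self.duration < 1.5:
            raise InvalidSpecError(
                f"duration must be >= 1.5 s, got {self.duration}"
            )
        if not 60.0 <= self.f0 <= 400.0:
            raise InvalidSpecError(f"f0 must lie in [60, 400] Hz, got {self.f0}")
        if self.jitter_pct < 0 or self.shimmer_pct < 0:
            raise InvalidSpecError("jitter_pct and shimmer_pct must be >= 0")
        if not 0.0 <= self.tremor_depth <= 0.1:
            raise InvalidSpecError(
                f"tremor_depth must lie in [0, 0.1], got {self.tremor_depth}"
            )
        centers = [f for f, _ in self.formants]
        if any(b <= 0 for _, b in self.formants):
            raise InvalidSpecError("formant bandwidths must be positive")
        if any(c2 <= c1 for c1, c2 in zip(centers, centers[1:])):
            raise InvalidSpecError("formant centers must be strictly increasing")
        if self.distortion_rate < 0 or self.distortion_duration <= 0:
            raise InvalidSpecError("distortion parameters must be non-negative")


@dataclass(frozen=True)
class ChannelSpec:
    """Recording-channel model: passband, output rate and word length."""

    kind: str  # "telephone" | "smartphone"
    passband: tuple[float, float]
    target_fs: int
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.kind not in ("telephone", "smartphone"):
            raise InvalidSpecError(f"unknown channel kind {self.kind!r}")
        if self.kind == "telephone":
            lo, hi = self.passband
            if not (300.0 <= lo < hi <= 3400.0):
                raise InvalidSpecError(
                    "telephone passband must lie within 300-3400 Hz"
                )
            if self.target_fs != 8000:
                raise InvalidSpecError("telephone channel requires 8 kHz output")
        else:
            if self.target_fs != 44100:
                raise InvalidSpecError("smartphone channel requires 44.1 kHz output")
        if self.bit_depth != 16:
            raise InvalidSpecError("only 16-bit quantization is supported")


TELEPHONE = ChannelSpec(kind="telephone", passband=(300.0, 3400.0), target_fs=8000)
SMARTPHONE = ChannelSpec(kind="smartphone", passband=(0.0, 22050.0), target_fs=44100)


def _resonator_coeffs(center: float, bandwidth: float, fs: float):
    """Two-pole resonator (unit numerator); stability from bandwidth > 0."""
    r = math.exp(-math.pi * bandwidth / fs)
    theta = 2.0 * math.pi * center / fs
    return [1.0], [1.0, -2.0 * r * math.cos(theta), r * r]


def _band_limited_pulses(
    times_s: np.ndarray, amps: np.ndarray, n: int, fs: float
) -> np.ndarray:
    """Place windowed-sinc impulses at fractional sample positions."""
    out = np.zeros(n + 2 * _PULSE_HALF_WIDTH)
    m = np.arange(-_PULSE_HALF_WIDTH, _PULSE_HALF_WIDTH + 1, dtype=np.float64)
    cutoff = 0.45  # fraction of fs
    for t, a in zip(times_s, amps):
        pos = t * fs
        center = int(round(pos))
        frac = pos - center
        u = m - frac
        kernel = 2.0 * cutoff * np.sinc(2.0 * cutoff * u)
        # Blackman taper evaluated at the fractional offsets
        x = u / (_PULSE_HALF_WIDTH + 1)
        taper = 0.42 + 0.5 * np.cos(math.pi * x) + 0.08 * np.cos(2 * math.pi * x)
        out[center : center + 2 * _PULSE_HALF_WIDTH + 1] += a * kernel * taper
    return out[_PULSE_HALF_WIDTH : _PULSE_HALF_WIDTH + n]


def _spectral_tilt(x: np.ndarray, fs: float) -> np.ndarray:
    """-12 dB/octave roll-off above the glottal corner (two one-pole LPs)."""
    a = math.exp(-2.0 * math.pi * _TILT_CORNER_HZ / fs)
    for _ in range(2):
        x = lfilter([1.0 - a], [1.0, -a], x)
    return x


def synthesize_vowel(
    spec: VowelSpec, fs: int, seed: int | np.random.Generator
) -> Waveform:
    """Render one sustained vowel according to ``spec`` at rate ``fs``.

    Deterministic given ``seed``.  Output samples lie in [-1, 1] with the
    peak at 0.9 to leave headroom for channel filtering.
    """
    if fs not in (8000, 44100):
        raise InvalidSpecError(f"fs must be 8000 or 44100 Hz, got {fs}")
    if any(c >= fs / 2 for c, _ in spec.formants):
        raise InvalidSpecError("formant center at or above Nyquist")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # --- distortion events -------------------------------------------------
    n_events = rng.poisson(spec.distortion_rate * spec.duration)
    ev_times = np.sort(rng.uniform(0.0, spec.duration, size=n_events))
    ev_f0_dev = rng.uniform(0.02, 0.06, size=n_events) * rng.choice(
        [-1.0, 1.0], size=n_events
    )
    ev_amp = rng.uniform(0.45, 0.8, size=n_events)

    def event_factors(t: float) -> tuple[float, float]:
        f_dev, a_fac = 0.0, 1.0
        for te, fd, af in zip(ev_times, ev_f0_dev, ev_amp):
            if te <= t < te + spec.distortion_duration:
                f_dev += fd
                a_fac *= af
        return f_dev, a_fac

    # --- glottal cycle sequence -------------------------------------------
    sigma_j = spec.jitter_pct / 100.0 * PERTURBATION_CALIBRATION
    sigma_s = spec.shimmer_pct / 100.0 * PERTURBATION_CALIBRATION
    times, amps = [], []
    t = 1.0 / spec.f0  # settle-in before the first pulse
    while t < spec.duration - 1.0 / spec.f0:
        f_dev, a_fac = event_factors(t)
        f_inst = spec.f0 * (
            1.0
            + spec.tremor_depth * math.sin(2.0 * math.pi * spec.tremor_rate * t)
            + f_dev
        )
        eta = float(np.clip(rng.normal(0.0, sigma_j), -0.4, 0.4)) if sigma_j else 0.0
        xi = float(np.clip(rng.normal(0.0, sigma_s), -0.6, 0.6)) if sigma_s else 0.0
        times.append(t)
        amps.append((1.0 + xi) * a_fac)
        t += (1.0 / f_inst) * (1.0 + eta)

    n = int(round(spec.duration * fs))
    source = _band_limited_pulses(np.asarray(times), np.asarray(amps), n, fs)
    source = _spectral_tilt(source, fs)

    # --- vocal-tract filtering --------------------------------------------
    periodic = source
    for center, bandwidth in spec.formants:
        b, a = _resonator_coeffs(center, bandwidth, fs)
        periodic = lfilter(b, a, periodic)
    # the pulse train has a DC pedestal that the tilt and resonator filters
    # all pass; remove it so the HNR power accounting reflects the voiced
    # (AC) component only
    periodic = periodic - periodic.mean()

    # --- aspiration noise at the target HNR --------------------------------
    signal = periodic
    if np.isfinite(spec.hnr_db):
        noise = rng.standard_normal(n)
        for center, bandwidth in spec.formants:
            b, a = _resonator_coeffs(center, bandwidth, fs)
            noise = lfilter(b, a, noise)
        p_sig = float(np.mean(periodic**2))
        p_noise = float(np.mean(noise**2))
        if p_noise > 0:
            target = p_sig / (10.0 ** (spec.hnr_db / 10.0))
            noise = noise * math.sqrt(target / p_noise)
        signal = periodic + noise

    peak = float(np.max(np.abs(signal)))
    if peak == 0.0:
        raise InvalidSpecError("synthesis produced a silent signal")
    signal = 0.9 * signal / peak
    return Waveform(
        samples=signal,
        fs=fs,
        provenance=f"synthetic vowel f0={spec.f0:.1f}Hz fs={fs}",
    )


def apply_channel(w: Waveform, ch: ChannelSpec) -> Waveform:
    """Pass a waveform through the recording-channel model.

    Telephone: zero-phase FIR band-pass to the passband, resampling to
    8 kHz.  Smartphone: identity filter at 44.1 kHz.  Both paths quantize
    to the channel word length and rescale to [-1, 1].
    """
    if len(w.samples) == 0:
        raise InvalidSpecError("empty waveform")
    x = w.samples
    fs = w.fs
    if ch.kind == "telephone":
        numtaps = int(0.05 * fs) // 2 * 2 + 1  # ~50 ms, odd
        taps = firwin(numtaps, list(ch.passband), pass_zero=False, fs=fs)
        x = filtfilt(taps, [1.0], x)
        if fs != ch.target_fs:
            g = math.gcd(fs, ch.target_fs)
            x = resample_poly(x, ch.target_fs // g, fs // g)
            fs = ch.target_fs
    else:
        if fs != ch.target_fs:
            g = math.gcd(fs, ch.target_fs)
            x = resample_poly(x, ch.target_fs // g, fs // g)
            fs = ch.target_fs
    full_scale = 2 ** (ch.bit_depth - 1) - 1
    x = np.clip(x, -1.0, 1.0)
    x = np.round(x * full_scale) / full_scale
    return Waveform(
        samples=x, fs=fs, provenance=f"{w.provenance}; channel={ch.kind}"
    )


@dataclass(frozen=True)
class GroupRanges:
    """Uniform sampling ranges for one cohort group's vowel parameters."""

    f0_male: tuple[float, float]
    f0_female: tuple[float, float]
    jitter_pct: tuple[float, float]
    shimmer_pct: tuple[float, float]
    hnr_db: tuple[float, float]
    tremor_rate: tuple[float, float]
    tremor_depth: tuple[float, float]
    distortion_rate: tuple[float, float]
    duration: tuple[float, float] = (2.5, 4.0)


#: Healthy-control defaults: steady phonation, mild perturbation, clear voice.
#: Group F0 centers follow the printed smartphone-cohort means (males 116 Hz,
#: females 192 Hz for HC; 123 Hz / 188 Hz for PD).
HC_DEFAULTS = GroupRanges(
    f0_male=(106.0, 126.0),
    f0_female=(182.0, 202.0),
    jitter_pct=(0.2, 0.6),
    shimmer_pct=(1.5, 4.0),
    hnr_db=(20.0, 28.0),
    tremor_rate=(4.0, 6.0),
    tremor_depth=(0.0, 0.004),
    distortion_rate=(0.0, 0.0),
)

#: PD-like defaults: elevated jitter/shimmer, reduced HNR, F0 tremor ripples
#: and transient distortion events.
PD_DEFAULTS = GroupRanges(
    f0_male=(113.0, 133.0),
    f0_female=(178.0, 198.0),
    jitter_pct=(1.2, 3.0),
    shimmer_pct=(5.0, 11.0),
    hnr_db=(8.0, 16.0),
    tremor_rate=(4.0, 7.0),
    tremor_depth=(0.008, 0.03),
    distortion_rate=(0.3, 1.0),
)


@dataclass(frozen=True)
class CohortSpec:
    """A labeled two-group cohort under one channel condition."""

    n_pd: int
    n_hc: int
    channel: ChannelSpec = TELEPHONE
    pd: GroupRanges = PD_DEFAULTS
    hc: GroupRanges = HC_DEFAULTS
    male_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pd < 1 or self.n_hc < 1:
            raise InvalidSpecError("n_pd and n_hc must both be >= 1")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise InvalidSpecError("male_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class LabeledRecording:
    """One subject's recording with its label, sex and channel condition."""

    subject_id: str
    label: str  # "PD" | "HC"
    sex: str  # "M" | "F"
    waveform: Waveform
    channel: ChannelSpec
    spec: VowelSpec | None = field(repr=False, default=None)


def _sample_spec(rng: np.random.Generator, ranges: GroupRanges, sex: str) -> VowelSpec:
    u = lambda lo_hi: float(rng.uniform(*lo_hi))  # noqa: E731
    f0 = u(ranges.f0_male if sex == "M" else ranges.f0_female)
    return VowelSpec(
        duration=u(ranges.duration),
        f0=f0,
        jitter_pct=u(ranges.jitter_pct),
        shimmer_pct=u(ranges.shimmer_pct),
        tremor_rate=u(ranges.tremor_rate),
        tremor_depth=u(ranges.tremor_depth),
        hnr_db=u(ranges.hnr_db),
        distortion_rate=u(ranges.distortion_rate),
    )


def generate_cohort(
    cs: CohortSpec, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, list[LabeledRecording]]:
    """Generate ``n_pd + n_hc`` labeled recordings (one per subject).

    Deterministic given ``cs.seed``.  When ``out_dir`` is given, writes one
    PCM16 WAV per subject plus ``manifest.csv`` (columns ``subject_id,
    label, sex, path, channel``) and the cohort configuration as YAML; the
    manifest ``path`` column then references the written files.
    """
    synth_fs = 8000 if cs.channel.kind == "telephone" else 44100
    ss = np.random.SeedSequence(cs.seed)
    children = ss.spawn(cs.n_pd + cs.n_hc + 1)
    param_rng = np.random.default_rng(children[-1])

    recordings: list[LabeledRecording] = []
    rows = []
    labels = ["PD"] * cs.n_pd + ["HC"] * cs.n_hc
    for i, label in enumerate(labels):
        sex = "M" if param_rng.uniform() < cs.male_fraction else "F"
        ranges = cs.pd if label == "PD" else cs.hc
        spec = _sample_spec(param_rng, ranges, sex)
        voice = synthesize_vowel(spec, synth_fs, np.random.default_rng(children[i]))
        voice = apply_channel(voice, cs.channel)
        subject_id = f"{label.lower()}{i:04d}"
        recordings.append(
            LabeledRecording(
                subject_id=subject_id,
                label=label,
                sex=sex,
                waveform=voice,
                channel=cs.channel,
                spec=spec,
            )
        )
        rows.append(
            {
                "subject_id": subject_id,
                "label": label,
                "sex": sex,
                "path": f"{subject_id}.wav",
                "channel": cs.channel.kind,
            }
        )
    manifest = pd.DataFrame(rows, columns=["subject_id", "label", "sex", "path", "channel"])

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec in recordings:
            write_wav(rec.waveform, out_dir / f"{rec.subject_id}.wav")
        manifest = manifest.assign(
            path=[str(out_dir / f"{r.subject_id}.wav") for r in recordings]
        )
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        config = {
            "n_pd": cs.n_pd,
            "n_hc": cs.n_hc,
            "channel": cs.channel.kind,
            "male_fraction": cs.male_fraction,
            "seed": cs.seed,
        }
        (out_dir / "cohort.yaml").write_text(yaml.safe_dump(config))
    return manifest, recordings
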