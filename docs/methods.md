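# Methods

This note documents the models, estimators and numerical choices behind
`vowelpd`, in the order the pipeline applies them.

## Synthetic voice model

The generator follows the source-filter view of sustained phonation. The
glottal source is a train of band-limited impulses (81-tap windowed-sinc
kernels placed at *fractional* sample positions, so cycle lengths are
not quantized to the sample grid) with a −12 dB/octave spectral tilt
realized as two cascaded one-pole low-pass filters cornered at 100 Hz.
The vocal tract is a cascade of second-order resonators; the default /a/
formants are (700, 130), (1220, 70), (2600, 160), (3500, 200) Hz
(center, bandwidth), chosen because group differences in this task
concentrate near the first two /a/ formants. The pulse train carries a
DC pedestal that every filter in the chain passes; the periodic path is
therefore mean-removed before power accounting, otherwise the
harmonics-to-noise calibration would be biased by several dB.

Dysphonia parameters, all per `VowelSpec`:

| parameter | meaning | units | default |
|---|---|---|---|
| `f0` | fundamental frequency | Hz | 120 |
| `jitter_pct` | target local jitter | % of mean period | 0.5 |
| `shimmer_pct` | target local shimmer | % of mean amplitude | 3 |
| `hnr_db` | harmonics-to-noise ratio | dB | 25 |
| `tremor_rate`, `tremor_depth` | slow sinusoidal F0 modulation | Hz, fraction | 5, 0 |
| `distortion_rate`, `distortion_duration` | transient F0/amplitude deviation events | events/s, s | 0, 0.15 |

Jitter is injected as i.i.d. Gaussian cycle-length perturbation. For
i.i.d. Gaussian η with standard deviation σ, the expected local jitter
E|η_i − η_{i−1}| equals 2σ/√π, so the generator uses the closed-form
calibration σ = (jitter_pct/100)·√π/2; shimmer is calibrated
identically on the amplitude side. Aspiration noise is white noise
passed through the same resonator cascade and scaled so the AC-power
ratio of periodic to noise paths equals `hnr_db`.

The channel model is a zero-phase FIR band-pass (300–3400 Hz, ~50 ms of
taps, applied forward-backward) plus resampling to 8 kHz for the
telephone condition, or the identity at 44.1 kHz for the smartphone
condition; both quantize to 16-bit words. Zero-phase filtering avoids a
phase-distortion confound between the two conditions.

Cohort defaults encode the group structure the analysis assumes: HC
jitter 0.2–0.6%, shimmer 1.5–4%, HNR 20–28 dB, negligible tremor and no
distortion events; PD jitter 1.2–3%, shimmer 5–11%, HNR 8–16 dB, tremor
depth 0.8–3% at 4–7 Hz, 0.3–1 distortion events/s. Group F0 centers are
116/123 Hz (HC/PD males) and 192/188 Hz (HC/PD females), the published
smartphone-cohort means. Durations are uniform on 2.5–4 s
(telephone-cohort-like). Ranges are uniform and configurable, so the
PD–HC effect size can be widened or collapsed. No quantitative
distribution of PD perturbations is published for these cohorts; the
defaults are chosen for estimator testability, not clinical realism.

**What the generator does not emulate**: articulatory dynamics, room
acoustics and device nonlinearities, ambient noise, vocal fry, and the
age/sex covariate structure of real cohorts. Passing tests demonstrate
that the estimators and the evaluation harness behave correctly on
signals with known ground truth — not that real PD voices are separable
at any particular AUC.

## Preprocessing

Fixed order: rescale to [−1, 1] → (decimate smartphone recordings by 5
with a zero-phase FIR anti-alias filter cut at 0.45 of the output rate)
→ trim silence → select the longest voiced segment → clip 1.5 s at the
midpoint. The silence gate uses 25 ms windows, 10 ms hop, and retains
the span of frames whose energy exceeds 1% (−20 dB) of the maximum
frame energy; when the first/last frame passes, the retained span
extends to the signal edge so that re-running the chain on its own clip
reproduces the clip. Voicing requires a normalized-autocorrelation peak
above 0.45 within 60–500 Hz *and* energy above the silence gate;
unvoiced gaps up to 0.25 s are bridged inside one phonation (transient
distortions must not split a take), while longer pauses separate
repeated attempts. Recordings shorter than 1.5 s after trimming are
excluded with a machine-readable `too-short` reason.

Two analysis rates are supported: 8000 Hz (telephone) and 8820 Hz
(44.1 kHz decimated by 5). The documented window counts (205 and 424
spectral windows for 3.3 s and 6.8 s recordings; 48 linear and 260 mel
spectrogram windows for a 1.5 s clip) are reproduced at 8000 Hz for the
spectral features and 8820 Hz for the spectrograms respectively.

## Pitch, cycles, and the phonation vector

The pitch tracker computes, per 10 ms hop over a window of three periods
of the lowest tracked pitch (60 Hz), a normalized autocorrelation in
which lag k's raw autocorrelation is divided by the geometric mean of
the energies of the two k-shifted sub-frames. Two details matter:

- the autocorrelation is trigonometrically interpolated (zero-padded
  spectrum) to 4× lag resolution before peak-picking, because the peak
  of a wide-band voiced frame is only a few samples wide and integer-lag
  sampling can understate its height by several percent — enough to bias
  HNR by ~5 dB and voicing decisions near threshold;
- among local maxima within 0.02 of the global maximum the *shortest*
  lag wins (octave guard), and a post-pass snaps isolated halving or
  doubling errors back to the track median.

Glottal cycles are marked by waveform matching: each period is the
normalized-cross-correlation lag (parabolically refined) between the
current cycle and the signal one expected period later, searched over
[0.8, 1.25] of the locally expected period, with the expected period
clamped to [0.75, 1.33] of the track median. Template matching repeats
exactly on a perfectly periodic signal, so the measured jitter floor is
~0.05%; simple peak-picking was tried first and breaks above ~1%
injected jitter. Near the signal edges the template shrinks (floor 0.4
periods) so the first and last cycles are still marked; two to three
edge cycles per recording remain unmeasurable in principle. Per-cycle
amplitudes are parabolically interpolated waveform maxima; resonator
ringing smooths amplitude modulation, so measured shimmer understates
the injected value by ~15–25% at high levels while remaining strictly
monotone (rank correlation > 0.97).

Jitter and shimmer follow the standard voice-report formulas on this
cycle sequence. DDP and DDA are computed literally as 3·RAP and 3·APQ3
(the algebraic identities hold to machine precision by construction).
HNR per voiced frame is 10·log10(r/(1−r)) at the pitch lag, averaged
over frames and capped at +40 dB. Formants come from LPC root-finding
(order 2 + fs/1000, pre-emphasis 0.97, Hamming window; candidates
require 90 Hz < f < fs/2 − 50 Hz and bandwidth < 400 Hz, assigned
ascending); a partial-result flag is set when more than half of the
frames yield fewer than four candidates.

The published feature set enumerates 22 nameable entries (2 F0 + 8
formant + 1 HNR + 5 jitter + 6 shimmer) but counts 23; the identity of
the 23rd is not listed anywhere. This package fills the slot with the
unvoiced frame fraction, a standard voice-report quantity, and documents
the choice here. All 23 entries are invariant to global gain, exactly.

## Spectral features

No pre-emphasis is applied before AR analysis, matching plain
autocorrelation-method defaults; frames are raw (untapered) 256-sample
windows. The biased autocorrelation estimator guarantees |k_i| < 1 and
hence finite log-area ratios. MFCC uses 26 mel filters (a conventional
count; the filter count is a config knob for parity studies), natural
logs, an orthonormal DCT-II, and excludes c0 so the retained
coefficients are exactly gain-invariant. Silent frames produce zero LPC
vectors and floored log energies rather than errors. Mean and *sample*
variance (ddof = 1) summarize each coefficient track; variance requires
at least two frames.

## Spectrograms

The mel recipe's nominal 90% overlap of a 512-sample window implies a
non-integer hop of 51.2; this implementation fixes hop = 51 with
reflect center-padding, a dialect choice that yields floor(n/51) + 1 =
260 windows for the 1.5 s clip at 8820 Hz. The linear recipe uses no
padding (floor((n − 1024)/256) + 1 = 48 windows). Rendering maps values
in [−80, 0] through a fixed perceptually-uniform colormap ("magma",
stamped into the image object) and bilinearly resizes to 600×600; PNG
is the default (lossless, bit-reproducible), JPEG quality 95 is a
compatibility option. Group-average difference maps subtract
element-wise group means of matched-shape matrices.

## Classifiers and evaluation

The random forest uses the study hyperparameters (1000 trees, 6
candidate variables per split, terminal node size 5; ceil(√p) when
fewer than 6 features exist). Stepwise logistic regression standardizes
features, then adds at each step the candidate minimizing the AIC,
accepting it only if it also lowers the 3-fold cross-validated
log-loss; without that guard, screening ~30 candidates admits several
noise features per fit because the best-of-p in-sample likelihood gain
clears the AIC penalty by selection alone. Perfect separation falls
back to an L2-penalized fit and is flagged.

The CNN path is transfer-learning shaped: a frozen convolutional
backbone feeds a trainable head (batchnorm → two dense-1024 relu layers
→ dropout 0.2 → 2-class softmax; Adam at 1e-3, 10 epochs, batch 4). The
shipped backbone is the "tiny-random" option — a fixed-seed two-layer
random convolutional network with 4×4 average pooling (512 features)
accepting 128×128 images. Random convolutional features preserve local
spectro-temporal structure well enough for the head to classify
separable spectrograms, keep the model dependency-free and
deterministic, and any callable image→feature map can be plugged in
instead. Batch normalization is realized as standardization with
statistics frozen from the training set (the inference-mode view, which
is what a frozen-backbone small-data setup reduces to); dropout is
active only during training.

Repeated holdout draws simple random (unstratified) 70/30 splits at the
subject level — one recording per subject makes row splits
identity-independent by construction; splits missing a class on either
side are resampled and counted. Within the harness, frozen backbone
features are computed once and shared across iterations. AUC is the
tie-corrected Mann–Whitney rank statistic. The AUC-distribution
comparison is the unpaired two-sided Wilcoxon rank-sum test (exact for
small samples without ties), with a paired signed-rank option, since
pairing of iterations across representations is not inherent to the
design. Shapley importance uses permutation sampling: each draw walks a
random feature permutation from a random background row toward the
observation, attributing the marginal probability change to the flipped
feature; per-draw contributions telescope to f(x) − f(background).

A label-permutation control must refresh the permutation across
replicates: holdout iterations of a single fixed permutation retain
that permutation's chance alignment with the features and sit visibly
above 0.5.

## Problem sizes and numerical conventions

Tests and the acceptance script use 30+30 synthetic cohorts, 20 holdout
iterations for the random forest, 5 for the CNN head, 100 random AR
systems for the DSP oracles, and 100 replicates for the comparison
power check — sizes chosen so the whole suite completes in minutes on
one CPU while keeping Monte-Carlo error well inside the asserted
margins. Log floors: 1e-10 relative (spectrograms), 1e-12 absolute (mel
energies); HNR caps at 40 dB; seeds fan out from one global seed by
SHA-256 stage-name hashing, keeping every derived seed below 2^31.

## Known limitations

- Shimmer is recovered with a systematic multiplicative deficit at high
  levels (resonator smoothing of per-cycle peaks); ranking is preserved.
- The cycle extractor cannot mark the outermost two or three cycles of
  a phonation.
- Formant estimates assume a telephone-like band; the fourth formant
  sits close to the band edge at 8 kHz and is the least reliable entry.
- The tiny-random backbone is not a pretrained network; absolute AUCs
  on real spectrograms are not comparable to a pretrained-backbone
  deployment, only the harness behavior is.
- Exact numerical parity with any specific external phonation-analysis
  tool is out of scope; the contracts are the formulas documented here
  applied to this package's own cycle sequence.
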