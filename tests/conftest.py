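"""Shared fixtures: synthetic voices and a reusable labeled cohort.

Everything is generated programmatically at test time; the cohort fixture
is session-scoped because synthesizing and featurizing 60 recordings is
the dominant cost of the suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from vowelpd.acoustic import assemble_phonation_features
from vowelpd.evaluate import FeatureDataset, ImageDataset
from vowelpd.pipeline import _image_for_backbone
from vowelpd.preprocess import Waveform, preprocess_recording
from vowelpd.spectral import coefficient_track, combine_features, summarize_coefficients
from vowelpd.spectrogram import mel_spectrogram
from vowelpd.synth import CohortSpec, VowelSpec, synthesize_vowel, generate_cohort

COHORT_SEED = 20240901  # fixed study-conditions seed for the shared cohort


@pytest.fixture(scope="session")
def clean_vowel():
    """Perfectly periodic 150 Hz /a/ at 8 kHz (no perturbation, no noise)."""
    spec = VowelSpec(
        duration=3.0,
        f0=150.0,
        jitter_pct=0.0,
        shimmer_pct=0.0,
        tremor_depth=0.0,
        hnr_db=np.inf,
    )
    return synthesize_vowel(spec, 8000, seed=1)


@pytest.fixture(scope="session")
def sine_150():
    """Pure 150 Hz sine, 1.5 s at 8 kHz."""
    t = np.arange(0, 1.5, 1 / 8000)
    return Waveform(samples=0.9 * np.sin(2 * np.pi * 150.0 * t), fs=8000)


@pytest.fixture(scope="session")
def cohort():
    """30 PD-like + 30 HC-like telephone-channel recordings with features.

    Returns a dict with the raw recordings, the combined
    variance-MFCC + phonation feature dataset, and the mel-spectrogram
    image dataset (backbone-sized), shared across evaluation tests.
    """
    cs = CohortSpec(n_pd=30, n_hc=30, seed=COHORT_SEED)
    _, recordings = generate_cohort(cs)

    subjects, labels, combined, images = [], {}, [], []
    phonation = {}
    for rec in recordings:
        res = preprocess_recording(rec.waveform)
        pf = assemble_phonation_features(res.voiced)
        track = coefficient_track(res.voiced, "mfcc")
        summary = summarize_coefficients(track, rec.subject_id)
        combined.append(combine_features(summary, pf, rec.subject_id, "var"))
        images.append(_image_for_backbone(mel_spectrogram(res.clip)))
        subjects.append(rec.subject_id)
        labels[rec.subject_id] = rec.label
        phonation[rec.subject_id] = pf

    y = np.array([1 if labels[s] == "PD" else 0 for s in subjects])
    features = FeatureDataset(
        X=np.vstack([v.values for v in combined]),
        y=y,
        subject_ids=tuple(subjects),
        feature_names=combined[0].names,
    )
    image_ds = ImageDataset(
        images=np.stack(images),
        y=y,
        subject_ids=tuple(subjects),
        scale="mel",
    )
    return {
        "recordings": recordings,
        "phonation": phonation,
        "features": features,
        "images": image_ds,
    }
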