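"""Configuration-driven orchestration of the full analysis pipeline.

A single YAML config drives: cohort synthesis (or a user-supplied WAV
manifest) -> preprocessing with per-recording exclusion bookkeeping ->
phonation + spectral feature extraction -> spectrogram image generation
-> repeated-holdout evaluation -> a JSON report with per-stage counts,
AUC summaries, importance tables and scale-comparison p-values.

One global seed fans out to per-stage seeds through stable name hashing,
so deleting intermediate outputs and re-running reproduces identical
results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from pydantic import BaseModel, ConfigDict, Field, ValidationError

import vowelpd
from vowelpd.acoustic import assemble_phonation_features, features_to_frame
from vowelpd.errors import (
    ConfigError,
    DegenerateInputError,
    InsufficientCyclesError,
    TooShortError,
    VowelPDError,
)
from vowelpd.evaluate import (
    EvalResult,
    FeatureDataset,
    ImageDataset,
    ModelSpec,
    compare_auc_distributions,
    fit_random_forest,
    repeated_holdout,
)
from vowelpd.nnet import TINY_INPUT_SIZE
from vowelpd.preprocess import Waveform, preprocess_recording, read_wav
from vowelpd.spectral import coefficient_track, combine_features, summarize_coefficients
from vowelpd.spectrogram import (
    linear_spectrogram,
    mel_spectrogram,
    render_spectrogram_image,
    save_image,
)
from vowelpd.synth import SMARTPHONE, TELEPHONE, CohortSpec, generate_cohort

SMARTPHONE_DECIMATION = 5  # 44.1 kHz -> 8.82 kHz before analysis


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed below 2**31 by hashing the stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class PipelineConfig(BaseModel):
    """Validated pipeline settings; defaults equal the study settings."""

    model_config = ConfigDict(extra="forbid")

    channel: Literal["telephone", "smartphone"] = "telephone"
    n_pd: int = Field(default=30, ge=1)
    n_hc: int = Field(default=30, ge=1)
    manifest: str | None = None  # use real recordings instead of synthesis
    feature_kinds: list[Literal["lpc", "lar", "lpcc", "mfcc"]] = Field(
        default_factory=lambda: ["mfcc"]
    )
    spectral_stat: Literal["mean", "var"] = "var"
    spectrogram_scales: list[Literal["linear", "mel"]] = Field(
        default_factory=lambda: ["mel", "linear"]
    )
    models: list[Literal["random_forest", "stepwise_lr", "cnn_head"]] = Field(
        default_factory=lambda: ["random_forest", "cnn_head"]
    )
    n_iter: int = Field(default=100, ge=1)
    train_frac: float = Field(default=0.7, gt=0.0, lt=1.0)
    seed: int = 0
    out_dir: str = "vowelpd_run"
    save_images: bool = False


def validate_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML/JSON config file.

    An empty (or absent) file yields all defaults; unknown keys and
    out-of-range values raise :class:`ConfigError` naming the offender.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw)}")
    try:
        return PipelineConfig(**raw)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigError(f"invalid config: {details}") from exc


@dataclass
class RunReport:
    """Machine-readable account of one pipeline run."""

    config: dict
    version: str
    counts: dict = field(default_factory=dict)
    exclusions: list[dict] = field(default_factory=list)
    eval_summaries: dict = field(default_factory=dict)
    importance: dict = field(default_factory=dict)
    comparisons: dict = field(default_factory=dict)
    log: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=float)


def _load_manifest_recordings(manifest_path: str) -> list[tuple[str, str, Waveform]]:
    frame = pd.read_csv(manifest_path)
    required = {"subject_id", "label", "path"}
    missing = required - set(frame.columns)
    if missing:
        raise ConfigError(f"manifest missing columns: {sorted(missing)}")
    out = []
    base = Path(manifest_path).parent
    for row in frame.itertuples():
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        out.append((str(row.subject_id), str(row.label), read_wav(p)))
    return out


def _image_for_backbone(matrix) -> np.ndarray:
    """Render a spectrogram matrix and resize to the backbone input size."""
    img = render_spectrogram_image(matrix)
    small = Image.fromarray(img.pixels, mode="RGB").resize(
        (TINY_INPUT_SIZE, TINY_INPUT_SIZE), resample=Image.BILINEAR
    )
    return np.asarray(small, dtype=np.float64) / 255.0


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full pipeline and write report + CSVs to ``out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.model_dump(), version=vowelpd.__version__)

    # --- stage 1: obtain recordings ---------------------------------------
    if config.manifest:
        triples = _load_manifest_recordings(config.manifest)
    else:
        channel = TELEPHONE if config.channel == "telephone" else SMARTPHONE
        cs = CohortSpec(
            n_pd=config.n_pd,
            n_hc=config.n_hc,
            channel=channel,
            seed=stage_seed(config.seed, "synth"),
        )
        manifest, recordings = generate_cohort(cs)
        triples = [(r.subject_id, r.label, r.waveform) for r in recordings]
    report.counts["recordings_in"] = len(triples)

    # --- stage 2: preprocessing with exclusion bookkeeping -----------------
    decim = SMARTPHONE_DECIMATION if config.channel == "smartphone" else None
    processed = {}
    labels = {}
    for subject_id, label, wav in triples:
        try:
            processed[subject_id] = preprocess_recording(wav, decimate_factor=decim)
            labels[subject_id] = label
            report.log.append(
                {"stage": "preprocess", "subject_id": subject_id, "status": "ok"}
            )
        except TooShortError:
            report.exclusions.append(
                {"subject_id": subject_id, "reason": "too-short"}
            )
        except (DegenerateInputError, InsufficientCyclesError):
            report.exclusions.append(
                {"subject_id": subject_id, "reason": "unvoiced"}
            )
        except VowelPDError:
            report.exclusions.append(
                {"subject_id": subject_id, "reason": "unreadable"}
            )
    report.counts["recordings_processed"] = len(processed)
    report.counts["recordings_excluded"] = len(report.exclusions)
    if len(processed) < 4:
        report.counts["error"] = "too few processable recordings"
        (out_dir / "report.json").write_text(report.to_json())
        return report

    # --- stage 3: features --------------------------------------------------
    phonation = {}
    for subject_id, res in processed.items():
        try:
            phonation[subject_id] = assemble_phonation_features(res.voiced)
        except VowelPDError:
            report.exclusions.append(
                {"subject_id": subject_id, "reason": "unvoiced"}
            )
    subjects = sorted(phonation)
    features_to_frame(phonation).to_csv(out_dir / "phonation_features.csv")

    combined_sets: dict[str, FeatureDataset] = {}
    for kind in config.feature_kinds:
        vecs = []
        for subject_id in subjects:
            track = coefficient_track(processed[subject_id].voiced, kind)
            summary = summarize_coefficients(track, subject_id)
            vecs.append(
                combine_features(
                    summary, phonation[subject_id], subject_id, config.spectral_stat
                )
            )
        X = np.vstack([v.values for v in vecs])
        y = np.array([1 if labels[s] == "PD" else 0 for s in subjects])
        combined_sets[kind] = FeatureDataset(
            X=X,
            y=y,
            subject_ids=tuple(subjects),
            feature_names=vecs[0].names,
        )
        pd.DataFrame(X, index=subjects, columns=list(vecs[0].names)).to_csv(
            out_dir / f"combined_{kind}_{config.spectral_stat}.csv"
        )

    # --- stage 4: spectrogram images ---------------------------------------
    image_sets: dict[str, ImageDataset] = {}
    for scale in config.spectrogram_scales:
        make = mel_spectrogram if scale == "mel" else linear_spectrogram
        images = []
        kept = []
        for subject_id in subjects:
            try:
                matrix = make(processed[subject_id].clip)
            except VowelPDError:
                report.exclusions.append(
                    {"subject_id": subject_id, "reason": "too-short"}
                )
                continue
            images.append(_image_for_backbone(matrix))
            kept.append(subject_id)
            if config.save_images:
                save_image(
                    render_spectrogram_image(matrix, subject_id=subject_id),
                    out_dir / "images" / f"{subject_id}_{scale}.png",
                )
        image_sets[scale] = ImageDataset(
            images=np.stack(images),
            y=np.array([1 if labels[s] == "PD" else 0 for s in kept]),
            subject_ids=tuple(kept),
            scale=scale,
        )
    report.counts["subjects_with_features"] = len(subjects)

    # --- stage 5: evaluation ------------------------------------------------
    auc_rows = []
    for model_kind in config.models:
        if model_kind in ("random_forest", "stepwise_lr"):
            for kind, ds in combined_sets.items():
                name = f"{kind}_{config.spectral_stat}+phonation"
                result = repeated_holdout(
                    ds,
                    ModelSpec(kind=model_kind),
                    n_iter=config.n_iter,
                    train_frac=config.train_frac,
                    seed=stage_seed(config.seed, f"eval:{model_kind}:{kind}"),
                )
                report.eval_summaries.setdefault(name, {})[model_kind] = (
                    result.summary()
                )
                auc_rows.append(
                    pd.DataFrame(
                        {
                            "feature_set": name,
                            "model": model_kind,
                            "iteration": np.arange(len(result.aucs)),
                            "auc": result.aucs,
                        }
                    )
                )
                if model_kind == "random_forest":
                    _, gini = fit_random_forest(
                        ds, seed=stage_seed(config.seed, f"gini:{kind}")
                    )
                    report.importance[name] = gini.values.to_dict()
        else:  # cnn_head on each spectrogram scale
            scale_results: dict[str, EvalResult] = {}
            for scale, ids in image_sets.items():
                result = repeated_holdout(
                    ids,
                    ModelSpec(kind="cnn_head"),
                    n_iter=config.n_iter,
                    train_frac=config.train_frac,
                    seed=stage_seed(config.seed, f"eval:cnn:{scale}"),
                )
                scale_results[scale] = result
                report.eval_summaries.setdefault(f"spectrogram_{scale}", {})[
                    "cnn_head"
                ] = result.summary()
                auc_rows.append(
                    pd.DataFrame(
                        {
                            "feature_set": f"spectrogram_{scale}",
                            "model": "cnn_head",
                            "iteration": np.arange(len(result.aucs)),
                            "auc": result.aucs,
                        }
                    )
                )
            if {"mel", "linear"} <= set(scale_results):
                stat, p = compare_auc_distributions(
                    scale_results["mel"], scale_results["linear"]
                )
                report.comparisons["mel_vs_linear"] = {
                    "statistic": stat,
                    "p_value": p,
                }

    if auc_rows:
        pd.concat(auc_rows, ignore_index=True).to_csv(
            out_dir / "auc_iterations.csv", index=False
        )
    (out_dir / "report.json").write_text(report.to_json())
    with (out_dir / "log.jsonl").open("w") as fh:
        for record in report.log:
            fh.write(json.dumps(record) + "\n")
    return report


def summarize_results(reports: list[RunReport]) -> pd.DataFrame:
    """Mean-AUC comparison table across one or more run reports.

    Rows are feature sets / representations, columns classifiers, cells
    the mean held-out AUC formatted to 2 decimals; a Wilcoxon column is
    appended when a report carries a mel-vs-linear comparison.
    """
    if not reports:
        raise ValueError("need at least one report")
    cells: dict[str, dict[str, str]] = {}
    comparisons = {}
    for rep in reports:
        for feature_set, by_model in rep.eval_summaries.items():
            for model, summary in by_model.items():
                cells.setdefault(feature_set, {})[model] = f"{summary['mean']:.2f}"
        comparisons.update(rep.comparisons)
    table = pd.DataFrame.from_dict(cells, orient="index").fillna("")
    table.index.name = "feature_set"
    if comparisons:
        for name, cmp_ in comparisons.items():
            table[f"wilcoxon_{name}_p"] = f"{cmp_['p_value']:.3g}"
    return table
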