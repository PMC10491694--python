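"""Training loop and the per-video macro-averaged evaluation protocol.

Training re-augments every training video with a freshly sampled plan each
epoch (mode-dependent: none, the hand-designed 'custom' trio, RA, URA, or
TRA), caches per-frame features in a buffer that is reset at the end of
each video, and optimizes the temporal network with Adam under a
class-weighted cross-entropy loss.  Model selection keeps the epoch with
the best validation F1.

Evaluation follows the per-video protocol: accuracy plus macro-averaged
precision/recall/F1 over the classes present in each video's ground truth,
then an unweighted mean over videos.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, precision_recall_fscore_support

from .augment_core import (
    AugmentPolicy,
    randaugment,
    trandaugment,
    uniform_randaugment,
)
from .model import (
    FeatureBuffer,
    FeatureExtractorSpec,
    FramePredictions,
    SSTCN,
    SSTCNSpec,
    build_extractor,
    compute_class_weights,
    extract_features,
)
from .transform_bank import TransformBank
from .video_io import DatasetManifest, VideoSample, load_frames, load_labels

AUGMENT_MODES = ("none", "custom", "ra", "ura", "tra")

# the manually designed baseline augmentation trio, applied video-uniformly
CUSTOM_SUBSET = ("horizontal-flip", "saturation", "rotate")


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults: 50 epochs, lr 1e-5, batch 64)."""

    epochs: int = 50
    learning_rate: float = 1e-5
    batch_size: int = 64
    augment_mode: str = "tra"
    policy: AugmentPolicy = field(default_factory=AugmentPolicy)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.augment_mode not in AUGMENT_MODES:
            raise ValueError(f"augment_mode must be one of {AUGMENT_MODES}")


@dataclass
class MetricReport:
    """Per-video ACC/PR/RE/F1 plus the unweighted mean over videos."""

    per_video: dict[str, dict[str, float]]
    aggregate: dict[str, float]

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"per_video": self.per_video, "aggregate": self.aggregate},
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_csv(self, path) -> None:
        rows = [{"video_id": vid, **m} for vid, m in sorted(self.per_video.items())]
        rows.append({"video_id": "__aggregate__", **self.aggregate})
        pd.DataFrame(rows).to_csv(path, index=False)


def _as_label_array(pred) -> np.ndarray:
    if isinstance(pred, FramePredictions):
        return pred.labels
    return np.asarray(pred, dtype=np.int64)


def evaluate(
    predictions: Mapping[str, Union[FramePredictions, np.ndarray]],
    truths: Mapping[str, np.ndarray],
) -> MetricReport:
    """Per-video metrics, macro-averaged across the classes present in each
    video's ground truth, then averaged (unweighted) across videos."""
    if not truths:
        raise ValueError("empty video set")
    per_video: dict[str, dict[str, float]] = {}
    for vid, truth in truths.items():
        truth = np.asarray(truth, dtype=np.int64)
        pred = _as_label_array(predictions[vid])
        if len(pred) != len(truth):
            raise ValueError(f"{vid}: prediction/truth length mismatch")
        present = np.unique(truth)
        pr, re, f1, _ = precision_recall_fscore_support(
            truth, pred, labels=present, average="macro", zero_division=0
        )
        per_video[vid] = {
            "ACC": float(accuracy_score(truth, pred)),
            "PR": float(pr),
            "RE": float(re),
            "F1": float(f1),
        }
    # average in sorted-id order so the aggregate is independent of the
    # caller's video ordering (bit-exact)
    ordered = [per_video[vid] for vid in sorted(per_video)]
    aggregate = {
        k: float(np.mean([m[k] for m in ordered])) for k in ("ACC", "PR", "RE", "F1")
    }
    return MetricReport(per_video=per_video, aggregate=aggregate)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _augment_for_epoch(
    sample: VideoSample,
    config: TrainConfig,
    epoch: int,
    video_index: int,
    bank: Optional[TransformBank],
) -> np.ndarray:
    """A fresh augmentation plan per (video, epoch); 'none' is a no-op."""
    mode = config.augment_mode
    if mode == "none":
        return sample.frames
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, epoch, video_index])
    )
    policy = config.policy
    if mode == "custom":
        policy = replace(policy, subset=CUSTOM_SUBSET, N=max(policy.N, 1))
        return uniform_randaugment(sample.frames, policy, bank=bank, rng=rng)
    if mode == "ura":
        return uniform_randaugment(sample.frames, policy, bank=bank, rng=rng)
    if mode == "ra":
        return randaugment(sample.frames, policy, bank=bank, rng=rng)
    return trandaugment(sample.frames, policy, bank=bank, rng=rng)


def buffered_features(
    frames: np.ndarray,
    extractor_spec: FeatureExtractorSpec,
    extractor: Callable[[np.ndarray], np.ndarray],
    batch_size: int,
    video_id: str = "",
) -> np.ndarray:
    """Extract features batch-by-batch through a per-video buffer, returning
    the full Υ×f matrix; the buffer is reset at the end of the video."""
    buffer = FeatureBuffer(video_id)
    for start in range(0, frames.shape[0], batch_size):
        chunk = frames[start : start + batch_size]
        buffer.append(extract_features(chunk, extractor_spec, extractor=extractor))
    feats = buffer.features
    buffer.reset()
    return feats


def predict_video(
    sample: VideoSample,
    extractor_spec: FeatureExtractorSpec,
    extractor: Callable[[np.ndarray], np.ndarray],
    model: SSTCN,
    batch_size: int = 64,
) -> FramePredictions:
    feats = buffered_features(
        sample.frames, extractor_spec, extractor, batch_size, sample.video_id
    )
    return model.predict(feats)


@dataclass
class TrainResult:
    model: SSTCN
    report: MetricReport  # validation report of the selected epoch
    best_epoch: int
    history: dict


def load_split(
    manifest: DatasetManifest,
    split: str,
    root,
    target_size: tuple[int, int],
) -> list[VideoSample]:
    """Materialize one manifest split as VideoSamples."""
    root = Path(root)
    samples = []
    for entry in manifest.split(split):
        sample = load_frames(
            root / entry["frames"],
            target_size=target_size,
            video_id=entry["video_id"],
        )
        sample.labels = load_labels(
            root / entry["labels"], sample.n_frames, manifest.class_names
        )
        samples.append(sample)
    return samples


def train(
    train_samples: Sequence[VideoSample],
    val_samples: Sequence[VideoSample],
    extractor_spec: FeatureExtractorSpec,
    tcn_spec: SSTCNSpec,
    config: TrainConfig,
    bank: Optional[TransformBank] = None,
) -> TrainResult:
    """Train the temporal model; returns the best-validation-F1 checkpoint.

    Per epoch: videos are shuffled, each video is re-augmented with a fresh
    plan, its frames pass through the (frozen) extractor into the feature
    buffer, and one weighted-cross-entropy Adam step is taken over the full
    cached sequence.  The buffer is reset at each video end.  Fully
    deterministic given the config seed.
    """
    if not train_samples or not val_samples:
        raise ValueError("train and val splits must be non-empty")
    for s in list(train_samples) + list(val_samples):
        if s.labels is None:
            raise ValueError(f"{s.video_id}: missing labels")

    extractor = build_extractor(extractor_spec)
    model = SSTCN(tcn_spec, seed=config.seed)
    counts = np.bincount(
        np.concatenate([s.labels for s in train_samples]), minlength=tcn_spec.n_classes
    )
    weights = compute_class_weights(counts)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2**20]))

    # features of unaugmented validation videos never change; cache them
    val_feats = [
        buffered_features(
            s.frames, extractor_spec, extractor, config.batch_size, s.video_id
        )
        for s in val_samples
    ]

    history: dict = {"train_loss": [], "val_f1": [], "plan_signatures": []}
    best_f1, best_epoch, best_params, best_report = -1.0, -1, None, None
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(train_samples))
        losses = []
        for v in order:
            sample = train_samples[int(v)]
            frames = _augment_for_epoch(sample, config, epoch, int(v), bank)
            history["plan_signatures"].append(
                (epoch, sample.video_id, int(np.asarray(frames).sum()))
            )
            feats = buffered_features(
                frames, extractor_spec, extractor, config.batch_size, sample.video_id
            )
            losses.append(
                model.train_step(feats, sample.labels, weights, config.learning_rate)
            )
        history["train_loss"].append(float(np.mean(losses)))

        preds = {
            s.video_id: model.predict(f) for s, f in zip(val_samples, val_feats)
        }
        report = evaluate(preds, {s.video_id: s.labels for s in val_samples})
        history["val_f1"].append(report.aggregate["F1"])
        # ties keep the most recent checkpoint (more training at equal val F1)
        if report.aggregate["F1"] >= best_f1:
            best_f1 = report.aggregate["F1"]
            best_epoch = epoch
            best_params = copy.deepcopy(model.params)
            best_report = report

    model.params = best_params
    return TrainResult(
        model=model, report=best_report, best_epoch=best_epoch, history=history
    )
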