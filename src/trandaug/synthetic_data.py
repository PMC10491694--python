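"""Synthetic long-video generator with segment-structured labels.

Emulates the label structure of surgical workflow video: each video is a
sequence of contiguous activity segments (runs of one class, each at least
``min_segment_len`` frames), and each class carries a distinct visual
signature — a base color modulated by a class-specific low-frequency
sinusoidal texture — plus i.i.d. Gaussian pixel noise.  Flat color makes
photometric transforms observable; the texture makes geometric warps
observable.  Everything is deterministic given the spec's seed.

What this does NOT emulate: instruments, anatomy, camera motion, lighting
drift, or inter-class visual ambiguity.  Results on these videos bound the
pipeline's correctness, not its performance on real endoscopic footage.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .video_io import DatasetManifest, VideoSample, write_frames, write_labels

TEXTURE_AMPLITUDE = 0.15


@dataclass(frozen=True)
class SynthSpec:
    """Generator configuration (desk-scale defaults).

    ``noise_sd`` is in [0, 1] pixel units (fraction of full scale).
    ``frames_per_video`` must allow every class at least one minimum-length
    segment.
    """

    n_videos: int = 10
    n_classes: int = 3
    frames_per_video: int = 60
    min_segment_len: int = 10
    frame_size: tuple[int, int] = (64, 64)
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_videos < 1 or self.n_classes < 1:
            raise ValueError("n_videos and n_classes must be >= 1")
        if self.min_segment_len < 1:
            raise ValueError("min_segment_len must be >= 1")
        if self.frames_per_video < self.n_classes * self.min_segment_len:
            raise ValueError(
                "frames_per_video must be >= n_classes * min_segment_len "
                f"({self.n_classes} * {self.min_segment_len})"
            )
        if not (0.0 <= self.noise_sd <= 1.0):
            raise ValueError("noise_sd must lie in [0, 1]")


def class_signature(spec: SynthSpec, class_id: int) -> tuple[np.ndarray, float, float]:
    """(base RGB color in [0,1], texture frequency, texture phase) for a class.

    Colors are evenly spaced hues, so signatures are pairwise distinct.
    """
    if not (0 <= class_id < spec.n_classes):
        raise ValueError(f"class_id {class_id} outside [0, {spec.n_classes})")
    hue = class_id / spec.n_classes
    base = np.array(colorsys.hsv_to_rgb(hue, 0.55, 0.75))
    freq = 2.0 + class_id
    phase = 2.0 * np.pi * class_id / spec.n_classes
    return base, freq, phase


def render_frame(
    spec: SynthSpec, class_id: int, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """One H×W×3 uint8 frame of a class signature (+ noise when rng given)."""
    h, w = spec.frame_size
    base, freq, phase = class_signature(spec, class_id)
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    texture = TEXTURE_AMPLITUDE * np.sin(2.0 * np.pi * freq * (xx + yy) / h + phase)
    img = base[None, None, :] + texture[:, :, None]
    if rng is not None and spec.noise_sd > 0:
        img = img + spec.noise_sd * rng.standard_normal((h, w, 3))
    return (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def class_mean_colors(spec: SynthSpec) -> np.ndarray:
    """Mean RGB of each class's noiseless signature frame (reference for a
    nearest-signature classifier)."""
    return np.stack(
        [render_frame(spec, c).reshape(-1, 3).mean(axis=0) for c in range(spec.n_classes)]
    )


def _sample_label_runs(
    spec: SynthSpec, rng: np.random.Generator, required_class: Optional[int] = None
) -> np.ndarray:
    """Contiguous label runs, each >= min_segment_len, adjacent runs distinct."""
    n = spec.frames_per_video
    max_runs = n // spec.min_segment_len
    n_runs = int(rng.integers(1, max_runs + 1))
    lengths = np.full(n_runs, spec.min_segment_len, dtype=np.int64)
    lengths += rng.multinomial(n - n_runs * spec.min_segment_len, np.full(n_runs, 1.0 / n_runs))
    classes = np.empty(n_runs, dtype=np.int64)
    for i in range(n_runs):
        if i == 0 and required_class is not None:
            classes[i] = required_class
            continue
        choices = np.arange(spec.n_classes)
        if i > 0 and spec.n_classes > 1:
            choices = choices[choices != classes[i - 1]]
        classes[i] = int(rng.choice(choices))
    return np.repeat(classes, lengths)


def generate_video(
    spec: SynthSpec,
    rng: np.random.Generator,
    video_id: str = "",
    required_class: Optional[int] = None,
) -> VideoSample:
    """One labeled synthetic video; deterministic given the rng state."""
    labels = _sample_label_runs(spec, rng, required_class=required_class)
    frames = np.stack([render_frame(spec, int(c), rng) for c in labels], axis=0)
    return VideoSample(frames=frames, labels=labels, fps=1.0, video_id=video_id)


def generate_samples(spec: SynthSpec) -> list[VideoSample]:
    """All videos of the dataset, in order.  Video v is forced to open with
    class v mod n_classes, so every class appears somewhere in the dataset."""
    rng = np.random.default_rng(spec.seed)
    return [
        generate_video(
            spec, rng, video_id=f"video_{v:03d}", required_class=v % spec.n_classes
        )
        for v in range(spec.n_videos)
    ]


def split_sizes(n_videos: int) -> tuple[int, int, int]:
    """60/20/20 train/val/test split by video (at least one val and test
    video whenever possible)."""
    n_test = max(1, round(0.2 * n_videos)) if n_videos >= 3 else (1 if n_videos >= 2 else 0)
    n_val = max(1, round(0.2 * n_videos)) if n_videos >= 3 else 0
    n_train = n_videos - n_val - n_test
    return n_train, n_val, n_test


def generate_dataset(spec: SynthSpec, out_dir) -> DatasetManifest:
    """Materialize the dataset: per-video frame dirs + label CSVs + manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = generate_samples(spec)
    n_train, n_val, _ = split_sizes(spec.n_videos)
    entries = []
    for v, sample in enumerate(samples):
        split = "train" if v < n_train else ("val" if v < n_train + n_val else "test")
        frames_dir = out_dir / sample.video_id
        labels_csv = out_dir / f"{sample.video_id}_labels.csv"
        write_frames(sample.frames, frames_dir)
        write_labels(sample.labels, labels_csv)
        entries.append(
            {
                "video_id": sample.video_id,
                "frames": str(frames_dir.relative_to(out_dir)),
                "labels": str(labels_csv.relative_to(out_dir)),
                "split": split,
            }
        )
    manifest = DatasetManifest(
        entries=entries, class_names=[f"class_{c}" for c in range(spec.n_classes)]
    )
    manifest.save(out_dir / "manifest.yaml")
    return manifest
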