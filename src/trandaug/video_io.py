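"""Frame-sequence and label I/O.

Videos are handled as ordered RGB frame sequences.  The extraction
convention mirrors common practice in surgical workflow analysis: frames
are subsampled to a target rate (keep every round(fps_in/fps_out)-th frame
starting at index 0) and stretched to a fixed spatial size, 224×224 by
default — the input size of standard image backbones.  Frame indexing is
0-based with half-open intervals throughout.

On disk a video is a directory of zero-padded PNG/JPEG frames; labels are a
per-video CSV with columns (frame_index, class_id); a dataset is described
by a YAML manifest listing videos, paths, and train/val/test splits.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

IMAGE_EXTS = {".png", ".jpg", ".jpeg"}
DEFAULT_SIZE = (224, 224)  # (H, W)


@dataclass
class VideoSample:
    """Ordered frames x_{1:Υ} with optional frame-wise labels y_{1:Υ}."""

    frames: np.ndarray  # Υ×H×W×3 uint8
    labels: Optional[np.ndarray] = None
    fps: float = 1.0
    video_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[3] != 3:
            raise ValueError(f"frames must be Υ×H×W×3, got {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise ValueError("a video needs at least one frame")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if len(self.labels) != self.n_frames:
                raise ValueError(
                    f"labels length {len(self.labels)} != frame count {self.n_frames}"
                )

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_size(self) -> tuple[int, int]:
        return (int(self.frames.shape[1]), int(self.frames.shape[2]))


@dataclass
class DatasetManifest:
    """List of videos with frame/label paths and split assignments."""

    entries: list[dict] = field(default_factory=list)
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e["video_id"] for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("video_ids must be unique")
        for e in self.entries:
            if e.get("split") not in ("train", "val", "test"):
                raise ValueError(f"bad split for {e.get('video_id')}: {e.get('split')}")

    def split(self, name: str) -> list[dict]:
        return [e for e in self.entries if e["split"] == name]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"class_names": self.class_names, "entries": self.entries},
                fh,
                sort_keys=False,
            )

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(entries=payload["entries"], class_names=payload["class_names"])


def _list_frame_files(directory: Path) -> list[Path]:
    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in IMAGE_EXTS
    )
    if not files:
        raise IOError(f"no frame images found in {directory}")
    return files


def _resize(frame: np.ndarray, target_size: tuple[int, int]) -> np.ndarray:
    h, w = target_size
    if frame.shape[0] == h and frame.shape[1] == w:
        return frame
    img = Image.fromarray(frame, mode="RGB")
    # plain stretch, bilinear; PIL size order is (W, H)
    return np.asarray(img.resize((w, h), resample=Image.BILINEAR), dtype=np.uint8)


def load_frames(
    path,
    target_size: tuple[int, int] = DEFAULT_SIZE,
    fps_in: float = 1.0,
    fps_out: float = 1.0,
    video_id: Optional[str] = None,
) -> VideoSample:
    """Load a frame directory (or multi-frame image file) as a VideoSample.

    Frames are kept at stride ``round(fps_in / fps_out)`` starting at index
    0, then resized to ``target_size`` (H, W).
    """
    if fps_in <= 0 or fps_out <= 0:
        raise ValueError("fps values must be positive")
    if fps_out > fps_in:
        raise ValueError(f"fps_out {fps_out} exceeds fps_in {fps_in}")
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such path: {path}")

    if path.is_dir():
        files = _list_frame_files(path)
        raw = [np.asarray(Image.open(f).convert("RGB"), dtype=np.uint8) for f in files]
    else:
        import imageio.v2 as imageio

        raw = [np.asarray(fr)[..., :3].astype(np.uint8) for fr in imageio.mimread(path)]
        if not raw:
            raise IOError(f"no frames decoded from {path}")

    stride = max(1, int(round(fps_in / fps_out)))
    kept = raw[::stride]
    frames = np.stack([_resize(f, target_size) for f in kept], axis=0)
    return VideoSample(
        frames=frames,
        fps=fps_out,
        video_id=video_id if video_id is not None else path.stem,
    )


def write_frames(frames: np.ndarray, out_dir) -> list[Path]:
    """Write frames as zero-padded PNGs (lossless round-trip)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(np.asarray(frames)):
        p = out_dir / f"{i:06d}.png"
        Image.fromarray(frame, mode="RGB").save(p)
        paths.append(p)
    return paths


def load_labels(
    path, n_frames: int, class_names: Optional[Sequence[str]] = None
) -> np.ndarray:
    """Read a (frame_index, class_id) CSV into a dense length-Υ vector.

    Every index 0..n_frames-1 must be present exactly once; class ids must
    fall inside the manifest's class list when one is given.
    """
    df = pd.read_csv(path)
    required = {"frame_index", "class_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"label CSV must have columns {sorted(required)}")
    idx = df["frame_index"].to_numpy()
    if len(idx) != n_frames or not np.array_equal(np.sort(idx), np.arange(n_frames)):
        raise ValueError(
            f"label CSV must enumerate frame indices 0..{n_frames - 1} exactly once"
        )
    labels = np.empty(n_frames, dtype=np.int64)
    labels[idx] = df["class_id"].to_numpy(dtype=np.int64)
    if labels.min() < 0:
        raise ValueError("negative class id")
    if class_names is not None and labels.max() >= len(class_names):
        raise ValueError(
            f"class id {int(labels.max())} outside known classes (n={len(class_names)})"
        )
    return labels


def write_labels(labels: np.ndarray, path) -> None:
    labels = np.asarray(labels, dtype=np.int64)
    pd.DataFrame(
        {"frame_index": np.arange(len(labels)), "class_id": labels}
    ).to_csv(path, index=False)
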