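"""Image transform bank and magnitude scaling.

The augmentation policy draws from a fixed bank of image operations.  Each
operation exposes a single scalar parameter whose strength is controlled by
an integer magnitude ``M`` on a 0–30 scale: the resolved parameter is the
linear interpolation between the operation's minimum and maximum values.

The default bank contains 10 operations — five geometric (rotate,
translate-x/y, shear-x/y), a horizontal flip, and four photometric
enhancement factors (brightness, contrast, saturation, sharpness).
Operations that produce drastically unnatural endoscopic imagery
(posterize, solarize, equalize) are deliberately absent.  Geometric
operations fill exposed borders by edge replication rather than a constant
color, since hard black borders do not occur in surgical video.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import yaml
from PIL import Image, ImageEnhance
from scipy import ndimage

MAGNITUDE_MAX = 30

GEOMETRIC = "geometric"
PHOTOMETRIC = "photometric"


@dataclass(frozen=True)
class TransformSpec:
    """One image operation with its magnitude-to-parameter mapping.

    ``param_min`` is the parameter at magnitude 0 and ``param_max`` at
    magnitude 30.  ``signed`` operations additionally receive a random
    direction (sampled by the policy, not here).  ``kind`` separates
    geometric warps from photometric enhancement factors.
    """

    name: str
    param_min: float
    param_max: float
    signed: bool
    kind: str

    def __post_init__(self) -> None:
        if self.param_min > self.param_max:
            raise ValueError(
                f"{self.name}: param_min {self.param_min} > param_max {self.param_max}"
            )
        if self.kind not in (GEOMETRIC, PHOTOMETRIC):
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")


class TransformBank:
    """Ordered, name-unique collection of :class:`TransformSpec`."""

    def __init__(self, transforms: Iterable[TransformSpec]):
        self.transforms: list[TransformSpec] = list(transforms)
        names = [t.name for t in self.transforms]
        if len(set(names)) != len(names):
            raise ValueError("transform names must be unique")
        self._by_name = {t.name: t for t in self.transforms}

    def __len__(self) -> int:
        return len(self.transforms)

    def __iter__(self):
        return iter(self.transforms)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.transforms]

    def get(self, name: str) -> TransformSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown transform {name!r}; bank has {self.names}") from None

    def subset(self, names: Sequence[str]) -> "TransformBank":
        """Restrict the bank to ``names`` (a τ′ ⊂ τ selection), keeping order."""
        if not names:
            raise ValueError("subset must be non-empty")
        missing = [n for n in names if n not in self._by_name]
        if missing:
            raise KeyError(f"subset names not in bank: {missing}")
        return TransformBank([self._by_name[n] for n in names])

    # --- serialization -------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = [
            {
                "name": t.name,
                "param_min": float(t.param_min),
                "param_max": float(t.param_max),
                "signed": bool(t.signed),
                "kind": t.kind,
            }
            for t in self.transforms
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TransformBank":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(TransformSpec(**entry) for entry in payload)


def default_bank() -> TransformBank:
    """The 10-operation default bank.

    Ranges follow common random-augmentation practice: rotations up to 30°,
    translations and shears up to 0.3 of the image extent / shear factor,
    enhancement factors from the identity point 1.0 up to 1.9.  The flip is
    parameter-free (magnitude is ignored).
    """
    factor = dict(param_min=1.0, param_max=1.9, signed=True, kind=PHOTOMETRIC)
    return TransformBank(
        [
            TransformSpec("rotate", 0.0, 30.0, True, GEOMETRIC),
            TransformSpec("translate-x", 0.0, 0.3, True, GEOMETRIC),
            TransformSpec("translate-y", 0.0, 0.3, True, GEOMETRIC),
            TransformSpec("shear-x", 0.0, 0.3, True, GEOMETRIC),
            TransformSpec("shear-y", 0.0, 0.3, True, GEOMETRIC),
            TransformSpec("horizontal-flip", 0.0, 0.0, False, GEOMETRIC),
            TransformSpec("brightness", **factor),
            TransformSpec("contrast", **factor),
            TransformSpec("saturation", **factor),
            TransformSpec("sharpness", **factor),
        ]
    )


def scale_magnitude(spec: TransformSpec, M: int) -> float:
    """Resolve a transform parameter from an integer magnitude in [0, 30].

    Linear map: ``param_min + (M / 30) * (param_max - param_min)``.  For
    ``signed`` transforms the caller samples a direction sign separately.
    """
    if not (0 <= M <= MAGNITUDE_MAX):
        raise ValueError(f"magnitude M={M} outside [0, {MAGNITUDE_MAX}]")
    return spec.param_min + (M / MAGNITUDE_MAX) * (spec.param_max - spec.param_min)


def _check_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"expected an RGB H×W×3 image, got shape {frame.shape}")
    if frame.dtype != np.uint8:
        raise ValueError(f"expected uint8 pixels, got {frame.dtype}")
    return frame


def _mirrored_factor(factor: float, sign: int) -> float:
    # Enhancement factors live on [1.0, 1.9]; a negative sign mirrors the
    # strength below the identity point (1.45 -> 0.55), never below 0.
    if sign >= 0:
        return factor
    return max(2.0 - factor, 0.0)


def _affine(frame: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Centered 2-D affine warp, bilinear, edge-replicate fill."""
    h, w = frame.shape[:2]
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - matrix @ center
    out = np.empty_like(frame)
    for c in range(3):
        plane = ndimage.affine_transform(
            frame[:, :, c].astype(np.float64),
            matrix,
            offset=offset,
            order=1,
            mode="nearest",
        )
        out[:, :, c] = np.clip(np.rint(plane), 0, 255).astype(np.uint8)
    return out


_ENHANCERS = {
    "brightness": ImageEnhance.Brightness,
    "contrast": ImageEnhance.Contrast,
    "saturation": ImageEnhance.Color,
    "sharpness": ImageEnhance.Sharpness,
}


def apply_transform(
    frame: np.ndarray, spec: TransformSpec, resolved_param: float, sign: int = 1
) -> np.ndarray:
    """Apply one resolved transform to an RGB frame, returning a new image.

    The input frame is never modified.  Transforms whose ``param_min`` is
    their identity point return a pixel-identical copy when the resolved
    parameter equals it (geometric parameter 0, enhancement factor 1).
    """
    frame = _check_frame(frame)
    name = spec.name

    if name == "horizontal-flip":
        return np.ascontiguousarray(frame[:, ::-1, :])

    if spec.kind == GEOMETRIC:
        if resolved_param == 0.0:
            return frame.copy()
        p = sign * resolved_param
        if name == "rotate":
            out = np.empty_like(frame)
            for c in range(3):
                plane = ndimage.rotate(
                    frame[:, :, c].astype(np.float64),
                    p,
                    reshape=False,
                    order=1,
                    mode="nearest",
                )
                out[:, :, c] = np.clip(np.rint(plane), 0, 255).astype(np.uint8)
            return out
        h, w = frame.shape[:2]
        if name == "translate-x":
            return _shift(frame, 0.0, p * w)
        if name == "translate-y":
            return _shift(frame, p * h, 0.0)
        if name == "shear-x":
            # output->input map: in_col = col + p*row (centered in _affine)
            return _affine(frame, np.array([[1.0, 0.0], [p, 1.0]]))
        if name == "shear-y":
            return _affine(frame, np.array([[1.0, p], [0.0, 1.0]]))
        raise KeyError(f"unknown geometric transform {name!r}")

    # photometric
    if name not in _ENHANCERS:
        raise KeyError(f"unknown transform {name!r}")
    factor = _mirrored_factor(resolved_param, sign)
    if factor == 1.0:
        return frame.copy()
    img = Image.fromarray(frame, mode="RGB")
    out = _ENHANCERS[name](img).enhance(factor)
    return np.asarray(out, dtype=np.uint8).copy()


def _shift(frame: np.ndarray, dy: float, dx: float) -> np.ndarray:
    out = np.empty_like(frame)
    for c in range(3):
        plane = ndimage.shift(
            frame[:, :, c].astype(np.float64), (dy, dx), order=1, mode="nearest"
        )
        out[:, :, c] = np.clip(np.rint(plane), 0, 255).astype(np.uint8)
    return out
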