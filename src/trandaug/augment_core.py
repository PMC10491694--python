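"""Temporal random augmentation: TRA and its RA/URA degenerate cases.

A video of Υ frames is split into T′ temporal segments, T′ drawn uniformly
from [1, min(T, Υ)].  Each segment receives its own composition of N
transforms, each drawn uniformly (with replacement) from the active subset
τ′ of the bank and applied with identical resolved parameters to every
frame of the segment.  The policy is the triple (M, N, T) plus the subset
and a seed.

Two degenerate cases recover the classical baselines:

* ``uniform_randaugment`` — T fixed to 1: one composition for the whole
  video (URA).
* ``randaugment`` — every frame its own segment (T′ forced to Υ):
  independent per-frame draws (RA).

Both share the exact sampling code path with ``trandaugment``, so the
reductions hold byte-for-byte for a shared seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .transform_bank import (
    MAGNITUDE_MAX,
    TransformBank,
    apply_transform,
    default_bank,
    scale_magnitude,
)

FrameSeq = Union[np.ndarray, Sequence[np.ndarray]]

BOUNDARY_MODES = ("equal", "random")


@dataclass(frozen=True)
class AugmentPolicy:
    """The (M, N, T) search space plus transform subset τ′ and seed.

    M: magnitude 0–30; N: transforms per segment (0 disables augmentation);
    T: maximum number of temporal segments.  ``subset=None`` means the full
    bank τ.  ``boundary_mode``: 'equal' splits into equal-length contiguous
    segments (remainder on the last); 'random' draws T′−1 distinct cut
    points uniformly.
    """

    M: int = 30
    N: int = 1
    T: int = 5
    subset: Optional[tuple[str, ...]] = None
    seed: int = 0
    boundary_mode: str = "equal"

    def __post_init__(self) -> None:
        if not (0 <= self.M <= MAGNITUDE_MAX):
            raise ValueError(f"M={self.M} outside [0, {MAGNITUDE_MAX}]")
        if self.N < 0:
            raise ValueError("N must be >= 0")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.subset is not None and len(self.subset) == 0:
            raise ValueError("subset must be non-empty when given")
        if self.boundary_mode not in BOUNDARY_MODES:
            raise ValueError(f"boundary_mode must be one of {BOUNDARY_MODES}")

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "M": self.M,
            "N": self.N,
            "T": self.T,
            "subset": list(self.subset) if self.subset is not None else None,
            "seed": self.seed,
            "boundary_mode": self.boundary_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AugmentPolicy":
        d = dict(d)
        if d.get("subset") is not None:
            d["subset"] = tuple(d["subset"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "AugmentPolicy":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SegmentPlan:
    """A sampled realization of a policy on one video.

    ``boundaries`` are half-open [start, end) frame intervals that partition
    [0, n_frames); ``ops[i]`` holds segment i's N resolved
    (name, parameter, sign) triples, applied in order to every frame of the
    segment.
    """

    n_frames: int
    t_prime: int
    boundaries: list[tuple[int, int]]
    ops: list[list[tuple[str, float, int]]]

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (1 <= self.t_prime <= self.n_frames):
            raise ValueError("t_prime outside [1, n_frames]")
        if len(self.boundaries) != self.t_prime or len(self.ops) != self.t_prime:
            raise ValueError("boundaries/ops length must equal t_prime")
        cursor = 0
        for start, end in self.boundaries:
            if start != cursor or end <= start:
                raise ValueError("boundaries must be contiguous non-empty intervals")
            cursor = end
        if cursor != self.n_frames:
            raise ValueError("boundaries must cover [0, n_frames)")

    def composition_key(self, segment: int) -> tuple:
        return tuple(self.ops[segment])

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_frames": self.n_frames,
                "t_prime": self.t_prime,
                "boundaries": self.boundaries,
                "ops": self.ops,
            }
        )


def _resolve_subset(policy: AugmentPolicy, bank: TransformBank) -> TransformBank:
    if policy.subset is None:
        return bank
    return bank.subset(policy.subset)


def sample_segment_plan(
    n_frames: int,
    policy: AugmentPolicy,
    rng: np.random.Generator,
    bank: Optional[TransformBank] = None,
    force_t_prime: Optional[int] = None,
) -> SegmentPlan:
    """Sample a :class:`SegmentPlan` for a video of ``n_frames`` frames.

    Draw order is fixed — T′ (unless forced), cut points (random mode only),
    then per-segment ops in segment order — so the plan is fully determined
    by (n_frames, policy, rng state).  T′ is clipped to min(T, Υ) so every
    segment holds at least one frame.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    bank = bank if bank is not None else default_bank()
    active = _resolve_subset(policy, bank)

    t_max = min(policy.T, n_frames)
    if force_t_prime is not None:
        if not (1 <= force_t_prime <= n_frames):
            raise ValueError("forced t_prime outside [1, n_frames]")
        t_prime = force_t_prime
    else:
        t_prime = int(rng.integers(1, t_max + 1))

    if policy.boundary_mode == "random" and t_prime > 1:
        cuts = np.sort(rng.choice(np.arange(1, n_frames), size=t_prime - 1, replace=False))
        edges = [0, *cuts.tolist(), n_frames]
    else:
        base, rem = divmod(n_frames, t_prime)
        edges = [0]
        for i in range(t_prime):
            edges.append(edges[-1] + base + (rem if i == t_prime - 1 else 0))
    boundaries = [(int(edges[i]), int(edges[i + 1])) for i in range(t_prime)]

    specs = active.transforms
    ops: list[list[tuple[str, float, int]]] = []
    for _ in range(t_prime):
        seg_ops = []
        for _ in range(policy.N):
            spec = specs[int(rng.integers(len(specs)))]
            param = scale_magnitude(spec, policy.M)
            sign = (1 if int(rng.integers(2)) == 0 else -1) if spec.signed else 1
            seg_ops.append((spec.name, float(param), int(sign)))
        ops.append(seg_ops)

    plan = SegmentPlan(n_frames=n_frames, t_prime=t_prime, boundaries=boundaries, ops=ops)
    plan.validate()
    return plan


def _as_list(frames: FrameSeq) -> list[np.ndarray]:
    if isinstance(frames, np.ndarray):
        if frames.ndim != 4:
            raise ValueError(f"expected Υ×H×W×3 array, got shape {frames.shape}")
        return [frames[i] for i in range(frames.shape[0])]
    return list(frames)


def _pack_like(frames: FrameSeq, out: list[np.ndarray]) -> FrameSeq:
    if isinstance(frames, np.ndarray):
        return np.stack(out, axis=0)
    return out


def apply_plan(
    frames: FrameSeq, plan: SegmentPlan, bank: Optional[TransformBank] = None
) -> FrameSeq:
    """Apply a sampled plan: every frame of segment i receives the identical
    ordered composition of segment i's ops.  Input frames are not modified."""
    bank = bank if bank is not None else default_bank()
    frame_list = _as_list(frames)
    if len(frame_list) != plan.n_frames:
        raise ValueError(
            f"frame count {len(frame_list)} does not match plan.n_frames {plan.n_frames}"
        )
    plan.validate()
    out: list[np.ndarray] = [None] * plan.n_frames  # type: ignore[list-item]
    for (start, end), seg_ops in zip(plan.boundaries, plan.ops):
        for t in range(start, end):
            frame = frame_list[t]
            if not seg_ops:
                frame = frame.copy()
            for name, param, sign in seg_ops:
                frame = apply_transform(frame, bank.get(name), param, sign)
            out[t] = frame
    return _pack_like(frames, out)


def _rng_for(policy: AugmentPolicy, rng: Optional[np.random.Generator]) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(policy.seed)


def trandaugment(
    frames: FrameSeq,
    policy: AugmentPolicy,
    bank: Optional[TransformBank] = None,
    rng: Optional[np.random.Generator] = None,
    return_plan: bool = False,
):
    """TRA: segment-consistent random augmentation, deterministic given
    (frames, policy) when no external rng is supplied."""
    frame_list = _as_list(frames)
    if len(frame_list) < 1:
        raise ValueError("need at least one frame")
    rng = _rng_for(policy, rng)
    plan = sample_segment_plan(len(frame_list), policy, rng, bank=bank)
    out = apply_plan(frames, plan, bank=bank)
    return (out, plan) if return_plan else out


def uniform_randaugment(
    frames: FrameSeq,
    policy: AugmentPolicy,
    bank: Optional[TransformBank] = None,
    rng: Optional[np.random.Generator] = None,
    return_plan: bool = False,
):
    """URA: one composition applied uniformly to the whole video (T = 1)."""
    return trandaugment(
        frames, replace(policy, T=1), bank=bank, rng=rng, return_plan=return_plan
    )


def randaugment(
    frames: FrameSeq,
    policy: AugmentPolicy,
    bank: Optional[TransformBank] = None,
    rng: Optional[np.random.Generator] = None,
    return_plan: bool = False,
):
    """RA: independent per-frame draws (every frame its own segment)."""
    frame_list = _as_list(frames)
    if len(frame_list) < 1:
        raise ValueError("need at least one frame")
    rng = _rng_for(policy, rng)
    plan = sample_segment_plan(
        len(frame_list), policy, rng, bank=bank, force_t_prime=len(frame_list)
    )
    out = apply_plan(frames, plan, bank=bank)
    return (out, plan) if return_plan else out
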