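"""Spatiotemporal recognition model.

A per-frame visual feature extractor feeds a single-stage temporal
convolutional network (SS-TCN) built from causal dilated convolutions: the
prediction at time t depends only on the current and the n previous frames,
which makes the model usable for online recognition.  Training uses a
class-weighted cross-entropy loss to counter the strong class imbalance of
frame-wise activity labels.

The extractor is pluggable.  The ``tiny-test-cnn`` variant is a compact,
deterministically initialized convolutional feature map suited to small
synthetic frames; the ``full-residual-50`` variant is a hook for an
externally supplied pretrained backbone (a 2048-dimensional residual
network), which this package does not ship.

The temporal network and its optimizer are implemented directly on NumPy
arrays (explicit forward/backward passes), which keeps every operation
inspectable and bit-reproducible across runs on the same machine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureExtractorSpec:
    """Configuration of the per-frame visual feature extractor.

    ``feature_dim`` is the length f of the per-frame feature vector
    (2048 for the full residual backbone).  ``input_size`` is the expected
    (H, W) of incoming RGB frames.
    """

    feature_dim: int = 2048
    input_size: tuple[int, int] = (224, 224)
    variant: str = "tiny-test-cnn"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be >= 1")
        if self.variant not in ("tiny-test-cnn", "full-residual-50"):
            raise ValueError(f"unknown extractor variant {self.variant!r}")


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int) -> np.ndarray:
    """Valid 2-D convolution; x: H×W×Cin, w: k×k×Cin×Cout."""
    k = w.shape[0]
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(0, 1))
    win = win[::stride, ::stride]  # Ho×Wo×Cin×k×k
    return np.tensordot(win, w, axes=([3, 4, 2], [0, 1, 2])) + b


class TinyCNN:
    """Small fixed-weight convolutional extractor for test-scale frames.

    Two strided 3×3 convolution + ReLU stages, global average pooling, raw
    per-channel mean/std statistics, and a seeded linear projection to
    ``feature_dim``.  Weights are drawn once from the spec's seed and never
    trained, so extraction is deterministic.
    """

    def __init__(self, spec: FeatureExtractorSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        he = lambda *shape, fan: rng.standard_normal(shape) * np.sqrt(2.0 / fan)
        self.w1 = he(3, 3, 3, 8, fan=3 * 3 * 3)
        self.b1 = np.zeros(8)
        self.w2 = he(3, 3, 8, 16, fan=3 * 3 * 8)
        self.b2 = np.zeros(16)
        stats_dim = 16 + 6  # pooled channels + raw mean/std per RGB channel
        self.proj = rng.standard_normal((stats_dim, spec.feature_dim)) / np.sqrt(stats_dim)
        self.proj_b = np.zeros(spec.feature_dim)

    def __call__(self, frame: np.ndarray) -> np.ndarray:
        x = frame.astype(np.float64) / 255.0
        h = np.maximum(_conv2d(x, self.w1, self.b1, stride=2), 0.0)
        h = np.maximum(_conv2d(h, self.w2, self.b2, stride=2), 0.0)
        pooled = h.mean(axis=(0, 1))
        stats = np.concatenate([pooled, x.mean(axis=(0, 1)), x.std(axis=(0, 1))])
        return stats @ self.proj + self.proj_b


def build_extractor(
    spec: FeatureExtractorSpec,
    external: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> Callable[[np.ndarray], np.ndarray]:
    """Instantiate the per-frame extractor for a spec.

    The full residual variant requires an externally supplied callable
    (pretrained weights are an optional external asset, not shipped here).
    """
    if external is not None:
        return external
    if spec.variant == "tiny-test-cnn":
        return TinyCNN(spec)
    raise ValueError(
        "variant 'full-residual-50' needs an externally supplied pretrained "
        "backbone; pass it via the 'external' argument"
    )


def extract_features(
    frames: np.ndarray,
    spec: FeatureExtractorSpec,
    extractor: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> np.ndarray:
    """Map Υ frames to an Υ×f feature matrix, order-preserving."""
    frames = np.asarray(frames)
    if frames.ndim != 4 or frames.shape[3] != 3:
        raise ValueError(f"expected Υ×H×W×3 frames, got {frames.shape}")
    if tuple(frames.shape[1:3]) != tuple(spec.input_size):
        raise ValueError(
            f"frame size {frames.shape[1:3]} != spec.input_size {spec.input_size}"
        )
    fn = extractor if extractor is not None else build_extractor(spec)
    feats = np.stack([fn(frames[i]) for i in range(frames.shape[0])], axis=0)
    if feats.shape != (frames.shape[0], spec.feature_dim):
        raise ValueError(
            f"extractor produced {feats.shape}, expected ({frames.shape[0]}, {spec.feature_dim})"
        )
    return feats


class FeatureBuffer:
    """Per-video cache of past frame features; reset at the end of a video."""

    def __init__(self, video_id: str = ""):
        self.video_id = video_id
        self._chunks: list[np.ndarray] = []

    def append(self, features: np.ndarray) -> None:
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        self._chunks.append(features)

    @property
    def features(self) -> np.ndarray:
        if not self._chunks:
            return np.empty((0, 0))
        return np.concatenate(self._chunks, axis=0)

    def __len__(self) -> int:
        return sum(c.shape[0] for c in self._chunks)

    def reset(self) -> None:
        self._chunks = []


# ---------------------------------------------------------------------------
# Causal single-stage TCN
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SSTCNSpec:
    """Architecture of the single-stage TCN.

    Defaults follow the standard single-stage design: 10 residual layers of
    3-tap dilated causal convolutions with dilation 2^l and hidden width 64.
    The receptive field is 1 + (kernel−1)·Σ dilations frames, all in the
    past.
    """

    in_dim: int
    n_classes: int
    n_layers: int = 10
    kernel_size: int = 3
    hidden_dim: int = 64
    dilations: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.kernel_size < 1 or self.n_layers < 1 or self.hidden_dim < 1:
            raise ValueError("kernel_size, n_layers, hidden_dim must be >= 1")
        if self.dilations is not None and len(self.dilations) != self.n_layers:
            raise ValueError("dilations must have one entry per layer")

    @property
    def dilation_schedule(self) -> tuple[int, ...]:
        if self.dilations is not None:
            return tuple(self.dilations)
        return tuple(2**l for l in range(self.n_layers))

    @property
    def receptive_field(self) -> int:
        return 1 + (self.kernel_size - 1) * sum(self.dilation_schedule)


@dataclass
class FramePredictions:
    """Per-frame class scores and their argmax labels ŷ_{1:Υ}."""

    scores: np.ndarray  # Υ×C
    labels: np.ndarray  # Υ

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.scores.ndim != 2 or len(self.labels) != self.scores.shape[0]:
            raise ValueError("scores must be Υ×C with one label per frame")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite scores")


class SSTCN:
    """Single-stage TCN over frame features, NumPy forward/backward.

    Layout: a 1×1 input projection, then per layer a dilated causal 1-D
    convolution → ReLU → 1×1 convolution with a residual connection, then a
    1×1 output head.  Left-only zero padding enforces causality.
    """

    def __init__(self, spec: SSTCNSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        f, h, c, k = spec.in_dim, spec.hidden_dim, spec.n_classes, spec.kernel_size
        glorot = lambda *shape, fan: rng.standard_normal(shape) * np.sqrt(1.0 / fan)
        self.params: dict[str, np.ndarray] = {
            "W_in": glorot(f, h, fan=f),
            "b_in": np.zeros(h),
        }
        for l in range(spec.n_layers):
            self.params[f"Wd{l}"] = glorot(k, h, h, fan=k * h)
            self.params[f"bd{l}"] = np.zeros(h)
            self.params[f"Wp{l}"] = glorot(h, h, fan=h)
            self.params[f"bp{l}"] = np.zeros(h)
        self.params["W_out"] = glorot(h, c, fan=h)
        self.params["b_out"] = np.zeros(c)
        self._adam_m: Optional[dict[str, np.ndarray]] = None
        self._adam_v: Optional[dict[str, np.ndarray]] = None
        self._adam_t = 0

    # --- forward --------------------------------------------------------
    def forward(self, features: np.ndarray, cache: Optional[dict] = None) -> np.ndarray:
        """Features Υ×f → logits Υ×C.  Pass a dict as ``cache`` to enable
        a subsequent backward()."""
        x = np.asarray(features, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != self.spec.in_dim:
            raise ValueError(
                f"expected Υ×{self.spec.in_dim} features, got {x.shape}"
            )
        if x.shape[0] < 1:
            raise ValueError("empty feature sequence")
        p, k = self.params, self.spec.kernel_size
        h = x @ p["W_in"] + p["b_in"]
        layers = []
        for l, d in enumerate(self.spec.dilation_schedule):
            pad = np.zeros(((k - 1) * d, h.shape[1]))
            xp = np.concatenate([pad, h], axis=0)
            conv = p[f"bd{l}"] + sum(
                xp[j * d : j * d + h.shape[0]] @ p[f"Wd{l}"][j] for j in range(k)
            )
            a = np.maximum(conv, 0.0)
            o = a @ p[f"Wp{l}"] + p[f"bp{l}"]
            if cache is not None:
                layers.append({"h_in": h, "xp": xp, "conv": conv, "a": a})
            h = h + o
        logits = h @ p["W_out"] + p["b_out"]
        if cache is not None:
            cache.update({"x": x, "layers": layers, "h_final": h})
        return logits

    def predict(self, features: np.ndarray) -> FramePredictions:
        logits = self.forward(features)
        return FramePredictions(scores=logits, labels=np.argmax(logits, axis=1))

    # --- backward -------------------------------------------------------
    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        p, k = self.params, self.spec.kernel_size
        grads = {name: np.zeros_like(arr) for name, arr in p.items()}
        grads["W_out"] = cache["h_final"].T @ dlogits
        grads["b_out"] = dlogits.sum(axis=0)
        dh = dlogits @ p["W_out"].T
        T = cache["x"].shape[0]
        for l in reversed(range(self.spec.n_layers)):
            d = self.spec.dilation_schedule[l]
            lay = cache["layers"][l]
            do = dh  # residual branch gradient
            grads[f"Wp{l}"] = lay["a"].T @ do
            grads[f"bp{l}"] = do.sum(axis=0)
            da = do @ p[f"Wp{l}"].T
            dconv = da * (lay["conv"] > 0)
            grads[f"bd{l}"] = dconv.sum(axis=0)
            dxp = np.zeros_like(lay["xp"])
            for j in range(k):
                grads[f"Wd{l}"][j] = lay["xp"][j * d : j * d + T].T @ dconv
                dxp[j * d : j * d + T] += dconv @ p[f"Wd{l}"][j].T
            dh = dh + dxp[(k - 1) * d :]
        grads["W_in"] = cache["x"].T @ dh
        grads["b_in"] = dh.sum(axis=0)
        return grads

    # --- optimization ---------------------------------------------------
    def adam_step(
        self,
        grads: dict[str, np.ndarray],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        if self._adam_m is None:
            self._adam_m = {n: np.zeros_like(a) for n, a in self.params.items()}
            self._adam_v = {n: np.zeros_like(a) for n, a in self.params.items()}
        self._adam_t += 1
        t = self._adam_t
        for n, g in grads.items():
            self._adam_m[n] = beta1 * self._adam_m[n] + (1 - beta1) * g
            self._adam_v[n] = beta2 * self._adam_v[n] + (1 - beta2) * g * g
            mhat = self._adam_m[n] / (1 - beta1**t)
            vhat = self._adam_v[n] / (1 - beta2**t)
            self.params[n] -= lr * mhat / (np.sqrt(vhat) + eps)

    def train_step(
        self,
        features: np.ndarray,
        labels: np.ndarray,
        class_weights: np.ndarray,
        lr: float,
    ) -> float:
        cache: dict = {}
        logits = self.forward(features, cache=cache)
        loss, dlogits = _weighted_ce_with_grad(logits, labels, class_weights)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss: {loss}")
        self.adam_step(self.backward(cache, dlogits), lr)
        return loss

    # --- persistence ------------------------------------------------------
    def save(self, path) -> None:
        meta = dict(
            in_dim=self.spec.in_dim,
            n_classes=self.spec.n_classes,
            n_layers=self.spec.n_layers,
            kernel_size=self.spec.kernel_size,
            hidden_dim=self.spec.hidden_dim,
            dilations=np.asarray(self.spec.dilation_schedule),
        )
        np.savez(path, **{f"param_{n}": a for n, a in self.params.items()}, **meta)

    @classmethod
    def load(cls, path) -> "SSTCN":
        data = np.load(path)
        spec = SSTCNSpec(
            in_dim=int(data["in_dim"]),
            n_classes=int(data["n_classes"]),
            n_layers=int(data["n_layers"]),
            kernel_size=int(data["kernel_size"]),
            hidden_dim=int(data["hidden_dim"]),
            dilations=tuple(int(d) for d in data["dilations"]),
        )
        model = cls(spec)
        for key in data.files:
            if key.startswith("param_"):
                model.params[key[len("param_") :]] = data[key]
        return model


def sstcn_forward(features: np.ndarray, spec: SSTCNSpec, seed: int = 0) -> FramePredictions:
    """Convenience one-shot forward pass with a freshly initialized network."""
    return SSTCN(spec, seed=seed).predict(features)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def compute_class_weights(label_counts: np.ndarray) -> np.ndarray:
    """Inverse-frequency class weights, normalized to mean 1.

    weight_c ∝ total / (C · count_c) for observed classes; classes with a
    zero count get weight 0 and are excluded from the normalization.
    """
    counts = np.asarray(label_counts, dtype=np.float64)
    if counts.ndim != 1 or np.any(counts < 0):
        raise ValueError("label_counts must be a 1-D vector of counts >= 0")
    total = counts.sum()
    if total == 0:
        raise ValueError("all class counts are zero")
    c = len(counts)
    weights = np.zeros(c)
    nz = counts > 0
    weights[nz] = total / (c * counts[nz])
    weights[nz] /= weights[nz].mean()
    return weights


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(
    scores: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray,
    normalize: bool = True,
) -> float:
    """Class-weighted cross-entropy over frames.

    With ``normalize`` (default) the per-frame losses are averaged with the
    frame weights as the averaging weights — Σ w_{y_t}·ℓ_t / Σ w_{y_t} — so
    a global rescaling of the weights leaves the loss unchanged.  Without
    it, the plain mean of w_{y_t}·ℓ_t is returned.
    """
    loss, _ = _weighted_ce_with_grad(scores, labels, weights, normalize=normalize)
    return loss


def _weighted_ce_with_grad(
    scores: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray,
    normalize: bool = True,
) -> tuple[float, np.ndarray]:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    weights = np.asarray(weights, dtype=np.float64)
    if np.any(weights < 0):
        raise ValueError("class weights must be >= 0")
    n, c = scores.shape
    if len(labels) != n:
        raise ValueError("scores/labels length mismatch")
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError(f"label outside [0, {c})")
    probs = _softmax(scores)
    logp = np.log(np.clip(probs[np.arange(n), labels], 1e-300, None))
    w = weights[labels]
    denom = w.sum() if normalize else float(n)
    if denom == 0:
        raise ValueError("all frames carry zero class weight")
    loss = float(-(w * logp).sum() / denom)
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits *= (w / denom)[:, None]
    return loss, dlogits
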