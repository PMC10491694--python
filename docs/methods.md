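# Methods

## Augmentation model

A video is an ordered sequence of Υ RGB frames with one activity label per
frame. TRandAugment (TRA) samples, per video and per training epoch:

1. **T′ ~ Uniform{1, …, min(T, Υ)}** — the number of temporal segments.
   Clipping at Υ guarantees non-empty segments on degenerate short videos.
2. **Segment boundaries.** Default `equal`: contiguous equal-length
   segments, remainder frames appended to the last segment (deterministic
   given T′). Optional `random`: T′−1 distinct cut points drawn uniformly
   from the Υ−1 interior positions. The equal split is the default because
   it adds no extra randomness beyond T′ and matches the mental picture of
   a video cut into clips; the random mode preserves generality.
3. **Per segment, N transforms** drawn independently and uniformly *with
   replacement* from the active subset τ′ of the bank (each draw has
   probability 1/|τ′|), each resolved at magnitude M, with a direction sign
   drawn per segment for signed transforms. Sampling the sign per segment —
   not per frame — preserves within-segment consistency, which is the
   method's defining property.

Draw order is fixed (T′, cuts, then per-segment ops) so a plan is fully
determined by (Υ, policy, rng state). URA is TRA with T := 1 and RA is TRA
with T′ forced to Υ, both through the identical code path, so the
reductions are byte-exact for a shared seed — this is asserted in the test
suite rather than assumed.

### Transform bank

| name | parameter range (M=0 → M=30) | signed | kind |
|---|---|---|---|
| rotate | 0° → 30° | yes | geometric |
| translate-x / translate-y | 0 → 0.3 × image extent | yes | geometric |
| shear-x / shear-y | 0 → 0.3 shear factor | yes | geometric |
| horizontal-flip | parameter-free | no | geometric |
| brightness / contrast / saturation / sharpness | factor 1.0 → 1.9 | yes | photometric |

The resolved parameter is `param_min + (M/30)·(param_max − param_min)`, so
M=0 is the identity point for every transform except the flip. Signed
photometric factors mirror below the identity point (f → 2 − f, floored at
0); signed geometric parameters negate. Operations that produce images
unlike anything seen in endoscopic video (posterize, solarize, equalize)
and mixing-based augmentations are excluded by design. The bank is
configurable (YAML) so an alternative list can be dropped in; subsets τ′
are selected by name.

Geometric warps use bilinear interpolation with edge-replicate fill (no
artificial black borders, which do not occur in surgical video). Pixel
identity at the identity parameter is guaranteed by short-circuiting
(geometric parameter 0 and enhancement factor 1 return a copy), so
bit-exactness holds within a run without depending on the interpolation
backend's rounding.

## Recognition model

Per-frame features feed a **single-stage TCN**: a 1×1 input projection,
then L residual layers of (dilated causal 3-tap convolution → ReLU → 1×1
convolution), then a 1×1 output head. Left-only zero padding makes every
layer causal; the receptive field is n = 1 + (k−1)·Σ dilations with
dilations 2^l. Defaults: 10 layers, kernel 3, hidden width 64 (the standard
single-stage design); the desk-scale tests use 6 layers × width 32.

The network, its backward pass, and the Adam optimizer are implemented
directly on NumPy arrays. Gradients were verified against central finite
differences (see the test suite), and causality is checked by perturbing
future frames and asserting bit-identical earlier outputs.

**Feature extractor.** The `tiny-test-cnn` variant is a fixed, seeded
two-stage strided CNN whose pooled activations are concatenated with raw
per-channel mean/std statistics and projected to the configured feature
dimension. It is frozen: training optimizes the temporal network on cached
features, consistent with the feature-buffer contract below (past features
are constants). The `full-residual-50` variant (f = 2048, 224×224 input) is
a hook for an externally supplied pretrained backbone and raises a clear
error if none is provided.

**Feature buffer.** Features are extracted batch-by-batch (batch size 64 by
default) and appended to a per-video buffer; the temporal network consumes
the full cached sequence and the buffer is reset at the end of each video.

**Loss.** Class weights are inverse-frequency, `w_c ∝ total/(C·count_c)`,
normalized to mean 1 over observed classes; absent classes get weight 0.
The loss is the weight-normalized average `Σ w_{y_t} ℓ_t / Σ w_{y_t}` of
per-frame cross-entropies, so a global rescaling of the weights leaves it
unchanged. Median-frequency or other weightings are drop-in replacements
(the formula is isolated in one function).

## Training and evaluation protocol

Defaults follow the reference protocol for this model family: 50 epochs,
learning rate 1e-5, batch size 64, Adam (the optimizer is otherwise
unstated in that protocol; Adam is the field default). Each epoch reshuffles
videos and re-augments every training video with a freshly sampled plan —
the point of the method is that the dataset is extended with differently
augmented segment compositions, so plans must not be frozen across epochs.
Augmentation modes: `none`, `custom` (the manually designed trio
flip + saturation + rotation applied video-uniformly), `ra`, `ura`, `tra`.
With N = 0 every mode reduces exactly to `none`; this is asserted in tests.

Model selection keeps the epoch with the best validation F1; ties keep the
most recent epoch (on easy synthetic data validation F1 saturates early and
the first-saturating checkpoint is still under-trained).

Evaluation: per video, frame accuracy plus macro-averaged precision, recall
and F1 over the classes present in that video's ground truth; aggregates
are unweighted means across videos, accumulated in sorted-video-id order so
they are independent of caller ordering. The metrics are computed with
scikit-learn and cross-checked in the tests against an independent explicit
confusion-matrix implementation.

**Desk-scale problem sizes.** The test suite and the acceptance script
train the tiny extractor (f = 32, 64×64 frames) with a 6-layer, width-32
TCN for 15 epochs at learning rate 3e-3 on the default synthetic dataset —
sizes chosen so the full pipeline trains in seconds while still exercising
every contract. The 1e-5 default learning rate is matched to full-scale
pretrained backbones and is far too small for this tiny randomly
initialized network, which is why the smoke configurations pass an explicit
rate.

## Synthetic data

Each synthetic video is a sequence of contiguous label runs (each at least
`min_segment_len` frames, adjacent runs of different classes); a class
renders as a base color (evenly spaced hues) modulated by a class-specific
low-frequency sinusoidal texture, plus i.i.d. Gaussian pixel noise. Flat
color makes photometric transforms observable in tests; the texture makes
geometric warps observable. Defaults: 10 videos × 60 frames × 3 classes at
64×64, noise sd 0.03, split 60/20/20 by video. Video v opens with class
v mod n_classes so every class appears in the dataset.

What the generator does **not** emulate: instruments, anatomy, camera
motion, occlusions, lighting drift, class-ambiguous appearance, or
long-range label grammar. Passing the end-to-end test therefore shows the
pipeline is wired correctly and can recover an easy signal — it says
nothing about recognition performance on real endoscopic video, which
requires large annotated datasets and a pretrained backbone.

## Numerical and I/O conventions

- Frame indexing is 0-based; all intervals are half-open.
- fps subsampling keeps every `round(fps_in/fps_out)`-th frame starting at
  index 0 (kept count = ceil(Υ/stride)); resizing is a plain bilinear
  stretch to 224×224 (no letterboxing), overridable.
- Frames are stored as zero-padded PNGs (lossless round-trip); labels as a
  per-video `(frame_index, class_id)` CSV validated for dense coverage;
  datasets as a YAML manifest. Multi-frame image files are read through
  imageio's bundled decoders; frame directories are the primary input form.
- All randomness flows through explicit `numpy` Generators; per-(epoch,
  video) augmentation streams are derived with `SeedSequence`, so training
  is bit-reproducible and TRA with N = 0 reproduces the unaugmented run
  exactly.

## Known limitations

- The visual extractor is frozen during training; end-to-end fine-tuning of
  a pretrained backbone is out of scope at desk scale.
- Segment boundary placement in the `equal` mode is deterministic given T′;
  only the `random` mode randomizes cut positions.
- The NumPy temporal network targets correctness and reproducibility, not
  throughput; it is not meant for full-scale video corpora.
- Compressed video containers (MP4) require a decoder plugin not bundled
  here; extract frames to a directory first.
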