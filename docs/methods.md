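# Methods

## Problem setting

Endoscopic submucosal dissection (ESD) resects an early gastric cancer
lesion en bloc. The fixed specimen is cut into parallel strips at
2.0–3.0 mm intervals, each strip is processed into a histology slide and
scanned as a whole-slide image (WSI), and pathologists annotate cancerous
(CR), intestinal-metaplasia (IR) and normal (NR) mucosa. A *mucosal
recovery map* projects those microscopic annotations back onto the
macroscopic photograph of the sectioned specimen, linking the endoscopic
and pathological views. `mucomap` implements the full computational chain:
tiling, patch segmentation, slide-level reassembly, and section-to-specimen
mapping.

## Segmentation model

The segmenter is a U-Net with a ResNet-34 encoder and squeeze-and-excitation
(SE) channel recalibration:

- **Encoder** — ResNet-34 layout: 7×7/2 stem, 3×3/2 max pool, then four
  stages of basic residual blocks (3, 4, 6, 3) producing skip features at
  strides 4, 8, 16 and 32. Each residual block is two 3×3 conv → batch
  norm → ReLU units plus an identity (or 1×1-projected) shortcut added
  before the final ReLU. The closing batch-norm scale of every residual
  branch is initialized to zero so each block starts as (a projection of)
  the identity; this materially stabilizes short training runs.
- **Decoder** — five stages of 2× nearest-neighbor upsampling followed by
  two 3×3 conv-BN-ReLU units, concatenating the matching encoder skip at
  the first four stages. Nearest-neighbor + convolution avoids the
  checkerboard artifacts of transposed convolutions. Decoder widths are
  `(4w, 2w, w, w, 2w)` for stem width `w`; keeping the tail wide (rather
  than tapering to `w/4`) proved decisive for reaching confident class
  margins in short schedules — a narrow final stage caps the attainable
  logit magnitude under a bounded optimizer path and leaves stray
  false-positive pixels, which the absent-class IoU convention punishes
  severely.
- **SE blocks** — one on every decoder stage output (placement
  configurable; `"none"` gives the plain U-Net baseline used for
  comparison). Squeeze is a global average pool; excitation is a
  C → C/r → C bottleneck (ReLU, then logistic) whose gates rescale the
  channels. The reduction ratio `r` (default 16) must divide every gated
  channel count. There is no single canonical place for SE blocks in a
  U-Net; per-decoder-stage placement applies channel recalibration
  throughout the reconstruction path and is exposed as configuration
  rather than asserted as the unique answer.
- **Head** — 1×1 convolution to 3 classes and a per-pixel softmax (the
  three mask colors imply mutually exclusive classes), so the output is a
  probability map at input resolution. Total downsampling is 32×, hence
  input sizes must be divisible by 32.

Weights are seeded He-normal draws. There is no deep-learning runtime
dependency: convolutions, batch normalization, pooling, the SE gates and
Adam are implemented in numpy (im2col + BLAS matmul) with explicit
forward/backward passes, verified against finite differences. An
ImageNet-pretrained encoder is consequently not available; all results here
are from-scratch training.

## Loss

The training objective is the sum of a soft Jaccard distance and
cross-entropy. The Jaccard part is a *per-pixel* ratio sum,

  l_jd = 1 − (1/N) Σ_i (p_i·y_i + ε) / (p_i + y_i − p_i·y_i + ε),

averaged over pixels and class channels, with smoothing ε = 1 so an
empty-vs-empty summand counts as perfect overlap (the 0/0 case is otherwise
undefined). The cross-entropy part is the conventional
−(1/N_pixels) Σ y log p with probabilities clipped at 1e-7. Note two
deliberate normalization choices: cross-entropy is divided by pixel count so
the two parts are comparable across batch sizes, and the conventional
−Σ y log p orientation is used (the labels-in-the-log variant is undefined
for binary labels). The two parts are reported separately and their sum is
exactly additive.

## Data handling

- **Tiling** — slides are cut into `tile_size` squares (512 in production)
  on a stride-aligned grid, zero-padded right/bottom so every tile is
  full-size; stitching crops the padding. Coordinates are 0-based (x, y) =
  (column, row), half-open. With overlapping strides, stitched probability
  maps are per-pixel averages and exact argmax ties resolve to the lowest
  class index.
- **Blank filtering** — a tile is blank when fewer than 5% of its pixels
  have HSV saturation above 0.07: stained tissue is strongly colored while
  glass background (white) and scanner dropouts (black) are achromatic.
  Both thresholds are configurable; filtering can be applied to either
  split.
- **Oversampling** — lesion patches are rare, so class-presence strata
  (normal-only / contains-CR / contains-IR / both) are equalized by
  duplicating rows with replacement up to the largest stratum, seeded. The
  original manifest is always a sub-multiset of the output. Patch-level
  duplication is used because pixel-level oversampling is ill-defined for
  segmentation.
- **Augmentation** — online, per draw: rotation uniform in 0–359°,
  vertical/horizontal translation up to 50 px (production patch size) with
  reflection padding, and random vertical/horizontal flips, in the fixed
  order rotate → shift → flip. The identical transform is applied to image
  (bilinear) and class map (nearest-neighbor, so no fractional classes).
  The "cropping (shift range 0∼50 pixels)" recipe is read as random
  translation, consistent with its "shift range" wording.
- **Input scaling** — patches are mapped to `(x/255 − 0.5)/0.25` before the
  stem; centering matters for short from-scratch schedules.
- **Training** — Adam (lr 3e-4, β = 0.9/0.999), batch 4, 50 epochs in the
  production configuration; per-epoch mean loss (both parts) and optional
  held-out MIoU are logged; a checkpoint is written per epoch and the final
  model is the last epoch (no early stopping). Runs are deterministic given
  the seed.

## Evaluation

Per-class IoU and Dice are computed from hard-label pixel counts; the mean
is over classes present in prediction *or* truth (a class absent from both
would be 0/0 and is excluded; a class hallucinated by the prediction counts
as IoU 0). Per-patch scores are averaged and reported as mean ± sd. This
convention is harsh on small mistakes — a few stray lesion pixels on a
normal-only patch drop that patch's MIoU from 1.0 to 0.33 — which is why
confident margins matter.

## Synthetic data

No public cohort accompanies the pipeline, so a seeded generator produces
structurally faithful stand-ins:

- **Slides** — an NR-textured field with smooth non-overlapping blob
  lesions (perturbed ellipses; area within ~[0.6, 1.25]·πr²) of the two
  lesion classes, and a pixel-exact class map by construction. Textures are
  base color + Poisson-scattered darker nuclei spots + Gaussian noise
  (sd 5): NR pale pink with sparse nuclei; CR the same hue family at ~10×
  nuclei density; IR a strong blue-purple shift with goblet-like spots. The
  margins are deliberately large so that a small network separates the
  classes within a desk-scale budget; real H&E variation (stain drift,
  folds, blur, nuclear pleomorphism) is *not* modeled, so passing these
  tests demonstrates the pipeline's correctness, not clinical performance.
- **Cases** — one large virtual specimen is cut into parallel strips at an
  interval drawn from 2.0–3.0 mm; each strip is rendered as its own
  slide/mask pair and drawn onto a cork-board photo at `photo_scale`
  (default 0.25 photo px per slide px) with per-section jitter of ±10 px
  and ±3° relative to the nominal grid — emulating strips that never sit
  perfectly straight. The case retains both the true and nominal layouts
  and the ground-truth recovery map, which equals composing each strip's
  class map through its true layout (verified as a self-consistency
  property).

## Section mapping

Placement is a rigid similarity transform per section (scale, rotation,
anchor), applied with nearest-neighbor resampling for labels. Refinement
renders the section into photo scale and maximizes normalized
cross-correlation within a ±15 px search window over a coarse ±4° rotation
grid (1° steps); a peak below 0.2, or a featureless section, returns the
initial layout flagged low-confidence, and the refined score never falls
below the initial one. Full optical-flow stitching of deformed sections is
out of scope; the module boundary accepts a drop-in aligner. Compositing is
in cut order with lower section index winning overlaps (logged). Areas are
reported in mm² from microns-per-pixel and layout scale, or in pixels with
a warning when resolution metadata is absent.

## Desk-scale benchmark protocols

The production configuration is far beyond a single CPU, so the package
fixes two seeded protocols (`mucomap.benchmark`):

- **Segmentation** — 200 training / 50 held-out 128×128 patches; the
  reduced network keeps the ResNet-34 block layout at quarter width
  (w = 16, SE reduction 4) and trains 5 epochs with the production
  optimizer settings (Adam 3e-4, batch 4) and augmentation shifts scaled to
  the patch size (0–20 px). Both the SE network and the identically
  configured plain U-Net are trained and scored, reproducing the
  comparison design rather than any absolute number.
- **Mapping** — a 6-section case at 40 µm/px working resolution
  (strips ~60 px tall, photo scale 0.6); layouts start from the nominal
  grid, are refined, and the rebuilt map is scored against the generator's
  ground truth.

## Numerical and degenerate-case choices

- Mask decoding assigns each pixel the nearest scheme color within a
  tolerance; unmatched pixels (e.g. anti-aliased edges) fall back to
  normal and are counted in a logged tally — unknown tissue is treated as
  background rather than lesion.
- `stride > tile_size` is rejected (it would drop pixels); empty images,
  empty manifests and duplicate section indices are errors; missing tiles
  at stitch time leave class 0 and log a warning.
- Lesion placement retries up to 200 times before failing rather than
  emitting overlapping classes.
- Probability ties at argmax go to the lowest class index (deterministic).
- Batch-norm running statistics use momentum 0.1; evaluation always uses
  running statistics.

## Known limitations

- No ImageNet-pretrained encoder (no deep-learning runtime), so training
  from scratch needs the conditioning measures above; absolute scores on
  real WSIs would require the original data and longer schedules.
- The synthetic texture model is color/density-based; methods that exploit
  it say nothing about robustness to stain variation.
- Rigid per-strip alignment cannot correct the non-rigid deformation and
  shrinkage of real fixed sections.
- `10x magnification` is treated as a target resolution (~1 µm/px) chosen
  at read time; pyramid-level selection from proprietary scanner formats is
  not implemented.
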