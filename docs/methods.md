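# Methods

This note documents the models and procedures implemented in `surgloc`, the
parameter defaults and why they were chosen, the numerical conventions, and
the limits of the synthetic validation.

## 1. Synthetic scene generator (`surgloc.synthetic`)

The generator emulates the *structural* properties of laparoscopic frames
that the pipeline's assumptions rest on, not their appearance:

* **Edge-anchored elongated tools.** Real instruments enter the field of
  view through trocars at the image border, which is precisely the heuristic
  the contour filter exploits.  Each rendered tool is a capsule (thick line
  segment) whose base point lies exactly on a uniformly chosen border, with
  the shaft pointing inward (±45° of the inward normal), capped by a
  brighter tip disk at the interior end.  The tip highlight scales the
  tool's own colour (×1.25) so the class signal is preserved at the tip.
* **Class-distinctive colours.** The seven tools carry mutually distant RGB
  colours (red, blue, yellow, cyan, magenta, green, white) with ±15 jitter.
  This makes presence learnable by a small classifier from image-level
  labels — the property the weak-supervision pipeline needs — without
  claiming visual realism.
* **Imbalance.** Default per-class presence probabilities are the Cholec80
  per-tool occurrence counts normalized by their total (sum = 1, about one
  tool per frame on average): hook ≈ 0.42, grasper ≈ 0.42, scissors ≈ 0.013.
  A frame renders at most `max_tools_per_frame` (default 3) tools.
* **Background.** Dark red-brown base plus two octaves of bilinearly
  upsampled value noise, clipped below intensity 90, optionally Gaussian
  blurred (`blur_sigma`, default 0.6 px) with additive uniform pixel noise
  (`noise_level`, default 0.02).
* **Distractors.** With probability `distractor_rate` (default 0) one dim
  interior blob is added that touches no border and gets no label or box —
  a negative control for the edge-touch filter.

Determinism: each frame's RNG stream is keyed on `(seed, frame_index)`, so
generation is order-independent and byte-identical across runs.  Frames
default to 64×64 px, which is large enough for multi-tool geometry while
keeping a from-scratch training run in the tens of seconds.

Ground truth: each box is the tight axis-aligned box of one tool's pre-blur
pixel support; label bit k is 1 iff at least one class-k tool was rendered.
Boxes use 0-based half-open `(x_min, y_min, x_max, y_max)` with x rightward
and y downward, as does every interface in the package.

**What passing on this generator shows** — that the mechanism works: the
classifier can learn presence under realistic imbalance, its attention lands
on the objects, and the post-processing converts attention into accurate
boxes.  **What it does not show** — robustness to specular highlights,
smoke, blood, occlusion, motion blur beyond mild Gaussian, or deformable
objects; tissue can resemble tools in colour; real attention maps are far
noisier.  Occlusion severity in real data is unquantified, so the
generator's noise options are free parameters rather than calibrated ones.

## 2. Classifier (`surgloc.classifier`, `surgloc.nn`)

**Loss.** Multi-label BCE-with-logits with per-class balancing weights
`CW_k = N/(K·n_k)` computed on the training split only (weights exist to
balance the *training* objective; test prevalence must not leak in).  The
implementation uses the stable form `max(z,0) − z·y + log(1+e^{−|z|})` and
is tested to 1e-9 against a naive direct-formula oracle.  The exact identity
`Σ_k CW_k·n_k = N` (each term is `N/K`) is asserted for random count
vectors.  A class with zero training occurrences has no defined weight:
`compute_class_weights` raises; the training entry point offers an explicit
`zero_count_policy="unit"` fallback (weight 1, logged) for small synthetic
draws where a rare class may vanish from a split.  Batch reduction is the
mean of per-sample losses.

**Surrogate backbone.** `surrogate_small` is a ~5k-parameter NumPy CNN:
3×3 conv (16 ch) → ReLU → 2×2 max pool → 3×3 conv (32 ch) → ReLU (the
designated feature layer) → **global max pooling** → linear logits.  All
layers implement exact analytic backprop; training and inference are fully
deterministic given the seed.

*Why max pooling for the presence head:* multi-label presence semantics is
"at least one location responds".  With average pooling the logit scales
with object area, which systematically ranks small or rare tools below
large off-class tools; with max pooling the logit is area-independent.
Grad-CAM is unaffected in form — channel weights are spatially averaged
logit gradients either way.

*Output-bias initialization:* head biases start at the log-odds of each
class's training prevalence, so no optimizer steps are spent learning base
rates — standard practice for sparse multi-label outputs.

**Training schedules.** `TrainConfig` defaults to the fine-tuning recipe
appropriate for a large pretrained encoder: Adam (β = 0.9/0.999), lr 5e-5,
batch 32, 1000 linear warmup steps, 8 epochs, constant rate after warmup
(warmup is specified for this setting; no decay is assumed — the simplest
faithful schedule).  That recipe cannot move a randomly initialized network
within 8 epochs of a few hundred frames (~100 optimizer steps), so
`surrogate_train_config()` keeps the epoch count and betas but uses lr 5e-3,
warmup 20 and batch 8 — the smaller batch exists purely to raise the number
of optimizer steps per epoch.  Convergence is monitored as a logged
per-epoch loss curve (also plotted by the CLI), not by an early-stopping
rule.

Input frames are consumed at their native 64×64 by the surrogate; a
pretrained-encoder adapter would resize to its own convention (224×224
square, bilinear) via the same documented preprocessing hook.

The `pretrained_transformer` backbone name is a registry hook only: for a
transformer encoder the designated feature layer is the final token grid
reshaped to its patch lattice with the classification token dropped — only
spatially indexed activations admit a heat map — but no transformer
implementation ships with the package.

## 3. Grad-CAM (`surgloc.gradcam`)

The backward pass targets the **pre-sigmoid logit** of the requested class
(a sigmoid-attenuated gradient would vanish exactly where the model is most
confident).  Channel weights are the spatial means of the feature-layer
gradients; the map is the rectified weighted sum of feature maps.
Rectification is exposed as a flag (default on): only features with
positive influence on the class score should contribute evidence *for* the
class.  Upsampling is bilinear to the input size, followed by min–max
normalization to [0, 1]; a constant map (no spatial signal) normalizes to
all zeros rather than dividing by zero.  Quantization `round(255·v)` happens
only at the hand-off to Otsu; the heat map itself stays real-valued.

## 4. Heat map → boxes (`surgloc.localization`)

* **Otsu threshold.** The threshold maximizing between-class variance of the
  256-bin histogram, computed in *exact integer arithmetic* (the criterion
  is a ratio of integer polynomials; comparisons are done by
  cross-multiplication).  Mathematical ties — e.g. empty histogram bins
  between the two modes — therefore break deterministically toward the
  smallest threshold instead of on floating-point rounding.  Equivalence
  with an exhaustive rational-arithmetic search is asserted exactly;
  agreement with scikit-image's implementation is cross-checked on bimodal
  images (identical foreground partition).  Foreground is `value > t`;
  a constant image raises a degenerate-image signal that callers treat as
  an empty mask.
* **Contours.** 8-connected components (SciPy labelling), ordered by their
  first pixel in raster order; each carries its pixel set, an ordered
  boundary trace (marching squares snapped onto component pixels) and its
  area.  Component counts are verified against an explicit flood-fill
  oracle.
* **Filtering.** A contour survives iff some pixel lies within
  `edge_margin_px` (default 2) of any border *and* its area is at least
  `min_area_fraction` (default 0.5%) of the frame.  The margin tolerates
  anti-aliased borders; the floor suppresses threshold speckle.  These two
  rules plus NMS are the full false-positive-removal chain; no contour
  clustering step is implemented (a clustering of contours is sometimes
  mentioned alongside such pipelines but has no defined procedure here —
  users should be aware detections are per-component).
* **NMS.** Greedy: keep the highest-confidence remaining detection, discard
  others with IoU above `nms_iou_threshold` (default 0.5); ties break by
  larger area, then input order; output sorted by confidence descending.
  Verified exactly, including ordering, against a brute-force oracle.
* **Confidence.** Every box of class k in a frame carries the classifier's
  sigmoid probability for k — the only confidence signal weak supervision
  provides.  Classes at or below `presence_threshold` (default 0.5) are
  skipped entirely.

## 5. Evaluation (`surgloc.evaluation`)

* **AP** is the non-interpolated rank sum `Σ_k Precision(k)·ΔRecall(k)`
  over the descending score ordering (stable sort; ties keep input order).
  A sometimes-seen extra `1/n` prefactor on this sum would prevent perfect
  rankings from reaching AP = 1 and is treated as typographical — the bare
  rank sum is the standard definition and matches scikit-learn's
  `average_precision_score`, against which the implementation is
  cross-checked.  AP is undefined without positive labels; report builders
  either propagate that or, explicitly opted in, drop the class from the
  mean with a log entry.
* **Matching** is greedy one-to-one per class by descending confidence
  (ties: larger area), claiming the best-IoU unmatched truth above the IoU
  threshold; one detection can never satisfy two truths.  Mode `paper`
  follows the convention in which *every* failed detection — low confidence,
  or confident but IoU ≤ 0.5 — counts as a false negative (the FN clause is
  the more specific one and takes precedence where the clauses overlap).  A
  structural consequence is that paper-mode precision is 1 whenever any true
  positive exists; and since F1 weighs FP and FN symmetrically, paper and
  standard F1 coincide exactly when no emitted detection is below the
  confidence threshold (which is the case for the pipeline's own output,
  as the presence gate already applies it).  Mode `standard` is the
  COCO-style convention (low-confidence detections ignored; confident
  unmatched detections are FPs).  Both are always reported side by side.
* **Zero denominators**: precision/recall of an empty confusion cell is 0
  (flagged), F1 of (0, 0) is 0.
* **Splits** are group-aware at video level.  k-fold partitions the shuffled
  video list into test sets whose sizes differ by at most one — for 80
  videos and k = 3 that is {27, 27, 26}; an exactly equal 26-video split of
  80 is arithmetically impossible (3×26 = 78), so the balanced partition is
  used and documented rather than silently dropping videos.  The
  fixed-fraction scheme reproduces the classic 40/40 comparison split.
* Percentages are reported to 2 decimals; all means are unweighted across
  classes.

## 6. Validation studies (`surgloc.studies`)

**Planted-blob study.** 200 synthetic heat maps, each with 1–3 blobs
centred on a frame border and 0–2 interior distractor blobs, run through
the thresholding/contour/filter/NMS chain with default parameters.  Blobs
are steep-edged super-Gaussians `exp(−(d/σ)^6)` (σ ∈ [4, 7] px for planted,
[2.5, 4] for distractors): their thresholded support is nearly independent
of where Otsu lands between ~30% and ~70% of peak height, so each blob has
a well-defined ground-truth extent (half-maximum box).  Placement enforces
2σ-padded separation so supports stay disjoint.  Recovery = detection with
IoU ≥ 0.5 against a planted box; rejection = no detection with IoU ≥ 0.5
against a distractor box.  The contract is ≥ 90% recovery and ≥ 95%
rejection; with default parameters the measured rates are 100%.

**End-to-end study.** 500 frames, 8 videos, default (Cholec80-proportional)
prevalences; 50/50 video split; surrogate trained 8 epochs with its default
recipe; classification and localization scored on the held-out videos.  The
contract is held-out mAP ≥ 0.90 and paper-mode localization mean F1 ≥ 0.60;
typical runs land at mAP 0.92–0.99 and F1 0.75–0.94 depending on seed.
These bounds validate the *mechanism* on separable synthetic scenes; they
say nothing about performance on real surgical video, which requires a
large pretrained backbone and the real datasets.

## 7. Known limitations

* The surrogate's receptive field is small; it localizes by colour and
  local texture, not shape — adequate for the synthetic distribution,
  not for real scenes.
* Paper-mode matching cannot produce false positives by construction; users
  comparing against precision-sensitive baselines should quote the standard
  mode as well.
* Heat-map quality degrades for classes the classifier is unsure about; the
  presence gate hides most of this, but borderline probabilities (≈ 0.5)
  produce unstable box counts between seeds.
* Checkpoints store raw parameter arrays (`.npz` + JSON sidecar); there is
  no cross-version migration.
* No temporal modelling: every frame is processed independently.
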