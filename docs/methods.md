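# Methods

`polypdet` re-implements a polyp-detection method built from three parts: a
compact single-stage anchor-based detector, a **parallel** channel/spatial
attention block (P-CBAM) inserted at the bottom of the backbone, and a
**Gaussian-Wasserstein** bounding-box regression loss (GWD) replacing the
usual CIoU term. This note records the model as implemented, the parameters
that matter, the numerical choices, and what the synthetic-data experiments
do and do not show.

## Detector

The architecture follows the CSP single-stage family: a backbone of
stride-2 Conv–BatchNorm–SiLU units and C3 blocks (split–transform–concat with
`n` bottlenecks) closed by SPPF; an FPN (top-down) + PAN (bottom-up) neck;
and an anchor-based head emitting, per scale `s ∈ {8, 16, 32}`, a tensor of
shape `(batch, anchors, H/s, W/s, 5 + n_classes)`.

* **Scaling.** All channel counts derive from the reference table
  (64, 128, 256, 512, 1024) × `width_multiple`, and block repeats from
  (3, 6, 9, 3) × `depth_multiple`. The shipped default (0.25 / 0.33) yields
  ≈1.77 M parameters — small enough to train on one CPU core in minutes.
* **SPPF.** Three serial 5×5 stride-1 max-pools; their outputs equal parallel
  SPP pooling with kernels 5/9/13 exactly (asserted in the tests), while
  costing three small pools instead of one large one.
* **Decoding.** Per cell `(i, j)` with anchor `(a_w, a_h)`:
  `cx = (2σ(t_x) − 0.5 + i)/W_g`, `w = (2σ(t_w))² a_w` (likewise `cy`, `h`);
  confidence is objectness × best class score; class-wise greedy NMS at IoU
  0.45, confidence threshold 0.25. The transform has an exact inverse
  (`encode_box`), and an encode→decode round trip recovers boxes to ≤1e-6.
* **Assignment.** A target matches anchor `a` at a scale when
  `max(wh_t/wh_a, wh_a/wh_t) < 4`; each match claims its center cell plus the
  nearer neighbor cell along each axis. Objectness targets are 1 on positive
  cells, 0 elsewhere.

The engine underneath is a purpose-built numpy reverse-mode autodiff module
(`polypdet.autodiff`): im2col convolution, max-pooling, nearest upsampling,
batch normalisation and binary cross-entropy, each gradient-checked against
central finite differences. Python scalar constants are kept at float32 so a
float32 model never silently upcasts.

## Parallel attention (P-CBAM)

For an input feature map `F ∈ R^{H×W×C}`:

* channel gate `M_c(F) = σ(MLP(avgpool(F)) + MLP(maxpool(F)))`, pooling over
  space; the MLP is a shared two-layer bottleneck `C → max(C/r, 1) → C` with
  ReLU between (reduction ratio `r`, default 16);
* spatial gate `M_s(F) = σ(f^{7×7}([avgpool(F); maxpool(F)]))`, pooling over
  channels, 7×7 convolution with symmetric padding 3;
* fusion `F_out = (α₁·F_c + α₂·F_s + α₃·F) / (α₁+α₂+α₃)` with
  `F_c = M_c ⊙ F`, `F_s = M_s ⊙ F`.

Unlike serial CBAM, both gates see the *original* `F`; a regression test
asserts the two blocks genuinely differ on generic inputs. Because the fused
output is a normalized convex combination, it lies elementwise inside the
min/max envelope of `{F_c, F_s, F}`, and `α = (0, 0, 1)` reproduces `F`
exactly.

Design choices that were genuinely open:

* The original formulation writes the channel transform only as "Conv"; we
  follow the CBAM convention it cites — a shared two-layer bottleneck applied
  to both pooled descriptors. The no-sharing alternative is noted but not
  implemented.
* Whether the fusion weights are learned is unstated; here they are learnable
  scalars kept positive by a softplus reparameterisation, initialised to
  (1, 1, 1), with `learn_alphas: false` freezing them. No claims are made
  about recovered α values.
* Placement: one block, after the last backbone C3 and before SPPF,
  switchable via `model.attention`.
* Numerics: the functional gates clip to the nearest representable values in
  the open interval (0, 1), so the documented strict bounds hold even where
  the float sigmoid would saturate.

## Gaussian-Wasserstein box loss

A box `(cx, cy, w, h)` maps to the Gaussian `N(μ, Σ)` whose unit Mahalanobis
level set is the box's inscribed ellipse: `μ = (cx, cy)`,
`Σ = diag((w/2)², (h/2)²)`. (The source prints the density with `Σ` rather
than `Σ⁻¹` in the exponent; only the `Σ⁻¹` reading makes the ellipse equation
and the density consistent, so that is what is implemented.) Between two such
Gaussians

    W₂²(A, B) = ‖μ_a − μ_b‖² + ‖Σ_a^{1/2} − Σ_b^{1/2}‖_F²
              = Δcx² + Δcy² + ((w_a−w_b)/2)² + ((h_a−h_b)/2)²,

verified against the general matrix-square-root formula to ≤1e-10 on 1,000
random pairs. The property that motivates the loss is explicit: under a pure
translation δ, `W₂² = δ²` *independent of box size*, whereas IoU between two
δ-shifted boxes collapses to 0 as the boxes shrink.

The distance is unbounded, so the loss squashes it:

    L_gwd = 1 − 1/(τ + ln(1 + W₂²)),   τ ≥ 1 (default 1),

strictly increasing in `W₂²` with range `[1 − 1/τ, 1)`; a config switch
(`gwd_squash: linear`) selects `1 − 1/(τ + W₂²)` instead. The squashing form
and τ are this package's choices — the original work does not specify a
normalisation.

The composite training loss is `L = w_cls·L_cls + w_obj·L_obj + w_box·L_box`
(defaults 0.5 / 1.0 / 1.0): binary cross-entropy for objectness over every
anchor cell (per-scale balance 4.0/1.0/0.4, small grid emphasised) and for
classification over positives (zero when there is a single class), and the
mean GWD loss over positive assignments. `box_loss: ciou` restores the CIoU
baseline for ablation parity; GWD fully replaces CIoU, it is never mixed.

## Data pipeline

* **Labels.** YOLO text (`class cx cy w h`, normalized, 6-decimal output);
  read∘write is the identity to 5e-7.
* **Split.** Seeded shuffle, then largest-remainder apportionment of 8:1:1
  (1,200 → 960/120/120; 9 → 7/1/1), ties toward train.
* **Mosaic.** Four quadrant crops around a center jittered in the central 50%
  of the canvas; remapped boxes are clipped and dropped below 1 px. Mixup
  (`Beta(8,8)` blend) is implemented but off by default.
* **Anchors.** k-means on (w, h) pairs with 1 − IoU dissimilarity
  (Euclidean selectable), deterministic farthest-point initialisation — the
  result is invariant to input permutation. Nine anchors, area-sorted, three
  per scale.

## Synthetic scenes

Real colonoscopy frames are not distributable with this package, so training
and evaluation run on a seeded generator that emulates only the gross
features a detector sees: a pink-red mucosal background with a smooth
directional gradient, radial vignette, a few specular highlights and texture
noise; polyps as rotated soft-edged ellipses offset from the local background
by a contrast Δ (intensity units), non-overlapping by rejection sampling,
labeled by the ellipse's axis-aligned bounding box. Ellipse aspect ratio is
bounded to [0.6, 1] so the box-to-mask IoU stays ≥0.6.

Scenario presets fix the study conditions: `typical` (Δ=35, radii
0.05–0.14), `low_contrast` (Δ=10), `small` (all box sides ≤0.08), `multi`
(3–5 polyps). The default mix is 40/20/20/20.

What passing tests show: the pipeline learns, the loss decreases, and recall
on held-out synthetic scenes is high. What they do **not** show: performance
on clinical imagery — the generator has no bowel-preparation artifacts, no
motion blur, no flat or sessile morphology variation, and its background
statistics are far simpler than tissue.

## Desk-scale experiment sizes

The end-to-end check trains the 0.25/0.33 model on 160 training scenes
(of 200 generated, 8:1:1 split) at 128×128 for 12 epochs, batch 8, Adam with
cosine decay from 5e-3 to 5e-4 — about one minute on one CPU core — then
evaluates the 20-scene held-out split at IoU 0.3, confidence 0.25. Under
seed 1 this reaches recall ≈0.93 with training loss falling 0.73 → 0.06.
Precision at that operating point is low (≈0.3): twelve epochs saturate
recall long before the objectness head learns to suppress vignette corners
and specular dots, and the health bar for the pipeline is recall.

## Known limitations

* Batch-norm tie-breaking in max-pool gradients routes ties to the first
  window slot; ties are measure-zero for continuous activations.
* Training determinism is exact for a fixed seed on a fixed BLAS; across
  BLAS builds, floating-point reduction order may differ.
* The checkpoint format (`.npz` archive, versioned) stores parameters,
  buffers, anchors and config; optimizer state is not checkpointed.
* `wasserstein2_sq` assumes the diagonal covariances produced by
  `box_to_gaussian`; rotated-box Gaussians are out of scope.
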