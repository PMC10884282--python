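# polypdet

Detection of colorectal polyps in colonoscopy imagery with a compact
single-stage detector, a **parallel channel/spatial attention block
(P-CBAM)** and a **Gaussian-Wasserstein bounding-box loss (GWD)**.

Polyps are early precursors of colorectal cancer, and the cost of a missed
polyp is far higher than that of a false alarm. Two properties of the imagery
make detection hard: polyps often show very low contrast against the
surrounding mucosa, and many are small — small enough that IoU-based box
losses lose their gradient the moment a predicted box stops overlapping the
target. This package is for researchers and engineers who want a tested,
desk-scale (CPU-trainable) implementation of the two ideas addressing those
failure modes, together with the surrounding detector, data pipeline,
synthetic-scene generator and evaluation code.

## Method

**Parallel attention.** For a feature map `F ∈ R^{H×W×C}`, a channel gate and
a spatial gate are computed *from the same input* and fused with a residual:

    M_c(F) = σ(MLP(avgpool(F)) + MLP(maxpool(F)))        ∈ (0,1)^{1×1×C}
    M_s(F) = σ(f^{7×7}([avgpool(F); maxpool(F)]))        ∈ (0,1)^{H×W×1}
    F_out  = (α₁·M_c⊙F + α₂·M_s⊙F + α₃·F) / (α₁+α₂+α₃)

Serial CBAM chains the gates (channel first, spatial on the gated map);
giving both branches equal priority avoids the serial block's bias. One
P-CBAM block sits at the bottom of the backbone, before SPPF.

**Gaussian-Wasserstein box loss.** Each box maps to the 2-D Gaussian whose
unit level set is its inscribed ellipse, `μ = (cx, cy)`,
`Σ = diag((w/2)², (h/2)²)`, and boxes are compared by

    W₂²(A,B) = ‖μ_a − μ_b‖² + ‖Σ_a^{1/2} − Σ_b^{1/2}‖_F²
             = Δcx² + Δcy² + ((w_a−w_b)/2)² + ((h_a−h_b)/2)²

squashed into `L_box = 1 − 1/(τ + ln(1 + W₂²))`. Under a pure shift δ,
`W₂² = δ²` at *every* box size, while the IoU of two δ-shifted tiny boxes is
already zero — which is exactly why GWD keeps a useful gradient for small
polyps. The composite loss is `L = L_cls + L_obj + L_box` (binary
cross-entropy for the first two).

The detector is a width/depth-scalable CSP-style single-stage network
(C3 blocks, SPPF, FPN+PAN neck, anchor-based head at strides 8/16/32) running
on a small numpy autodiff engine — no GPU or deep-learning framework needed.
Anchors come from IoU-distance k-means on the dataset's box shapes.

Because the original hospital dataset is private, the package ships a seeded
generator of colonoscopy-like scenes (mucosal background with vignette and
specular highlights; elliptical polyps with controllable contrast, size and
count) with scenario presets for the hard cases: `low_contrast`, `small`,
`multi`.

## Worked example

Generate 200 synthetic 128×128 scenes, estimate anchors, train the tiny
(width 0.25 / depth 0.33, ≈1.8 M parameter) model for 12 epochs on CPU
(~1 minute), and evaluate:

```bash
polypdet generate demo --n 200 --size 128 --seed 7
polypdet anchors demo/manifest.yaml --out demo/anchors.yaml --k 9
polypdet train demo/manifest.yaml --out demo/run -c demo_cfg.yaml
polypdet eval demo/run/checkpoint.npz demo/manifest.yaml --out demo/report.csv -c demo_cfg.yaml
polypdet detect demo/run/checkpoint.npz demo/images/scene_00003.png -c demo_cfg.yaml
```

with `demo_cfg.yaml`:

```yaml
model: {width_multiple: 0.25, depth_multiple: 0.33}
train: {epochs: 12, img_size: 128}
seed: 7
```

Printed output (seed 7):

```
wrote 200 scenes to demo
wrote 9 anchors to demo/anchors.yaml
final loss 0.0617  val P=0.336 R=0.929 F1=0.494
checkpoint: demo/run/checkpoint.npz
IoU 0.30: TP=395 FP=755 FN=11 P=0.343 R=0.973 F1=0.508
IoU 0.50: TP=357 FP=793 FN=49 P=0.310 R=0.879 F1=0.459
class=0 conf=0.544 cx=0.5583 cy=0.6457 w=0.1253 h=0.1318
class=0 conf=0.532 cx=0.7270 cy=0.4489 w=0.2148 h=0.2154
...
```

Reading this: training loss fell to 0.06; on the 8:1:1 validation split the
model recovers 93% of polyps at IoU 0.3 (recall), at a permissive operating
point that also admits many duplicates/false alarms (precision 0.34 — twelve
epochs saturate recall long before the objectness head learns to reject
vignette corners). The `detect` lines are normalized center-format boxes with
confidences; the top detection (cx 0.558, cy 0.646, w 0.125, h 0.132) matches
the scene's first ground-truth object (0.545, 0.618, 0.157, 0.136). The eval
rows show the expected monotonicity: raising the IoU bar converts matches
into misses.

Evaluation metrics are the standard triple

    Precision = TP/(TP+FP)    Recall = TP/(TP+FN)    F1 = 2PR/(P+R)

under greedy confidence-ordered one-to-one matching.

See `docs/methods.md` for the full model description, parameter defaults,
and what the synthetic scenes do and do not demonstrate.

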