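"""Published precision/recall/F1 operating points for polyp detection.

These are the reported evaluation rows of the ablation study (baseline
detector, serial attention, parallel attention, Wasserstein box loss, and the
full model) and of the model comparison on the same private colonoscopy
dataset. They serve as arithmetic regression fixtures: the F1 column must be
the harmonic mean of the printed precision and recall, and the improvement
deltas quoted for the full model must equal the row differences.

Each row is (label, precision, recall, f1) exactly as printed (3 d.p.).
"""

ABLATION_ROWS = [
    ("baseline", 0.871, 0.877, 0.874),
    ("baseline+cbam", 0.878, 0.886, 0.882),
    ("baseline+pcbam", 0.882, 0.890, 0.886),
    ("baseline+gwd", 0.879, 0.895, 0.887),
    ("baseline+pcbam+gwd", 0.885, 0.913, 0.899),
]

COMPARISON_ROWS = [
    ("rcnn", 0.907, 0.889, 0.897),
    ("faster-rcnn", 0.914, 0.896, 0.905),
    ("yolov4", 0.881, 0.879, 0.880),
    ("yolov7", 0.783, 0.764, 0.773),
    ("yolov8", 0.904, 0.878, 0.891),
    ("rt-detr-r50", 0.868, 0.872, 0.870),
    ("pcbam+gwd (ours)", 0.885, 0.913, 0.899),
]

# quoted improvements of the full model over the baseline (percentage points)
FULL_MODEL_PRECISION_DELTA = 0.014
FULL_MODEL_RECALL_DELTA = 0.036
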