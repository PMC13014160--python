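"""Pretrain the reference detector on the source domain and evaluate it.

Trains the CPU reference detector on a small labeled FDG-like cohort, then
reports AP at three IoU thresholds and FROC operating points on held-out
subjects from both domains, showing the cross-domain performance drop that
the adaptation loop is meant to close.
"""

from tracershift import (
    AdaptationConfig,
    AnchorSet,
    MinimalDetector,
    average_precision,
    default_domain_specs,
    froc_curve,
    generate_dataset,
    kmeans_shapes,
    normalize_channels,
    pretrain_source,
    sensitivity_at_fp,
)

fdg, psma = default_domain_specs()
train = [normalize_channels(s) for s in generate_dataset(fdg, 20, shape=(48, 48, 48), seed=0)]
held_out = {
    "FDG (in-domain)": generate_dataset(fdg, 12, shape=(48, 48, 48), seed=100),
    "PSMA (cross-domain)": generate_dataset(psma, 12, shape=(48, 48, 48), seed=200),
}

# anchor shapes from k-means over the labeled source boxes
boxes = [b for s in train for b in s.boxes]
anchors = AnchorSet(tuple(map(tuple, kmeans_shapes(boxes, K=3, seed=0))))
print("source k-means anchors (voxels):",
      [tuple(round(float(v), 1) for v in s) for s in anchors.shapes])

cfg = AdaptationConfig(seed=0)
detector = MinimalDetector(n_anchors=3, seed=0)
losses = pretrain_source(detector, train, anchors, epochs=60, cfg=cfg)
print(f"pretraining loss: {losses[0]:.3f} -> {losses[-1]:.3f} over 60 epochs\n")

for name, subjects in held_out.items():
    per = [
        (detector.predict(normalize_channels(s).volume(), anchors), list(s.boxes))
        for s in subjects
    ]
    aps = {thr: average_precision(per, thr) for thr in (0.1, 0.25, 0.5)}
    curve = froc_curve(per, iou_thr=0.1)
    print(f"{name}:")
    print("  " + "  ".join(f"AP@{t}={v:.3f}" for t, v in aps.items()))
    print(f"  sensitivity at 1 FP/scan: {sensitivity_at_fp(curve, 1.0):.3f}")

print(
    "\nThe same weights lose most of their precision on the shifted tracer:\n"
    "its lesions are smaller, dimmer, and sit in unfamiliar background\n"
    "clutter. That gap is the adaptation target."
)
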