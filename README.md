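# spinegrader

Automated analysis of sagittal spinal MR scans: detection and anatomical
labelling of vertebral bodies, followed by per-disc and per-vertebra
radiological grading. The package is aimed at researchers in medical image
analysis and at spine/back-pain research groups who need a transparent,
fully testable reference implementation of this pipeline — every stage is
trainable and verifiable at desk scale on a bundled synthetic spine-phantom
generator, without access to clinical data.

## The method

**Stage 1 — detection by Vector Field Regression (VFR).** A
fully-convolutional network maps each sagittal slice (or 50 cm patch of it,
40% overlap) to 13 channels: Gaussian heatmaps for the four vertebral-body
corner types and the centroid (peak 1, σ ∝ √area), plus a 2-component
vector field per corner type that, near each corner, points at the owning
centroid. Training minimises

  L = L_detect + L_group,

where L_detect is a class-balanced L1 loss on the heatmaps (pixels with
target ≥ T weighted N/(N+P), others P/(N+P), T = 0.01) and L_group is the
summed squared field error over square corner neighbourhoods of edge
√area⁄3. At inference, non-maximum suppression yields landmarks; each
corner is assigned to the centroid its field points closest to (greedy in
the pointing error ‖p + v(p) − c‖, with uniqueness); a quad missing one
corner is completed by point reflection through the centroid, and four
consistent leftover corners recover a missed centroid. Per-slice quads are
stacked into 3-D vertebra instances by polygon IOU across neighbouring
slices.

**Stage 2 — level labelling.** An appearance classifier predicts a 23-way
distribution (C3…S1) for each detected vertebra from a volume around it;
the temperature-softmaxed (T = 0.1) predictions are written onto the
instance's height band of an H×23 probability-height map, refined by a
1-D convolutional context network along the height axis, and decoded by a
penalised beam search into a strictly descending, repeat-free level
sequence (skipped levels cost (g−1)·log 0.2, a transitional lumbosacral
variant costs log 0.1).

**Stage 3 — grading with a context-aware spinal transformer (CAST).** Disc
volumes (2:1 aspect, endplate-aligned) or vertebral-body volumes are
encoded slice-by-slice; learned-query attention pools the slices into one
token per volume, a 2-layer transformer with learnt level and sequence
embeddings lets information flow between vertebrae and MR sequences
(T1w/T2w/STIR/… in any subset), a final attention pool merges sequences
per unit, and per-task linear heads emit class probabilities. Units
labelled "unknown" contribute no loss; studies with only a study-level
flag are trained through the most positive per-unit prediction
(multiple-instance learning).

All neural components run on a small numpy autograd engine inside the
package (`spinegrader.nn`) — no deep-learning framework is required.

## Worked example

Generate a lumbar phantom study, train the tiny demo models and run the
full pipeline:

```python
from dataclasses import replace
from spinegrader import pipeline, zoo
from spinegrader.scan_io import Sequence
from spinegrader.synthetic import PhantomSpec, generate_phantom

bundle = zoo.train_demo_bundle(seed=0)              # ~10 minutes, one CPU
spec = PhantomSpec(n_vertebrae=7, lowest_level="S1", noise_sd=0.02, seed=903)
study = {"T2w": generate_phantom(spec)[0],
         "T1w": generate_phantom(replace(spec, sequence=Sequence.T1W))[0]}
cfg = pipeline.PipelineConfig(patch_edge_cm=15.0)   # phantom field of view
report = pipeline.run_pipeline([study], bundle, seed=9, config=cfg)
for inst in report["studies"][0]["instances"]:
    print(inst["level"], [round(v, 1) for v in inst["centroid_mm"]],
          round(inst["confidence"], 3))
print(len(report["studies"][0]["discs"]), "discs graded")
```

prints the decoded level, millimetre centroid and detection confidence of
each vertebra, superior to inferior:

```
T12 [6.0, 16.2, 24.1] 0.875
L1 [6.0, 38.5, 25.9] 0.885
L2 [6.0, 62.5, 27.6] 0.885
L3 [6.0, 85.5, 27.9] 0.875
L4 [6.0, 110.1, 28.0] 0.893
L5 [6.0, 136.2, 26.5] 0.9
S1 [6.0, 161.6, 23.9] 0.877
6 discs graded
```

— all seven phantom vertebrae detected and labelled T12…S1, and all six
intervening discs graded jointly from the T1w and T2w stacks. Each disc
entry carries softmax probabilities for the two synthetic tasks
("degeneration": the disc's own T2 signal is low; "neighbour": the
adjacent disc's signal is low, solvable only with context) plus the
slice- and sequence-attention weights; the first disc of this study, with
a heavily degenerate grade, prints
`{'degeneration': [0.0, 1.0], 'neighbour': [0.0, 1.0]}`. Labels on these
phantoms are correct for roughly nine vertebrae in ten (the decoded
sequence occasionally shifts by one level on scans without a strong
anatomical anchor, mirroring the within-one-level failure mode seen on
real scans).

A command-line interface mirrors the stages:

```bash
spinegrader make-phantoms --output phantoms/ --n 3 --seed 0
spinegrader train-demo --output ckpt/ --seed 0
spinegrader pipeline --input phantoms/phantom_000.nii.gz \
    --checkpoint ckpt/ --output report.json
```

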