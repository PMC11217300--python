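# Methods

`spinegrader` implements a three-stage analysis of sagittal spinal MR:
vertebral-body detection by vector field regression, anatomical level
labelling by a penalised beam search over appearance/context predictions,
and per-disc / per-vertebra radiological grading by a context-aware
transformer. Every stage is trainable and testable at desk scale on a
synthetic spine-phantom generator that ships with the package. This note
records the model assumptions, the parameters that matter, and the design
choices made where the design was genuinely open.

## Coordinate conventions

All grids are indexed `(slice, row, col)`, 0-based, half-open boxes. Row 0
is the most superior row, so the row axis doubles as the superior→inferior
"height" axis used by the labeller. The physical position of in-plane pixel
`(r, c)` is `(r·row_mm, c·col_mm)` from the slice top-left. Patch resampling
is corner-aligned: patch pixel `(0, 0)` sits exactly on the window origin,
which makes affine round trips exact and is asserted in the tests.

Intensity normalisation rescales the 1st–99th percentile to `[0, 1]`
(robust to spike artefacts); a constant image maps to zeros. The source
material does not state a normalisation, so this is the package's choice.

## Vector field regression (detection)

Each vertebral body (VB) is annotated per slice as a quadrilateral with
four named corners (AS, PS, AI, PI) and a centroid. The detector is a
fully-convolutional network with 13 output channels per slice patch:

* **5 detection channels** — one Gaussian heatmap per landmark type, peak
  value 1, `σ = c_peak·√A` where `A` is the quad area. `c_peak` defaults to
  0.05 at the clinical 224-px patch profile and to 0.2 for the 64-px tiny
  profile; the proportionality constant is a free parameter of the method
  and is exposed in configuration.
* **8 grouping channels** — for each corner type, a two-component vector
  field defined on a square neighbourhood of edge `√A/3` centred on the
  corner. We fix the field direction as *value at (i,j) = centroid − (i,j)*,
  i.e. the field points **toward** the owning centroid, so the grouping
  error of corner `p` with centroid `c` is `‖p + v(p) − c‖`. The opposite
  sign convention is equivalent up to a global flip; one convention is fixed
  package-wide and documented here.

**Losses.** The detection channels use a class-balanced L1 loss: pixels
whose target is ≥ T (T = 0.01) are weighted `N/(N+P)` and the rest
`P/(N+P)`, with `P`/`N` the per-channel positive/background pixel counts.
A channel with no positive pixels contributes zero (the weights degenerate),
which the implementation treats as a defined limit. The grouping channels
use a plain summed squared error over the neighbourhoods. For *training*
the composite objective scales the grouping term by `group_weight`
(default 1/16): the squared field errors are two orders of magnitude larger
than the balanced L1 term at initialisation and otherwise dominate the
shared trunk's gradients. The reference loss functions used in tests are
unscaled.

**Decoding.** Landmarks are local maxima ≥ 0.3 with minimum separation 4 px
(both configurable; unstated in the source method), refined to sub-pixel
positions by a separable log-parabola fit, exact for Gaussian profiles. At
most 64 peaks per channel are kept, which bounds the grouping cost on
degenerate plateau heatmaps from untrained or saturated models.

**Grouping.** All (corner, centroid) pairs are scored by the pointing error
and accepted greedily in increasing error under uniqueness: each corner
joins at most one centroid, each centroid takes at most one corner per
type. A simple per-centroid loop could double-assign corners; the greedy
global variant is validated against the optimal per-type assignment
(Hungarian) in the tests and agrees on ≥ 99% of randomised instances.
Pairs with error above `τ = 0.5 × median nearest-centroid spacing` stay
unassigned. Centroids with three corners are completed by point reflection
of the diagonally opposite corner through the centroid (exact for
parallelograms; within 15% of the diagonal for the sheared phantoms);
centroids with fewer corners are dropped. Four leftover corners, one per
type, whose pointing endpoints mutually agree within `τ` recover a missed
centroid at their mean endpoint.

**Patching.** Slices larger than one patch are tiled with square physical
windows of edge 50 cm and 40% overlap (stride 60% of the edge); a smaller
slice yields exactly one patch. Landmarks are mapped back through the
patch affine (pointing vectors rescaled per axis) and duplicates of the
same kind within 3 mm are merged keeping the higher score. The merge
radius is a package choice.

**Stacking.** Per-slice quads are stacked into 3-D instances starting from
the slice with the most detections and extending outward; a quad attaches
to the instance whose adjacent-slice quad overlaps it most (polygon IOU
≥ 0.5, greedy one-to-one, ties by IOU then centroid distance). The greedy
matching equals maximum-weight matching on the small per-slice-pair
problems that occur in practice, asserted against `linear_sum_assignment`.

## Level labelling

The 23-level ladder runs C3…C7, T1…T12, L1…L5, S1. C1/C2 and the sacrum
below S1 are excluded (poorly approximated by quadrilaterals in sagittal
view).

A volume around each instance (tight cuboid, expanded 50% per in-plane
direction, square-padded so in-plane resampling is isotropic, slices not
expanded) feeds a small convolutional **appearance classifier** with a
23-way softmax. Its temperature-softmaxed predictions (T = 0.1, applied to
logits) are written onto the instance's height band `[y_c − (y_b−y_a)/2,
y_c + (y_b−y_a)/2)` of an H×23 **probability-height map**; overlapping
bands combine by element-wise max and rows re-normalise (the combination
rule is a package choice). A 1-D convolutional encoder–decoder along the
height axis (**context network**, 23 input channels) refines the map;
during its training each band is zeroed with probability 0.1 while its
loss is kept, teaching it to infer a missing detection's level from its
neighbours.

**Decoding.** Per-instance probabilities are the mean of refined-map rows
over the instance band (the aggregation over a band is a package choice).
A beam search (width 50) finds the best strictly-descending, repeat-free
label sequence; skipping `g > 1` levels between adjacent instances costs
`(g−1)·log 0.2`, and a transitional lumbosacral variant — modelled as a
virtual extra lumbar slot "L6" between L5 and S1, emitting L5's probability
— costs `log 0.1` and sets a reportable flag. Penalty magnitudes are not
prescribed by the source method; both are configurable. The beam uses
hypothesis recombination (best hypothesis per `(slot, variant)` state), so
with width 50 ≥ 48 reachable states the decode provably equals the exact
dynamic-programming optimum; the tests assert this against an independent
Viterbi implementation on 500 random maps.

## Volume extraction for grading

Disc volumes are centred at the midpoint of two adjacent instance
centroids, rotated in-plane so the upper instance's inferior endplate
(AI→PI edge) is horizontal, sized to twice the larger VB width with a 2:1
width:height aspect, and resampled to 112×224 per slice. VB volumes are a
tight axis-aligned cuboid expanded by 20% per direction ("slightly
expanded"; the exact figure is a package choice) and resampled to 224×224.
Both keep the slices covered by the instances plus one margin slice and
carry an invertible affine back to scan coordinates (round-trip exact to
1e-6, tested).

## Context-aware transformer grading (CAST)

A shared single-channel 2-D convolutional encoder embeds each sagittal
slice; a learned-query multi-head attention pools the S slice features into
one token per volume, so any slice count works unchanged and the attention
weights identify the influential slices. Tokens receive learnt level and
sequence embeddings and pass through a 2-layer pre-norm transformer encoder
(dropout 0.5 at the clinical profile, 0.1 at the tiny profile). Tokens of
the same unit across sequences merge through a final attention pool that
outputs a *convex combination* of its inputs (weights from a learned query,
values are the raw tokens): a unit seen in one sequence passes through with
weight exactly 1, and zero-weight sequences cannot influence the result.
Per-task linear heads produce softmax probabilities. The learned-query
formulation (rather than a CLS token) is a package choice.

Supervision: known unit labels contribute cross-entropy; "unknown" labels
contribute nothing; a task with only a study-level flag trains the maximum
positive-class probability across units toward the flag (multiple-instance
learning). Negative study flags symmetrically push the most positive unit
down — the source method spells out only the positive aggregation. With
known labels the MIL loss reduces *exactly* to masked cross-entropy
(asserted). The compression default-negative rule (unlabelled levels are
negative, not unknown) is applied when reading label files, not in the
loss. During training a study with two sequences drops one with
probability 0.4 and both with probability 0.1; standard per-vertebra
augmentations (rotation ±15°, translation ±32 px at the 224-px scale,
scaling ±10%, intensity ±10%) are implemented and bounds-tested.

## Neural-network engine

All models run on a compact reverse-mode automatic-differentiation engine
written on numpy inside the package (`spinegrader.nn`): broadcasting
arithmetic, matmul, conv2d via im2col (rectangular kernels, stride,
padding), nearest-neighbour upsampling, attention, layer norm, dropout and
Adam. Every primitive is checked against central finite differences in the
test suite. Model initialisation and training draw from explicit
`numpy.random.Generator` instances, so results are bit-reproducible from a
seed, and checkpoints are single `.npz` files with an embedded JSON config.

## The phantom generator

Phantoms render a column of bright convex quadrilaterals (mild per-vertebra
shear and rotation, global curvature) separated by disc gaps, over 1–15+
sagittal slices with lateral slices tapered, plus Gaussian noise. Level
identity is encoded in appearance cues chosen to survive both the
fixed-size resampling of the classification volumes and the per-scan
percentile intensity rescale (which is an affine map, so relative
contrasts and geometry are preserved while absolute brightness is not):
VB height ramps from 7 px (C3) to 21 px (S1) while width stays near 16 px
(so in-plane aspect falls caudally); the disc-gap/VB-height ratio falls
caudally; S1 is strongly sheared; marrow signal brightens caudally; and a
central marrow notch inside each VB deepens in relative contrast and
drifts inferiorly along the ladder. Disc signal decreases
linearly with the synthetic degeneration grade on T2w and only weakly on
T1w, mirroring the loss of T2 disc signal that underlies Pfirrmann
grading; grading labels derived from the grades are therefore learnable
from the rendered images, which the tests verify with an intensity
threshold (≥ 99% separation of grades {0,1} from {3,4}).

Optional pathology and nuisance factors: hypointense lesion blobs inside
VBs, chopped corners (annotation unchanged — exercises robust completion),
a missing vertebra (removed from truth — exercises skip penalties), and
transitional anatomy (an inserted L6 or deleted L5).

What the phantoms do **not** emulate: realistic MR texture, partial-volume
effects, bias fields, pathology beyond blobs and collapsed shapes, or the
weak and entangled level cues of real anatomy. Passing the desk-scale
training criteria therefore demonstrates that the pipeline's mechanics
(targets, losses, grouping, decoding, attention, MIL) are correct and
learnable end-to-end, not that the tiny profiles would reach clinical
accuracy on real scans.

## Desk-scale study conditions

The tests and the acceptance script train the tiny profiles at fixed
problem sizes: the detector on 300 phantom slices (64-px patches, 10
epochs, batch 1, Adam lr 1e-3, no warping augmentation — at this budget
the phantom variety already covers pose and scale, and augmentation slows
convergence below the working range); the appearance net on 400 phantoms
(300 epochs) with the context net trained on probability-height maps from
120 phantoms the appearance net never saw (16 epochs); the grader on 200
studies (35 epochs, tiny profile D = 64). Evaluation uses held-out
phantoms: 30 for detection, 100 for labelling with 10% dropped
detections, 60 studies for grading. All recipes train on
percentile-normalised scans, matching the pipeline's preprocessing. Small
batches are used deliberately: with only a few hundred examples the Adam
step count, not the epoch count, limits convergence.

## Known limitations

* The clinical-scale backbones (ResNet18-encoded U-Net, VGG-F, ResNet18
  slice encoder) are represented by configurable tiny profiles; the
  package's engine favours clarity and reproducibility over speed and has
  no GPU path.
* Grading tasks are wired for the synthetic two-task battery by default;
  the clinical task batteries (Pfirrmann 5-class, disc narrowing, CCS,
  spondylolisthesis, endplate/marrow, metastasis/fracture/compression) are
  declared and supported by the heads/losses but have no bundled data.
* Wall-clock timings are kept out of the canonical JSON report so that
  fixed-seed runs are byte-identical; timings live in the in-memory report
  and the logs.
* DICOM support covers single-frame, one-series-per-directory sagittal
  stacks; NIfTI volumes are assumed sagittal-major.
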