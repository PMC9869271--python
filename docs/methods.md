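# Methods

## The segmentation model

Pigment glands occupy only a few pixels each, so the usual encoder-first
design (halve the resolution several times, then decode) destroys most of
the evidence for a gland before any deep feature sees it. The network here
inverts that order. For a 120×120 RGB tile the schedule is:

| stage  | operations                         | spatial | channels |
|--------|------------------------------------|---------|----------|
| up 1   | [3×3 conv → BN → ReLU] ×2, NN ×2   | 120→240 | 3→16     |
| up 2   | [3×3 conv → BN → ReLU] ×2, NN ×2   | 240→480 | 16       |
| bottom | [3×3 conv → BN → ReLU] ×2          | 480     | 16       |
| down 1 | maxpool 2×2, concat up-2, conv ×2  | 480→240 | 16+16→32 |
| down 2 | maxpool 2×2, concat up-1, conv ×2  | 240→120 | 32+16→32 |
| head   | 1×1 conv → ReLU                    | 120     | 32→1     |

All convolutions are "same" (stride 1, odd kernel, symmetric zero pad), so
spatial size is controlled only by the interpolation and pooling stages.
Nearest-neighbour interpolation was chosen over transposed convolution: it
is parameter-free and cannot introduce checkerboard artefacts on objects a
few pixels wide. The concrete channel schedule (constant 16 on the
enlarging path, 32 after each skip concatenation) is the smallest one
consistent with the design constraints above; it is exposed in
`NetworkSpec` (`base_channels`, with post-concat blocks at `2×base`), and
the default spec has exactly 54,129 learnable parameters.

The head is a rectifier, so responses are non-negative, and the literal
binarisation rule "negative → 0, positive → 1" corresponds to threshold
τ = 0. Under MSE training against {0,1} targets the rectifier actively
drives background responses to exactly 0, so τ = 0 is meaningful — but any
infinitesimal positive activation then counts as gland, which is fragile
at inference. τ is therefore configurable everywhere, with 0.5 (the
midpoint of the target values) used for validation metrics and prediction.

Initialisation is He-uniform for kernels, zeros for biases, under an
explicit seed; batch-norm statistics are frozen (running estimates) at
inference, so evaluation is deterministic and batch-order independent.

### Implementation

The layers are implemented directly on numpy arrays (NCHW, float32) with
numba-jitted row kernels for the 3×3 same-convolutions — the hot path at
480×480 — and BLAS matrix products for the convolution weight gradients.
Gradients of every layer are verified in the test suite against numerical
differentiation and, for the convolution, a float64 brute-force oracle.
Adam is implemented with standard bias correction.

## Training

Loss is plain MSE over all pixels; the optimiser defaults follow the
canonical Adam settings (lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-8) since only the
optimiser name is prescribed. The configured schedule (default 60 epochs ×
250 steps × batch 2) samples batches uniformly *with replacement* — with
thousands of tiles and 250 steps an "epoch" is a step budget, not a pass
over the data. After every epoch the validation loss, pixel accuracy and
confusion-matrix metrics are logged (row 0 of the history is the untrained
state); the parameters with the lowest validation loss are retained. A
NaN loss aborts the run and restores the best finite parameters. There is
no learning-rate schedule and no early stopping.

## Tiling and stitching

Full frames (e.g. 1600×1200) are divided into non-overlapping 100×100
cores; each core is predicted inside a 120×120 context window and the
10-px margin of each prediction is discarded before reassembly. Stitching
is therefore exactly inverse to cropping, and every stitched pixel was
predicted with ≥10 px of true context, which suppresses the bright-stripe
seam artefacts of edge-to-edge tiling. Borders (and right/bottom
remainders of non-divisible images) are reflection-padded rather than
zero-padded, because a zero border is dark and dark-is-gland is exactly
the feature the network learns. A trimmed margin of (context−tile)/2 = 10
px per side is the only symmetric choice that lets the cores tile the
frame seamlessly.

## Post-processing and counting

The binarised mask is cleaned and counted as: optional binary closing with
a disk (the mask is zero-padded by the radius first, so closing is
extensive and idempotent out to the border), connected-component labelling
(8-adjacency by default — diagonal gland pixels are one gland), then an
area filter keeping regions of 2 to 938,744 px. The lower bound removes
single-pixel noise (the smallest credible gland spans ~3 px); the upper
bound is kept verbatim from the reference workflow and is effectively
"unbounded above". Only area is filtered; other shape features (e.g.
roundness) are left as an extension hook since no thresholds are
specified for them. Closing is **off by default in counting studies**: it
fills intra-gland gaps but also welds glands ≤2·radius apart into one
component (adhesion), biasing counts low exactly in the dense regimes of
interest. Per-tile counts (for density stratification) are taken on
100×100 cores; whole-leaf counts on the stitched mask, so boundary glands
are counted once.

## Metrics

With gland pixels positive: precision TP/(TP+FP), recall TP/(TP+FN),
F1 = 2TP/(2TP+FP+FN), pixel accuracy (TP+TN)/total. Mean IoU averages the
gland-class IoU TP/(TP+FP+FN) with the background-class IoU
TN/(TN+FN+FP) — i.e. the confusion matrix with the class roles swapped;
this two-class reading reproduces the published score table from its
published confusion matrix to four decimals, which is the package's main
exact validation surface. Degenerate ratios (e.g. precision of an empty
prediction) return NaN, flag the report as degenerate, and are never
silently clamped. Counting agreement is the squared Pearson correlation
(not a regression-through-origin R²) between per-tile predicted and
reference counts.

## Synthetic scenes

The generator emulates the features that matter to this pipeline: a green
blade (R/G/B ≈ 0.62/1/0.55 of a base level drawn from 130–170), dark
curved vein strokes (quadratic Bézier, default width 3 px, darkened by
45 gray levels) drawn on the image only, and dark near-circular glands
(radius 1–5 px at the inferred 45 µm/px scale, intensity 30–80 with a
brown cast) whose union is the mask. Gaussian pixel noise (σ = 6) is added
last. Spots are placed by rejection sampling with enough rim clearance
(>1+√2 px between rendered disk edges, so no two disks can yield adjacent
mask pixels) that the 8-connected component count of the mask equals the
construction count
— this is what makes counting exactly testable. Placement failure at
infeasible densities raises an error naming the achievable maximum.
Vein, spot and noise draws come from independent substreams of the seed,
so the mask depends only on spot placement. Density levels use half-open
bins on the count per 100×100-px (4.5×4.5 mm) area: [0,40) → 1,
[40,80) → 2, [80,∞) → 3; the boundary counts 40 and 80, unassigned by the
convention's wording, go to the upper level so the bins partition all
counts. Flip augmentation produces the original, horizontal flip, vertical
flip and 180° rotation ("mirrored"), i.e. exactly 4 variants per scene.

What the generator does **not** model: illumination gradients, specular
leaf-edge highlights, blur, gland-gland overlap (an overlap-allowed mode
exists but is excluded from count studies because the true count is then
ill-defined), and the texture of real vein shadows. Passing tests on
synthetic scenes therefore demonstrate that the architecture, training
loop, tiling, filtering and counting machinery are correct and that the
network can learn to separate dark round spots from dark elongated
confounders — not that the shipped defaults reach any particular accuracy
on real leaves.

## The desk-scale study

`glandseg.study.reduced_level1_study` is the end-to-end benchmark used by
the acceptance script: 4 training scenes of 1000×500 px (200 context
tiles) at level-1 densities of 14/20/26/32 glands per tile and 2 held-out
scenes of 500×500 px (50 tiles) at densities 16 and 30, spot radii 1–3 px,
5 veins per scene; a base-8-channel network trained for 5 epochs × 100
steps at batch 2; validation F1/mIoU at τ = 0.5 from the retained
parameters, and per-tile counting r² (closing off, min area 2) against the
ground-truth-mask counts. These sizes — an order of magnitude below the
full-scale schedule — are the package's chosen desk-scale conditions: two
different held-out densities give the count vector enough spread for a
meaningful r², and the narrower network keeps the study in the minutes
range on one CPU core while preserving the architecture's structure.

## Numerical and degenerate-input choices

* Rasterisation of polygon annotations: a pixel belongs to a polygon iff
  its centre (x+0.5, y+0.5) is inside or on the boundary (shapely
  predicate); an independent ray-casting oracle checks this in the tests.
* Masks are {0,1} uint8 in memory, 0/255 PNG on disk; coordinates are
  0-based, row-major, origin top-left.
* Dataset splits shuffle under an explicit seed and take the first
  ⌊fraction·n⌋ items; by-image grouping is available against tile-level
  leakage (the default random-by-tile mirrors the reference workflow).
* `binarize` rejects NaN inputs; `count_r2` rejects length <3 and
  zero-variance vectors by name; `crop_tiles` rejects images smaller than
  one tile; max-pool rejects odd spatial sizes (unreachable through the
  public spec, which doubles sizes before pooling).

## Known limitations

* Real-image performance is unvalidated here: no gland dataset is
  deposited publicly, so full-scale scores (e.g. pixel accuracy ≈0.967 or
  per-density r² up to ≈0.97 reported for leaf data) are context, not
  reproducible targets of this package.
* Training is CPU-bound and single-threaded; the full 60×250 schedule is
  hours of compute. The implementation is faithful but not a GPU
  framework replacement.
* The channel schedule beyond "first block widens to 16" is one
  consistent reading of the architecture's description; alternatives are
  expressible through `NetworkSpec`.
* τ = 0 binarisation is honoured as the literal rule but validation and
  prediction default to τ = 0.5 (see above).
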