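# Methods

## The retinotopic transform

The package models foveated retinotopy — the dense central and sparse
peripheral sampling of the visual field shared by primates and many other
species — as a fixed preprocessing step: a log-polar resampling of the image
about a fixation point `(x0, y0)`.

With image coordinates normalized so that `x, y ∈ [−1, 1]` and `(0, 0)` is the
image center, each retinotopic sample `(i, j)` reads the source at

```
(x, y) = (x0 + ρ_i cos θ_j,  y0 + ρ_i sin θ_j)
ρ_i = r_min (r_max / r_min)^(i/(Nρ−1)),   θ_j = 2π j / Nθ
```

i.e. azimuths are uniform on `[0, 2π)` and eccentricities are geometrically
spaced, so that `log2 ρ` is uniform on `[log2 r_min, log2 r_max]`.  Geometric
spacing is essential: it is what turns a rotation by `α` about the fixation
into a circular shift of `α·Nθ/2π` columns and a zoom by `s` into a shift of
`log2(s)·(Nρ−1)/(log2 r_max − log2 r_min)` rows.  Defaults are
`Nθ = Nρ = 224`, `log2 r_min = −5`, `log2 r_max = 0` (the outer ring is the
circle tangent to the image box) and fixation at the center.  `ρ` and `θ` are
undefined at the fixation point itself; the grid never contains `ρ = 0`
because the innermost ring sits at `r_min > 0`, so no special case is needed.

Sampling is bilinear in both directions.  Sampling positions outside the
`[−1, 1]` square receive a fill value (0 by default); positions inside the
square but beyond the outermost pixel centers clamp to the edge pixels.  The
inverse map wraps the azimuth axis circularly (angles near `2π` interpolate
with the `θ = 0` column) and maps radii below `r_min` to the innermost ring so
the center of gaze is not reconstructed as a hole.  Non-square rasters are
supported; the normalized coordinates span `[−1, 1]` independently per axis,
so pixels are anisotropic in that case.  Some retinotopic pixels near the
fovea are smaller than source pixels; no anti-aliasing is applied on the
oversampled side, and none is applied to the undersampled periphery either —
the transform is deliberately plain resampling.

## Geometric transforms and equivariance measurement

`rotate`, `zoom` and `translate_roll` implement the three perturbations the
evaluation protocols use.  Rotation and zoom are inverse-mapped bilinear
resamplings (same interpolation rule as the transform); `rotate(I, 0)` and
`zoom(I, 1)` return the input bit-exactly.  The roll is quantized to whole
pixels because sub-pixel wraparound would blend opposite image edges; it is
therefore a permutation of pixels and conserves the value multiset exactly.

`equivariance_error` measures how closely the retinotopic raster of a
transformed image matches the analytically shifted raster of the original, as
a Pearson correlation.  Predicted fractional shifts are applied by linear
interpolation (circularly along azimuth).  The innermost 5 rings are excluded
by default: the fovea oversamples a handful of source pixels, and
interpolation error dominates there without carrying information about
equivariance.  The translation witness brute-forces all integer circular
(row, column) shifts and reports the best correlation, which stays low
because a translation of the scene scrambles the log-polar raster nonlinearly.

## Worst-case geometric attacks

Given a classifier that maps images to probability vectors, an attack
evaluates a parameter grid — rotations from −180° to 180° in 15° steps, zoom
factors geometric from ×1 down to ×0.1 (zoom-out only, since zoom-in attacks
always saturate at maximum zoom), or an 11×11 grid of fixation placements
implemented by rolling the image so each fixation lands at the center — and
selects the parameter maximizing the cross-entropy `−log p[y]` of the true
label, then reports the predicted label at that worst parameter.  Ties break
to the first grid point for determinism.  Probabilities are floored at
`1e−12` before the log so confidently wrong classifiers yield finite losses.
Perturbations are applied in image space, *before* the classifier's own
preprocessing (circular mask or retinotopic transform), mirroring the
perturb → foveate → classify pipeline.  The zoom sweep grid defaults to 21
geometric steps from ×10 to ×0.1 (symmetric about ×1 in log space); the
attack grid is its zoom-out half (11 steps).

## Fixation likelihood maps and saccades

The visual-search protocol fixates a `G × G` linear grid (default 11×11,
covering the image borders inclusive; cell (5, 5) is the image center).  At
each fixation the largest croppable sample is taken: its radius is the
distance from the fixation to the nearest image border, floored at a 1:10
ratio — the whole image at the center, a minimal sample at the border.  This
distance-to-border rule is the unique "largest possible sample" rule
consistent with both endpoint behaviors.  The crop is resized to the
classifier's input resolution, preprocessed by the classifier's reference
frame (mask or log-polar), and the whole grid is classified as one batch; the
probability assigned to the cued label forms the likelihood map.  Maps for
several labels reuse a single set of evaluations.  A "saccade" selects the
maximum-likelihood fixation (row-major first maximizer on ties) and
re-classifies from there.

Aggregation recenters each map so its peak sits at the middle of a
`(2G−1) × (2G−1)` canvas; canvas cells a shifted map does not reach are
excluded from that map's contribution and the aggregate is the mean over
contributing maps only (cells never reached are NaN).  Map algebra produces
cellwise differences and log-odds ratios `logit(a) − logit(b)` with
probabilities clamped to `[ε, 1−ε]`, `ε = 1e−6`; cells undefined in either
operand stay undefined.

Likelihood maps are computed with plain cropping; border rolling is used only
by the translation attack, where the full-field wraparound is the point.

## Ground truth and localization scores

Bounding boxes are rasterized onto the fixation grid by marking every cell
whose fixation coordinate falls inside the box (boundary-inclusive); a box
smaller than a cell marks the cell nearest its center so masks are never
empty.  Keypoint annotations become heat maps: the per-cell maximum of
isotropic Gaussians centered on the keypoints (maximum, not sum, so the peak
stays at 1), with `σ = 0.25 ×` the object scale, which defaults to the
diagonal of the keypoint cloud's bounding box; the map is rendered at high
resolution, area-averaged down to the grid, renormalized to peak 1 and
thresholded at 0.2 to delineate the assumed object contour (a unit-peak
Gaussian crosses 0.2 at radius `σ√(2 ln 5) ≈ 1.794 σ`).

Scores: the pointing game (peak cell inside the mask — invariant to monotone
rescalings of the map), an energy variant (fraction of map mass inside the
mask) reported alongside, mean activation inside/outside the mask and their
ratio (the dataset-level ratio is the ratio of dataset means; the mean of
per-image ratios is reported alongside, since both conventions are in use),
and IoU between the thresholded map and the mask across 101 uniform
thresholds with its peak value and first-maximizing threshold.  An empty
union yields IoU 0.  Dataset reports add central-fixation accuracy, saccade
accuracy and their difference.

## Synthetic scenes

Fixture scenes place one analytic shape (disk, square, cross or ring) on a
band-limited noise background: white Gaussian noise low-pass filtered at 6
cycles/image, mean 0.45, contrast 0.12, clipped to [0, 1].  Band-limiting
guarantees nonzero variance everywhere (well-conditioned correlations) and a
texture smooth enough for interpolation-based checks.  Shapes are rendered
from signed-distance functions with a one-pixel antialiasing band at
intensity 0.95; bounding boxes are the exact analytic extent of the rotated
shape and keypoints are its center plus four boundary landmarks.  Rendering
is integer-grid and seeded, so identical seeds give identical scenes.

Benchmark defaults — the study conditions — are: 64×64 grayscale rasters
(desk-scale; the 224 retinotopic default remains for real use), object
centers uniform in `[−0.4, 0.4]²` (objects always fully inside the frame),
characteristic radii uniform in `[0.15, 0.3]`, and orientations uniform in
`±15°`.  The narrow orientation range emulates the canonical-orientation
(upright) bias of photographic datasets, which is precisely what makes
Cartesian classifiers rotation-sensitive; a `center_bias` knob can
additionally shrink positions toward the center to emulate photographer's
framing bias (off by default so position-recovery tests are unbiased).  The
"focus" variant of each scene is the smallest square containing its bounding
box, clamped inside the frame and resized — the gaze-centered counterpart of
the full scene, with annotations remapped into the crop frame.

What the generator does *not* emulate: natural image statistics, clutter and
distractor objects, occlusion, lighting, or intra-class appearance
variability.  Passing tests therefore demonstrate that the protocols behave
as designed and that the geometric mechanisms (equivariance, fixation
sensitivity, likelihood-based localization) operate as claimed — not that any
particular accuracy transfers to photographs.

## The toy classifier

The harness trains a deliberately small numpy CNN: average-pool 2× (input
antialias), three 5×5/3×3/3×3 convolution blocks of 8/16/32 channels with
leaky ReLU (slope 0.1) and 2× average pooling between blocks, global average
pooling, and a linear head.  In retinotopic mode the input is the log-polar
transform of the image (64×64 grid) and all convolutions pad circularly along
the azimuth axis, so a rotation about the fixation — a circular column shift —
leaves the pooled features approximately invariant (exactly invariant for
shifts divisible by the total stride of 8).  In Cartesian mode the input is
the circular-masked image with ordinary zero padding.

Training is SGD with momentum 0.9 and cross-entropy, batch size 10, initial
learning rate 0.2 with cosine decay and global-norm gradient clipping at 1.0,
He initialization, inputs centered at 0.5.  Clipping and decay are what make
runs at this tiny scale converge reliably; leaky ReLU prevents the feature
collapse that plain ReLU suffers in such short runs.  All randomness derives
from a single integer seed.

The study classifiers are trained on a mixture: the regular scenes, their
focus crops (the two-generation regular-then-focus scheme collapsed into one
joint set, which avoids catastrophic forgetting at this scale), and 25%
object-free background textures labelled as an explicit background class.
The background class mimics the calibration of many-class photographic
networks, which spread background-texture probability over many labels; a
4-way toy without it assigns confident object labels to heavily zoomed
background crops and corrupts likelihood maps at border fixations.  Half of
the background images are re-cropped at fixations drawn from the protocol's
own 11×11 grid, so the rejection class covers background appearance at every
magnification the fixation protocol can present — full-resolution textures
alone leave extreme-zoom border crops out of distribution, where they attract
confident object labels.  Likelihood maps and attacks always cue the object
labels.  The study trains for 20 epochs, at which the cosine schedule has
brought held-out accuracy on object-centered scenes to its ceiling across
seeds; shorter runs leave seed-to-seed variation in map quality.

## Study design and problem sizes

The toy study trains 3 seeds × 2 reference frames on 500 scenes (plus crops
and backgrounds, 1250 training images), evaluates rotation robustness on 50
held-out object-centered scenes (sweep and attack on the 15° grid — rotating
about the central fixation there rotates the object in place), the
fixation-placement attack on 50 held-out full scenes (11×11 roll grid), and
localization on the same full scenes with 11×11 likelihood maps.  These sizes
keep a full run in minutes on one CPU while leaving the qualitative contrasts
far from their decision boundaries.  The planted-object recovery rate counts
scenes whose maximum-likelihood fixation lies within one grid cell (Chebyshev
distance ≤ 1 on the fixation grid) of the cell nearest the object center.

The translation attack is evaluated on full scenes rather than on
object-centered crops for a structural reason: the synthetic objects occupy
at most a 0.3 radius, so on a crop the 11×11 roll grid always contains
placements that move the object entirely outside the unit visual disk, where
no classifier of any kind can recover the label — worst-case accuracy is
forced to exactly zero in both reference frames and the comparison
degenerates to a difference of baselines.  On full scenes each reference
frame has an informative scene baseline and the worst-case drop reflects its
own translation sensitivity.  Both attacked accuracies are reported either
way.

## Known limitations

* The retinotopic transform is fixed preprocessing; there is no gradient
  pathway through it and no GPU implementation.
* Only the three studied perturbations (rotation, zoom, wraparound
  translation) are provided — no general affine machinery.
* Rotation equivariance of the toy classifier is approximate between grid
  multiples of the pooling stride; the paired-comparison design (retinotopic
  versus Cartesian under identical conditions) is what carries the
  conclusions.
* The toy classifier is a means of exercising the protocols, not a model of
  any particular network family.
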