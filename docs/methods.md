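# Methods

This note documents the models and procedures implemented in `mitodyn`,
the assumptions behind them, the tunable parameters and their defaults,
what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Intensity model and segmentation

A frame is assumed to be a non-negative grayscale image in arbitrary
units (bit depth and camera gain are not modeled) containing thin bright
objects — mitochondria are sub-micron-wide tubules, i.e. under ~10 px at
the default 0.1 µm/px — on a smooth noisy background.

**Top-hat flattening** (`preprocess_frame`): the white top-hat
`frame − opening(frame)` with a square structuring element of side
`tophat_size_px` (default 3) whose erosion and dilation are each iterated
`tophat_counts` times (default 5), for an effective opening scale of
11×11 px.  This removes smooth background at scales above ~1.1 µm and
passes structures thinner than that.  Consequence: any object wider than
the effective opening in *both* axes is suppressed; the analysis is
intended for tubular/compact organelles below that scale, and the
synthetic generator respects the same bound.  A vendor deconvolution
step sometimes used upstream of such pipelines is not modeled; a
`prefilter` callable hook on `preprocess_frame`/`segment_movie` lets the
user insert any frame transform of their choosing before the top-hat.

**Threshold estimation** (`estimate_threshold`): ROI intensities are
square-root transformed (variance stabilization).  The histogram (bin
width by Freedman–Diaconis on the sqrt values) is assumed to be a
unimodal background distribution plus a strictly-brighter object
shoulder.  The background mean is the center of the maximal bin (the
mode *m*); its SD is the *left-mirrored* RMS, σ̂ = RMS of (x − m) over
x ≤ m, so the shoulder cannot inflate it.  The lower limit is
m + `threshold_sigma_mult`·σ̂ (default 3) in sqrt space, squared back to
raw units.  Monte-Carlo tests confirm the limit moves < 5% when 20% of
pixels are bright objects.  The threshold is estimated once per series
on the first frame by default (`threshold_per_frame` recomputes it per
frame); both modes are provided because either is defensible when
illumination is stable.

**Binarization** ("clean"/"separate", `binarize_and_label`): pixels above
the limit, then `clean_iterations` (2) rounds of binary opening with a
3×3 cross and removal of components under 4 px; then touching objects
are separated.  Separation semantics: each 8-connected component is
eroded (3×3 cross) exactly `separate_iterations` (3) times; if the
residue falls into ≥ 2 pieces, those pieces seed a watershed on the
Gaussian-smoothed distance transform (σ = 1 px) that divides the
component's pixels; otherwise the component is left intact.  This is the
erosion-count reading of an iterated "separate" operation: it cuts
necks thinner than the erosion budget (~6 px for 3 cross-erosions)
between distinct touching objects, while leaving intact both genuinely
fused organelles (fat waist) and thin tubules of any length (whose
residue vanishes entirely).  A distance-transform-maxima marker rule was
considered and rejected: it over-splits constant-width tubules, whose
ridge carries many spurious maxima.  Objects are labeled 8-connected;
holes are counted 4-connected, the standard complementary pairing.

## Event detection

Regions of frames t and t+1 are related by overlap: (i, j) is related
iff overlap ≥ 1 px and i maximizes overlap(·, j) over frame-t regions
*or* j maximizes overlap(i, ·) over frame-(t+1) regions; all argmax ties
are included (inclusion keeps the conservation law exact).  Each
frame-(t+1) region carries unit weight regardless of size, split equally
among its ancestors; the score of a frame-t region is the sum of weights
received.  Scores are computed in exact rational arithmetic
(`fractions.Fraction`), so `score == 1` and the conservation invariant
Σᵢ sᵢ = #{descendant regions with ≥ 1 ancestor} are exact, not
tolerance-based.  An overlap-proportional split is available
(`overlap_weighted_scores`) but equal split is the default.

Calls: score > 1 → fission, < 1 → fusion, = 1 → stable, with a
consistency check against the frame two ahead using the same strict
inequalities; disagreement yields `unconfirmed`, which is excluded from
feature analysis.  This enforces ≥ `persistence_frames` (2) frames —
10 s at 5 s intervals — of persistence.  Regions with no descendants
(disappearance) or no ancestors (appearance) are logged separately
rather than silently dropped, since they usually indicate segmentation
failures.

Known limitation: a one-frame contact ("passing") is rejected as a
fusion at its onset frame, but the *separation* of the transient merged
region satisfies the fission rule literally (the fragmented state does
persist).  `evaluate_events` therefore scores detections against ground
truth with passing-episode detections excluded from the precision
denominator: their truth class is "passing", which the three-way calling
scheme cannot represent.  On the default segmentation this case rarely
arises from images, because the thin transient bridge is separated by
the clean/separate step before scoring.

## Morphometry

Conventions: row-major 0-based pixel indices; a pixel is a unit square;
µm values are pixel values times `pixel_size_um`.  The outer boundary of
a region is traced with Moore-neighbor tracing (Jacob's stopping
criterion), giving a closed cyclic pixel sequence; one-pixel-wide spurs
are traversed once per side, which is the correct boundary curve.

- **area**: pixel count × pixel area.
- **perimeter**: length of the closed polygon through boundary pixel
  centers (1 per axial step, √2 per diagonal).  An edge-pixel-count
  variant (`perimeter_edge_pixel_count`) is provided; the polygon form
  is the default because it is the better-behaved metric.
- **extent, solidity, eccentricity**: bounding-box ratio, convex-hull
  ratio and second-moment ellipse eccentricity (scikit-image
  regionprops; solidity verified against an independent convex-hull
  oracle in tests).
- **Euler number**: 1 − number of 4-connected holes, the standard
  characteristic (a "number of holes" report is an affine transform of
  it and would not change any ranking).
- **necks**: D[p, q] = Euclidean distance (µm) between boundary pixels p
  and q, smoothed with a 2D Gaussian, cyclic in both indices (the
  boundary is a closed curve; non-cyclic smoothing would create
  artifacts at the arbitrary trace start).  The kernel "width"
  `neck_kernel_px` (5) is taken as the FWHM, σ = 5/2.355 ≈ 2.12 index
  units.  Necks are local minima of the smoothed matrix over a window of
  ± `neck_kernel_px` indices; pairs with boundary-arc separation under
  3×`neck_kernel_px` are excluded (they are near-neighbors along the
  contour, not constrictions), and surviving minima closer than
  3×`neck_kernel_px` in index space (exact-tie plateaus on symmetric
  shapes, duplicates within one constriction) are merged by non-maximum
  suppression.  The kernel-scale window (rather than 3×3) matters: on a
  constant-width tube the cross-tube valley is flat and keeps descending
  toward the (arc-excluded) tube ends, so it contains no kernel-scale
  basin and a straight bar correctly reports zero necks, while a
  dumbbell's basin at the bridge center survives.  The reported width is
  the *unsmoothed* center-to-center distance of the minimal pair —
  a real distance between two boundary pixels, understating a k-px
  constriction by about one pixel.  Constrictions reachable only
  through a hole's inner boundary (e.g. two parallel bridges enclosing
  a hole) are outside the operator's domain, which walks the outer
  boundary.
- **positional**: nearest-neighbor distance is the minimum gap between
  pixel squares of this and any other region (axially adjacent pixels
  are at distance 0); neighboring surface is the summed boundary length
  of other regions' boundary pixels within `neighbor_radius_um` (10 µm)
  of this region's boundary, each pixel carrying half of its two
  adjacent polygon segments; orientation is the acute angle (0–90°)
  between the second-moment major axis and the nucleus→centroid radial
  axis (a proxy for microtubule orientation), undefined for isotropic
  regions and missing when no nucleus is given.

Missing values (lone region, absent nucleus, no necks) are NaN and are
imputed by the class-agnostic column median at training time (recorded
in the model).

## Classification

`train_forest` fits a bootstrap-aggregated forest
(scikit-learn `RandomForestClassifier`; `n_trees` = 2000,
`rf_split_candidates` = 3 candidate features per split, the conventional
mtry reading of that parameter).  All OOB statistics are computed here
from the per-tree bootstrap complements: the OOB error is the
misclassification rate of the OOB majority vote, equal to the
class-frequency-weighted mean of the class error rates; class priors are
left as observed (no reweighting), so the majority class is expected to
be predicted better.  Importance is OOB permutation importance: per tree
and feature, the increase in that tree's OOB error after permuting the
feature among the tree's OOB rows; the reported value is the mean over
trees and the SD is the per-tree standard deviation divided by √n_trees
(the importanceSD convention of the classical RF framework).
Class-conditional columns restrict the error to rows of one true class.
A drop-one-feature refit variant (`method="refit"`) is provided; the
permutation form is the default because it is the standard
operationalization and yields per-tree SDs.  The error curve accumulates
OOB votes tree by tree, so its final point reproduces the fitted model's
class errors exactly.  `stump_boundary` scans all midpoints between
consecutive sorted unique values for the minimum size-weighted Gini
impurity, breaking ties toward the smaller threshold.

## Pre-event dynamics

For 1→2 fissions and 2→1 fusions (each fusion partner traced
separately), perimeter P and solidity S are measured backward for up to
`pre_event_frames` (8) frames, following the unique stable ancestor:
a step back is taken only when the backward relation is exactly 1→1.
Traces terminate early otherwise — truncation, not imputation, with the
per-offset n reported — and ratios are normalized to offset 0 (exactly 1
there by construction).  Summary rows carry mean ± SE (sample SD/√n).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis relies
on: a normal background (mean 100, SD 8, arbitrary units) with object
pixels at 250 — more than 6 background SDs above the mean, giving the
two-population histogram with a right shoulder; compact blobs (ellipses,
radii 2.5–4.5 px), straight rods and branched tubules (dilated
random-walk polylines, widths 3–7 px) sized to survive the 11×11
top-hat opening; and scripted events on a 220×220 px field (0.1 µm/px,
≈ 22 µm × 22 µm) over 60 frames at 5 s.  Fission deletes a 2-px-wide gap
across the parent perpendicular to its major axis (children persist to
the end of the movie); fusion joins the partners with a waist as thick
as the thinner partner, so the product is a genuinely fused organelle
rather than a thin contact; passing draws a 2-px bridge for exactly one
frame.  Object placement enforces ≥ 4 px separation (event pairs sit at
a 3-px gap).  All randomness flows from one seed.

Not emulated: organelle motion (drift in the source acquisitions was
negligible, and the overlap relation tolerates small displacements but
the generator does not exercise them), photobleaching, shot noise or a
point-spread function, 3D structure, and continuous shape dynamics
between frames.  Passing tests on these scenes therefore demonstrates
the correctness of the measurement and scoring machinery under the
stated intensity and morphology assumptions — not robustness to optics,
motion or focus artifacts of real microscopy.

For classifier tests, `generate_feature_dataset` measures ~800 random
organelles with the morphometry operators and assigns labels from a
logistic model, P(fission) = logistic(2·z(perimeter) − 2·z(solidity) + c)
with c calibrated by bisection so the expected fission fraction is 0.30
(the ~70/30 fusion/fission imbalance typical of such experiments).  The
shape mix (blobs, rods, curved and branched tubules of varying width) is
chosen so area and extent are informative but not collinear with
perimeter and solidity; the planted structure — perimeter and solidity
as the top two predictors, OOB error well under 25%, fusion predicted
better than fission — is then recoverable and is asserted in the tests.

## Degenerate inputs and numerical details

Fewer than 1000 ROI pixels, constant intensity profiles, single-class
training data, under 50 training rows, constant stump features and label
stacks shorter than 3 frames raise `ValueError` with explicit messages.
Empty foreground yields an empty label frame.  Regions with fewer than
12 boundary pixels report 0 necks.  Tie-breaks: argmax ties in the
overlap relation include all tied pairs; stump threshold ties go to the
smaller value; OOB vote ties go to the fission class (argmax order),
affecting only exactly-tied vote counts.  Problem sizes in the test
suite (scene sizes, 800-event training sets, 2000-tree forests) are the
package's default study conditions; the full suite runs in about a
minute on one CPU.
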