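# mitodyn

Single-organelle analysis of mitochondrial fission and fusion in
time-lapse fluorescence movies.

Mitochondria constantly remodel through two opposing processes — fission
(one organelle dividing into two or more) and fusion (two or more joining
into one).  Whether an organelle's *current shape* carries information
about its *next move* is a quantitative question: it requires segmenting
every mitochondrion in every frame, deciding objectively which ones
split or merged, measuring their geometry in the frame just before the
event, and asking a classifier which geometric features predict the
outcome.  `mitodyn` implements that full pipeline for cell biologists and
image analysts working with single-channel time-lapse movies (TIFF, fixed
pixel size and frame interval), together with a ground-truthed
synthetic-movie generator so every stage is testable without raw imaging
data.

## The method

**Segmentation.** Each frame is background-flattened with an iterated
white top-hat (3×3 structuring element, 5 counts).  The ROI intensity
histogram is square-root transformed and treated as a background
distribution plus a brighter right shoulder of object pixels; the
background mean is the histogram mode *m*, its standard deviation σ is
estimated from the left flank only (mirrored about the mode), and the
lower threshold is *m* + 3σ.  The binary mask is cleaned (2× opening with
a 3×3 cross, despeckle < 4 px) and touching objects are separated where
the connection erodes away within 3 erosions (watershed assignment of
pixels to the eroded cores).

**Event scoring.** Regions of consecutive frames are related by pixel
overlap: (i, j) are related iff they overlap and one is the other's
maximal-overlap counterpart.  Each Frame-2 region j carries unit weight
split equally among its ancestors A_j; the score of a Frame-1 region i is

    s_i = Σ_{j ∈ B_i} 1 / |A_j|

with s_i > 1 poised for fission, s_i < 1 for fusion, s_i = 1 stable.  A
call is confirmed only if the score recomputed two frames ahead agrees,
so a product configuration must persist ≥ 2 frames (10 s at 5 s
intervals) — transient one-frame contacts between passing organelles are
rejected.

**Morphometry.** Eleven features per organelle, measured in the frame
preceding its event: area (µm²), perimeter (µm, traced boundary
polygon), extent, solidity, eccentricity, Euler number, number of necks
and narrowest neck width (isolated minima of the Gaussian-smoothed
matrix of pairwise boundary-pixel distances), nearest-neighbor distance
through cytosol, neighboring surface length within 10 µm, and the acute
angle between the major axis and the nucleus radial axis.

**Classification.** A random forest (2,000 trees, 3 candidate features
per split) predicts fission vs fusion; out-of-bag (OOB) votes give the
error estimate, per-class errors, the error-versus-forest-size curve,
and permutation importance with per-tree SDs.  Depth-one trees ("stumps")
give single-feature decision boundaries.

**Dynamics.** Perimeter and solidity are tracked backward through the
unique stable ancestor for 8 frames before each 1→2 fission / 2→1
fusion, normalized to the pre-event frame (P/P₀, S/S₀), and averaged
with standard errors.

## Worked example

```sh
python examples/04_rank_features.py
```

generates ~800 synthetic organelles whose fission probability increases
with perimeter and decreases with solidity (~70/30 fusion/fission
imbalance), trains the forest, and prints:

```
800 organelles, 30% poised for fission
OOB error 10.4% (fission 18.0%, fusion 7.0%)
 rank      feature  importance_all   sd_all
    1     solidity        0.139229 0.001444
    2 perimeter_um        0.099437 0.001496
    3     area_um2        0.032205 0.000735
    4       extent        0.028491 0.000947
single-split boundary on perimeter_um: 5.71 (fission above)
single-split boundary on solidity: 0.77 (fission below)
```

The forest recovers the planted structure: perimeter and solidity lead
the importance ranking, the stump boundaries put fission on the
high-perimeter and low-solidity sides, and the majority fusion class is
predicted better than the minority fission class.  The other examples
(`examples/01…05`) walk through simulation + segmentation, event
detection (scores 2.0 for splits, 0.5 for merge partners, with recall
and precision 1.0 against the script), morphometry of canonical shapes,
and pre-event traces.

A thin CLI wraps the same library calls:

```sh
mitodyn simulate --seed 5 --out-dir sim
mitodyn run-all --seed 5 --out-dir results sim/movie.tif
```

writing `labels.tif`, `threshold.json`, `events.csv`, `features.csv`,
`importance.csv` (when enough events accrue), `traces.csv` and a JSON
run manifest.  Every subcommand is a pure function of its inputs and the
seed: reruns are byte-identical.

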