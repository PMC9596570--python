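# Methods

This note documents the models, parameters and numerical choices behind
`mitoflux`, what the synthetic-data generator does and does not emulate,
and the known limitations of the approach.

## Detection model

Puncta are modelled as isotropic 2-D Gaussian intensity spots of scale
σ = 3 px (round(precision/2) at a 56.6 nm pixel size, i.e. the ~250 nm
diffraction limit). Detection filters the frame with a scale-normalised,
negated Laplacian of Gaussian, `-σ²·∇²G_σ`, with reflective boundaries, so
bright blobs of matched scale give positive peaks. The truncated discrete
LoG kernel has a tiny nonzero sum; we subtract this DC leak (times a
unit-sum Gaussian blur), which makes the response exactly zero on constant
frames and exactly equivariant under affine intensity maps `a·I + b`.

The binary mask is `response > μ + z·σ` with μ, σ the response mean and SD
over the analysis support (the cell mask when available, the whole frame
otherwise). The threshold is a z-score of the response distribution: this
is the minimal reading of an "intensity-adaptive" threshold governed by a
unitless preference called a z-value, and it makes the detection decision
intensity scale-free. The published construction of the threshold lives in
the original spot-detection software; our z-score form is an explicit
stand-in isolated in `threshold_response`, and the autotune mapping
`z_eff = z_base / ratio` (so the documented recall/precision ratio of 3.75
gives z ≈ 0.47) is likewise isolated in `autotune_z` so either can be
swapped without touching the rest of the pipeline.

Masks are labelled with 8-connectivity (configurable). The area filter
removes objects of area ≤ 25 px in fixed-cell mode and ≤ 4 px in live mode.
The boundary is inclusive (area exactly 25 is removed); the source
descriptions of the fixed-cell rule differ on this point ("smaller than 25"
vs "25 … or less") and we adopt the inclusive form, which matches the
unambiguous live-mode rule; `area_filter_inclusive` exposes the choice.

**Behaviour on signal-free images.** Because the threshold is scale-free,
on a cell with *no* true spots it adapts down into the noise: the
LoG-smoothed noise field has correlation length ~σ√2, and a handful of its
excursion clusters exceed 25 px at z = 1.75 (of order 10 per cell in our
fixtures). Two properties keep the readout clean: false clusters in the
two channels are independent and essentially never coincide, so the dual
count stays near zero; and any genuine signal inflates the response SD,
lifting the threshold above the noise clusters (on scenes with puncta the
detected count equals the true count). The live-cell QC filters remove the
single-channel floor explicitly. Mask monotonicity in z is exact
(pixelwise); the object *count* is additionally monotone whenever objects
do not merge, which holds on well-separated spots over the operating range
z ∈ [1, 2] and above.

## Cell segmentation (live mode)

Per reference channel: set pixels at or below the image's 90th-percentile
intensity to zero (the cell is the bright minority; the background becomes
"black"), run median filters of window 3, 5, 9 in cascade, binarise, and
keep the largest connected component. The mask is then widened by
4 dilations of radius 2 px (2 × the 2-px system precision) — realised as a
single exact Euclidean dilation by the cumulative 8 px radius, because
iterating discrete disk dilations accumulates an octagonal bias — then
closed and hole-filled. Channel masks must agree pairwise (Jaccard ≥ 0.8;
the metric and threshold are our choice, the source only requires
"consistency"); the consensus is the union, so weak labelling in one
channel cannot clip objects at the cell edge. Frames whose mask touches
the image border are skipped. Manual-ROI (fixed-cell) mode bypasses
segmentation but keeps the border check.

Quantile suppression is scale-free, so segmentation inherits affine
intensity invariance. Whether "filtering out the 90% quantile" suppresses
the dim or the bright side is not stated verbatim in the source; we
suppress dim pixels (the subsequent step treats background as filtered
black), and the reading is isolated in `_segment_channel`.

## QC filters (live mode)

High-recall detections are filtered per object: (1) pooled-SD Cohen's *d*
of the object's pixel intensities against all pixels of the (dilated) cell
mask must be ≥ 0; (2) the object's maximum intensity must exceed the Tukey
fence Q3 + 1.5·IQR of the cell distribution; (3) area must exceed 4 px.
Quartiles use linear interpolation; the cell distribution includes object
pixels (the source states no exclusion). The dilated mask matters: its dim
rim pixels widen the IQR and raise the fence, which is part of why the
filters remove ≥ 95% of noise-only detections in our fixtures while keeping
every true spot at SNR ≥ 5.

## Association and ratios

Dual puncta are connected components of the bipartite cross-channel
overlap graph (≥ 1 shared pixel), with the pixel union as the object; the
one-to-many case is handled by the component rule, which reduces to the
pairwise definition when overlaps are unique. Edge distance is the exact
minimum Euclidean distance between pixel centres (KD-tree accelerated,
verified against an all-pairs scan); ≤ 5 px counts as associated,
boundary inclusive. Mitochondria are segmented with the same detector on
the dye channel at z = 1.75 with no area filter (the source does not state
a mitochondrial area filter; 0 is our explicit default). Objects
straddling the cell boundary are kept when ≥ 50% of their pixels are
inside.

For each dual punctum the overlap pixels are its intersection with the
mitochondrial mask; the *adjacent* segment is the one sharing the most
overlap pixels (ties → nearest centroid; if there is no overlap but the
punctum is within the association cutoff, the nearest segment's own mean is
used). `ratio_segment = overlap mean / segment mean` and
`ratio_cell = overlap mean / mean over all segment pixels` — dye-positive
pixels only, never the whole frame. Ratios are invariant to positive
rescaling of the dye channel. Per-cell summaries are boxplot statistics
(linear-interpolation quartiles, 1.5·IQR whiskers); movie records are
pooled across Z-slices and timepoints.

## Sensitivity study

The hypothesis grid is the Cartesian product of unordered condition pairs,
cell lines and the z grid; m is always computed from the design, never
user-supplied (4 conditions × 2 lines × 21 z-values → m = 252, corrected
α = α/252). Pairwise two-group Kruskal–Wallis tests (tie-corrected H,
χ² p-value with k−1 df) compare per-cell counts; the unit of observation is
the cell. The exact 21 z-values of the original design are not published;
the default grid spans (0, 2] uniformly and is configurable. Degenerate
input (all counts identical) yields H = 0, p = 1 by convention rather than
an error.

The χ² approximation is used at all sample sizes, matching common
practice. Its error is O(1/n), which for groups of a few dozen cells is
around 1–3% in p — larger than the Monte-Carlo resolution of a 20,000-draw
permutation oracle (2 SE ≈ 0.7%). The test suite therefore checks
calibration statistically: at group sizes 40–80, at least 90% of 50 random
cases must fall within 2 Monte-Carlo SE of the permutation p and all within
4 SE (a hard all-cases 2-SE bound would be failed by an *exact* p-value
with ~90% probability). Family-wise error under a simulated null
(all groups i.i.d., 200 replicate sweeps of the full 252-test grid) is
verified ≤ α.

## Synthetic-data generator

The generator renders what the analysis assumes: one elliptical cell of
diffuse cytosolic signal on a dark background, Gaussian puncta truncated at
4σ (dual puncta at identical coordinates in both channels), and a
mitochondrial network of dilated random-walk tubules, each a separate
connected component whose intensity is `base × potential` with potential in
(0, 1]. Camera noise is Poisson (gain 1) plus Gaussian read noise
(SD 2 ADU), applied last; spot amplitudes are specified as peak SNR against
the background noise SD. The cell boundary falls off with a Gaussian
profile of σ = 10 px — diffuse cytosolic signal imaged through a
diffraction-limited system cannot produce a pixel-sharp step, and a
sharp-edged fixture would inject edge artifacts no real image has.

Defaults (512×512 frame, cell semi-axes 100×80 px ≈ 10% of the frame,
10 dual + 5 + 5 puncta, peak SNR 6, 6 mitochondrial segments of length
60 px and width 5 px) are fixture choices: the original study reports no
SNR or puncta-per-cell statistics, so these numbers are what we consider a
realistic single-cell field, not claims about the data. "Near-mito" dual
puncta are centred on a mitochondrial pixel (edge distance 0) and "far"
puncta kept well beyond the 5-px cutoff, so ground-truth association flags
are unambiguous under the same edge-distance metric the measurement uses;
ground-truth expected counts are recomputed by brute force from the puncta
and segment pixel sets. Placement uses rejection sampling with a minimum
centre separation of 16 px (so detected footprints of ~4.5 px radius do not
merge) and raises a `PlacementError` when a spec is infeasible.

Time-lapse mode translates the shared geometry by a per-frame drift and
renders each of the (default 7) Z-slices at 500 nm spacing with independent
noise; Z-slices are independently generated 2-D scenes with shared
geometry, not a 3-D render. A frame's ground truth is marked invalid when
the true cell outline comes within 10 px of the border — the 8 px mask
dilation plus ~2 px segmentation overshoot — so ground-truth validity
predicts the pipeline's border rejection; drift fixtures avoid placing any
frame within a few pixels of that decision boundary.

What the generator does **not** emulate: optical PSF beyond the Gaussian
spot model, photobleaching, autofluorescence, organelle texture in the
cytosol, cell-shape irregularity, or 3-D continuity across Z. Passing
tests therefore demonstrate the pipeline's correctness and calibration
under its own model assumptions, not performance on real microscopy data.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` use scaled problem sizes
chosen as a package decision: detection recovery uses 5 scenes of 30
puncta; the stratified-ratio study 100 (suite) / 30 (script) single-cell
replicates; null calibration 200 replicate sweeps of the full 252-test
grid at 20 cells/group (count-level simulation — the sweep consumes
per-cell count tables); and the flux-effect experiment 15 cells/group,
Poisson rates 4 vs 12 (a 3× effect, draws capped at 18 for placement
feasibility) on 256×256 scenes over a 5-point z grid around 1.75, for 20
(suite) / 5 (script) replicate experiments.

## Known limitations

- The z-score threshold and the autotune mapping are documented stand-ins
  for the published software's internal constructions.
- Single cell per field; no instance segmentation or cross-frame tracking.
- Slices are analysed independently: a punctum visible in two Z-slices is
  counted twice, as in the source protocol.
- No correction for bleaching or focus drift across a time series.
- The ratio statistic measures dye intensity, a surrogate for membrane
  potential; no claim about potential per se is made.
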