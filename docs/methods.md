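# Methods

This note documents the models, estimators and numerical choices behind
`spinefret`, in the order the pipeline applies them. Everything stated
here is either a definition or a property the test suite and
`scripts/acceptance.py` compute at run time.

## Calibrated stacks and preprocessing

Images live in a `T×Z×C×Y×X` float64 array with physical calibration:
0.07 µm lateral pixels, 0.35 µm z-steps and a 2.5-min frame interval by
default — the confocal settings typical of single-spine imaging.
Coordinates are 0-based with pixel centres on the integer lattice, so a
physical position is `index × pixel_size`. Quantisation to uint16
happens only when writing OME-TIFF; analysis never leaves float64.

Frame times are reported relative to the treatment instant: with a
treatment frame index `tf`, baseline frames end at `−Δt` and the first
post-treatment frame sits at `+Δt`, so baseline points always have
negative times.

**Drift registration** estimates a per-frame translation (no
rotation/scale — stage and tissue drift is translational at this field
size) by subpixel phase correlation of one reference channel against a
reference frame, and applies the inverse shift to every channel of that
frame by linear interpolation. Border pixels exposed by the shift are
filled with the frame's modal background. Integer drifts are recovered
exactly; half-pixel drifts to better than 0.1 px RMS over 50 frames.

**Background.** Three estimators per (frame, z) plane: the 256-bin
histogram mode refined to the median of the modal bin (default — robust
when bright structures are sparse), a user background-ROI mean, and a
low percentile. The FRET pipeline, which has a label mask in hand, uses
the mean over the out-of-mask pixels (mask dilated 3 px): the blind mode
estimator wobbles by a fraction of an intensity unit frame-to-frame,
and with only a few baseline frames that wobble propagates into the
bleach slope.

**Blurring** is a per-plane Gaussian with σ = 0.5 px — slight smoothing
that suppresses single-pixel noise without moving structure. The
discrete half-pixel kernel is not exactly semigroup (two σ = 0.5 passes
differ from one σ = √0.5 pass by ~1% RMS on white noise); at σ ≥ 1 px
the sampled kernel composes to ~1e-5.

**Percentile scaling** divides each channel by the 99.9th-percentile
intensity of the control condition, putting conditions on a common scale
before thresholding; the operation is invariant to a common intensity
rescale.

## FRET quantification

The biosensor readout is the pixelwise acceptor/donor ratio
`R = F_A / F_D` (YPet over mTurquoise). The ratio is computed only
inside the label mask and where the donor exceeds a floor (3× the
MAD-based residual noise of the corrected donor by default), which
prevents ratio blow-up in dim pixels.

**Bleach correction** is linear and operates on the ratio, not the
channels: a straight line `a + b·t` fitted to the pre-treatment frames
is flattened by multiplying frame `t` by `a/(a + b·t)`. Correction
factors outside (0.2, 5) mark the model unreliable and raise. Two
pipeline-level refinements reduce the variance of this fit, which with
only 3 baseline points is otherwise the dominant error source:

1. the per-frame statistic is the **ratio of summed intensities** over
   the mask rather than the mean of pixel ratios — both follow the same
   multiplicative trend, but the sums average the photon noise away
   before the division;
2. after an initial correction and responder call, the slope is
   **refitted on all frames of the ROIs without a clear response**
   (they are trend-only by definition) and the series re-corrected
   once. The refit pool excludes only clear responders (6σ), because
   dropping borderline ROIs would select against upward noise and bias
   the slope.

Per-ROI series are the frame-wise means of valid ratio pixels (frames
with no valid pixel are missing, never zero), normalised by the baseline
mean. An ROI is called a **responder** when its mean normalised
post-treatment ratio exceeds `1 + k·σ̂` with `k = 2`, where `σ̂` is the
baseline SD divided by the small-sample unbiasing constant c4(n) (with
3 baseline points the raw SD underestimates the noise scale by ~11%).
This rule is an operational surrogate — the original separation of
responding spines was visual.

Under the study conditions (200×200 px, 12 frames, 3 baseline, 20 ROIs
of ~0.7 µm radius, +30% step in half, 2%/frame acceptor bleach, 1
px/frame drift, shot noise at 3 photons/a.u. plus read noise 3.4 a.u. —
SNR ≈ 15 at the 100 a.u. signal), the chain recovers the programmed
step to well within 5% relative, holds non-responders within 3% of
unity, and calls responders with sensitivity 1.0 at a false-positive
rate at or below 5% over 200 ROIs.

## F/G-actin mapping

Fraction `FR = I_F/(I_F + I_G)` and ratio `R = I_F/I_G` are computed
voxel-wise on a foreground mask; `FR = R/(1+R)` holds at every voxel
where both are defined, and `R` is masked (not infinite) where `I_G = 0`
while `FR` is 1 there. Foreground is the **union** of the per-channel
unimodal thresholds, so purely-F or purely-G regions are retained;
intersection mode is available. Whole-cell summaries are means over
defined voxels in 3D, not over a projection, to avoid projection-induced
ratio bias; the z-max projection is for display.

The **unimodal (background-symmetry) threshold** takes a 256-bin
histogram between the image minimum and maximum and places the threshold
at the bin with maximum perpendicular distance to the chord from the
histogram peak to the last occupied bin. The bin count changes the
threshold and is therefore fixed and stated. The implementation agrees
bin-for-bin with an exhaustive scan on 1000 random unimodal histograms.

**Membrane profiles**: the cell contour is the 0.5-level of the slightly
smoothed mask (smoothing suppresses the pixel staircase, which otherwise
inflates perimeters by ~6%), oriented counterclockwise. At points spaced
0.5 µm along the contour, the image is sampled by bilinear interpolation
along the inward normal from −3 µm (outside) to +3 µm (inside) in
pixel-size steps; the inward direction is resolved against the polygon
itself. Line spacing, half-length and step are configuration, not
literature values. On a synthetic cell with a 1-µm cortical band at
enrichment 0.4 and SNR ≥ 10, the profile peak falls inside the band and
the recovered enrichment (twice the peak-minus-plateau of the FR
profile) is within 10% of truth.

Display gamma (0.8 by default) is monotone, applied only to
[0, 1]-normalised images, and never feeds quantification.

## Spine morphometry

From a spine mask and the shaft mask it touches:

* **base** — centroid of the spine pixels 4-adjacent to the shaft;
* **length** — geodesic distance (within the spine) from the base
  pixels to the farthest spine pixel, plus 1 px for the half-pixel lost
  at each end, times the pixel size;
* **local widths** — spine pixels are binned by geodesic distance; each
  bin's medial point is its maximum-distance-transform pixel;
* **neck width** — minimum over the proximal half of twice the distance
  from the (subpixel-refined) medial point to the *raw* marching-squares
  boundary of spine∪shaft. The raw contour is used because smoothing
  partially fills the concave pocket between shaft and head flare and
  would inflate short necks; straight neck walls carry no staircase
  bias;
* **head width** — a slab-averaged chord at the widest distal
  cross-section: the mask extent between interpolated 0.5-crossings,
  perpendicular to the local axis (tangent taken from the geodesic
  path), is profiled along the axis; the equator is located on the
  smoothed profile; and the mean chord over a ±1.5 px slab is inverted
  through the circular mean-chord formula. A single-row extent carries
  the full ±1 px rasterisation noise of one chord and an
  inscribed-circle radius (a minimum statistic) is biased ~0.5 px low;
  the slab average is unbiased for disc-like heads and returns
  parallel-sided heads to within ~2%.

Head/neck search windows (distal and proximal 50% of the path) are
configurable. Across 500 randomly drawn spines (length 0.5–6 µm, neck
0.1–0.8 µm, head 0.2–1.5 µm at 0.07 µm/px) the estimators are unbiased
with SD ≈ 0.3–0.5 px; worst-case errors sit at the rasterisation limit
(~1 px), which no estimator of a half-coverage binary mask can beat.

**Classification** applies strict first-match rules: length > 4 µm →
filopodium; length/neck < 2 → stubby; head > 0.75 µm → mushroom; else
thin. Boundary values fall through to the next rule, and the rule order
matters: a short wide spine (e.g. 0.8/0.5/0.8 µm) satisfies both the
stubby and mushroom conditions and is stubby. The head-width/length
ratio serves as the scale-free shape parameter; time-lapse changes are
reported as log10(x_t/x_0) (base 10 chosen for readability of
fold-changes), 0 at t₀ by construction. Spine identity over time
follows the label mask; across re-segmented frames labels are matched
by ≥ 50% mask overlap, else the track ends.

## Cell shape and nested statistics

**Compactness** is polygon area over convex-hull area (solidity): the
convex hull is the only "inscribing polygon" reading that gives the
documented 0–1 range with 1 for convex (rounded) cells. It is exact
(shapely), invariant under similarity transforms, and rejects
self-intersecting polygons.

**Automated morphology scoring** (rounded / flattened / neurite-bearing)
is a surrogate for blinded visual scoring, with stated defaults:
rounded if compactness ≥ 0.9 and circularity 4πA/P² ≥ 0.8;
neurite-bearing if the longest skeleton branch reaches ≥ 2× the
equivalent radius √(A/π); else flattened.

**Nested comparison**: spine observations are averaged per cell
(unweighted — each cell is one unit regardless of its spine count), and
conditions are compared by one-way ANOVA on cell means. The naive
spine-level ANOVA is always computed alongside: under a null with
intraclass correlation 0.5 and 20 spines/cell it rejects at ~50%+
while the nested test holds its nominal 5% size. Post-hoc comparisons
are stepwise Newman–Keuls on the studentized range (widest spans first;
a non-significant span blocks everything nested inside it); because
Newman–Keuls error control is approximate, a permutation variant
(cells permuted across conditions, F as statistic) is provided.

**Rank correlation** between per-spine morphology change and biosensor
activity change is Spearman's rho with a permutation p-value
(`(1 + #{|ρ*| ≥ |ρ|}) / (n_perm + 1)`); constant inputs are rejected
because ranks are undefined.

## The synthetic scenes, and what they do not show

The generators emulate the study's acquisitions with exact ground
truth: two-channel FRET time-lapses whose acceptor is the donor times
the programmed ratio pixel-for-pixel (so noise-free scenes round-trip
exactly), dual-stain actin cells with a cortical F-band, dendrites with
parametric spines, and silhouettes of known compactness. Degradations
are applied in physical order: per-channel linear multiplicative bleach,
then subpixel drift (linear interpolation; ground truth stays in frame-0
coordinates), then Poisson shot noise at `poisson_scale` photons per
intensity unit plus Gaussian read noise. A single seed drives a
hierarchical RNG (scene → object → frame); identical spec + seed is
bit-identical.

Deliberate simplifications: no optical PSF beyond the optional Gaussian
blur, no spectral bleed-through, no focus drift, no autofluorescence
gradients, and spines are rendered as neck rectangle + head disc rather
than segmented from an image. Spine positions carry subpixel jitter —
pinning them to pixel centres would systematically round rasterised
widths up by half a pixel. Passing tests therefore demonstrate that the
measurement chain is correct and well-calibrated on data satisfying its
model, not that segmentation of real micrographs is solved (the original
workflow segmented spines interactively; that step is out of scope
here).

Default study conditions used by the tests and the acceptance script,
chosen to mirror the acquisition protocol: 12 frames of which 3 are
baseline, 20 ROIs per field, responder fraction 0.5, step +30%,
acceptor bleach 2%/frame with the donor unbleached (so the *ratio*
decays linearly at 2%/frame, the regime the linear ratio correction
addresses), drift 1 px/frame, photon scale 3 and read noise 3.4 for
SNR ≈ 15. The morphometry sweep draws geometries uniformly from the
stated ranges subject to head ≥ neck and length ≥ head + 0.2 µm — a
spine whose head disc spans its entire length has no neck anywhere in
its rendered mask, so "neck width" is not a recoverable quantity for
such shapes at any resolution.

## Known limitations

* Width estimates cannot beat the half-coverage rasterisation of a
  binary mask: worst-case errors approach 1 px even for an unbiased
  estimator. On real data the segmentation, not the rasterisation,
  would dominate.
* The linear bleach model is only a local approximation of exponential
  photobleaching; the reliability bounds on the correction factor guard
  against extrapolating it too far.
* Newman–Keuls does not strictly control the family-wise error rate;
  the permutation alternative exists for exactly that reason.
* The responder rule and the cell-morphology rules are automated
  surrogates for judgements the original workflow made by eye; their
  thresholds are stated defaults, not fitted constants.
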