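# Methods

This note documents the models and procedures implemented in `cupquant`,
the defaults and why they were chosen, the numerical decisions, and the
known limits of what the synthetic validation shows.

## Synthetic movie generator

The generator (`cupquant.synth`) emulates two-channel time-lapse imaging
of a single amoeboid cell, as acquired on a spinning-disk confocal at
high magnification. The cell is star-convex: a radius function r(θ)
around a centroid that drifts at constant speed in a random direction.
All angles are measured counter-clockwise from the +x axis in image
coordinates (x = column·pixel, y = row·pixel, y increasing downward);
membrane patches are half-open angular intervals [θ_start, θ_end) on
this circle, which keeps the ground truth directly comparable with the
contour-indexed measurements.

**Imaging model.** Per frame and channel, the noiseless image is
piecewise constant: cytosol at `cyto_mean`, a membrane band of thickness
`membrane_band_um` centred on r(θ) at `baseline_membrane_fold`×cytosol,
multiplied by `patch_fold` inside patch intervals (patch channel) and by
`ring_fold` inside ring segments (ring channel); background is zero.
Noise is shot noise then read noise: Poisson(scale·I)/scale +
N(0, σ_read), clipped at zero; with both noise parameters zero the
render is a deterministic function of the truth. Each patch lineage
carries a lognormal intensity multiplier (`patch_fold_cv`, default 0.15)
because real reporter levels vary between structures; without this
between-patch variability, intensity comparisons between conditions
would detect arbitrarily small measurement artifacts as significant.

**Ring placement.** Ring segments sit *outside* each patch interval,
abutting its boundaries, with physical width `ring_width_um` (default
2.4 µm of arc). Segments are clipped wherever they would enter another
patch's interval — the ring reporter is excluded from patch interiors —
which matters across the narrow gap between freshly split siblings. Two
generator switches exist for control experiments: `interior` places the
segments just inside the boundaries (flipping the sign of the
channel-correlation), and `coincident` renders the ring channel on the
patch intervals themselves (a positive-control second reporter).

**Patch dynamics.** Births follow a Poisson process (`patch_birth_rate`
per frame, from frame 1). Each birth draws its origin: with probability
`split_probability` it is a split of a live patch, otherwise de novo. A
de novo patch is placed uniformly at random where its full target
footprint (target width plus a 6° margin per side) does not collide
with any patch born since, or closed less than three frames ago (the
refractory window prevents a birth exactly where a patch just closed,
which no tracker could distinguish from a continuation). It grows from
a sub-resolution 6° over three frames to a target width drawn from
N(`patch_width_deg_mean`, `patch_width_deg_sd`), clipped to stay
physical. A split detaches a small daughter (14–26°) from one end of a
fully grown parent at least 40° wide, leaving a gap that widens from 8°
to 12° over two frames; the parent lineage keeps the remainder and the
daughter is a new lineage of origin "split" inheriting the parent's
intensity. Patches close abruptly after a Poisson-distributed lifetime
(`patch_lifetime_frames_mean`). Origin draws that cannot yet be
realised (no splittable parent, no free membrane) are deferred to later
frames rather than converted, so the realised origin mix remains
Bernoulli; a split intent waits at most `split_patience_frames`
(default 8) before forming de novo instead, which prevents extinction
in small movies. With patience effectively infinite and a parent-rich
regime (low birth rate, wide long-lived patches), the realised split
fraction is binomially consistent with `split_probability` — the
regime the corresponding property test and reproduction script use.

**Motility.** Two protrusion modes: `global` (default) superimposes a
three-lobed radial wave whose amplitude oscillates in time
(`protrusion_amp_um`, `protrusion_freq`), providing generic membrane
motion; `patch` places radial bumps on the ring segments whose height
tracks patch growth, so protrusive speed co-localises with the ring
reporter — the construction behind the speed-vs-intensity sign check.

**Defaults as study conditions.** 256×256 px at 0.1 µm/px, 1 s frames,
an 8 µm cell radius, cytosol mean 100 counts, folds 3×, Poisson scale 5
and read noise SD 2 (patch-to-cytosol contrast ≈ 25σ per pixel, SNR well
above 5), four initial steady-state patches of mean width 50° with
births at 0.3/frame. These were chosen once to resemble a vegetative
cell imaged at 100×: patch coverage fluctuates around 40% of the
perimeter with 3–4 concurrent patches, which keeps every pooled
statistic (correlations, centre/edge tests) well conditioned in a
50-frame movie.

## Segmentation and contour

Cells are segmented on the patch channel: Gaussian smoothing (default
0.1 µm), Otsu threshold (parameter-free; "mean" and fixed thresholds
are available), largest connected component, hole filling. The contour
is the 0.5 iso-contour of the smoothed mask (marching squares),
resampled densely, smoothed circularly to remove pixel-scale
jaggedness, and resampled to N = 100 equal-arclength points,
counter-clockwise with index 0 nearest the +x ray from the centroid.
Cytosol statistics use the mask eroded by `erosion_margin_um`
(default 1.0 µm), which safely excludes the membrane band.

## Membrane sampling

Each contour point's intensity is the mean of 7 bilinear samples along
its inward normal over `band_width_um` (default 0.5 µm), starting
`band_inset_um` (default 0.25 µm) inside the contour, with samples
outside the cell mask discarded. The inward placement and inset are
deliberate: the threshold crossing that defines the segmentation
boundary moves *outward* where the membrane is bright, so a band
centred on the contour would mix in extracellular background
preferentially at patches and bias every membrane measurement downward.
With the inset, the ring channel at patch centres reads 1.00× cytosol
(unbiased), which the centre-vs-background test requires. The mean
(not maximum) over the band is used for robustness to single-pixel
noise.

## Patch calling and statistics

The threshold is strict: raw intensity greater than cytosol mean plus
k·SD (default k = 1); a value exactly at threshold is excluded. Calls
are maximal circular runs with wrap-around merged; `min_patch_points`
(default 3 of 100) suppresses single-point noise runs; a profile
entirely above threshold is one full-circle patch. The reported patch
intensity is the mean over the run's core (two boundary points trimmed
per side when the run exceeds six points) so that it does not depend on
patch size through partial-coverage dilution at the edges; the peak is
taken over the whole run. Patch size is membrane arc length
(points × arc spacing). Group comparisons use two-tailed t-tests —
paired where the design pairs observations, Welch otherwise — and Holm
correction when more than two tests are reported as a family.
Per-frame re-sightings of one patch are not independent observations:
both the centre/edge-vs-cytosol tests and the between-condition
comparisons of size and intensity therefore aggregate per tracked
lineage before testing (several cells can be pooled, since every
quantity is cytosol-normalised).

## Edge profiles and sharpness

Profiles run along the membrane arc through each called boundary
(2·half_width+1 points, default half-width 8), oriented so the patch
interior is on the left; edges without clearance (interior shorter than
the half-width, or another patch within it on the exterior side) are
skipped and counted. Contrast anchors are the means of the three
innermost and outermost samples. d₉₀₋₁₀ interpolates the 10% crossing
(first sample below the level) and anchors the 90% crossing at the last
sample above the level *before* it, so plateau noise cannot inflate the
width; the result is floored at one sample spacing and is invariant
under affine intensity changes. Against Gaussian-blurred step edges the
estimator recovers 2·1.2816·σ within a few percent for σ down to about
two sample spacings.

## Dynamics

Contour correspondence is the circular index offset minimising summed
squared point distances, then each point is refined to its nearest
point on the next contour's polyline (densified 8×). This replaces a
full electrostatic contour-matching scheme on purpose: for the modest
inter-frame motions of interest (displacement below two arc spacings),
the refined displacement projected on the outward normal matches the
analytic normal-velocity field of affine motions with under 10% RMS
error, which is the regime the speed analyses need. Speeds are computed
forward (t→t+1) and assigned to frame t.

Membrane kymographs align rows using only the cumulative rigid offsets,
so each column is a permutation of that frame's profile (column sums
are conserved); the per-point refinement is used for speeds only. Edge
kymographs sample intensity along a line from a tracked patch-edge
point towards the centroid, concatenated per frame, with the closure
frame annotated.

Patch tracks link calls across frames by greedy interval overlap
(largest first, one-to-one) in offset-aligned indices, with a
configurable gap tolerance (default 1 frame) for sub-threshold flicker.
A new track overlapping a live track's previous interval is a split
birth (the overlapping track is recorded as parent); otherwise de novo.
Which sibling of a split keeps the parent's track identity is
arbitrary, so event-level evaluation accepts either. Origin summaries
exclude tracks and lineages present at frame 0 (their origin predates
the movie) and, when scored event-by-event, births within five frames
of the movie end (a patch born there never reaches the calling
resolution, so no method could classify it).

## What the synthetic validation does and does not show

The generator reproduces the statistical structure the measurements
rely on — cytosolic pools, a bright membrane rim, patch/ring geometry,
shot and read noise, drift, protrusions, and birth/growth/split/closure
dynamics — and therefore validates the *machinery*: thresholding
behaviour, circular topology, centre/edge geometry, tracking logic,
speed and sharpness estimators, and statistical calibration. It does
not emulate uneven illumination, photobleaching, out-of-focus light,
3D cup geometry projected into 2D, multi-cell fields, or biological
shape changes beyond smooth radial protrusions; blebs and
pseudopod-vs-cup shape distinctions are out of scope. Passing these
tests therefore establishes correctness of the algorithms under their
stated assumptions, not performance on any particular microscope's
data.

## Problem sizes in the tests and reproduction script

The standard movies are 50–100 frames at 256² pixels (about 2 s of
compute each with full per-frame analysis); origin statistics use a
260-frame movie accumulating ≥ 50 births; the sharpness comparison
pools edges from two 80-frame movies; the size-discrimination power and
null calibration use 100 and 1000 draws of 30-patch groups from the
generator's width distribution. These sizes give every statistic
comfortable margins over its acceptance threshold while keeping the
whole suite under a minute of compute per movie set.
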