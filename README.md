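# cupquant

Quantification of membrane signalling patches and their edge-associated
rings in two-channel single-cell fluorescence movies.

## The problem

During macropinocytosis, amoeboid cells such as *Dictyostelium* organise
cup-shaped membrane protrusions around intense membrane domains
("patches") of PIP3 and active Ras, while the actin nucleation-promoting
SCAR/WAVE complex accumulates in a narrow ring at the patch periphery —
at the edge, never the centre. Quantifying this organisation from
time-lapse microscopy requires a chain of image measurements: segmenting
the cell, tracing its outline, sampling membrane-bound fluorescence,
calling patches by an objective threshold, relating a second reporter to
patch centres and edges, following patches through time (including the
characteristic birth of new cups by *splitting* of existing ones), and
measuring membrane kinetics and patch-edge sharpness.

`cupquant` implements this pipeline as a tested, reusable library for
two-channel movies of single cells, together with a synthetic movie
generator with full ground truth so that every stage is verifiable
without any imaging data.

## The model and the measurements

- **Contour**: the cell outline is the 0.5 iso-contour of the smoothed
  segmentation mask, resampled to N equal-arclength sub-pixel points
  (default N = 100), counter-clockwise, indexed from the +x ray.
- **Membrane profile**: at each contour point, the mean of bilinear
  samples along the inward normal over a cortex band (default 0.5 µm,
  inset 0.25 µm), restricted to the cell mask; intensities are
  normalised to the cytosolic mean of the same channel.
- **Patch calling**: a patch is a maximal circular run of contour points
  whose raw intensity *I* satisfies *I* > µ_cyto + k·σ_cyto
  (default k = 1), where µ_cyto and σ_cyto are the mean and SD of the
  cytosolic pool (eroded cell interior). Wrap-around runs are merged;
  runs shorter than 3 points are discarded.
- **Centre/edge quantification**: for each called patch, a second
  channel is read at the patch centre and at its two boundaries
  (boundary point plus immediate outside neighbour averaged), in
  cytosol-normalised units, and compared with the cytosolic background
  by paired two-tailed t-tests.
- **Dynamics**: frame-to-frame contour correspondence is a rigid
  circular index offset plus nearest-point refinement; signed local
  membrane speed is the refined displacement projected on the outward
  normal. Membrane kymographs are row-aligned by the cumulative rigid
  offsets; patch lineages are linked by greedy interval overlap, and a
  new lineage that overlaps a live lineage's previous interval is
  classified as a **split** origin, otherwise **de novo**.
- **Edge sharpness**: intensity profiles along the membrane across each
  patch boundary, oriented interior→exterior; sharpness is the 10–90%
  fall distance d₉₀₋₁₀ (for a Gaussian-blurred step, d₉₀₋₁₀ = 2.563 σ).

## Worked example

Run the full pipeline on a generated movie (default study conditions:
256×256 px at 0.1 µm/px, 50 frames at 1 s, a ~16 µm motile cell, patch
channel 3× cytosol inside patches, ring channel 3× in segments flanking
patch edges, Poisson + Gaussian noise):

```bash
cupquant report --seed 11 --outdir demo
```

prints

```json
{
 "n_patches": 259,
 "mean_size_um": 4.027762321212794,
 "patch_vs_ring_r": -0.5426632004035753,
 "split_fraction": 0.5,
 "outdir": "demo"
}
```

and writes the full `report.json` plus every stage artifact (masks,
contours, profiles, calls, speeds, kymographs, tracks) to `demo/`. In
this run: 259 patch sightings were called across 50 frames with mean
membrane arc length 4.0 µm; the pooled per-point correlation between the
patch and ring channels is r = −0.54 (the ring reporter avoids patch
interiors); the ring channel at patch *edges* averaged 1.60× cytosol
(paired t-test vs cytosol, p ≈ 2×10⁻¹⁹²) while at patch *centres* it
averaged 1.00× (p = 0.74, indistinguishable from background); and 50% of
newly appearing patch lineages arose by splitting from an existing one,
matching this movie's ground truth exactly.

Stages can also be re-run individually (`cupquant generate / segment /
profile / call / dynamics / compare`), each reading the previous stage's
files. The same operations are available as a library:

```python
from cupquant import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(seed=11, outdir="demo"))
```

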