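# Methods

This note records the models implemented in `dropsort`, the parameter
choices that matter, and what the synthetic data does and does not
emulate.

## Synthetic micrographs

`fixtures.render_frame` draws an (image, background) pair emulating a
brightfield droplet held at the detection zone of a microfluidic
channel:

* **Static background** — base level 180/255 with a gentle linear
  illumination gradient (±3 intensity) and 3–6 dark debris specks.
  Identical in both frames, so absolute background subtraction cancels
  it exactly.
* **Droplet** — interior disk brightened by +5 (lensing), surrounded by
  a dark rim annulus. The rim models the refraction at the droplet–oil
  interface. Rim width defaults to 4 px and rim darkness to −60
  intensity; neither is a measured quantity, they are free parameters
  chosen so that the rim clears the edge threshold (12) by a wide
  margin while the interior stays below the droplet threshold (10).
* **Cells** — brightfield cells are uniform dark ellipses (contrast
  −40); fluorescent cells are anisotropic Gaussian nuclei (peak +175 on
  a ~5/255 background), with sigma set to half the ellipse semi-axis so
  the region above the adaptive 25% threshold approximates the ellipse.
* **Noise** — Gaussian (sigma 2 intensity units) followed by
  salt-and-pepper speckle (fraction 0.001). Defaults exercise the
  denoising steps of the segmentation chain without overwhelming them.

Cells flagged `at_boundary` are centred on the rim so they merge with
the droplet edge during segmentation — the boundary/lensing effect that
causes undercounting in real rigs.

All randomness flows from one integer seed through splittable
`numpy.random.SeedSequence` children (static features, noise, stream
draws, per-droplet placement each get their own child), so frames and
streams are bit-reproducible.

**What is not emulated:** diffraction and the point-spread function,
partial focus, multi-droplet frames, cell internal texture, motion
blur, and 3-D geometry. Passing tests therefore demonstrate the
correctness of the *algorithmic chain* under the stated imaging
assumptions, not segmentation robustness on real micrographs.

## Stream model

`simulate_stream` draws per-droplet volumes `Normal(V_mean, cv*V_mean)`
(truncated at 0.2 V_mean) and counts `Poisson(CC * V_i)`. Defaults:
V_mean = 155 pL, cv = 0.05, droplet rate 3.5 Hz. The cv is a modelling
choice representing typical droplet-generator monodispersity; at 5% it
perturbs the marginal count distribution by far less than sampling
noise at the n used in tests.

Volume maps to pixel radius through the cylinder model `V = pi r^2 h`
with channel height h = 30 um (configurable; 34 um is an equally
defensible preset and both appear in practice). The unit identity used
throughout is 1 pL = 10^3 um^3.

Frame geometry defaults follow the emulated rig: 0.25 um pixels,
384×384 frames, so a 155 pL droplet has a ~162 px radius (~81 um
width). Cells default to 3.75 um semi-major axis (~15 px, red blood
cell scale) with axis ratio drawn uniformly from [1, 3] to mimic the
orientation-dependent projection of biconcave discs. Interior cells are
placed by rejection sampling with a 4 px pairwise clearance and kept
≥ 4 px clear of the rim; this guarantees exact countability on
noise-free frames, which is what the end-to-end purity check relies
on.

## Segmentation chain

1. `|image − background|` as 8-bit. Absolute difference serves both
   modes with one rule (brightfield features darker, fluorescent
   brighter).
2. Droplet mask: threshold > 10, drop components < 5 px
   (8-connectivity), fill holes, keep the largest component; error if
   it is below 500 px.
3. Cell mask: threshold > 12 keeps rim + cells; flood fill of non-edge
   pixels from the droplet centroid (4-connectivity so the fill cannot
   leak diagonally through the rim; spiral seed fallback within 5 px,
   then largest-interior-component fallback for the case of a cell
   sitting exactly on the centroid); dilate the fill twice with a 3×3
   square (removes speckle holes); invert; remove the border-connected
   component and sub-5 px components.
4. Fluorescent path: threshold > 0.25 × frame maximum; error below a
   noise floor of 20.

Thresholds keep pixels strictly above T; the choice only moves single
boundary intensities. The double dilation erodes the apparent cell by
~2–3 px of radius; cell areas from the cell mask are therefore
systematically low (a 15 px cell reports ~75% of its true area, an
8 px cell ~45%). Counting, which is the decision-relevant output, is
unaffected as long as cells are ≥ 3 px apart.

## Feature estimators

* Perimeter: marching-squares boundary polyline at level 0.5. A
  pixel-edge count would bias the Heywood factor of a rasterized circle
  up to ~1.2; the polyline keeps it within 5% of 1.
* Ellipse ratio: ratio of the second-moment equivalent-ellipse axes
  (no discrete-pixel correction), matching the brute-force moment
  oracle exactly; a 10×40 px rectangle gives 4.02, the continuous limit
  being 4.
* Feret diameters: exact caliper over pixel *corner* points, computed
  as the convex hull of the pixel-center hull's corner expansion (the
  Minkowski-sum identity makes this exact and fast). Feret min uses
  rotating calipers.
* Intensity statistics are taken from the original image, not the
  difference image.

## Detection

The ROI detector tracks the region mean as an exponential moving
average (decay 0.99/frame — "averaged over time" with bounded memory)
and triggers on a drop below `0.98 × mean`; the mean is updated only by
frames at or above threshold, and the detector re-arms after two
consecutive above-threshold frames, so a slow transit produces one
event. Because the threshold is proportional to the mean, detection is
invariant to global illumination rescaling.

The laser path is modelled as pure 1-D signal processing: departure
from a trailing-window baseline by more than a configurable delta, with
refractory hold. The trigger delta and sampling rate are free
parameters (the physical chain's values are hardware-specific).

## Decisions

Gates are inclusive at the threshold ("higher than 4" rejected means 4
kept). Cell-level gates must pass for *every* cell in the droplet.

The classifier is `StandardScaler + SVC(kernel="poly", degree=2,
coef0=1, C=1)`. `coef0=1` makes the kernel `(1 + x·y)^2`, the full
quadratic monomial expansion a "quadratic SVM" denotes; C = 1 is the
recorded default since no principled value is available, and z-scoring
is required because raw area (um^2) is three orders of magnitude larger
than circularity. The artifact stores features, C, seed, classes and
the fitted pipeline so decisions are replayable.

## Virtual sorter

Droplets default to waste. A keep decision fires the 20-pulse / 500 Hz
/ 40 ms / 1.32 kV actuation; it succeeds with probability
`1 − failure_probability` (default 0). Any droplet detected while the
field is still active is co-sorted with the target — the collision
mechanism that caps throughput at 1/40 ms = 25 Hz. Junction-to-outlet
travel is 50 ± 5 ms (Gaussian, configurable); only the 200 ms
verification window is a rig-specified quantity, the travel time is a
modelling choice placed comfortably inside it. Verification matches
keep-outlet arrivals to actuations FIFO and one-to-one; unmatched
arrivals are false positives.

## Metrics

Efficiency, purity, yield and enrichment over the confusion counts,
with 0/0 reported as NaN plus an `undefined` flag instead of an
exception, so batch reports survive an empty outlet. An optional
percentile bootstrap (1000 droplet resamples, seeded) gives an
enrichment interval. `targets_detected` is the count of true targets
the imaging flagged, which makes efficiency exactly 1 whenever
actuation is perfect, regardless of detection errors — matching its
role as a measure of the electromechanical sorting step.

## Problem sizes and numerical checks

Statistical suites use n = 10^5 droplet draws (lambda recovery within
3 SE, chi-square goodness of fit at alpha = 0.01); the rendered
end-to-end run uses 2000 droplets at lambda = 1, chosen to make the
binomial 3-sigma band on the 36.8% single-cell fraction about ±3
percentage points while keeping the full suite comfortably within a
desktop-scale run. Feature oracles are exhaustive pixel loops on random
≤ 30×30 masks. The Gaussian FWHM fit initialises deterministically
(argmax peak, second-moment sigma) and recovers noiseless widths to
better than 1e-6 relative.

## Known limitations

* Cell areas from the brightfield chain are biased low by the fill
  dilation (see above); use the fluorescent path or the hole-area
  before dilation if unbiased size matters.
* Overlapping or near-touching cells (< 3 px gap) merge into one
  component; the generator avoids this, real data does not.
* The ROI detector assumes the ROI mean drops during a transit; bright
  droplets on a dark background need the multiplier inverted.
* Enrichment is undefined for perfect runs (0/0) and extremely noisy
  when `others_keep` is small — it is a ratio of ratios.
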