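# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `chromapupil`. It is written for users who need to judge what
the toolkit's numbers mean and what its passing tests do and do not show.

## Background

Chromatic pupillometry measures the pupil light reflex (PLR) separately for
blue and red stimuli. Melanopsin-bearing, intrinsically photosensitive
retinal ganglion cells (ipRGCs, peak sensitivity near 482 nm) add a sustained
constriction after a blue stimulus that red stimuli do not elicit. The
standard readout is the post-illumination pupil response 6 s after stimulus
offset (PIPR-6s), expressed as percent of the pre-stimulus baseline area;
the red-minus-blue PIPR-6s difference is about 10% in healthy eyes and is
reduced in several neuro-ophthalmological diseases. Because ipRGC density
peaks in the perifovea — an annulus 1.25–2.75 mm from the foveal centre —
a ring-shaped stimulus of the right angular size stimulates them selectively,
which is what the optics layer designs for.

## Ring-light optics

The eye is modelled as a reduced schematic eye: every chief ray passes
undeviated through a single nodal point sitting one posterior nodal distance
(PND) in front of the retina. A point source offset laterally by `x` at
distance `d` subtends `tan θ = x/d`, so it lands at retinal eccentricity

```
e = PND · x / d        (x, d in cm; e, PND in mm)
```

Defaults: PND = 16.67 mm (Emsley reduced eye), axial length 22.22 mm,
photopic pupil aperture 2 mm. The aperture is informational: in a chief-ray
model it blurs the landing spot but does not move its centroid, and the
centroid is the designed-for quantity. With these defaults a 3 cm diameter
ring viewed at 15 cm lands at 1.667 mm — inside the perifoveal band — and
the inverse design (`ring_diameter_for_eccentricity`) is the exact algebraic
inverse, so round-trips are identities to floating-point precision.

The same formula, applied to the effective lateral offset of the ambient
lamp that keeps the video exposed, verifies that ambient light misses the
band (`source_in_band`). No finite-aperture ray tracing, chromatic
aberration, Stiles–Crawford weighting or radiometric calibration is
attempted; the model answers geometric placement questions only.

## Ground-truth PLR model (simulator)

Real recordings carry no per-frame ground truth, so every downstream stage
is validated against a generative model. Normalised pupil area (% baseline):

* 100 before stimulus onset + latency (default latency 0.25 s);
* `100 − A_c·(1 − exp(−t'/τ_c))` during the stimulus (constriction
  amplitude `A_c` %, τ_c = 0.8 s, `t'` from onset+latency);
* `100 − A_f·exp(−Δt/τ_f) − A_s·exp(−Δt/τ_s)` after offset (`Δt` from
  offset; fast re-dilation `A_f`, τ_f = 1.5 s; sustained component `A_s`,
  τ_s = 30 s).

The model is phenomenological: the two-exponential recovery is the simplest
form that separates blue from red the way melanopsin does, with `A_s` the
melanopsin-like knob. The curve is exactly continuous at offset when the
constriction is fully developed and `A_f + A_s = A_c`; with the default
τ_c ≪ 5 s stimulus the residual step is < 0.15% of baseline.

Presets (protocol: 10 s baseline, 5 s stimulus, 25 s post, 30 fps — the
acquisition schedule of the smartphone system being emulated):

| preset | A_c | A_f | A_s | ground-truth PIPR-6s |
|--------|-----|-----|------|----------------------|
| red    | 40  | 40  | 0    | 99.27 |
| blue   | 55  | 40  | 10·e^(6/30) ≈ 12.21 | 89.27 |

`A_s(blue)` is chosen so the sustained term contributes exactly
`A_s·e^(−6/30) = 10.0%` at the 6 s readout: the preset pair has a
ground-truth red−blue difference of exactly 10 percentage points, making
end-to-end recovery quantitative. The deeper blue constriction mirrors the
larger maximal constriction seen for blue stimuli at moderate intensities.

Sampling adds i.i.d. Gaussian noise on the normalised scale (default sd 1%
of baseline — a convention; the per-frame noise statistics of real
smartphone recordings are not characterised) and maps to area via
`area = baseline·(pct + ε)/100`, so area/baseline recovers the noisy
percentage exactly. Default baseline area 7000 px² (pupil radius ≈ 47 px),
sized like a cropped smartphone eye frame.

## Rendering

Frames are 8-bit, default 200×200 px: dark pupil disc (level 20) centred in
a brighter iris disc (level 150, radius 80 px) on a sclera-level background
(level 220), plus Gaussian pixel noise (sd 2 levels). `ambient_tint="red"`
emits RGB with the full signal in the red channel (G, B attenuated),
emulating recording under red ambient light, which preserves pupil/iris
contrast. Blinks are rendered as an eyelid band covering the iris — an
occlusion, not an area change — so the *detector* must discover them; blink
frames carry `valid=False` and an empty mask in the ground truth. The
ground-truth mask is the rasterised disc of the scheduled radius (pixel
centres within radius), which matches the scheduled area to within a
one-pixel perimeter band.

Not modelled: iris texture, corneal reflections, gaze drift, perspective,
partial blinks, motion blur. Passing tests therefore demonstrate correctness
of the measurement chain on geometrically clean dark-pupil footage, not
robustness to every artefact of real recordings.

## Pupil detection

Per frame: grayscale (ITU-R 601 luma, or the red channel for strongly
red-lit frames), optional ROI crop, Gaussian smoothing (kernel 5 px,
σ = kernel/4), dark thresholding, morphological opening+closing (disc,
radius 3 px), connected-component selection, second-moment ellipse fit.

Threshold modes: `otsu` (default), `percentile`, `fixed`. Two refinements
make the Otsu mode robust on eye frames:

1. **Recursive descent into the dark class.** Eye frames are tri-modal
   (pupil/iris/sclera-skin) and Otsu's strongest valley can be the
   iris–sclera one, which would segment the entire iris. Otsu is re-run
   inside the dark class for as long as the valley found there has a larger
   class-mean separation than the current dark/bright separation, settling
   into the deepest (pupil) mode. The rule is parameter-free and
   shift-invariant, and stops correctly both on bimodal frames and on the
   thin blurred-edge band inside the pupil class (whose internal separation
   is always weaker than pupil-vs-surround).
2. **Edge mid-level snap.** Otsu may place its cut anywhere inside the
   blurred pupil edge, biasing the segmented radius by a fraction of the
   smoothing width (up to ~2.6% area error measured on clean discs). The
   threshold is snapped to the midpoint of the median interior level
   (eroded mask) and the median level of a thin ring outside the mask —
   where a symmetric blur crosses half-way exactly at the geometric
   boundary. Residual per-frame area error on rendered sequences is < 1%.

Component selection takes the most circular component (circularity
`4πA/P²` ≥ 0.6) within area bounds [200, 50000] px², rejecting components
that touch the image border (eyelid bands and shadows run off the frame; a
pupil does not) and components whose median level is not at least 20 gray
levels below their immediate surround (blobs carved out of noise on
occluded frames fail this; a genuine pupil clears it by ~100 levels). All
thresholds are configurable; the defaults are tuned to nothing more specific
than "dark pupil, brighter iris, 8-bit video".

The ellipse fit uses the pixel-coordinate covariance: semi-axes are twice
the square roots of its eigenvalues (exact for a uniformly filled ellipse),
centre is the centroid, `area = πab`. Components under 5 px are invalid.

Detectors are chained in priority order; the chain returns the first valid
fit, so an external detector (e.g. PuRe) can be slotted ahead of the
threshold detector through the one-frame-in, one-fit-out contract. Any
invalid or absent fit counts as that detector failing on the frame.

## PLR analysis

Fixed processing order (the literature lists the steps without an order;
this one is chosen and documented):

1. **Blink flagging** — a sample is invalidated if its detection failed or
   its area jumps more than `max_rel_step` = 0.5 (relative) from the *last
   valid* sample; comparing to the last valid sample rather than the literal
   previous row keeps the recovery frame after a one-frame dropout valid.
   Valid islands shorter than `min_gap` = 3 frames squeezed between invalid
   runs are merged into them.
2. **EWMA smoothing** over valid samples (`y_i = α·x_i + (1−α)·y_{i−1}`,
   α = 0.3 by default, α = 1 is the identity); the recursion skips invalid
   samples, propagating across blink gaps.
3. **Residual outlier pass** — samples with `|raw − smoothed|` above 4
   robust standard deviations (1.4826·MAD) of the residuals are invalidated
   and the smoothing recomputed.
4. **Baseline** — mean of *raw* valid areas over the 10 s pre-stimulus
   window (the baseline is itself defined as an average, so it is taken on
   unsmoothed data). No valid baseline samples make the trial unusable.
5. **Normalisation** — `100 − (baseline − area)/baseline·100`, identically
   `100·area/baseline`; by construction the valid baseline-window samples
   average to exactly 100.
6. **PIPR** — mean of valid normalised samples in a window of half-width
   0.25 s centred 6 s after stimulus offset. The window (rather than a
   single sample) buys robustness to frame-rate jitter at negligible bias on
   the slow recovery curve (< 0.05% for the default kinetics); both the
   smoothed (default) and raw normalised curves can be read out.

Aggregation is per-trial-first: PIPR per trial, then mean and sample sd
(n−1) across the repeats — matching how repeated measurements per condition
are reported — not PIPR of the averaged curve. Curve aggregation resamples
each trial's valid samples onto a common grid by linear interpolation. With
a single trial the sd is reported as 0 by convention.

## Pipeline and reproducibility

A run is one YAML-loadable `RunConfig` with exactly one input source
(simulator spec, frames directory, video file, or a manifest CSV of trials).
Per-trial seeds derive from the run seed through `numpy` `SeedSequence`
spawn keys `(colour index, trial index)`, so any trial is reproducible in
isolation and identical config+seed gives a byte-identical PIPR summary.
Trial-level analysis failures are recorded per trial without aborting the
batch. The manifest written with each run records the hash of the scientific
configuration (paths and log level excluded), the seed, and library
versions.

## Problem sizes used in the shipped checks

The full-protocol end-to-end check runs 3 blue + 3 red trials at 30 fps for
40 s (1200 frames of 200×200 px per trial, 1% area noise, 2 random blinks
per trial) and requires the recovered red−blue PIPR-6s difference within
±1 percentage point of the generator's exact 10.0% and every non-blink
frame's detected area within 3% of schedule. Unit-level checks use
scaled-down trials (10 fps, 120×120 px, baseline 2000 px²) — the dynamics
and detector settings are identical; only sampling density and image size
shrink.

## Known limitations

* The optics layer answers placement questions for a centred, on-axis eye;
  fixation error and eye movements are not modelled.
* The simulator's kinetics are a convenient parametric family, not a fitted
  physiological model; absolute PIPR values from real eyes need not match
  the presets, only the machinery that measures them is validated.
* The threshold detector assumes dark-pupil imaging with the pupil fully
  inside the frame; bright-pupil (coaxial IR) footage and pupils clipped by
  the ROI are out of scope.
* Video-container input requires an imageio backend able to decode it;
  directories of PNG/JPEG frames are the always-available path.
* No statistical testing across cohorts, no maximum-constriction latency or
  velocity metrics, and no net-PIPR variants are computed.
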