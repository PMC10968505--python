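# chromapupil

Chromatic pupillometry toolkit for melanopsin-targeted (perifoveal)
ring-light stimulation: optics design, synthetic ground-truth eye video,
dark-pupil detection, and PIPR-6s analysis.

## The problem

The pupil light reflex (PLR) to coloured stimuli separates the contributions
of cones/rods from those of melanopsin-bearing ipRGCs: after a **blue**
stimulus near the 482 nm melanopsin peak, healthy eyes keep the pupil partly
constricted for tens of seconds, while after a **red** stimulus the pupil
re-dilates quickly. The standard statistic is the post-illumination pupil
response 6 s after stimulus offset,

```
PIPR-6s = normalised pupil area at t_off + 6 s,
normalised area = 100 − (baseline − absolute)/baseline × 100   [% of baseline]
```

with the baseline the mean pupil area over the 10 s before stimulus onset.
The red − blue PIPR-6s difference is ≈ 10% in healthy eyes and shrinks in
glaucoma and other optic neuropathies, which makes it a candidate screening
statistic — provided it can be measured with cheap, portable hardware.

Because ipRGC density peaks in the perifovea (1.25–2.75 mm from the foveal
centre), a **ring-shaped** stimulus of the right angular size stimulates
them selectively. Under a reduced schematic eye (posterior nodal distance
PND = 16.67 mm), a source offset `x` at distance `d` lands at retinal
eccentricity `e = PND·x/d`; a 3 cm ring at 15 cm lands at 1.67 mm — inside
the band.

`chromapupil` implements the full software side of such a system: sizing the
ring (`optics`), generating seeded synthetic eye videos with exact ground
truth (`simulate`), per-frame dark-pupil detection with a pluggable fallback
chain (`detect`), and the normalisation/PIPR analysis with blink handling
and trial aggregation (`analysis`), tied together by a reproducible pipeline
and a thin CLI. It is aimed at researchers prototyping smartphone or
low-cost pupillometers who need every stage testable without human
recordings.

## Worked example

From `examples/detect_and_analyze.py` — render a synthetic blue-stimulus
trial, detect the pupil in every frame, and recover PIPR-6s:

```python
import chromapupil as cp

timing = cp.ProtocolTiming(frame_rate=10.0)          # 10 s base / 5 s stim / 25 s post
kinetics = cp.blue_preset(baseline_area_px2=2000.0)  # sustained melanopsin-like term
trace = cp.simulate_trace(kinetics, timing, noise_sd_pct=1.0, seed=3)
seq = cp.render_sequence(trace, cp.RenderConfig(
    image_size=(120, 120), iris_radius_px=40.0, ambient_tint="red",
    blink_schedule=((18.0, 0.3),), seed=3))

chain = [cp.AlwaysFailDetector(), cp.ThresholdDetector()]   # external-detector slot first
detections = cp.detect_sequence(seq.frames, timing.frame_rate, chain)
result = cp.process_trace(cp.build_trace(detections, timing))
print(result.pipr, cp.ground_truth_pipr(kinetics, timing))
```

Output:

```
397/400 frames with a valid fit
baseline pupil area : 1993 px^2
recovered PIPR-6s   : 89.43 % of baseline
ground truth        : 89.27 % (error +0.17 points)
```

The recovered PIPR-6s sits well below 100%: the sustained post-stimulus
constriction that marks ipRGC activation. The red preset, lacking the
sustained term, recovers ≈ 99.3%, and the blue/red preset pair is built so
its ground-truth difference is exactly 10.0 percentage points — which the
full simulate → render → detect → analyse chain recovers to within a few
tenths of a point (`examples/full_pipeline.py` prints the batch version
with per-colour means and sds).

Other examples: `design_ring_light.py` (ring sizing and the ambient-light
check), `simulate_trial.py` (ground-truth generation and rendering).

## Command line

```bash
chromapupil optics --ring-diameter 3 --distance 15      # band check + inverse design
chromapupil simulate --color blue --out trial/ --seed 1 # frames + ground truth CSV
chromapupil detect trial/ --fps 30 --out det.csv        # frames/video -> detections
chromapupil analyze det.csv --fps 30                    # PIPR from a detections CSV
chromapupil run --config run.yaml                       # end-to-end batch
chromapupil report rundir/                              # re-aggregate a run
```

Exit codes: 0 success, 1 configuration, 2 I/O, 3 analysis failure.

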