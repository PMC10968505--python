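"""End-to-end batch run: blue and red trials through one reproducible config.

Writes detections, normalised traces, a PIPR summary and a mean +/- sd PLR
plot into ``example_run/``; the same config and seed always reproduce the
same summary byte for byte.
"""

import json

from chromapupil.pipeline import RunConfig, SimulateSpec, run_pipeline
from chromapupil.simulate import ProtocolTiming

cfg = RunConfig(
    simulate=SimulateSpec(
        n_trials_per_color=2,
        noise_sd_pct=1.0,
        blinks_per_trial=1,
        render={"image_size": (120, 120), "iris_radius_px": 40.0},
        kinetics={"baseline_area_px2": 2000.0},
    ),
    protocol=ProtocolTiming(frame_rate=10.0),
    output_dir="example_run",
    seed=42,
    log_level="WARNING",
)

report = run_pipeline(cfg)
print(json.dumps(report["aggregate"], indent=2, sort_keys=True))
# difference_red_minus_blue near 10% reflects the generator's melanopsin-like
# sustained component in the blue trials; artifacts are in example_run/.
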