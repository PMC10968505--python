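"""Shared fixtures: synthetic frames and a small rendered trial.

All fixtures are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

import chromapupil as cp


def make_eye_frame(
    pupil_radius: float,
    size: int = 200,
    iris_radius: float = 80.0,
    pupil_level: int = 20,
    iris_level: int = 150,
    sclera_level: int = 220,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """A single synthetic eye frame: dark pupil disc in a brighter iris disc."""
    c = (size - 1) / 2.0
    yy, xx = np.ogrid[:size, :size]
    d2 = (yy - c) ** 2 + (xx - c) ** 2
    img = np.full((size, size), float(sclera_level))
    img[d2 <= iris_radius**2] = iris_level
    img[d2 <= pupil_radius**2] = pupil_level
    if noise_sd > 0:
        img += np.random.default_rng(seed).normal(0, noise_sd, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def disc_mask(radius: float, size: int = 200) -> np.ndarray:
    """Rasterised disc (pixel centres within radius) — the area oracle."""
    c = (size - 1) / 2.0
    yy, xx = np.ogrid[:size, :size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


@pytest.fixture(scope="session")
def small_timing() -> cp.ProtocolTiming:
    """Scaled-down protocol for rendered fixtures (10 fps, standard phases)."""
    return cp.ProtocolTiming(frame_rate=10.0)


@pytest.fixture(scope="session")
def rendered_trial(small_timing):
    """One rendered blue trial with a blink, shared across detection and
    analysis tests (small frames keep it cheap)."""
    kinetics = cp.blue_preset(baseline_area_px2=2000.0)  # radius ~25 px
    trace = cp.simulate_trace(kinetics, small_timing, noise_sd_pct=1.0, seed=11)
    rc = cp.RenderConfig(
        image_size=(120, 120),
        iris_radius_px=40.0,
        ambient_tint="red",
        blink_schedule=((4.0, 0.3), (20.0, 0.25)),
        seed=12,
    )
    return cp.render_sequence(trace, rc)


@pytest.fixture(scope="session")
def rendered_detections(rendered_trial, small_timing):
    """Detections table for the shared rendered trial."""
    return cp.detect_sequence(
        rendered_trial.frames, small_timing.frame_rate, [cp.ThresholdDetector()]
    )
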