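"""Synthetic pupil-light-reflex dynamics and rendered eye-frame sequences.

Every downstream stage (detection, trace building, normalisation, PIPR) is
validated against this generator, because chromatic-pupillometry recordings of
real eyes carry no per-frame ground truth.  The generator produces:

* a ground-truth normalised pupil-area curve from a small kinetic model,
* a noisy pupil-area time series sampled at the recording frame rate,
* rendered 8-bit eye frames (dark pupil inside a brighter iris, optional red
  ambient tint, scheduled eyelid blinks) with per-frame ground-truth masks.

The kinetic model is phenomenological.  Pupil area, as a percentage of its
pre-stimulus baseline, is

* 100 before stimulus onset plus a latency;
* an exponential approach to ``100 - A_c`` while the stimulus is on
  (constriction amplitude ``A_c`` % of baseline, time constant ``tau_c``);
* after stimulus offset, a two-exponential recovery

      100 - A_f * exp(-dt/tau_f) - A_s * exp(-dt/tau_s)

  with ``dt`` measured from offset.

The fast term (``A_f``, ``tau_f`` of a second or two) is the ordinary
re-dilation shared by all stimulus colours.  The sustained term (``A_s``,
``tau_s`` tens of seconds) models the melanopsin-driven ipRGC after-response:
blue stimuli near the 482 nm melanopsin peak leave a long-lasting extra
constriction that red stimuli do not.  The post-illumination pupil response
six seconds after offset (PIPR-6s) is simply this curve at ``dt = 6`` and is
monotonically decreasing in ``A_s`` — the blue/red contrast the method exists
to measure.

The curve is continuous at offset when the constriction has fully developed
and ``A_f + A_s = A_c``; with the default short ``tau_c`` relative to the 5 s
stimulus the residual mismatch is a fraction of a percent.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "ProtocolTiming",
    "PLRKinetics",
    "RenderConfig",
    "SimulatedTrace",
    "RenderedSequence",
    "blue_preset",
    "red_preset",
    "normalized_model",
    "ground_truth_pipr",
    "simulate_trace",
    "render_sequence",
    "write_sequence",
]


@dataclass(frozen=True)
class ProtocolTiming:
    """Acquisition schedule: dark-adapted baseline, stimulus, post-stimulus.

    Defaults follow the standard chromatic-pupillometry protocol used here:
    10 s of baseline recording, a 5 s ring-light stimulus, 25 s of continued
    recording after the LEDs switch off.
    """

    baseline_s: float = 10.0
    stimulus_s: float = 5.0
    post_s: float = 25.0
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        for name in ("baseline_s", "stimulus_s", "post_s", "frame_rate"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    @property
    def onset_s(self) -> float:
        """Stimulus onset time (end of baseline window)."""
        return self.baseline_s

    @property
    def offset_s(self) -> float:
        """Stimulus offset time; post-illumination delays count from here."""
        return self.baseline_s + self.stimulus_s

    @property
    def total_s(self) -> float:
        return self.baseline_s + self.stimulus_s + self.post_s

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate * self.total_s))

    def times(self) -> np.ndarray:
        """Frame timestamps in seconds, frame k at k / frame_rate."""
        return np.arange(self.n_frames) / self.frame_rate


@dataclass(frozen=True)
class PLRKinetics:
    """Parameters of the piecewise pupil-area model (amplitudes in % baseline)."""

    baseline_area_px2: float = 7000.0
    latency_s: float = 0.25
    constriction_amplitude: float = 40.0
    constriction_tau_s: float = 0.8
    fast_recovery_amplitude: float = 40.0
    fast_tau_s: float = 1.5
    sustained_amplitude: float = 0.0
    sustained_tau_s: float = 30.0

    def __post_init__(self) -> None:
        if self.baseline_area_px2 <= 0:
            raise ConfigurationError("baseline_area_px2 must be positive")
        for name in ("constriction_tau_s", "fast_tau_s", "sustained_tau_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.latency_s < 0:
            raise ConfigurationError("latency_s must be non-negative")
        if not 0.0 <= self.constriction_amplitude <= 100.0:
            raise ConfigurationError("constriction_amplitude must lie in [0, 100]")
        if self.fast_recovery_amplitude < 0 or self.sustained_amplitude < 0:
            raise ConfigurationError("recovery amplitudes must be non-negative")
        if (
            self.fast_recovery_amplitude + self.sustained_amplitude
            > self.constriction_amplitude + 1e-12
        ):
            raise ConfigurationError(
                "fast + sustained recovery amplitudes must not exceed the "
                "constriction amplitude"
            )


#: Sustained amplitude of the blue preset.  With tau_s = 30 s the ground-truth
#: PIPR-6s deficit it adds is A_s * exp(-6/30) = 10.0 % exactly, so the
#: blue/red preset pair has a ground-truth PIPR-6s difference of 10.0 %.
BLUE_SUSTAINED_AMPLITUDE = 10.0 * math.exp(6.0 / 30.0)


def red_preset(**overrides) -> PLRKinetics:
    """Red-stimulus kinetics: full fast re-dilation, no sustained component."""
    params = dict(
        constriction_amplitude=40.0,
        fast_recovery_amplitude=40.0,
        sustained_amplitude=0.0,
    )
    params.update(overrides)
    return PLRKinetics(**params)


def blue_preset(**overrides) -> PLRKinetics:
    """Blue-stimulus kinetics: deeper constriction plus a sustained
    melanopsin-like component that lowers PIPR-6s by 10 % relative to red."""
    params = dict(
        constriction_amplitude=55.0,
        fast_recovery_amplitude=40.0,
        sustained_amplitude=BLUE_SUSTAINED_AMPLITUDE,
    )
    params.update(overrides)
    return PLRKinetics(**params)


def normalized_model(
    t: float | np.ndarray,
    kinetics: PLRKinetics,
    timing: ProtocolTiming,
) -> float | np.ndarray:
    """Ground-truth normalised pupil area (% of baseline) at time ``t``.

    ``t`` may be a scalar or array; every element must lie in
    ``[0, timing.total_s]``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > timing.total_s + 1e-12):
        raise ValueError("t outside the recorded interval [0, total_s]")

    k = kinetics
    start = timing.onset_s + k.latency_s
    out = np.full_like(t_arr, 100.0)

    during = (t_arr >= start) & (t_arr < timing.offset_s)
    dt_on = t_arr[during] - start
    out[during] = 100.0 - k.constriction_amplitude * (
        1.0 - np.exp(-dt_on / k.constriction_tau_s)
    )

    after = t_arr >= timing.offset_s
    dt_off = t_arr[after] - timing.offset_s
    out[after] = (
        100.0
        - k.fast_recovery_amplitude * np.exp(-dt_off / k.fast_tau_s)
        - k.sustained_amplitude * np.exp(-dt_off / k.sustained_tau_s)
    )
    out = np.clip(out, 0.0, 100.0)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def ground_truth_pipr(
    kinetics: PLRKinetics,
    timing: ProtocolTiming | None = None,
    delay_s: float = 6.0,
) -> float:
    """Ground-truth PIPR (% of baseline) ``delay_s`` after stimulus offset."""
    if delay_s < 0:
        raise ValueError("delay_s must be non-negative")
    timing = ProtocolTiming() if timing is None else timing
    return float(normalized_model(timing.offset_s + delay_s, kinetics, timing))


@dataclass(frozen=True)
class SimulatedTrace:
    """Sampled ground truth: times, true %, noisy areas, validity flags."""

    times_s: np.ndarray
    true_pct: np.ndarray
    area_px2: np.ndarray
    valid: np.ndarray
    kinetics: PLRKinetics
    timing: ProtocolTiming
    noise_sd_pct: float
    seed: int


def simulate_trace(
    kinetics: PLRKinetics,
    timing: ProtocolTiming | None = None,
    noise_sd_pct: float = 1.0,
    seed: int = 0,
) -> SimulatedTrace:
    """Sample the kinetic model at the frame rate and add area noise.

    Noise is i.i.d. Gaussian on the normalised (%) scale, mapped to area via
    ``area = baseline * (true_pct + eps) / 100`` — so the noisy area series
    divided by the baseline recovers ``true_pct + eps`` exactly.  Identical
    seeds give identical output.
    """
    timing = ProtocolTiming() if timing is None else timing
    if timing.n_frames < 2:
        raise ConfigurationError("need at least two samples (frame_rate * total)")
    times = timing.times()
    true_pct = normalized_model(times, kinetics, timing)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd_pct, size=times.shape) if noise_sd_pct > 0 else 0.0
    area = kinetics.baseline_area_px2 * (true_pct + eps) / 100.0
    return SimulatedTrace(
        times_s=times,
        true_pct=true_pct,
        area_px2=area,
        valid=np.ones(times.shape, dtype=bool),
        kinetics=kinetics,
        timing=timing,
        noise_sd_pct=noise_sd_pct,
        seed=seed,
    )


@dataclass(frozen=True)
class RenderConfig:
    """How eye frames are drawn.

    A dark pupil disc sits centred in a brighter iris disc on a sclera-level
    background; blinks are eyelid occlusions (a skin-level band covering the
    iris), so the detector — not the generator — must discover them.
    ``ambient_tint="red"`` emits RGB frames with the red channel carrying the
    full signal, emulating recording under red ambient light.
    """

    image_size: tuple[int, int] = (200, 200)
    iris_radius_px: float = 80.0
    iris_gray_level: int = 150
    pupil_gray_level: int = 20
    sclera_gray_level: int = 220
    eyelid_gray_level: int = 180
    ambient_tint: str = "none"
    pixel_noise_sd: float = 2.0
    blink_schedule: tuple[tuple[float, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pupil_gray_level >= self.iris_gray_level:
            raise ConfigurationError("pupil must be darker than iris")
        if self.ambient_tint not in ("none", "red"):
            raise ConfigurationError("ambient_tint must be 'none' or 'red'")
        if self.iris_radius_px <= 0:
            raise ConfigurationError("iris_radius_px must be positive")
        for start, dur in self.blink_schedule:
            if dur <= 0 or start < 0:
                raise ConfigurationError("blink intervals must be positive-length")


@dataclass(frozen=True)
class RenderedSequence:
    """Frames plus per-frame ground truth from the same schedule."""

    frames: np.ndarray  # (n, h, w) uint8 or (n, h, w, 3) uint8
    masks: np.ndarray  # (n, h, w) bool ground-truth pupil masks
    valid: np.ndarray  # (n,) bool; False on blink frames
    trace: SimulatedTrace
    config: RenderConfig

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _blink_flags(times: np.ndarray, schedule, total_s: float) -> np.ndarray:
    blink = np.zeros(times.shape, dtype=bool)
    for start, dur in schedule:
        if start + dur > total_s + 1e-9:
            raise ConfigurationError(
                f"blink ({start}, {dur}) extends past the protocol duration"
            )
        blink |= (times >= start) & (times < start + dur)
    return blink


def render_sequence(trace: SimulatedTrace, config: RenderConfig) -> RenderedSequence:
    """Rasterise a simulated trace into an 8-bit eye-frame sequence.

    For non-blink frames the ground-truth mask is the rasterised pupil disc
    (pixel centres within the scheduled radius), whose pixel count matches
    the scheduled area to within a one-pixel perimeter band.  Blink frames
    carry an empty mask and ``valid=False``.
    """
    h, w = config.image_size
    radii = np.sqrt(np.asarray(trace.area_px2) / math.pi)
    if np.max(radii) >= config.iris_radius_px:
        raise ConfigurationError(
            f"scheduled pupil radius {np.max(radii):.1f} px does not fit inside "
            f"the iris radius {config.iris_radius_px} px"
        )

    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.ogrid[:h, :w]
    dist2 = (yy - cy) ** 2 + (xx - cx) ** 2
    iris_mask = dist2 <= config.iris_radius_px**2
    blink = _blink_flags(trace.times_s, config.blink_schedule, trace.timing.total_s)
    eyelid_rows = min(h, int(math.ceil(cy + config.iris_radius_px + 2)))

    n = trace.times_s.shape[0]
    rng = np.random.default_rng(config.seed)
    frames = np.empty((n, h, w), dtype=np.uint8)
    masks = np.zeros((n, h, w), dtype=bool)

    base = np.full((h, w), float(config.sclera_gray_level))
    base[iris_mask] = config.iris_gray_level

    for i in range(n):
        img = base.copy()
        if blink[i]:
            img[:eyelid_rows, :] = config.eyelid_gray_level
        else:
            pupil = dist2 <= radii[i] ** 2
            img[pupil] = config.pupil_gray_level
            masks[i] = pupil
        if config.pixel_noise_sd > 0:
            img += rng.normal(0.0, config.pixel_noise_sd, size=img.shape)
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)

    if config.ambient_tint == "red":
        rgb = np.empty((n, h, w, 3), dtype=np.uint8)
        rgb[..., 0] = frames
        rgb[..., 1] = (frames * 0.45).astype(np.uint8)
        rgb[..., 2] = (frames * 0.40).astype(np.uint8)
        frames = rgb

    return RenderedSequence(
        frames=frames,
        masks=masks,
        valid=~blink,
        trace=trace,
        config=config,
    )


def write_sequence(seq: RenderedSequence, out_dir: str | Path) -> Path:
    """Write a rendered sequence as numbered PNGs + ground-truth CSV + sidecar.

    Layout: ``frame_000000.png`` ..., ``ground_truth.csv`` (time_s, true_pct,
    area_px2, valid) and ``params.json`` recording every generator parameter
    and seed, so a simulated trial is reproducible from its directory alone.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i in range(seq.n_frames):
        iio.imwrite(out / f"frame_{i:06d}.png", seq.frames[i])

    import pandas as pd

    t = seq.trace
    pd.DataFrame(
        {
            "time_s": t.times_s,
            "true_pct": t.true_pct,
            "area_px2": t.area_px2,
            "valid": seq.valid.astype(int),
        }
    ).to_csv(out / "ground_truth.csv", index=False)

    sidecar = {
        "kinetics": asdict(t.kinetics),
        "timing": asdict(t.timing),
        "noise_sd_pct": t.noise_sd_pct,
        "trace_seed": t.seed,
        "render": {**asdict(seq.config), "blink_schedule": list(
            map(list, seq.config.blink_schedule)
        )},
        "note": "simulator defaults are conventions; real recordings' "
        "per-frame noise statistics are not characterised",
    }
    (out / "params.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return out
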