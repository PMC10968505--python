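"""End-to-end orchestration: simulate/load -> detect -> analyse -> report.

A run is described by a single :class:`RunConfig` (YAML-loadable, CLI-flag
overridable) with exactly one input source:

* ``simulate`` — generate trials for the blue and red presets, render frames,
  and push them through detection and analysis (the self-validation path);
* ``frames`` / ``video`` — one recorded trial;
* ``manifest`` — a CSV listing trials (subject, color, intensity, trial,
  path), e.g. built from a ``<subject>/<color>_<intensity>/<trial_k>/``
  directory tree.

Outputs land in the run directory: per-trial detections and normalised-trace
CSVs, a PIPR summary (JSON + CSV), a mean+/-sd PLR plot with the stimulus
interval shaded, and a manifest recording the config hash, seed and library
versions.  Identical config and seed give a byte-identical PIPR JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as cpio
from .analysis import (
    AnalysisConfig,
    PIPRMetrics,
    aggregate,
    aggregate_pipr,
    build_trace,
    pipr_difference,
    process_trace,
)
from .detect import DetectorConfig, ThresholdDetector, detect_sequence
from .errors import AnalysisError, ConfigurationError
from .simulate import (
    ProtocolTiming,
    RenderConfig,
    blue_preset,
    ground_truth_pipr,
    red_preset,
    render_sequence,
    simulate_trace,
)

__all__ = ["RunConfig", "SimulateSpec", "run_pipeline", "load_run_config", "plot_curves"]

log = logging.getLogger("chromapupil")


@dataclass(frozen=True)
class SimulateSpec:
    """What to simulate when the input source is the generator."""

    n_trials_per_color: int = 3
    noise_sd_pct: float = 1.0
    blinks_per_trial: int = 2
    colors: tuple[str, ...] = ("blue", "red")
    intensity: str = "14%"
    render: dict = field(default_factory=dict)
    kinetics: dict = field(default_factory=dict)  # overrides applied to both presets


@dataclass(frozen=True)
class RunConfig:
    """Full description of a pipeline run (exactly one input source)."""

    simulate: SimulateSpec | None = None
    frames: str | None = None
    video: str | None = None
    manifest: str | None = None
    protocol: ProtocolTiming = field(default_factory=ProtocolTiming)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output_dir: str = "chromapupil_run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        sources = [
            s for s in (self.simulate, self.frames, self.video, self.manifest) if s
        ]
        if len(sources) != 1:
            raise ConfigurationError(
                "exactly one input source (simulate | frames | video | manifest) "
                "must be configured"
            )


def load_run_config(path: str | Path, **overrides: Any) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file plus keyword overrides."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return _config_from_dict(raw)


def _config_from_dict(raw: dict) -> RunConfig:
    kwargs: dict[str, Any] = {}
    inp = raw.get("input", raw)
    if "simulate" in inp and inp["simulate"] is not None:
        sim = inp["simulate"] if isinstance(inp["simulate"], dict) else {}
        sim = {**sim}
        if "colors" in sim:
            sim["colors"] = tuple(sim["colors"])
        kwargs["simulate"] = SimulateSpec(**sim)
    for key in ("frames", "video", "manifest"):
        if inp.get(key):
            kwargs[key] = str(inp[key])
    if "protocol" in raw:
        kwargs["protocol"] = ProtocolTiming(**raw["protocol"])
    if "detector" in raw:
        det = {**raw["detector"]}
        if det.get("roi") is not None:
            det["roi"] = tuple(det["roi"])
        kwargs["detector"] = DetectorConfig(**det)
    if "analysis" in raw:
        kwargs["analysis"] = AnalysisConfig(**raw["analysis"])
    for key in ("output_dir", "seed", "log_level"):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)


def _config_hash(cfg: RunConfig) -> str:
    """Hash of the scientific configuration (paths and logging excluded)."""
    payload = dataclasses.asdict(cfg)
    payload.pop("output_dir", None)
    payload.pop("log_level", None)
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _blink_schedule(rng: np.random.Generator, n: int, timing: ProtocolTiming):
    """Random eyelid blinks, kept clear of the record's very ends."""
    if n <= 0:
        return ()
    starts = np.sort(rng.uniform(1.0, timing.total_s - 2.0, size=n))
    durations = rng.uniform(0.15, 0.30, size=n)
    return tuple((float(s), float(d)) for s, d in zip(starts, durations))


def _simulated_trials(cfg: RunConfig):
    """Yield (trial_meta, frames) for every simulated trial."""
    spec = cfg.simulate
    presets = {"blue": blue_preset, "red": red_preset}
    for color_idx, color in enumerate(spec.colors):
        for k in range(spec.n_trials_per_color):
            child = np.random.SeedSequence(
                entropy=cfg.seed, spawn_key=(color_idx, k)
            )
            trace_seed, render_seed, blink_seed = (
                int(s) % (2**31) for s in child.generate_state(3)
            )
            kinetics = presets[color](**spec.kinetics)
            trace = simulate_trace(
                kinetics, cfg.protocol, spec.noise_sd_pct, seed=trace_seed
            )
            blink_rng = np.random.default_rng(blink_seed)
            render_kwargs = dict(spec.render)
            render_kwargs.setdefault("ambient_tint", "red")
            rc = RenderConfig(
                blink_schedule=_blink_schedule(
                    blink_rng, spec.blinks_per_trial, cfg.protocol
                ),
                seed=render_seed,
                **render_kwargs,
            )
            seq = render_sequence(trace, rc)
            meta = {
                "subject": "sim",
                "color": color,
                "intensity": spec.intensity,
                "trial": k + 1,
                "ground_truth_pipr": ground_truth_pipr(
                    kinetics, cfg.protocol, cfg.analysis.pipr_delay_s
                ),
            }
            yield meta, seq.frames


def _input_trials(cfg: RunConfig):
    if cfg.simulate is not None:
        yield from _simulated_trials(cfg)
        return
    if cfg.manifest is not None:
        mpath = Path(cfg.manifest)
        if not mpath.is_file():
            raise IOError(f"manifest not found: {mpath}")
        man = pd.read_csv(mpath)
        for _, row in man.iterrows():
            meta = {
                "subject": str(row.get("subject", "unknown")),
                "color": str(row.get("color", "unknown")),
                "intensity": str(row.get("intensity", "unknown")),
                "trial": int(row.get("trial", 1)),
                "ground_truth_pipr": None,
            }
            yield meta, list(cpio.iter_frames(row["path"]))
        return
    path = cfg.frames or cfg.video
    meta = {
        "subject": "unknown",
        "color": "unknown",
        "intensity": "unknown",
        "trial": 1,
        "ground_truth_pipr": None,
    }
    yield meta, list(cpio.iter_frames(path))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute a configured run; returns the report also written to disk.

    Per-trial analysis errors are recorded in the trial's record (status
    "error") without aborting the batch.  The report contains one record per
    trial plus one aggregate record.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info(
        "protocol: baseline=%.1fs stimulus=%.1fs post=%.1fs fps=%.1f",
        cfg.protocol.baseline_s,
        cfg.protocol.stimulus_s,
        cfg.protocol.post_s,
        cfg.protocol.frame_rate,
    )
    chain = [ThresholdDetector(cfg.detector)]
    log.info("detector chain: %s", [getattr(d, "method", "?") for d in chain])

    trial_records = []
    by_color: dict[str, list[float]] = {}
    curves: dict[str, list] = {}
    for meta, frames in _input_trials(cfg):
        trial_id = f"{meta['subject']}_{meta['color']}_{meta['intensity']}_t{meta['trial']}"
        record = dict(meta)
        try:
            detections = detect_sequence(frames, cfg.protocol.frame_rate, chain)
            detections.to_csv(out / f"detections_{trial_id}.csv", index=False)
            trace = build_trace(detections, cfg.protocol)
            processed = process_trace(trace, cfg.analysis)
            nt = processed.normalized
            pd.DataFrame(
                {
                    "time_s": nt.times_s,
                    "normalized_pct": nt.normalized_pct,
                    "smoothed_pct": processed.smoothed_pct,
                    "valid": nt.valid.astype(int),
                }
            ).to_csv(out / f"normalized_{trial_id}.csv", index=False)
            record.update(
                status="ok",
                pipr=round(processed.pipr, 6),
                baseline_px2=round(processed.baseline_px2, 3),
                valid_fraction=round(processed.valid_fraction, 4),
            )
            by_color.setdefault(meta["color"], []).append(processed.pipr)
            curves.setdefault(meta["color"], []).append(nt)
            log.info(
                "trial %s: pipr=%.2f%% valid_fraction=%.3f",
                trial_id,
                processed.pipr,
                processed.valid_fraction,
            )
        except AnalysisError as exc:
            record.update(status="error", error=str(exc))
            log.warning("trial %s failed: %s", trial_id, exc)
        trial_records.append(record)

    aggregate_record: dict[str, Any] = {"n_trials": len(trial_records)}
    for color, values in by_color.items():
        mean, sd = aggregate_pipr(values)
        aggregate_record[f"pipr_{color}_mean"] = round(mean, 6)
        aggregate_record[f"pipr_{color}_sd"] = round(sd, 6)
    if "blue" in by_color and "red" in by_color:
        metrics = PIPRMetrics(
            pipr_blue=aggregate_record["pipr_blue_mean"],
            pipr_red=aggregate_record["pipr_red_mean"],
            difference=pipr_difference(
                aggregate_record["pipr_red_mean"], aggregate_record["pipr_blue_mean"]
            ),
            delay_s=cfg.analysis.pipr_delay_s,
            window_halfwidth_s=cfg.analysis.window_halfwidth_s,
            n_trials=min(len(by_color["blue"]), len(by_color["red"])),
            dispersion_blue=aggregate_record["pipr_blue_sd"],
            dispersion_red=aggregate_record["pipr_red_sd"],
        )
        aggregate_record["difference_red_minus_blue"] = round(metrics.difference, 6)

    report = {
        "trials": trial_records,
        "aggregate": aggregate_record,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
    }
    (out / "pipr_summary.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    pd.DataFrame(trial_records).to_csv(out / "pipr_summary.csv", index=False)

    import chromapupil

    manifest = {
        "config_hash": report["config_hash"],
        "seed": cfg.seed,
        "versions": {"chromapupil": chromapupil.__version__, "numpy": np.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    if curves:
        plot_curves(curves, cfg.protocol, out / "plr_curves.png")
    return report


def plot_curves(
    curves: dict[str, list], timing: ProtocolTiming, path: str | Path
) -> Path:
    """Mean +/- sd PLR curves per colour with the stimulus interval shaded."""
    from matplotlib.figure import Figure

    grid = np.arange(0.0, timing.total_s, 1.0 / timing.frame_rate)
    fig = Figure(figsize=(7, 4))
    ax = fig.add_subplot(111)
    palette = {"blue": "tab:blue", "red": "tab:red"}
    for color, traces in sorted(curves.items()):
        mean, sd = aggregate(traces, grid)
        c = palette.get(color, "tab:gray")
        ax.plot(grid, mean, color=c, label=f"{color} (n={len(traces)})")
        ax.fill_between(grid, mean - sd, mean + sd, color=c, alpha=0.2)
    ax.axvspan(timing.onset_s, timing.offset_s, color="gray", alpha=0.25)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("pupil area (% of baseline)")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    return Path(path)


def report_from_outputs(run_dir: str | Path) -> dict:
    """Re-aggregate an existing run directory's per-trial PIPR records."""
    p = Path(run_dir) / "pipr_summary.json"
    if not p.is_file():
        raise IOError(f"no pipr_summary.json in {run_dir}")
    report = json.loads(p.read_text())
    by_color: dict[str, list[float]] = {}
    for rec in report["trials"]:
        if rec.get("status") == "ok":
            by_color.setdefault(rec["color"], []).append(rec["pipr"])
    agg: dict[str, Any] = {"n_trials": len(report["trials"])}
    for color, values in by_color.items():
        mean, sd = aggregate_pipr(values)
        agg[f"pipr_{color}_mean"] = round(mean, 6)
        agg[f"pipr_{color}_sd"] = round(sd, 6)
    if "blue" in by_color and "red" in by_color:
        agg["difference_red_minus_blue"] = round(
            agg["pipr_red_mean"] - agg["pipr_blue_mean"], 6
        )
    report["aggregate"] = agg
    return report
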