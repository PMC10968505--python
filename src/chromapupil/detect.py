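"""Per-frame dark-pupil detection.

Under the red ambient light used for smartphone recording the pupil appears
as the darkest, roundest blob in the eye region, so a classical pipeline
suffices: grayscale conversion, optional crop and Gaussian smoothing,
low-intensity thresholding, morphological cleanup, connected-component
selection by area and circularity, and a second-moment ellipse fit.

Detectors are interchangeable: anything callable as
``detector(frame, frame_index, timestamp) -> PupilFit`` can join the fallback
chain, which returns the first valid fit in priority order.  This is the slot
where an external detector (such as PuRe) plugs in ahead of the threshold
detector; the package itself ships the threshold detector and an always-fail
stub used to exercise the fallback contract.

Coordinates are pixels with the origin at the top-left, x rightward and
y downward; areas are px^2 (absolute scale is normalised away downstream).

The Otsu mode descends recursively into the dark class: eye frames are often
tri-modal (pupil / iris / sclera-skin) and the strongest histogram valley can
be the iris-sclera one, which would segment the whole iris.  Otsu is re-run
inside the dark class for as long as the valley it finds there is stronger
(larger class-mean separation) than the current dark/bright separation, so
the threshold settles into the deepest dark mode — the pupil.  The descent is
parameter-free and invariant to gray-level shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk

from .errors import ConfigurationError

__all__ = [
    "DetectorConfig",
    "GrayFrame",
    "PupilFit",
    "ThresholdDetector",
    "AlwaysFailDetector",
    "preprocess",
    "threshold_segment",
    "select_pupil_component",
    "fit_ellipse",
    "detect_pupil",
    "detect_sequence",
]

DETECTION_COLUMNS = [
    "frame_index",
    "time_s",
    "cx",
    "cy",
    "a",
    "b",
    "orientation",
    "area_px2",
    "method",
    "valid",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Parameters of the threshold pupil detector.

    roi:
        Optional crop ``(x, y, width, height)`` in full-frame pixels.
    smoothing_kernel_px:
        Gaussian smoothing kernel size; the Gaussian sigma is kernel/4.
    threshold_mode / threshold_value:
        ``otsu`` (value ignored), ``percentile`` (value = percentile of the
        intensity histogram) or ``fixed`` (value = gray level).
    min_area_px2 / max_area_px2:
        Acceptable pupil-component area range.
    min_circularity:
        Minimum 4*pi*A/P^2 of the accepted component.
    morph_radius_px:
        Disc radius of the binary opening/closing that removes speckle and
        fills pinholes in the pupil mask.
    gray_mode:
        ``luma`` (ITU-R 601 weights) or ``red`` (red channel only; useful
        for strongly red-lit frames).
    min_contrast:
        Minimum mean gray-level difference between the pixels outside and
        inside the candidate mask.  A genuine dark pupil against the iris
        scores far above this; masks carved out of noise (e.g. on an
        eyelid-occluded blink frame) score near zero and are rejected.
    """

    roi: tuple[int, int, int, int] | None = None
    smoothing_kernel_px: float = 5.0
    threshold_mode: str = "otsu"
    threshold_value: float | None = None
    min_area_px2: float = 200.0
    max_area_px2: float = 50000.0
    min_circularity: float = 0.6
    morph_radius_px: int = 3
    gray_mode: str = "luma"
    min_contrast: float = 20.0

    def __post_init__(self) -> None:
        if self.min_area_px2 >= self.max_area_px2:
            raise ConfigurationError("min_area_px2 must be < max_area_px2")
        if not 0.0 < self.min_circularity <= 1.0:
            raise ConfigurationError("min_circularity must lie in (0, 1]")
        if self.threshold_mode not in ("otsu", "percentile", "fixed"):
            raise ConfigurationError("unknown threshold_mode")
        if self.threshold_mode in ("percentile", "fixed") and self.threshold_value is None:
            raise ConfigurationError(
                f"threshold_mode={self.threshold_mode!r} requires threshold_value"
            )
        if self.gray_mode not in ("luma", "red"):
            raise ConfigurationError("gray_mode must be 'luma' or 'red'")
        if self.smoothing_kernel_px < 0 or self.morph_radius_px < 0:
            raise ConfigurationError("kernel and morph radius must be non-negative")


@dataclass(frozen=True)
class GrayFrame:
    """A preprocessed grayscale frame with its position in the sequence."""

    pixels: np.ndarray  # float32, grayscale, cropped and smoothed
    frame_index: int = 0
    timestamp_s: float = 0.0
    roi_offset: tuple[int, int] = (0, 0)  # (x, y) of the crop origin


@dataclass(frozen=True)
class PupilFit:
    """One frame's detected pupil: ellipse, area, quality, provenance.

    ``area_px2 = pi * a * b`` holds for valid fits; invalid fits carry NaN
    geometry and make no geometric claims.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation: float
    area_px2: float
    circularity: float
    method: str
    valid: bool

    @classmethod
    def invalid(cls, method: str = "none") -> "PupilFit":
        nan = float("nan")
        return cls(
            center=(nan, nan),
            semi_axes=(nan, nan),
            orientation=nan,
            area_px2=nan,
            circularity=nan,
            method=method,
            valid=False,
        )


def _to_gray(frame: np.ndarray, mode: str) -> np.ndarray:
    if frame.ndim == 2:
        return frame.astype(np.float32)
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        rgb = frame[..., :3].astype(np.float32)
        if mode == "red":
            return rgb[..., 0]
        return rgb @ np.array([0.299, 0.587, 0.114], dtype=np.float32)
    raise ConfigurationError(f"unsupported frame shape {frame.shape}")


def preprocess(
    frame: np.ndarray,
    cfg: DetectorConfig,
    frame_index: int = 0,
    timestamp_s: float = 0.0,
) -> GrayFrame:
    """Grayscale conversion, ROI crop and Gaussian smoothing."""
    if frame.size == 0:
        raise ConfigurationError("empty frame")
    gray = _to_gray(frame, cfg.gray_mode)
    offset = (0, 0)
    if cfg.roi is not None:
        x, y, w, h = cfg.roi
        if x < 0 or y < 0 or w <= 0 or h <= 0 or x + w > gray.shape[1] or y + h > gray.shape[0]:
            raise ConfigurationError(f"roi {cfg.roi} outside frame bounds {gray.shape}")
        gray = gray[y : y + h, x : x + w]
        offset = (x, y)
    if cfg.smoothing_kernel_px > 0:
        gray = ndimage.gaussian_filter(
            gray, sigma=cfg.smoothing_kernel_px / 4.0, mode="nearest"
        )
    return GrayFrame(
        pixels=gray, frame_index=frame_index, timestamp_s=timestamp_s, roi_offset=offset
    )


def _compute_threshold(values: np.ndarray, cfg: DetectorConfig) -> float | None:
    """Threshold below-or-equal which pixels count as pupil; None = empty mask."""
    if cfg.threshold_mode == "fixed":
        return float(cfg.threshold_value)
    if cfg.threshold_mode == "percentile":
        return float(np.percentile(values, cfg.threshold_value))
    # Otsu: a single-level (degenerate) histogram has no valley.
    if np.ptp(values) == 0:
        return None
    thr = float(threshold_otsu(values))
    # Descend into the dark class while the valley inside it is stronger
    # than the current dark/bright separation (see module docstring).
    for _ in range(4):
        dark = values <= thr
        if not dark.any() or dark.all():
            break
        dark_vals = values[dark]
        if np.ptp(dark_vals) == 0:
            break
        outer_sep = float(values[~dark].mean()) - float(dark_vals.mean())
        sub = float(threshold_otsu(dark_vals))
        lo, hi = dark_vals[dark_vals <= sub], dark_vals[dark_vals > sub]
        if lo.size == 0 or hi.size == 0:
            break
        if float(hi.mean()) - float(lo.mean()) <= outer_sep:
            break
        thr = sub
    return _refine_to_edge_midlevel(values, thr)


def _refine_to_edge_midlevel(values: np.ndarray, thr: float) -> float:
    """Snap an Otsu threshold to the pupil/surround mid-level.

    Otsu places its cut anywhere inside the blurred pupil edge, which biases
    the segmented radius by a fraction of the smoothing width.  The unbiased
    cut is the mid-level between the dark interior and its immediate
    surround (where a symmetric blur crosses half-way exactly at the
    geometric boundary), estimated from medians of the eroded mask interior
    and of a thin ring just outside the mask.  Shift-equivariant.
    """
    mask = values <= thr
    if not mask.any() or mask.all():
        return thr
    interior = ndimage.binary_erosion(mask, iterations=2)
    ring = ndimage.binary_dilation(mask, iterations=4) & ~mask
    if interior.any() and ring.any():
        thr = 0.5 * (
            float(np.median(values[interior])) + float(np.median(values[ring]))
        )
    return thr


def threshold_segment(gray: GrayFrame, cfg: DetectorConfig) -> np.ndarray:
    """Binary pupil-candidate mask: dark pixels, morphologically cleaned.

    Whether a component is genuinely darker than its surround (the
    dark-pupil criterion) is judged per component at selection time; see
    :func:`component_contrast`.
    """
    values = gray.pixels
    thr = _compute_threshold(values, cfg)
    if thr is None:
        return np.zeros(values.shape, dtype=bool)
    mask = values <= thr
    if cfg.morph_radius_px > 0 and mask.any():
        footprint = disk(cfg.morph_radius_px)
        mask = ndimage.binary_opening(mask, structure=footprint)
        mask = ndimage.binary_closing(mask, structure=footprint)
    return mask


def _circularity(prop) -> float:
    perim = prop.perimeter
    if perim <= 0:
        return 0.0
    return 4.0 * math.pi * prop.area / (perim * perim)


def component_contrast(prop, values: np.ndarray) -> float:
    """Median gray-level step from a component to its immediate surround.

    A real dark pupil sits ~100 levels below the surrounding iris; a blob
    carved out of noise (e.g. on an eyelid-occluded blink frame) sits at the
    level of its surround.  The ring is a 3-pixel dilation of the component.
    """
    comp_mask = np.zeros(values.shape, dtype=bool)
    comp_mask[prop.coords[:, 0], prop.coords[:, 1]] = True
    ring = ndimage.binary_dilation(comp_mask, iterations=3) & ~comp_mask
    if not ring.any():
        return 0.0
    return float(np.median(values[ring])) - float(np.median(values[comp_mask]))


def select_pupil_component(
    mask: np.ndarray, cfg: DetectorConfig, values: np.ndarray | None = None
):
    """Most circular connected component within the area bounds, or None.

    Circularity is 4*pi*A/P^2 with the perimeter measured on the component
    contour; a disc scores near 1, elongated artefacts (eyelashes, shadows)
    score near 0.  Components touching the image border are rejected — a
    pupil sits inside the eye region, whereas eyelid occlusions and shadow
    bands run off the frame edge.  When the grayscale ``values`` are
    supplied, components failing the dark-pupil contrast criterion
    (:func:`component_contrast` below ``cfg.min_contrast``) are skipped.
    Absence of a plausible pupil is a value, not an error.
    """
    if not mask.any():
        return None
    labelled = label(mask)
    h, w = mask.shape
    best, best_circ = None, -1.0
    for prop in regionprops(labelled):
        if not cfg.min_area_px2 <= prop.area <= cfg.max_area_px2:
            continue
        r0, c0, r1, c1 = prop.bbox
        if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
            continue
        circ = _circularity(prop)
        if circ < cfg.min_circularity or circ <= best_circ:
            continue
        if values is not None and component_contrast(prop, values) < cfg.min_contrast:
            continue
        best, best_circ = prop, circ
    return best


def fit_ellipse(component, method: str = "threshold") -> PupilFit:
    """Second-moment ellipse of a component's pixel set.

    The centroid gives the centre; the semi-axes are twice the square roots
    of the eigenvalues of the pixel-coordinate covariance (exact for a
    uniformly filled ellipse), so ``area = pi*a*b`` recovers the filled area.
    Components of fewer than five pixels cannot constrain an ellipse and
    yield an invalid fit.
    """
    coords = component.coords  # (row, col)
    if coords.shape[0] < 5:
        return PupilFit.invalid(method=method)
    y = coords[:, 0].astype(float)
    x = coords[:, 1].astype(float)
    cx, cy = float(x.mean()), float(y.mean())
    dx, dy = x - cx, y - cy
    mxx = float(np.mean(dx * dx))
    myy = float(np.mean(dy * dy))
    mxy = float(np.mean(dx * dy))
    common = math.hypot(mxx - myy, 2.0 * mxy)
    l1 = (mxx + myy + common) / 2.0
    l2 = (mxx + myy - common) / 2.0
    if l2 <= 0:
        return PupilFit.invalid(method=method)
    a, b = 2.0 * math.sqrt(l1), 2.0 * math.sqrt(l2)
    orientation = 0.5 * math.atan2(2.0 * mxy, mxx - myy)
    return PupilFit(
        center=(cx, cy),
        semi_axes=(a, b),
        orientation=orientation,
        area_px2=math.pi * a * b,
        circularity=_circularity(component),
        method=method,
        valid=True,
    )


class PupilDetector(Protocol):
    """Per-frame detector contract: frame in, :class:`PupilFit` out."""

    def __call__(
        self, frame: np.ndarray, frame_index: int = 0, timestamp_s: float = 0.0
    ) -> PupilFit: ...


class ThresholdDetector:
    """The dark-pupil threshold detector as a chainable callable."""

    method = "threshold"

    def __init__(self, cfg: DetectorConfig | None = None):
        self.cfg = cfg or DetectorConfig()

    def __call__(
        self, frame: np.ndarray, frame_index: int = 0, timestamp_s: float = 0.0
    ) -> PupilFit:
        gray = preprocess(frame, self.cfg, frame_index, timestamp_s)
        mask = threshold_segment(gray, self.cfg)
        component = select_pupil_component(mask, self.cfg, values=gray.pixels)
        if component is None:
            return PupilFit.invalid(method=self.method)
        fit = fit_ellipse(component, method=self.method)
        if fit.valid and gray.roi_offset != (0, 0):
            ox, oy = gray.roi_offset
            fit = replace(fit, center=(fit.center[0] + ox, fit.center[1] + oy))
        return fit


class AlwaysFailDetector:
    """Stub standing in the slot of an external detector; never detects."""

    method = "stub"

    def __call__(
        self, frame: np.ndarray, frame_index: int = 0, timestamp_s: float = 0.0
    ) -> PupilFit:
        return PupilFit.invalid(method=self.method)


def detect_pupil(
    frame: np.ndarray,
    chain: Sequence[Callable[..., PupilFit]],
    frame_index: int = 0,
    timestamp_s: float = 0.0,
) -> PupilFit:
    """First valid fit along an ordered detector chain.

    The chain is a pure priority order: a later detector is consulted only
    when every earlier one returned an invalid fit.  If all fail, the result
    is an invalid fit tagged ``"none"``.
    """
    if not chain:
        raise ConfigurationError("detector chain must not be empty")
    for detector in chain:
        fit = detector(frame, frame_index=frame_index, timestamp_s=timestamp_s)
        if fit.valid:
            return fit
    return PupilFit.invalid(method="none")


def detect_sequence(
    frames: Sequence[np.ndarray] | np.ndarray,
    frame_rate: float,
    chain: Sequence[Callable[..., PupilFit]] | None = None,
) -> pd.DataFrame:
    """Run the chain over a frame sequence; one detections row per frame.

    Columns: frame_index, time_s, cx, cy, a, b, orientation, area_px2,
    method, valid — the on-disk detections format consumed by the analysis
    stage.
    """
    if frame_rate <= 0:
        raise ConfigurationError("frame_rate must be positive")
    if chain is None:
        chain = [ThresholdDetector()]
    rows = []
    for i, frame in enumerate(frames):
        t = i / frame_rate
        fit = detect_pupil(frame, chain, frame_index=i, timestamp_s=t)
        rows.append(
            {
                "frame_index": i,
                "time_s": t,
                "cx": fit.center[0],
                "cy": fit.center[1],
                "a": fit.semi_axes[0],
                "b": fit.semi_axes[1],
                "orientation": fit.orientation,
                "area_px2": fit.area_px2,
                "method": fit.method,
                "valid": fit.valid,
            }
        )
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)
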