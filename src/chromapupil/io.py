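"""Reading frame sequences and detection tables from disk."""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

FRAME_EXTENSIONS = (".png", ".jpg", ".jpeg", ".tif", ".tiff")


def iter_frame_directory(path: str | Path) -> Iterator[np.ndarray]:
    """Yield frames from a directory of numbered image files, sorted by name."""
    import imageio.v3 as iio

    p = Path(path)
    if not p.is_dir():
        raise IOError(f"frames directory not found: {p}")
    files = sorted(f for f in p.iterdir() if f.suffix.lower() in FRAME_EXTENSIONS)
    if not files:
        raise IOError(f"no image frames found in: {p}")
    for f in files:
        yield iio.imread(f)


def iter_video(path: str | Path) -> Iterator[np.ndarray]:
    """Yield frames from a video container via imageio.

    Requires an imageio backend able to decode the container (e.g. an ffmpeg
    plugin for mp4); raises an I/O error naming the path otherwise.
    """
    import imageio.v3 as iio

    p = Path(path)
    if not p.is_file():
        raise IOError(f"video file not found: {p}")
    try:
        yield from iio.imiter(p)
    except Exception as exc:  # backend-specific decode failures
        raise IOError(f"cannot decode video {p}: {exc}") from exc


def iter_frames(path: str | Path) -> Iterator[np.ndarray]:
    """Dispatch on path type: directory of frames or a video file."""
    p = Path(path)
    if p.is_dir():
        return iter_frame_directory(p)
    return iter_video(p)


def read_detections(path: str | Path) -> pd.DataFrame:
    """Read a detections CSV written by :func:`chromapupil.detect.detect_sequence`."""
    p = Path(path)
    if not p.is_file():
        raise IOError(f"detections file not found: {p}")
    df = pd.read_csv(p)
    df["valid"] = df["valid"].astype(bool)
    return df
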