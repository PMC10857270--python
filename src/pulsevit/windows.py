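"""Frame-rate resampling, fixed windows, and (min, max, avg) HR labels.

The model consumes non-overlapping windows of W consecutive frames (default
W = 15, stride = 15, chosen to decorrelate training samples); higher-rate
sources are first down-sampled by nearest-index frame selection.  Each
window is labeled with the minimum, maximum, and mean of the heart-rate
trace interpolated at its frame timestamps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np

from .roi import ProcessedFrame

__all__ = [
    "FrameWindow",
    "HRTriple",
    "resample_fps",
    "make_windows",
    "label_window",
    "save_window_store",
    "load_window_store",
]


@dataclass
class HRTriple:
    """(min, max, avg) heart rate in BPM over one window.

    Used both as a window label (validated: ordered, physiological range)
    and as a raw model prediction (unvalidated reals).
    """

    min_bpm: float
    max_bpm: float
    avg_bpm: float

    def validate_label(self) -> "HRTriple":
        if not (self.min_bpm <= self.avg_bpm <= self.max_bpm):
            raise ValueError("label must satisfy min <= avg <= max")
        if self.min_bpm < 30.0 or self.max_bpm > 240.0:
            raise ValueError("label must lie in [30, 240] BPM")
        return self

    def as_array(self) -> np.ndarray:
        return np.array([self.min_bpm, self.max_bpm, self.avg_bpm], dtype=float)


@dataclass
class FrameWindow:
    """W consecutive preprocessed frames."""

    frames: list                            # of ProcessedFrame
    start_index: int
    fps: float

    def __post_init__(self):
        if len(self.frames) < 1:
            raise ValueError("a window needs at least one frame")

    @property
    def images(self) -> np.ndarray:
        return np.stack([f.image for f in self.frames])

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames])


def resample_fps(frame_timestamps, source_fps: float, target_fps: float) -> np.ndarray:
    """Select frame indices that down-sample ``source_fps`` to ``target_fps``.

    Returns indices ``round(j * source_fps / target_fps)`` for j = 0, 1, ...
    while the index stays below the frame count, de-duplicated to a strictly
    increasing sequence.  Up-sampling is refused.
    """
    if target_fps <= 0:
        raise ValueError("target_fps must be positive")
    if target_fps > source_fps:
        raise ValueError("cannot up-sample: target_fps exceeds source_fps")
    n = len(frame_timestamps)
    ratio = source_fps / target_fps
    out = []
    j = 0
    while True:
        idx = int(round(j * ratio))
        if idx >= n:
            break
        if not out or idx > out[-1]:
            out.append(idx)
        j += 1
    return np.asarray(out, dtype=int)


def make_windows(frames, W: int = 15, stride: int = 15) -> list:
    """Cut a frame sequence into windows starting at 0, stride, 2*stride, ...

    Trailing partial windows are dropped; a sequence shorter than W yields an
    empty list (the empty-result signal for short videos).
    """
    if W < 1 or stride < 1:
        raise ValueError("W and stride must be >= 1")
    n = len(frames)
    out = []
    start = 0
    while start + W <= n:
        fps = None
        chunk = list(frames[start:start + W])
        if isinstance(chunk[0], ProcessedFrame) and len(chunk) > 1:
            dt = chunk[1].timestamp - chunk[0].timestamp
            fps = 1.0 / dt if dt > 0 else 0.0
        out.append(FrameWindow(frames=chunk, start_index=start, fps=fps or 0.0))
        start += stride
    return out


def label_window(window: FrameWindow, hr_rows) -> HRTriple:
    """Label a window with (min, max, avg) of the interpolated HR trace.

    ``hr_rows`` is an (M, 2) array-like of (time_s, bpm) rows.  The trace is
    piecewise-linearly interpolated at the window's frame timestamps, with
    nearest-sample extrapolation at the edges.
    """
    rows = np.asarray(hr_rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] < 1 or rows.shape[1] != 2:
        raise ValueError("hr_rows must be a non-empty (time_s, bpm) table")
    order = np.argsort(rows[:, 0])
    times, bpm = rows[order, 0], rows[order, 1]
    vals = np.interp(window.timestamps, times, bpm)
    lo, hi = float(vals.min()), float(vals.max())
    # guard the mean against float round-off on (near-)constant traces
    avg = float(np.clip(vals.mean(), lo, hi))
    return HRTriple(lo, hi, avg).validate_label()


def save_window_store(path, frames: np.ndarray, labels: np.ndarray, meta: dict) -> None:
    """Persist windows to HDF5: frames (n, W, S, S, 3), labels (n, 3), meta JSON attr."""
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=frames.astype(np.float32), compression="gzip")
        f.create_dataset("labels", data=labels.astype(np.float64))
        f.attrs["meta"] = json.dumps(meta)


def load_window_store(path):
    with h5py.File(path, "r") as f:
        frames = f["frames"][()]
        labels = f["labels"][()]
        meta = json.loads(f.attrs["meta"])
    return frames, labels, meta
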