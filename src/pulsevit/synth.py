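"""Synthetic facial-video generator with known PPG, landmarks, and heart rate.

Real rPPG corpora pair facial video with a contact PPG channel.  This module
emulates that pairing at test scale: an elliptical skin-colored face whose
color is modulated by a pseudo-PPG waveform (the green channel carries the
full modulation, red/blue half of it, mirroring the green channel's superior
PPG signal-to-noise ratio), exact 68-point landmark tracks laid out by
formula on the face ellipse, and an exact BPM trace.  Everything is a pure
function of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "PPGTrace",
    "SyntheticScene",
    "gen_ppg_trace",
    "render_scene",
    "write_scene",
    "gen_dataset",
]

HR_MIN_BPM = 30.0
HR_MAX_BPM = 240.0

#: relative amplitude of the second harmonic (crude dicrotic notch)
DICROTIC_AMPLITUDE = 0.25

#: per-channel modulation routing: green full depth, red/blue half
CHANNEL_GAIN = np.array([0.5, 1.0, 0.5])


@dataclass
class PPGTrace:
    """A pseudo-PPG waveform with its per-sample ground-truth heart rate."""

    samples: np.ndarray        # arbitrary units, peak-normalized to 1
    fs: float                  # sampling rate, Hz
    hr_trace: np.ndarray       # BPM per sample

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.hr_trace = np.asarray(self.hr_trace, dtype=float)
        if self.samples.shape != self.hr_trace.shape:
            raise ValueError("samples and hr_trace must have equal length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if np.any(self.hr_trace < HR_MIN_BPM) or np.any(self.hr_trace > HR_MAX_BPM):
            raise ValueError(f"hr_trace must lie in [{HR_MIN_BPM}, {HR_MAX_BPM}] BPM")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class SyntheticScene:
    """Render parameters plus ground truth for one synthetic video."""

    ppg: PPGTrace
    frame_rate: float = 25.0
    image_size: tuple = (64, 64)            # (height, width)
    skin_color: tuple = (200.0, 150.0, 120.0)
    modulation_depth: float = 0.05
    noise_sd: float = 0.0
    motion_amplitude: float = 0.0           # pixels
    seed: int = 0
    landmark_tracks: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not 0.0 <= self.modulation_depth <= 0.5:
            raise ValueError("modulation_depth must lie in [0, 0.5]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.ppg.duration * self.frame_rate))


def gen_ppg_trace(hr_fn, duration: float, fs: float, seed: int = 0) -> PPGTrace:
    """Synthesize a quasi-periodic pulse waveform via phase accumulation.

    The instantaneous fundamental frequency at time ``t`` is ``hr_fn(t)/60``
    Hz.  The pulse shape is a sinusoid plus a second harmonic at
    0.25 amplitude; the waveform is peak-normalized.  ``seed`` only sets the
    initial phase, so two traces with the same parameters differ by a
    deterministic phase offset.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    hr = np.asarray([float(hr_fn(ti)) for ti in t])
    if np.any(hr < HR_MIN_BPM) or np.any(hr > HR_MAX_BPM):
        raise ValueError(f"hr_fn must return values in [{HR_MIN_BPM}, {HR_MAX_BPM}] BPM")
    rng = np.random.default_rng(seed)
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    freq = hr / 60.0                       # Hz
    # phase[i] integrates frequency up to (not including) sample i
    phase = phase0 + 2.0 * np.pi * np.concatenate(([0.0], np.cumsum(freq[:-1]))) / fs
    samples = np.sin(phase) + DICROTIC_AMPLITUDE * np.sin(2.0 * phase)
    samples /= np.max(np.abs(samples))
    return PPGTrace(samples=samples, fs=fs, hr_trace=hr)


# -----------------------------------------------------------------------------
# Landmark layout: 68 points by formula on the face ellipse.
# Regional order matches the detector convention used downstream:
# face(jaw) 0-16, eyebrows 17-26, nose 27-35, eyes 36-45, mouth 46-67.
# -----------------------------------------------------------------------------

def _base_landmarks(image_size: tuple) -> tuple[np.ndarray, tuple]:
    h, w = image_size
    cx, cy = w / 2.0, h / 2.0
    a, b = 0.32 * w, 0.42 * h              # ellipse semi-axes (x, y)
    pts = []
    # jaw: lower half of the ellipse, left ear -> chin -> right ear
    for k in range(17):
        th = np.pi - k * np.pi / 16.0
        pts.append((cx + a * np.cos(th), cy + b * np.sin(th)))
    # eyebrows: two horizontal rows of 5
    for sign in (-1, 1):
        for k in range(5):
            x = cx + sign * (0.15 + 0.10 * k) * a
            pts.append((x, cy - 0.45 * b))
    # nose: 4 points down the bridge + 5 across the nostril row
    for k in range(4):
        pts.append((cx, cy - 0.20 * b + k * 0.10 * b))
    for k in range(5):
        pts.append((cx + (k - 2) * 0.075 * a, cy + 0.18 * b))
    # eyes: 5 points on a small ellipse each
    for sign in (-1, 1):
        ex = cx + sign * 0.35 * a
        ey = cy - 0.25 * b
        for k in range(5):
            th = 2.0 * np.pi * k / 5.0
            pts.append((ex + 0.10 * a * np.cos(th), ey + 0.05 * b * np.sin(th)))
    # mouth: 22 points on an ellipse ring
    mx, my = cx, cy + 0.50 * b
    for k in range(22):
        th = 2.0 * np.pi * k / 22.0
        pts.append((mx + 0.26 * a * np.cos(th), my + 0.12 * b * np.sin(th)))
    return np.asarray(pts, dtype=float), (cx, cy, a, b)


def render_scene(scene: SyntheticScene):
    """Render a scene to (frames, landmark tracks, HR rows).

    Returns
    -------
    frames : uint8 array, shape (n_frames, H, W, 3)
    landmarks : float array, shape (n_frames, 68, 2), (x, y) pixel coordinates
    hr_rows : float array, shape (n_frames, 2), columns (time_s, bpm)
    """
    h, w = scene.image_size
    base_pts, (cx, cy, a, b) = _base_landmarks(scene.image_size)
    amp = float(scene.motion_amplitude)
    if cx - a - amp < 0 or cx + a + amp > w - 1 or cy - b - amp < 0 or cy + b + amp > h - 1:
        raise ValueError("image too small to contain the face ellipse plus jitter")

    n = scene.n_frames
    rng = np.random.default_rng(scene.seed)
    if amp > 0:
        jitter = rng.integers(-int(np.floor(amp)), int(np.floor(amp)) + 1, size=(n, 2)).astype(float)
    else:
        jitter = np.zeros((n, 2))

    yy, xx = np.mgrid[0:h, 0:w]
    skin = np.asarray(scene.skin_color, dtype=float)
    frames = np.zeros((n, h, w, 3), dtype=np.uint8)
    landmarks = np.zeros((n, 68, 2))
    hr_rows = np.zeros((n, 2))
    fs = scene.ppg.fs
    n_ppg = len(scene.ppg.samples)

    for i in range(n):
        t = i / scene.frame_rate
        idx = min(int(round(t * fs)), n_ppg - 1)
        v = scene.ppg.samples[idx]
        dx, dy = jitter[i]
        inside = ((xx - (cx + dx)) / a) ** 2 + ((yy - (cy + dy)) / b) ** 2 <= 1.0
        color = skin * (1.0 + scene.modulation_depth * CHANNEL_GAIN * v)
        img = np.zeros((h, w, 3))
        img[inside] = color
        if scene.noise_sd > 0:
            noise = rng.normal(0.0, scene.noise_sd, size=(int(inside.sum()), 3))
            img[inside] += noise
        frames[i] = np.clip(np.round(img), 0, 255).astype(np.uint8)
        landmarks[i] = base_pts + np.array([dx, dy])
        hr_rows[i] = (t, scene.ppg.hr_trace[idx])

    scene.landmark_tracks = landmarks
    return frames, landmarks, hr_rows


def write_scene(out_dir, frames, landmarks, hr_rows, fps: float) -> dict:
    """Write one rendered scene in the on-disk dialect.

    frame_%06d.png per frame; landmarks CSV with header frame,point_id,x,y;
    HR CSV with header time_s,bpm.  Returns the manifest entry (without seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(out_dir / f"frame_{i:06d}.png", frame)
    n, p = landmarks.shape[:2]
    lm = pd.DataFrame({
        "frame": np.repeat(np.arange(n), p),
        "point_id": np.tile(np.arange(p), n),
        "x": landmarks[:, :, 0].ravel(),
        "y": landmarks[:, :, 1].ravel(),
    })
    lm_csv = out_dir / "landmarks.csv"
    lm.to_csv(lm_csv, index=False)
    hr_csv = out_dir / "hr.csv"
    pd.DataFrame(hr_rows, columns=["time_s", "bpm"]).to_csv(hr_csv, index=False)
    return {
        "video_dir": str(out_dir),
        "landmarks_csv": str(lm_csv),
        "hr_csv": str(hr_csv),
        "fps": fps,
    }


def gen_dataset(
    n_videos: int,
    hr_range: tuple,
    duration: float,
    fps: float,
    seed: int,
    out_dir,
    image_size: tuple = (64, 64),
    modulation_depth: float = 0.05,
    noise_sd: float = 0.0,
    motion_amplitude: float = 0.0,
    ppg_fs: float = 60.0,
    mode: str = "constant",
) -> Path:
    """Generate ``n_videos`` synthetic scenes and a JSON manifest.

    Per-video heart rates are drawn reproducibly from ``hr_range``; with
    ``mode="ramp"`` each video ramps linearly between two draws from the
    range.  Returns the manifest path.
    """
    if n_videos < 1:
        raise ValueError("n_videos must be >= 1")
    low, high = hr_range
    if not (HR_MIN_BPM <= low <= high <= HR_MAX_BPM):
        raise ValueError(f"hr_range must satisfy {HR_MIN_BPM} <= low <= high <= {HR_MAX_BPM}")
    if mode not in ("constant", "ramp"):
        raise ValueError("mode must be 'constant' or 'ramp'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    entries = []
    for k in range(n_videos):
        vid_seed = int(rng.integers(0, 2**31 - 1))
        if mode == "constant":
            hr0 = hr1 = float(rng.uniform(low, high))
        else:
            hr0, hr1 = (float(rng.uniform(low, high)) for _ in range(2))
        hr_fn = (lambda t, h0=hr0, h1=hr1, d=duration: h0 + (h1 - h0) * min(t / d, 1.0))
        ppg = gen_ppg_trace(hr_fn, duration, ppg_fs, seed=vid_seed)
        scene = SyntheticScene(
            ppg=ppg, frame_rate=fps, image_size=image_size,
            modulation_depth=modulation_depth, noise_sd=noise_sd,
            motion_amplitude=motion_amplitude, seed=vid_seed,
        )
        frames, landmarks, hr_rows = render_scene(scene)
        entry = write_scene(out_dir / f"video_{k:03d}", frames, landmarks, hr_rows, fps)
        entry["seed"] = vid_seed
        entries.append(entry)
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps(entries, indent=2))
    return manifest
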