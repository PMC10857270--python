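"""Facial ROI preprocessing: landmarks -> masked, cropped, normalized frame.

The detector convention is 68 named points (17 jaw/face outline, 10 eyebrow,
9 nose, 10 eyes, 22 mouth).  Two forehead points are constructed from the
left-most and right-most eyebrow points, the frame is masked to the convex
hull of all 70 points, and the nonzero region is cropped, padded to square,
resized, and standardized for the backbone.

Coordinates are pixel units, origin top-left, x rightward, y downward,
0-based frame indices; "upward" means decreasing y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.transform import resize as _sk_resize

__all__ = [
    "REGION_COUNTS",
    "LandmarkSet",
    "ProcessedFrame",
    "add_forehead_points",
    "mask_face",
    "crop_resize_normalize",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
]

#: regional point counts of the 68-point schema, in index order
REGION_COUNTS = {"face": 17, "eyebrow": 10, "nose": 9, "eyes": 10, "mouth": 22}

#: channel statistics of the backbone pretraining convention
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)

IDENTITY_MEAN = (0.0, 0.0, 0.0)
IDENTITY_STD = (1.0, 1.0, 1.0)


def region_slices(counts: dict = REGION_COUNTS) -> dict:
    """Map region name -> index range over the first 68 points (+ forehead)."""
    out, start = {}, 0
    for name, c in counts.items():
        out[name] = range(start, start + c)
        start += c
    out["forehead"] = range(start, start + 2)
    return out


@dataclass
class LandmarkSet:
    """The 68 detector points plus the 2 constructed forehead points."""

    points: np.ndarray                      # (70, 2) float, (x, y)
    region_index: dict = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (70, 2):
            raise ValueError(f"expected 70 (x, y) points, got shape {self.points.shape}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")
        if self.region_index is None:
            self.region_index = region_slices()
        n68 = sum(len(r) for name, r in self.region_index.items() if name != "forehead")
        if n68 != 68:
            raise ValueError("the named regions must partition the first 68 points")


@dataclass
class ProcessedFrame:
    """One masked, cropped, resized, normalized frame ready for the model."""

    image: np.ndarray                       # (S, S, 3) float32
    mask_fraction: float
    timestamp: float = 0.0

    def __post_init__(self):
        if self.image.ndim != 3 or self.image.shape[0] != self.image.shape[1] or self.image.shape[2] != 3:
            raise ValueError("image must be square with 3 channels")
        if not 0.0 < self.mask_fraction <= 1.0:
            raise ValueError("mask_fraction must lie in (0, 1]")


def add_forehead_points(landmarks68: np.ndarray, k: float = 0.25,
                        region_counts: dict = REGION_COUNTS) -> LandmarkSet:
    """Append two forehead points above the eyebrow extremes.

    The left-most and right-most eyebrow points are each translated upward
    (decreasing y) by ``k`` times the height of the bounding box of the 68
    points.  The original 68 points are returned unchanged.
    """
    pts = np.asarray(landmarks68, dtype=float)
    if pts.shape != (68, 2):
        raise ValueError(f"expected 68 (x, y) points, got shape {pts.shape}")
    slices = region_slices(region_counts)
    brows = pts[list(slices["eyebrow"])]
    height = pts[:, 1].max() - pts[:, 1].min()
    if height <= 0:
        raise ValueError("degenerate landmark bounding box (zero height)")
    left = brows[np.argmin(brows[:, 0])]
    right = brows[np.argmax(brows[:, 0])]
    lift = np.array([0.0, -k * height])
    out = np.vstack([pts, left + lift, right + lift])
    return LandmarkSet(points=out, region_index=slices)


def mask_face(frame: np.ndarray, landmarks) -> np.ndarray:
    """Zero out every pixel whose center lies outside the landmark hull.

    The kept region is the convex hull of all 70 points; pixels on the hull
    boundary count as inside.  Pixel (row r, col c) has center (x=c, y=r).
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("frame must be an RGB image (H, W, 3)")
    pts = landmarks.points if isinstance(landmarks, LandmarkSet) else np.asarray(landmarks, float)
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError("landmark hull has zero area (collinear points)") from exc
    h, w = frame.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    centers = np.stack([xx.ravel(), yy.ravel(), np.ones(h * w)], axis=1)
    # hull.equations rows (a, b, c): inside iff a*x + b*y + c <= 0 for all faces
    inside = np.all(centers @ hull.equations.T <= 1e-9, axis=1).reshape(h, w)
    out = np.zeros_like(frame)
    out[inside] = frame[inside]
    return out


def crop_resize_normalize(masked: np.ndarray, size: int = 224,
                          mean=IMAGENET_MEAN, std=IMAGENET_STD,
                          timestamp: float = 0.0) -> ProcessedFrame:
    """Crop to the nonzero bounding box, pad to square, resize, standardize.

    The masked image (values in 0..255) is cropped to the tight bounding box
    of nonzero pixels, zero-padded centered to square, bilinearly resized to
    ``size`` x ``size``, scaled to [0, 1], then per-channel standardized with
    ``mean``/``std`` (identity constants give the plain [0, 1] image).
    """
    masked = np.asarray(masked)
    nonzero = np.any(masked != 0, axis=2)
    if not nonzero.any():
        raise ValueError("masked image has no nonzero pixels")
    rows = np.flatnonzero(nonzero.any(axis=1))
    cols = np.flatnonzero(nonzero.any(axis=0))
    crop = masked[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1].astype(np.float64)
    h, w = crop.shape[:2]
    side = max(h, w)
    top = (side - h) // 2
    left = (side - w) // 2
    square = np.zeros((side, side, 3))
    square[top:top + h, left:left + w] = crop
    mask_fraction = float(np.any(square != 0, axis=2).mean())
    if (side, side) == (size, size):
        resized = square
    else:
        resized = _sk_resize(square, (size, size, 3), order=1,
                             anti_aliasing=False, preserve_range=True)
    img01 = resized / 255.0
    img = (img01 - np.asarray(mean)) / np.asarray(std)
    return ProcessedFrame(image=img.astype(np.float32),
                          mask_fraction=mask_fraction, timestamp=timestamp)
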