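"""Classical green-channel spectral heart-rate estimator.

The green channel carries the strongest PPG signal-to-noise ratio of the
three RGB channels, so the oldest rPPG baseline simply tracks the spatial
mean of green over the skin region and reads the heart rate off the
dominant spectral peak in the physiological band.  Here it serves both as
a comparison method and as an independent check that synthetic videos
encode their programmed heart rate (synth -> roi -> oracle closes the loop
with no learned component).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

__all__ = ["SpectralEstimate", "green_series", "green_hr"]

#: default physiological band, Hz (42-180 BPM)
DEFAULT_BAND = (0.7, 3.0)

#: minimum zero-padded DFT length for sub-BPM peak resolution
MIN_NFFT = 8192


@dataclass
class SpectralEstimate:
    """Spectral-peak heart rate with a crude reliability score."""

    hr_bpm: float
    peak_power_ratio: float       # peak-bin power / total band power
    band: tuple

    def is_reliable(self, min_ratio: float = 0.01) -> bool:
        return np.isfinite(self.hr_bpm) and self.peak_power_ratio >= min_ratio


def green_series(masked_frames) -> np.ndarray:
    """Spatial mean of the green channel over nonzero-mask pixels, per frame."""
    out = np.empty(len(masked_frames))
    for i, frame in enumerate(masked_frames):
        frame = np.asarray(frame, dtype=float)
        mask = np.any(frame != 0, axis=2)
        out[i] = frame[mask, 1].mean() if mask.any() else 0.0
    return out


def green_hr(masked_frames, fps: float, band: tuple = DEFAULT_BAND) -> SpectralEstimate:
    """Estimate heart rate from masked frames via the green-channel spectrum.

    Pipeline: spatial-mean green series -> detrend by subtracting a 1 s
    moving average -> Hann window -> zero-pad to >= 8192 samples -> DFT
    magnitude restricted to ``band`` -> HR = 60 x argmax frequency.
    """
    n = len(masked_frames)
    if n < 2 * fps:
        raise ValueError("need at least ~2 s of frames for a spectral estimate")
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError("band must satisfy 0 < low < high")
    if hi >= fps / 2:
        raise ValueError("band upper edge must lie below the Nyquist frequency")
    series = green_series(masked_frames)
    trend = uniform_filter1d(series, size=max(1, int(round(fps))), mode="nearest")
    x = (series - trend) * np.hanning(n)
    nfft = MIN_NFFT
    while nfft < n:
        nfft *= 2
    spec = np.abs(np.fft.rfft(x, n=nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fps)
    in_band = (freqs >= lo) & (freqs <= hi)
    band_power = spec[in_band]
    total = band_power.sum()
    if total <= 0:
        return SpectralEstimate(hr_bpm=float("nan"), peak_power_ratio=0.0, band=band)
    k = int(np.argmax(band_power))
    return SpectralEstimate(
        hr_bpm=60.0 * float(freqs[in_band][k]),
        peak_power_ratio=float(band_power[k] / total),
        band=band,
    )
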