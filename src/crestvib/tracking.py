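"""Frame-sequence to position-series conversion.

Mirrors the video stage used on the real crests: per region of interest,
each frame is auto-contrast enhanced, thresholded, and the mean position of
the bright object (crest flag or shaker mount) is taken as the
intensity-weighted centroid of the above-threshold pixels.

Conventions: image origin top-left, x rightward, y downward, 0-based pixel
indexing with centroids reported at pixel centers.  Motions are assumed to
lie in the image plane (no perspective or lens-distortion correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from skimage.filters import threshold_otsu

from .errors import InsufficientDataError, InvalidParameterError, TrackingError


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest, pixel units, origin top-left."""

    x0: int
    y0: int
    width: int
    height: int
    name: str = ""

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise InvalidParameterError("ROI width/height must be positive")

    def crop(self, frame: np.ndarray) -> np.ndarray:
        h, w = frame.shape
        if self.x0 < 0 or self.y0 < 0 or self.x0 + self.width > w or self.y0 + self.height > h:
            raise InvalidParameterError(f"ROI {self} outside frame bounds {frame.shape}")
        return frame[self.y0:self.y0 + self.height, self.x0:self.x0 + self.width]


@dataclass
class TrackConfig:
    """Configuration of the thresholding/centroid tracker."""

    rois: list[ROI]
    threshold_mode: str = "otsu_like_automatic"
    fixed_threshold: float | None = None
    min_blob_area: int = 1

    def __post_init__(self):
        if not self.rois:
            raise InvalidParameterError("at least one ROI is required")
        if self.threshold_mode == "fixed":
            if self.fixed_threshold is None:
                raise InvalidParameterError("fixed_threshold required in fixed mode")
        elif self.threshold_mode != "otsu_like_automatic":
            raise InvalidParameterError(f"unknown threshold_mode {self.threshold_mode!r}")


@dataclass
class PositionSeries:
    """Tracked position of one object over time.

    Frames where no blob was found hold NaN and are flagged in ``missing``;
    they are never silently dropped.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    object_id: str
    fs: float
    scale_mm_per_px: float | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise InvalidParameterError("t, x, y must have equal length")

    @property
    def missing(self) -> np.ndarray:
        return ~(np.isfinite(self.x) & np.isfinite(self.y))

    def interpolate_missing(self, max_gap: int = 3) -> "PositionSeries":
        """Linearly fill gaps of at most ``max_gap`` consecutive frames.

        Longer gaps raise TrackingError: the spectral stages need gap-free,
        honestly interpolated series.
        """
        miss = self.missing
        if not miss.any():
            return self
        runs = _run_lengths(miss)
        if runs and max(runs) > max_gap:
            raise TrackingError(
                f"gap of {max(runs)} frames exceeds max_gap={max_gap} for {self.object_id!r}"
            )
        if miss[0] or miss[-1]:
            raise TrackingError("cannot extrapolate missing frames at series edges")
        good = ~miss
        x = self.x.copy()
        y = self.y.copy()
        x[miss] = np.interp(self.t[miss], self.t[good], self.x[good])
        y[miss] = np.interp(self.t[miss], self.t[good], self.y[good])
        return PositionSeries(self.t, x, y, self.object_id, self.fs, self.scale_mm_per_px)


def _run_lengths(mask: np.ndarray) -> list[int]:
    runs, count = [], 0
    for m in mask:
        if m:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return runs


def _centroid(patch: np.ndarray, config: TrackConfig) -> tuple[float, float]:
    """Contrast-stretch, threshold, intensity-weighted centroid. NaNs if empty."""
    patch = patch.astype(float)
    lo, hi = patch.min(), patch.max()
    if hi <= lo:  # featureless region: nothing to track
        return np.nan, np.nan
    stretched = (patch - lo) / (hi - lo)
    if config.threshold_mode == "fixed":
        thr = config.fixed_threshold
    else:
        thr = threshold_otsu(stretched, nbins=256)
    mask = stretched > thr
    if mask.sum() < config.min_blob_area:
        return np.nan, np.nan
    # baseline-subtracted weights decay continuously to zero at the threshold
    # boundary, removing the sub-pixel truncation bias a hard cut would cause
    weights = np.clip(stretched - thr, 0.0, None)
    total = weights.sum()
    ys, xs = np.mgrid[0:patch.shape[0], 0:patch.shape[1]]
    return float((weights * xs).sum() / total), float((weights * ys).sum() / total)


def track_objects(
    frames: np.ndarray,
    config: TrackConfig,
    fs: float = 240.0,
    max_missing_frac: float = 0.05,
) -> list[PositionSeries]:
    """Track one object per ROI across a frame stack.

    ``frames`` is (n_frames, height, width), grayscale; RGB input is
    converted by channel averaging.  Raises TrackingError with a per-ROI
    report when any ROI has more than ``max_missing_frac`` missing frames.
    """
    frames = np.asarray(frames)
    if frames.ndim == 4:  # RGB -> luminance
        frames = frames.mean(axis=-1)
    if frames.ndim != 3 or len(frames) < 2:
        raise InsufficientDataError("need a (n_frames, h, w) stack with >= 2 frames")
    n = len(frames)
    t = np.arange(n) / fs
    out = []
    failures = {}
    for i, roi in enumerate(config.rois):
        xs = np.empty(n)
        ys = np.empty(n)
        for j, frame in enumerate(frames):
            xs[j], ys[j] = _centroid(roi.crop(frame), config)
        xs += roi.x0
        ys += roi.y0
        name = roi.name or f"roi{i}"
        series = PositionSeries(t, xs, ys, name, fs)
        n_missing = int(series.missing.sum())
        if n_missing > max_missing_frac * n:
            failures[name] = n_missing
        out.append(series)
    if failures:
        report = ", ".join(f"{k}: {v}/{n} frames missing" for k, v in failures.items())
        raise TrackingError(f"tracking failed ({report})")
    return out


def detrend_center(
    series: PositionSeries,
    axis: str = "x",
    scale_mm_per_px: float | None = None,
) -> np.ndarray:
    """Mean- and linear-trend-removed 1-D motion along one axis.

    Missing samples must have been interpolated explicitly first.  Returns
    px, or mm when a scale is given (argument overrides the series' own).
    """
    if axis not in ("x", "y"):
        raise InvalidParameterError("axis must be 'x' or 'y'")
    v = series.x if axis == "x" else series.y
    if not np.isfinite(v).all():
        raise TrackingError("series has missing samples; interpolate_missing() first")
    out = _signal.detrend(v, type="linear")
    scale = scale_mm_per_px if scale_mm_per_px is not None else series.scale_mm_per_px
    if scale is not None:
        out = out * scale
    return out
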