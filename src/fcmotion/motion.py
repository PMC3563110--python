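"""Frame-wise motion quantification: RMS, FD, DVARS, and censor masks.

Framewise displacement (FD) of frame *i* is the sum of absolute backward
differences of the six rigid-body parameters, with each rotation delta
converted from radians to mm as arc length on a sphere of radius 50 mm
(the approximate cortex-to-head-center distance).  DVARS is the spatial
root-mean-square of the backward temporal difference of the signal over
all channels.  Both are defined as 0 at the first frame, which has no
predecessor.

Volume censoring ("scrubbing") removes every frame whose metric exceeds
a threshold, together with 1 frame before and 2 frames after it, to
account for temporal blurring of the artifact by the band-pass filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .io import CensorMask, RealignmentSeries

__all__ = [
    "MotionTrace",
    "compute_fd",
    "compute_dvars",
    "compute_rms",
    "make_censor_mask",
    "motion_trace",
    "lowess_diagnostic",
]

DEFAULT_RADIUS_MM = 50.0


@dataclass
class MotionTrace:
    """Per-run motion summary: FD/DVARS series and scalar statistics."""

    fd: np.ndarray
    dvars: np.ndarray | None
    rms_total: float
    radius_mm: float = DEFAULT_RADIUS_MM

    @property
    def mean_fd_pre(self) -> float:
        return float(np.mean(self.fd))

    def mean_fd_post(self, mask: CensorMask) -> float:
        """Mean FD over the retained frames of a censor mask."""
        if mask.n_frames != self.fd.size:
            raise ValueError("mask length does not match FD series")
        if mask.n_kept == 0:
            return float("nan")
        return float(np.mean(self.fd[mask.keep]))


def compute_fd(series: RealignmentSeries, radius_mm: float = DEFAULT_RADIUS_MM) -> np.ndarray:
    """Framewise displacement in mm; FD of the first frame is 0."""
    if series.n_frames < 2:
        raise ValueError("FD needs at least 2 frames")
    deltas = np.diff(series.params, axis=0)
    fd = (
        np.abs(deltas[:, :3]).sum(axis=1)
        + radius_mm * np.abs(deltas[:, 3:]).sum(axis=1)
    )
    return np.concatenate([[0.0], fd])


def compute_dvars(channels: np.ndarray, normalize: bool = True,
                  target_median: float = 1000.0) -> np.ndarray:
    """DVARS of a channel x time matrix; first frame is 0.

    With ``normalize`` the channels are first rescaled so the run's median
    intensity is 1000 (a channel-level stand-in for volumetric mode-1000
    intensity normalization), putting the conventional threshold of 4 on a
    comparable footing across runs.  A run whose median intensity is 0
    cannot be rescaled; DVARS is then returned unnormalized with a warning.
    """
    channels = np.asarray(channels, dtype=float)
    if channels.ndim != 2:
        raise ValueError("channels must be a 2-D channel x time matrix")
    n_channels, n_frames = channels.shape
    if n_frames < 2 or n_channels < 1:
        raise ValueError("DVARS needs >= 2 frames and >= 1 channel")
    if normalize:
        med = np.median(channels)
        if med == 0:
            warnings.warn(
                "median intensity is 0; DVARS returned unnormalized",
                RuntimeWarning,
                stacklevel=2,
            )
        else:
            channels = channels * (target_median / med)
    diffs = np.diff(channels, axis=1)
    dvars = np.sqrt(np.mean(diffs ** 2, axis=0))
    return np.concatenate([[0.0], dvars])


def compute_rms(series: RealignmentSeries, radius_mm: float = DEFAULT_RADIUS_MM,
                rms_exclusion: float = 1.5) -> tuple[float, bool]:
    """Total run RMS of the six parameters (rotations as arc length, mm).

    Returns ``(rms, excluded)``; a run is excluded only when its RMS
    strictly exceeds the 1.5 mm default limit ("exceeding" the limit, so
    a run exactly at the boundary is retained).
    """
    if series.n_frames < 1:
        raise ValueError("RMS needs at least 1 frame")
    values = series.params.copy()
    values[:, 3:] *= radius_mm
    rms = float(np.sqrt(np.mean(np.sum(values ** 2, axis=1))))
    return rms, rms > rms_exclusion


def make_censor_mask(metric: np.ndarray, threshold: float, n_before: int = 1,
                     n_after: int = 2, source_metric: str = "none") -> CensorMask:
    """Censor mask from a per-frame metric: frame i with metric > threshold
    removes frames i-n_before .. i+n_after (clipped to the run), and the
    removal sets of all trigger frames are unioned."""
    metric = np.asarray(metric, dtype=float)
    if metric.ndim != 1:
        raise ValueError("metric must be a 1-D series")
    if not np.all(np.isfinite(metric)):
        raise ValueError("metric series contains non-finite values")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    n = metric.size
    keep = np.ones(n, dtype=bool)
    for i in np.flatnonzero(metric > threshold):
        keep[max(0, i - n_before): min(n, i + n_after + 1)] = False
    return CensorMask(keep=keep, source_metric=source_metric, threshold=threshold)


def motion_trace(series: RealignmentSeries, channels: np.ndarray | None = None,
                 radius_mm: float = DEFAULT_RADIUS_MM,
                 rms_exclusion: float = 1.5) -> MotionTrace:
    """Bundle FD, DVARS (when channel data is available) and run RMS."""
    fd = compute_fd(series, radius_mm=radius_mm)
    dvars = compute_dvars(channels) if channels is not None else None
    rms, _ = compute_rms(series, radius_mm=radius_mm, rms_exclusion=rms_exclusion)
    return MotionTrace(fd=fd, dvars=dvars, rms_total=rms, radius_mm=radius_mm)


def lowess_diagnostic(x: np.ndarray, y: np.ndarray, bandwidth: float = 0.3) -> np.ndarray:
    """Locally weighted (LOWESS) smooth of y on x, for FD-vs-DVARS
    inspection plots.  Purely diagnostic; never feeds statistics.

    Returns an (n, 2) array of (x, smoothed y) sorted by x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 10:
        raise ValueError("LOWESS diagnostic needs at least 10 points")
    return _sm_lowess(y, x, frac=bandwidth, return_sorted=True)
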