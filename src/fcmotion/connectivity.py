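"""ROI time-series cleaning and correlation-matrix construction.

The cleaning chain mirrors standard resting-state functional connectivity
preprocessing at the ROI level: a zero-phase temporal band-pass
(0.009-0.08 Hz), then ordinary-least-squares regression of nuisance
channels (global / white-matter / ventricle analogs) together with their
first-order backward-difference derivatives.

Correlation matrices are symmetric R x R Pearson matrices with a Fisher
r-to-z companion and a per-edge validity mask.  Edges touching a constant
channel, or with |r| = 1 (infinite z), are carried as *invalid* rather
than raising, so one degenerate channel does not kill a subject.  Edges
are indexed canonically by the row-major upper triangle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal
from scipy.spatial.distance import pdist

from .io import CensorMask, RoiSet

__all__ = [
    "ConnectivityMatrix",
    "edge_index",
    "bandpass",
    "nuisance_regress",
    "correlation_matrix",
    "partial_correlation_matrix",
    "edge_distances",
]


def edge_index(n_rois: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical edge ordering: row-major upper triangle (i < j)."""
    return np.triu_indices(n_rois, k=1)


@dataclass
class ConnectivityMatrix:
    """Symmetric Pearson/Fisher-z connectivity matrix with validity mask.

    ``valid`` is True on off-diagonal entries whose z value is finite and
    whose channels were non-degenerate over the frames used.
    """

    r: np.ndarray
    z: np.ndarray
    valid: np.ndarray
    n_frames_used: int
    subject_id: str = ""

    @property
    def n_rois(self) -> int:
        return self.r.shape[0]

    @property
    def n_edges(self) -> int:
        n = self.n_rois
        return n * (n - 1) // 2

    def edge_vector(self, which: str = "z") -> np.ndarray:
        """Unique off-diagonal edges in canonical order."""
        iu = edge_index(self.n_rois)
        if which == "r":
            return self.r[iu]
        if which == "z":
            return self.z[iu]
        if which == "valid":
            return self.valid[iu]
        raise ValueError(f"unknown edge field {which!r}")


def bandpass(ts: np.ndarray, tr_seconds: float, f_lo: float = 0.009,
             f_hi: float = 0.08, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-pass per ROI channel, then demean."""
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    fs = 1.0 / tr_seconds
    nyquist = fs / 2.0
    if f_hi >= nyquist:
        raise ValueError(
            f"upper cutoff {f_hi} Hz is not below the Nyquist frequency "
            f"{nyquist:.4g} Hz for TR = {tr_seconds} s"
        )
    sos = _signal.butter(order, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    # sosfiltfilt needs runs longer than its padding window
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(),
                                             (sos[:, 5] == 0).sum()))
    if ts.shape[1] <= padlen:
        raise ValueError(f"run too short for band-pass filtering ({ts.shape[1]} frames)")
    out = _signal.sosfiltfilt(sos, ts, axis=1)
    return out - out.mean(axis=1, keepdims=True)


def _with_derivatives(nuisance: np.ndarray) -> np.ndarray:
    """Stack nuisance channels with backward-difference derivatives (first
    derivative sample set to 0)."""
    deriv = np.diff(nuisance, axis=0, prepend=nuisance[:1, :])
    return np.hstack([nuisance, deriv])


def nuisance_regress(ts: np.ndarray, nuisance: np.ndarray,
                     add_derivatives: bool = True) -> np.ndarray:
    """OLS residuals of each ROI series after regressing out nuisance
    channels, their backward-difference derivatives, and an intercept.

    ``ts`` is ROI x time; ``nuisance`` is channel x time.
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
    if nuisance.shape[1] != ts.shape[1]:
        raise ValueError("nuisance length does not match time series")
    design = nuisance.T
    if add_derivatives:
        design = _with_derivatives(design)
    design = np.hstack([design, np.ones((design.shape[0], 1))])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the offending columns for the caller
        keep: list[int] = []
        for j in range(design.shape[1]):
            if np.linalg.matrix_rank(design[:, keep + [j]]) > len(keep):
                keep.append(j)
        collinear = sorted(set(range(design.shape[1])) - set(keep))
        raise ValueError(
            f"nuisance design is rank deficient; collinear columns {collinear} "
            "(derivative columns follow the channels, intercept last)"
        )
    beta, *_ = np.linalg.lstsq(design, ts.T, rcond=None)
    return (ts.T - design @ beta).T


def _pearson_matrix(ts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson matrix with degenerate (constant) channels flagged."""
    n = ts.shape[0]
    sd = ts.std(axis=1)
    ok = sd > 0
    r = np.zeros((n, n), dtype=float)
    if ok.sum() >= 2:
        r_ok = np.corrcoef(ts[ok])
        idx = np.flatnonzero(ok)
        r[np.ix_(idx, idx)] = r_ok
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    valid = np.outer(ok, ok)
    np.fill_diagonal(valid, False)
    return r, valid


def correlation_matrix(ts: np.ndarray, mask: CensorMask | None = None,
                       min_frames: int = 30, subject_id: str = "") -> ConnectivityMatrix:
    """Pearson/Fisher-z connectivity over the retained frames of ``mask``.

    With fewer than ``min_frames`` retained frames the matrix cannot be
    estimated; a ValueError is raised (cohort-level eligibility rules are
    applied by the procedure layer, which never lets this trip on eligible
    subjects).
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    if mask is not None:
        if mask.n_frames != ts.shape[1]:
            raise ValueError("censor mask length does not match time series")
        ts = ts[:, mask.keep]
    n_used = ts.shape[1]
    if n_used < max(min_frames, 3):
        raise ValueError(
            f"only {n_used} frames retained; need at least {max(min_frames, 3)}"
        )
    r, valid = _pearson_matrix(ts)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    valid &= np.isfinite(z)
    return ConnectivityMatrix(r=r, z=z, valid=valid, n_frames_used=n_used,
                              subject_id=subject_id)


def partial_correlation_matrix(ts: np.ndarray, covariates: np.ndarray,
                               mask: CensorMask | None = None,
                               min_frames: int = 30,
                               subject_id: str = "") -> ConnectivityMatrix:
    """Edge-wise partial correlations controlling frame-wise covariates.

    Each edge value is the Pearson correlation of the two ROI series after
    OLS regression of both on [covariates, intercept].  An empty covariate
    set degenerates to the plain correlation matrix.
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.size == 0:
        return correlation_matrix(ts, mask=mask, min_frames=min_frames,
                                  subject_id=subject_id)
    if covariates.shape[1] != ts.shape[1]:
        raise ValueError("covariate length does not match time series")
    if mask is not None:
        if mask.n_frames != ts.shape[1]:
            raise ValueError("censor mask length does not match time series")
        ts = ts[:, mask.keep]
        covariates = covariates[:, mask.keep]
    design = np.hstack([covariates.T, np.ones((covariates.shape[1], 1))])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate design is rank deficient (with intercept)")
    beta, *_ = np.linalg.lstsq(design, ts.T, rcond=None)
    resid = (ts.T - design @ beta).T
    # channels (numerically) absorbed by the covariates are degenerate:
    # zero them so their edges are flagged invalid instead of carrying
    # machine-noise correlations
    scale = np.linalg.norm(ts, axis=1)
    absorbed = np.linalg.norm(resid, axis=1) <= 1e-10 * np.maximum(scale, 1e-300)
    resid[absorbed] = 0.0
    cm = correlation_matrix(resid, mask=None, min_frames=min(3, min_frames),
                            subject_id=subject_id)
    cm.n_frames_used = ts.shape[1]
    return cm


def edge_distances(rois: RoiSet) -> np.ndarray:
    """Per-edge Euclidean distance (mm) between ROI centers, in canonical
    edge order (scipy's condensed pdist order matches the row-major upper
    triangle)."""
    return pdist(rois.coords)
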