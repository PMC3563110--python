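"""Edge-wise age association, FDR control, the short/long-range distance
analysis, and the frame-removal degradation simulation.

The age association correlates every Fisher-z edge with subject age
(optionally partially, controlling each subject's mean FD), applies
Benjamini-Hochberg FDR, and splits the significant edges by the sign of
the age correlation: edges strengthening with age versus weakening.
Comparing the Euclidean ROI distances of the two sets quantifies the
short-range/long-range developmental pattern that motion artifact is
known to mimic.

The frame-removal simulation quantifies how much a low-motion reference
subject's correlation matrix degrades when real censoring patterns
(donor masks from high-motion subjects) are imposed on it, either by
recomputing on the retained frames or by cubic-spline imputation of the
censored frames.  Degradation is measured as 1 - r between the
vectorized upper triangles of the baseline and degraded matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats
from scipy.interpolate import CubicSpline

from .connectivity import correlation_matrix
from .io import CensorMask

__all__ = [
    "AgeAssociation",
    "DistanceSplit",
    "edge_age_correlation",
    "bh_fdr",
    "distance_split",
    "frame_removal_simulation",
]


@dataclass
class AgeAssociation:
    """Per-edge age correlation with FDR flags."""

    r: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    tested: np.ndarray           # edges entering the test (valid across subjects)
    distance: np.ndarray | None = None
    partial: bool = False

    @property
    def stronger_with_age(self) -> np.ndarray:
        return self.significant & (self.r > 0)

    @property
    def weaker_with_age(self) -> np.ndarray:
        return self.significant & (self.r < 0)


def _pearson_columns(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of every column of X with y (columns with zero variance
    get r = 0)."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r[~np.isfinite(r)] = 0.0
    return np.clip(r, -1.0, 1.0)


def _residualize(v: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    design = np.column_stack([covariates, np.ones(covariates.shape[0])])
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def edge_age_correlation(Z: np.ndarray, ages: np.ndarray,
                         covariate: np.ndarray | None = None,
                         valid: np.ndarray | None = None,
                         q: float = 0.05,
                         distance: np.ndarray | None = None) -> AgeAssociation:
    """Correlate each edge's Fisher-z values with age across subjects.

    ``Z`` is subjects x edges.  With ``covariate`` (e.g. per-subject mean
    FD) the partial correlation is computed as the correlation of OLS
    residuals of both edge values and age on the covariate, with one
    degree of freedom charged per covariate column.  Edges invalid for any
    subject are skipped and flagged (``tested`` False, p = 1).
    """
    Z = np.asarray(Z, dtype=float)
    ages = np.asarray(ages, dtype=float)
    n, m = Z.shape
    if n < 10:
        raise ValueError("age association needs at least 10 subjects")
    if ages.size != n:
        raise ValueError("ages length does not match the matrix stack")
    tested = np.ones(m, dtype=bool) if valid is None else np.asarray(valid, bool).copy()
    tested &= np.all(np.isfinite(Z), axis=0)

    n_cov = 0
    y = ages
    X = Z
    if covariate is not None:
        cov = np.atleast_2d(np.asarray(covariate, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        n_cov = cov.shape[1]
        y = _residualize(ages, cov)
        X = Z - np.column_stack([cov, np.ones(n)]) @ np.linalg.lstsq(
            np.column_stack([cov, np.ones(n)]), Z, rcond=None)[0]

    r = np.zeros(m)
    r[tested] = _pearson_columns(X[:, tested], y)
    df = n - 2 - n_cov
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
    p = np.ones(m)
    finite_t = np.isfinite(t) & tested
    p[finite_t] = 2.0 * _stats.t.sf(np.abs(t[finite_t]), df)
    p[tested & ~finite_t] = 0.0  # |r| = 1 exactly
    significant = np.zeros(m, dtype=bool)
    significant[tested] = bh_fdr(p[tested], q)
    return AgeAssociation(r=r, p=p, significant=significant, tested=tested,
                          distance=distance, partial=covariate is not None)


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: reject the hypotheses with the k
    smallest p-values where k is the largest index with
    ``p_(k) <= k * q / m``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    passes = ranked <= (np.arange(1, m + 1) * q / m)
    reject = np.zeros(m, dtype=bool)
    if passes.any():
        k = np.flatnonzero(passes).max()
        reject[order[: k + 1]] = True
    return reject


@dataclass
class DistanceSplit:
    """Distances of FDR-significant edges split by age-effect sign."""

    stronger_distances: np.ndarray
    weaker_distances: np.ndarray
    mean_stronger: float
    mean_weaker: float
    t_statistic: float
    p_value: float
    defined: bool

    @property
    def gap(self) -> float:
        """Mean long-range (stronger) minus short-range (weaker) distance."""
        return self.mean_stronger - self.mean_weaker


def distance_split(assoc: AgeAssociation,
                   distance: np.ndarray | None = None) -> DistanceSplit:
    """Split significant edges by sign of the age correlation and compare
    their ROI distances with a Welch two-sample t-test.

    With fewer than 2 edges on a side, the report is still produced but
    the test is marked undefined.
    """
    d = assoc.distance if distance is None else np.asarray(distance, dtype=float)
    if d is None:
        raise ValueError("no edge distances available")
    stronger = d[assoc.stronger_with_age]
    weaker = d[assoc.weaker_with_age]
    defined = stronger.size >= 2 and weaker.size >= 2
    if defined:
        t, p = _stats.ttest_ind(stronger, weaker, equal_var=False)
        t, p = float(t), float(p)
    else:
        t, p = float("nan"), float("nan")
    return DistanceSplit(
        stronger_distances=stronger,
        weaker_distances=weaker,
        mean_stronger=float(stronger.mean()) if stronger.size else float("nan"),
        mean_weaker=float(weaker.mean()) if weaker.size else float("nan"),
        t_statistic=t,
        p_value=p,
        defined=defined,
    )


# ---------------------------------------------------------------------------
# frame-removal degradation simulation
# ---------------------------------------------------------------------------

def _matrix_distance(baseline: np.ndarray, degraded: np.ndarray) -> float:
    """1 - Pearson r between the vectorized upper triangles."""
    iu = np.triu_indices(baseline.shape[0], k=1)
    a, b = baseline[iu], degraded[iu]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(1.0 - np.corrcoef(a, b)[0, 1])


def _spline_impute(ts: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Impute censored frames per ROI by natural cubic spline over frame
    index; frames outside the kept range take the nearest kept value."""
    out = ts.copy()
    kept_idx = np.flatnonzero(keep)
    missing = np.flatnonzero(~keep)
    if missing.size == 0:
        return out
    if kept_idx.size < 4:
        raise ValueError("too few retained frames for spline imputation")
    inside = missing[(missing > kept_idx[0]) & (missing < kept_idx[-1])]
    before = missing[missing <= kept_idx[0]]
    after = missing[missing >= kept_idx[-1]]
    spline = CubicSpline(kept_idx, ts[:, kept_idx], axis=1, bc_type="natural")
    if inside.size:
        out[:, inside] = spline(inside)
    if before.size:
        out[:, before] = ts[:, [kept_idx[0]]]
    if after.size:
        out[:, after] = ts[:, [kept_idx[-1]]]
    return out


def frame_removal_simulation(references: dict[str, np.ndarray],
                             donor_masks: dict[str, CensorMask],
                             variant: str = "both") -> pd.DataFrame:
    """Impose each donor's censoring pattern on each low-motion reference.

    ``references`` maps reference subject id to a cleaned ROI x time
    series; ``donor_masks`` maps donor id to its censor mask.  A donor
    mask longer than the reference run is truncated with a warning.
    Returns a tidy frame with columns reference, donor, variant,
    fraction_removed, distance.
    """
    if variant not in ("censor", "spline", "both"):
        raise ValueError(f"unknown variant {variant!r}")
    variants = ["censor", "spline"] if variant == "both" else [variant]
    rows: list[dict] = []
    for ref_id, ts in references.items():
        ts = np.atleast_2d(np.asarray(ts, dtype=float))
        T = ts.shape[1]
        baseline = correlation_matrix(ts, min_frames=3).r
        for donor_id, mask in donor_masks.items():
            keep = mask.keep
            if keep.size > T:
                warnings.warn(
                    f"donor mask {donor_id} ({keep.size} frames) truncated to "
                    f"reference run length {T}",
                    RuntimeWarning,
                    stacklevel=2,
                )
                keep = keep[:T]
            elif keep.size < T:
                keep = np.concatenate([keep, np.ones(T - keep.size, dtype=bool)])
            frac = float(1.0 - keep.mean())
            for var in variants:
                if keep.all():
                    dist = 0.0  # nothing removed: degraded == baseline
                elif keep.sum() < 4:
                    dist = float("nan")
                elif var == "censor":
                    degraded = correlation_matrix(ts[:, keep], min_frames=3).r
                    dist = _matrix_distance(baseline, degraded)
                else:
                    degraded = correlation_matrix(_spline_impute(ts, keep),
                                                  min_frames=3).r
                    dist = _matrix_distance(baseline, degraded)
                rows.append({
                    "reference": ref_id,
                    "donor": donor_id,
                    "variant": var,
                    "fraction_removed": frac,
                    "distance": dist,
                })
    return pd.DataFrame(rows)
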