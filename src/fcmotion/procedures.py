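"""The ten motion-correction procedures as a configurable strategy layer.

Each procedure combines a subject-level transform (how a subject's
connectivity matrix is computed), an optional cohort-level action
(mean-motion covariate or subject "matching"), and an eligibility rule
on the fraction of censored frames:

====  ============================================================  ================  ==============
id    subject-level transform                                       cohort action     eligibility
====  ============================================================  ================  ==============
P1    regression of the 6 realignment parameters during cleaning    none              none
P2    P1 cleaning + partial correlation on the 6 frame-to-frame     none              none
      backward-difference parameters
P3    P1 cleaning + partial correlation on FD                       none              none
P4    cleaning regresses the 6 frame-to-frame parameters instead    none              none
      of the realignment parameters
P5    P1 matrices                                                   mean-FD age       none
                                                                    covariate
P6    P1 matrices                                                   mean-FD matching  none
P7    P1 cleaning + FD > 0.2 mm censoring (1 before / 2 after)      none              < 60% removed
P8    as P7                                                         post-censor       < 60% removed
                                                                    mean-FD matching
P9    P1 cleaning + DVARS > 4 censoring                             post-censor mean  < 60% removed
                                                                    -DVARS matching
P10   polynomial distance correction of P1 r-values using the       none              >= 40% frames
      censoring-induced delta-r (no frame loss in the estimate)                       remaining
====  ============================================================  ================  ==============

Subject matching removes subjects greedily until the motion summary is
statistically unrelated to age.  The polynomial correction is exposed
both as a function and as the sklearn-style
:class:`PolynomialDistanceCorrection` estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats
from sklearn.base import BaseEstimator, TransformerMixin

from . import connectivity as _conn
from . import motion as _motion
from .config import AnalysisConfig
from .connectivity import ConnectivityMatrix
from .io import CensorMask
from .synthetic import SubjectData

__all__ = [
    "ProcedureSpec",
    "PROCEDURES",
    "PolynomialDistanceCorrection",
    "apply_procedure",
    "match_subjects",
    "fit_polynomial_correction",
    "eligibility_filter",
]


@dataclass(frozen=True)
class ProcedureSpec:
    """One motion-correction procedure (a row of the strategy table)."""

    id: str
    transform: str            # subject-level pipeline
    cohort_action: str = "none"
    eligibility: str = "none"  # none | lt60_removed | ge40_remaining
    censor_metric: str = "none"


PROCEDURES: dict[str, ProcedureSpec] = {
    "P1": ProcedureSpec("P1", transform="traditional"),
    "P2": ProcedureSpec("P2", transform="partial_frame_params"),
    "P3": ProcedureSpec("P3", transform="partial_fd"),
    "P4": ProcedureSpec("P4", transform="frame_param_regression"),
    "P5": ProcedureSpec("P5", transform="traditional", cohort_action="mean_fd_covariate"),
    "P6": ProcedureSpec("P6", transform="traditional", cohort_action="fd_matching"),
    "P7": ProcedureSpec("P7", transform="censor", eligibility="lt60_removed",
                        censor_metric="fd"),
    "P8": ProcedureSpec("P8", transform="censor", cohort_action="fd_matching_postcensor",
                        eligibility="lt60_removed", censor_metric="fd"),
    "P9": ProcedureSpec("P9", transform="censor", cohort_action="dvars_matching_postcensor",
                        eligibility="lt60_removed", censor_metric="dvars"),
    "P10": ProcedureSpec("P10", transform="poly_correction", eligibility="ge40_remaining",
                         censor_metric="fd"),
}


def _frame_params(subject: SubjectData) -> np.ndarray:
    """Six frame-to-frame backward-difference parameters (first row 0)."""
    p = subject.realignment.params
    return np.diff(p, axis=0, prepend=p[:1, :]).T


def _clean(subject: SubjectData, config: AnalysisConfig,
           motion_regressors: np.ndarray) -> np.ndarray:
    """Band-pass then nuisance+motion regression of the ROI time series."""
    ts = _conn.bandpass(subject.roi_ts, subject.tr_seconds,
                        f_lo=config.f_lo, f_hi=config.f_hi)
    nuis = np.vstack([subject.nuisance, motion_regressors])
    return _conn.nuisance_regress(ts, nuis)


def _fd(subject: SubjectData, config: AnalysisConfig) -> np.ndarray:
    return _motion.compute_fd(subject.realignment, radius_mm=config.radius_mm)


def _dvars(subject: SubjectData) -> np.ndarray:
    if subject.channels is None:
        raise ValueError(
            "procedure requires channel-level data for DVARS, none available"
        )
    return _motion.compute_dvars(subject.channels)


def apply_procedure(subject: SubjectData, spec: ProcedureSpec,
                    config: AnalysisConfig | None = None,
                    distances: np.ndarray | None = None,
                    ) -> tuple[ConnectivityMatrix, CensorMask | None, bool]:
    """Dispatch one subject through a procedure's subject-level pipeline.

    Returns ``(matrix, censor_mask_or_None, eligible)``.  Cohort-level
    actions (covariates, matching) are handled by the callers that see the
    whole cohort.  ``distances`` (canonical edge order, mm) is required
    for the polynomial-correction transform.
    """
    config = config or AnalysisConfig()
    traditional = subject.realignment.params.T

    if spec.transform == "traditional":
        ts = _clean(subject, config, traditional)
        return _conn.correlation_matrix(ts, min_frames=config.min_frames,
                                        subject_id=subject.subject_id), None, True

    if spec.transform == "frame_param_regression":
        ts = _clean(subject, config, _frame_params(subject))
        return _conn.correlation_matrix(ts, min_frames=config.min_frames,
                                        subject_id=subject.subject_id), None, True

    if spec.transform == "partial_frame_params":
        ts = _clean(subject, config, traditional)
        cm = _conn.partial_correlation_matrix(ts, _frame_params(subject),
                                              min_frames=config.min_frames,
                                              subject_id=subject.subject_id)
        return cm, None, True

    if spec.transform == "partial_fd":
        ts = _clean(subject, config, traditional)
        cm = _conn.partial_correlation_matrix(ts, _fd(subject, config)[None, :],
                                              min_frames=config.min_frames,
                                              subject_id=subject.subject_id)
        return cm, None, True

    if spec.transform == "censor":
        ts = _clean(subject, config, traditional)
        if spec.censor_metric == "fd":
            metric, thr = _fd(subject, config), config.fd_threshold
        else:
            metric, thr = _dvars(subject), config.dvars_threshold
        mask = _motion.make_censor_mask(metric, thr, n_before=config.frames_before,
                                        n_after=config.frames_after,
                                        source_metric=spec.censor_metric)
        eligible = _eligible(mask, spec.eligibility)
        if mask.n_kept < max(config.min_frames, 3):
            return (_conn.correlation_matrix(ts, min_frames=config.min_frames,
                                             subject_id=subject.subject_id),
                    mask, False)
        cm = _conn.correlation_matrix(ts, mask=mask, min_frames=min(
            config.min_frames, mask.n_kept), subject_id=subject.subject_id)
        return cm, mask, eligible

    if spec.transform == "poly_correction":
        if distances is None:
            raise ValueError("P10 requires per-edge ROI distances")
        ts = _clean(subject, config, traditional)
        original = _conn.correlation_matrix(ts, min_frames=config.min_frames,
                                            subject_id=subject.subject_id)
        mask = _motion.make_censor_mask(_fd(subject, config), config.fd_threshold,
                                        n_before=config.frames_before,
                                        n_after=config.frames_after,
                                        source_metric="fd")
        eligible = _eligible(mask, spec.eligibility)
        if not eligible or mask.n_kept < max(config.min_frames, 3):
            return original, mask, False
        scrubbed = _conn.correlation_matrix(ts, mask=mask, min_frames=min(
            config.min_frames, mask.n_kept), subject_id=subject.subject_id)
        _, corrected = fit_polynomial_correction(original, scrubbed, distances,
                                                 degree=config.poly_degree)
        return corrected, mask, True

    raise ValueError(f"unknown procedure transform {spec.transform!r}")


def _eligible(mask: CensorMask, rule: str) -> bool:
    if rule == "none":
        return True
    if rule == "lt60_removed":
        return mask.fraction_removed < 0.60
    if rule == "ge40_remaining":
        return (1.0 - mask.fraction_removed) >= 0.40
    raise ValueError(f"unknown eligibility rule {rule!r}")


def eligibility_filter(masks: list[CensorMask | None], rule: str,
                       subject_ids: list[str] | None = None,
                       ) -> tuple[np.ndarray, list[dict]]:
    """Apply an eligibility rule across a cohort.

    Subjects without a censor mask (procedures that do not censor) are
    always retained.  Returns a boolean retention array and an exclusion
    log of ``{subject_id, fraction_removed, rule}`` records.
    """
    ids = subject_ids or [f"subject{k}" for k in range(len(masks))]
    retained = np.ones(len(masks), dtype=bool)
    log: list[dict] = []
    for k, mask in enumerate(masks):
        if mask is None:
            continue
        if not _eligible(mask, rule):
            retained[k] = False
            log.append({"subject_id": ids[k],
                        "fraction_removed": mask.fraction_removed,
                        "rule": rule})
    return retained, log


# ---------------------------------------------------------------------------
# subject matching (Procedures 6, 8, 9)
# ---------------------------------------------------------------------------

def match_subjects(motion_summary: np.ndarray, target: np.ndarray,
                   subject_ids: list[str] | None = None, alpha: float = 0.05,
                   max_removed_frac: float = 0.5,
                   ) -> tuple[np.ndarray, list[dict], float]:
    """Greedy motion matching: remove subjects until the motion summary is
    unrelated to the target (Pearson p >= alpha).

    Each step removes the single subject whose exclusion maximally reduces
    |r| (exhaustive single-removal scan); ties break on lexicographic
    subject id, making the loop deterministic.  Aborts when more than
    ``max_removed_frac`` of the cohort would be removed.

    Returns ``(retained_bool, removal_log, final_p)``.
    """
    motion_summary = np.asarray(motion_summary, dtype=float)
    target = np.asarray(target, dtype=float)
    n = motion_summary.size
    if n < 10:
        raise ValueError("matching needs at least 10 subjects")
    ids = subject_ids or [f"subject{k}" for k in range(n)]
    retained = np.ones(n, dtype=bool)
    log: list[dict] = []

    def corr_p(mask: np.ndarray) -> tuple[float, float]:
        x, y = motion_summary[mask], target[mask]
        if x.std() == 0 or y.std() == 0:
            return 0.0, 1.0
        res = _stats.pearsonr(x, y)
        return float(res.statistic), float(res.pvalue)

    r, p = corr_p(retained)
    while p < alpha:
        if retained.sum() - 1 < n * (1 - max_removed_frac):
            raise RuntimeError(
                f"matching would remove more than {max_removed_frac:.0%} of the "
                f"cohort (|r| = {abs(r):.3f}, p = {p:.3g} with "
                f"{int(retained.sum())} subjects left); cohort cannot be matched"
            )
        candidates = np.flatnonzero(retained)
        best = None
        for k in candidates:
            trial = retained.copy()
            trial[k] = False
            r_k, _ = corr_p(trial)
            key = (abs(r_k), ids[k])
            if best is None or key < best[0]:
                best = (key, k, r_k)
        _, drop, _ = best
        retained[drop] = False
        r, p = corr_p(retained)
        log.append({"subject_id": ids[drop], "abs_r_after": abs(r), "p_after": p})
    return retained, log, p


# ---------------------------------------------------------------------------
# polynomial distance correction (Procedure 10)
# ---------------------------------------------------------------------------

class PolynomialDistanceCorrection(BaseEstimator, TransformerMixin):
    """Per-subject polynomial correction of the distance-dependent
    censoring effect on correlation values.

    Fit on ``(distance_e, delta_r_e)`` pairs where
    ``delta_r = scrubbed r - original r``; ``transform`` adds the
    predicted delta to original r-values, approximating the scrubbed
    estimate without frame loss.  The fit is on r (not z); z is
    recomputed from corrected r downstream.

    Parameters
    ----------
    degree : polynomial degree (the constant term is included).

    Attributes
    ----------
    coef_ : ascending-power polynomial coefficients, length degree + 1.
    precorrection_corr_ : Pearson correlation of delta_r with distance
        before correction.
    """

    def __init__(self, degree: int = 3):
        self.degree = degree

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PolynomialDistanceCorrection":
        d = np.asarray(X, dtype=float).reshape(-1)
        delta = np.asarray(y, dtype=float).reshape(-1)
        if d.size != delta.size or d.size < self.degree + 1:
            raise ValueError("need at least degree + 1 (distance, delta) pairs")
        self.coef_ = np.polynomial.polynomial.polyfit(d, delta, deg=self.degree)
        if d.std() > 0 and delta.std() > 0:
            self.precorrection_corr_ = float(np.corrcoef(d, delta)[0, 1])
        else:
            self.precorrection_corr_ = 0.0
        self.n_features_in_ = 1
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = np.asarray(X, dtype=float).reshape(-1)
        return np.polynomial.polynomial.polyval(d, self.coef_)

    def transform(self, X: np.ndarray, r_values: np.ndarray | None = None) -> np.ndarray:
        """Corrected r-values: ``r + poly(distance)``, clipped into (-1, 1)."""
        pred = self.predict(X)
        if r_values is None:
            return pred
        return np.clip(np.asarray(r_values, dtype=float) + pred,
                       -1 + 1e-7, 1 - 1e-7)


def fit_polynomial_correction(original: ConnectivityMatrix,
                              scrubbed: ConnectivityMatrix,
                              distances: np.ndarray, degree: int = 3,
                              ) -> tuple[PolynomialDistanceCorrection, ConnectivityMatrix]:
    """Fit the censoring-delta polynomial and return the corrected matrix.

    Fits on edges valid in both matrices; validity flags of the original
    matrix are preserved.  The model records a self-check statistic,
    ``residual_corr_``: the correlation between the residual delta
    (scrubbed - corrected) and distance, which a successful correction
    drives toward zero.
    """
    if original.n_rois != scrubbed.n_rois:
        raise ValueError("matrices are not on the same ROI set")
    iu, ju = _conn.edge_index(original.n_rois)
    dist = np.asarray(distances, dtype=float)
    if dist.size != original.n_edges:
        raise ValueError("distance vector does not match the edge count")
    ok = original.edge_vector("valid") & scrubbed.edge_vector("valid")
    delta = scrubbed.edge_vector("r") - original.edge_vector("r")
    model = PolynomialDistanceCorrection(degree=degree).fit(dist[ok], delta[ok])

    corrected_edges = model.transform(dist, r_values=original.edge_vector("r"))
    resid = delta[ok] - model.predict(dist[ok])
    if dist[ok].std() > 0 and resid.std() > 0:
        model.residual_corr_ = float(np.corrcoef(dist[ok], resid)[0, 1])
    else:
        model.residual_corr_ = 0.0

    r = original.r.copy()
    r[iu, ju] = corrected_edges
    r[ju, iu] = corrected_edges
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    corrected = ConnectivityMatrix(r=r, z=z, valid=original.valid.copy(),
                                   n_frames_used=original.n_frames_used,
                                   subject_id=original.subject_id)
    return model, corrected
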