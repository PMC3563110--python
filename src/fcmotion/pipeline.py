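"""Cohort-level orchestration: run a motion-correction procedure over a
whole cohort and hand the result to the age or classification analyses.

This is the glue between the per-subject procedure dispatch and the
group statistics: it computes every subject's matrix, applies the
procedure's eligibility rule and cohort action (mean-FD covariate or
motion matching), and stacks the surviving subjects' Fisher-z edges into
a subjects x edges feature matrix with a shared validity mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import motion as _motion
from .age import AgeAssociation, DistanceSplit, distance_split, edge_age_correlation
from .config import AnalysisConfig
from .connectivity import edge_distances
from .io import CensorMask
from .procedures import PROCEDURES, apply_procedure, eligibility_filter, match_subjects
from .synthetic import Cohort

__all__ = ["CohortProcedureResult", "run_cohort_procedure", "run_age_analysis"]

logger = logging.getLogger(__name__)


@dataclass
class CohortProcedureResult:
    """Stacked output of one procedure over one cohort (retained subjects)."""

    procedure: str
    Z: np.ndarray                 # n_retained x n_edges Fisher-z features
    valid: np.ndarray             # per-edge: valid for every retained subject
    ages: np.ndarray
    subject_ids: list[str]
    labels: np.ndarray            # diagnosis per retained subject
    covariate: np.ndarray | None  # mean FD, for covariate-style procedures
    distances: np.ndarray         # per-edge ROI distance, mm
    retained: np.ndarray          # over the input cohort order
    masks: list[CensorMask | None]
    exclusion_log: list[dict]


def run_cohort_procedure(cohort: Cohort, proc_id: str,
                         config: AnalysisConfig | None = None,
                         ) -> CohortProcedureResult:
    """Apply one procedure to every cohort subject and resolve its
    eligibility rule and cohort-level action."""
    config = config or AnalysisConfig()
    spec = PROCEDURES[proc_id]
    distances = edge_distances(cohort.rois)

    z_rows, valid_rows, masks, eligible = [], [], [], []
    mean_fd_pre, mean_post = [], []
    for subject in cohort.subjects:
        cm, mask, ok = apply_procedure(subject, spec, config, distances=distances)
        z_rows.append(cm.edge_vector("z"))
        valid_rows.append(cm.edge_vector("valid"))
        masks.append(mask)
        eligible.append(ok)
        fd = _motion.compute_fd(subject.realignment, radius_mm=config.radius_mm)
        mean_fd_pre.append(float(fd.mean()))
        if spec.cohort_action == "dvars_matching_postcensor":
            metric = _motion.compute_dvars(subject.channels)
        else:
            metric = fd
        mean_post.append(float(metric[mask.keep].mean())
                         if mask is not None and mask.n_kept else float(metric.mean()))

    ids = [s.subject_id for s in cohort.subjects]
    ages = cohort.table["age"].to_numpy(dtype=float)
    labels = cohort.table["diagnosis"].to_numpy()
    retained = np.asarray(eligible, dtype=bool)
    log: list[dict] = [
        {"subject_id": ids[k], "reason": f"eligibility ({spec.eligibility})"}
        for k in np.flatnonzero(~retained)
    ]
    for entry in log:
        logger.info("excluded %s: %s", entry["subject_id"], entry["reason"])

    covariate = None
    if spec.cohort_action == "mean_fd_covariate":
        covariate = np.asarray(mean_fd_pre)
    elif spec.cohort_action in ("fd_matching", "fd_matching_postcensor",
                                "dvars_matching_postcensor"):
        summary = np.asarray(
            mean_fd_pre if spec.cohort_action == "fd_matching" else mean_post)
        idx = np.flatnonzero(retained)
        kept, match_log, final_p = match_subjects(
            summary[idx], ages[idx], [ids[k] for k in idx],
            alpha=config.match_alpha)
        for entry in match_log:
            logger.info("matching removed %s (p -> %.3g)",
                        entry["subject_id"], entry["p_after"])
            log.append({"subject_id": entry["subject_id"],
                        "reason": "motion matching"})
        retained[idx[~kept]] = False

    keep_idx = np.flatnonzero(retained)
    Z = np.asarray(z_rows)[keep_idx]
    valid = np.all(np.asarray(valid_rows)[keep_idx], axis=0)
    return CohortProcedureResult(
        procedure=proc_id,
        Z=Z,
        valid=valid,
        ages=ages[keep_idx],
        subject_ids=[ids[k] for k in keep_idx],
        labels=labels[keep_idx],
        covariate=None if covariate is None else covariate[keep_idx],
        distances=distances,
        retained=retained,
        masks=masks,
        exclusion_log=log,
    )


def run_age_analysis(result: CohortProcedureResult,
                     q: float = 0.05) -> tuple[AgeAssociation, DistanceSplit]:
    """Edge-wise age association (with the procedure's covariate, if any)
    followed by the short/long-range distance split."""
    assoc = edge_age_correlation(result.Z, result.ages,
                                 covariate=result.covariate,
                                 valid=result.valid, q=q,
                                 distance=result.distances)
    return assoc, distance_split(assoc)
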