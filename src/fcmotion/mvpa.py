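"""SVR brain-maturity prediction, growth-curve normalization (fcMI), and
LOOCV SVM subtype classification with confound adjustment.

All learners follow the conventions of the source analyses: an RBF kernel
parameterized by sigma, ``K(x, y) = exp(-||x - y||^2 / (2 sigma^2))``
with sigma = 2 (the solver's rate parameter is ``gamma = 1/(2 sigma^2)``),
epsilon-insensitive SVR with a hard-margin surrogate ``C = 1e6`` and
``epsilon = 1e-5`` for age, and a soft-margin SVM with ``C = 1`` for
diagnosis; multiclass problems use one-vs-rest with winner-takes-all on
the decision values.  Feature vectors are Fisher-z edge values used
unstandardized by default.

Univariate feature filtering (top-300 age-correlated edges passing FDR
for regression; top-150 t-test/ANOVA edges for classification) is redone
inside every leave-one-out fold, so the held-out subject never informs
the selection.

Predicted ages are summarized by a Von Bertalanffy growth curve
``a * (1 - exp(-b * age))``; the functional connectivity maturity index
(fcMI) rescales predictions so the fitted curve equals 1 at the oldest
chronological age.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin, clone
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import LeaveOneOut
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC, SVR
from sklearn.utils.validation import check_is_fitted

from .age import bh_fdr
from .config import AnalysisConfig

__all__ = [
    "UnivariateFeatureFilter",
    "VonBertalanffyGrowth",
    "ConfoundAdjuster",
    "GrowthModel",
    "ClassificationReport",
    "univariate_filter",
    "loocv_svr_age",
    "fit_growth_curve",
    "confound_adjust",
    "loocv_svm_classify",
    "balance_groups",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# univariate feature filtering
# ---------------------------------------------------------------------------

class UnivariateFeatureFilter(SelectorMixin, BaseEstimator):
    """Top-k univariate feature filter.

    Modes
    -----
    ``age_corr_fdr`` : rank by |Pearson r| with a continuous target and
        additionally require a BH-FDR pass at ``fdr_q``; when fewer than
        k features pass, all passers are returned (logged).
    ``ttest`` : rank by |two-sample t| (exactly 2 classes).
    ``anova`` : rank by one-way ANOVA F across classes.

    Ties break on the lower feature (edge) index.
    """

    def __init__(self, mode: str = "anova", k: int = 150, fdr_q: float = 0.05):
        self.mode = mode
        self.k = k
        self.fdr_q = fdr_q

    def _scores(self, X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (score, eligible) per feature."""
        n, m = X.shape
        eligible = np.ones(m, dtype=bool)
        if self.mode == "age_corr_fdr":
            Xc = X - X.mean(axis=0)
            yc = y - y.mean()
            sx = np.sqrt((Xc ** 2).sum(axis=0))
            sy = np.sqrt((yc ** 2).sum())
            with np.errstate(divide="ignore", invalid="ignore"):
                r = (Xc.T @ yc) / (sx * sy)
            r[~np.isfinite(r)] = 0.0
            r = np.clip(r, -1, 1)
            df = n - 2
            with np.errstate(divide="ignore"):
                t = r * np.sqrt(df / (1 - r ** 2))
            p = np.where(np.isfinite(t), 2 * _stats.t.sf(np.abs(t), df), 0.0)
            eligible = bh_fdr(p, self.fdr_q)
            return np.abs(r), eligible
        if self.mode == "ttest":
            classes = np.unique(y)
            if classes.size != 2:
                raise ValueError("ttest mode requires exactly 2 classes")
            a, b = X[y == classes[0]], X[y == classes[1]]
            t, _ = _stats.ttest_ind(a, b, axis=0, equal_var=True)
            t = np.where(np.isfinite(t), t, 0.0)
            return np.abs(t), eligible
        if self.mode == "anova":
            classes = np.unique(y)
            if classes.size < 2:
                raise ValueError("anova mode requires >= 2 classes")
            groups = [X[y == c] for c in classes]
            f, _ = _stats.f_oneway(*groups, axis=0)
            f = np.where(np.isfinite(f), f, 0.0)
            return f, eligible
        raise ValueError(f"unknown mode {self.mode!r}")

    def fit(self, X, y):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        score, eligible = self._scores(X, y)
        self.scores_ = score
        n_eligible = int(eligible.sum())
        k = min(self.k, n_eligible) if self.mode == "age_corr_fdr" else min(
            self.k, X.shape[1])
        if self.mode == "age_corr_fdr" and n_eligible < self.k:
            logger.info(
                "only %d features pass FDR at q=%g (requested top %d); using all passers",
                n_eligible, self.fdr_q, self.k,
            )
        masked = np.where(eligible, score, -np.inf)
        # stable argsort on negated scores -> ties broken by feature index
        order = np.argsort(-masked, kind="stable")
        selected = order[:k]
        selected = selected[np.isfinite(masked[selected])]
        support = np.zeros(X.shape[1], dtype=bool)
        support[selected] = True
        self.support_ = support
        self.selected_indices_ = np.sort(selected)
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def univariate_filter(X, y, mode: str, k: int, fdr_q: float = 0.05) -> np.ndarray:
    """Selected feature indices (ascending) for a training set."""
    filt = UnivariateFeatureFilter(mode=mode, k=k, fdr_q=fdr_q).fit(X, y)
    return filt.selected_indices_


# ---------------------------------------------------------------------------
# SVR age prediction (LOOCV)
# ---------------------------------------------------------------------------

def loocv_svr_age(X: np.ndarray, ages: np.ndarray,
                  config: AnalysisConfig | None = None) -> np.ndarray:
    """Leave-one-out SVR age prediction with in-fold feature filtering.

    For each held-out subject the top-k (default 300) FDR-passing
    age-correlated features are selected on the remaining subjects, an
    epsilon-SVR (RBF, hard-margin surrogate) is trained, and the held-out
    subject's age predicted.  Returns the per-subject predictions.
    """
    config = config or AnalysisConfig()
    X = np.asarray(X, dtype=float)
    ages = np.asarray(ages, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("LOOCV age prediction needs at least 10 subjects")
    preds = np.full(n, np.nan)
    filt = UnivariateFeatureFilter(mode="age_corr_fdr", k=config.top_k_age,
                                   fdr_q=config.fdr_q)
    for train, test in LeaveOneOut().split(X):
        f = clone(filt).fit(X[train], ages[train])
        if f.selected_indices_.size == 0:
            preds[test] = ages[train].mean()
            continue
        svr = SVR(kernel="rbf", C=config.svr_c, epsilon=config.svr_epsilon,
                  gamma=config.gamma)
        svr.fit(X[np.ix_(train, f.selected_indices_)], ages[train])
        preds[test] = svr.predict(X[np.ix_(test, f.selected_indices_)])
    return preds


# ---------------------------------------------------------------------------
# Von Bertalanffy growth curve / fcMI
# ---------------------------------------------------------------------------

def _vb(x, a, b):
    return a * (1.0 - np.exp(-b * x))


class VonBertalanffyGrowth(BaseEstimator, RegressorMixin):
    """Saturating growth model ``a * (1 - exp(-b * age))`` fit by
    nonlinear least squares with deterministic multi-starts.

    Attributes (after fit): ``a_``, ``b_``, ``r_squared_``,
    ``resid_std_``, ``boundary_flag_`` (True when b collapses toward 0,
    i.e. the data carry no saturating trend).
    """

    #: multiplicative perturbations applied to the base start (a0, b0)
    _STARTS = [(1.0, 1.0), (0.5, 0.5), (2.0, 2.0), (1.0, 0.2), (1.5, 5.0)]

    def __init__(self, max_b: float = 50.0):
        self.max_b = max_b

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size or x.size < 5:
            raise ValueError("growth fit needs >= 5 (age, prediction) pairs")
        if np.any(x <= 0):
            raise ValueError("ages must be positive")
        a0 = max(float(np.max(y)), 1e-6)
        b0 = 0.1
        best = None
        errors = []
        for fa, fb in self._STARTS:
            try:
                popt, _ = curve_fit(
                    _vb, x, y, p0=[a0 * fa, b0 * fb],
                    bounds=([1e-9, 1e-9], [np.inf, self.max_b]), maxfev=20000,
                )
            except RuntimeError as exc:  # non-convergence for this start
                errors.append(str(exc))
                continue
            sse = float(np.sum((y - _vb(x, *popt)) ** 2))
            if best is None or sse < best[0]:
                best = (sse, popt)
        if best is None:
            raise RuntimeError(
                "growth-curve fit failed from all starts; data summary: "
                f"n={x.size}, age range=({x.min():.3g}, {x.max():.3g}), "
                f"prediction range=({y.min():.3g}, {y.max():.3g}); {errors[-1]}"
            )
        sse, (a, b) = best
        self.a_, self.b_ = float(a), float(b)
        sst = float(np.sum((y - y.mean()) ** 2))
        self.r_squared_ = 1.0 - sse / sst if sst > 0 else 0.0
        resid = y - _vb(x, a, b)
        self.resid_std_ = float(resid.std(ddof=min(2, x.size - 1)))
        self.boundary_flag_ = bool(b < 1e-6 or not np.isfinite(b))
        self.max_age_ = float(np.max(x))
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "a_")
        return _vb(np.asarray(X, dtype=float).reshape(-1), self.a_, self.b_)

    def maturity_index(self, predicted_ages: np.ndarray,
                       max_age: float | None = None) -> np.ndarray:
        """fcMI: predicted ages rescaled so the fitted curve equals 1 at
        the oldest chronological age."""
        check_is_fitted(self, "a_")
        ref = _vb(max_age if max_age is not None else self.max_age_,
                  self.a_, self.b_)
        return np.asarray(predicted_ages, dtype=float) / ref

    def prediction_limits(self, X, level: float = 0.90) -> tuple[np.ndarray, np.ndarray]:
        """Symmetric prediction limits from the residual spread."""
        check_is_fitted(self, "a_")
        zcrit = _stats.norm.ppf(0.5 + level / 2.0)
        fitted = self.predict(X)
        return fitted - zcrit * self.resid_std_, fitted + zcrit * self.resid_std_


@dataclass
class GrowthModel:
    """Growth-curve fit summary plus per-subject fcMI."""

    a: float
    b: float
    r_squared: float
    fcmi: np.ndarray
    lower_90: np.ndarray
    upper_90: np.ndarray
    boundary_flag: bool
    estimator: VonBertalanffyGrowth


def fit_growth_curve(predicted_ages: np.ndarray,
                     chronological_ages: np.ndarray) -> GrowthModel:
    """Fit the growth model of predicted on chronological age and derive
    per-subject fcMI and 90% prediction limits."""
    model = VonBertalanffyGrowth().fit(chronological_ages, predicted_ages)
    lo, hi = model.prediction_limits(chronological_ages, level=0.90)
    return GrowthModel(
        a=model.a_, b=model.b_, r_squared=model.r_squared_,
        fcmi=model.maturity_index(predicted_ages),
        lower_90=lo, upper_90=hi,
        boundary_flag=model.boundary_flag_, estimator=model,
    )


# ---------------------------------------------------------------------------
# confound adjustment
# ---------------------------------------------------------------------------

class ConfoundAdjuster(BaseEstimator, TransformerMixin):
    """Per-edge OLS confound adjustment retaining the diagnosis effect.

    Fits ``y = b0 + b1 * dx + b2 * site + b3 * sex + b4 * iq + e`` for
    every edge and returns ``b0 + b1 * dx + residual``: site, sex and IQ
    are partialled out while the diagnosis effect of interest is kept.
    Categorical site uses dummy coding (first site as reference).
    """

    def __init__(self):
        pass

    @staticmethod
    def _design(confounds: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
        dx = confounds["diagnosis_code"].to_numpy(dtype=float)
        cols = [np.ones(len(confounds)), dx]
        names = ["intercept", "diagnosis"]
        site = pd.get_dummies(confounds["site"].astype(str), drop_first=True)
        for c in site.columns:
            cols.append(site[c].to_numpy(dtype=float))
            names.append(f"site[{c}]")
        sex = confounds["sex"].astype(str)
        cols.append((sex == sorted(sex.unique())[-1]).to_numpy(dtype=float))
        names.append("sex")
        cols.append(confounds["iq"].to_numpy(dtype=float))
        names.append("iq")
        design = np.column_stack(cols)
        return design, dx, names

    def fit(self, X, confounds: pd.DataFrame):
        X = np.asarray(X, dtype=float)
        design, dx, names = self._design(confounds)
        if not np.all(np.isfinite(design)):
            raise ValueError("confound design contains non-finite values (missing IQ?)")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            keep: list[int] = []
            for j in range(design.shape[1]):
                if np.linalg.matrix_rank(design[:, keep + [j]]) > len(keep):
                    keep.append(j)
            bad = [names[j] for j in range(design.shape[1]) if j not in keep]
            raise ValueError(f"confound design is rank deficient; columns {bad}")
        self.coef_, *_ = np.linalg.lstsq(design, X, rcond=None)
        self.design_columns_ = names
        self.n_features_in_ = X.shape[1]
        self._design_cache = (design, dx)
        return self

    def transform(self, X, confounds: pd.DataFrame | None = None):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if confounds is None:
            design, dx = self._design_cache
        else:
            design, dx, _ = self._design(confounds)
        fitted = design @ self.coef_
        resid = X - fitted
        kept = self.coef_[0][None, :] + dx[:, None] * self.coef_[1][None, :]
        return kept + resid


def confound_adjust(X: np.ndarray, diagnosis: np.ndarray, site: np.ndarray,
                    sex: np.ndarray, iq: np.ndarray) -> np.ndarray:
    """Functional convenience wrapper over :class:`ConfoundAdjuster`.

    ``diagnosis`` may be strings (coded 0 for TDC, 1 otherwise) or a
    numeric code.
    """
    dx = np.asarray(diagnosis)
    if dx.dtype.kind in "UOS":
        dx = (dx != "TDC").astype(float)
    confounds = pd.DataFrame({
        "diagnosis_code": dx,
        "site": np.asarray(site).astype(str),
        "sex": np.asarray(sex).astype(str),
        "iq": np.asarray(iq, dtype=float),
    })
    adj = ConfoundAdjuster().fit(X, confounds)
    return adj.transform(X)


# ---------------------------------------------------------------------------
# LOOCV SVM classification
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    """LOOCV classification outcome with per-fold selections."""

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    per_class_accuracy: dict[str, float]
    predictions: np.ndarray
    fold_features: list[np.ndarray]
    consensus_features: np.ndarray
    classes: tuple[str, ...]


def loocv_svm_classify(X: np.ndarray, labels: np.ndarray,
                       config: AnalysisConfig | None = None,
                       positive_label: str | None = None) -> ClassificationReport:
    """Leave-one-out SVM classification with in-fold feature filtering.

    2-group problems filter with a two-sample t-test and report
    accuracy/sensitivity/specificity (the ADHD group as the positive
    class unless overridden); 3-group problems filter with one-way ANOVA
    and classify one-vs-rest with winner-takes-all on the decision
    values, reporting per-class and overall accuracy.  Groups must be
    balanced (use :func:`balance_groups` first).
    """
    config = config or AnalysisConfig()
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels).astype(str)
    classes = tuple(sorted(np.unique(labels)))
    counts = {c: int((labels == c).sum()) for c in classes}
    if len(set(counts.values())) != 1:
        raise ValueError(
            f"groups are unbalanced {counts}; subsample with balance_groups first"
        )
    if min(counts.values()) < 10:
        raise ValueError("need at least 10 subjects per group")
    mode = "ttest" if len(classes) == 2 else "anova"
    filt = UnivariateFeatureFilter(mode=mode, k=config.top_k_dx)
    preds = np.empty(labels.size, dtype=object)
    fold_features: list[np.ndarray] = []
    for train, test in LeaveOneOut().split(X):
        f = clone(filt).fit(X[train], labels[train])
        idx = f.selected_indices_
        fold_features.append(idx)
        svc = SVC(kernel="rbf", C=config.svm_c, gamma=config.gamma)
        if len(classes) == 2:
            svc.fit(X[np.ix_(train, idx)], labels[train])
            preds[test[0]] = svc.predict(X[np.ix_(test, idx)])[0]
        else:
            ovr = OneVsRestClassifier(svc)
            ovr.fit(X[np.ix_(train, idx)], labels[train])
            decision = ovr.decision_function(X[np.ix_(test, idx)])
            preds[test[0]] = ovr.classes_[int(np.argmax(decision))]
    preds = preds.astype(str)

    consensus = fold_features[0]
    for idx in fold_features[1:]:
        consensus = np.intersect1d(consensus, idx)
    accuracy = float((preds == labels).mean())
    per_class = {c: float((preds[labels == c] == c).mean()) for c in classes}
    sensitivity = specificity = None
    if len(classes) == 2:
        pos = positive_label or next(
            (c for c in classes if c.startswith("ADHD")), classes[1])
        neg = next(c for c in classes if c != pos)
        sensitivity = per_class[pos]
        specificity = per_class[neg]
    return ClassificationReport(
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        per_class_accuracy=per_class, predictions=preds,
        fold_features=fold_features, consensus_features=consensus,
        classes=classes,
    )


# ---------------------------------------------------------------------------
# balanced subsampling
# ---------------------------------------------------------------------------

def balance_groups(cohort: pd.DataFrame, size: int,
                   match_on: tuple[str, ...] = ("age",),
                   group_column: str = "diagnosis", seed: int = 0) -> pd.DataFrame:
    """Equal-size subsample per group, greedily matched on standardized
    covariates.

    The group closest in size to ``size`` provides the reference
    distribution (trimmed to its ``size`` members nearest the group
    centroid); for every reference subject each other group contributes
    its nearest unused member in covariate space.  Deterministic under
    ``seed`` (which only shuffles the reference visiting order).
    """
    groups = sorted(cohort[group_column].astype(str).unique())
    counts = cohort[group_column].value_counts()
    short = [g for g in groups if counts.get(g, 0) < size]
    if short:
        raise ValueError(
            f"insufficient subjects for size {size}: "
            + ", ".join(f"{g} has {counts.get(g, 0)}" for g in short)
        )
    covs = cohort[list(match_on)].to_numpy(dtype=float)
    sd = covs.std(axis=0)
    sd[sd == 0] = 1.0
    covs = (covs - covs.mean(axis=0)) / sd
    rng = np.random.default_rng(seed)

    ref_group = min(groups, key=lambda g: (counts[g], g))
    ref_rows = np.flatnonzero((cohort[group_column] == ref_group).to_numpy())
    if ref_rows.size > size:
        centroid = covs[ref_rows].mean(axis=0)
        dist = np.linalg.norm(covs[ref_rows] - centroid, axis=1)
        ref_rows = ref_rows[np.argsort(dist, kind="stable")[:size]]
    order = rng.permutation(ref_rows.size)

    selected = {ref_group: list(ref_rows)}
    for g in groups:
        if g == ref_group:
            continue
        pool = list(np.flatnonzero((cohort[group_column] == g).to_numpy()))
        chosen: list[int] = []
        for ref_i in ref_rows[order]:
            d = np.linalg.norm(covs[pool] - covs[ref_i], axis=1)
            j = int(np.argmin(d))
            chosen.append(pool.pop(j))
        selected[g] = sorted(chosen)
    rows = sorted(i for idxs in selected.values() for i in idxs)
    out = cohort.iloc[rows].reset_index(drop=True)
    for g in groups:
        sub = out[out[group_column] == g]
        logger.info("balanced group %s: n=%d, %s", g, len(sub),
                    {c: round(float(sub[c].mean()), 3) for c in match_on})
    return out
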