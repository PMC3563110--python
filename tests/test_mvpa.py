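"""Feature filtering, SVR age prediction, growth-curve fitting, confound
adjustment, LOOCV SVM classification, and balanced subsampling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics.pairwise import rbf_kernel

from fcmotion.config import AnalysisConfig
from fcmotion.mvpa import (
    ConfoundAdjuster,
    UnivariateFeatureFilter,
    VonBertalanffyGrowth,
    balance_groups,
    confound_adjust,
    fit_growth_curve,
    loocv_svm_classify,
    loocv_svr_age,
    univariate_filter,
)


class TestUnivariateFilter:
    def test_perfect_feature_ranked_first(self, rng):
        y = rng.uniform(7, 14, 40)
        X = np.column_stack([y, rng.normal(size=(40, 30))])
        idx = univariate_filter(X, y, mode="age_corr_fdr", k=5)
        assert 0 in idx

    def test_fewer_passers_than_k(self, rng):
        y = rng.uniform(7, 14, 30)
        X = np.column_stack([y + rng.normal(0, 0.1, 30),
                             rng.normal(size=(30, 50))])
        idx = univariate_filter(X, y, mode="age_corr_fdr", k=40)
        assert idx.size < 40  # only FDR passers are returned

    def test_ttest_ranking_matches_brute_force(self, rng):
        labels = np.repeat(["a", "b"], 10)
        X = rng.normal(size=(20, 50))
        idx = univariate_filter(X, labels, mode="ttest", k=7)
        t = np.array([stats.ttest_ind(X[:10, j], X[10:, j]).statistic
                      for j in range(50)])
        expect = np.sort(np.argsort(-np.abs(t), kind="stable")[:7])
        np.testing.assert_array_equal(idx, expect)

    def test_anova_matches_sklearn_f_classif(self, rng):
        from sklearn.feature_selection import f_classif

        labels = np.repeat(["a", "b", "c"], 8)
        X = rng.normal(size=(24, 40))
        filt = UnivariateFeatureFilter(mode="anova", k=10).fit(X, labels)
        f_ref, _ = f_classif(X, labels)
        np.testing.assert_allclose(filt.scores_, f_ref, atol=1e-8)

    def test_k_below_one_rejected(self, rng):
        with pytest.raises(ValueError):
            univariate_filter(rng.normal(size=(20, 5)),
                              np.repeat(["a", "b"], 10), mode="ttest", k=0)

    def test_sklearn_transform_selects_columns(self, rng):
        y = rng.uniform(7, 14, 30)
        X = rng.normal(size=(30, 20))
        X[:, 3] = y
        filt = UnivariateFeatureFilter(mode="age_corr_fdr", k=1).fit(X, y)
        np.testing.assert_array_equal(filt.transform(X), X[:, [3]])


class TestKernelConvention:
    def test_sigma_to_gamma_conversion(self, rng):
        """gamma = 1/(2 sigma^2) reproduces exp(-||x-y||^2/(2 sigma^2))."""
        cfg = AnalysisConfig(kernel_sigma=2.0)
        X = rng.normal(size=(10, 4))
        explicit = np.exp(
            -((X[:, None, :] - X[None, :, :]) ** 2).sum(-1) / (2 * 2.0 ** 2))
        np.testing.assert_allclose(rbf_kernel(X, gamma=cfg.gamma), explicit,
                                   atol=1e-12)
        assert cfg.gamma == pytest.approx(0.125)

    def test_kernel_matrix_is_psd(self, rng):
        X = rng.normal(size=(40, 12))
        K = rbf_kernel(X, gamma=0.125)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestLoocvSvr:
    def test_recovers_linear_age_signal(self, rng):
        ages = rng.uniform(7, 14, 60)
        informative = np.outer(ages, rng.normal(size=5) / 10)
        X = np.hstack([informative, rng.normal(size=(60, 45))])
        preds = loocv_svr_age(X, ages)
        assert np.corrcoef(preds, ages)[0, 1] > 0.95

    def test_constant_features_predict_near_mean(self, rng):
        ages = rng.uniform(7, 14, 20)
        X = np.ones((20, 10))
        preds = loocv_svr_age(X, ages)
        assert np.all(np.abs(preds - ages.mean()) < 2.0)

    def test_permuted_ages_leave_no_growth_fit(self, rng):
        """Permutation null: destroying the age-feature link leaves the
        downstream growth fit without explanatory power."""
        ages = rng.uniform(7, 14, 40)
        X = np.hstack([np.outer(ages, rng.normal(size=3)),
                       rng.normal(size=(40, 30))])
        r2 = []
        for _ in range(10):
            perm = rng.permutation(40)
            preds = loocv_svr_age(X, ages[perm])
            r2.append(fit_growth_curve(preds, ages[perm]).r_squared)
        true_r2 = fit_growth_curve(loocv_svr_age(X, ages), ages).r_squared
        assert np.mean(r2) < 0.2
        assert true_r2 > np.mean(r2)

    def test_selection_ignores_held_out_subject(self, rng):
        """No information leak: a fold's feature selection must not change
        when its held-out subject's features are corrupted."""
        from sklearn.base import clone

        ages = rng.uniform(7, 14, 15)
        X = rng.normal(size=(15, 30))
        filt = UnivariateFeatureFilter(mode="age_corr_fdr", k=5, fdr_q=1.0)
        hold = 4
        train = np.delete(np.arange(15), hold)
        before = clone(filt).fit(X[train], ages[train]).selected_indices_
        X2 = X.copy()
        X2[hold] = rng.normal(size=30) * 100
        after = clone(filt).fit(X2[train], ages[train]).selected_indices_
        np.testing.assert_array_equal(before, after)


class TestGrowthCurve:
    def test_exact_recovery(self):
        ages = np.linspace(7, 14, 40)
        preds = 20.0 * (1.0 - np.exp(-0.2 * ages))
        model = VonBertalanffyGrowth().fit(ages, preds)
        assert model.a_ == pytest.approx(20.0, abs=1e-6)
        assert model.b_ == pytest.approx(0.2, abs=1e-6)
        assert model.r_squared_ == pytest.approx(1.0, abs=1e-9)

    def test_noisy_recovery_within_ten_percent(self, rng):
        """Median relative error of a-hat stays below 10% at n=200 with
        1-year prediction noise, across 20 simulations."""
        errors = []
        for _ in range(20):
            ages = rng.uniform(7, 14, 200)
            preds = 20.0 * (1.0 - np.exp(-0.2 * ages)) + rng.normal(0, 1.0, 200)
            model = VonBertalanffyGrowth().fit(ages, preds)
            errors.append(abs(model.a_ - 20.0) / 20.0)
        assert np.median(errors) < 0.10

    def test_constant_predictions_flag_boundary(self):
        ages = np.linspace(7, 14, 30)
        model = VonBertalanffyGrowth().fit(ages, np.full(30, 10.0))
        # a flat line carries no saturating trend: either b collapses to
        # the boundary or the curve is flat over the observed range
        curve_range = np.ptp(model.predict(ages))
        assert model.boundary_flag_ or curve_range < 0.1

    def test_fcmi_is_one_on_curve_at_max_age(self):
        ages = np.linspace(7, 14, 25)
        preds = 18.0 * (1.0 - np.exp(-0.15 * ages))
        gm = fit_growth_curve(preds, ages)
        on_curve = gm.a * (1 - np.exp(-gm.b * ages.max()))
        assert gm.estimator.maturity_index([on_curve])[0] == pytest.approx(1.0)

    def test_prediction_limits_bracket_fit(self):
        ages = np.linspace(7, 14, 25)
        preds = 18.0 * (1.0 - np.exp(-0.15 * ages))
        gm = fit_growth_curve(preds + np.sin(ages), ages)
        assert np.all(gm.lower_90 <= gm.upper_90)


class TestConfoundAdjust:
    def _cohort(self, rng, n=40):
        dx = np.repeat(["TDC", "ADHD-C"], n // 2)
        site = rng.choice(["A", "B"], n)
        sex = rng.choice(["F", "M"], n)
        iq = rng.normal(110, 10, n)
        return dx, site, sex, iq

    def test_no_confound_effect_is_identity(self, rng):
        """When the data carry exactly zero site/sex/IQ coefficients, the
        adjustment returns the input untouched."""
        dx, site, sex, iq = self._cohort(rng)
        confounds = pd.DataFrame({
            "diagnosis_code": (dx == "ADHD-C").astype(float),
            "site": site, "sex": sex, "iq": iq})
        design, _, _ = ConfoundAdjuster._design(confounds)
        noise = rng.normal(size=(40, 15))
        # remove every component the design could explain, then add back a
        # pure intercept + diagnosis structure
        noise -= design @ np.linalg.lstsq(design, noise, rcond=None)[0]
        X = 0.5 + 0.3 * (dx == "ADHD-C")[:, None] + noise
        adjusted = confound_adjust(X, dx, site, sex, iq)
        np.testing.assert_allclose(adjusted, X, atol=1e-10)

    def test_planted_site_offset_removed(self, rng):
        dx, site, sex, iq = self._cohort(rng)
        X = rng.normal(size=(40, 10))
        shifted = X + 2.0 * (site == "B")[:, None]
        adjusted = confound_adjust(shifted, dx, site, sex, iq)
        for g in ("A", "B"):
            for h in ("A", "B"):
                if g < h:
                    gap = adjusted[site == g].mean(0) - adjusted[site == h].mean(0)
                    raw_gap = shifted[site == g].mean(0) - shifted[site == h].mean(0)
                    assert np.abs(gap).mean() < np.abs(raw_gap).mean() / 10

    def test_permutation_equivariance(self, rng):
        dx, site, sex, iq = self._cohort(rng)
        X = rng.normal(size=(40, 8))
        adjusted = confound_adjust(X, dx, site, sex, iq)
        perm = rng.permutation(40)
        adjusted_perm = confound_adjust(X[perm], dx[perm], site[perm],
                                        sex[perm], iq[perm])
        np.testing.assert_allclose(adjusted_perm, adjusted[perm], atol=1e-9)

    def test_rank_deficiency_names_columns(self, rng):
        dx = np.repeat(["TDC", "ADHD-C"], 10)
        site = np.where(dx == "TDC", "A", "B")  # site confounded with dx
        with pytest.raises(ValueError, match="rank deficient"):
            confound_adjust(rng.normal(size=(20, 5)), dx, site,
                            np.repeat(["F", "M"], 10), rng.normal(110, 10, 20))


class TestLoocvSvm:
    def test_separable_two_group_is_perfect(self, rng):
        labels = np.repeat(["TDC", "ADHD-C"], 20)
        X = rng.normal(size=(40, 30)) * 0.01
        X[:20, :5] += 5.0
        report = loocv_svm_classify(X, labels)
        assert report.accuracy == 1.0
        assert report.sensitivity == 1.0 and report.specificity == 1.0

    def test_unbalanced_groups_rejected(self, rng):
        labels = np.array(["TDC"] * 25 + ["ADHD-C"] * 15)
        with pytest.raises(ValueError, match="balance_groups"):
            loocv_svm_classify(rng.normal(size=(40, 10)), labels)

    def test_consensus_on_stable_selection(self, rng):
        """When the informative features dominate every fold, the consensus
        equals each fold's selection."""
        labels = np.repeat(["TDC", "ADHD-I"], 15)
        X = rng.normal(size=(30, 20)) * 0.01
        X[labels == "ADHD-I", :3] += 10.0
        cfg = AnalysisConfig(top_k_dx=3)
        report = loocv_svm_classify(X, labels, cfg)
        np.testing.assert_array_equal(report.consensus_features, [0, 1, 2])
        for fold in report.fold_features:
            np.testing.assert_array_equal(np.sort(fold), [0, 1, 2])

    def test_three_group_reports_per_class(self, rng):
        labels = np.repeat(["TDC", "ADHD-C", "ADHD-I"], 12)
        X = rng.normal(size=(36, 30)) * 0.01
        X[labels == "ADHD-C", :4] += 4
        X[labels == "ADHD-I", 4:8] += 4
        report = loocv_svm_classify(X, labels)
        assert set(report.per_class_accuracy) == {"TDC", "ADHD-C", "ADHD-I"}
        assert report.accuracy > 0.9


class TestBalanceGroups:
    def _table(self, sizes, rng):
        rows = []
        for g, n in sizes.items():
            for _ in range(n):
                rows.append({"diagnosis": g, "age": rng.uniform(7, 14),
                             "sex": rng.choice(["F", "M"]),
                             "mean_fd": rng.uniform(0.02, 0.3)})
        return pd.DataFrame(rows)

    def test_identity_when_already_balanced(self, rng):
        table = self._table({"TDC": 10, "ADHD-C": 10}, rng)
        out = balance_groups(table, 10, match_on=("age",), seed=0)
        assert len(out) == 20
        assert out["diagnosis"].value_counts().to_dict() == {
            "TDC": 10, "ADHD-C": 10}

    def test_52_from_unequal_groups(self, rng):
        table = self._table({"ADHD-I": 60, "ADHD-C": 80, "TDC": 112}, rng)
        out = balance_groups(table, 52, match_on=("age", "mean_fd"), seed=1)
        assert out["diagnosis"].value_counts().to_dict() == {
            "ADHD-I": 52, "ADHD-C": 52, "TDC": 52}

    def test_deterministic_under_seed(self, rng):
        table = self._table({"TDC": 40, "ADHD-C": 25}, rng)
        a = balance_groups(table, 20, seed=7)
        b = balance_groups(table, 20, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_insufficient_subjects_reported(self, rng):
        table = self._table({"TDC": 30, "ADHD-C": 8}, rng)
        with pytest.raises(ValueError, match="ADHD-C has 8"):
            balance_groups(table, 20)
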