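"""Synthetic cohort generator: geometry, determinism, target covariance
convergence, motion-age confound, and planted-effect recovery."""

import numpy as np
import pytest
from scipy import stats

from fcmotion.connectivity import correlation_matrix, edge_distances, edge_index
from fcmotion.motion import compute_fd, make_censor_mask
from fcmotion.synthetic import (
    SyntheticConfig,
    _plan_effects,
    generate_cohort,
    generate_roi_geometry,
    generate_subject,
    load_cohort,
    save_cohort,
)


class TestGeometry:
    def test_160_rois_6_networks(self):
        rois = generate_roi_geometry(160, 6, seed=1)
        assert rois.n_rois == 160
        assert len(set(rois.networks)) == 6
        assert "default" in rois.networks and "cerebellum" in rois.networks

    def test_two_roi_distance_is_euclidean(self):
        rois = generate_roi_geometry(2, 1, seed=5)
        d = edge_distances(rois)[0]
        assert d == pytest.approx(np.linalg.norm(rois.coords[0] - rois.coords[1]))

    def test_seed_determinism(self):
        a = generate_roi_geometry(40, 6, seed=9)
        b = generate_roi_geometry(40, 6, seed=9)
        np.testing.assert_array_equal(a.coords, b.coords)
        assert list(a.networks) == list(b.networks)

    def test_more_networks_than_rois_rejected(self):
        with pytest.raises(ValueError):
            generate_roi_geometry(4, 6, seed=0)

    def test_coordinates_inside_brain_box(self):
        rois = generate_roi_geometry(200, 6, seed=2)
        assert np.all(np.abs(rois.coords[:, 0]) <= 70)
        assert np.all(np.abs(rois.coords[:, 1]) <= 100)
        assert np.all(np.abs(rois.coords[:, 2]) <= 70)


def _toy_setup(**kw):
    defaults = dict(n_per_group=4, n_rois=30, n_frames=120, seed=0)
    defaults.update(kw)
    cfg = SyntheticConfig(**defaults)
    rois = generate_roi_geometry(cfg.n_rois, cfg.n_networks, seed=3)
    plan = _plan_effects(rois, cfg, np.random.default_rng(3))
    return cfg, rois, plan


class TestSubject:
    def test_no_spikes_means_only_drift_fd(self):
        cfg, rois, plan = _toy_setup(spike_rate_mean=0.0)
        subj, truth = generate_subject(10.0, "TDC", rois, plan, cfg, seed=1)
        fd = compute_fd(subj.realignment)
        assert truth.spike_frames.size == 0
        assert fd.max() < 0.1  # only the small random-walk drift remains

    def test_seed_bit_identical(self):
        cfg, rois, plan = _toy_setup()
        a, _ = generate_subject(9.0, "ADHD-C", rois, plan, cfg, seed=7)
        b, _ = generate_subject(9.0, "ADHD-C", rois, plan, cfg, seed=7)
        np.testing.assert_array_equal(a.roi_ts, b.roi_ts)
        np.testing.assert_array_equal(a.channels, b.channels)
        np.testing.assert_array_equal(a.realignment.params, b.realignment.params)

    def test_age_outside_range_rejected(self):
        cfg, rois, plan = _toy_setup()
        with pytest.raises(ValueError, match="age"):
            generate_subject(30.0, "TDC", rois, plan, cfg, seed=1)

    def test_long_run_converges_to_target(self):
        """Monte-Carlo convergence: at T=5000 with no spikes or effects the
        empirical correlations sit within +-0.03 of the target for >=95%
        of edges."""
        cfg = SyntheticConfig(
            n_rois=30, n_frames=5000, spike_rate_mean=0.0, age_slope=0.0,
            delta_combined=0.0, delta_inattentive=0.0, delta_sensorimotor=0.0,
        )
        rois = generate_roi_geometry(30, 6, seed=3)
        plan = _plan_effects(rois, cfg, np.random.default_rng(3))
        subj, truth = generate_subject(10.0, "TDC", rois, plan, cfg, seed=42)
        iu = edge_index(30)
        target = np.tanh(truth.clean_z[iu])
        err = np.abs(correlation_matrix(subj.roi_ts).edge_vector("r") - target)
        assert (err <= 0.03).mean() >= 0.95

    def test_spike_frames_within_run(self, small_cohort):
        T = small_cohort.config.n_frames
        for truth in small_cohort.ground_truth:
            assert np.all((truth.spike_frames >= 0) & (truth.spike_frames < T))
            assert np.allclose(truth.clean_z, truth.clean_z.T)


class TestCohort:
    def test_group_sizes(self, small_cohort):
        counts = small_cohort.table["diagnosis"].value_counts()
        assert counts.to_dict() == {"TDC": 8, "ADHD-I": 8, "ADHD-C": 8}

    def test_age_motion_correlation_realized(self):
        """Requested rho(age, motion) is realized within sampling error."""
        cfg = SyntheticConfig(n_per_group=50, n_rois=12, n_frames=80,
                              rho_age_motion=-0.3, seed=10)
        cohort = generate_cohort(cfg)
        r = np.corrcoef(cohort.table["age"], cohort.table["true_mean_fd"])[0, 1]
        assert r == pytest.approx(-0.3, abs=0.15)

    def test_null_cohort_yields_few_fdr_discoveries(self, clean_cohort):
        """With no planted effects the age analysis controls false
        discoveries."""
        from fcmotion.age import edge_age_correlation

        Z = np.array([correlation_matrix(s.roi_ts).edge_vector("z")
                      for s in clean_cohort.subjects])
        assoc = edge_age_correlation(Z, clean_cohort.table["age"].to_numpy(),
                                     q=0.05)
        assert assoc.significant.mean() <= 0.05

    def test_round_trip_through_disk(self, tmp_path, small_cohort):
        save_cohort(small_cohort, tmp_path / "cohort")
        back = load_cohort(tmp_path / "cohort")
        assert len(back.subjects) == len(small_cohort.subjects)
        s0, b0 = small_cohort.subjects[0], back.subjects[0]
        np.testing.assert_allclose(b0.roi_ts, s0.roi_ts, rtol=1e-8)
        np.testing.assert_allclose(b0.realignment.params, s0.realignment.params,
                                   atol=1e-12)
        np.testing.assert_array_equal(
            back.ground_truth[0].spike_frames,
            small_cohort.ground_truth[0].spike_frames)


class TestArtifactStructure:
    def test_censoring_unbiased_without_artifact(self):
        """With artifact gain 0, censoring spike frames leaves edge
        estimates unchanged in expectation (paired across seeds)."""
        cfg, rois, plan = _toy_setup(artifact_gain=0.0,
                                     dvars_disruption_gain=0.0,
                                     spike_rate_mean=0.15, n_frames=150)
        diffs = []
        for seed in range(20):
            subj, _ = generate_subject(10.0, "TDC", rois, plan, cfg, seed=seed)
            fd = compute_fd(subj.realignment)
            mask = make_censor_mask(fd, 0.2)
            if mask.n_kept < 30 or mask.fraction_removed == 0:
                continue
            full = correlation_matrix(subj.roi_ts).edge_vector("r")
            scrub = correlation_matrix(subj.roi_ts, mask=mask).edge_vector("r")
            diffs.append((scrub - full).mean())
        t, p = stats.ttest_1samp(diffs, 0.0)
        assert p > 0.01

    def test_scrubbing_delta_is_distance_dependent(self):
        """With artifact present, the scrubbing-induced delta-r follows the
        inter-ROI distance profile (inflated proximal pairs corrected
        downward, deflated distant pairs upward)."""
        cfg, rois, plan = _toy_setup(n_frames=200)
        dist = edge_distances(rois)
        slopes = []
        for seed in range(8):
            subj, _ = generate_subject(8.0, "TDC", rois, plan, cfg, seed=seed,
                                       spike_prob=0.25)
            fd = compute_fd(subj.realignment)
            mask = make_censor_mask(fd, 0.2)
            if mask.n_kept < 30:
                continue
            full = correlation_matrix(subj.roi_ts).edge_vector("r")
            scrub = correlation_matrix(subj.roi_ts, mask=mask).edge_vector("r")
            slopes.append(np.corrcoef(dist, scrub - full)[0, 1])
        assert np.mean(slopes) > 0
        assert (np.asarray(slopes) > 0).mean() >= 0.75

    def test_planted_age_slopes_recoverable(self):
        """Edge-on-age regression over a clean cohort returns the planted
        slope within 2 standard errors for >=90% of planted edges."""
        cfg = SyntheticConfig(n_per_group=20, n_rois=40, n_frames=300,
                              spike_rate_mean=0.0, seed=6)
        cohort = generate_cohort(cfg)
        ages = cohort.table["age"].to_numpy()
        Z = np.array([correlation_matrix(s.roi_ts).edge_vector("z")
                      for s in cohort.subjects])
        truth = cohort.ground_truth[0]
        planted = np.flatnonzero(truth.age_effect != 0)
        X = np.column_stack([ages, np.ones(ages.size)])
        beta, res, *_ = np.linalg.lstsq(X, Z[:, planted], rcond=None)
        dof = ages.size - 2
        resid = Z[:, planted] - X @ beta
        se = np.sqrt((resid ** 2).sum(axis=0) / dof
                     / ((ages - ages.mean()) ** 2).sum())
        within = np.abs(beta[0] - truth.age_effect[planted]) <= 2 * se
        assert within.mean() >= 0.90
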