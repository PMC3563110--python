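# Methods

`fcmotion` implements a micro-movement-aware analysis chain for
resting-state functional connectivity: motion quantification, ten
motion-correction strategies, edge-wise developmental statistics, a
frame-removal degradation simulation, SVR-based brain-maturity
prediction, and LOOCV SVM subtype classification.  Because volumetric
images are out of scope, everything operates at the ROI level: the unit
record is an ROI-by-time matrix plus a six-parameter rigid-body
realignment series.

## Motion metrics

Framewise displacement of frame *i* is
`FD_i = |Δd_ix| + |Δd_iy| + |Δd_iz| + |Δα_i| + |Δβ_i| + |Δγ_i|`, a
backward difference of the six rigid-body parameters with each rotation
delta converted from radians to mm as arc length on a 50 mm sphere (the
approximate cortex-to-head-center distance).  `FD_0 := 0` since the
first frame has no predecessor.  DVARS is the spatial root-mean-square
of the backward temporal difference over all channels,
`DVARS_t = sqrt(<[I_t - I_{t-1}]^2>)`, with channels rescaled so the run
median intensity is 1000 before differencing — a channel-level stand-in
for volumetric mode-1000 normalization that makes the conventional
DVARS threshold of 4 meaningful.  Whether that threshold belongs on a
x1 or x10 scale of mode-1000 units is not standardized; 4 on the x1
scale is our assumption and the value is config-exposed
(`dvars_threshold`).

Run-level RMS is defined as the frame-wise root mean square over the six
parameters (rotations converted at 50 mm); the common usage names only
"total RMS", so this concrete definition is ours and both the radius and
the 1.5 mm exclusion limit are configurable.  All thresholds are strict
inequalities: a run at exactly 1.5 mm RMS, or a frame at exactly 0.2 mm
FD, is retained.

Censoring removes every frame whose metric strictly exceeds the
threshold plus 1 frame before and 2 after (union over triggers, clipped
to the run), compensating for temporal blurring of the artifact by the
band-pass filter.

## Time-series cleaning and connectivity

Cleaning is a zero-phase order-2 Butterworth band-pass (0.009–0.08 Hz)
followed by OLS regression of the nuisance channels (global,
white-matter and ventricle analogs), their backward-difference
derivatives, an intercept, and the procedure's motion regressors.  The
band-pass realization (order, type) is a choice — only the band itself
is canonical.  Volumetric spatial smoothing has no ROI-level analog and
is omitted.

Connectivity matrices are Pearson correlations over the (optionally
censored) frames with Fisher z = atanh(r) companions.  Degenerate edges
(constant channels, |r| = 1, covariate-absorbed channels in partial
correlations) are carried with a per-edge `valid = False` flag rather
than raised, so one bad channel never discards a subject.  Edges are
indexed by the row-major upper triangle of the ROI-ordered matrix; a
160-ROI set yields 12,720 unique edges.  Subjects with fewer than 30
retained frames (`min_frames`) are excluded with a logged reason.

## The ten procedures

P1 regresses the six realignment parameters during cleaning (the
traditional correction; it is also the cleaning base for P2–P3 and
P5–P10).  P2/P3 compute partial correlations with the six frame-to-frame
parameter series / the FD series as frame-wise covariates.  P4 replaces
the realignment-parameter regressors with the frame-to-frame parameters.
P5 carries the subject's mean FD into the group analysis as a covariate.
P6 "matches" the cohort: subjects are removed until mean FD is unrelated
to age.  P7 censors frames with FD > 0.2 mm; P8 adds post-censor mean-FD
matching; P9 censors on DVARS > 4 and matches on post-censor mean DVARS.
P10 fits, per subject, a polynomial to the censoring-induced delta-r
(scrubbed minus original) as a function of inter-ROI distance and adds
the predicted delta back to the original r-values — approximating the
scrubbed estimate without losing frames.

Open choices resolved here:

* **Matching algorithm.**  Only the goal (no motion–age relationship) is
  canonical.  We use a greedy loop: while the Pearson p-value is below
  alpha (0.05), remove the single subject whose exclusion maximally
  reduces |r| (exhaustive single-removal scan, ties broken by subject
  id).  This is deterministic and idempotent; it aborts with a
  diagnostic if more than half the cohort would be removed.
* **Polynomial degree** defaults to 3 (the general form leaves the
  degree open) and is fit on r, not z, with z recomputed afterwards;
  corrected r is clipped into (−1, 1) before the transform.  Because the
  fit includes all powers of distance up to the degree, the residual
  delta is orthogonal to distance by construction — the model's
  `residual_corr_` self-check should be near zero whenever any frames
  were censored.
* **Eligibility.**  The <60%-frames-removed rule is applied to P7, P8
  and P9 (the censoring family) and the ≥40%-frames-remaining rule to
  P10.  The DVARS-censoring procedure has no stated rule; sharing the
  censoring family's guard is our choice.

## Age analysis

Each valid edge's Fisher-z values are Pearson-correlated with age
(partial correlation via OLS residuals when a procedure supplies a
covariate, charging one degree of freedom per covariate column), with
two-sided p-values from the t distribution and Benjamini–Hochberg FDR at
q = 0.05 (q is not canonical; it is config-exposed).  Significant edges
are split by the sign of the age correlation; the Euclidean distances of
the two sets are compared with Welch's unequal-variance t-test (the test
choice is ours).  The "gap" — mean distance of strengthening edges minus
mean distance of weakening edges — is the summary that motion artifact
inflates.

The frame-removal simulation takes low-motion reference subjects (at
most 1% of frames over threshold) and imposes other subjects' real
censoring patterns on them, either by recomputing the matrix on retained
frames or by imputing censored frames with a natural cubic spline over
frame index (run-edge gaps take the nearest retained value, since
splines extrapolate poorly).  Degradation is `1 − r` between vectorized
upper triangles of the baseline and degraded matrices.  Filtering is run
once, before censoring or imputation; we do not re-filter interpolated
series.

## Learners

SVR brain-maturity prediction uses an epsilon-insensitive SVR with RBF
kernel `K(x,y) = exp(−‖x−y‖² / (2σ²))`, σ = 2 (the solver's rate
parameter is `gamma = 1/(2σ²) = 0.125`; the conversion is unit-tested
against the explicit kernel), ε = 1e−5, and `C = 1e6` as a finite
hard-margin surrogate for "C = ∞".  Feature vectors are Fisher-z edges,
used unstandardized (a scaling flag exists but defaults off).  Feature
filtering — the top 300 edges by |age correlation| that also pass FDR —
is recomputed inside every leave-one-out fold; when fewer than 300 edges
pass, all passers are used and the event is logged.  Predicted ages are
fit with the Von Bertalanffy curve `a(1 − e^{−b·age})` by nonlinear
least squares with five deterministic multi-starts
(a₀ = max prediction, b₀ = 0.1, perturbed); fcMI divides predictions by
the fitted curve's value at the oldest chronological age, so the curve
equals 1 there.  90% prediction limits come from the residual spread.

Classification uses a soft-margin SVM (C = 1, same kernel), top-150
in-fold t-test (2-group) or ANOVA (3-group) filtering, one-vs-rest with
winner-takes-all on decision values for 3 groups, and balanced groups
produced by greedy nearest-neighbor subsampling on standardized
covariates (deterministic under a seed).  Sensitivity is reported with
the ADHD group as the positive class.  Confound adjustment fits, per
edge, `y = β₀ + β₁·dx + β₂·site + β₃·sex + β₄·IQ + ε` by OLS and
returns `β₀ + β₁·dx + residual`, keeping the diagnosis effect while
partialling out the nuisances; it is fit on the analysis subsample.
Consensus features are the intersection of all folds' selections; node
strength sums |z| weights over a region's incident consensus edges
(t statistics are converted to normal z-scores for diagnosis contrasts,
Fisher z of the age correlation for age contrasts — the choice of weight
is ambiguous in common usage, so both are exposed).

## Synthetic cohort generator

The generator is the package's test bed: it emulates a multi-site
developmental ADHD cohort at the level of statistical structure, with
planted ground truth for recovery tests.

**Geometry.**  ROI centers are uniform in a ±70 × ±100 × ±70 mm box;
network labels come from k-means on the coordinates (spatially coherent
networks), with the inferior-most cluster named "cerebellum" and the
remaining five given canonical resting-state names when six networks are
requested.

**Clean signal.**  A per-subject target is built in Fisher-z space:
within-network baseline atanh(0.35), between-network atanh(0.05), plus a
proximity term `0.25·exp(−d/30 mm)`.  Age trends of ±0.025 z/year
(age centered mid-range) are planted on 150 long-range (≥60 mm)
within-network edges (+) and 150 short-range (15–45 mm) between-network
edges (−); diagnosis offsets of −0.10 z are planted on default-network
edges (ADHD-C) and fronto-parietal/cerebellar edges (ADHD-I), with a
shared −0.06 z sensorimotor offset.  The z target maps to correlations,
is projected to the nearest positive-definite correlation matrix
(eigenvalue clipping at 1e−4, diagonal renormalization), and the signal
is sampled as an AR(1)-in-time (φ = 0.15) multivariate normal with that
stationary covariance.  Effect sizes were chosen so that recovered
2-group classification accuracies fall in the low-70s-to-low-90s percent
range and 3-group around 70% at n = 52/group — the regime reported for
cohorts of this kind — rather than at ceiling.

**Motion and artifact.**  Each subject has a per-frame spike probability
drawn lognormally (σ = 0.9) around 10%, with a latent Gaussian coupling
to age of ρ = −0.45 — younger subjects move more, matching the
motion–age association seen in pediatric cohorts; the confound acts
through this propensity, not through per-frame coupling.  Spike
magnitudes are lognormal (median ≈ 0.33 mm, so spikes straddle the
0.2 mm censoring threshold); each spike adds a one-frame displacement
pulse to the realignment parameters (distributed over the six
parameters; FD at the pulse equals the magnitude) on top of a small
random-walk drift.  Each spike also injects a correlated artifact into
the ROI signal: a fresh spatially smooth Gaussian field with covariance
`exp(−d/60 mm)`, spatially demeaned, scaled by gain 4 z/mm times the
spike magnitude.  Averaged over frames this adds covariance proportional
to the (demeaned) spatial kernel — systematically inflating proximal
pairs and slightly deflating distant ones, the short-inflated /
long-deflated distance profile that volume censoring is known to remove.
The 60 mm decay and the demeaning were chosen because a short-range
(≈15 mm) kernel produces a qualitatively wrong confound: the artifact's
added variance then attenuates mid-range within-network correlations in
high-motion subjects, creating spurious *strengthening*-with-age edges
at mid distances instead of the proximal weakening the literature
documents.  The kernel form is a modeling choice exposed in config, not
a claim about any particular dataset.

**Channels and DVARS.**  Each ROI is expanded to 3 noisy channel
replicates on a 1000-baseline intensity scale (signal amplitude 1.5,
channel noise 1).  Spikes additionally inject a per-channel intensity
burst (gain 15 × magnitude) into the channels only — the echo-planar
signal-loss analog.  This term drives DVARS (baseline ≈ 2.5, spike
frames typically > 4) without entering the ROI series, decoupling DVARS
detectability from the size of the connectivity artifact; with a single
shared term, no setting makes spikes DVARS-visible without the artifact
drowning the planted effects.  Nuisance channels are the ROI mean
(global analog) and two AR(1) noise channels with a small artifact
loading (white-matter/ventricle analogs).

**What the generator does not emulate.**  Hemodynamics, scanner physics,
spatial autocorrelation within ROIs, site-specific acquisition
differences (site labels are random), realistic FD temporal
autocorrelation, and non-Gaussian BOLD features.  Passing tests
demonstrate that the pipeline recovers structure *of the planted kind*
under motion contamination; they do not certify behavior on real scans.

## Numerical choices and degenerate inputs

* Nearest-PD projection: eigenvalue floor 1e−4, failure if the projected
  matrix is still indefinite beyond tolerance.
* Censor masks use 1 = keep; frame indices are 0-based internally and
  1-based in file error messages.
* AFNI-dialect realignment files are read as translations-first with
  rotations in degrees and converted to radians on read; dialects are
  always user-declared, never sniffed.
* Tie-breaks: feature ranking resolves ties by the lower edge index
  (stable sorts throughout); matching resolves ties lexicographically by
  subject id.
* Growth fit: bounds a, b > 0, b ≤ 50/year; a `boundary_flag_` marks
  collapse toward b = 0 (no saturating trend).
* Masked correlation with fewer than `min_frames` retained frames raises
  at the library level; the cohort layer converts procedure-eligibility
  violations into logged exclusions instead.

## Problem sizes in tests and the acceptance script

The test suite exercises the full study conditions (n = 120, R = 160,
T = 200, 10 seeds) for the procedure-comparison check and n = 52/group
with R = 160 for subtype classification.  The chance-calibration runs
(permuted diagnosis labels) use 52/group on a reduced 60-ROI set —
1,770 candidate edges still dwarf the 150 the in-fold filter keeps, and
the chance level of a balanced 3-group problem does not depend on the
feature count — with 20 permutation replicates.  Shared fixtures use
40–100 ROIs.  These sizes are the package's choices for a desk-scale
reproduction; all of them are parameters.
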