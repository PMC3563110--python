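# fcmotion

Micro-movement-aware resting-state functional connectivity analysis.

Head motion as small as a few tenths of a millimeter systematically
distorts functional connectivity estimates: abrupt frame-to-frame
displacements inflate correlations between nearby regions and deflate
long-range ones.  In developmental and hyperkinetic clinical cohorts
(children with ADHD being the prototypical case) motion also correlates
with the variables of interest — age and diagnosis — so the artifact
masquerades as biology.  `fcmotion` is a toolbox for quantifying that
artifact and comparing strategies for removing it, aimed at researchers
analyzing ROI-level resting-state time series.

What it implements:

* **Motion metrics** — framewise displacement
  `FD_i = |Δd_ix| + |Δd_iy| + |Δd_iz| + |Δα_i| + |Δβ_i| + |Δγ_i|`
  (rotations converted to mm on a 50 mm sphere), DVARS (spatial RMS of
  the backward signal difference on a median-1000 intensity scale), run
  RMS exclusion, and volume censoring ("scrubbing": metric > threshold
  removes the frame, 1 before and 2 after).
* **Ten correction procedures** (P1–P10) as one strategy layer:
  realignment-parameter regression, frame-to-frame-parameter and FD
  partial correlations, mean-FD group covariates, motion "matching"
  (removing subjects until motion is unrelated to age), FD- and
  DVARS-based censoring with matching, and a per-subject polynomial
  correction of the censoring-induced delta-r as a function of
  inter-ROI distance.
* **Edge-wise age statistics** — Pearson/partial correlation of each
  Fisher-z edge with age, Benjamini–Hochberg FDR, and the short-range /
  long-range distance split of significant edges.
* **A frame-removal simulation** measuring matrix degradation
  (1 − r between vectorized matrices) as real censoring patterns are
  imposed on low-motion reference subjects, for censoring vs
  cubic-spline imputation.
* **Brain-maturity prediction** — leave-one-out SVR (RBF, σ = 2) on
  in-fold top-300 age-correlated edges, summarized by a Von Bertalanffy
  growth fit `a(1 − e^{−b·age})` and the fcMI maturity index.
* **Subtype classification** — balanced LOOCV SVM (C = 1, one-vs-rest
  winner-takes-all) on in-fold top-150 t-test/ANOVA edges, with confound
  adjustment, consensus features, and node-strength maps.
* **A synthetic cohort generator** with planted age trends, subtype
  offsets, and a distance-dependent motion artifact whose propensity
  correlates negatively with age — ground truth included, so every claim
  above is testable.

Estimator-shaped pieces (`UnivariateFeatureFilter`,
`VonBertalanffyGrowth`, `ConfoundAdjuster`,
`PolynomialDistanceCorrection`) follow scikit-learn conventions and
compose with its pipelines and model selection.

## Worked example

Generate a motion-contaminated cohort and compare the age-association
distance profile under traditional correction (P1) versus censoring
(P7):

```python
from fcmotion import SyntheticConfig, generate_cohort
from fcmotion.pipeline import run_cohort_procedure, run_age_analysis

cohort = generate_cohort(SyntheticConfig(n_per_group=30, n_rois=40,
                                         n_frames=200, seed=5,
                                         short_range_max_mm=60.0))
for proc in ("P1", "P7"):
    result = run_cohort_procedure(cohort, proc)
    assoc, split = run_age_analysis(result)
    print(f"{proc}: {len(result.subject_ids)} subjects retained, "
          f"{int(assoc.stronger_with_age.sum())} edges stronger with age "
          f"(mean {split.mean_stronger:.1f} mm), "
          f"{int(assoc.weaker_with_age.sum())} weaker "
          f"(mean {split.mean_weaker:.1f} mm), gap {split.gap:.1f} mm")
```

prints

```
P1: 90 subjects retained, 30 edges stronger with age (mean 82.0 mm), 28 weaker (mean 51.0 mm), gap 31.1 mm
P7: 80 subjects retained, 11 edges stronger with age (mean 79.1 mm), 12 weaker (mean 54.0 mm), gap 25.1 mm
```

Edges that strengthen with age link distant regions; edges that weaken
link proximal ones.  Under traditional correction the mean-distance gap
between the two sets is 31.1 mm; censoring frames with FD > 0.2 mm
(which also excludes 10 high-motion subjects) shrinks it to 25.1 mm —
part of the "developmental" short-range weakening was motion artifact
riding on the age–motion confound.

The same pipeline is scriptable from the shell:

```bash
fcmotion simulate --seed 3 --out cohort/
fcmotion motion --realign cohort/sub0001_realign.txt --dialect generic \
    --channels cohort/sub0001_channels.csv --out trace.json --censor-out mask.txt
fcmotion age --proc P7 --cohort cohort/ --out age_assoc.tsv
fcmotion classify --proc P10 --cohort cohort/ --groups TDC,ADHD-C --out report.json
```

## Documentation

`docs/methods.md` describes the models, the synthetic generator's
assumptions and limits, and every numerically consequential choice
(thresholds, tie-breaks, degenerate-input handling).
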