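# navregsim

Simulation and statistical analysis of patient-registration accuracy in
image-guided spine surgery.

Spinal navigation requires registering the patient's anatomy to an image
volume. Two approaches dominate: **automatic registration**, where a
fiducial matrix with radio-opaque and tracked markers sits in the
intraoperative CBCT scan volume and the registration is computed from
two chained paired-point fits; and **manual surface matching**, where the
surgeon digitizes three orientation landmarks and 17 surface points on
the exposed vertebra and the software matches them to a bone model
segmented from the preoperative CT. Their accuracy is compared by
implanting three lamina micro-screws, picking their head centres in the
image ("planned" points), digitizing them with a pointer ("acquired"
points), and transforming the planned points into the patient-reference
frame through each method's transformation chain:

```
automatic:        p_ref = T_uair · p_cbct
surface matching: p_ref = T_sm · T_fusion · p_cbct
```

The per-dataset accuracy is `RMS = sqrt(mean_i ‖T(p_i) − a_i‖²)` over the
three screws, and the study-level analysis is a paired comparison of RMS
values: Shapiro–Wilk normality gate, one-sided paired non-inferiority
t-test with a margin of 10% of the comparator mean (α = 0.05), post-hoc
two-sided paired t-test (α = 0.01), 99% Student-t confidence intervals,
and Bland–Altman agreement (bias ± 1.96·SD).

Because the clinical per-patient data are not public, the package ships a
synthetic-data generator that emulates the whole operating-room scene —
parametric vertebra surface, screw targets, fiducial matrix, dynamic
reference frame, ground-truth frame chains, Gaussian localization noise,
and discrete user-error events (wrong-level matching, reference-frame
displacement) at the study's observed rates. This is aimed at people who
build or evaluate surgical-navigation registration pipelines and want a
controlled testbed for error-chain logic and study statistics.

## Worked example

```
$ python examples/cohort_study.py
                         item  count
             initial_datasets     50
       excluded_image_quality      0
        excluded_missing_data      1
excluded_wrong_level_mismatch      5
     excluded_region_mismatch      0
    excluded_drf_displacement      2
               excluded_total      8
          analyzable_datasets     42

n = 42 paired datasets
Automatic registration RMS: 1.25 ± 0.34 mm (min 0.56, max 1.99, 99% CI 1.11 to 1.39)
Surface matching RMS:       2.07 ± 0.61 mm (min 0.84, max 3.48, 99% CI 1.82 to 2.33)
Mean difference: -0.82 mm (99% CI -1.09; -0.56)
Shapiro-Wilk p: 0.488 / 0.903 (normality confirmed)
Non-inferiority (margin 0.21 mm, alpha 0.05): p = 1.97e-13 -> non-inferior
Post-hoc paired t (alpha 0.01): p = 2.22e-10 -> significant difference
Bland-Altman: bias -0.82 mm, SD 0.64 mm, limits of agreement -2.07 to 0.43 mm
```

A 50-dataset cohort is simulated with the study's contamination pattern;
8 flagged datasets are excluded, and on the remaining 42 paired RMS
values automatic registration comes out non-inferior and, post hoc,
significantly more accurate — with simulated means close to the
clinically reported 1.20 ± 0.42 mm vs 1.94 ± 0.64 mm.

Other examples: `rigid_transform_chains.py` (frame-safe transform
algebra), `simulate_and_register.py` (one scene, both registrations),
`reproduce_reported_statistics.py` (published summary statistics
re-derived from printed inputs).

A thin CLI wraps the same pipeline:

```
navregsim simulate --config config.toml --seed 7 --out cohort/
navregsim analyze --cohort cohort/ --out results/
navregsim reproduce-stats
```

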