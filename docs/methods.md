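# Methods

`navregsim` simulates and analyses a paired accuracy study of two
patient-registration methods for image-guided spine surgery: automatic
registration from a fiducial matrix imaged in an intraoperative CBCT
("automatic" / UAIR-style), and manual landmark + surface matching
against a model segmented from the preoperative CT. This note records the
model, its assumptions, the parameter choices, and what the simulation
does and does not show about real operating-room data.

## Coordinate model

Five frames: `intraop_cbct`, `preop_ct`, `matrix`, `patient_ref` (the
dynamic reference frame, DRF), and `tracker` (the simulation's world
frame). All ground truth lives in the tracker frame; every measurement
is a ground-truth quantity pushed through the true frame chain plus
noise. Transforms are proper rigid motions stored as rotation matrix +
translation; frame labels are mandatory and composition across
mismatched labels is a hard error, because silent mischaining is the
dominant failure mode when implementing a multi-chain error procedure.
Lengths are millimetres everywhere; angles are degrees at APIs.

## Scene geometry

The registration vertebra is a parametric posterior-arch heightfield
(40 x 35 mm, 30 x 30 grid, ~1.7k triangles): a Gaussian spinous ridge
whose amplitude varies cranio-caudally, laminar plates falling off
laterally, and a sagittal bow. This is not an anatomical atlas — the
registration mathematics only needs a bone-like surface with curvature
in both directions (so that 20 digitized points constrain all six
degrees of freedom). Three orientation landmarks (right, left, center)
and three lamina screw targets are snapped exactly onto the mesh; screw
targets are pairwise >= 10 mm apart, mirroring the instruction to place
the reference micro-screws as far apart as possible. The fiducial matrix
is a fixed six-marker manufactured geometry (four plate corners, two
raised posts; non-coplanar by construction) posed beside the vertebra.
The adjacent vertebral level sits 20 mm cranio-caudally (mid-thoracic
spacing); it drives the wrong-level failure mode. The preoperative-CT
pose differs from the intraoperative pose by a random <= 5 degree /
5 mm change, emulating supine-to-prone repositioning.

## Measurement and noise model

Each simulated dataset contains planned screw points (picked in the
CBCT), acquired screw points (pointer digitization in the DRF frame),
the 3 landmark + 17 surface picks of manual registration, and the
fiducial-marker observations (radio-opaque in the image, tracked in the
DRF frame). Every localization is truth + iid Gaussian noise; surface
picks additionally slide along the local surface normal
(`surface_offset_sigma`), modelling pointer-tip skidding on bone.
The image-fusion transform (CBCT to preoperative CT) is intensity-based
in the clinical software; image processing is out of scope, so it is
modelled as the true chain plus a small random rigid perturbation — a
stated simulation shortcut, not a fusion algorithm.

Two discrete user-error modes fire mutually exclusively at configured
rates, plus two data-completeness modes:

* `wrong_level` (default rate 0.10): all manual-registration picks are
  displaced by the neighbor offset — equivalent to matching the true
  picks against the adjacent, geometrically identical level. Five of
  fifty datasets in the source study were wrong-level matches.
* `drf_displaced` (0.04): the reference frame translates by 15 mm
  between registration and screw acquisition — the only ordering that
  corrupts both methods at once and produces the large paired outliers
  seen clinically.
* `missing_data` (0.02): one acquired screw point is lost.
* `image_quality` (0.0 by default): the fiducial matrix is not resolved
  in the scan, so automatic registration has no input. In the study this
  happened three times before the analyzed cohort and was fixed by a
  higher-dose scan mode, hence the zero default.

### Noise calibration

No device noise magnitudes are published for this workflow, so the
sigma defaults are a one-time calibration: they were chosen so that a
default clean cohort lands near the clinically observed accuracy ranges
(automatic 1.20 +- 0.42 mm, surface matching 1.94 +- 0.64 mm), and then
frozen. The calibrated defaults are

| parameter | mm | role |
|---|---|---|
| `fle_image_sigma` | 0.45 | radio-opaque marker localization in CBCT |
| `fle_tracker_sigma` | 0.35 | tracked-marker localization |
| `pointer_sigma` | 0.40 | manual pointer digitization |
| `surface_offset_sigma` | 1.80 | pointer skidding along the bone normal |
| `screw_plan_sigma` | 0.40 | screw-head centre picking in the image |
| `fusion_noise_sigma_mm_deg` | (0.7, 0.7 deg) | fusion perturbation |

With these values an 80-dataset clean cohort gives automatic
1.26 +- 0.34 mm and surface matching 1.93 +- 0.59 mm. The split between
the surface-matching error sources (skidding vs. fusion vs. pointer) is
not identifiable from the published summary statistics; the calibration
is a plausible allocation, not a measurement, and all values are
tunable through `NoiseConfig`.

## Registration algorithms

*Paired-point registration* is closed-form absolute orientation
(Kabsch/Horn): centre both sets, SVD of the cross-covariance, proper
rotation enforced by flipping the smallest singular direction if the
unconstrained optimum is a reflection. Correspondence is by point label,
not row order. FRE is the RMS residual. Degenerate inputs (< 3 points,
collinear configurations in either set) raise.

*Automatic registration* chains two paired-point fits — image-to-matrix
from the radio-opaque observations and matrix-to-reference from the
tracked observations — exactly as the clinical device computes its
linear transformation in two stages.

*Surface matching* seeds with a paired-point fit of the three landmark
picks to the model landmarks, then runs point-to-surface ICP: exact
closest point on the model mesh for each pick (vectorized
point-to-triangle, Ericson's region decomposition — exact, not vertex
snapping, since 17 points are far too few for vertex correspondence),
followed by a closed-form rigid update; iterate until the RMS residual
changes by < 1e-4 mm or 100 iterations. The residual is provably
non-increasing and is asserted so in tests. Non-convergence is flagged
in the result, not raised — wrong-level datasets legitimately fail to
settle. The commercial algorithm's internals (weighting, robustness)
are undisclosed; plain least-squares ICP is an explicit stand-in.

## Error computation

Per dataset, planned screw points are pushed into the patient-reference
frame through each method's chain (automatic: one transform; surface
matching: fusion then matching transform) and compared with the acquired
points. The per-point error is the Euclidean distance; the per-dataset
accuracy is the RMS over the three screws; cohort statistics are over
per-dataset RMS values. Whether the source study pooled points across
the cohort or summarized per dataset is not stated; the per-dataset
reading matches its per-dataset box plot and method means, and is the
one implemented. Exclusion is driven by the simulated event flags
(mirroring a post-hoc case review with ground truth available); an
optional threshold rule (`rms_region_threshold`, off by default) flags
unexplained datasets with RMS above a cutoff as region mismatches for
analyses without ground truth.

## Statistics

* Sample size: normal-approximation paired design,
  `n = ((z_{1-a/2} + z_power) sd / delta)^2`, rounded to nearest (the
  only reading that reproduces the published 42 and 46 from the cited
  priors delta = 0.95 - 0.80 mm and sd = 0.30 mm).
* 99% CIs: Student-t quantiles. This reproduces three of the four
  published bounds exactly at two decimals and the fourth within
  0.01 mm (rounded printed inputs).
* Non-inferiority: one-sided paired t with margin = 10% of the
  comparator (surface-matching) mean computed from the data at hand —
  the published margin base is not stated; a fraction of the comparator
  mean is the conventional reading. p decreases monotonically in the
  margin, and the test is exactly calibrated at the null boundary
  (rejection rate = alpha under normal differences), which the
  acceptance suite verifies at 10^4 replicates.
* Post hoc: standard two-sided paired t at alpha 0.01.
* Normality gate: Shapiro-Wilk at p > 0.05 per method.
* Bland-Altman: bias and 1.96-SD limits of agreement of the paired
  differences.
* Degenerate inputs: paired difference SD below 1e-12 mm (e.g. a
  noise-free cohort) raises rather than returning meaningless p-values.

## What the simulation shows, and what it cannot

Passing tests demonstrate: the error chains close exactly (noise-free
RMS ~1e-14 mm); the registration solvers match independent oracles (a
brute-force nonlinear optimizer; the closed-form expected-TRE formula);
the contamination modes reproduce the clinically observed failure
signatures (wrong-level RMS near the 20 mm level spacing, i.e. the
>= 10 mm outlier regime); and the study's conclusions (non-inferiority
and post-hoc superiority of automatic registration) are stable across
simulation seeds *under the calibrated noise model*. They do not
validate the noise magnitudes themselves against hardware, do not model
respiration, tissue deformation, anatomical variation, or image quality,
and therefore do not by themselves establish the clinical accuracy
values — those enter only as calibration targets.

## Problem sizes

Default study replication uses 50-dataset cohorts (the study's
collection size) across 20 seeds; Monte-Carlo oracle checks use
100-1200 replicates per configuration; the type-I calibration uses
10^4 replicates at n = 50. Heavier invariance sweeps in the unit tests
run on a coarser 12 x 12 surface grid, which leaves the geometry
constraints intact.
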