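# Methods

## Problem

In online-adaptive radiotherapy (ART) a new plan is optimized on each
day's cone-beam CT anatomy before delivery; in image-guided radiotherapy
(IGRT) the original *scheduled* plan is delivered after positioning only.
For pelvic targets that deform substantially between fractions
(gynecologic tumors being the motivating case), the scheduled plan can
under-cover the deformed clinical target volume (CTV) whenever the daily
anatomy moves beyond the planning margin. This package quantifies that
effect per fraction and over a whole series, and implements an offline
monitoring rule that flags, from scheduled-plan dosimetry alone, the
patients who should be moved from IGRT to ART.

## Dosimetric model

All metrics derive from the cumulative dose-volume histogram (DVH) of a
structure: D95/D98/D99 (dose to the hottest 95/98/99% of the volume),
V95/V100 (percent of volume at ≥95/100% of the prescription), the minimum
dose, and the generalized equivalent uniform dose

    gEUD(a) = ( Σᵢ vᵢ dᵢᵃ )^(1/a)

over DVH bins with fractional volume vᵢ and midpoint dose dᵢ.  The target
exponent is a = −20, which makes the gEUD a smooth surrogate for the cold
spot; serial organs at risk (bladder, rectum) use a = +8 by default.  The
OAR exponent is a configurable package assumption, not an externally fixed
value.  Numerical notes:

* gEUD factors out the dominant dose before exponentiation, keeping the
  power sums finite for |a| up to several hundred.
* gEUD(a → −∞) converges to the minimum dose at rate (v_cold)^(−1/a); the
  bound "within 0.5% at a = −200" therefore holds when the coldest bin
  carries a volume fraction ≥ e⁻¹, which is the regime the analytic test
  suite exercises.  For a continuous dose distribution where the coldest
  bin holds a single voxel the finite-a gap is larger; this is a property
  of the statistic, not a discretization artifact.
* Default bin width is 0.1% of the prescription; Dx% is linearly
  interpolated on the cumulative curve and clamped below by the exact
  voxel minimum (Dx% ≥ min dose holds exactly).  Structures containing
  zero-dose voxels have gEUD 0 for a < 0 (the mathematical limit),
  returned with a warning.

## Deviation statistics

Every characteristic of the deformed target (iCTV) at fraction *i*,
evaluated under the adapted plan Aᵢ or the scheduled plan Sᵢ, is
normalized as a percentage deviation from the same characteristic of the
undeformed structure under the reference plan.  The adaptation gain is
Δ = %char(Aᵢ) − %char(Sᵢ).  Distributions over fractions are reported as
the median with the empirical 5th–95th percentile range (linear
interpolation between order statistics).  A percentile-bootstrap interval
for the median is provided as an alternative reading of a
"median (90% CI)" report; the percentile range is the default because the
intervals it produces track the spread of the per-fraction empirical
distribution functions rather than the (much narrower) sampling
uncertainty of a median at n ≈ 60.

## Margin expansion and dose accumulation

CTV→PTV expansion uses a Euclidean distance transform on the voxel
lattice with anisotropic spacing: a voxel joins the expansion iff its
center lies within the margin of some source-voxel center.  Dose
accumulation maps each fraction's dose to the reference frame by a
pull-back through the fraction's displacement field (reference point x
receives the fraction dose at x + dvf(x), trilinear interpolation) and
sums voxel-wise.  The pull-back direction avoids scattered-data
push-forward entirely; mapped points outside the fraction grid contribute
0 Gy and are counted.  Accumulation can re-grid the reference geometry to
an isotropic resolution first (1 mm in the clinical workflow this
mirrors, and in the acceptance run); unit tests use the native grid,
where N identity-field fractions accumulate to exactly N× one fraction.

## Switching rule

A violation is a scheduled-plan %gEUD_iCTV strictly below the cutpoint
(−7%).  Evaluating sequentially, the series switches to ART at the
earliest fraction where either (a) the second violation occurs within the
first 9 fractions, or (b) beyond fraction 9, violations exceed 20% of all
fractions observed so far.  "Thereafter" is read as the running proportion
over all fractions seen — the simplest auditable reading; a config flag
(`late_post_window_only`) restricts the count to post-window fractions
instead.  If both triggers would fire at the same fraction the early
trigger is reported.  Both comparisons are strict (< cutpoint, > 20%).

## Nonparametric tests

Paired comparisons use the Wilcoxon signed-rank test (zero differences
discarded — Wilcoxon's original policy and the common software default),
two independent groups the Mann-Whitney U, k groups Kruskal-Wallis with
tie correction, association Pearson r with a t-based p, and trend plots
ordinary least squares with t-based 95% confidence and prediction bands.
Exact null distributions are computed by dynamic programming — sign-flip
enumeration over (doubled, possibly tied) midranks for the signed-rank
statistic at n ≤ 25, and the interleaving recurrence for U when
min(n, m) ≤ 8 without ties; otherwise a normal approximation with
continuity and tie corrections is used.  Two-sided p-values double the
smaller tail and cap at 1.  Both modes are exposed because which mode a
given clinical analysis used at n ≈ 60 is generally unknowable.

## Synthetic series generator

The generator emulates the data structure of an adaptive course, not its
physics:

* **Reference plan** — ellipsoidal CTV (semi-axes 16/20/16 mm), PTV = CTV
  ⊕ margin (5 mm default; 0 mm studied as the limit), dose flat at the
  fraction prescription inside the PTV with a sigmoidal penumbra
  Rx / (1 + exp(d/σ − 3)) outside (σ = 4 mm ≈ 5%/mm falloff, ~95% of Rx
  at the PTV surface).
* **Per-fraction anatomy** — a rigid translation drawn per axis from
  N(0, drift_sd²) (default 4 mm, a realistic interfractional motion scale
  for pelvic soft-tissue targets) plus a smooth sinusoidal elastic field
  (amplitude 2 mm, random phases).  Bladder-like and rectum-like
  ellipsoids move coherently with the same mapping.
* **Scheduled dose** — the reference dose fixed in room coordinates while
  the anatomy moves under it.  **Adapted dose** — the same conformal
  recipe re-applied to the margin expansion of the day's deformed CTV,
  i.e. a re-conformation surrogate for daily re-optimization.  The
  surrogate preserves the property the analysis measures (the adapted
  dose conforms to the anatomy of the day) and makes adapted deviations
  essentially zero by construction; real adaptive plans scatter within a
  few percent of the reference, so the synthetic adapted distribution is
  tighter than a clinical one.
* **Displacement field** — the forward reference→fraction mapping,
  recorded on the reference grid for pull-back accumulation.  The mask
  inverse uses the first-order approximation y − t − e(y − t), exact for
  pure translations.
* Edit-class labels are drawn from the categorical distribution of the
  motivating cohort's contour-edit grades, and the delivered-plan flag is
  Bernoulli with the cohort's adaptive-delivery share; both are metadata
  generators only and do not influence dosimetry.

Default problem sizes: 64³ voxels at 2 mm and 6 fractions × 10 series for
cohort-level runs; 24³–32³ grids in unit tests.  A single seeded
generator drives every draw; per-series seeds are spawned from the cohort
seed and recorded in the manifest.

What the generator does **not** model: CBCT imaging and segmentation
error, dose calculation on changing densities, intrafractional motion,
volume change (the elastic component is divergence-limited), realistic
organ-at-risk reference contours (the reference OAR gEUD uses the first
fraction's organ as the stand-in when no planning contour exists), or
plan-quality variation between re-optimizations.  Passing tests therefore
demonstrate the correctness and direction-of-effect of the *evaluation
machinery*, not clinical effect sizes: cohort medians and switch counts
from the simulator are functions of the chosen drift scale, and only
their qualitative contrasts (adapted ≈ reference; scheduled deteriorates;
both effects stronger at 0 mm margin; no switches without drift) are
meaningful claims.

## Serialization

Volumes are NRRD (via SimpleITK): masks as 8-bit 0/1 (bit-exact round
trip), doses as float64 (≤1e-6 Gy round trip), displacement fields as
3-component vector volumes; a JSON manifest holds prescription, margin,
per-fraction file names, delivered plan and edit class.  Arrays are
stored (z, y, x); physical coordinates are voxel-center based,
origin + index·spacing, reported (x, y, z) in mm.  Grid geometries are
compared with a 1e-6 mm tolerance.  DICOM-RT import is a possible future
adapter, deliberately out of scope.

## Known limitations

* The adapted-plan surrogate has no plan-quality noise (see above).
* The mask inverse of the elastic deformation is first-order; at the
  default 2 mm amplitude the induced boundary error is well under a
  voxel.
* Out-of-grid pull-back contributes 0 Gy; on small grids with large
  drift this can artificially cool accumulated edges (logged and
  counted).  Cohort-scale runs keep the target deep inside the grid.
* The edit-class tally accepts an explicit denominator because a graded
  subset can be smaller than the number of assessed fractions.
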