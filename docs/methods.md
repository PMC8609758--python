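# Methods

## Problem and scope

Guided endodontic access drills a bur along a virtually planned path
through a tooth-supported template. Accuracy is judged by superimposing
the post-operative scan onto the planning scan and comparing the executed
bur pose with the planned one. This package implements the analysis layer
only: landmark-based superimposition, the deviation statistics, the
sleeve tolerance model, the statistical reporting, and a synthetic study
generator that stands in for the imaging data. It does not process
DICOM/STL volumes, plan cavities, or model the physical drilling
protocol.

## Deviation geometry

A drill path is a directed segment from coronal base to apical tip in a
single right-handed millimetre frame. Given a planned pose *v* and an
executed pose *a* expressed in the same frame:

* coronal deviation = |v.base − a.base| (mm)
* apical deviation = |v.tip − a.tip| (mm)
* angular deviation = angle between the directed unit axes (degrees)

Axes are deliberately directed (no folding to [0°, 90°]): both paths share
the coronal→apical orientation, so a near-180° result flags a
reversed-axis input instead of masking it. The angle is computed as
`2·atan2(|u−v|, |u+v|)`, algebraically equal to `arccos(u·v)` but exact
near 0° and 180°, where the arccos form has a ~10⁻⁶-degree conditioning
floor. All angles are degrees end to end; values carry full float
precision and are rounded (half-up, two decimals) only when a report is
rendered.

## Registration

The superimposition transform is the closed-form least-squares proper
rigid fit (centroid subtraction, SVD of the cross-covariance, smallest
singular direction sign-corrected to force det = +1). Correspondence is
by landmark label, order-independent, unweighted. Collinear landmark sets
(second singular value below 10⁻⁹ of the largest) and fewer than three
correspondences are errors, as is any label mismatch. FRE is the RMS
residual after alignment. A similarity fit (`allow_scale=True`, Umeyama
scale) exists as a config option but defaults off: both frames image the
same physical models, so scale is unity. Executed poses are always mapped
post→pre (into the planning frame) before measurement.

## Sleeve intrinsic error

A bur shank of diameter *d* in a sleeve bore of diameter *D* and height
*h* has diametral play `gap = D − d` and can tilt at most
`θ_max = arctan(gap/h)` — the shank pivoting across the full diametral
play over the sleeve height. The worst-case lateral tip displacement at
drilling depth *z* beyond the sleeve exit is bounded by
`gap + tan(θ_max)·z`. For the default guide (1.09/1.0/3 mm, 13 mm of free
drilling below the sleeve) these are 1.7184° and 0.48 mm. Note
arctan(0.09/3) rounds to 1.72°; a truncated 1.71° sometimes appears in
the literature for the same geometry, and comparisons should allow
±0.015°.

The Monte-Carlo companion draws placements uniformly over the mechanical
feasible set: entry offset uniform on the disc of radius gap/2, tilt
azimuth uniform, tilt magnitude uniform up to the position-dependent
maximum that keeps the shank inside the bore over the full height. Every
draw satisfies the analytic bound by construction (with an explicit clamp
against float rounding at the pivot extreme); the sample maximum
approaches the bound as n grows. Under this sampling law the expected
number of draws within 0.05° of the supremum at n = 10⁵ is of order one,
so sup-convergence checks at that tolerance are run under a fixed seed.

## Synthetic study generator

The generator replicates a three-group ex-vivo design: anterior teeth
(n = 36), premolars (n = 33) and molars (n = 48) — 117 guided cavities
across six jaw models — with 16 mm working-length burs.

Per case, the executed pose perturbs the plan by:

1. a 2-D base offset perpendicular to the planned axis, iid Gaussian per
   axis with per-group sd `σ_c`; its magnitude is Rayleigh with mean
   `σ_c·√(π/2)`, and `σ_c` is calibrated so that mean equals the
   reference per-group coronal mean (0.09 / 0.07 / 0.22 mm);
2. a tilt about the executed base with uniform azimuth and half-normal
   magnitude of scale `s`, calibrated so the half-normal mean `s·√(2/π)`
   equals the reference per-group angular mean (1.73 / 2.23 / 4.00°) —
   the molar group's larger scales stand in for the occlusal-interference
   mechanism, with no mechanical model attempted;
3. independent 3-D Gaussian tip jitter, sd 0.15 mm per axis by default —
   one CBCT voxel (150 µm) of tip-localisation noise.

**The apical means are emergent, not calibrated.** A tilt *t* displaces a
16 mm tip by `2·16·sin(t/2)` ≈ 0.28·t[°] mm, so any rigid-pose generator
matching the reference angular means produces apical group means around
0.5–1.2 mm — larger than the reference apical means (0.28/0.40/0.64 mm).
The three reference means are in fact mutually incompatible with rigid
16 mm paths (the chord implied by the angular mean exceeds
coronal + apical in every group), presumably because the original
measurements were taken view-wise on screen rather than as 3-D vector
norms. We therefore calibrate the two free moments (coronal, angular),
let apical follow from the geometry, and validate the generator's apical
means against its own Monte-Carlo expectation.

**Accessibility rule.** Real studies probe each cavity with a size-10
K-file; in silico a transparent geometric stand-in is used and clearly
labelled as such in outputs: a canal target sits at the planned tip with
the planned axis, and a case is accessible iff the executed tip lands
within `orifice_radius_mm` of the entry *and* the executed axis is within
`max_entry_angle_deg` of the canal axis. Defaults (1.5 mm, 4.5°) were set
from the half-normal tail probabilities of the calibrated tilt scales so
that the default study reproduces the reference inaccessibility pattern
(expected ≈ 1.5/4.3/17.9 by group against 2/3/18; fraction ≈ 0.20 vs
23/117 = 0.197) and the reported discrimination ordering
(angular > apical > coronal). With an 0.35 mm radius the apical condition
would bind first and invert the ordering, which is why the radius is
deliberately generous. These knobs are configuration, not reported facts.

**Frames.** Each model's post-operative frame is a random rigid transform
of its pre-operative frame (rotation up to 10°, translation up to ±5 mm
per axis) plus iid Gaussian landmark localisation noise (default 0.1 mm,
sub-voxel picking precision); six landmarks per model by default. Pose
tables written to disk carry executed poses in the post frame, so reading
a written study forces the pipeline through genuine registration.

What the generator does *not* emulate: real CBCT artefacts, tooth-type
specific canal anatomy, correlated per-model operator effects, the
empirical K-file probing, or any occlusion mechanics. Passing tests
therefore demonstrate the correctness and calibration of the analysis
machinery, not the clinical accuracy figures themselves.

## Statistics

Group tables use sample SD (n−1; a singleton group reports 0). The
omnibus test is Kruskal–Wallis (midranks, tie-corrected, chi-square
reference); post-hocs are two-sided Mann–Whitney U with tie-corrected
normal approximation (no continuity correction) and Bonferroni
multiplication capped at 1 — the choice under which equivalent groups
report an adjusted p of exactly 1.00. The originating analyses do not
name their exact SPSS procedures; these choices are documented
assumptions.

ROC curves score each deviation metric against inaccessibility (higher
deviation = more positive). The AUC is the trapezoidal area over all
distinct thresholds and equals the tie-aware normalised Mann–Whitney U
exactly; the SE is Hanley–McNeil, the p-value a two-sided normal test of
AUC = 0.5, with a seeded label-permutation test available as a
robustness check. Fully degenerate cases (single-class labels) skip the
ROC stage with a warning rather than failing a run.

Pooled means are n-weighted means of group means. For the reference
values, pooling reproduces the published apical (0.46 mm) and angular
(2.8°) overall figures at printed precision; the published overall
coronal value (0.13 mm) is not reproducible from the published (rounded)
group means, which pool to 0.138, and is therefore not asserted anywhere.

## Numerical and design notes

* Rounding for reports is decimal half-up (0.125 → 0.13), matching
  two-decimal table conventions; machine outputs are full precision.
* Zero-noise studies measured through the registration path return
  deviations at the 10⁻¹⁴ float-residue level, not exact zeros; the
  generator's own truth table is exactly zero.
* Bur-pose CSVs are read with round-trip float parsing so write→read→write
  is byte-identical; they carry an extra `model_id` column tying cases to
  landmark frames.
* Test problem sizes: full-size studies (117 cases) for calibration and
  ordering checks (20 seeds for the AUC ordering median), 10⁴ draws for
  generator moment verification, 10⁵ for Monte-Carlo bound convergence,
  200 replicates per noise level for FRE monotonicity.

## Known limitations

* The accessibility rule is a geometric surrogate; its AUC magnitudes
  (near 1.0 for angular deviation) are tighter than empirically reported
  discrimination, because the synthetic label is a threshold on measured
  geometry. Only the ordering of the three metrics is asserted.
* Landmark configurations are uniform in a box, not anatomical; FRE/TRE
  ratios of real dentition may differ.
* No confidence intervals on group means, and no DeLong comparison
  between correlated AUCs.
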