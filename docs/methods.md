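# Methods

`adaptntcp` simulates, on synthetic anatomy, the analysis by which
online-adaptive head-and-neck proton therapy is evaluated for its effect on
normal tissue complication probability (NTCP).  Three treatment courses are
compared per patient:

* **A** — a plan robust to a 3 mm isotropic setup uncertainty, delivered
  unchanged at every fraction;
* **B** — a plan with no explicit setup robustness, delivered unchanged;
* **C** — the non-robust plan with daily online adaptation by partial
  spot-intensity re-optimization.

The per-endpoint differences `ΔNTCP_SUR = NTCP_B − NTCP_A`,
`ΔNTCP_AGC = NTCP_C − NTCP_B` and `ΔNTCP_SUR&AGC = NTCP_C − NTCP_A`
(percentage points, pp) isolate the contribution of setup-uncertainty
reduction (SUR), adaptation to geometric changes (AGC), and both combined.
The additivity identity `ΔSUR + ΔAGC = ΔSUR&AGC` holds algebraically and is
asserted on every report.

## Synthetic anatomy and motion model

Patients are voxelized phantoms (default 64×64×32 voxels at 2 mm isotropic,
homogeneous water-equivalent density 1) carrying eleven structures as
jittered ellipsoids in an anatomically ordered layout: two disjoint clinical
target volumes (boost CTV prescribed 70 Gy, low-risk CTV 57 Gy via a
simultaneous integrated boost), both parotids, oral cavity, superior
pharyngeal constrictor, supraglottic larynx and larynx, spinal cord
(cylindrical), brainstem and esophagus.  The layout is defined for a
128×128×64 mm reference volume and scaled to the actual grid extent, so
smaller grids host a proportionally smaller anatomy.  The boost CTV is
generated disjoint from the low-risk CTV so every target voxel carries a
single prescription, and targets never intersect the cord or brainstem.

Each fraction combines:

* a **residual rigid setup shift**, i.i.d. Gaussian per axis with
  `setup_sigma_mm` (default 1.5 mm).  This models the error remaining after
  in-room rigid alignment; the alignment itself is not simulated.  The
  magnitude is a package default, not a reported value.
* a **systematic anatomical drift** whose magnitude grows linearly with
  fraction index: a centripetal affine shrink of both parotids (default 10%
  linear contraction at course end, ≈ 27% volume loss — the order observed
  clinically) and of the boost CTV (5%), plus an anterior–superior larynx
  displacement (default 4 mm at course end) whose spatial profile is the
  cosine-squared taper of a wide window around the larynx.  The larynx
  amplitude deliberately exceeds the oropharyngeal drift, reflecting the
  much larger inter-fraction mobility of the larynx.  An optional medial
  parotid translation (`parotid_medial_drift_mm`, default 0) is available as
  an additional stressor; it is off by default because a sub-voxel
  translation aliases thresholded masks and breaks the monotone-volume
  guarantee of the shrink model.

Displacement fields map planning to daily coordinates (`φ(x) = x + u(x)`);
the exact inverse is computed by fixed-point iteration and stored, so dose
accumulation needs no image registration and is exactly testable.  At the
default geometry the forward∘inverse round trip is identity to < 0.06 voxel,
and the field gradient stays below 0.75 mm/mm (configurable cap; values ≥ 1
would not be invertible).  Daily densities and contours are pull-backs of
the planning volumes through the inverse field (masks thresholded at 0.5).

What the generator does **not** emulate: CT/CBCT image formation and
artifacts, contour-propagation/registration error (deliberately neglected so
adaptation is evaluated under a best-case geometry), heterogeneous tissue by
default, treatment interruptions, and random day-to-day organ deformation —
drift is purely systematic, so the generator's anatomical variation is
smoother than clinical reality.  Passing tests therefore demonstrate the
internal consistency and the qualitative mechanism structure of the
analysis, not clinical effect sizes.

## Dose engine

An analytic pencil-beam model stands in for Monte Carlo transport.  The
integral depth dose is a flat-ish entrance plateau cut off sigmoidally at
the nominal range plus an asymmetric Gaussian Bragg peak (proximal σ 3 mm,
distal falloff σ 1 mm); its maximum sits within a voxel of the nominal
range, and dose beyond range + 5 falloff widths is < 1% of the peak.  The
lateral profile is Gaussian with σ(d) = 3 mm + 0.02·d.  Water-equivalent
depth comes from an exact ray-box integral on homogeneous phantoms and from
a rotate–cumulative-sum–rotate-back integration (padded so no material crops
off) on heterogeneous ones; the two agree with an independent ray-march
oracle to about one voxel.  A constant RBE of 1.1 is folded into the
influence matrices, stored sparse with entries below 1e-4 of the per-column
maximum dropped (this cutoff slightly perturbs exact-conservation checks).

Beams are parallel (no divergence) in the axial plane at gantry angles 60°,
180° and 300°.  A rigid setup error is an isocenter translation; for a
parallel beam only the component perpendicular to the beam axis changes the
dose, because water-equivalent depth is measured from the patient surface,
which translates with the patient.  Spots are placed on a beam's-eye-view
lateral grid (7 mm default spacing) with energy layers every 7 mm of
water-equivalent depth, covering both CTVs.

## Planning and online adaptation

The optimization objective is a sum of one-sided quadratic penalties:
per-voxel target corridors at 95%–107% of prescription for both CTVs
(weight 100), mean-dose limits of 26 Gy per parotid, 42 Gy superior
constrictor, 40 Gy larynx (weight 2), per-voxel maximum-dose limits of
45 Gy cord and 54 Gy brainstem (weight 5), and small quadratic
dose-minimization terms for oral cavity and esophagus (weight 0.02),
mirroring organs whose dose is minimized without compromising coverage.
Percentile metrics themselves (D98%, D2%) are evaluated post hoc; the
corridor is their standard smooth surrogate.  The per-term weights are
package defaults — no conclusion of the analysis depends on their exact
values.  Range uncertainty, delineation uncertainty and variable RBE are
out of scope.

Robust plans minimize the worst case over a discrete scenario set: the six
axis-aligned ±3 mm shifts plus nominal.  The minimax is smoothed by a
temperature-scaled log-sum-exp (relative temperature 1e-3) and solved with
projected quasi-Newton iterations (L-BFGS-B, `w ≥ 0`, iteration cap 500,
relative tolerance 1e-6); with a single scenario the smoothed objective is
identically the plain objective.  Accepted iterates descend monotonically,
and a warm start is never worsened.

Online adaptation selects the smallest set of spots carrying at least 33%
of the total weight (descending-weight greedy scan, which attains minimum
cardinality for a sum threshold; ties break toward the lower spot index),
padded to at least ⌈10%⌉ of all spots, the selection being computed from
the original planning weights.  Only the selected weights are re-optimized
on the daily anatomy with the original objectives; all others are returned
bit-exactly unchanged.  The 33% rule is applied globally over all beams.
Each day's solve starts from the original plan weights by default
(`start_from="previous"` switches to warm-starting from the previous day's
adapted weights).  Because the base weights are feasible for the restricted
problem, adaptation can never worsen the daily objective beyond solver
tolerance; near an optimum the restricted problem has flat directions, so
weights may drift a few percent along an iso-objective valley even when the
dose is essentially unchanged.

## Accumulation and NTCP

Per-fraction dose is the plan dose divided uniformly over the course
(30–35 fractions, consistent with ≈ 2 Gy per boost fraction), computed on
the daily geometry.  Accumulation pulls each daily dose back to the
planning grid by trilinear interpolation at `x + u(x)` (dose interpolation,
not energy–mass transfer); positions mapping outside the grid contribute
zero with a logged warning.

Dose-volume metrics are computed on the exact voxel-dose empirical
distribution (no binning): `D_p%` is the smallest voxel dose `d` such that
the fraction of the structure receiving ≥ d is ≤ p/100; a 0.1 Gy-binned
cumulative curve is kept only for export.  gEUD is the power mean with
exponent 1/n (n = 1 reduces exactly to the mean dose, the only case the
shipped models use; the general form is an extension).  The six endpoint
models are: oral mucositis, logistic `(1 + (D50/D)^k)^-1` with D50 = 51 Gy,
k = 1 on mean oral-cavity dose (the oral-cavity structure plays the role of
the oral mucosa); xerostomia, probit `Φ((gEUD − D50)/(m·D50))` with
D50 = 39.9 Gy, m = 0.4 on the contralateral parotid; swallowing dysfunction
for solids (a = 5.98, b = 0.074 Gy⁻¹, c = −1.209 with X2 ≡ 1, implemented
literally as a constant intercept shift) and liquids (a = 6.89, b = 0.049,
c = 0.048) and physician-rated dysphagia (a = 6.09, b = 0.057, c = 0.037),
all multivariable logistic `(1 + e^(a − b·X1 − c·X2))^-1` on mean doses of
supraglottic larynx and superior constrictor; and aspiration, probit with
D50 = 46.5 Gy, m = 0.5 on the larynx.  A structure that is absent, empty,
or entirely inside the target volumes makes its endpoint "not evaluable",
which propagates as missing — never as zero — and excludes the endpoint
from totals.

The "any-of-four" total over xerostomia, dysphagia, aspiration and oral
mucositis is `1 − Π(1 − p_i)` under an independence assumption (the choice
is recorded in every export header); the plain sum of per-endpoint
reductions is exported alongside.  Clinical significance per mechanism uses
a configurable two-branch rule modeled on model-based patient-selection
criteria: any single endpoint reduced by ≥ 10 pp, or summed reductions
≥ 15 pp over the four main endpoints.  Both thresholds are configuration,
not asserted constants.  Cohort means are taken over evaluable patients
only.

The linearity experiment re-plans one patient at setup-uncertainty settings
{0, 1, 3} mm, delivers each plan without adaptation over the same fraction
series, and reports per-endpoint NTCP per setting plus the interpolation
residual of the middle setting against the line through the endpoints.

## Numerical choices and problem sizes

Unit tests run on a 32×32×16 grid; the conservation/null-recovery check
runs at the full 64×64×32 study geometry; the seeded demonstration cohort
(5 patients × 30–35 fractions, default motion) runs on 48×48×24 — sizes
chosen so the whole suite completes on a single desktop CPU in minutes.
Because drift amplitudes are physical (mm) while tiny grids shrink the
anatomy, deliberately small test fixtures use a reduced larynx amplitude;
the 0.1-voxel invertibility guarantee is stated and tested at the default
geometry.  Daily influence matrices are cached per fraction and shared
across the three courses; static fractions reuse the planning influence
exactly, which is what makes zero-motion courses collapse to the static
plan dose to floating-point accuracy.

Known limitations: the dose engine is qualitative (no nuclear halo, no
divergence, no heterogeneity conversion); adaptation quality is evaluated
under ground-truth anatomy, a best case; NTCP models are applied to
photon-derived parameters as shipped; and cohort-level numbers from the
synthetic cohort characterize the pipeline's mechanics, not any patient
population.
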