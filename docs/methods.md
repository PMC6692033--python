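# Methods

This note documents the models, algorithms and design choices behind
`vmatqa`, in the order the analysis runs.

## Geometry contract

All dose grids and masks live on regular lattices described by an origin
(the centre of voxel (0,0,0)), a per-axis spacing and voxel counts, in
millimetres, axes ordered (x, y, z). Two objects are *co-registered* when
origin, spacing, dims and frame label all agree (coordinates to 1e-9 mm);
every cross-grid operation requires co-registration and raises otherwise.
Masks are plain boolean volumes on the same lattice; structure volumes are
voxel-counted (count × voxel volume) with no partial-volume weighting,
which is consistent because masks are rasterised on the very grid the doses
live on.

## Gamma engine

The gamma index combines a dose-difference term and a
distance-to-agreement (DTA) term; for each non-excluded reference point the
engine minimises over evaluated positions

γ(r) = min over e of sqrt( (D_e(e) − D_r(r))² / tol(r)² + ‖e − r‖² / δ² ).

Implementation choices:

* **Candidate set.** The evaluated dose is linearly resampled onto a fine
  lattice whose nodes contain the reference voxel centres; the subdivision
  factor per axis is round(spacing / `resample_step`), default step 1 mm on
  a 3 mm grid. Because the fine lattice is an exact integer subdivision,
  the multilinear interpolation reduces to separable weighted sums and the
  DTA minimisation to integer lattice shifts.
* **Search strategy.** Offsets are visited sorted by physical distance and
  the scan terminates once the distance term alone, dist/δ, reaches every
  point's current best γ — an exact (not heuristic) termination. The search
  radius is `search_radius_factor` × δ (default 3) and γ is reported capped
  at that factor; since the cap exceeds the pass limit, capping can never
  flip a pass/fail decision.
* **Normalization.** `local` (the default; the dose tolerance is a
  percentage of the local reference dose) or `global` (of the reference
  maximum). Local normalization at zero reference dose is undefined; such
  points are excluded alongside the threshold-excluded set.
* **Low-dose threshold.** Points whose reference dose falls below 10% of
  the global reference maximum are excluded from both the numerator and the
  denominator of %GP. Which distribution the threshold reads
  (`threshold_on`) is a flag because measurement systems differ; reference
  is the default.
* **Pass rule.** γ ≤ 1 passes, boundary inclusive, with an absolute
  tolerance of 1e-9 at the boundary so that a dose offset lying exactly at
  tolerance classifies deterministically rather than by rounding luck.
* **2D mode.** A plane (by default the axial plane through the planned dose
  maximum) is extracted from both grids and the DTA search is restricted to
  that plane, matching what a planar detector array can see. The low-dose
  threshold then references the plane maximum.
* **Oracle.** `brute_force_gamma` minimises exhaustively over *every* fine
  lattice point with no radius and no cap (O(N_ref × N_eval), refused above
  a size cap). It shares only the candidate-lattice construction with the
  fast path; the minimisation code is independent, and the test suite
  asserts agreement to 1e-9 wherever the cap is not hit.

Monotonicity — loosening (ΔD, δ) from 1%/1 mm to 2%/2 mm to 3%/3 mm never
decreases %GP — holds exactly in this construction: every candidate's γ
value decreases and the candidate set grows, so the per-point minimum
decreases while the excluded set is unchanged.

## DVH engine

DVH curves are exact empirical survival functions of the masked voxel-dose
sample — no histogram binning — so D_x% (the dose received by the hottest
x% of the structure) is the (1 − x/100) sample quantile with linear
interpolation, deterministically. D_max is the maximum single voxel; no
small-volume surrogate (D_0.03cc etc.) is applied, though callers can
request any D_x% instead. The per-site metric presets cover target coverage
(PTV D_1%, D_98%, D_mean) and the standard pelvic organ-at-risk dose points
(bladder/rectum D_x%, femoral head D_max/D_x%, bowel, penile bulb, bone
marrow).

%DE is the signed relative error 100·(D_eval − D_ref)/D_ref, undefined for
non-positive reference dose (the error message reports the absolute dose
difference instead). Cohort tables report the **mean of per-plan %DE**, not
the %DE of the mean doses; on heterogeneous cohorts the two differ
substantially (a structure whose reference dose varies by an order of
magnitude across patients can show a large mean relative error alongside a
small gap in mean dose), and the per-plan mean is the quantity that the
correlation analysis consumes.

## QA statistics

* **Pearson correlation** per (criterion, method, structure, metric) cell
  between per-plan %GP and %DE, with the two-sided p-value from the t
  distribution on n − 2 degrees of freedom (delegated to scipy). Cells with
  fewer than 3 plans or constant input are flagged and skipped.
* **Cohort summaries** report the mean of |r| per criterion and method —
  correlation *strength* regardless of sign — alongside the share of
  negative coefficients (a negative r means larger dose errors at lower
  passing rates, the direction a useful QA metric should show).
* **FN/TP classification** at the clinical action levels: a case is one
  (plan, structure-metric) pair; condition-positive means |%DE| > 3% (a
  `signed` flag restricts to hot errors only); %GP ≥ 95% counts as a QA
  pass, the boundary deliberately assigned to the pass side. Pass+positive
  = FN, fail+positive = TP, fail+clean = FP, pass+clean = TN; the four
  counts partition the cases for any thresholds.
* **ROC/AUC** over the %GP decision threshold, scoring −%GP (lower passing
  rate = more suspicious). The curve and trapezoid AUC are delegated to
  scikit-learn; the tests verify the AUC against an exhaustive
  Mann–Whitney pair-counting oracle (ties ½) and its invariance under
  monotone score transforms.
* **Paired t-test** between dose sources on per-plan differences (scipy);
  zero-variance differences are flagged degenerate with p = 1 for identical
  vectors.

## Synthetic cohorts

The generator replaces the clinical planning/measurement chain and is
explicitly a stylisation: its purpose is to produce paired dose grids whose
*statistical structure* (smooth target plateau, penumbra gradients,
low-dose bath, small measurement-chain perturbations, known injected
errors) exercises the analysis, not to model any TPS.

**Planned dose.** Default grids are 64×64×48 voxels at 3 mm — a pelvic
field of view at the calculation resolution typical for VMAT plans, sized
so that a full 3D gamma evaluation of a cohort stays comfortable on a
single CPU. Anatomy is ellipsoidal: a PTV at the isocentre and
site-specific organ ellipsoids (bladder, rectum, bowel, femoral heads,
penile bulb or bone marrow), each jittered per plan by a 2 mm s.d. normal
displacement; structures colliding with the grid boundary trigger a bounded
re-draw. The dose is a sigmoidal plateau over the PTV — logistic in the
(first-order) signed distance to the PTV surface, length scale 3 mm,
plateau extended 9 mm beyond the surface so the target stays covered — plus
a 30%-amplitude low-dose bath decaying with 55 mm length, modulated by a
smooth ~1% multiplicative texture, and finally normalised so the PTV mean
dose equals the prescription (50 Gy prostate-like, 45 Gy
endometrial-like, 25 fractions). This yields D_98% ≈ 0.95–0.97 of
prescription and organ-at-risk doses in clinically familiar ranges.

**Error model.** Reconstructed = noise(hotspots(scale(blur(shift(planned)))))
in that fixed order: rigid shift (linear interpolation, zero-padded, with a
warning when integral dose leaves the grid), Gaussian blur parameterised by
FWHM, global scale ×(1+s), multiplicative Gaussian hot/cold spots
(amplitude % of local dose, Gaussian radial profile), and multiplicative
voxel noise of s.d. 0.5% — the statistical uncertainty typical of a Monte
Carlo dose calculation. The 7.62 mm centre-to-centre pitch of a 32×32
ion-chamber array is kept as the `DETECTOR_PITCH_MM` constant: an
*uncorrected* array measurement corresponds to a blur FWHM of roughly that
pitch, but a reconstruction-corrected chain leaves only a small residual
blur, so the identity — not the raw pitch — is the `ErrorModel` default and
the default study law draws FWHM from 1.5–3.5 mm.

**Error laws.** Cohorts draw per-plan parameters from named laws: `zero`
(identity), `noise_only`, `scale_only` (uniform 0–4% output drift,
straddling the 3% action level), `recovery` (symmetric ±4% scale, for
slope recovery), `hotspot_only` (one ±8% spot, radius 8–14 mm, placed
40–65 mm from the isocentre — localised errors away from the target), and
`study` (the default mix of small residual errors). All randomness flows
from a single cohort seed through `numpy.random.SeedSequence.spawn`, with
per-plan children for anatomy, error draw and noise; equal seeds give
bit-identical cohorts.

**What passing tests do and do not show.** The synthetic cohorts reproduce
the *mechanisms* — %GP monotone in the criteria, global scale errors
driving %GP and target %DE together (strong negative correlation),
localised errors degrading %GP while leaving the target DVH untouched
(weak correlation, false negatives at the action level) — but not the
numerical values of any clinical cohort: real plans have non-ellipsoidal
anatomy, heterogeneity corrections, multi-arc fluence structure, and
measurement chains with correlated, not independent, errors. Cohort-level
clinical results (mean %GP per criterion, per-metric correlation tables,
AUC values) therefore cannot be compared number-for-number against this
package's synthetic output.

## Numerical choices

* Portable text I/O prints float64 with `%.17g`, which round-trips
  bit-exactly; round-trip identity is property-tested.
* Gamma boundary tolerance 1e-9 (absolute, on γ); oracle-agreement
  tolerance 1e-9; coordinate equality 1e-9 mm.
* D_x% inverse interpolation is the linear-interpolated sample quantile;
  ties in the gamma minimisation are irrelevant (a min over a finite set).
* The brute-force oracle refuses problems above 5·10⁷ reference×candidate
  pairs and chunks its broadcasts to bound memory.
* `run_study` is fail-fast: any stage failure raises an error naming the
  stage and removes partial outputs; the JSON log records version, config,
  seeds and per-stage wall time, sufficient to re-run bit-identically.

## Problem sizes used in tests and the acceptance script

Oracle-equivalence checks run on 200 randomised small pairs (12×12 planes
and 6×6×5 volumes at 3 mm). Cohort-level checks use full-size 64×64×48
plans: 8–10 plans for criterion monotonicity (all three criteria, 2D and
3D), and 25-plan cohorts for scale recovery and for the scale-vs-hotspot
correlation contrast (3%/3 mm). These sizes keep a complete run in the
minutes range on one CPU while leaving every mechanism measurable.

## Known limitations

* Anatomy is ellipsoidal and dose synthesis isotropic around the target; no
  CT, no heterogeneity, no arc/fluence structure.
* No biological indices (EUD, NTCP/TCP), no plan (RTPLAN) handling, no
  small-volume D_max surrogate by default.
* 2D mode models a single coronal/axial plane with in-plane DTA only; real
  planar arrays also integrate obliquely through the phantom.
* The DICOM reader covers the common RTDOSE layout (uniform frame offsets)
  and planar RTSTRUCT contours only.
* Multiple-testing correction is deliberately absent from the correlation
  tables; the cell-level p-values are descriptive.
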