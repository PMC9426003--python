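# Methods

This note records the models, conventions and design choices behind
`eulplan`, and what the synthetic phantom cohort does and does not emulate.

## Voxel model and units

All volumes live on a shared rectilinear lattice, axis order `(z, y, x)`
(slice, anterior–posterior, left–right), 0-based indices. File headers use
millimetres (imaging convention); every user-facing length — distances,
margins, EUL — is in centimetres, and conversion happens in one place
(`grid.MM_PER_CM`). Dose is absorbed dose in gray. Masks on mismatched
lattices are rejected rather than resampled; resampling is out of scope.

## Distance maps and EUL

`distance_map` computes, for every voxel, the shortest centre-to-centre
Euclidean distance to the nearest PTV voxel, with anisotropic spacing
respected (`scipy.ndimage.distance_transform_edt`). The convention is
unsigned: voxels inside the PTV are at distance zero, and organ voxels
inside the PTV contribute `L_i = 0` to the EUL mean rather than being
excluded. This keeps the metric well defined for organs overlapping the
target; a signed-distance variant is deliberately not offered. Sub-voxel
surface distance is not modelled — distances are exact for voxel centres,
which makes the implementation verifiable against an exhaustive
min-over-source oracle (the suite checks agreement to 1e-9 cm).

EUL and gEUD share one power-mean kernel. For numerical robustness the mean
is rescaled by the extreme element (`M_a = m·(mean((x/m)^a))^(1/a)` with
`m = max` for `a > 0`, `m = min` for `a < 0`), which keeps exponents of
order ±500 finite. `a = 0` is rejected (undefined exponent), as is `a < 0`
with any zero value. The EUL unit is cm; the regression slopes (≈ −5 to −6
Gy per unit) are only physically plausible on that scale.

## Rings and assistant structures

Ring shells are half-open: `inner < L ≤ outer` (inner-exclusive,
outer-inclusive), so stepped rings tile without overlap and every ring is
disjoint from its source. `dilate` includes voxels with `L ≤ margin`;
margin 0 is the identity.

The assistant-structure procedure intersects a preliminary structure (the
body restricted to the 40% isodose of a parallel-opposed setup-beam dose)
with ring shells at (0.5, 1.0), (1.0, 1.5), (1.5, 2.5), (2.5, 3.5) and
(3.5, 4.5) cm to give AS1–AS5. AS4 additionally receives the part of the
outermost shell lying outside the preliminary structure — implemented
literally as specified even though that range coincides with AS5's shell;
disjointness still holds because AS5 is inside the preliminary structure
and the extra part is outside it. AS6 is the remainder of the preliminary
structure beyond the 0.5 cm PTV expansion. The preliminary structure is
intersected with the body contour (whether to do so is a free choice; the
body restriction is the conservative one). The resulting six structures
are pairwise disjoint and avoid the 0.5 cm-expanded PTV by construction;
`ASSet.validate` re-checks both at run time.

## Dose metrics

* gEUD: the shared power-mean kernel on organ doses; `a = 1` is the mean
  dose, and the suite checks monotonicity in `a` and the large-`|a|`
  extreme-dose limits. The limit check uses `|a| = 500`: for `N` voxels
  the gap to the extreme is bounded by a factor `N^(1/a)`, which for
  `N = 100` is within 1% only once `|a| ≳ 460`.
* All volume metrics count voxels exactly; the binned DVH curve is kept for
  plotting/inspection, but `v_at_dose`/`d_at_volume` answer from the sorted
  per-voxel doses. `d_at_volume(v)` returns the largest dose received by at
  least `v`% of the volume (so `D95` is the `ceil(0.95·N)`-th largest dose).
* HI = (D2% − D98%) / D50% and CI is Paddick's
  `TV_rx² / (TV · V_rx)` — the dominant conventions; no formula is uniquely
  standard, so these are package choices and the suite pins them with
  hand-computed fixtures.
* `normalize_plan` rescales so D95(PTV) equals the prescription, matching
  the coverage requirement "95% of the PTV receives the prescription";
  PTV `V95` is likewise reported as the percent of PTV at or above the
  prescription dose (not 95% of it).

## Knowledge-based models

`fit_eekb` is simple OLS (via `scipy.stats.linregress`) with
`R² = 1 − SSR/SST`, `adj R² = 1 − (1−R²)(n−1)/(n−2)`, the two-sided Pearson
test and residual standard error `sqrt(SSR/(n−2))`. Intervals use the
standard t-based forms: PI half-width
`t_{(1+γ)/2, n−2} · s · sqrt(1 + 1/n + (x−x̄)²/Sxx)`, CI drops the leading 1.
t-quantiles are always computed numerically; no normal approximation at any
n. Plan-set consistency reports both plain and adjusted R² — adjusted
because only the adjusted form can go negative for uncorrelated plan sets,
plain because it is what a reader expects of a regression summary.

The shipped published models (`bladder_a1.json`, `rectum_a1.json`) carry
coefficients, n and R² only; they have no residual spread, so interval
queries on them raise instead of fabricating a band. Model JSON encodes
reals as decimal strings, making save → load round-trips bit-exact.

`paired_t_test` is the classic two-tailed paired t with `df = n−1`;
identical samples return `t = 0, p = 1` by convention, while zero-variance
differences with nonzero mean raise (the statistic diverges).

## Synthetic phantom cohort — what it emulates

The phantom is an elliptical body on a 48×64×64 grid at 4 mm isotropic
spacing (the calculation-grid resolution of the emulated plans), with an
ellipsoidal PTV at centre, a bladder anterior, an elongated rectum
posterior and two spherical femoral heads lateral. The anatomy centre is
snapped to a voxel centre and organ positions are placed so the requested
PTV–organ gap is realized on the lattice to within half a voxel; a ±10%
seeded jitter of the bladder/rectum semi-axes varies organ size across a
cohort. Negative gaps push the organ into the target (overlap).

Dose is not transported. Inside the PTV the dose is the prescription;
outside it falls off as `rx · exp(−k·L)` with independent rates `k` for the
anterior and posterior half-spaces (split at the PTV centroid's coronal
plane). Because each organ's gEUD is strictly decreasing in its half-space
rate, the rate meeting a requested gEUD target is found by `brentq`
bisection (achieved within 1e-4 Gy; verified to 1e-3 Gy end to end).
Exponential fall-off is the simplest monotone model that makes exact target
matching possible with one scalar per organ; it reproduces none of the
beam-level texture of a real optimizer (no hot spots, no streaks, perfectly
conformal prescription isodose), so plan-quality numbers from the phantom
are smoother and more favourable than clinical ones. Passing tests
demonstrate correct *computation* of the metrics and recovery of the
generating model, not clinical realism.

The default cohort (`CohortSpec`) encodes the emulated study conditions:
60 cases, gaps uniform in 0.2–1.8 cm per organ, truth lines equal to the
published bladder/rectum coefficients, Gaussian EUD noise of 1.5 Gy around
the line, `a = 1`, prescription 59.4 Gy / 33 fractions. The noise level
was chosen so that a refit of a simulated cohort lands near the published
R² (≈ 0.7–0.8) given the geometric EUL spread the gap range produces.
Targets falling outside the achievable gEUD range are clipped (with a
0.1 Gy safety margin) and flagged in the truth table so recovery analyses
can exclude them; with the default conditions clipping does not occur.
`generate_cohort(..., include_dose=False)` skips the dose-grid stage for
geometry-only studies (EULs and targets are identical either way; only the
re-measured achieved gEUD — which differs from the target by ≤ 1e-3 Gy —
is skipped). The 200-replicate coverage check in the suite uses this fast
path; a separate test runs the full dose stage.

The setup-beam simulator (`simulate_ap_pa_dose`) models two opposed beams
along the anterior–posterior axis as a prescription-dose corridor over the
PTV's beam's-eye-view projection dilated by 0.5 cm, decaying exponentially
with lateral distance (default 1.5 cm⁻¹, chosen to give the 40% isodose a
realistic 0.6 cm penumbra). It exists to derive the preliminary assistant
structure, nothing more.

## Numerical choices and degenerate inputs

* Voxel membership in analytic shapes uses a 1e-9 relative tolerance so
  centres lying exactly on a surface are included deterministically.
* Empty structures raise (`EmptyStructureError`) everywhere a mean or
  distance is required; `plan_metrics` skips empty OARs with a warning
  instead, since one missing contour should not void a plan evaluation.
* Conformity index returns 0 when no voxel reaches the prescription.
* Bisection brackets are `[0, 8] cm⁻¹`; at 8 cm⁻¹ the dose 1 cm from the
  target is 0.03% of prescription, i.e. the practical lower bound of
  achievable organ gEUDs.

## Known limitations

* No DICOM-RT: structures and doses come from NRRD/NIfTI volumes or the
  phantom module; contour rasterization and TPS integration are out of
  scope, as is any optimizer — the package predicts objectives and
  evaluates plans, it does not optimize fluence.
* Distances are centre-to-centre; organs thinner than a voxel are not
  reliably represented at the default 4 mm grid.
* The published models ship without residual spread, so uncertainty
  statements require refitting on a local plan library.
* Only axis-aligned (identity-direction) volumes are read; oblique
  acquisitions must be resampled upstream.
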