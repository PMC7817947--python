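# Methods

This note documents the models, conventions, numerical choices, and known
limitations behind `kbplan`. Everything stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external data.

## Geometry and histograms

All computation happens on one axis-aligned regular voxel lattice. Voxel
indices are 0-based; physical positions refer to voxel centers; structure
masks are binary (no partial-volume weighting) and are resampled onto the
dose grid (nearest-neighbor for masks, trilinear for dose) before any
histogram is taken, so every dose-volume index is evaluated on dose-native
voxels.

**DVH.** Cumulative, "dose-at-least" convention: the ordinate at dose d is
the percent of structure volume receiving ≥ d. Bin edges are multiples of
the bin width (default 0.1 Gy), ending one bin past the structure maximum,
so the terminal ordinate is 0. Computed by sorting the member-voxel doses
and counting with a binary search; this is exactly the per-voxel definition
(verified against exhaustive counting on random grids, bit-for-bit).

**DTH.** The signed distance of each OAR voxel to the target surface,
accumulated into a cumulative curve (percent of OAR volume within distance
≤ r; default 1 mm bins). The target surface is the set of mask voxels with
at least one non-mask 6-neighbor inside the grid. Distances are computed
with a single exact Euclidean distance transform on the complement of the
surface set, which equals the minimum over all surface-voxel centers — the
same quantity an exhaustive pairwise search produces, including on
anisotropic grids. The sign is negative strictly inside the target, zero on
surface voxels, positive outside; an unsigned variant (clipped at zero
inside the target) is available via a flag. When multiple PTVs exist, the
DTH is taken against their union by default, with a per-call override to a
single PTV.

## Curve parameterization

Families of DVH/DTH curves sampled on one common abscissa (101 points; DVH
on a relative-dose axis 0–110% of the prescription, DTH on −25…+80 mm) are
parameterized by PCA: a mean curve plus orthonormal shape components.
`fit_embedding` retains the smallest k ≤ 4 components whose cumulative
explained-variance fraction reaches the target (default 0.97); if four do
not suffice, four are kept and the achieved fraction recorded. The
"contribution over 97%" rule is read as *cumulative*; a per-component
reading is possible but ambiguous, and the cumulative form is the one the
retention rule can act on. A zero-variance family degenerates to one
nominal component carrying no variance.

Reconstructed curves are projected back onto the set of valid cumulative
curves: clipped to [0, 100], then monotonized by a running maximum (from
the right for DVHs). This is the minimal projection onto valid curves;
on any curve already in the model span it is the identity, so full-rank
round-trips reproduce inputs to machine precision.

The relative-dose axis makes a trained model transferable across
prescription levels: curves are converted to Gy at the boundary
(training input, prediction output) using each case's prescription.

## The DVH prediction model

Per OAR, independently (no cross-OAR coupling):

1. **Features.** Volumetric: OAR volume (cc), target volume (cc), fraction
   of OAR inside the PTV, OAR/body volume ratio. Spatial: the 1–4 DTH
   principal-component scores. Case metadata (T stage, prescription) ride
   along but are not regressors.
2. **Feature selection.** Ordinary multivariate linear regression of each
   DVH score on all usable features; features with coefficient p < 0.05 are
   kept (at least one — the best — if none qualify). Constant columns and
   later near-duplicates of earlier columns are dropped with a warning.
   The DTH scores are additionally *always* retained
   (`TrainConfig.always_keep_dth`): a curve-shape score can depend on a DTH
   score strongly but non-monotonically (e.g. a curvature component that is
   an even function of distance), and a linear significance screen would
   discard exactly the spatial signal the model exists for. Measured on
   phantom cohorts, dropping it made one component's held-out RMSE worse
   than predicting the mean.
3. **Regression.** One ε-insensitive SVR (RBF kernel) per retained DVH
   score, on standardized features and standardized responses. Defaults:
   C = 10, ε = 0.01, gamma = "scale", tolerance 1e-8. ε is kept small so
   the insensitive tube (±ε·SD on the response) does not itself become a
   systematic prediction error; with these defaults the held-out
   mean-absolute curve error on a zero-noise 60-case phantom cohort is
   ≤ 2 percentage points at every dose level (measured 1.0–2.2 pp across
   cohort seeds). The DVH embedding used by the *model* keeps its full
   (up to four component) parameterization (`variance_target = 1.0`,
   zero-variance components trimmed): truncating at 0.97 was measured to
   leave a ~3 pp reconstruction floor on these cohorts, larger than the
   model's target accuracy.
4. **Training determinism.** Cases are sorted into a canonical
   lexicographic order on the feature matrix before fitting, so training is
   exactly invariant to input order.
5. **95% band.** Per-score residual quantiles (2.5%/97.5%) computed from
   *out-of-fold* residuals (deterministic 5-fold refits): a flexible
   regressor shrinks its own training residuals, and a band built from them
   under-covers. Cohorts smaller than 40 fall back to ±1.96·SD. The band is
   forced to contain zero. On the curve, the per-score intervals are mapped
   through the component basis as a pointwise envelope (sum of per-component
   minima/maxima), which guarantees lower95 ≤ mean ≤ upper95 at every dose.
   Band edges are projected *outward* onto valid curves (lower bound by a
   running minimum, upper bound by a running maximum) so post-processing
   never narrows the band. Because the envelope combines marginal
   per-score intervals, its pointwise coverage is approximate: measured
   90–95% at the mid-axis dose level on held-out noisy phantom cohorts
   (n = 200), with the misses concentrated at anatomies just outside the
   training feature support, where the RBF regressor extrapolates.
6. **Refinement (flag-only).** A prior plan is flagged as suboptimal when
   its planned DVH exceeds the predicted upper95 by more than 5 percentage
   points of volume over more than 20% of the dose axis. When the screened
   plans are the model's own training set (the normal refinement loop),
   each plan is predicted by a deterministic k-fold refit that holds the
   plan's fold out — a model trained on a plan cannot judge that plan; the
   default regressor was observed to memorize an isolated planted outlier
   otherwise. Flagged plans are exported for external re-optimization and
   may be re-imported; the toolkit never edits doses itself.

## Objectives

Each OAR's objective doses are read off a source curve at the sample
volumes {2, 30, 50, 70}% (linear interpolation of the dose–volume inverse).
The source is the lower bound of the 95% band — the aggressive choice that
maximizes sparing pressure — except for the four adjacent OARs (optic
chiasm, optic nerve, pituitary, inner ear; laterality suffixes are
stripped before matching) in T3/T4 cases, which use the predicted mean.
Because the band is ordered by construction, lower-bound objective doses
never exceed mean-strategy doses. The per-structure choice is recorded in a
strategy log. Target objectives are not predicted: they are emitted from
the prescription configuration (defaults 70/60/54 Gy at 98% coverage) as
lower DVH points. Priorities default to a three-tier scheme following the
score table's organ levels (targets 100 > critical 80 > sub-critical 60 >
other 40) and are fully overridable; the sample volumes and the tier values
are declared approximations, not derived quantities.

## Dosimetric indices and plan scoring

- CI (Paddick) = (V_Tref/V_T)·(V_Tref/V_ref), computed either from the
  three volumes or directly from grids (reference isodose = the target's
  prescription); both routes agree exactly.
- HI = (D_2% − D_98%)/D_50%.
- D_x% (and D_1cc = D at 100·(1 cc / volume)%) use the right-continuous
  step inverse of the cumulative curve: the largest sampled dose whose
  ordinate still reaches x. This reads plateau edges exactly (uniform dose
  ⇒ D_x% equals that dose and HI = 0 identically) and is otherwise within
  one bin width. D_max is the largest abscissa with positive ordinate;
  D_1cc on structures below 1 cc falls back to D_max with a warning.
- D_mean integrates the differential histogram at mid-bin: unbiased, with
  error bounded by half a bin width (0.05 Gy at defaults).
- V_x (Gy) reads the ordinate at x by linear interpolation; target V_x%
  levels are percentages of that target's prescription.

The default score table awards 200 points across 28 banded entries on 17
structures in four levels (targets 100, critical 60, sub-critical 25, other
normal organs 15). Band thresholds are strict inequalities; a value exactly
on a threshold falls into the next (worse) band, and each entry's last band
is a catch-all. The temporal-lobe D_max row's printed middle band is
interpreted as the 60–65 Gy range and encoded as (<60, <65, >65). Paired
organs (parotid, lens, eye, inner ear, TMJ, temporal lobe, optic nerve) are
scored per side and averaged (a worst-side mode is available). Missing
metrics score 0 with a warning by default (configurable to error). Scoring
is deterministic and independent of entry order.

## Synthetic phantoms

Phantoms place a spherical PTV (default radius 10 mm) on a 64³ lattice at
2 mm spacing, with OAR shapes (sphere/shell/cylinder) whose *centers* sit a
controlled distance from the PTV surface. Dose is prescription (70 Gy)
inside the PTV and Rx·exp(−λ·d) outside, λ = 0.06/mm by default —
approximately the dose-gradient scale of clinical IMRT — optionally plus
Gaussian noise truncated at zero. Cohorts draw OAR placement distances
uniformly from 8–20 mm (surface-to-center; with the 6 mm default OAR radius
this spans near-abutting to well-separated anatomies, and mid-axis DVH
ordinates vary across the cohort). The coverage study uses 2 Gy voxel
noise. All randomness flows through explicit integer seeds.

What the phantoms emulate: a smooth, monotone geometry→dose relationship
with controllable spread and noise, spanning the score table's bands. What
they do not emulate: multiple dose prescriptions in one plan, anisotropic
beam arrangements, inter-planner variability, heterogeneous OAR shapes, or
multi-PTV geometries. Passing tests on phantoms therefore demonstrate that
the pipeline recovers a known anatomical signal and calibrates its band
under iid conditions — not that clinical prediction accuracy reaches any
particular level.

`scoring_reference_case()` additionally builds a fully scoreable ideal
plan — three disjoint target spheres, each uniformly at its prescription,
and 21 unirradiated OAR spheres (≥1 cc so D_1cc is defined) — which lands
every table entry in its best band (total 200); it exists to exercise the
whole metrics-and-scoring path with a known answer.

## Problem sizes used in the validation suite

Chosen as the package's own validation design: histogram oracles run on 200
random grids up to 16³ (exhaustive checks are exact, so size adds nothing);
model recovery uses 60 training + 20 held-out zero-noise cases; band
coverage uses 200 + 200 noisy cases; refinement uses a 20-case cohort with
one planted outlier (falloff length scale doubled, i.e. λ halved — the
direction that adds dose and makes a plan genuinely suboptimal).

## Known limitations

- Linear PCA on shifted sigmoid-like curve families has a slowly decaying
  spectrum; four components leave ~0.5 pp reconstruction error on the
  phantom cohorts and more on wider anatomical ranges.
- The band is global per score: prediction error is heteroscedastic across
  anatomy (steep-dose cases near the feature-support edge err most), so
  pointwise coverage dips below nominal exactly there.
- The RBF regressor extrapolates poorly outside the training feature range;
  predictions for anatomies beyond the database's spread should be treated
  with caution (as with any KBP model).
- Masks are binary; sub-voxel surface placement and partial volumes are
  ignored, so all distances and volumes are quantized at the voxel scale.
- DICOM-RT ingestion assumes axis-aligned geometry (no oblique
  orientations) and uniform slice spacing in RTDOSE.
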