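# Methods

## Deformation marker

Real deformation-based morphometry pipelines register a template surface to
each subject with a diffeomorphic flow and read off the Jacobian determinant
of that map as the local deformation marker. This package starts one step
later: its inputs are the corresponded surfaces themselves (identical face
lists, shared vertex indexing), not the volumetric flow. The marker is
therefore defined as the **discrete surface-area-element ratio**

    J_k(s) = A_k(subject s) / A_k(template),

where `A_k` is the barycentric vertex area (one third of the incident
triangle areas). This is the 2-D analogue of the Jacobian determinant
restricted to the surface and has the same sign semantics: `J > 1` is local
expansion of the subject relative to the template, `J < 1` local atrophy.
Under a similarity scaling of the whole surface by `c`, `J = c²` exactly.
Statistics are run on `log J` by default so contraction and expansion are
treated symmetrically (a raw-scale flag exists); for a planted linear
contraction of fraction `a` the expected log marker shift is `2 log(1 − a)`.
Correspondence is declared, never estimated — a subject whose face list
differs from the template's is rejected.

## Vertex-wise model and inference

At each template vertex `k` the group comparison is the linear model

    J_k(s) = β_{k,0} + β_{k,1} γ(s) + Σ_cov α_cov X_cov(s) + ε_k(s),

`γ(s) ∈ {0, 1}` (1 = patient), covariates age (years), sex (0/1) and
intracranial volume (mm³) by default, mean-centred; the group column stays
binary so the intercept is the covariate-adjusted control mean. Estimation is
OLS, vectorised across vertices via the design pseudoinverse but numerically
identical to per-vertex fits; `t_k = β̂_{k,1} / SE` with `n − p` residual
degrees of freedom. A residual variance at pure roundoff level relative to
the response (a constant marker column) yields `t = 0` rather than noise.

Multiplicity across vertices is handled single-step with the **maximum
statistic**: for each of `B` permutations the full model is refitted and
`max_k |t_k|` recorded; then

    p_fwer(k) = (1 + #{b : max_j |t_b(j)| ≥ |t_obs(k)|}) / (B + 1).

Design choices, all standard practice for permutation GLM inference:

- **Freedman–Lane residual permutation** is the default scheme (fit the
  nuisance-only model, permute its residuals, refit the full model), because
  plain label permutation is not exchangeable in the presence of covariate
  effects; label permutation is available as an option.
- **Add-one estimator** `(b+1)/(B+1)`: valid p-values, never zero, floor
  `1/(B+1)`. Ties between permuted and observed statistics count as
  exceedances (conservative).
- Permutations are sampled uniformly **with replacement**, the identity
  permutation is excluded from the sampled set (its contribution is the
  add-one term), and the whole stream is driven by one seed.
- Testing is two-sided via |t|; direction is read off the sign of `β̂_{k,1}`
  (negative = atrophy in patients when markers are logged).
- Per-vertex uncorrected permutation p-values are computed from the same
  draws; `p_fwer ≥ p_unc` holds by construction.

The structure-level "shape p" reported in summaries is the **minimum
corrected vertex p** — an "is anything significant anywhere" summary,
labelled as such; no omnibus statistic is claimed.

Volumes use the same model and permutation machinery on a single outcome
(no multiplicity correction needed), after z-scoring against the control
group: `z(s) = (v(s) − mean_HC) / sd_HC` with the n−1 SD over controls only,
so controls self-standardize to mean 0, SD 1. Effect sizes are pooled-SD
Cohen's d,

    d = (m₁ − m₂) / s_p,  s_p² = ((n₁−1)s₁² + (n₂−1)s₂²) / (n₁+n₂−2).

## Subregion quantification

For the entire structure and each subregion: the percentage of surface area
at FWER-significant vertices, **area-weighted** (each vertex contributes its
barycentric area) because the quantity of interest is surface area, not
vertex count; a count-weighted mode exists for sensitivity analysis. The
entire-structure percentage is exactly the area-weighted combination of the
subregion rows. Effect summaries are the unweighted mean and n−1 SD of |d|
over significant vertices; an empty significant set is reported as "none"
(explicitly absent), not as zero, and a single significant vertex has an
undefined (NaN) SD. Overlay meshes carry per-vertex fields (percent linear
atrophy `100(1 − exp(β̂₁/2))` masked to significant vertices, significance,
p, d, subregion label) as PLY vertex properties or VTK POINT_DATA.

## Synthetic cohort generator

The generator stands in for segmentation + registration and defines the
conditions under which the pipeline is validated. What it emulates:

- **Templates**: anisotropic ellipsoids from subdivided icosahedra (level 3
  = 642 vertices ≈ the surface resolution of a small subcortical structure).
  Default semi-axes give realistic volumes — left/right amygdala ≈ 1.7/1.8
  mL, left/right hippocampus ≈ 3.4/3.5 mL, the hippocampi elongated and
  gently bent. An optional small seeded radial perturbation (2% of radius)
  breaks perfect symmetry. Each template is partitioned into four non-empty,
  edge-connected sectors (anterior/posterior × medial/lateral) carrying the
  anatomical subregion names.
- **Cohort**: 92 patients vs 106 controls by default, ages
  22.40 ± 5.59 vs 23.68 ± 4.04 years, male fractions 42/92 vs 59/106,
  ICV ~ N(1.45×10⁶, 1.5×10⁵) mm³ in both groups.
- **Subject surfaces**: displacement along template vertex normals, the sum
  of (i) the group effect — inward removal of `a · taper(k)` times the
  normal component of the position vector, which on a sphere is exactly
  similarity scaling by `1 − a·taper` — applied to patients only; (ii)
  linear covariate effects; (iii) a smooth zero-mean random field.
- **Taper**: the planted effect falls off as a cubic smoothstep of the
  signed graph-geodesic distance to the target-subregion boundary over one
  correlation length (default 3 mm), straddling the boundary — no crease,
  and a realistic diffuse margin. Ground truth records the taper, its
  support (the effect mask) and the expected log-marker shift
  `2 log(1 − a·taper)`.
- **Noise**: white vertex noise diffused by iterated one-ring averaging
  (iteration count ≈ squared correlation length in mean-edge units, the
  random-walk scaling), recentred and rescaled to the requested SD
  (default 0.25 mm of normal displacement — a small fraction of the
  structures' 6–10 mm radii, consistent with segmentation-grade surface
  uncertainty).
- **Covariate coefficients** (free parameters of the simulation, not
  estimates from any dataset): age −0.01 mm/yr, male sex +0.1 mm,
  ICV 1×10⁻⁶ mm per mm³ (≈0.15 mm per ICV SD), acting on deviations from
  the cohort-level expected means so the template is the average head.

What it does **not** emulate: real amygdalar/hippocampal geometry or
parcellation boundaries, segmentation artifacts, registration error
correlated with group, non-Gaussian demographics, scanner effects. Passing
tests therefore demonstrate the statistical machinery's correctness and
calibration under a controlled generating law — not anatomical validity of
any particular finding on real data.

## Validation experiments and problem sizes

- **Empirical FWER** (`calibration.empirical_fwer`, also the acceptance
  script): 200 replicate null cohorts, 30 per group, one 642-vertex
  structure, B = 500, α = 0.05, Freedman–Lane with age/sex/ICV. These sizes
  give a binomial SE of ~0.015 on the estimated FWER in minutes of compute;
  the package-level defaults for a real analysis remain B = 10,000 at
  α = 0.05.
- **Planted recovery** (`calibration.planted_recovery`): amplitude 0.1 on
  two subregions, 40 per group, B = 2000; reports area-weighted sensitivity
  on the taper support, false-positive area fraction outside it, and the
  observed core log-marker shift against `2 log(0.9)`.
- The permutation estimator is checked against exhaustive enumeration of all
  20 relabelings at n = 3+3; the vectorised GLM against independent
  normal-equation solves and statsmodels OLS; geometry against closed forms
  (cube, icosphere) and trimesh; mesh I/O by round-trip and against trimesh.

## Numerical choices and degenerate inputs

- Units fixed: mm / mm² / mm³; 0-based vertex and face indexing throughout.
- Closed-manifold validation: every directed edge exactly once with its
  twin present; degenerate faces and unreferenced vertices rejected;
  offending edges listed. Signed divergence-theorem volume (positive =
  outward orientation); writers emit 17 significant digits so ASCII
  round-trips are lossless at double precision.
- OLS uses the SVD pseudoinverse (stable for the ill-conditioned designs
  that mm³-scale covariates produce); rank deficiency is reported with the
  names of the collinear columns.
- Zero control-group variance (volume z-scores), degenerate pooled SD
  (Cohen's d), empty significant sets and constant marker columns all have
  defined, explicit behaviour rather than NaN propagation.
- All randomness flows from `numpy` `SeedSequence` spawning: one root seed
  per cohort/pipeline run, per-stage and per-subject substreams, so runs are
  bit-identically reproducible and subjects are independent.

## Known limitations

- The area-element marker measures the surface-intrinsic part of the
  deformation only; a volumetric Jacobian could differ where deformation is
  dominated by motion normal to the surface.
- Single-step max-statistic correction is slightly conservative relative to
  step-down procedures; the observed null FWER sits a little under the
  nominal level.
- The generator's quadrant parcellation and ellipsoid geometry are
  deliberately schematic; cross-hemisphere comparisons and longitudinal
  designs are out of scope.
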