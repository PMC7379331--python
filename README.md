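# shapemorph

Deformation-based surface morphometry for subcortical structures: vertex-wise
shape statistics on corresponded triangle meshes, with max-statistic
permutation control of the family-wise error rate (FWER).

## The problem

Volume comparisons of structures such as the amygdala and hippocampus are
global: localized atrophy confined to a subregion (a hippocampal subfield, an
amygdalar nucleus) can be invisible in the total volume. Deformation-based
shape analysis works instead on the structure's *surface*: after segmentation
and diffeomorphic registration put every subject's surface on a shared
template parameterization, each template vertex carries, per subject, a
scalar **deformation marker** measuring local expansion or contraction
relative to the template. This package implements everything downstream of
registration for a patient-versus-control design (the motivating application
is first-episode schizophrenia, FES, versus healthy controls, HC):

- the marker itself — the discrete surface-area-element ratio
  `J_k(s) = A_k(subject s) / A_k(template)`, the surface analogue of the
  Jacobian determinant of the template-to-subject deformation
  (`J > 1` expansion, `J < 1` atrophy; statistics default to `log J`);
- the vertex-wise general linear model
  `J_k(s) = β_{k,0} + β_{k,1} γ(s) + Σ_cov α_cov X_cov(s) + ε_k(s)`,
  with binary group indicator `γ` and nuisance covariates (age, sex,
  intracranial volume), testing `β_{k,1} = 0` at every vertex;
- multiplicity control by **max-statistic permutation inference**: each
  observed |t| is referred to the permutation distribution of
  `max_k |t_k|` (Freedman–Lane residual permutation by default), which
  controls the FWER across all vertices;
- volume analysis on the same model: z-scores against the control group
  (`(v − mean_HC) / sd_HC`), permutation p-values, pooled-SD Cohen's d;
- per-subregion quantification: percentage of surface area at significant
  vertices and mean ± SD of |d| over them, for the entire structure and each
  of its four named subregions (amygdala: basolateral, basomedial,
  centromedial, lateral nucleus; hippocampus: CA1, CA2, CA3/DG, subiculum);
- a **synthetic cohort generator** that manufactures labeled ellipsoid
  templates and vertex-corresponded subject surfaces with planted,
  ground-truth-known group atrophy, covariate effects and smooth spatial
  noise — so the whole pipeline's error control and sensitivity are testable.

Mesh I/O covers ASCII OFF, PLY and legacy-VTK polydata, with per-vertex
scalar fields (statistical overlays) on PLY and VTK.

## Worked example

Plant a 10% linear atrophy on two amygdalar subregions in 40 patients vs 40
controls, then recover it:

```python
from shapemorph import ShapeGLM, simulate_cohort, significant_area_percentage
from shapemorph.calibration import single_structure_config
from shapemorph.synthetic import EffectSpec

effect = EffectSpec(target_subregions={"basolateral", "centromedial"},
                    atrophy_amplitude=0.10)
config = single_structure_config(40, effect=effect)
sim = simulate_cohort(config, seed=42)

markers = sim.marker_field("left_amygdala")          # log area-element markers
results = ShapeGLM(markers, sim.cohort).fit(n_permutations=2000, seed=42)
print(results.summary())

template, labeling = sim.templates["left_amygdala"]
table = significant_area_percentage(template, labeling, results.vertex_stats)
print(table[["subregion", "pct_significant_area", "mean_abs_d", "sd_abs_d"]]
      .round(3).to_string(index=False))
```

which prints

```
Vertex-wise shape GLM (max-statistic permutation FWER)
  vertices: 642   subjects: 80
  design:   intercept + group + age + sex + icv
  scheme:   freedman-lane   permutations: 2000   alpha: 0.05
  significant vertices: 328 (51.09%)
  min p_fwer (structure-level): 0.0004998
  |d| over significant vertices: 2.442 +/- 0.626

       subregion  pct_significant_area  mean_abs_d  sd_abs_d
entire structure                50.648       2.442     0.626
     basolateral                93.338       2.510     0.512
      basomedial                 3.164       0.940     0.114
    centromedial                94.715       2.463     0.645
         lateral                 3.134       1.026     0.183
```

The two target subregions light up (>93% of their surface area significant)
while the untouched subregions stay near zero — only their tapered boundary
zones, where the planted effect bleeds across, are detected. The minimum
corrected p, 1/(B+1) ≈ 0.0005, is the attainable floor of the add-one
permutation estimator.

A self-check of the effect-size arithmetic against bundled published
reference statistics (four structures, 92 patients / 106 controls):

```
$ shapemorph verify-reported
        structure  computed_diff_mm3  reported_diff_mm3  diff_ok  computed_d  reported_d  d_ok
    left_amygdala             117.14             117.14     True      0.4205       0.419  True
   right_amygdala             164.50             164.50     True      0.5415       0.541  True
 left_hippocampus             160.56             160.56     True      0.3311       0.331  True
right_hippocampus             139.47             139.47     True      0.2634       0.263  True
```

The CLI also offers `simulate`, `markers`, `stats`, `summarize` and `run`
(the full chain from a YAML config to tables, overlays and a manifest); see
`shapemorph --help`.

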