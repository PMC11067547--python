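# fcpoct

Spatially resolved structure–function analysis for non-exudative
age-related macular degeneration (AMD): registration of fundus-controlled
perimetry (FCP, "microperimetry") stimulus grids to OCT en-face
layer-thickness maps, point-wise thickness sampling and biomarker grading,
deviation-from-control normalization, and crossed random-intercept
linear mixed models — together with a synthetic cohort generator that makes
the whole pipeline testable end to end without patient data.

## Who this is for

Ophthalmic imaging and visual-psychophysics groups who co-register
per-stimulus retinal sensitivity (mesopic and scotopic thresholds in dB
from a 56-point, 10°×10° fovea-centered grid) with structural OCT
biomarkers — sub-RPE drusen, subretinal drusenoid deposits (SDD), pigment
epithelium detachment (PED), hyper-reflective foci (HRF), vitelliform and
refractile lesions, and incomplete/complete RPE and outer retinal atrophy
(iRORA/cRORA) — and model their local association with rod- and
cone-mediated function, cross-sectionally and over annual follow-up visits.

## The model

For eye *i*, visit *j* and stimulus position *k*, the sensitivity
deviation from the control-cohort mean (dB; negative = loss) is modelled
as

```
dev_ijk = β₀ + β_age·age_i + β_pseudo·pseudo_i + Σ_b β_b·1[biomarker b at (i,j,k)]
          + u_i + v_ij + w_k + ε_ijk
```

with random intercepts for patient (`u_i`), visit within patient (`v_ij`)
and grid position (`w_k`, crossed with patient), fitted by REML separately
for mesopic and scotopic testing. The inter-visit model replaces the
endogenous variable with the point-wise sensitivity change between
consecutive visits and adds years elapsed plus nine retinal-layer
thickness z-scores (RNFL … RPEDC, normalized to the control mean/SD at the
same position, covariates taken at the earlier visit).

Upstream of the models, the pipeline

1. estimates the FCP→OCT similarity transform from landmark
   correspondences (fovea, optic disc, vessel bifurcations; weighted
   orthogonal Procrustes in closed form), mirroring right eyes to left-eye
   orientation first;
2. samples each layer map over the scotopic Goldmann V stimulus disc
   (1.7°) at every mapped stimulus position and grades biomarker presence
   from binary lesion masks (any-overlap rule by default);
3. normalizes sensitivities to deviations and thicknesses to z-scores
   against the control cohort, with a small SD floor.

The synthetic cohort generator reproduces the study design (54 AMD eyes of
49 patients, 27 control eyes, up to 4 annual visits) and draws
sensitivities from exactly the mixed-model structure above, using the
published coefficient sets as configurable ground truth; the presence
flags entering the generative model are the *graded* flags produced by the
extraction stage, so grading conventions cannot bias parameter recovery.

## Worked example

```python
from fcpoct import (ModelSpec, apply_normalization, build_normative,
                    extract_cohort, fit_cross_sectional, simulate_cohort,
                    table2_scenario)

config = table2_scenario(seed=1, n_patients_amd=20, n_eyes_amd=22,
                         n_controls=12, n_visits_max=2, map_size_px=128)
cohort = simulate_cohort(config)
table = extract_cohort(cohort)                      # register + sample + grade
reference = build_normative(table)                  # control means/SDs
normalized = apply_normalization(table, reference)  # deviations + z-scores
result = fit_cross_sectional(normalized, ModelSpec(modality="mesopic"))
print(result.fixed_effects.round(3).to_string())
```

prints

```
                    estimate     se  ci_low  ci_high  p_value
intercept              7.931  2.696   2.646   13.216    0.003
age                   -0.122  0.040  -0.201   -0.043    0.003
pseudophakic          -0.078  0.209  -0.488    0.332    0.709
flag_subrpe_drusen    -0.235  0.068  -0.368   -0.102    0.001
flag_sdd              -0.427  0.138  -0.697   -0.156    0.002
flag_ped              -1.322  0.117  -1.552   -1.093    0.000
flag_hrf              -1.009  0.140  -1.285   -0.734    0.000
flag_vitelliform      -0.543  0.231  -0.996   -0.090    0.019
flag_refractile          NaN    NaN     NaN      NaN      NaN
flag_irora            -0.547  0.199  -0.937   -0.158    0.006
flag_crora            -1.361  0.309  -1.968   -0.755    0.000
```

Each biomarker row is the mean estimated sensitivity change (dB) at
stimulus positions where that biomarker is present, holding the others
fixed: here PED presence costs ≈1.3 dB of mesopic sensitivity, close to
the configured truth of −1.30 dB even in this reduced 22-eye cohort. The
refractile row is `NaN` because no refractile deposit was generated in
this small cohort, so its coefficient is not identifiable (aliased columns
are dropped and reported rather than silently removed).

A command-line interface wraps the same stages
(`fcpoct simulate|register|extract|normalize|fit|report|run`); `fcpoct run
--config cfg.yaml --out DIR` executes the whole pipeline and writes
result CSVs mirroring the two coefficient-table layouts plus a
`recovery_report.csv` comparing configured truth with recovered estimates.

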