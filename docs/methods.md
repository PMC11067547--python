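# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the design decisions taken where the problem left
the design open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate conventions and geometry

All retinal positions are fovea-centered visual-field coordinates in
degrees, x rightward, y downward; pixel grids are `[row, col]` with
`(0, 0)` top-left and a pixel's *center* carrying its coordinate.
Left-eye orientation is canonical: right-eye data (landmark sets,
thickness stacks, lesion masks, and the fovea-tracked stimulus grid) are
reflected about the vertical axis through the fovea before any cross-eye
analysis, so the optic disc sits nasally at about (−15.5°, −1.5°).
Mirroring an array is an exact column flip, so mirror∘mirror is
bit-identical and the extraction pipeline is exactly invariant under
simultaneous mirroring of all inputs.

En-face maps default to 256×256 px over a 30° field (8.53 px/°), a
desk-scale stand-in for the device's 768×768 export; all geometry is
carried per file. Degrees↔µm conversion uses 288 µm/° (emmetropic model
eye), configurable.

## Registration

The FCP frame and the OCT en-face frame are related by a similarity
transform (scale, rotation, translation). Given ordered landmark
correspondences — fovea, optic disc, then vessel bifurcations — the
transform minimizing the weighted sum of squared residuals is solved in
closed form by weighted orthogonal Procrustes with scale (Umeyama's
construction). The fovea and optic disc act as primary anchors with
weight 3 versus 1 per vessel bifurcation (configurable). Reflections are
excluded (`det R = +1`) because mirroring is handled explicitly upstream;
a full affine fit is available behind a flag and requires three
non-collinear pairs. Fit diagnostics (per-point residuals, unweighted RMS)
accompany every estimate.

The stimulus grid is *fovea-tracked*: stimulus k sits at
`fovea_FCP + centers[k]` in the FCP frame, where `fovea_FCP` is the fovea
landmark. Mapping therefore applies the estimated transform to
anchor-plus-center, and the effective stimulus diameter is rescaled by the
transform's isotropic scale factor.

## Point-wise extraction

The 56-point, 10°×10° device pattern is not published; the default layout
is three concentric, 4-fold-symmetric rings of 12/20/24 points at radii
1°/3°/5°, centroid at the fovea, and any measured 56-point pattern can be
substituted. Stimulus sizes are treated as visual-angle diameters:
Goldmann III ≈ 0.43° (mesopic), Goldmann V ≈ 1.7° (scotopic). Thickness
extraction averages over the scotopic Goldmann V disc — the mean over
pixels whose centers fall inside the disc — because the scotopic stimulus
defines the sampled retinal area; a point sample at the center is the main
alternative reading and is not used. Discs with less than half of their
pixel footprint on the map yield an explicit missing value with a reason
code. Biomarker presence is graded as any overlap between the stimulus
disc and the lesion mask (`min_fraction = 0`), mirroring a reader who
flags a biomarker seen anywhere within the stimulus area; the covered
fraction is retained so stricter thresholds remain available.

## Normalization

Sensitivities are reported as point-wise deviations from the control-cohort
mean at the same grid position (negative = loss); thicknesses as z-scores
against the control mean and sample SD (ddof = 1) at the same position.
Every position must receive valid observations from at least two distinct
control eyes. Control SDs below 0.25 dB (sensitivity) or 0.5 µm
(thickness) are floored to those values: with ~27 controls the raw
per-position SDs are unstable and would otherwise explode z-scores.
Controls are used as a plain mean/SD reference without age adjustment.

## Mixed models

Both association models are linear mixed models with three random
intercepts — patient, visit nested within patient, and grid position
crossed with patient — estimated by REML, with Wald normal-approximation
SEs, 95% CIs and p-values (flagged as `wald-normal` in the result
metadata; Satterthwaite degrees of freedom are the main alternative).
Mesopic and scotopic are fitted as two separate models. Missing data are
handled complete-case with dropped-row counts reported. Fixed-effect
columns that are constant or collinear in a given cohort (e.g. a biomarker
that never occurs) are dropped left-to-right and reported as `NaN`,
matching how lmer treats a rank-deficient fixed-effect matrix.

Because every random term is a pure intercept over a categorical factor,
the REML criterion profiled over the fixed effects and the residual scale
depends on the data only through fixed cross-products (Z′Z, Z′X, Z′y,
X′X, X′y, y′y). The default solver precomputes these and evaluates each
objective value with one q×q Cholesky factorization (q = total random
levels, ≈ 300 at full scale), optimizing the three log variance ratios by
Nelder–Mead (xatol 1e-7). A fit takes ~2 s at 12,000 rows;
`backend="mixedlm"` fits the identical model through statsmodels MixedLM
(one-group variance-component formulation) and agrees to ≈1e-4 on
estimates, SEs and variance components (checked in the test suite). When
the OLS residual variance is below 1e-10 of the outcome scale the solver
short-circuits to the OLS solution with zero variance components; in that
degenerate limit the fixed effects equal OLS exactly for any variance
values, which is what the noise-free tests exploit.

The inter-visit endogenous variable is the change in deviation between
consecutive visits (later − earlier); years elapsed is Δmonths/12, and all
exogenous covariates — biomarker flags and layer z-scores — are taken at
the earlier visit of the pair (prognostic reading). Device-range censoring
is flagged per observation; the default fit treats censored values as
observed at the bound, and `drop_censored=True` drops affected rows
(pairs, for the change model) as a sensitivity analysis.

## Synthetic cohort generator

The generator emulates the study design: 49 AMD patients contributing 54
eyes (5 bilateral), ages 70.7 ± 9.1 y, ~26% pseudophakic; 27 control eyes
(63.4 ± 8.9 y); up to 4 visits at 12 ± 2 month intervals; all visits use
the ND 2.0 filter (the extraction stage drops any visit tested with a
different filter, since thresholds are not comparable across filters).

**Sensitivity model.** Control sensitivities are the normative profile
(mesopic 17 dB, scotopic 12 dB at the fovea, −0.15 dB/° radially — mid
dynamic range for an MP-1-class device under ND 2.0) plus patient, visit,
grid and residual noise. AMD sensitivities follow the cross-sectional
linear predictor with the published coefficient sets as defaults; the
presence flags in the predictor are the *graded* flags obtained by running
the extraction stage on the rasterized lesion masks at the true stimulus
positions, so generation and analysis share one grading convention and
recovery is unbiased by construction. An optional reader-noise mode flips
flags with configurable probability (off by default). In longitudinal
mode, visits after baseline evolve by the inter-visit change model (its
own fixed effects and smaller variance components: patient 0.5, visit 0.5,
grid 0.3, residual 1.5 dB), with flags and z-scores taken from the
truth-side extraction of the earlier visit; the latent trajectory
accumulates and the observation is clipped to the device range
[0, 20] dB with a censoring flag.

**Variance components** (not reported by the source study; package
defaults): patient 1.5, visit 0.5, grid point 0.8, residual 1.5 dB,
chosen to give coefficient SEs of the same order as the published tables.

**Thickness model.** Each layer is a smooth radial baseline profile with
anatomically plausible magnitudes (e.g. ONL peaking ~90 µm at the fovea,
RPEDC ~30 µm) plus a per-eye offset (SD per layer; RPEDC 1.98 µm so that
one z-unit corresponds to ≈2 µm, as in the study cohort) and per-pixel
noise (1 µm). Drusen, PED and refractile deposits add raised-cosine bumps
to the RPEDC map (peak = lesion height; PED ≥ 200 µm); SDD and
vitelliform material bump the outer segments; cRORA multiplies ONL/OS/
RPEDC by 0.35 inside its mask and iRORA by 0.7. Thicknesses are clipped
at 0.

**Lesions.** Per biomarker: a per-eye prevalence, a count range, a
diameter range respecting the consensus minima (PED ≥ 1000 µm basal
diameter and ≥ 200 µm height; cRORA ≥ 250 µm; iRORA < 250 µm), and a
diameter growth rate per year. Centers are uniform within 6° of the
fovea. cRORA lesions onset at a random follow-up visit (none at baseline,
matching the study's exclusion of baseline cRORA); iRORA growth is capped
just below 250 µm, and an optional iRORA→cRORA conversion rule exists but
is off by default because the grading protocol does not specify one.
iRORA masks are carved disjoint from cRORA.

**Landmarks.** OCT-frame landmarks are the fovea at the origin, the disc
at (∓15.5°, −1.5°), and vessel bifurcations at radii 4–13°; the FCP-frame
landmarks are their images under a per-visit similarity transform (scale
0.97–1.03, rotation ±2°, translation ±0.5°) plus isotropic click noise
(SD 0.05° by default).

**What the generator does not emulate:** real OCT segmentation error and
its spatial correlation, fixation instability within an examination,
reader disagreement beyond independent flag flips, lesion shapes other
than discs, exudative conversion, and dropout (every eye completes all
visits). Passing recovery tests therefore demonstrates the pipeline's
correctness under the stated generative model, not robustness to these
real-data features.

## Recovery analyses and their problem sizes

The recovery suites simulate five replicate cohorts per scenario at the
full study scale (54 AMD eyes × 4 visits × 56 points ≈ 12,000 rows per
modality) and compare seed-averaged coefficients against the configured
truth within max(0.15 dB, 2 × model SE). The inter-visit recovery fits
use `drop_censored=True`: with the configured truth, stimulus positions
carrying refractile deposits lose ≈3.5 dB of scotopic sensitivity per
year and inevitably cross the 0 dB floor within three intervals, so the
observed-at-bound default attenuates exactly the steep coefficients; a
residual attenuation from floor-truncation selection (pairs are kept only
when the later endpoint stayed in range) remains and is the main known
bias of the longitudinal scenario. The null-calibration check (all true
effects zero, ≤10% of biomarker coefficients outside ±2 SE) runs at 34
eyes/30 patients — the smallest scale at which the normal-approximation
Wald intervals are honest for spatially clustered flags; at smaller
cohorts the effective degrees of freedom per biomarker contrast (the
number of carrier eyes) are too few for the normal quantile, which is the
same small-sample issue that Satterthwaite corrections address. The
noise-free (OLS-limit) checks run the longitudinal scenario over a single
interval so the device-range truncation never binds, with an explicit
assertion that no observation was censored.

## Numerical choices

- Pixel-in-disc tests use pixel centers with a ≤ boundary; 0-based
  indexing, (0, 0) top-left.
- Disc sampling excludes NaN pixels from the mean but counts them toward
  the footprint used by the 50% edge-coverage rule.
- Thickness maps are stored float32 in memory (halves the footprint of a
  full cohort) and written as text with `%.17g`, so float64 maps round-trip
  losslessly on disk.
- The similarity fit guards against coincident source landmarks and
  non-positive scale; affine against collinearity (SVD rank check).
- REML optimization starts at unit variance ratios; log-ratios are clipped
  to ±30 to keep the Cholesky factorization well-posed at the boundary.
- Config hashing uses a canonical sorted-key YAML dump (sha256, 16 hex
  chars) so pipeline manifests identify the exact run conditions.

## Known limitations

- Wald normal-approximation inference is anti-conservative for rare,
  spatially clustered biomarkers in small cohorts (see above).
- Coefficients of biomarkers affected by floor/ceiling censoring are
  attenuated under the default observed-at-bound handling; the package
  offers row dropping, not a censored-likelihood (Tobit-type) fit.
- The grid random intercept is crossed with patient as a single global
  factor; a per-eye grid effect (eye×position interaction) is not modelled,
  matching the fitted specification but not necessarily real data.
- Lesion masks are unions of discs; grading of real, irregular lesions may
  behave differently near stimulus boundaries.
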