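# Methods

This note records the models, estimators, numerical choices and known
limitations of `spermhelix`, in the spirit of a package vignette.

## 1. Per-gyre volume estimator (`geometry`)

**Model.** The mitochondrial helix is an elliptical tube wound around the
flagellum.  Within one gyre the tube is treated as straight: its length is
`sqrt(g^2 + c^2)` with `g` the gyre interval (pitch) and
`c = pi * d` the flagellum circumference at the gyre's mean flagellum
diameter `d`; its cross-section area is `pi * (M/2) * (m/2)` with major
axis `M` (one measure per gyre) and minor axis `m` (mean of the two
per-half-gyre subtraction values).  Cell volume is the sum over measured
gyres plus `k` times the mean per-gyre volume, where `k` is the rounded
ratio of each fully obscured stretch's length to the mean gyre interval.

**Known bias.** The tube's true centerline winds at radius
`d/2 + m/2`, not `d/2`, and tapering makes per-gyre means lag the local
integrand; both effects are second-order.  Against the 3D integration
oracle (section 3) the estimator is within 10% for every tapering cell in
the default generator ranges, with median error ~2%.  This tolerance is a
property of the estimator, not of the implementation, and is asserted
as-is in the tests.

**Conventions where the measurement protocol is silent.**

* Longitudinal coordinates are µm from the head–flagellum junction,
  increasing tailward.
* A gyre interval is defined between gyres with *adjacent recorded
  indices*; an index gap (fully obscured stretch) contributes no interval,
  so multi-pitch spans never contaminate the pitch series.
* The terminal gyre, which has no following interval, reuses the preceding
  interval (`last_interval="cell_mean"` selects the alternative).
* Missing-gyre counts round half-up; negative subtraction results are
  errors, never clamped to zero — they indicate data-entry faults.
* Cell-mean imputation uses only directly measured values, per measurement
  kind; "mean per-gyre volume" for hidden gyres uses after-imputation
  gyre volumes.

## 2. Phylogenetic statistics (`phylostats`)

**PGLS.** `fit_pgls` solves the exact GLS normal equations under
`V(λ) = λ σ² C + (1-λ) σ² diag(C)` with `C[i,j]` the shared root-to-MRCA
path length.  λ is profiled on a 101-point grid over [0, 1] with bounded
local refinement; ties break toward smaller λ.  The profile uses the
*restricted* likelihood by default: in calibration runs at n = 55 species
(correctly specified generator) ML-profiled λ produced slope CI coverage
near 0.80, while REML-profiled λ restored ~0.95, matching the behaviour
that makes REML the field default for variance parameters.  ML remains
available (`method="ml"`) and is used for all likelihood-ratio tests.
Coefficient CIs are t-based with n − p degrees of freedom; the λ CI is a
χ²(1) profile interval.

**Phylogenetic mixed model.** For repeated observations per species,
`fit_phylo_lmm` fits `y = Xβ + a + e`, `a ~ N(0, σ_a² C)` broadcast from
species to observations, `e ~ N(0, σ_e² I)`.  The single variance ratio
γ = σ_a²/σ_e² is profiled (grid on log γ plus bounded refinement) under
REML; the likelihood is evaluated with the Woodbury identity so each step
costs one species-by-species solve.  Reported λ is the phylogenetic
variance proportion `σ_a² h̄ / (σ_a² h̄ + σ_e²)` with `h̄` the mean diagonal
of C — this definition is stated in the run manifest because "λ" is used
loosely in the comparative literature.  Fixed-effect p-values and the
interaction-retention rule use ML likelihood-ratio tests (interaction kept
iff p < 0.05, two-sided).

**Repeatability.** Intraclass correlation from a Gaussian random-intercept
model (marked point as the grouping factor, measurement kind as a fixed
effect): `R = σ_point² / (σ_point² + σ_resid²)`.  The CI is a parametric
bootstrap (default 1000 refits).  Exactly repeated values short-circuit to
R = 1.  The engine is cross-checked against statsmodels MixedLM in the
test suite.

## 3. Synthetic data (`synthetic`)

**Geometric route (volume oracle).** `HelixSpec` defines a flagellum whose
diameter tapers linearly in arc position over the whole cell, and a helical
tube over the midpiece whose minor/major axes and pitch taper linearly over
the midpiece.  `true_helix_volume` integrates cross-section area times the
centerline arc element `sqrt(1 + (2π a / P)²)` (winding radius
`a = d/2 + m/2`) by Simpson's rule, with a halving-step convergence gate of
1e-6 relative.  `project_measurements` emulates the SEM protocol: half-gyre
centers located by inverting the winding-angle integral, two width pairs
per gyre, one major axis per gyre, multiplicative lognormal noise,
per-measurement missingness and optional fully obscured sections.

**Comparative route (recovery bundles).** `generate_dataset` simulates a
unit-height Yule tree (dendropy), species log flagellum lengths with
covariance `λ σ² C + (1-λ) σ² I`, midpiece lengths from the log-log
allometric link, and one measured cell per species.  The longitudinal
links (flagellum diameter, minor and major axes, log gyre interval) are
imposed *directly at the rank-based ordinal positions of the locations
that survive missingness* — i.e. on exactly the predictor the analysis
defines.  The two routes intentionally differ here: linear-in-arc taper is
the right geometry for the volume oracle, while linear-in-ordinal-position
links are the generating model the regression stages estimate; conflating
the two inflates within-cell coefficient error by the rank distortion of
missing locations and made recovery tests fail for the wrong reason.

**Default study conditions** (chosen once, as realistic field values):
55 species, one cell each; root flagellum length 100 µm with Brownian SD
0.25 on the log scale; λ_true 0.85; allometry −1.99 + 1.38·log(L), residual
SD 0.08; flagellum diameter 0.33 µm with −0.11 per unit position,
+0.04 per 100 µm length, interaction −0.03, species SD 0.013; log minor
axis −1.87 − 0.51·position − 0.04·length; log major axis −1.44 − 0.25·pos
− 0.07·length; log gyre interval 1.43 − 0.08·pos + 0.23·length,
interaction 0.05, per-gyre SD 0.05.  Measurement noise is multiplicative
lognormal with σ = 0.0185, calibrated so the expected range of four
repeated measures of one point is ≈ 3.8% of its value; widths are positive
and measurement error scales with size, which motivates the multiplicative
form.  Midpiece length is capped at 0.92–0.95 of flagellum length so the
tail stays positive in the rare long-midpiece draws.

**What the generator does not emulate:** projection foreshortening of the
major axis (which depends on local helix inclination), non-elliptical
(triangular/bean-shaped) helix cross-sections, additional helical
structures (granular/fibrous helices) except as an exclusion label, and
within-species between-male variation (one cell per species, as in the
emulated protocol).  Passing recovery tests therefore show the estimators
are correct *under these conditions*, not that real SEM data are free of
those complications.

## 4. Pipeline stages (`pipeline`)

* Longitudinal position is the ordinal rank proportion within a cell
  (first measured location 0, last 1); flagellum length is mean-centred
  over the cells entering the given model and divided by 100 (so a unit is
  100 µm), with the grand mean recorded in the stage notes.
* The response is log-transformed iff doing so raises the Shapiro–Wilk W
  of the conditional residuals (both candidate models are actually fit);
  the gyre-interval stage is log by construction.  Non-positive responses
  force the raw scale.  The decision is recorded in
  `ModelFit.transform_applied`.
* Proximal/distal 25% submodels take the ⌈0.25 n⌉ smallest/largest ranks
  per cell and contain flagellum length as the only predictor.
* The tail-start diameter is the most distal measured flagellum width;
  its model uses light-microscopy species means for both tail and midpiece
  predictors (the protocol prescribes light-microscopy tails; using the
  same source for midpiece keeps the two predictors commensurable) and
  reports a variance-inflation diagnostic.
* The allometry rerun excludes, by default, the species with the shortest
  midpiece (the canonical residual outlier); the volume rerun excludes the
  family flagged as carrying an extra fibrous helix (Turdidae label),
  pruning the covariance accordingly.
* `run_all` is deterministic given config and seed; report CSVs carry no
  timestamps (timestamps live only in `run.log`).

## 5. Validation design

Every estimator has an independent oracle: closed forms for constant
geometry; 3D numerical integration for tapering volume; explicit-inverse
GLS on small random systems; a direct multivariate-normal likelihood
optimization for the λ profile; statsmodels MixedLM for the random-intercept
engine; and simulation-based recovery with CI-coverage assertions (200
replicates for PGLS, 100 bundle replicates for the longitudinal stages) at
the default study conditions.  Problem sizes in the test suite (55 species,
~20 gyres per cell, 100–200 replicates) were chosen as the smallest sets
that make coverage assertions statistically meaningful.

## Limitations

* The volume estimator inherits the straight-tube-per-gyre approximation;
  its documented bias (≤ ~5% median under realistic taper) is part of the
  method, not corrected away.
* λ in the mixed model is a variance proportion, not Pagel's λ on
  residuals; the two coincide only for one observation per species on an
  ultrametric tree.
* p-values are asymptotic χ² likelihood-ratio tests; at 55 species they
  are adequate for interaction screening but no small-sample correction
  (e.g. Kenward–Roger) is applied.
* Effective degrees of freedom for mixed-model Wald CIs use the normal
  quantile; between-species effects at small clade sizes will be slightly
  anticonservative.
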