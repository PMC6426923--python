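# Methods

This note documents the models, the defaults and the reasoning behind
the open design choices in `adcontinuum`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## 1. The sparse varying-coefficient model

### Model and penalty

Memory z-scores are modelled as
y_i = Σ_j β_j(t_i) x_ij + ε_i, where t_i is the subject's CDR sum-of-boxes
severity. Each coefficient function is expanded in a B-spline basis,
β_j(t) = Σ_l γ_jl B_l(t), and estimation minimises

(1/2n) ‖y − Zγ‖² + λ Σ_j √(γ_jᵀ Ω γ_j),

where Z has columns x_ij·B_l(t_i) and Ω_lm = ∫ B_l B_m dt so the
penalty equals λ Σ_j √(∫β_j²(t)dt). The penalty is a group LASSO on
whole coefficient functions: a predictor either carries an entire
severity-varying curve or is excluded.

### Basis

L = 4 basis functions, cubic, no interior knots on [min t, max t] — the
minimal natural configuration with exactly four cubic B-splines, whose
span is the space of cubic polynomials on the observed severity range.
The basis is clamped (partition of unity; each function nonnegative).
For L > degree + 1, interior knots are placed at severity quantiles.
The penalty Gram is computed by per-span Gauss–Legendre quadrature
(64 nodes), exact for products of cubics.

The measure in ∫β_j²(t)dt is Lebesgue on the basis domain. The
empirical design measure would be an alternative; Lebesgue was chosen
because it keeps the penalty independent of the severity distribution
and makes the Gram matrix a fixed property of the basis.

### Solver

Block coordinate descent after the change of variables u_j = R γ_j
(Ω = RᵀR), which turns each block penalty into a Euclidean norm. Each
block subproblem min ½uᵀHu − vᵀu + λ‖u‖ is solved *exactly* through the
eigendecomposition of H: u = (H + μI)⁻¹v with μ the unique root of
μ‖(H + μI)⁻¹v‖ = λ (u = 0 iff ‖v‖ ≤ λ), found by safeguarded Newton.
Exact block minimisation guarantees monotone objective decrease. When a
full sweep still moves coefficients substantially, the active set is
refined by iteratively reweighted least squares (majorising λ‖u_j‖ by
λ(‖u_j‖²/2s_j + s_j/2)), which converges far faster than coordinate
steps on ill-conditioned designs — the severity axis concentrates mass
at t = 0 (all healthy controls), so the Gram matrix is poorly
conditioned at small λ. Blocks whose norm collapses during IRLS are set
to zero and re-checked against their KKT condition by the next full
sweep. Convergence: max coefficient change < 1e-7 (1e-5 inside CV
folds), cap 10⁴ sweeps. KKT residuals at convergence are the solver's
correctness certificate and are asserted in the tests.

### λ selection and preprocessing

Predictors are standardized to zero mean and unit variance (the scaling
record is kept for back-transformation); y is centred and the centre
restored for predictions — the model has no intercept term. λ is chosen
by five-fold cross-validation over 50 log-spaced values from λ_max (the
smallest λ with an all-zero solution) down to 10⁻³ λ_max, warm-started
along the decreasing path; ties in CV error resolve to the larger λ.
Nuisance covariates (age, gender, handedness, ethnicity) are penalized
identically to the brain measures, so the model treats all ten
predictors symmetrically.

One observation per subject is the supported design (cross-sectional
severity); the API accepts repeated severities, which is all a
longitudinal extension would need at the design-matrix level.

### Stability and specificity

"Replicates" are nonparametric bootstrap resamples of subjects
(schemes `subsample` 0.8 and `cv-refit` are also available); each
replicate reruns the full pipeline including CV, on the full-sample
basis so all trajectories share one severity grid. Reported per
predictor: pointwise replicate mean, pointwise SE, and selection
frequency; "stably selected" means selected in every replicate.
Specificity: the memory scores are permuted n_perm times and the whole
stability pipeline is rerun per permutation; the distribution of stable
sets over permutations (ideally mostly empty) measures how easily the
procedure invents stable predictors from noise. Trajectory summaries
above CDR-SB 10 are flagged low-support, reflecting the sparsity of
very severe subjects in the generating cohort.

## 2. Free-water elimination

Per voxel, S(g,b) = S0[fw·exp(−b·3×10⁻³) + (1−fw)·exp(−b·gᵀDg)], with
the free-water diffusivity fixed at 3×10⁻³ mm²/s. S0 is the mean over
b0 volumes; DW signals are normalised by S0 and fitted by Gaussian
nonlinear least squares (`scipy.optimize.least_squares`, trust-region
reflective; Rician generation is supported in the synthetic module but
the fit uses the Gaussian approximation appropriate at moderate SNR).
The tensor is parameterised by its log-Cholesky factor, making positive
semidefiniteness structural; fw is box-bounded to [0,1].

**Single-shell identifiability.** With one b-value the model is not
identifiable on part of its parameter space: for an isotropic tissue
tensor, any (fw, MD) pair on a one-parameter ridge fits the data
exactly. Two mitigations substitute for the spatial regularisation the
original imaging method uses (out of scope here):

* the tissue mean diffusivity is softly constrained to
  [0.1, 2.0]×10⁻³ mm²/s;
* fw is initialised from the mean-DW-attenuation heuristic
  fw₀ = (Ā − T)/(A_fw − T), with T the attenuation of a reference
  healthy-tissue MD of 0.74×10⁻³ mm²/s, and the tissue tensor from a
  free-water-corrected log-linear fit. Two starts are polished (the
  heuristic start and a near-zero-fw single-tensor start) and the
  lower-residual solution kept, with a small improvement margin so
  exact ties on the degenerate ridge resolve to the heuristic start.

Consequences worth knowing: on the ridge the estimate equals the
heuristic initialisation, which is only correct when the true tissue
MD matches the reference value; and under measurement noise single
voxel estimates scatter substantially (region means remain close to
unbiased — the phantom test checks 32-voxel region means, not single
voxels). FA_T is undefined at fw = 1 (zero tissue signal weight).
The multi-start scheme also guarantees the bi-tensor residual never
exceeds the single-tensor (fw = 0) residual on the same voxel.

## 3. Screening

Voxelwise OLS of maps on memory with nuisance covariates; the t-map of
the memory coefficient is the test statistic (zero-variance voxels get
t = 0; exact fits are capped at |t| = 10⁶). Family-wise error is
controlled by max-statistic permutation with the Freedman–Lane scheme:
maps are residualised against the covariates-only model, residual maps
are row-permuted and the covariate fit re-added before the full-model t
is recomputed. Three statistics are available: voxel |t| (maxT), max
TFCE-enhanced |t|, and max suprathreshold cluster statistic at a
two-sided height threshold (p < 0.01 by default). The cluster statistic
defaults to cluster *mass* (summed suprathreshold excess |t|); cluster
extent is available but, being integer-valued, its permutation null is
heavily tied on small unsmoothed grids and the achievable significance
levels skip over alpha = 0.05, making it conservative there — mass has
a continuous null and calibrates exactly. Corrected p-values are
(1 + #{null ≥ observed})/(n_perm + 1); defaults α = 0.05,
TFCE E = 0.5, H = 2, dh = max/100, 26-connectivity (all configurable).
These permutation corrections deliberately replace parametric
Gaussian-random-field corrections: they are exact under exchangeability
at simulation scale and need no smoothness estimation; every run report
logs the substitution. An analysis mask restricts any of these to a
subregion (e.g. a DMN mask for connectivity maps). ROI extraction is
the per-subject arithmetic mean over each significant mask.

## 4. Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the analysis
assumes, not images of real brains:

* **Cohort** — groups HC/aMCI/AD with sizes 51/54/46 (scalable),
  severities from truncated normals with means (SD) 0 (0), 0.8 (0.8),
  6.7 (2.8), rounded to the 0.5-point CDR-SB grid and clipped to the
  diagnostic bounds (HC = 0; aMCI < 4; AD in [4, 18]); rounding happens
  before the final clip so an aMCI draw can never round up onto 4.
  Demographics per group use the reference frequencies (gender,
  handedness, ethnicity) and means (age, education). Severities above
  CDR-SB 10 are naturally rare under the AD distribution, mirroring the
  sparse right tail a real cohort shows.
* **Generating trajectories** — control points interpolated with a
  shape-preserving monotone cubic (PCHIP); a single control point means
  a constant coefficient. The default scenario encodes the reported
  peak associations: FW −0.9 early; fornix FA_T +4.5 early; mPFC +4.5
  early; PCC +1.4 early; hippocampus +2.4 near the aMCI/AD boundary;
  DMN connectivity constant +0.8; nuisance trajectories zero. The
  control points densely trace cubic shapes — exactly representable in
  the L = 4 cubic spline space the model itself uses — with peaks near
  t ≈ 1.8 (t ≈ 4.75 for hippocampus) and gradual decay to a minimum at
  t = 14; being cubics, the curves turn gently past t = 14 (FW dips
  again — its secondary negative bump in the AD range; the positive
  trajectories rise slightly), in a severity region where the cohort
  has essentially no subjects. Exact representability makes peak
  recovery measure estimation error rather than basis-approximation
  error — the natural encoding given that the reported curves are
  themselves L = 4 spline fits.
* **Brain measures** — linear severity trends plus independent Gaussian
  noise per measure (FW rising, FA/GMV/FC falling), scaled so the
  severity–measure correlations are moderate (≈0.5–0.75). Cross-measure
  residual correlation is not modelled by default. The noise multiplier
  `noise_sd` = 1 is the default level.
* **Memory** — y from the varying-coefficient model applied to
  *standardized* predictors (so generating betas are per-SD, matching
  what the model estimates), plus N(0, 1) errors. The residual SD of
  1.0 in memory-z units is this package's choice of a realistic noise
  level; no reference value exists for it.
* **Diffusion voxels** — the acquisition protocol (61 golden-spiral
  directions at b = 1150 s/mm², 7 b0) with optional Rician noise.
* **Effect maps** — iid Gaussian 3-D noise per subject plus spherical
  clusters whose intensity is proportional to the subject's memory
  score.

What passing tests on these data do **not** show: robustness to
registration error, spatially correlated noise, site effects,
non-Gaussian measure distributions, cross-measure residual dependence,
or longitudinal within-subject dynamics. Recovery results quantify the
estimator under its own assumptions.

## 5. Pipeline

Stages (generate/ingest → optional screening → SVC → stability →
optional specificity) run from a YAML config with per-stage seeds
derived from one master seed by hashing. Stage outputs are cached by a
content digest of the stage's config subsection; reruns with the same
config reuse them, and the generated cohort is always round-tripped
through its TSV so cached and fresh runs consume byte-identical inputs.
The run report (JSON, sorted keys) carries peak summaries, stable
selection counts, stage digests and the deviations log, and regenerates
byte-identically from the same config. The default inference profile is
scaled down (n_rep = 20, n_perm = 20); the full 100×100 profile is a
config change.

## 6. Problem sizes in the shipped checks

The shipped tests use: n ≈ 1000 cohorts for trajectory recovery;
100 000 draws for generator bounds; 100 random instances for solver KKT
certificates; an 11 × 5 noiseless grid for free-water forward–inverse
consistency; 200 null simulations on 16³ grids with 100 permutations
each for FWE calibration of all three corrections; and the 20 × 20
reduced specificity profile on the default 151-subject cohort. These
sizes were chosen as the smallest at which each property is
statistically decidable.

## 7. Known limitations

* The SVC basis (4 cubic functions, no interior knots) cannot express
  sharp or multi-bump coefficient functions; trajectories beyond the
  observed severity range are extrapolations of a cubic and are not
  reported.
* CV-minimising λ tends to over-select at n ≈ 150; the stability
  criterion (selected in *all* replicates) is the intended selection
  rule, and the specificity experiment shows a nonzero rate of
  single-variable stable sets under the null — matching the behaviour
  of the procedure it reimplements, not a defect of the solver.
* Voxelwise single-shell free-water estimates are noise-sensitive by
  nature; treat single-voxel FW values with caution and prefer ROI
  means.
* The permutation corrections assume exchangeable subjects under the
  null (no family/site structure).
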