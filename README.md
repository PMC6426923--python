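# adcontinuum

Severity-indexed multimodal brain–memory modelling across the
Alzheimer's disease continuum.

## The problem

As Alzheimer's disease progresses, different kinds of brain
deterioration — extracellular free-water accumulation in white matter,
microstructural damage to tracts such as the fornix, grey-matter
atrophy, loss of default-mode-network (DMN) connectivity — are thought
to matter for memory at *different stages* of the disease. A single
linear regression of memory on brain measures assumes one fixed
association per measure and cannot see this. `adcontinuum` implements a
two-stage analysis for cross-sectional cohorts spanning healthy
controls, amnestic mild cognitive impairment (aMCI) and clinical AD:

1. **Screening** — voxelwise general linear models of brain maps on the
   memory score (with age, gender, handedness and ethnicity as
   covariates), corrected for family-wise error by max-statistic
   permutation (voxel maxT, threshold-free cluster enhancement, or
   cluster extent), followed by mean extraction over the significant
   regions.
2. **Sparse varying-coefficient (SVC) regression** — memory z-scores
   are modelled as

   y_i = Σ_j β_j(t_i) · x_ij + ε_i,

   where t is dementia severity (CDR sum-of-boxes, 0–18 in half-point
   steps) and each coefficient function β_j(t) is a linear combination
   of L = 4 cubic B-spline basis functions. Fitting minimises the
   penalised least squares

   (1/2n) Σ_i [y_i − Σ_j x_ij β_j(t_i)]² + λ Σ_j √(∫ β_j²(t) dt),

   a *functional group LASSO* that zeroes whole coefficient functions,
   with λ chosen by five-fold cross-validation. Stability bands and
   selection frequencies come from refitting on bootstrap replicates;
   specificity is assessed by permuting the memory scores and re-running
   the whole stability pipeline.

The package also implements the free-water elimination step that
produces two of the inputs: a per-voxel two-compartment diffusion model
(isotropic free water with fixed diffusivity 3×10⁻³ mm²/s plus a tissue
tensor) yielding FW and FA_T maps from single-shell diffusion MRI.

Because the clinical data behind this kind of analysis are access
restricted, the package ships a first-class synthetic-data module that
generates seeded cohorts with the reference group structure (51 HC /
54 aMCI / 46 AD; CDR-SB 0, 0.8 ± 0.8 and 6.7 ± 2.8 respectively, with
diagnostic bounds HC = 0, aMCI < 4, AD ≥ 4), severity-coupled brain
measures, memory scores generated from known coefficient trajectories,
bi-tensor diffusion voxels (61 directions at b = 1150 s/mm² plus
7 b0), and 3-D effect-map stacks for screening calibration.

## Worked example

```python
from adcontinuum import SVCModel, default_group_specs, generate_dataset

# a synthetic cohort of ~1000 subjects under the default generating
# scenario (severity-varying effects for FW, fornix FA_T, GMV and FC)
specs = default_group_specs(scale=1000 / 151)
data, _, _ = generate_dataset(specs, seed=1)

model = SVCModel.from_dataframe(data)   # standardizes the 10 predictors
result = model.fit(seed=1)              # 5-fold CV for lambda, then final fit
print(result.summary())
```

```
Sparse varying-coefficient model
================================================================
n subjects:   1001    predictors: 10    basis L: 4 (degree 3)
lambda:     0.0035245    objective: 0.5894    KKT resid: 5.77e-11
----------------------------------------------------------------
predictor        selected   peak beta  at CDR-SB   ||beta||
FW                    yes      -0.955        1.6      2.467
FA_T-fornix           yes       4.475        1.8     11.414
GMV-mPFC              yes       4.375        1.7     10.886
GMV-PCC               yes       1.325        1.7      3.458
GMV-HIP               yes       2.387        5.2      6.575
FC-DMN                yes       1.091       14.5      3.112
age                   yes      -0.131       10.9      0.300
gender                yes      -0.192       14.5      0.328
handedness            yes      -0.016        0.0      0.018
ethnicity             yes      -0.205       14.5      0.363
================================================================
```

The peak column is the signed extremum of each fitted coefficient
trajectory over the observed severity range: free water is most
strongly (negatively) associated with memory early in the aMCI range
and fades with severity; fornix FA_T and prefrontal/posterior-cingulate
grey matter peak early and diminish; hippocampal volume peaks near the
aMCI/AD boundary; DMN connectivity stays constant. The four nuisance
covariates (zero generating effect) are shrunk to near zero.
`result.trajectories()` returns β̂_j(t) on a severity grid,
`stability_replicates(model, n_rep=100)` adds bootstrap bands and
selection frequencies, and `permutation_specificity(model)` runs the
null-permutation check.

Command-line entry points wrap the same library code:

```bash
adcontinuum run --config run.yaml          # full pipeline, staged + cached
adcontinuum svc-fit --data cohort.tsv --out results/
adcontinuum fit-freewater --dwi dwi.nii.gz --bval dwi.bval --bvec dwi.bvec \
    --out-fw fw.nii.gz --out-fat fat.nii.gz
adcontinuum screen --maps maps.nii.gz --outcome cohort.tsv --method tfce
```

## Layout

| module | contents |
| --- | --- |
| `adcontinuum.svc` | `SVCModel` / `SVCResults`, CV, bootstrap stability, permutation specificity |
| `adcontinuum.basis` | B-spline coefficient-function bases and the penalty Gram |
| `adcontinuum.grouplasso` | block-coordinate-descent functional group-LASSO solver |
| `adcontinuum.freewater` | bi-tensor free-water fit, FW / FA_T maps, NIfTI + bval/bvec IO |
| `adcontinuum.screening` | voxelwise GLM, TFCE, permutation FWE, ROI extraction |
| `adcontinuum.synthetic` | seeded generators: cohorts, trajectories, DWI voxels, effect maps |
| `adcontinuum.pipeline` | config-driven orchestration, caching, run reports |

See `docs/methods.md` for the modelling assumptions, parameter
defaults, and known limitations.
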