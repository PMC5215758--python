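# morphoface

Geometric morphometric image analysis of standardized frontal face
photographs: how are body covariates such as body mass index (BMI, kg/m²) and
waist-to-hip ratio (WHR) reflected in facial **shape** and facial **texture**
(the pattern of color across the face)?

The package is written for morphometricians and human-biology researchers who
digitize landmark configurations on standardized photographs and want a
tested, reproducible pipeline from raw TPS landmark files and images to
effect visualizations and cross-validated prediction accuracies.  Because
face photograph collections are usually private, the package ships a seeded
synthetic-cohort generator with exported ground truth, so every stage of the
method can be validated end to end.

## The method

1. **Superimposition.** Landmark configurations (119 points per face by
   default: anatomical landmarks plus semilandmarks digitized on curves) are
   standardized for location, scale, and orientation by generalized
   Procrustes analysis (GPA).  Semilandmarks are then relaxed by the sliding
   landmark algorithm: each may move along its curve tangent so as to
   minimize the thin-plate-spline bending energy between the specimen and the
   sample average.  The shape analysis uses a 69-point subset of the slid
   configurations; all 119 points drive the image warping.
2. **Registration.** Each photograph is warped to the sample mean shape by
   thin-plate-spline (TPS) interpolation with kernel U(r) = r² log r²
   (backward mapping, bilinear sampling).  The registered images all hold the
   same shape, so their RGB pixel values are a pure texture representation.
3. **Statistics.** Both blocks — Procrustes shape coordinates *X* (n × 2k)
   and registered RGB values (n × 3HW) — are analyzed by PCA and by
   multivariate linear regression on a covariate *x*:
   b = cov(X, x)/var(x).  Individual *effect scores* are the projections of
   the centered data on b (equivalent to first-dimension PLS scores for a
   single covariate); effects are visualized by adding multiples of b to the
   mean (reconstructions at x̄, x̄ ± 2 SD, x̄ ± 4 SD).  Prediction of the
   covariate uses the scores, principal-component regression, and ridge
   regression (dual form for p ≫ n), all corrected by leave-one-out
   cross-validation; significance of the multivariate regressions comes from
   a permutation test on the score correlation.

## Worked example

Simulate a 49-face cohort and analyze it:

```sh
morphoface simulate --seed 1 --n 49 --out demo_data
morphoface analyze --input demo_data --out demo_out --seed 1
```

which prints

```
n = 49, seed = 1
shape PC1+PC2 variance: 38.8%
texture PC1+PC2 variance: 64.7%
bmi: shape r = 0.96 (0.95 cross-validated, p = 0.001); texture r = 0.84 (0.82 cross-validated, p = 0.001); combined r_cv = 0.96
whr: shape r = 0.69 (0.56 cross-validated, p = 0.007); texture r = 0.54 (0.47 cross-validated, p = 0.084); combined r_cv = 0.54
```

Reading the output: the first two principal components carry 38.8% of shape
variation; the BMI effect scores computed from shape correlate r = 0.96 with
BMI within sample and r = 0.95 after leave-one-out cross-validation (the
synthetic defaults are deliberately high signal-to-noise so that effect
recovery can be verified; see `docs/methods.md`).  WHR is predicted less well
than BMI — it influences the face only through its correlation with BMI
(r ≈ 0.47) in the generator, mirroring the weaker WHR associations expected
in real cohorts.  `demo_out/` contains `report.json`, `report.txt`, a
resolved configuration copy, and figures: scree plots, PC1–PC2 ordinations
with the direction of maximal covariate increase, reconstructed faces at
x̄ ± 2 SD and ± 4 SD (shape-only, texture-only, and combined rows), and
per-channel hue panels (per-pixel brightness removed).

The same `analyze` command runs on real data: a directory containing
`landmarks.tps` (TPSdig dialect), `covariates.csv` (columns `id,bmi,whr`),
`scheme.yaml` (curves, fixed landmarks, shape subset), and `images/<id>.png`.
Specimen ids must match exactly across files; mismatches are hard errors.

The same functionality is available as a library:

```python
from morphoface import SyntheticSpec, RunConfig, run_full_analysis

cfg = RunConfig(output_dir="out", synthetic=SyntheticSpec(n=49, seed=1), seed=1)
report = run_full_analysis(cfg)
print(report.covariate_results["bmi"]["shape"])
```

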