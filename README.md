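# radtex

Radiomics texture analysis for 3D volumetric images (brain MRI and beyond):
a full feature-extraction stack — shape, first-order intensity statistics,
and the five standard texture matrices (GLCM, GLSZM, GLRLM, NGTDM, GLDM) —
plus the **decreasing gray-level matrix (DGLM)**, a directional co-occurrence
filter that keeps only pixel pairs whose intensities do not decrease along
the scan direction. Features feed an ensemble-classification pipeline
(bagging, random forest, AdaBoost, gradient boosting, XGBoost) with
importance-based feature selection and group-aware cross-validated
sensitivity/specificity/accuracy/AUC evaluation, aimed at screening-style
decision support (e.g., separating CDR = 0 controls from CDR > 0 scans).

## The methods in brief

Intensities inside a region of interest are binned into `Ng` gray levels
(default 32, equal-width). From the level array the package builds:

- **GLCM** `P(i,j | θ, δ)` — co-occurrences of levels `(i, j)` at offset
  `δ·θ`; symmetric (Haralick) by default, 13 unique 3D directions, features
  averaged across directions.
- **GLSZM** `P(i,s)` — connected zones (26-connectivity) of level `i` and
  size `s`.
- **GLRLM** `P(i,r | θ)` — maximal runs of level `i` with length `r`.
- **NGTDM** `(n_i, p_i, s_i)` — per-level sums of `|i − Ḡ|`, where `Ḡ` is
  the mean level of the in-mask Chebyshev neighborhood (center excluded).
- **GLDM** `P(i,d)` — voxels of level `i` with exactly `d` neighbors within
  gray-level tolerance `γ`; the dependence column starts at `d = 0`.
- **DGLM** `P(i,j | θ, δ)` with the constraint `i ≤ j` — the asymmetric
  co-occurrence matrix masked to its upper triangle. Unlike every matrix
  above, DGLM is *not* invariant to reversing the pair order, so it can see
  directional, chirality-bearing texture (e.g., slow-rise/fast-fall
  intensity ramps) that symmetric statistics cannot. Computed slice-wise at
  the four in-plane angles 0°/45°/90°/135° and feature-averaged.

Shape descriptors come from a marching-cubes mesh of the ROI (volume as a
sum of signed tetrahedra, area as summed triangle areas, max 3D/axial
diameters) and from the eigenvalues `γ` of the voxel-coordinate covariance
(axis length `4√γ`, elongation `√(γ_minor/γ_major)`, flatness
`√(γ_least/γ_major)`).

Evaluation uses stratified *group-aware* k-fold CV: a scan and all of its
augmented copies share a `source_id` and always land in the same fold, so
augmentation can never leak between train and test. Metrics are
`sensitivity = TP/(TP+FN)`, `specificity = TN/(TN+FP)`,
`accuracy = (TP+TN)/total`, and AUC as the Mann–Whitney rank statistic on
pooled out-of-fold scores.

## Worked example

Everything runs on synthetic phantoms — no data download. The generator
produces Gaussian-random-field volumes whose two classes differ in texture
correlation length (0 vs 4 voxels) and mean offset (1 σ) inside an
ellipsoidal ROI:

```python
import radtex as rt

spec = rt.PhantomSpec(effect_size=1.0)        # the "large effect" condition
samples = rt.generate_dataset(50, spec, seed=1)  # 50 scans per class
table = rt.build_table(samples)               # 100 rows x 94 features
report = rt.evaluate(table, "gradient_boosting", folds=5, seed=1)
print(f"sensitivity={report.sensitivity:.3f} specificity={report.specificity:.3f} "
      f"accuracy={report.accuracy:.3f} auc={report.auc:.3f}")
```

```
sensitivity=1.000 specificity=1.000 accuracy=1.000 auc=1.000
```

A correlation-length difference of 4 voxels is a large texture effect — the
co-occurrence and dependence features separate the classes essentially
perfectly, so the pipeline recovers the planted labels at AUC 1.0. At
`effect_size=0.0` the two classes are generated from identical parameters
and the same pipeline returns chance-level accuracy (≈ 0.5), which is the
package's leakage check.

The same flow is available from the shell:

```bash
radtex simulate --n-per-class 50 --effect 1.0 --seed 1 --out sim/
radtex extract --in sim/ --out features.csv
radtex evaluate --table features.csv --folds 5 --seed 1
radtex importances --table features.csv --top 10
radtex run --in sim/ --out results/ --seed 1    # end-to-end with artifacts
```

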