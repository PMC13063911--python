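# lvshape

3D shape analysis of the lateral ventricles for predicting the outcome
of shunt surgery in idiopathic normal-pressure hydrocephalus (iNPH).

iNPH is a ventricular-enlargement syndrome whose gait, cognitive and
urinary symptoms are potentially reversible by CSF shunting — but only
some patients respond, and classical 2D radiological markers (Evans
index, callosal angle, DESH) predict response imperfectly. `lvshape`
implements a fully automated 3D alternative: it converts lateral
ventricle segmentation masks (NIfTI) into standardized triangle meshes,
extracts 27 global / local / curvature shape features, and evaluates an
L1-penalized logistic classifier ("LogitNet") of binary shunt response
under repeated nested cross-validation, ranking features by how often
the L1 penalty keeps them.

The pipeline, in the package's five steps:

1. **Mesh generation** (`voxmesh`): Surface-Nets dual contouring of the
   binary mask (marching cubes optional), Loop subdivision + quadric
   edge-collapse decimation to exactly N = 24,000 vertices, improved
   (HC) Laplacian smoothing (5 iterations, lambda = 1.0).
2. **Feature extraction** (`features_global`, `features_local`,
   `features_curvature`): 11 whole-mesh features (asphericity As and
   AsE from a least-squares sphere fit, SA, V, SAVR, integral mean
   curvature, convex-hull CHSA/CHV and ratios); 12 neighborhood
   features from the eigenvalues l1 >= l2 >= l3 of the local structure
   tensor (linearity (l1-l2)/l1, planarity (l2-l3)/l1, sphericity
   l3/l1, omnivariance (l1 l2 l3)^(1/3), anisotropy, eigen-entropy
   -sum e_i ln e_i, eigenvalue sum, change of curvature l3/sum(l), plus
   farthest distance, point density, height range and SD), averaged
   over all vertices; 4 discrete curvature means (angle-defect Gaussian
   K, cotangent-Laplacian mean H, principal curvatures H +/-
   sqrt(H^2 - K)).
3. **Preprocessing** (`model`): per-column empirical quantile map to
   uniform [0, 1], fitted on training data only.
4. **Classification** (`model`): minimize (1/n) deviance +
   lambda ||beta||_1 along a 100-point path from lambda_max down; 10x
   repeated nested CV (5 inner folds select lambda by ROC-AUC, 5 outer
   folds evaluate — 50 evaluations, 136 train / 34 test at n = 170).
   A PCA variant (standardize, keep components covering >= 95%
   variance) is included for comparison.
5. **Importance & reporting** (`model`, `report`): selection frequency
   across the 50 evaluations, per-feature KDEs by response, Kendall
   tau-b correlation heatmap with Ward clustering, 10th/90th-percentile
   exemplar subjects, ROC and pooled confusion figures.

The clinical cohort this protocol was designed for is private, so the
package ships a first-class synthetic module (`synthetic`): two-class
voxel phantoms (bump-perturbed ellipsoids whose elongation differs by a
controllable factor) and two-class Gaussian feature tables with a known
number of informative columns.

## Worked example

```python
import lvshape as lv

# two-class phantom cohort: class 1 ventricles elongated by 1.6x
cohort = lv.generate_phantom_cohort(lv.PhantomSpec(n_per_class=5, seed=0))
df = lv.cohort_features([m for m, _ in cohort], [l for _, l in cohort])
print(df.groupby("response")[["As", "SAVR", "CHVR"]].mean().round(4))

# nested-CV evaluation of a 170-subject synthetic table whose single
# informative feature (As) has a realistic effect size (d' = 0.58)
table = lv.generate_feature_table(lv.TableSpec(seed=0))
rep = lv.nested_cv(table, lv.ModelConfig(seed=0))
print(rep.aggregate().round(3))
print(lv.selection_frequency(rep).head(3))
```

Output:

```
              As    SAVR    CHVR
response
0         0.1121  0.1711  1.0198
1         0.2289  0.1583  1.0294
                    mean    std
auc                0.573  0.092
balanced_accuracy  0.519  0.048
sensitivity        0.917  0.115
specificity        0.121  0.149
  feature  frequency  response_correlation
0      As         48              0.213286
1      MC         26             -0.146657
2     CHV          9             -0.091857
```

Reading the numbers: the elongated phantom class has roughly twice the
asphericity (vertices deviate more from the best-fit sphere), a lower
surface-to-volume ratio (larger object) and a higher hull-volume ratio
(more concave). On the synthetic 170-subject table the classifier
reaches a mean ROC-AUC around 0.57 — nested CV on 170 subjects pays a
real price relative to the d' = 0.58 population AUC of 0.66, which is
the low-signal regime this kind of shape marker lives in — and the
informative feature As is kept by the penalty in 48 of 50 evaluations,
far ahead of any noise feature. The high sensitivity / low specificity
split reflects the 0.5 probability threshold on an imbalanced (95/75)
cohort with weak signal: the model leans toward the majority
(responder) class.

A command-line interface mirrors the library
(`lvshape extract | featurize | simulate | evaluate | report`), e.g.:

```bash
lvshape simulate phantoms --out masks/ --n-per-class 20 --seed 0
lvshape extract --in masks/phantom_000.nii.gz --out mesh.ply
lvshape evaluate --features features.csv --out report/
```

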