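# Methods

`lvshape` implements a five-step protocol for predicting the outcome of
shunt surgery in idiopathic normal-pressure hydrocephalus (iNPH) from the
3D shape of the lateral ventricles: (1) mesh generation from segmentation
masks, (2) extraction of 27 shape features, (3) preprocessing, (4)
L1-penalized logistic classification under repeated nested
cross-validation, and (5) feature-importance ranking by selection
frequency. This note documents the model choices, defaults, numerics and
limitations.

## Mesh generation

**Isosurfacing.** The default extractor is a binary Surface-Nets-style
dual contouring: one vertex per mixed 2x2x2 voxel cell, placed at the
centroid of the cell's iso-crossing edge points, and one quad (two
triangles) per sign-changing voxel edge. On a grid padded by one
background voxel the output is closed by construction; non-manifold
configurations (diagonally touching voxels) are rejected with a hard
error rather than repaired — a segmentation producing them deserves
inspection, not silent patching. `skimage` marching cubes at level 0.5 is
available behind `MeshConfig(algorithm="marching_cubes")`; both converge
to the same limit surface, and the downstream features only require a
watertight mesh. All coordinates are world millimetres (voxel index x
spacing). Left and right ventricle labels are merged into one mask, so a
mesh may contain two connected components.

A convention note: for an isolated single voxel the dual-contour surface
encloses 1/27 mm^3 (crossing-point centroids pull the eight cell vertices
inward); marching cubes gives the 1/6 mm^3 octahedron. Sub-voxel features
are below the method's resolution either way; the regression test pins
the dual-contour value.

**Vertex-count standardization.** Every mesh is brought to exactly
24,000 vertices so that point-density-dependent local features and
per-vertex averages are comparable across subjects scanned at different
resolutions. Meshes below the budget are Loop-subdivided (faces x4, new
vertices on the approximating smoothed surface) until at or above it,
then decimated by greedy quadric edge collapse (area-weighted
Garland–Heckbert quadrics; candidate positions endpoint/endpoint/
midpoint). Each collapse removes exactly one vertex, which is how the
budget is hit exactly; collapses violating the link condition or
flipping a face normal are rejected, preserving watertightness and
orientation.

**Smoothing.** Improved Laplacian smoothing in the HC (anti-shrink)
formulation: each of 5 iterations moves vertices toward their one-ring
uniform average with factor lambda = 1.0, then subtracts the
push-back correction `beta*b + (1-beta)*avg(b)` with original-position
weight alpha. lambda and the iteration count are the protocol constants;
alpha = 0.1 and beta = 0.5 are the correction weights (beta exposed in
`MeshConfig`). On convex solids the enclosed volume changes by well
under 5%.

## Features (27)

**Global (11).** Asphericity As = mean|d_i - R|/R and asphericity error
AsE = RMS(d_i - R)/R over the 24,000 vertex distances d_i to the
least-squares sphere (algebraic fit + Gauss–Newton refinement of the
geometric objective). These are dimensionless, rigid-motion and scale
invariant, zero exactly for a sphere, and AsE >= As always (RMS >= MAE).
SA, V and SAVR = SA/V come from triangle areas and signed tetrahedra;
IMC = sum over edges of length/2 x signed dihedral angle (convex edges
positive; 3*pi for the unit cube, 4*pi*r for a sphere). The convex hull
of the vertex set yields CHSA, CHV and the ratios CHSAR = CHSA/SA,
CHVR = CHV/V, CHSAVR = CHSA/CHV. CHV >= V is a theorem; CHSA <= SA is
*not* — for gently bumpy near-convex surfaces the hull tents over bump
peaks and CHSAR can marginally exceed 1. It reliably drops below 1 in
the regime the features target (fine surface irregularity).

**Local (12).** For each vertex, all vertices within a fixed radius
(self included) form a neighborhood; eigenvalues l1 >= l2 >= l3 >= 0 of
its covariance (population divisor k; eigenvalues below 1e-12 x l1
clamped to exact zero so rank-deficient neighborhoods behave exactly)
give linearity, planarity, sphericity, omnivariance, anisotropy,
eigen-entropy, eigenvalue sum and change-of-curvature; the farthest
distance, point density k/(4/3 pi r^3), height range and height SD (world
z) complete the set. Every pointwise value is averaged arithmetically
over the vertices. The radius defaults to 4x the median mesh edge length
(logged per mesh, typically ~1.2 mm at the standard vertex budget, ~60
neighbors), overridable as a fixed physical radius; the 4x factor keeps
neighborhoods locally planar while dense enough for stable tensors.
Height features are z-dependent by definition; meshes are not
re-oriented, so they assume a consistent subject orientation (true for
standard NIfTI and for the phantoms).

**Curvature (4).** Gaussian curvature by angle defect over one-third
barycentric vertex areas — its area-weighted total equals 2*pi*chi
exactly on any closed mesh (Gauss–Bonnet), the suite's strongest
correctness probe. Mean curvature from the cotangent Laplace–Beltrami
operator, signed convex-outward-positive; principal curvatures from
(H, K) with the discriminant clamped at zero. Features are *signed*
arithmetic vertex means. Caveat: an unweighted vertex mean equals the
surface average only when vertices sample the surface uniformly per
area; validation therefore compares against analytic curvatures
evaluated at the same vertices (0.1% agreement on a 10x10x20 ellipsoid)
rather than against closed-form surface integrals.

## Classification

Features are mapped per column to uniform [0, 1] by an empirical
quantile transform with min(1000, n_train) knots. The transform is
fitted inside each training portion only (the leakage-safe reading; a
`preprocess_global` flag reproduces the fit-once-on-everyone
alternative for sensitivity analysis).

The classifier ("LogitNet") minimizes (1/n) logistic deviance +
lambda * ||beta||_1 with an unpenalized intercept, solved by IRLS with
cyclic coordinate descent on the weighted least-squares subproblem
(Gram-matrix covariance updates, working weights floored at 1e-5,
numba-compiled). The penalty path has 100 log-spaced values from
lambda_max = max_j |x_j . (y - ybar)|/n — where every coefficient is
exactly zero — down to lambda_max/100, with warm starts. Near-zero
penalties agree with an unpenalized BFGS fit to ~1e-4.

Evaluation is 10-times-repeated nested cross-validation: five stratified
outer folds estimate performance (ROC-AUC by the tie-corrected
Mann–Whitney statistic, balanced accuracy, sensitivity and specificity
at probability 0.5, responders positive); five stratified inner folds
pick lambda by mean validation AUC, ties resolved toward the larger
(sparser) penalty — the 1-SE rule is deliberately not used. Two numerics
matter on strongly separated data: (i) test subjects are ranked by the
linear predictor rather than the sigmoid probability, which saturates to
exactly 1.0 in float64 beyond eta ~ 37 and would destroy the ranking;
(ii) because each inner fold's own lambda_max can exceed the outer-train
lambda_max, the path head can score perfectly inside while refitting to
the null model outside — among tied penalties the largest one whose
outer-train refit has active coefficients is selected. On 170
subjects this yields 50 evaluations, each training on 136 and testing
on 34. Feature importance is the count of evaluations in which a
feature's coefficient at the selected penalty exceeds 1e-8 in absolute
value, ties broken alphabetically, reported beside each feature's
descriptive Pearson correlation with the response (computed on the
all-data quantile scale; it annotates the ranking and is not part of
the CV). The PCA variant standardizes per training portion, keeps the
smallest component count reaching 95% cumulative explained variance,
and runs the identical path and selection on the scores.

## Synthetic data

The clinical registry behind the protocol is private, so two generators
define the package's study conditions.

*Phantoms*: ellipsoids (default semi-axes 19 x 14 x 25 mm, ~28 mL —
ventricle scale) rasterized at 1 mm on a 96^3 grid, with a band-limited
random radial bump field (8 random-direction sinusoids, RMS amplitude
1 mm, angular wavenumber 4) providing per-subject surface irregularity
independent of elongation. Class 1 stretches the third semi-axis by 1.6,
which raises asphericity — the pipeline's headline feature — well above
the bump-noise variability at 20 subjects per class. Phantoms emulate
mask-level geometry only: no scanner artifacts, no anatomical topology
(ventricles are not ellipsoids), no segmentation error; passing tests
demonstrate the machinery, not clinical performance.

*Feature tables*: class sizes default to 75/95, mirroring a 170-subject
cohort with 95 responders. Informative columns are N(0,1) vs N(d', 1)
and are assigned starting at the "As" column; noise columns are
exchangeably correlated (rho = 0.2). The default d' = 0.58 is the
two-Gaussian separation whose theoretical single-feature ROC-AUC,
Phi(d'/sqrt(2)) ~ 0.66, matches the effect size this class of shape
markers has shown in practice, so default runs operate in a realistic
low-signal regime.

## Numerical and design notes

- Stratified folds keep both classes in every fold (plain 5-fold
  partitioning of 170 gives the same 136/34 sizes).
- Identical seeds give bitwise-identical fold assignments, penalty
  paths, selected lambdas and reports.
- Replacing outer-test feature blocks with constants after fold
  assignment leaves every training-side quantity unchanged (asserted by
  an instrumentation hook in `nested_cv`).
- Kendall correlations use tau-b (feature tables contain ties);
  clustering uses Ward linkage on d = 1 - tau; exemplar selection uses
  linear-interpolation percentiles with ties to the lowest subject ID.
- Degenerate inputs fail loudly: empty segmentations, non-watertight
  surfaces, coplanar sphere fits, single-class folds.
- Problem sizes in the test-suite and acceptance script (64^3 unit-test
  phantoms at a 6,000-vertex budget, 20+20 subjects for the end-to-end
  study, 2 repeats for the phantom CV) are chosen so the full
  verification runs on a laptop-class single core in minutes while the
  default 24,000-vertex / 10-repeat protocol is exercised where the
  contract demands it.

## Limitations

- The decimation is greedy; it hits the vertex budget exactly but does
  not optimize global mesh quality, and vertex density after heavy
  decimation is not perfectly uniform.
- The neighborhood radius for local features is a modeling choice the
  original protocol leaves open; results should be reported with the
  radius used (the QC output records it).
- Curvature means are estimator- and sampling-convention dependent at
  the few-percent level on irregular meshes; cross-library numeric
  parity is a non-goal.
- Synthetic calibrations bound statistical behavior (chance-level nulls,
  theoretical AUC recovery) but say nothing about clinical validity on
  real cohorts.
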