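# Methods

`gmconn` implements a single-subject gray-matter covariance connectome
pipeline for predicting a binary tumor genotype (IDH mutant vs wild type)
from pre-surgical T1-derived gray-matter maps, together with a synthetic
cohort generator that makes every stage testable without patient data.

## Pipeline

**Input.** A modulated, spatially normalized gray-matter probability/volume
map per subject: a 3-D grid of non-negative voxel values in a common
template frame with a voxel→world affine. Voxel-based morphometry itself
(segmentation, DARTEL registration, modulation) is out of scope — the
pipeline starts where VBM ends.

**Nodes.** The volume is tiled from its origin into non-overlapping
3×3×3-voxel cubes; partial cubes at the far boundary are dropped. A cube
becomes a network node iff its mean value exceeds `min_gm` (default 0.1,
the usual gray-matter-probability floor) *and* its 27 values have nonzero
variance (numerical tolerance 1e-12 on the standard deviation) — a
constant cube has no defined correlation. Node centroids are the world
coordinates of cube centers via the affine. An all-excluded volume raises
a "degenerate subject" error naming the subject.

**Edges.** Similarity between two nodes is the Pearson correlation r of
their 27 aligned voxel values. A `rotation_invariant` option instead takes
the maximum r over the 48 cube orientations (full octahedral group) of one
member, as in similarity-based extraction schemes that align cube
orientation; it is off by default because plain aligned-voxel correlation
is the simpler reading of "correlation between voxel values" and is
rotation-consistent for aligned template-space data. The similarity matrix
is symmetric with unit diagonal to 1e-12.

**Thresholding.** Two binarization rules:

* `fixed_r`: edge iff r > c for a fixed cut c ∈ [−1, 1] (deterministic;
  used widely in tests);
* `permutation_fpr` (default, param 0.05): each node vector is permuted
  within itself (destroying spatial structure while keeping marginals), the
  permuted set's pairwise correlations form a null distribution, and the
  cut is its (1 − α) quantile, so structure-free data produces edges at
  rate α. The realized cut is always recorded (`threshold_used`) so runs
  are auditable. Default 20 permutation rounds; with n nodes each round
  contributes n(n−1)/2 null correlations, so the quantile is stable.

**Graph metrics.** Nodal efficiency of node i is
E(i) = (1/(n−1)) Σ_{j≠i} 1/d(i, j), with unweighted shortest-path hop
counts d from all-pairs BFS (scipy's csgraph implementation) and 1/d = 0
for unreachable pairs — 1 on a complete graph, 0 for an isolated node,
computed over the full graph with the (n−1) normalization. Three global
covariate features accompany the efficiencies: total brain volume
(Σ voxel values × voxel volume over the retained cubes, mm³), network size
n, and mean nodal degree 2|E|/n. Mean degree is the scalar summary chosen
for "number of nodal connections" because the feature layout requires one
number per subject and a mean is comparable across subjects with
different n.

**Feature assembly.** Cube efficiencies are averaged within 90 atlas
regions by centroid containment (world→voxel through the atlas affine,
nearest-voxel rounding; centroids outside the grid or on background count
as unassigned and are excluded). A region with no assigned node gets
efficiency 0 and is flagged in a warning — never silently. The core
feature vector is the documented fixed order [90 regional efficiencies in
atlas-table order, brain_volume, network_size, mean_degree] (93 columns);
the optional clinical block appends [age, hemisphere left=1 indicator,
6-category lobe one-hot incl. multifocal] (101 columns total). A bundled
synthetic atlas (5×6×3 rectangular partition of the template grid carrying
the conventional 90 AAL region names) keeps tests self-contained; a real
atlas can be supplied as NIfTI labels + TSV table.

**Classifiers.** Four families with the stock tuning of the classic Weka
workbench, backed by scikit-learn:

| family | settings |
|---|---|
| random_forest | 1000 trees, mtry = ⌊log₂ p⌋ + 1 (7 at p = 93) |
| svm_poly | degree-1 polynomial kernel, C = 1 |
| logistic_ridge | ridge 1e-8 (i.e. C = 1e8, effectively unpenalized) |
| mlp | one hidden layer of ⌊(p+2)/2⌋ units, SGD, lr 0.3, momentum 0.2, 500 epochs |

Scale-sensitive families (SVM, logistic, MLP) are standardized inside
their pipelines; the forest is scale-invariant and used raw. SVM ROC
scores come from a held-out-fold Platt calibration: a 1-D logistic fit on
cross-validated decision values, applied to the final SVM's decision
values — strictly monotone, so the margin ranking (hence AUC) is
preserved while scores live in [0, 1].

**Evaluation.** Leave-one-out cross-validation; random minority
oversampling (duplicate minority rows with replacement until counts are
equal, originals always retained) is applied *inside each training fold*
by default, so the held-out subject can never leak into training via a
duplicate; the leaky pre-CV variant is available for comparison and the
mode is recorded in every report. Out-of-fold scores are pooled into one
ROC; AUC is the rank statistic (ties count ½); accuracy/sensitivity/
specificity use a 0.5 score cut by default (configurable, recorded).

**AUC comparison.** Paired stratified bootstrap (default 2000 replicates,
the convention of the pROC tradition): positives and negatives are
resampled separately, both models' AUCs recomputed per replicate, and the
observed difference standardized by the bootstrap sd is referred to a
standard normal, two-sided.

**Nested feature selection.** Selection runs inside each outer training
fold, the outer loop repeated (default 50, with distinct derived seeds)
and summarized as mean ± sd of the per-repeat pooled AUCs:

* `rfe`: backward elimination over a halving-size schedule ranked by
  random-forest importance; the retained size is chosen by inner 5-fold
  AUC (ties favor fewer features);
* `elastic_net`: penalized logistic regression at mixing parameter 0.5,
  penalty strength by inner 5-fold CV, keeping nonzero-coefficient
  features (a fully-shrunk fit falls back to all features).

The outer loop defaults to LOOCV; `outer_cv=k` switches to stratified
k-fold where the quadratic cost of LOOCV-nested selection is not wanted.

**Reproducibility.** All randomness derives from one run seed through a
SHA-256 hash of (seed, stage name, indices), so every stage is
independently reproducible and no stage's draws depend on another's
consumption order.

## Synthetic cohort generator

The generator emulates the *statistical* situation of the study — two
classes whose cube-cube covariance structure differs — not neuroanatomy.
A cohort shares a baseline template (mean 0.5, voxel jitter sd 0.1, one
zero cube-shell of background so background voxels are exactly 0), a
partition of the interior cubes into `n_latent_regions` contiguous blocks
(default 20), and a fixed zero-mean unit-sd 27-voxel motif replicated in
every cube. Each subject draws per-block latent scores from an
equicorrelated multivariate normal: inter-block correlation ρ₀ = 0.05 for
wild-type-like subjects and min(ρ₀ + 0.3·effect_size, 0.95) for
mutant-like subjects. The voxel value is
template + 1.0·z_block·motif + N(0, noise_sd²), clipped at 0
(noise_sd default 0.1).

Within a subject, the correlation between two cubes is driven by the
product of their blocks' latent scores times the shared motif, so blocks
with aligned scores form densely connected cliques. Higher inter-block
coupling (mutant-like class) aligns more blocks, producing denser, more
efficient networks — a class difference expressed exactly where the
pipeline looks: in regional nodal efficiency, mean degree, and network
organization. At effect_size = 0 the label never enters the generative
path, making the classes exchangeable by construction. The signal
amplitude (1.0) and coupling slope (0.3 per unit effect) were fixed at
design time so that effect_size ≈ 3 ("strong") drives the class-1 coupling
near its 0.95 cap while effect_size ≈ 1 stays moderate; the scale was
chosen so a strong effect is clearly learnable at a 60-subject desk-scale
cohort while zero effect is chance-level.

Clinical covariates are drawn with a controllable class association
(`clinical_assoc` ∈ [0, 1]): mutant-like subjects are younger on average
(shift 12·assoc years against sd 13, base mean 48), more often frontal
(+0.20·assoc on the frontal probability before renormalization), and
slightly more often left-hemisphere (+0.12·assoc). Base frequencies follow
the typical presentation of diffuse glioma (frontal-dominant lobe
distribution, ~72% left). At the default assoc = 0.5 the clinical signal
is deliberately weak at n = 60 — enough for ordering tests (connectome
model ≫ clinical model) without making the clinical baseline competitive.
An optional spherical lesion (centered on a chosen block, radius in
voxels) multiplies intensities by 1 − reduction, for robustness probes;
off by default.

What the generator does *not* emulate: anatomy, scanner artifacts,
registration error, partial-volume effects, or the empirical AUC levels of
any real cohort. Passing tests therefore demonstrate that the pipeline
recovers covariance-structure differences it is designed to detect, and
that it is correctly calibrated under the null — not that any particular
clinical performance would be attained on real MRI.

## Problem sizes and numerical choices

Simulation-heavy checks run at desk scale, chosen as the package's own
test-size policy: 60-subject cohorts; a 30³ template (≈512 interior cube
nodes) for signal-recovery runs and 24³ (216 nodes) for the 20-seed null
calibration; the forest at its stock 100 trees for calibration runs (the
chance-level property does not depend on forest size) and the full 1000
trees for signal recovery. Real networks are an order of magnitude larger
(≈7,000 nodes); all graph algorithms are exact and scale as O(n·m), so
node count affects cost, not correctness.

Tolerances: similarity symmetry and efficiency-oracle agreement at 1e-12;
the variance floor for node retention at sd 1e-12; the permutation
threshold's calibration tested at Monte-Carlo tolerance; the null
calibration band is 0.5 ± 1.96·σ₀/√(#seeds) with σ₀ the analytic
Mann–Whitney null AUC sd for the cohort's class split. Ties in RFE size
selection go to the smaller feature set; an elastic-net fit that shrinks
everything to zero falls back to the full feature set rather than an
empty model.

## Known limitations

* Pooled LOOCV AUC with in-fold oversampling on an imbalanced cohort has
  a small pessimistic bias (each held-out subject's class is slightly
  depleted, and the opposite class up-weighted, in its training fold);
  at n = 60 this stays well inside the null calibration band but is
  visible as null means slightly below 0.5 for some families.
* Centroid-containment region assignment ignores cubes straddling region
  boundaries; no fractional assignment is attempted.
* The bundled atlas is a rectangular partition with AAL-style names, not
  the real AAL geometry; supply the real atlas by path for real data.
* Only unweighted graphs and nodal efficiency are implemented; other
  topological properties (clustering, betweenness, small-worldness) are
  out of scope.
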