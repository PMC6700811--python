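# Methods

## Scope and model of the data

The package treats a breeding nursery as: a north-up, georeferenced 3-band
(R, G, B) orthomosaic of 8-bit digital numbers; a vector layer of plot
polygons carrying the trial design (plot, trial, entry, block); and a set of
ordinal 1–5 visual severity ratings. Radiometric calibration is deliberately
out of scope — the workflow is defined on raw digital numbers, which is why
the segmentation index is a within-pixel band ratio rather than a calibrated
reflectance index.

## Stage 1 — plant/soil segmentation

Index: (R − G)/(R + G) per pixel, in [−1, 1]; pixels with R + G = 0 are set
to 0 and tallied. Green canopy (G > R) is negative, bare soil (R > G)
positive; chlorotic canopy sits near zero and necrotic brown canopy is
positive, which is the fundamental ambiguity of unsupervised plant/soil
separation under severe stress.

Clustering is our own Lloyd's k-means (k = 5 by default): the first centroid
is a seed-selected data point, the remainder are placed by farthest-point
traversal, and an empty cluster is re-seeded at the point farthest from its
assigned centroid. Convergence: centroid movement < 1e-6 or 300 sweeps.
Several deterministic restarts (sub-seeds seed..seed+n_init−1; 10 by default
for generic calls, 3 for whole-scene rasters) guard against local optima;
on small inputs (n ≤ 10, k ≤ 3) the result matches brute-force partition
enumeration exactly in the test suite, and centroids match
scikit-learn's KMeans on well-separated mixtures. Cluster ids are returned
sorted by centroid, so labels are stable across runs.

Recoding to plant/soil is either an explicit user mapping (the analogue of
grouping spectral classes by eye) or automatic thresholding of centroids at
index 0. A warning is logged when an automatically plant-assigned centroid
exceeds −0.02, because stressed canopy and soil overlap there and silent
automation would be unsafe.

## Stage 2 — green/yellow/brown classification

K-means (k = 3 by default) on the RGB triples of masked canopy pixels; an
HSV feature space is available by flag. Clusters are recoded by centroid
hue: green for hue in [75°, 170°), yellow for [40°, 75°), brown otherwise
(low-hue reds/oranges and dark necrotic material). The boundaries are
configurable and an explicit mapping overrides the rule; with k > 3,
clusters sharing a label merge. On fields with little necrosis the third
cluster may land inside the green–yellow continuum and no brown cluster
emerges — the label partition is still exhaustive over canopy pixels.

## Zonal features

Pixel membership: a pixel belongs to a polygon iff its center is inside,
with boundary centers counting only on the top/left (minimum-row/-col)
edges; implemented by nudging test points a sub-pixel epsilon (1e-7 pixel)
toward increasing row and col. This fixed rule makes zonal counts exactly
reproducible and translation-invariant. Per plot: color counts, proportions
of plant pixels, and canopy coverage = plant/(plant+soil) pixels. Plots with
no plant pixels keep coverage 0 and missing (not 0/0) proportions. Coverage
is compared across severity classes with one-way ANOVA and Tukey's HSD at
α = 0.05.

## Severity scoring

Features are (%G, %Y, %B); scores are treated as unordered categories.
The split is stratified by class, validation fraction 0.33 (training on the
complement), with a bounded redraw if a class drops out of training.

Random forest: scikit-learn's RandomForestClassifier with 100 trees, Gini
splits, minimum node size to split 10, and all three features searched per
split (subsampling is pointless at p = 3; a flag restores √p).

Neural network: implemented in-package — 3 tanh hidden units, softmax
output, mean cross-entropy, full-batch gradient descent at learning rate
0.1 for at most 500 epochs. Inputs are standardized internally (the usual
conditioning step; without it plain gradient descent at this budget
underfits). Early stopping monitors an internal 15% holdout of the training
split with patience 25 and keeps the best weights; hitting the epoch cap
warns and returns best-so-far. A zero learning rate is accepted and leaves
the initial parameters untouched, which pins down the update rule in tests.

Evaluation: 5×5 confusion matrix (rows reference, columns predicted,
row-normalized percentages) and overall accuracy; high/low-stress binning
maps 1–3 to "low" and 4–5 to "high" — coarsening can only convert
mismatches into matches, so binned accuracy is never below 5-class accuracy.

## Accuracy assessment

Equalized random sampling draws the same number of pixels per predicted
class, uniformly without replacement (avoids duplicate points at small
class sizes). Reference labels come from a user-supplied label file or, in
simulation, from the truth raster. The error matrix reports overall
accuracy (diagonal/total), user accuracy per predicted class (row-wise) and
producer accuracy per reference class (column-wise); overall accuracy is
identically the row-total-weighted mean of user accuracies, asserted
numerically in tests.

## Trial precision

Per trial, `score ~ C(entry) + C(block)` is fit by OLS (statsmodels);
incomplete designs are fit as-is with no imputation. MSE = SSR/df_resid;
for complete balanced designs this equals the classical two-way ANOVA
residual mean square, verified against an explicit sum-of-squares oracle to
1e-10 relative error. Entry means are least-squares means (predictions
averaged over block levels).

LSD modes: "paper" = t(1 − α/2, df)·√MSE, "standard" =
t(1 − α/2, df)·√(2·MSE/r). They coincide exactly at r = 2, the
two-replicate design this workflow targets; both are exposed because the
first form omits the √(2/r) factor and is only self-consistent at r = 2.
α defaults to 0.20, the relaxed threshold conventional in variety-trial
reporting (two-sided, i.e. the t quantile at cumulative 0.90). The
comparison module counts trials where the image-based LSD is strictly lower
and reports the mean difference.

## Synthetic field generator

What it emulates: an RCBD nursery of single-row plots (default 2 blocks;
entries randomized within each trial-block strip), 1.6 cm pixels, plots of
56×36 px (≈ 2000 pixels), soil alleys. Severity: latent = grand mean (2.3)
+ entry effect (sd 0.9) + block effect (sd 0.2) + residual (sd 0.3), all
normal; the same entry keeps its effect across blocks. Classes cut the
latent scale at 1.5, 2.5, 3.5, 4.5 (equal width — the verbal 1–5 scale
gives no generative model, so this is an artifact choice). These defaults
put roughly 20/38/31/10/1% of plots in classes 1–5, the skew typical of a
chlorosis nursery, and simulated "visual" ratings re-discretize the latent
value after adding rater noise (sd 0.3).

Canopy: per-plot coverage mean by class = 0.264, 0.246, 0.189, 0.096,
0.039; the realized canopy count is a binomial draw at that mean, rendered
as a union of random discs along the row axis (ragged edges exercise the
edge-pixel ambiguity) trimmed to the exact count. Canopy color classes are
multinomial per pixel from class mixes grading green-dominant (class 1:
85/12/3) to brown-dominant (class 5: 2/28/70); pixel RGB is Gaussian
(sd 10) around class centroids — green (60,140,50), yellow-green chlorotic
(175,200,60), necrotic brown (120,80,45) — and soil is Gaussian (sd 10)
around (155,110,85). The centroids were chosen once so that the
green/chlorotic canopy is index-separable from soil (the regime in which
unsupervised segmentation is reported to work at ~95%) while brown canopy
remains soil-like, preserving the real failure mode.

What it does not emulate: mosaicking seams, perspective, shadows, GPS
error, mixed border pixels, weeds, or inter-date growth. Passing tests
therefore demonstrate the pipeline's correctness and its behaviour under
controlled spectral overlap, not performance on real imagery — the
published field accuracies (68–77% for 5-class scoring) are not
reproducible without the original imagery and ratings.

One integer seed drives independent streams for scores and rendering;
identical config + seed gives bit-identical rasters, polygons and truth.

## Classifier benchmark

`idcpheno.benchmarks` draws (%G, %Y, %B) from class-conditional Dirichlet
distributions (means = the five color mixes, shared concentration 11,
+0.5 offset; equal priors), for which the Bayes-optimal rule and Bayes
accuracy are computable by Monte Carlo (~75%, the practical accuracy regime
for this task). Models are trained on n = 2000 and evaluated on an
independent draw of 2000; both the random forest and the network land
within a few points of the Bayes bound, and their errors concentrate almost
entirely (> 95%) in adjacent classes.

## Numerical and I/O choices

GeoTIFF georeferencing is read/written directly through the
ModelPixelScale, ModelTiepoint and GeoKeyDirectory tags (north-up only);
vectors travel as GeoJSON with required design attributes, validated for
unique plot ids. CRS identifiers are compared, never reprojected — a
mismatch is a hard error. File band order is assumed R,G,B with a
permutation flag. Degenerate inputs handled explicitly: R+G=0 pixels,
empty canopy, empty plots, single-class training data, saturated designs
(zero residual df), classes too small to sample — all raise or warn as
documented rather than propagating NaNs.

## Known limitations

- Brown/necrotic canopy is spectrally soil-like in the R−G index; stage 1
  systematically under-masks severe plots (coverage for classes 4–5 reads
  low). This mirrors field experience; a supervised masker would be needed
  to remove it.
- The hue recoding assumes daylight RGB; strong color casts would shift
  the fixed hue boundaries (they are configurable).
- The LSD analysis treats predicted 1–5 classes as numeric responses, and
  uses fixed effects only — no spatial correction or BLUPs.
- Scores are modelled as unordered categories; ordinal structure is used
  only in evaluation (adjacency, binning), not in fitting.
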