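# Methods

`nichecnn` implements weakly supervised spatial enrichment analysis for
segmented multiplexed-imaging data (CODEX, IMC and similar): given a per-cell
table of marker intensities, coordinates, cell-type annotations and a
sample-level phenotype, it learns which cell subsets — defined by molecular
profile, not by the annotated types — are enriched in spatial neighborhoods
associated with the phenotype.

## The model

A *multi-cell input* is the unordered set of marker vectors of the k nearest
cells (Euclidean distance, within one image) around an anchor, carrying one
label. Anchors come in three regimes: random cells per image labeled by
condition (**global**), every cell of a chosen anchor type labeled by
condition plus background neighborhoods labeled `BG` (**local**), and typed
anchors labeled by the neighborhood mean of a chosen functional marker, which
is removed from the features (**functional**, a regression).

The network is a single convolutional layer of F filters — per-cell affine
maps `a_fc = relu(w_f·x_c + b_f)` — followed by pooling across the cells of
an input (mean by default; max available) and a softmax or linear head.
Pooling makes the output invariant to the order of cells in an input. Two
implementation details guarantee that invariance *bitwise*, not just to
rounding: input rows are brought to a canonical lexicographic order before
the forward pass (BLAS accumulation order depends on row position), and mean
pooling sums each filter's activations in sorted order.

Training is mini-batch Adam (batch 64, at most 50 epochs, early stopping on
validation loss with patience 5) under a random hyperparameter search
(default 200 trials; scaled down in the bundled studies): filter count
1–8, learning rate log-uniform on [1e-3, 3e-2], dropout on the pooled layer
in {0, 0.25, 0.5}, and an L1 penalty on the filter weights in {0, 1e-4,
1e-3}. The lower learning-rate bound reflects the epoch budget — smaller
rates simply do not converge on nets this small — and the L1 choice follows
the regularization practice of the set-based single-cell models this
architecture descends from; sparse filters are also far easier to read as
marker signatures. Trials whose loss turns non-finite are dropped from model
selection. The model with the highest validation score (accuracy, or R² for
regression) wins; the held-out test score is computed once, for that model
only. In regression mode the filter count is fixed at two, so a
high-responding and a low-responding filter can be analyzed separately.

## Selection, frequencies, and inference

The *filter response* of a cell is the bare scalar product `w_f·x` (no bias,
no ReLU); cells with response above 0 are *selected*. Each filter is
attributed to the label class for which its output-head weight is largest
(sign of the head weight in regression). This matters because the selection
statistic is sign-symmetric: a filter that marks cells *depleted* in one
condition is the same classifier evidence as one marking cells enriched in
the other, and the head weights record which way the model actually uses it.
The pipeline reports, per k, the overall most significant filter and the best
filter per condition.

Per patient, the relative frequency of selected cells among the member-cell
occurrences of that patient's inputs is compared across conditions with a
two-sided Wilcoxon rank-sum test (exact when both groups are tie-free with
at most 25 samples, normal approximation otherwise). Two scopes are
computed:

* the **validation scope** drives the choice of k (global rule: smallest
  condition-vs-condition p; local rule: among k with condition p < 0.05, the
  smallest winning-condition-vs-background p; ties prefer smaller k) and the
  choice of reporting filter;
* the **held-out scope**, restricted to samples never seen in training, is
  the pipeline's headline inference. Frequencies of training samples are
  selection-biased — a trained filter can order the training samples' means
  even when the condition labels carry no information — so a rank-sum test
  on them is not level-α. On held-out samples the exact test is exactly
  calibrated by exchangeability; the null-calibration study (below) checks
  this end to end.

## Enrichment scores and marker shifts

Counts are taken per image with the neighborhood defined as the union of the
member cells of that image's anchor inputs (background inputs excluded).
With N cells in the image, N_T of type T, K in the neighborhood, and the
superscript S marking selected cells, the local score is
`ES_T = (K_T^S / E_T^S) / (K_T / E_T)` with expectations
`E_T^S = K^S·N_T^S/N^S` and `E_T = K·N_T/N`; the global score is
`ES_T = N_T^S / (N^S·N_T/N)`. ES above 1 means selected type-T cells
concentrate in the anchor neighborhood beyond what type abundance and
overall selection rates predict. A zero denominator makes the score
undefined for that image and type; undefined values are excluded from
aggregation and counted, never imputed. Cohort values are medians with MAD
error bars: per sample the median over that sample's images, then the median
over samples, computed per condition group.

Marker shifts between selected and non-selected cells are scored with the
two-sample Kolmogorov–Smirnov statistic (an effect size in [0, 1]; no
p-value is attached), in an all-cells scope and per cell type, with a
10-cell minimum per group before a scope is scored. KS is invariant to
monotone rescaling, so the min-max normalization applied for reporting does
not affect it.

## The synthetic cohort generator

The generator emulates a two-condition imaging study at the level the method
consumes: samples × images × cells, uniform cell positions in a unit square,
types drawn from a catalog of frequencies and mean marker signatures (12
markers by default), isotropic Gaussian marker noise (sd 1), and a
shifted-softplus map to keep raw intensities nonnegative. Two spatial
structures are planted around the anchor type (granulocytes, 5 per 1000-cell
image by default):

* **niche composition, in every condition** — 40% of macrophages and 12% of
  the target T cells relocate to within radius 0.03 of a random anchor,
  forming dense inflammatory foci. The companion macrophages carry the
  niche's compositional signature; keeping the *target* type mostly outside
  the niche is deliberate, since a target type concentrated in neighborhoods
  couples the enrichment score to any type affinity in the learned filter
  and washes the ES contrast out.
* **the planted effect, in the affected condition only** — a fraction
  (default 0.8) of target cells within the radius of an anchor receive an
  additive shift (default +3 sd on PD1). `ground_truth_mask` exposes exactly
  these cells.

In pipeline runs the local-mode background inputs are anchored at uniform
random *positions* rather than random cells: background neighborhoods then
sample generic tissue context instead of following the cell-density
distribution into the niches, which is what the BG class is meant to
control for. (Cell-anchored background remains available and is the
constructor default.)

What the generator does not emulate: tissue architecture beyond the planted
foci, marker spillover, segmentation errors, zero-inflated or heavy-tailed
intensity noise, and batch effects. Passing the bundled studies therefore
shows the machinery recovers planted structure under its own assumptions,
not that it is robust to real acquisition artifacts.

## Bundled studies and their sizes

* **Planted recovery** (`benchmarks.planted_recovery_study`): 12 samples per
  condition (6 held out per group — enough for the held-out rank-sum to
  reach p < 0.01), 6 images per sample, 1000 cells per image, k = 20, 20
  search trials. Measures validation/test accuracy, the held-out frequency
  p, target-type ES in both conditions, recall of the planted cells, and the
  KS ranking of the shifted marker.
* **Null calibration** (`benchmarks.null_calibration_study`): 200 replicate
  cohorts at zero effect (6 samples per condition, 2 images of 100 cells),
  global mode with 20 anchors per image, k = 10, 2 trials, 4 held-out
  samples per condition. With 4-vs-4 samples the exact test rejects at
  α = 0.05 only on perfect separation, so the true null rejection rate is
  2/70 ≈ 2.9%; the study checks the realized rate stays at that level.
* **Power curve** (in the test suite): detection frequency over effect sizes
  {0, 1, 2, 3} sd, 50 replicates each, on a smaller cohort (7 samples per
  condition, 2 images of 400 cells, 5-vs-5 held out) — non-decreasing in
  effect size up to Monte-Carlo slack.

## Numerical and design notes

* Natural log with offset 1e-3 for the intensity transform; Z-scores use
  dataset-wide moments (population sd) as the default
  (`scaling_scope="train_only"` restricts moments to chosen samples).
  Constant marker columns are an error, not a silent drop.
* k-NN ties break by ascending cell id; the anchor is excluded from its own
  neighborhood (`include_anchor` flag available). Images smaller than k+1
  cells are skipped with a warning, not an error.
* The train/validation split is input-level within the non-held-out samples
  (fraction 0.2); the test split is patient-level, so no patient leaks.
* Classification accuracy is input-level (no patient-level majority vote).
* Frequencies use member-cell occurrences within a patient's inputs as the
  denominator; a cell appearing in several inputs counts each time.
* No multiple-testing correction is applied across k values or filters; the
  k-selection rule is a model-selection heuristic, and the held-out p-value
  reported for the chosen configuration should be read accordingly.
* Sample sizes in the bundled studies are fixed, documented choices made for
  statistical resolution (e.g., held-out group sizes set by the attainable
  exact p-values); they are deliberately smaller than a real cohort.

## Known limitations

The method inherits the greedy character of model fitting: subsets weakly
but genuinely associated with the phenotype may be shadowed by a stronger
signal. Validation-scope p-values steer model and k selection only; they are
optimistically biased and must not be quoted as inference. ES is descriptive
(median ± MAD), with no permutation null attached. The NumPy trainer is
deliberately small-scale — single layer, CPU, full-batch-scale data — and is
not meant for millions of inputs.
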