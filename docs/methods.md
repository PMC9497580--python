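# Methods

This note records the models and procedures the package implements, the
parameters that matter, what the synthetic data does and does not emulate,
and the numerical and design choices made where the design was open.

## Preprocessing

Raw images are 2-D nonnegative intensity grids. The canonical chain is
**clip → scale → resize/stack → standardize**:

1. `clip_quantile(img, q=0.9995)` caps intensities at the empirical
   q-quantile (linear interpolation between order statistics, the common
   quantile convention). The intent is removal of tiny saturated landmark
   clusters: a cluster occupying ≤ 0.02% of pixels lies entirely above the
   0.9995 quantile and is flattened to the anatomical range, so min–max
   scaling afterwards preserves the useful dynamic range.
2. `scale_unit` maps min→0, max→1 affinely; a constant image maps to zeros
   (logged).
3. `resize_and_stack(side=224)` resizes bilinearly and replicates the
   gray channel three times, producing the 3×side×side tensor that
   channel-pretrained classifiers expect. An optional `crop` fraction takes
   a central crop first, a configurable stand-in for dedicated
   chest-region extraction, which is out of scope.
4. `standardize` subtracts/divides per-channel constants; the well-known
   ImageNet mean/SD are the defaults, while the synthetic fixture networks
   use (0.5, 0.25).

Numerical notes. Clipping at an interpolated quantile is idempotent only up
to the position of the threshold among the top ~0.05% order statistics;
re-clipping perturbs at most those already-clipped pixels by a
sub-threshold amount. Exact idempotence would require a discrete quantile
convention, which we did not adopt because the interpolated threshold is
the standard default.

`preprocess_batch` additionally accepts a **fixed intensity window**
(`intensity_range=(lo, hi)`) instead of per-image min–max scaling. This
matters for the localization benchmarks: with per-image scaling, the
brightest structure in the image sets the scale, so *every background
pixel's value encodes whether a bright signature is present anywhere* — a
global label leak. A classifier trained on such inputs learns this
shortcut (we observed exactly this: near-perfect AUC with saliency mass
placed on the background), which is a synthetic instance of the
"Clever Hans" effect the explainability pipeline exists to expose. The
blob benchmark and the end-to-end experiment therefore use a fixed window
so that label evidence stays local and localization claims are meaningful.

## Transfer strategies

*Label mapping.* Each target label owns a nonempty set of source-label
indices; the mapped score is the maximum source probability over the set.
The max is monotone: raising a source probability never lowers a target
score. The canonical chest-radiograph correspondence (e.g. cardiac ←
{enlarged cardiomediastinum, cardiomegaly}; lung ← six opacity-type
findings) ships as `CHEXPERT_TO_TARGET`.

*Stacking.* One random-forest metaclassifier per target label, trained on
the flattened K×L_t matrix of mapped base outputs (cross-label signals
help; a per-label-features mode restricts to the K columns of the label at
hand). Data are split 70/30 train/test. The forest defaults to the tuned
configuration (depth 10, min leaf 4, min split 10, gini, 100 trees); a
full grid search can be requested via a `TreeGridConfig` but is not the
default, because at desk scale the tuned configuration is
indistinguishable in accuracy and orders of magnitude cheaper.

*Embeddings + trees.* The embedding is the GAP vector: the channel-wise
spatial mean of the final convolutional maps (asserted equal to a
brute-force mean in the tests). Tree kinds are DT, RF and XRT, with
exhaustive grids (depth {1,2,3,4,5,10,20}, min leaf {1,2,4}, min split
{2,5,10}, criterion {gini, entropy}, and 10–300 trees for the forests).
Grid search evaluates every cell by stratified K-fold CV (default K=5;
folds are capped by the minority-class count per label), scores a cell by
mean fold AUC averaged across labels, breaks ties by a fixed lexicographic
order of parameter names *and values* (so the listing order of the grid
cannot change the selection), and refits the winner on the full training
split, one binary model per label. Labels with a single observed class are
skipped with a warning. The selection criterion and the per-label model
structure are our choices; per-label AUC reporting and label-wise class
imbalance motivate both.

*Fine-tuning.* The dense head is replaced by a fresh one sized to the
target labels and the whole network is retrained for 5 epochs, Adam,
binary cross-entropy, lr 1e-4 divided by ten after each epoch, early
stopping with patience 3 on validation mean AUC, best-epoch weights
restored. Two initialization details make this short protocol effective:

- the new head's weights are randomly initialized at small scale
  (sd 1e-4 by default): with ~100–200 Adam steps at lr ≤ 1e-4 the head
  moves only O(5e-3) from its start, so an O(0.1) random initialization
  would drown the learned signal in init noise;
- the head bias starts at the logit of each label's training prevalence
  (prior initialization, standard for detection heads). Without it the
  early gradient is dominated by the common-mode term that the bias should
  absorb: since GAP features are nonnegative, every head weight is pushed
  down together and scores become *anti*-correlated with total activation
  — we observed systematically inverted AUCs (~0.2) before adopting it.

Batch size (4) and the optimizer (Adam) are declared defaults; the
protocol's epoch count, patience, loss and learning-rate schedule are
fixed by the study design being implemented.

## Ensembling

`simple_average` is the arithmetic mean over classifiers. The
entropy-weighted combination is implemented literally,
ỹ_i = Σ_k (1 − H(p_{k,i})) p_{k,i} with base-2 binary entropy and the
0·log 0 = 0 convention. As written it is unnormalized — the weights need
not sum to one, so outputs live in [0, K]; that is harmless for AUC, which
only ranks. A normalized mode divides by Σ_k (1 − H) and falls back to the
simple average for labels where every classifier sits at p = 0.5. Both
modes ship because reported AUCs cannot distinguish them.

**Known limitation.** The literal map p ↦ (1 − H(p))·p is *non-monotone*
on (≈0.16, 0.5): it decreases toward zero as p → 0.5. A pool of diffident
classifiers whose probabilities all lie below 0.5 (e.g. briefly fine-tuned
heads on low-prevalence labels) is therefore ranked *in reverse*, which
surfaces in the end-to-end report as an entropy-ensemble AUC near
1 − AUC(simple). This is a property of the formula, not a bug; it is
invisible when classifiers are confident, and the normalized mode
mitigates but does not remove it.

## Evaluation

AUC is the trapezoidal area under the ROC curve with midrank tie handling,
which makes it exactly the Mann–Whitney concordance probability (ties
counted ½); the test suite asserts equality against an O(n²) pairwise
oracle. Labels with one observed class have undefined AUC, are reported as
missing, and are excluded from the unweighted mean over labels.

## Explainability

Grad-CAM: channel weights α_c = spatial mean of ∂(class logit)/∂A_c over
the final conv maps A_c; map = ReLU(Σ_c α_c A_c), bilinearly upsampled to
the image and min–max normalized. The gradient of the *logit* is used; a
sigmoid factor would rescale the map by a positive constant and cancel in
normalization. With a GAP head the gradient is the dense weight spread
uniformly over positions, so Grad-CAM equals CAM up to normalization —
asserted to 1e-5 across random initializations.

Averaging (across the K models for one image, or across a population of
images for one model) min–max normalizes each map first — different
networks have incomparable gradient scales — then takes the pixelwise mean
and renormalizes; a constant result is flagged degenerate. Saliency masks
keep pixels *strictly above* the map's 0.8 quantile ("larger than"
verbatim); on a distinct-valued map that is (1−q) of pixels to within one
pixel. Bounding boxes are the tightest axis-aligned cover of the mask, or
one box per 8-connected component. Agreement is |pred ∧ expert| / |expert|
computed on the quantile mask (the metric is defined on areas); a
box-based variant is available behind `use_box=True`. Empty expert masks
are undefined and reported missing.

## Synthetic data: what it emulates, and what it does not

The image generator draws a background level (default 400 intensity units,
Gaussian noise sd 30, clipped at zero), then for each label independently
with its prevalence draws a geometric signature — disc, bar, or half-ring
arc, default radius ≈ side/12 pixels, intensity lift +250 — in a
label-specific region (by default disjoint cells of a 3×3 grid, so
per-label localization is identifiable; overlap is opt-in). The truth mask
records exactly the signature pixels, so a label is positive iff its mask
is nonempty. With probability 0.1 an image receives a 2-pixel saturated
landmark cluster at 12× its 99th-percentile intensity — the artifact the
0.9995-quantile clip is designed to remove. The default label list and
prevalences follow a seven-finding hospital cohort (4%–45%).

The default end-to-end experiment uses five source labels mapping onto
three target labels (pleura and cardiac each union two sources, lung one),
240 images per collection at side 64, and three fixture networks of widths
(6,12), (8,16), (10,20); the target collection is drawn with background
+60 and noise ×1.4 to emulate a scanner/site shift. These sizes are chosen
so a full comparison runs in well under a minute on one CPU; the tree
stage consequently defaults to a reduced grid (depth {3,10}, 50 trees),
with the full grids available through `TreeGridConfig`.

Prediction matrices use a two-Gaussian latent model (positives shifted by
the skill parameter) passed through its exact posterior (calibrated mode),
a temperature-sharpened posterior (overconfident), or label-independent
noise near 0.5 (uninformative). Embedding matrices shift label-informative
dimensions by a configurable effect size. One global seed fans out to all
generators through fixed offsets, and every generator is byte-identical
under a fixed seed.

What passing tests do **not** show about real radiographs: the signatures
are high-contrast, rigid and disjoint, with no anatomy, no inter-label
correlation, no label noise, and no reader variability; domain shift is a
global brightness/noise change, not a population or protocol change. The
benchmarks validate the *machinery* — formulas, training dynamics,
localization plumbing — not clinical performance.

## Fixture networks

`FixtureCNN` is a NumPy implementation of the smallest architecture with
the contract the pipeline needs: 3×3 same-padding convolutions with ReLU
and 2×2 average pooling (2–3 blocks), global average pooling, and a dense
sigmoid head; Adam, binary cross-entropy, exact backpropagation (verified
against finite differences), float32 throughout. Side-64 inputs train at
roughly one second per epoch per network on one CPU. The final conv maps,
GAP embedding, per-label probabilities and analytic gradients of any logit
w.r.t. the final maps are all exposed, which is what the embedding,
fine-tuning and Grad-CAM stages consume.

## Reproducibility

All randomness flows from explicit integer seeds fanned out by fixed
offsets (`child_seed`); two runs of the full pipeline with the same seed
write byte-identical prediction CSVs (asserted in the tests). Reports
carry the config hash, seeds, split sizes and per-stage timings.
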