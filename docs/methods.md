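# Methods

`ibdmil` implements a weakly supervised pipeline for grading
inflammatory bowel disease (IBD) activity from whole-slide images of
H&E-stained biopsies, scored on the Nancy Histological Index (NHI,
grades 0–4). Only the slide-level grade supervises learning; no
region-level annotation is required. This note documents the models,
the parameters that matter, the synthetic data the tests run on, and
the numerical choices made where the design was open.

## Pipeline model

**Tiling and QC.** Tissue is detected on a block-averaged low-resolution
view (default 8×) by grayscale thresholding (tissue is darker than the
white scanner background; default threshold 220/255). A regular grid of
1520-px tiles is laid over the foreground at working resolution; the
tiler operates at whatever resolution it is handed, and bringing a
pyramidal scan to the intended magnification (20×) is the caller's
responsibility. Tiles with less than 5% tissue are removed, as are
tiles failing optical quality bounds on mean brightness, mean HSV
saturation/hue and Laplacian variance (a sharpness proxy). The 5%
tissue rule is a published cut-off; the optical bounds are package
defaults (brightness 10–235, saturation ≥ 0.01, Laplacian variance
≥ 2 on the 0–255 scale) because published pipelines tune them per
dataset. Checks run in a fixed order (tissue, brightness, saturation,
hue, sharpness) and a rejected tile records the first failure as its
single primary reason. Partial edge tiles are dropped, not padded.

**Annotation bundles.** An external multitask segmenter (run out of
band) supplies per-tile label maps: nucleus instance/type/boundary,
gland instance/type, lumen instance and tissue type, all co-registered
with the tile pixels. The package defines the data model, validation
(shape congruence, vocabulary closure, typed-pixel/instance
consistency) and a portable HDF5 container with a fixed dataset layout;
maps may be individually absent, and absence is explicit metadata. The
segmenter itself is a pluggable adapter; a deterministic rule-based
mock ships so the full pipeline runs offline, and requesting an
unconfigured real segmenter raises rather than silently falling back.

**Quantitative histology statistics.** Per tile: nuclei are counted per
unique instance id, typed by the majority type code over the
instance's pixels, and assigned to the tissue class under their
centroid pixel (background centroids are excluded from
cross-tabulations); glands are counted per unique instance with a
circularity 4πA/P² each, clamped to (0, 1]; tissue area is the pixel
count per class; surface epithelium is read from the gland-type map.
Slide-level features are sums over tiles normalized by the slide's
non-background tissue area, so tiling identical content k× changes
nothing. The epithelial-to-stromal nuclear ratio divides nuclei with
epithelial-class centroids by nuclei with stromal centroids and is
flagged undefined (never NaN-propagated) when the denominator is zero.
Mean gland circularity is the unweighted mean over glands; an
area-weighted mean was the alternative, but per-gland equal weighting
keeps the feature sensitive to the small distorted glands that matter
clinically. These features feed a gradient-boosting baseline
(scikit-learn) under patient-grouped stratified 5-fold CV with an
inner grid search (trees × depth × learning rate; the grid is config).

**Perimeter estimation.** Counting boundary pixel edges overestimates a
disc's perimeter by ~5% (staircase bias), which would systematically
depress circularity. The perimeter is instead measured as the
marching-squares contour length of the 0.5 level set of the lightly
Gaussian-smoothed mask (σ = 1 px): accurate to ~1% for discs of radius
≥ 10 px and within ~3% of the continuum π/4 value for large squares.
Shapes of a few pixels with no measurable level set are treated as
compact (circularity 1).

**Region filtering.** A tile enters the MIL stage iff (a) stroma plus
normal epithelium — the baseline reference tissue — cover at least
τ_ref = 10% of all tile pixels (background included in the
denominator; the two classes are summed, not required individually),
and (b) at least one pixel of an IBD-relevant class (abnormal
epithelium, inflammatory tissue, debris) is present. Kept tiles are
center-cropped 1520 → 1250 px (both sizes config) and subdivided into
25 non-overlapping 250-px patches; patches with ≥ 60% background
(tissue-map code 0 when a bundle exists, brightness otherwise) are
excluded. Boundary semantics follow the rules' wording: exactly 10%
reference keeps, exactly 60% background excludes. The retention rule
runs at tile level before subdivision, the background rule per patch.

**Embeddings.** Patch embeddings come from a frozen external encoder
(histology foundation models emit 1024-D or 2560-D vectors; the
dimension is config, as is the patch resize each encoder expects).
Embeddings persist in one HDF5 file per slide keyed by patient id and
deterministic patch base name, so bags load in one read and
patient-level splits provably induce disjoint embedding sets. The
shipped mock encoder — a seeded Gaussian random projection of the
16×16 downsampled patch — is synthetic plumbing that keeps the
pipeline executable offline; it carries no histological meaning.

## The MIL classifier

Each slide is a bag of patch embeddings. The network is:

1. *Instance encoder*: two fully connected layers with ReLU and
   dropout (rate 0.3), then layer normalization, projecting to 256
   dimensions (the interleaving order linear–ReLU–dropout ×2 →
   layer-norm is this package's fixed choice).
2. *Gated attention pooling*: per-instance score
   s_k = wᵀ(tanh(V h_k) ⊙ σ(U h_k)) with attention hidden width 128
   (config), softmax-normalized over the real instances of each bag;
   zero-padded slots carry mask 0 and receive attention weight exactly
   0. The bag vector is the attention-weighted sum, making the model
   permutation-invariant over instances.
3. *Classifier*: one linear layer to K logits (K = 2, 3 or 5 per the
   grouping scheme).

Training minimizes focal loss, −w_y (1−p_y)^γ log p_y with γ = 2
(config; γ = 0 recovers weighted cross-entropy exactly), with class
weights recomputed each epoch from that epoch's training label counts
as inverse frequencies normalized to mean 1 (smoothing ε = 1 keeps
empty classes finite). Bags are zero-padded per mini-batch with a
1/0 mask, shuffled each epoch and sorted by length within shuffle
buckets to bound padding waste. The optimizer is Adam (default
lr 1e-5, suited to cohort-scale data; the desk-scale experiments in
this repository use 1e-3). Validation macro F1 is monitored each
epoch; training stops after a patience of epochs without improvement
and the best checkpoint is restored, with ties resolved to the later
(more-trained) epoch. An optional L2 penalty on weight matrices
(`weight_decay`, default 0) widens the decision margin on small
cohorts; the synthetic experiments use 3e-3. The whole network is
plain NumPy with hand-derived backpropagation — at this size an
autodiff framework buys nothing — and the analytic gradients are
checked against central finite differences in the test suite. All
randomness (initialization, shuffling, dropout) flows through one
seeded generator, so training is bit-reproducible single-threaded.

**NHI groupings.** `five_class` is the identity; `type_A` (conventional)
maps 0–1 / 2 / 3–4 to No Active / Mild Active / Severe Active Colitis;
`type_B` (remission-separating) maps 0 / 1–2 / 3–4; `binary` maps
NHI < 2 vs ≥ 2. Patient-level labels take the maximum grade over the
patient's biopsy sites. Splits are stratified by that maximum and
allocated per stratum by seeded shuffling with largest-remainder
apportionment, so no patient ever straddles subsets; strata with fewer
than three patients warn and default to training.

**Ablation harness.** Four conditions wire the filtered and unfiltered
patch streams into training and evaluation: A = filtered throughout,
B = filtered training only, C = filtered evaluation only, D = fully
unfiltered. Each condition trains and evaluates end to end and tags
its report.

**Evaluation.** Accuracy, macro/weighted F1 (0/0 defined as 0),
per-class F1, per-class one-vs-rest AUC (midrank tie convention; a
class absent from the truth yields an undefined AUC, excluded from
averaging with a warning) and the confusion matrix with truth on rows.
Attention maps paint each kept patch's footprint with its weight into
a downscaled slide raster; cells outside kept patches are NaN, and the
raw raster (not its colormapped rendering) is the tested artifact.

## Synthetic data: what it emulates, what it does not

The cohorts this method targets are private, so the package generates
every input kind with exact ground truth:

* **Bundles** fill exact per-class pixel quotas (areas are exact by
  construction), place non-overlapping parametric glands
  (disc/square/ellipse, with analytic circularities for the ledger)
  and 3×3 nuclei whose centroid provably lies on the requested tissue
  class. Ledgers record the exact counts/areas the statistics module
  must reproduce.
* **Slide images** are noisy tissue-colored blobs on a white
  background with controllable blur and brightness, plus the exact
  foreground mask.
* **Bags** follow the standard MIL assumption that a minority of
  instances determines the label: background instances are standard
  normal in 32 dimensions (config), and each non-null class plants
  signal instances at rate 0.1 shifted by a separation of 6.0 along a
  class-specific axis (at this separation the background maximum over
  a cohort essentially never reaches the signal range, making the
  classes cleanly separable — the regime the recovery tests are
  defined in). Fixture classes carry NHI grades 0/2/3 so every
  grouping scheme keeps them distinct. Optional pure-noise instances
  (zero-mean, σ = 6) emulate uninformative patches that region
  filtering would remove; the ablation fixtures use noise rate 0.35,
  separation 3.0 and 40 bags per class.

Passing tests on these fixtures shows the machinery is correct —
counting is exact, rules fire at their boundaries, attention finds
planted instances, filtering noise helps — but says nothing about real
histology: the generators model neither tissue appearance, nor stain
variation, nor the label noise of intermediate NHI grades that
dominates errors on clinical cohorts.

## Problem sizes and numerical choices

The repository's experiments are sized for a single CPU: the recovery
experiment uses 201 bags (67 per class, 30–60 instances, dim 32) with
a 60/20/20 patient-level split, and the ablation 120 bags. Layer norm
uses ε = 1e-5; the masked softmax subtracts the per-bag maximum before
exponentiation; focal-loss gradients guard the (1−p)^(γ−1) term at
p → 1; Adam uses β = (0.9, 0.999), ε = 1e-8. Attention weights at
padded slots are exact zeros (excluded before normalization, not
masked after). HDF5 round-trips are bit-exact for integer maps and
float32 embeddings.

## Known limitations

* No pyramidal WSI reader: the tiler consumes plain rasters
  (TIFF/PNG/NPY) at the resolution given.
* The mock segmenter and mock encoder are deterministic plumbing, not
  models; real deployments plug adapters into the documented
  contracts.
* The gradient-boosting grid is small by design; exhaustive tuning is
  out of scope.
* Single-threaded determinism is the tested contract; multi-threaded
  BLAS may reorder reductions and perturb results in the last bits.
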