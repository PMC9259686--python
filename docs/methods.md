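# Methods

## Problem setting

Brightfield microscopy images routinely contain artifacts — dust, fibers,
cell debris, contamination — that corrupt downstream quantification.
Pixel-level annotation of artifacts is expensive; image-level labels
("clean" / "contains an artifact") are roughly two orders of magnitude
cheaper to produce. This package implements a weakly supervised
segmentation pipeline that converts image-level labels into pixel-level
artifact masks, together with the evaluation metrics, a clean-image
synthesis procedure, and two downstream impact analyses (nuclei
segmentation scoring and Hill-equation ligand-affinity estimation).

## The weakly supervised pipeline

**Training.** A residual CNN classifier is trained on image-level labels
(Adam, cross-entropy, initial learning rate 0.002 divided by 10 whenever
validation loss fails to improve for 10 consecutive epochs; the weights
with the best validation loss are kept). ScoreCAM then localises the
evidence for the artifact class:

1. the activation maps `A_k` of the last convolutional layer are extracted;
2. each map is bilinearly upscaled to the input size and min-max
   normalised to [0, 1] (a constant map normalises to all zeros — it
   carries no localisation signal);
3. each normalised map multiplies a copy of the (per-image min-max
   normalised) input, and every projected input is scored by the
   classifier; the artifact-class softmax probability is the map weight
   `w_k`;
4. the saliency map is `minmax(ReLU(Σ_k w_k Â_k))`.

Saliency maps of artifact-labelled training images are binarised
(strictly greater-than) into pseudo-label masks; clean-labelled images
contribute all-zero masks. The binarisation threshold is chosen on the
validation split by maximising mean per-image pixel IoU over a fixed grid
spanning (0.01 … 0.9); when no pixel-level validation masks exist, the
default threshold 0.05 is used. A U-Net is then trained on the
pseudo-labels with pixel-wise binary cross-entropy under the same
optimiser contract.

**Inference.** Classify-then-segment: the classifier gates each image
(artifact probability > 0.5); gated-out images receive an empty mask
without running the segmenter. The U-Net probability map of flagged
images is binarised at a model-specific cutoff and connected components
with strictly fewer than `min_object_size` pixels are removed
(8-connectivity). The reference operating cutoffs (0.001 for ScoreCAM and
ScoreCAM-U-Net, 0.45 for a strongly supervised U-Net) and minimum object
sizes (1000 / 500 / 500 pixels for the three source datasets) are exposed
as presets; on any new dataset — including the synthetic benchmark — the
cutoff is re-selected on validation IoU exactly as such operating points are
obtained in practice, and the small-object threshold is scaled to the
image area (30 px at 96×96, mirroring 500 px at ~1 Mpx).

**Ambiguities resolved.** The phrase "class-largest probability" in the
ScoreCAM weighting step is read as the *target (artifact) class*
probability of each projected input: pseudo-labels must localise the
artifact class specifically. The 0.05 pseudo-label threshold and the
0.001 evaluation cutoff are kept in their distinct roles. Clean training
images are included in U-Net training (with empty masks); they anchor the
background class.

## Network architectures

No GPU framework is assumed: both networks run on a compact NumPy engine
(im2col convolutions, Adam, the plateau schedule above) written for this
package. Training is exactly reproducible given a seed.

* **U-Net (full preset):** encoder of 15 convolutional layers (3×3, ReLU,
  64 filters) with 2×2 max-pooling and a skip connection after every third
  layer; a 3-layer bottleneck; a symmetric decoder of 15 layers with ×2
  nearest-neighbour upsampling after every third layer; skip connections
  merge by channel concatenation; a 1×1 sigmoid head yields per-pixel
  probabilities. Inputs must be divisible by 32; other sizes are
  reflect-padded and predictions cropped back.
* **U-Net (small preset):** the same every-third-layer motif at test
  scale — 6 + 2 + 6 convolutional layers, 16 filters, 2 pooling stages
  (divisor 4).
* **Classifier:** a stem convolution plus residual blocks
  (conv–ReLU–conv with projected identity) in 2 stages of 16 filters
  (small preset) or 3 stages up to 256 filters (full preset), global
  average pooling and a 2-way softmax head. ScoreCAM reads the activation
  maps of the final residual block before the last pooling stage, i.e. at
  1/4 (small) of the input resolution.

Unstated architectural details (skip merge operation, padding mode,
normalisation layers) follow common U-Net practice: concatenation, zero
padding, no batch normalisation.

## Clean-image synthesis

The background of a field is modelled as a two-dimensional second-order
polynomial `b(x, y) = c0 + c1x + c2y + c3x² + c4xy + c5y²` fitted by
least squares with pixel coordinates normalised to [−1, 1] per axis (raw
indices in the thousands make the normal equations ill-conditioned).
Artifact pixels are excluded from the fit — exclusion provably reduces
bias from bright or dark foreign objects. A zero-centred noise profile is
the set of mean-centred residuals at background pixels (non-artifact;
also non-nucleus when a nuclei mask is available). Inpainting replaces
each artifact pixel by the fitted background plus a draw *with
replacement* from the empirical residual pool — resampling preserves
non-Gaussian noise tails that a fitted Gaussian would discard. Pixels
outside the mask are never modified, and the procedure is deterministic
given a seed.

The round-trip guarantee is stated against the noiseless artifact-free
render: inpainted pixels carry fresh noise draws, so comparing against a
*noisy* render would compound two independent noise realisations (√2 σ)
and no 3σ bound could hold at the 99% level by construction.

## Evaluation metrics

Pixel-wise precision, recall, F1 and IoU from confusion counts; F1 is
computed as `2tp / (2tp + fp + fn)` so it is defined whenever any
positive exists on either side. Metrics with zero denominators are
reported as *undefined* (`None`), never silently as 0, and per-image
aggregation skips undefined entries — otherwise clean images (no
positives to find) would deflate dataset averages. Image-level F1 treats
"artifact" as the positive class. Object-wise F1 extracts connected
components (8-connectivity) from both masks, matches them one-to-one
greedily by descending pairwise IoU, and counts a match as a true
positive iff its IoU ≥ 0.5 (threshold configurable). Precision-recall
curves pool pixels across all images; the area is trapezoidal over
recall with an anchor at recall 0. Both per-image-averaged and
pooled-pixel aggregation are available; per-image averaging is the
default.

## Downstream analyses

**Stratified nuclei scoring.** Pixel metrics are computed over region
pixels only (inside artifacts / outside artifacts / all), so counts over
the two disjoint regions sum exactly to the whole-image counts. Objects
are assigned to a region by majority pixel overlap, ties inside. Empty
regions are flagged, not fabricated.

**Morphometry.** Per-object pixel area and solidity = area / rasterised
convex hull area. The hull is taken over pixel centres and rasterised by
centre-in-polygon; discrete hulls admit variants and this convention is
used consistently (it differs from conventions that use pixel corners,
which yield slightly larger hulls).

**Fluorescence quantification.** Per image, specific intensity = mean
over (cell ∧ ¬artifact) pixels − mean over (¬cell ∧ ¬artifact) pixels;
background is all non-cell pixels of the same image. Per well, the
per-image values are averaged. Wells with no usable cell pixels are
flagged rather than imputed.

When predicted masks drive pixel *exclusion*, the model is run at its
recall-favouring reference operating cutoff (0.001), not at the
IoU-optimal cutoff: a retained artifact pixel biases the intensity
means, while a wrongly discarded clean pixel merely costs a little
statistical efficiency. The IoU-optimal cutoff is the right operating
point only when the quantity of interest is segmentation overlap
itself.

**Hill regression.** `Y = Bottom + (Top − Bottom)/(1 + 10^(X − LogIC50))`
with `X = log10(concentration)` and the Hill slope fixed at −1, fitted by
bounded Levenberg-Marquardt least squares. Initialisation: Top/Bottom
from the response extremes, LogIC50 from the concentration whose response
is nearest the midpoint. The SD of LogIC50 is the asymptotic standard
error from the parameter covariance at the optimum (the reference
analysis used a commercial tool whose internal SD estimator is not
public; the asymptotic estimator is labelled as such). R² = 1 −
SS_res/SS_tot. Removal strategies are compared by per-curve |ΔLogIC50|,
paired R², and the Pearson correlation of well specific intensities.

## Synthetic data generator

The generator emulates the study conditions every test runs under:

* a smooth illumination surface (the same polynomial family the cleaner
  fits, default mean level ≈ 30 000 on a 16-bit-like scale, stored as
  floating point and quantised to 16 bits only on export);
* nuclei as smoothed disks ~12% darker than the local background
  (radius 3–6 px at 96×96), so a simple intensity-threshold segmenter can
  stand in for a trained nuclei model in downstream tests;
* heterogeneous artifacts — ellipses with a dark core plus bounded
  speckle, random-walk fibers dilated to 2–5 px width, and clumps of
  overlapping disks — at 25–45% contrast relative to the background
  level, so every artifact pixel deviates by at least half the configured
  contrast;
* Gaussian sensor noise (default sd 300 ≈ 1% of the background level);
* concentration-response plates: 9 half-log-spaced concentrations
  (10⁻¹⁰–10⁻⁴ M), duplicate wells per concentration, a fluorescence
  channel equal to a constant background plus the Hill response on cell
  pixels, and — on a configurable fraction of images — artifacts that add
  a strong positive fluorescence offset (debris autofluorescence), which
  is what biases affinity estimates when artifacts are not removed.

Randomness is structured so the artifact-free render of a field is
bit-identical to the artifactual one outside the artifact mask (nuclei,
noise, and each artifact draw from independent child streams of the field
seed); all outputs are bit-reproducible given a seed. Labels follow the
rule that a single artifact pixel makes an image "artifact". Dataset
splits are stratified by label with largest-remainder apportionment so
split sizes are exact.

What the generator does **not** emulate: optics (no point-spread
function, no defocus), real artifact texture statistics (unknown beyond
size/coverage summaries; appearance here is a documented free choice, not
a fit), cell-body morphology beyond dilated nuclei, plate-position
effects, or the specific cell lines of real screens. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that
weak supervision can localise discriminative artifact structure — not
that any particular accuracy transfers to real microscopes.

## Benchmark scale and numerical choices

The reference benchmark is 200 images at 96×96, 50% artifact prevalence,
small presets, 10 epochs per stage with batch size 8 (enough gradient
steps for the small classifier to converge), run entirely on one CPU.
At this scale the classifier reaches held-out image-level F1 ≈ 1.0, the
weakly supervised U-Net pixel IoU ≈ 0.55–0.72 after cutoff selection
(seed-dependent), and the strongly supervised reference ≈ 0.90–0.95,
reproducing the expected ordering between supervision regimes. Tie-breaks in threshold selection
go to the smallest threshold; binarisation is strictly greater-than;
max-pooling resolves ties by first index; all networks initialise with
He-normal weights from a seeded generator.

## Known limitations

* The NumPy engine is single-threaded and sized for the small presets;
  the full 33-layer U-Net builds and runs forward passes but training it
  at 1080×1080 scale is out of scope.
* ScoreCAM saliency is limited by the resolution of the last
  convolutional layer; very small artifacts (a few pixels) fall below
  what pseudo-labels can localise — consistent with the small-object
  removal step treating tiny components as noise.
* The asymptotic SD of LogIC50 underestimates uncertainty for poorly
  constrained fits (plateaus not reached within the concentration range).
* `compare_removal` assumes both strategies cover identical well sets;
  partially failed wells must be flagged upstream.
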