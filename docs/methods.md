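# Methods

This note documents the models, parameters and design choices behind
`ihcdetect`, and what the synthetic test bed does and does not show.

## The detection model

The pipeline estimates, for every pixel of an RGB tissue image, the
posterior probability that a positively stained (DAB-brown) immune cell
is centered there, and then reduces the resulting blob map to discrete
cell centers.

**Patch classifier.**  A 46×46 px window is large enough to contain a
lymphocyte nucleus (≈ 4–7 µm across at 0.228 µm/px) plus context.  The
default architecture maps the window through six 3×3 valid convolutions
with ReLU (32, 32, 64, 64, 128, 128 filters), 2×2/stride-2 max pools
after the 2nd and 4th convolution, a 256-wide fully connected layer and
a 2-way softmax; spatially 46 → 44 → 42 → 21 → 19 → 17 → 8 → 6 → 4.
Both fully connected layers are stored as convolution kernels (4×4 and
1×1), so the same forward pass evaluates single patches and whole
images.  Pixel intensities are scaled to [0, 1]; no other normalization
is applied.  Filter counts, kernel sizes and pool placement are
configurable (`CNNConfig`); the constraint checked at construction is
six convolutions, two pools, two fully connected layers, and a
receptive field that fits the 46-px input.

**Training.**  Softmax cross-entropy minimized by SGD with Nesterov
momentum in velocity form (`v ← µv − η∇; θ ← θ + µv − η∇`), learning
rate η = 0.01, momentum µ = 0.9, batch size 256, and a single pass over
the shuffled corpus by default — on the synthetic corpus the loss
plateaus well before the pass ends, and further passes do not improve
validation accuracy.  Initialization is He-normal from a seeded
generator.  Training, including the backward pass, is implemented on
numpy; convolutions are evaluated as kernel-offset shifted matrix
products, blocked to ≈ 60k rows per product, which keeps single-CPU
BLAS throughput high without im2col buffers.  Reproducibility is
promised per (platform, seed), not bitwise across platforms.

**Dense inference.**  The two stride-2 pools give the stacked network
an output stride of 4, so a stride-1 likelihood map is assembled by
shift-and-stitch: the network runs on the 16 (dy, dx) ∈ {0..3}²
croppings and the outputs interleave.  Valid-convolution arithmetic
makes each map value *identical* to classifying its window alone
(verified against a naive sliding-window oracle to 1e-4; in practice
agreement is ≈ 1e-13 in float64).  The 23-px border band, where no full
window fits, is zero.  Large images can be processed tile-wise
(halo ≥ 23 px guarantees tiling changes no value).  Inference defaults
to float64; a float32 fast path (≈ 2.3× faster, differs < 1e-6) is used
for the large-scale evaluation runs.

**Hard-negative mining.**  A first-round model reliably reaches
patch-level accuracy above 99 % yet still produces false detections on
images, because uniformly sampled negative windows rarely center a
confounder: windows centered on pigment clumps or erythrocytes are
essentially absent from the corpus, and the network has no incentive to
classify them correctly.  Mining runs dense inference on images known
to be free of positive cells, takes local maxima of the map above the
0.3 likelihood threshold (greedy non-maximum suppression within 9 px),
and cuts 46×46 negative patches there.  Two choices make one
retraining epoch sufficient: the mining images are generated
confounder-dense (so a couple hundred hard negatives are found), and
the mined patches are expanded with the standard augmentation set
(27×) before retraining so they are not drowned out by a 20,000-patch
corpus.  One such round removes pigment and erythrocyte false
positives completely in our measurements.

**Augmentation.**  Mirrors {identity, horizontal, vertical} × rotations
in 40° steps over the full circle (9 angles) — 27 output patches per
input, class balance preserved exactly.  Rotation by non-multiples of
90° uses bilinear interpolation with reflect padding and center crop,
avoiding black-corner artifacts that would leak label information; 0°
and multiples of 90° are exact.

**FRST detection.**  On the likelihood map, cells are bright,
approximately radially symmetric blobs.  For each pixel radius
n ∈ {1, …, ⌈4 µm / 0.228 µm⌉ = 18}: central-difference gradients are
computed; pixels whose gradient magnitude exceeds β·max(magnitude)
(β = 0.25; the relative reading makes β meaningful on probability maps
whose gradients are ≪ 1 — an absolute mode exists) each cast one vote
one radius ahead along the gradient direction (bright/positive votes
only: the blobs to find are maxima); the orientation count is clamped
at κ (8 for radius 1 px, 9.9 otherwise) and combined as
F = (Õ/κ)^α · (M/κ) with α = 0.5; F is smoothed with a Gaussian of
σ = n/4 and the responses averaged over radii.  Detection gates the
likelihood map at 0.3 *before* the transform, thresholds the response
at 0.1 × its maximum (scale-free; exposed as a parameter), labels
8-connected components, discards components below 2 px, and reports
each component's response-weighted centroid, ordered by (y, x).  Votes
landing outside the map are discarded; ties in vote targets resolve by
`rint` (banker's rounding), identically in the vectorized and reference
implementations.

**Matching and count statistics.**  Detections pair with ground-truth
centers by greedy nearest-first one-to-one matching within 4 µm (the
upper nucleus radius), deterministic with ties broken by
(distance, y, x).  Count agreement across raters uses the relative
difference to the cross-rater mean, diff = (mean − count)/mean, whose
per-image sum over raters is identically zero; the mean includes the
model by default (an observers-only mode exists because both
conventions appear in practice), over-counting raters get negative
differences (a sign flag flips this), and per-rater summaries report
mean, median and the linear-interpolation (type-7) 25th/75th
percentiles.  Both the signed mean and the mean absolute difference are
reported for the model, since the two are quoted interchangeably and
differ whenever the model is biased.

## The synthetic test bed

`synthetic_histology` renders what the classifier must learn to
separate: brown ellipses (cells) whose color interpolates from light
(201, 160, 108) to dark (92, 52, 18) brown with per-cell intensity in
[0.35, 1], aspect ratio ≤ 1.6, radius 1.8–3.5 µm; blue-purple unstained
nuclei; red-orange erythrocytes (rendered with G = B so they can never
satisfy the brown-chroma signature); near-black anthracotic pigment
clumps built from 3–6 grains with B ≥ R by construction and one grain
anchored at the ground-truth center; and faint low-chroma stain-trace
smears just below the positive intensity range, which exercise the
"sufficiently stained" decision boundary.  Flat shading plus a 0.6-px
edge blur and additive Gaussian noise (σ = 4 on the 8-bit scale) — not
an optical-density simulation.

Placement is rejection sampling (10,000 attempts per object, loud
failure rather than silent truncation): positive cells keep a pairwise
minimum separation of 8 µm — 60 cells at 10 µm on a 500×500 px tile
would exceed the random-sequential-adsorption jamming density —
confounders keep max(4 µm, half the cell separation) from cells and
4 µm among themselves.  Everything is bit-deterministic given the
config seed.

What passing tests on this bed shows: the numerical contracts hold
(dense ≡ per-window inference, FRST ≡ voting oracle, exact tiling), the
training loop learns, the mining round removes confounder-centered
false positives, and the geometry of detection (localization, counts,
matching) is correct.  What it does not show: performance on real
tissue — real slides add stain variability across laboratories,
focus/scanner artifacts, touching and clustered cells (explicitly out
of scope for the detector: the radius range and the component-based
splitting assume isolated nuclei), tissue texture, and annotation
noise.  Synthetic classes are more separable than real ones, so
patch-level accuracies near 100 % here say nothing quantitative about
real-slide accuracy.

## Problem sizes and runtime choices

The acceptance suite trains on 20,000 patches (one epoch per round) and
evaluates on twenty 500×500 px images with 40–60 cells each;
`scripts/acceptance.py` uses 8,000 + mined patches and eight evaluation
images.  These sizes were chosen so a full run completes in minutes on
a single CPU while keeping every stage of the method exercised at
realistic densities.  Dense inference in the large-scale runs uses the
float32 path; all oracle comparisons use the float64 default.

## Degenerate inputs and edge policies

Annotated centers closer than 23 px to a border are skipped with a
warning (padding would fabricate tissue).  Images smaller than 46 px
cannot be classified densely and raise.  A likelihood map entirely
below 0.3 yields no detections.  An all-zero map has no gradients,
hence an all-zero FRST response.  Count tables with a zero cross-rater
mean for some image exclude that image from the relative-difference
statistics with a warning rather than dividing by zero.  Confusion
rates for an absent class are NaN ("undefined"), never silently 0.

## Known limitations

* No declumping: two cells closer than roughly a blob diameter merge
  into one detection; the separation floor of the generator reflects
  that assumption rather than hiding it.
* The classifier is color-driven on the synthetic bed; nothing forces
  shape sensitivity, so a brown smear of cell-like size could fool it.
  Stain traces probe this only at low chroma.
* Single-scanner geometry: all physical constants assume the pixel size
  in the metadata is trustworthy.
* Training is single-threaded numpy; corpora beyond ~10⁵ patches per
  epoch become impractical compared to a GPU framework.
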