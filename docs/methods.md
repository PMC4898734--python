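# Methods

## Problem setting and assumptions

The package classifies single pollen grains in segmented light-microscope
images: one grain per image on a near-uniform background, organized one
directory per pollen type. Segmentation itself is out of scope — the
loader only *recovers* a binary foreground mask from the uniform
background. All randomness (fold partitions, k-means initialization,
synthetic rendering) is controlled by explicit integer seeds; ordering is
lexicographic everywhere so no result depends on filesystem enumeration.

## Mask recovery

The background color is the median RGB of the one-pixel image border —
robust if the grain touches an edge, because the median of the remaining
border pixels still lands on the background. Pixels farther than a
tolerance (default 10 of 255, Euclidean RGB) are foreground; the largest
8-connected component is kept and holes are filled, implementing the
one-grain-per-image contract. The tolerance is a user knob: real stained
slides with vignetting or gradient illumination may need a larger value,
and the synthetic generator's white background is deliberately easy. On
generated images, recovered masks reach IoU ≥ 0.99 against the
generator's ground truth.

## CST features

*Color.* RGB is converted to hue/saturation/brightness (HSV); the
arithmetic means of H, S, B and R over the foreground are emitted on the
[0, 1] scale. Means are computed over the mask only, which makes them
independent of the background. Hue is averaged arithmetically, not
circularly; for strongly red classes whose hue straddles the 0/1 wrap
this biases the mean, a known limitation (tests compare hue circularly
where it matters). Achromatic pixels take hue 0 by convention.

*Contour.* Moore-neighbor boundary tracing with Jacob's stopping
criterion, starting at the topmost-then-leftmost foreground pixel,
normalized to counter-clockwise orientation (shoelace sign in display
coordinates). The traced boundary is a closed walk of 8-adjacent pixels;
contours shorter than 4 points are rejected.

*Shape.* The shape factor divides the object's pixel area by the area of
the exact minimum enclosing circle of its contour (Welzl's randomized
incremental algorithm on the convex-hull vertices — not a bounding-box
approximation). Circularity is `4A/(πL²)`; `L` is read as the maximum
Feret (caliper) diameter, the interpretation under which a perfect disk
scores exactly 1. The classical perimeter-based isoperimetric quotient
`4πA/P²` (with the 8-connectivity perimeter, diagonal steps √2) is
available via `circularity_mode="perimeter"`; digital perimeters
overestimate continuous length by a few percent, so the default is the
Feret reading. Both descriptors are exactly invariant under translation
and 90° rotations.

*k-curvature.* At each contour point the angle between the vectors to the
points k samples back and forward (cyclic), in [0°, 180°], binned into
nine 20° bins. Default k = 15: at the default grain radius (~40–70 px,
contour length 300–500) this spans enough boundary to suppress
pixel-level staircase noise while still resolving spikes of echinate
grains. The degenerate case of a zero-length leg (self-intersecting thin
contour) scores 0°. Raw counts are kept — the histogram sums to the
contour length, so it also encodes grain size.

*Texture.* One co-occurrence matrix per (distance, angle) pair, distances
{1, 2} and angles {0°, 45°, 90°, 135°} by default, over the luma
grayscale quantized uniformly to 256 levels (configurable down to 8 for
speed). Only pixel pairs with both ends inside the mask are counted; each
matrix is symmetrized and normalized. Contrast and entropy (natural log
by default, base 2 as an option, with 0·log 0 ≡ 0) are emitted per
matrix and kept as separate features rather than averaged across
offsets. The implementation is vectorized (bincount over flattened pair
indices) and verified feature-by-feature against a brute-force
pair-enumeration oracle to 1e−9.

The full vector is the fixed-order concatenation color (4) + shape (2) +
curvature bins (9) + texture (2 × 8) = 31 features by default.

## Bag of visual words

Interest points are detected and described on the grayscale image with
scikit-image's SIFT — a gradient-based, scale- and rotation-tolerant
detector with fixed-length (128-d) descriptors. The detector sits behind
a pluggable contract (any keypoints-plus-descriptors callable works) and
its tag is persisted with each vocabulary for provenance. Keypoints
farther from the foreground than their own scale are discarded; on
segmented images the background is featureless, so this mostly removes
boundary artifacts. Zero keypoints is a valid outcome (a featureless
image), encoded as an all-zero histogram.

The vocabulary is a single seeded k-means run (k-means++ initialization,
iteration cap 300, relative tolerance 1e−4, Euclidean distance) over the
descriptors pooled from training images only; pooled sets larger than
150 000 descriptors are subsampled with the same seed. Encoding is hard
assignment to the nearest centroid (ties to the lowest index), producing
integer count histograms; mass conservation (counts sum to the keypoint
count) is an invariant, and an optional L1 normalization flag exists for
classifier robustness. Encoding never mutates the vocabulary.

Vocabulary-size tuning is a two-phase schedule: an exponential sweep
2, 4, 8, …, 4096 (cap 4392), then an arithmetic grid around the phase-1
optimum with step = optimum/8 spanning optimum/4 … 4·optimum. The grid
reaches sizes like 768 = 3·256 that lie off the power-of-two lattice; the
refinement granularity is a design choice, chosen so the grid both
brackets the phase-1 interval and stays affordable. Ties break to the
smaller size. The default vocabulary size is 768, the value this
schedule selects under the tuned protocol; tuning is opt-in because the
sweep dominates runtime.

## Classifiers and evaluation

Four classifier kinds, with defaults mirroring the common toolkit
defaults since only K and the vocabulary size are protocol-tuned:
linear-kernel SVM with C = 1 (the sequential/SMO-style learner),
RBF soft-margin SVM with C = 1 and kernel width 1/d (C-SVC-style),
a decision tree (minimum leaf 2), and KNN with K = 1 and Euclidean
distance. SVM kinds standardize features internally, with statistics fit
on the training fold only, and handle multiclass one-vs-one; their
per-class scores for AUC are one-vs-one vote fractions. Tree and KNN
scores are leaf / neighbor class frequencies.

Cross-validation is a seeded stratified k-fold partition (default 3
folds; stratification guarantees every class appears in every fold at 35
images/class). Everything fit from data — standardization, the BOW
vocabulary — is refit per training fold; in the orchestrated experiment
the per-fold vocabulary is built once and shared by all classifier kinds,
which is equivalent to refitting per combination because the partition
and seed are identical, and keeps the study-scale run affordable.

Metrics: CCR = trace/total of the confusion matrix; per-class F =
harmonic mean of precision and recall, aggregated by support weighting;
per-class one-vs-rest AUC computed by the Mann–Whitney rank statistic
(exactly the trapezoidal ROC area, ties counted 1/2), support-weighted
for the aggregate. Per-fold metrics give the mean ± sd; the pooled
confusion matrix (rows = true class) is rendered as a row-normalized
blue→red heatmap with the raw counts exported as CSV. Combinations are
compared by one-way ANOVA on per-fold CCR; when p < α (default 0.05),
Tukey's HSD yields adjusted pairwise p-values. All-identical groups are
reported as F = 0, p = 1; zero within-group variance with differing
means is flagged as a degenerate comparison rather than an error.

KNN's neighbor count is tuned by sweeping K = 1…13 on cross-validated
CCR, ties to the smallest K.

## Synthetic data: what it emulates and what it does not

Real pollen types differ in outline (round, elongated, echinate), exine
texture and staining color. Each synthetic class is a base shape — disk,
ellipse (axis ratio), or star (a disk whose radius dips sinusoidally
between `spike_count` spikes by `spike_depth`, preserving the outer
radius and hence the Feret length while shrinking area) — plus additive
Gaussian intensity noise (clipped to [0, 255] after addition), optional
sinusoidal brightness stripes (stable gradient structure for the
keypoint detector), and an HSV tint, on a uniform white background. Every
parameter receives 5% multiplicative per-image jitter and a random
orientation, giving within-class variance akin to grains photographed at
different angles. Generation is fully deterministic under (specs, n,
canvas, seed) via independent spawned seed streams per class and image.

The default class palette cycles through shape, radius, noise level,
stripe period and hue simultaneously, so any prefix of the list is
separable on several feature groups at once — the generator's documented
contract is that its classes are well-separated, and the end-to-end
recovery test (fused features + soft-margin SVM ≥ 0.95 CCR on 5 classes
× 35 images) holds by that construction.

What passing on synthetic data does **not** show: robustness to focus
blur, uneven illumination, stain variability, touching or overlapping
grains, or genuinely subtle inter-taxon differences — real pollen
classification is much harder (published accuracies on 23 real types sit
near 64%, not the ~100% these separable synthetic classes allow). The
generator validates the machinery, not field-grade accuracy.

## Problem sizes and numerical choices

The default study emulation uses 35 images per class at 256×256 — 5
classes for the recovery experiment, 23 classes (805 images) for the
full-scale smoke run — sizes chosen to mirror the structure of public
pollen collections while remaining desk-scale. Degenerate inputs are
rejected with named errors (empty masks, single-pixel contours, contours
shorter than 2k+1, GLCM offsets with no valid pair, classes smaller than
the fold count, vocabularies larger than the descriptor pool). Floating
point in feature tables is serialized as the shortest round-tripping
decimal, so write∘read is exact. The Welzl shuffle uses a fixed internal
seed: the minimum enclosing circle is unique, so the shuffle affects
runtime only.

## Known limitations

Arithmetic (non-circular) hue averaging near the red wrap; digital
perimeter bias in the optional perimeter-mode circularity; SIFT rather
than SURF as the bundled detector (same contract, different descriptor
dimension); single k-means run per vocabulary (no restarts); AUC for SVM
kinds is computed from discrete vote fractions, which yields coarser ROC
curves than calibrated probabilities would.
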