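# Methods

`pitt` classifies crop type per agricultural parcel in smallholder
landscapes by combining two complementary observation streams: a
medium-resolution (10 m) SAR backscatter time series covering the
growing season, and a single high-resolution (2 m) optical image.  The
central premise is that the usefulness of a parcel's time series
depends on its size: small fields contain mostly boundary "mixed"
pixels whose signal blends neighbouring covers, so their temporal
curves represent their crop poorly.  The framework therefore grades
parcels by scale, routes the scale-adequate ones through a time-series
branch, the rest through a texture branch, and fuses the two
probability streams.

## Scale grading

For each parcel polygon we compute the maximum inscribed circle
(iterative pole-of-inaccessibility; holes are respected) and compare
its radius R against thresholds

    R_ti = R_i + R_b ,

where `R_i` is the radius of the smallest circle centred on a pixel
center that fully contains the `i` nearest whole pixels of side L
(`R_0 = 0`, `R_1 = (√2/2)L`, `R_5 = √2.5·L`, `R_9 = √4.5·L`,
`R_16 = √8.5·L`), and `R_b` is a buffer compensating for the circle
centre not being pixel-aligned.  We take `R_b = (√2/2)L`, half a pixel
diagonal — the smallest buffer that guarantees a pixel center falls
inside the circle's central pixel regardless of alignment.  A custom
buffer is available through `buffer_mode="custom"`.  A parcel's scale
level is the largest `i` whose threshold its radius clears; level ≥ 5
("small", roughly ≥ 0.1 ha at L = 10 m) goes to the time-series
branch, below ("micro") to the texture branch.

## Time-series representativeness (GAS / TAS)

Group-average similarity is the mean of all n² pairwise Pearson
correlations in a stratum (self-pairs included); true-average
similarity is the mean correlation to a designated typical curve.
Both can instead use the time-weighted DTW distance with local cost

    d(i,j) = |x_i − y_j| + 1 / (1 + exp(−α(g_ij − β))) ,

g_ij the date gap in days, α = 0.1/day, β = 5 days, symmetric step
pattern, full alignment, no window.  Dates are day-of-year;
cross-year wrapping is out of scope.  Degenerate (zero-variance)
series get correlation 0 with a flag rather than an exception so that
group statistics over noisy strata never abort.

## The time-series branch

Pixel sets for extraction: all covered pixels (pixel-center-in-polygon
rule, unweighted mean), boundary-excluded (only pixels whose full
footprint lies strictly inside), or the k pixels nearest the parcel
centre.  Series are z-normalized ("standardized by the mean" plus unit
variance) before shape clustering because the shape-based distance
assumes it; mean-only centering is available by `mode="center"`.  The
raw mean level and spread of each series are retained.

k-Shape clustering uses the shape-based distance
`1 − max_s NCC_c(x, y; s)` with centroids refined by shape extraction
(dominant eigenvector of the centred Gram matrix of aligned members).
We run 5 restarts per fit and keep the solution with the lowest total
distance; a single restart was observed to occasionally pollute one
crop's centroid enough to empty its cluster at the 0.97 prototype
threshold.  The cluster count defaults to 3× the number of classes,
since clusters represent curve types, not crops.  Member confidence is
`(1 + NCC)/2 ∈ [0, 1]`, and the prototype threshold `prob_kshape`
(default 0.97) is applied on this scale.

Pseudolabel fine-tuning: (i) keep members at or above `prob_kshape`;
(ii) drop members whose raw mean level deviates from their cluster's
median by more than δ = 3 dB (similar shape at a different amplitude
is a different cover); (iii) map each cluster to the crop of its
nearest typical reference curve by TWDTW on the amplitude-restored
centroid (median member level and spread), with Pearson as the
tie-break and class order after that, and drop clusters holding less
than 1 % of all pseudolabels.

The classifier is an InceptionTime-family 1-D CNN implemented in
numpy with manual backpropagation: bottleneck 1×1 convolution,
parallel convolutions with kernels 9/5/3, a max-pool + 1×1 branch,
channel concatenation, a residual shortcut every third block, global
average pooling and a softmax head.  Desk-scale defaults: depth 3,
8 filters per branch, Adam at 1e-2, 120 epochs, batch 64, single
network (the canonical ensemble of five is available via
`n_ensemble`).  Gradients are verified against finite differences in
the test suite, and training is bit-deterministic for a fixed seed.
The classifier is trained on small-parcel pseudolabels only and then
predicts all parcels, small and micro.

The "plain k-Shape" baseline used in comparisons clusters with
k = number of classes and reads each cluster directly as the crop of
its nearest reference — the standalone-clustering route the
pseudolabel-plus-classifier design is meant to beat.

## The texture branch

The published texture pipeline (contrastive pretraining, prototype
clustering, consistency-regularised semi-supervised training) is
GPU-scale; this package implements the same stage contracts at desk
scale.

*Embedding.* A fixed convolutional filter bank: complex oriented
Gabor kernels at 0°/45°/90°/135° (the 90° and 135° kernels are exact
rotations of the 0°/45° ones, so rotating a chip permutes the features
exactly) at three frequencies, DC-removed, with mean and standard
deviation of the response magnitude pooled over both the full chip and
its central half crop, plus gradient and per-channel intensity
statistics.  The central crop keeps large windows informative about
the parcel itself when the chip is much bigger than the field.  A
seeded random-convolution embedding is available as an alternative.

*Prototype clustering.* k-means on standardized embeddings with a
normalized-margin member confidence `(d2 − d1)/d2` (1 on a center, 0
on a decision boundary); k defaults to 2× the number of classes.

*Label-set construction.* Mode 1 (small parcels) skips clustering:
parcels whose top time-series probability reaches `prob_KI = 0.99`
become image pseudolabels directly.  Mode 2 (micro parcels) clusters
first and refines prototypes with the time-series predictions by
three rules: split prototypes mixing several predicted crops; drop
members whose cosine similarity to their sub-prototype centroid is
below 0.8; merge same-crop sub-prototypes with centroid similarity at
or above 0.8.  Rules (ii) and (iii) iterate to a joint fixed point so
the whole pass is idempotent.

*Classifier.* The fixed filter bank serves as the convolutional
feature extractor for a two-layer dense head trained with Adam on
confidence-weighted pseudolabels and a FixMatch-style consistency
term: an unlabeled chip whose weakly augmented view (flips, ±2 px
translation) is predicted with confidence ≥ τ = 0.95 supervises its
strongly augmented view (flips + intensity jitter + cutout).  Three
augmented views per chip are precomputed and cycled over 20 epochs.
Setting τ > 1 reduces exactly to supervised training.  Chips smaller
than 32 px are upsampled to 32 by nearest-neighbour replication before
any model use.

## Fusion and evaluation

The two streams are fused per branch by a plain weighted average with
w = 0.5 by default (the heterogeneous models' confidences are not
calibrated against each other, so no confidence-based weighting is
attempted).  The class is the argmax, ties breaking by class order
(rape, wheat, other) with a flag.  Evaluation is one-vs-rest
precision/recall/F1 per class and macro-F1; the weight sweep covers
0.05–1.00 in steps of 0.05.

## The synthetic scene generator

The generator provides fully specified study conditions so every
stage is testable without external data.

*Geometry.* Per scale level, a horizontal band of jittered-Voronoi
cells (guard ring keeps interior cells bounded) is scaled about each
cell's inscribed-circle centre to a target radius drawn inside the
level's threshold interval; grading recovers the requested level for
≥ 95 % of parcels by construction.  The level-0 radius floor is
0.72 L so every parcel contains at least one pixel center (smaller
slivers would be unobservable in the SAR stack).  Default scene: 50
parcels per class per level in {0, 1, 5, 9}, 600 parcels total; the
representativeness benchmark uses the two crops only at 100 parcels
per stratum.

*SAR stack.* Ten acquisition dates, day-of-year 8–140 (early January
to late May).  Class VH templates (piecewise linear, dB): winter
wheat decreases monotonically from −13.5 to −19 over the season;
winter rapeseed rises to a −11 dB peak at day 105 (mid-April) and
declines sharply; the bare/grass class rises gently by ~2 dB
(spring green-up) — a flat template would z-normalize to pure noise,
which no real land cover does.  Each parcel's curve adds a level
offset and a smooth 4-knot perturbation whose standard deviations
(rape 0.3/0.6 dB, wheat 0.6/1.0 dB, other 0.5/0.8 dB — wheat is
deliberately the most heterogeneous crop) are multiplied by the
parcel's boundary-affected area fraction `clip(perimeter·L/area,
0.3, 1.5)`: small fields deviate more from their crop's typical curve
because proportionally more of their area is boundary zone.  Every
pixel's clean value is the footprint-area-weighted blend of all
overlapping parcel curves plus a −12 dB background — the mixed-pixel
mechanism — with i.i.d. Gaussian noise of 1 dB per pixel per date
(speckle-like multiplicative noise is available by flag).

*Texture image.* Within each parcel, oriented sinusoidal stripes
(rape 0°, wheat 90°, both 8 m period and 0.25 contrast; the third
class nearly textureless) on class-specific RGB bases, plus Gaussian
noise (σ = 0.03), on a 2 m grid.

What the generator does *not* emulate: SAR speckle statistics,
radiometric calibration effects, topography, within-parcel texture
heterogeneity beyond a single stripe pattern, cloud or acquisition
gaps, and label noise.  Passing tests therefore demonstrate that the
pipeline's information flow behaves as designed under controlled
conditions, not that the published real-data accuracy transfers.

## Numerical choices and degenerate inputs

Zero-variance series standardize to the zero vector with a flag;
correlation with such a series is 0.  Equidistant pixels in central-k
selection break ties in row-major order.  Fusion renormalizes only if
float drift exceeds 1e-6.  All stochastic stages take explicit seeds
derived from one master seed (`seed·1009 + stage offset`, mod 2³¹),
inputs are canonically id-sorted, and reruns are byte-identical.
Problem sizes used by the test suite and acceptance script — 600
parcels for the standard scene, 800 for the representativeness
benchmark, reduced scenes for structural tests — were chosen to keep
a full run on one CPU in minutes.

## Known limitations

Single polarization (VH) only; one planar CRS with no reprojection;
no parcel delineation (boundaries are inputs); the texture stage's
embedding is fixed rather than learned, so it cannot adapt to texture
families outside its filter bank's frequency range; fusion weights
are global per branch rather than calibrated per class.
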