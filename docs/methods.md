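# Methods

## The retrieval model

The package solves patch retrieval by appearance: given a query rectangle
`q` of size `h x w` inside a stained microscopy image, return the locations
in a set of images whose local appearance is most similar to `q`. The
pipeline has four stages — foreground localization, coarse-to-fine ranking,
detection fusion, and optional feedback re-ranking — each of which is
independently testable.

### Annular histograms

The core descriptor treats a patch as `r` concentric rectangular rings of
equal thickness. With the patch center at `(cy, cx) = ((H-1)/2, (W-1)/2)`,
a pixel's normalized Chebyshev-style distance is
`d = max(|y-cy|/(H/2), |x-cx|/(W/2))` and its ring index is
`floor(r*d) + 1`, clamped to `[1, r]` — ring `i` covers `d` in
`[(i-1)/r, i/r)`. For the fine descriptor each ring is additionally cut
into 8 angular octants about the center; octant 1 starts at the east axis,
proceeds counterclockwise, and boundary pixels (on the axes or diagonals)
go to the lower-numbered octant. Octant membership is decided by exact
integer comparisons on twice the pixel offsets, so the partition has no
floating-point boundary ambiguity and is bit-reproducible.

Histograms use 256 bins per RGB channel (raw RGB; no color normalization),
normalized by region pixel count so that candidates resampled from other
scales remain comparable. Ring/segment histograms conserve mass: the
unnormalized octant histograms of ring `i` sum exactly to the ring-`i`
histogram, and the rings sum to the whole-patch histogram. Distances are
plain Euclidean on the concatenated vectors.

The value of the ring structure is spatial sensitivity at near-zero cost
over a plain histogram: patches with identical color content but swapped
center/border layout are indistinguishable to the whole-patch histogram
(distance 0) and clearly separated by the 2-ring feature. The octant split
adds angular sensitivity, separating patches whose rings match but whose
content is mirrored or rotated between half-planes.

### Foreground localization

Foreground is "stained tissue": the image is deconvolved into
hematoxylin/eosin optical-density channels (Ruifrok–Johnston basis, which
also captures the purple chromatic axis of Giemsa), each channel is
thresholded by Otsu's method, and the union of the per-channel foregrounds
is cleaned by morphological opening (radius 2), closing (radius 4) and
removal of components under 64 px. The union matters in practice: Otsu on
a single dominant channel locks onto the most strongly stained structures
(nuclei) and misses eosinophilic material, which starves candidate
generation. A per-channel guard (mean foreground-background separation of
at least 0.01 OD) keeps pure-noise images from producing spurious masks.
Candidate windows of the query's size (per scale in the configured scale
set, default `{1}`; `{0.5, 1, 2, 3, 4}` for the multi-scale tissue case)
are tiled with stride `round(size * (1 - overlap))`, keeping windows with
at least 30% foreground coverage. Overlap defaults to 0.5; 0.9 trades
roughly 25x more candidates for tighter localization.

### Cascade, fine ranking, fusion

The coarse cascade scores candidates cumulatively: at stage `i` the
query-candidate distance uses rings `1..i`, and the top `ceil(n_i / 2)`
survive (ceil, so one candidate always survives). Ring histograms are
computed lazily; stage `i` therefore costs one ring histogram per
surviving candidate and total work is `n + n/2 + ... < 2n` histograms
versus `n*r` for exhaustive coarse scoring. A candidate identical to the
query has distance 0 at every stage and can never be eliminated. Survivors
of the last ring are re-ranked by the fine feature, ties broken by
incoming rank.

The top 10% of the fine ranking is fused by flat-kernel mean-shift on
window centers with bandwidth `b = sqrt(w^2 + h^2) / 2` — half the query
diagonal, chosen so detections whose centers overlap substantially merge
into one mode. Iteration stops when the shift drops below `1e-3 * b` or
after 100 rounds; converged points closer than `b/2` merge, scanning in
canonical (row, col) order so the mode set is invariant to input ordering;
every window joins its nearest mode and each mode reports its best-ranked
member as representative.

### Texture baselines

Two classical descriptors are included for comparison studies. The Gabor
feature convolves the luminance patch with a 5-scale x 8-direction complex
filter bank (center frequencies geometric from 0.05 to 0.4 cycles/pixel,
the standard texture-retrieval design) and records per-filter magnitude
mean and standard deviation (length 80); inputs are reflect-padded so
image borders do not register as texture. The co-occurrence feature
quantizes to 32 gray levels and computes symmetric normalized
co-occurrence matrices at offset 1 for orientations 0/45/90/135 degrees,
reporting Haralick contrast, correlation, energy and homogeneity per
orientation (energy is the angular second moment — the sum of squared
matrix entries; a constant patch's undefined correlation is reported
as 1). Because these features mix scales, they are z-scored over the
candidate pool (population SD, zero-variance columns pinned to 0) before
Euclidean comparison.

### Dual-similarity relevance feedback

Feedback re-ranks the top `K = 100` retrievals from two signals: reviewer
labels (relevant / non-relevant) and appearance distance to the query. The
coarse features of the feedback set are centered and projected onto the
smallest PCA basis reaching 90% cumulative explained variance (fit on the
feedback set itself — the on-line setting — not a global corpus). A
discrete AdaBoost ensemble of depth-1 decision stumps (T = 50 rounds)
is then trained, but its initial sample distribution is not uniform:
distances are min-max normalized and
`W_i ∝ (1 - D̃_i) + ε, ε = 1/K` — linear decay with a floor, the simplest
form that is strictly decreasing in distance, everywhere positive, and
hyperparameter-free. Rounds stop early on a perfect stump (stage weight
capped rather than infinite) or one no better than chance. Items are
reordered by descending ensemble margin with ties broken by original rank,
so a degenerate model leaves the ranking unchanged.

A known boundary of the stump ensemble: on exactly XOR-symmetric data the
first weak learner's weighted error sits at 0.5 and boosting cannot start;
on noisy XOR-like blobs it progresses but need not reach zero training
error. The tests pin our loop to an independent boosting implementation
on such data rather than asserting an unattainable zero.

### Evaluation

Precision = relevant retrieved / retrieved; recall = relevant retrieved /
all relevant. PR curves sweep the cutoff over the full ranked list, are
anchored at recall 0 with the first cutoff's precision, and integrate by
trapezoid over recall on normalized [0,1] x [0,1] axes (likewise the areas
under recall-vs-rank curves). Feedback classifiers are assessed by
stratified 10-fold cross-validation with scores pooled across folds before
a single ROC sweep (pooling is more stable than per-fold averaging at
K = 100; folds shrink with a warning if a class is smaller than the fold
count). `recall_after_feedback` draws `n_train` labeled items at random
(seeded, redrawn if single-class), trains, and compares held-out recall
curves under the initial-distance and post-feedback orderings.

## Synthetic fixtures

No public accessions exist for the two study settings, so a seeded
generator produces stylized stand-ins with exact ground truth.

*Smear fields* (default 1000x1000 px, emulating a 20x blood-smear field):
a pale background carpeted with ~2400 pink erythrocyte-like discs with
central pallor (roughly 60% area coverage, as in a well-spread smear), and
8 planted leukocyte-like cells drawn from five classes differing in size
(11–16 px radius), cytoplasm/nucleus color, and nucleus shape (tri-lobed,
bi-lobed, round, indented — composed ellipses). The class mix follows the
approximate adult differential (neutrophils 60–70%, lymphocytes 20–25%,
monocytes 3–8%, eosinophils 2–4%, basophils 0.5–1%), realized by
largest-remainder allocation. Within-class jitter is small (±1 px radius,
±2 gray levels of color) and Gaussian pixel noise (SD 2) is added last.
Cell centers are placed by rejection sampling with a minimum separation of
3 cell radii; impossible configurations raise after bounded retries.

*Renal fields* (default 1256x876 px, a quarter linear scale of the source
material's 5024x3504 crops): a textured pink background with ring-like
glomerulus structures in two states — intact (dense dark interior
stippling) and degraded (pale, sparsely fragmented interior) — each at a
scale drawn from `{0.5, 1, 2, 3, 4}` relative to a 45 px base radius.

The generator controls color and spatial statistics explicitly, which is
exactly what the annular features measure; it does not simulate staining
physics, focus blur, scanner artifacts, overlapping/touching cells, or the
continuous morphological variability of real leukocytes. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that
retrieval works when class appearance differences are of the planted kind;
they do not certify clinical-grade accuracy on stained tissue.

Fixture defaults were calibrated once against the pipeline's documented
recoverability target (at least 80% of planted same-class objects found
end-to-end with default search settings): the erythrocyte density keeps
the candidate pool large enough that the retained top-10% covers every
planted site, and stain colors sit safely above the Otsu thresholds of
their deconvolution channels. With grid stride = half the query size
(overlap 0.5), the worst-case alignment between a planted object and the
candidate grid bounds the best attainable IoU near 0.39, so detections are
matched to truth at IoU ≥ 0.25; per-field recall then varies with
placement luck, and the acceptance measurement aggregates over four fields
(40 planted cells, ~6 s/field single-core) for a dataset-level estimate.

## Numerical and design choices

- Coordinates are 0-based (row, col), half-open extents; windows carry
  their scale and source image id.
- 16-bit inputs are rescaled to 8-bit by integer division by 257;
  grayscale is replicated to 3 channels; resampling is bilinear with
  edge-clamped sampling, rounded back to uint8.
- Cumulative ring scoring in the cascade (rings `1..i` at stage `i`) makes
  the final coarse ranking use the full `H_c`; scoring ring `i` alone
  would let early rings drop out of the final ordering.
- All ties (equal distances, equal margins) break by list order, making
  every stage deterministic; repeated runs are bit-identical.
- The mean-shift bandwidth and the retained fraction (0.10) are the two
  fusion knobs; `r = 3` rings is the default (sufficient for the
  leukocyte-style setting; texture-rich multi-scale material benefits
  from more rings at proportional cost).
- Degenerate inputs: empty candidate lists warn and return empty results;
  an all-background image yields an empty mask; a feedback set with one
  class raises a dedicated error directing the caller to skip feedback.

## Limitations

Ranking quality degrades with query/grid misalignment at low overlap
ratios — the fused modes, not individual windows, are the intended output.
The 256-bin histograms are sensitive to global illumination shifts (no
stain normalization is applied). The parallel executor is thread-based and
in-process: it demonstrates the pull-model contract (order-independent
merge, single re-queue on failure) rather than distributed-scale
throughput. Whole-slide pyramid formats are out of scope; inputs are flat
PNG/TIFF/JPEG rasters.
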