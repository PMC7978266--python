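# Methods

This note records the models, conventions and numerical choices behind
`leafsense`, in the order the pipeline applies them, together with what the
synthetic benchmark does and does not demonstrate.

## Labels and panel statistics

Panel scores are integers 1–4, `n_panels` per image (default 12). The
target is the per-image mean rounded **half-up** (2.5 → 3); the "rounded
value of the mean" convention leaves the tie rule open, and half-up is the
fixed, documented choice here. Coarsening maps are 4→3 levels: {1→1, 2→2,
3→3, 4→3} and 4→2 levels: {1→1, 2→1, 3→2, 4→2}; predictions are always made
at 4 levels first and coarsened afterwards, so a model's 2-level accuracy
is never obtained by retraining. Coarsening can only merge a wrong
prediction onto the truth, never split a correct one, so accuracy is
provably non-decreasing in coarsening — this is also tested empirically.

σ<sub>i</sub> uses the population divisor n<sub>j</sub>, exactly as the
defining formula is written, and σ̄ is the unweighted mean over images.

The randomized-block ANOVA treats the complete n<sub>i</sub>×n<sub>j</sub>
score matrix as a two-factor layout without replication: SS_total =
SS_sample + SS_panel + SS_error, F = MS_factor/MS_error with
(n<sub>i</sub>−1), (n<sub>j</sub>−1) and (n<sub>i</sub>−1)(n<sub>j</sub>−1)
degrees of freedom. Cohen's f² is computed as SS_effect/SS_error (=
η²_partial/(1−η²_partial)); Cohen (1988) admits several forms and this one
is fixed here because it needs no model refits. Degenerate 0/0 cases (a
factor with zero SS in a table with zero residual) report F = 0, f² = 0.
Zero-variance features yield an *undefined* correlation flag rather than a
propagated NaN.

## Segmentation

Grayscale is BT.601 luma (0.299 R + 0.587 G + 0.114 B), the common imaging
default. Otsu's threshold is computed on a 256-bin histogram of the
8-bit-quantized raster; for threshold t the classes are {<t} and {≥t}, ties
in between-class variance break toward the smallest t, and a single-bin
histogram returns t = 0 with a degenerate flag. Foreground is **strictly
below** the threshold (inverted binarization; pixels equal to the threshold
are background) — a fixed, testable convention. No morphological cleanup is
applied. "490 × 653" is interpreted as width × height (portrait). Color
conversion happens after masking, matching the stated processing order;
L\*a\*b\* uses the standard sRGB→XYZ(D65)→Lab formulas and HSV the hexcone
model, both via scikit-image, kept in native ranges (L\* 0–100, H in
degrees) so hand-computed oracles stay checkable — downstream
standardization removes scale anyway.

## Color features

Mean, minimum and **population** standard deviation per channel are
computed over foreground pixels only. The masked image contains background
zeros; including them would make nearly every minimum trivially zero and
destroy the documented positive min-feature correlations, so they are
excluded. Hue is treated linearly (no circular statistics): leaf hues
occupy a narrow arc and standardization absorbs the scale.

## Local features

Detection and description are backed by `skimage.feature.ORB` with
conventional ORB settings (8 pyramid levels, scale 1.2, 500 keypoints per
channel cap, all exposed as parameters). Two primitives are additionally
implemented from first principles as verifiable references:
`fast_corner_test` (≥ n_arc contiguous pixels of the radius-3 ring all
brighter/darker than center ± t, default n_arc = 9) and
`intensity_centroid_orientation` (atan2(m01, m10) over a centered circular
patch, with a degenerate flag for centered mass). Each channel is
affine-mapped from its native range to integer [0, 255] before detection.
Detection runs on the bounding box of the foreground mask plus a 40 px
margin rather than the full frame: keypoints outside the mask are discarded
regardless, the flat background contributes no corners, and the crop makes
the 500-image study roughly three times faster. Keypoints whose center
falls outside the mask are dropped after detection; boundary keypoints with
centers inside the mask are kept, since the leaf silhouette itself is
informative texture.

Vocabularies are per-channel k-means (k = 20, k-means++, 10 restarts by
inertia, seeded) on descriptors cast bit→{0.0, 1.0}, using **training-split
descriptors only**; pools larger than 5,000 descriptors per channel are
subsampled (seeded) before clustering, standard bag-of-visual-words
practice that bounds the clustering cost without visibly moving the
centroids. Centroids are stored in a canonical order (first coordinate,
then lexicographic) so serialized vocabularies are comparable across runs.
Encoding assigns each descriptor to the nearest centroid (Euclidean on the
same cast; ties to the lowest index) and returns **raw counts** — no L1/L2
normalization, because the downstream standardizer normalizes every
histogram bar. The per-channel histogram therefore always sums to the
retained keypoint count (a partition), which is asserted in tests.

## Classification

The stratified 80:20 split draws the overall test count as
round(0.2·n) and apportions it across classes by largest remainder, keeping
every class within one image of exact proportionality (1,045 images with
the study's class counts give exactly 836/209); classes with fewer than two
members go to training with a warning. The standardizer (zero mean, unit
population variance; constant features pass through with scale 1) is fitted
on the training split only, and re-fitted inside every cross-validation
fold — the leak-free choice. Cross-validation folds are stratified and
seeded; the default grid is the single published operating point (SVM C =
9, γ = 0.001, rbf), with a user-suppliable grid whose ties resolve to the
first point.

The MLP is implemented directly in numpy (no deep-learning framework is a
dependency): layers 230-32-128-128-64-4, sigmoid on the first hidden layer
and ReLU on the rest, softmax output, categorical cross-entropy, Adam
(lr 0.001, β₁ 0.9, β₂ 0.999), inverted dropout 0.1 after each hidden
activation (training only), 80 epochs of shuffled mini-batches of 90, no
early stopping. Loss choice and dropout placement are unstated in the
published description; cross-entropy after softmax and per-hidden-layer
dropout are the standard readings. Weight initialization is seeded
Glorot-uniform; a fixed seed reproduces weights bit-for-bit.

## Synthetic data generator

The generator defines the study conditions for all synthetic-recovery
tests. Geometry: a randomized superellipse (exponent 2–3) with 2–5 lobed
cosine perturbations (amplitudes ≤ 0.05, clipped so the radius function
stays positive — the blob is star-convex, hence one connected component)
plus a stem rectangle, sized to stay off the frame border. Appearance: base
RGB (38+22f, 88+72f, 46+20f) scaled by `color_effect` (default 1), with
low-frequency shading (±8%) and pixel noise (σ 3); background at gray 230
(σ 2). Lightness and the green channel therefore increase linearly in
expectation with the latent freshness f. Texture: Poisson-many blemishes
with mean `texture_effect · (1−f)` (default texture_effect 40, so ~40 at
full wilt, exactly 0 at f = 1), 35% curvilinear wrinkle strokes (20–60 px,
1–2 px wide) and 65% speckle discs (3–9 px), each darkening the leaf to
30–60% of its local color and confined to the mask. Blemishes both depress
the foreground minima (driving the positive min-gray/g/v/L\* correlations)
and create FAST corners (driving the negative histogram-bin correlations).

Panel scores: score<sub>j</sub> = clamp(round(1 + 3f + b<sub>j</sub> +
ε<sub>j</sub>), 1, 4) with persistent per-panel biases b<sub>j</sub> ~
N(0, 0.15) (the random-block structure that makes the ANOVA panel factor
non-trivial) and per-image noise ε<sub>j</sub> ~ N(0, 0.55). The latent f
is drawn from a four-band mixture (bands are the preimages of the noiseless
labels, weights 0.16/0.36/0.43/0.05), giving the mid-heavy imbalanced label
distribution. The noise defaults were calibrated once so that σ̄ lands in
the 0.4–0.8 band around the real-study value ≈ 0.61 (measured ≈ 0.55 at
n = 500) — the only quantities the generator is calibrated to are σ̄ and
the class imbalance.

What the generator does **not** emulate: real leaf morphology and venation,
specular highlights and shadows, JPEG artifacts, camera optics, or
storage-time kinetics. Synthetic images are born at the 490×653 working
size, so the resize stage is an identity pass in synthetic runs (real
images still go through bilinear resize). Passing synthetic-recovery tests
therefore demonstrates that the pipeline's machinery is correct and that it
recovers a planted signal of realistic shape and strength; it does not
certify accuracy on real spinach photographs, for which the released study
data can be run through the identical `RunConfig(images_dir=...,
scores_path=...)` path.

## Determinism and problem sizes

Every stochastic component (generator, k-means and its subsampling, split,
folds, MLP) is driven by explicit seeds; a fixed configuration reproduces
byte-identical images, feature tables and models on the same platform.
The default synthetic study uses n = 500 images at full working resolution
(~10 minutes on one CPU), large enough that all calibration bands hold with
wide margins; unit tests use reduced frames (240×320) where only contracts,
not calibrated statistics, are at stake. The pipeline caches its extraction
stage in the run directory keyed by a configuration content hash, so
re-running an unchanged configuration skips straight to modelling.

## Known limitations

- The real study's headline accuracies (70/77/84%) and panel statistics
  (σ̄ = 0.61, f² = 0.13/1.77) are properties of its 1,045 photographs and
  12 raters; this package reproduces the method and validates it on
  synthetic data, and can re-run the real data when downloaded, but does
  not ship those images.
- The synthetic panel-bias SD (0.15) yields an f²_panel ≈ 0.02–0.04,
  smaller than the real panel effect; only σ̄ and the class imbalance were
  calibration targets.
- Hue statistics are non-circular; vocabularies are rebuilt per run rather
  than per CV fold (the split-level leak guarantee is what is audited).
- `skimage`'s ORB differs in minor details (FAST threshold semantics,
  sampling pattern) from other ORB implementations; the two reference
  primitives are oracle-tested, but descriptors are not bit-compatible with
  OpenCV's.
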