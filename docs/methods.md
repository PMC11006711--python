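# Methods

## Problem and model

The package classifies a face photograph into three nutritional states
derived from the PG-SGA Short Form score (cut points 2.0 and 5.0; a score
equal to a cut point enters the worse class, matching triage semantics).
The imaging signal is periorbital: loss of orbital fat-pad volume makes the
eye region look sunken and darker, which is one of the few facial features a
PG-SGA physical exam actually scores. The pipeline therefore (a) normalizes
face geometry from 68 landmarks, (b) describes local contrast with HOG, and
(c) biases the representation toward the eye region before classification.

## Geometry

* **Eye centers** are the arithmetic means of the six contour points of each
  eye; the alignment angle θ is the signed angle of the left→right center
  line against the horizontal (positive = right eye lower). The image and
  landmarks are rotated by −θ about the unweighted centroid of all 68
  landmarks ("overall face center"); the centroid of the 20 mouth points is
  the "mouth center". Rotation and resize use bilinear interpolation;
  out-of-canvas pixels are zero-padded, never an error.
* **Crop**: with D the distance from the eye midpoint to the mouth centroid,
  the crop is a D×D square of three vertical bands 0.3 D / 0.4 D / 0.3 D.
  The band heights fix the extent but not the anchoring; we center the
  middle band on the midpoint of the eye-midpoint→mouth-centroid segment
  (config `crop.anchor`), which places the eye line at the top edge of the
  crop and the mouth line at the bottom. The crop is resampled to 256×256.
* **Ocular ROI**: left edge from the leftmost left-brow point, right edge
  from the rightmost right-brow point, top from the highest brow point,
  bottom at the third nose landmark (index 29 in the 0-based 68-point
  ordering; configurable, and the 0- vs 1-based reading of "third" is the
  one genuinely open choice here). In crop coordinates the brow tops
  typically fall above the crop and are clipped at 0.
* The "full-face excluding eyes" variant zeroes the ROI pixels instead of
  removing rows, so every variant keeps the same grid geometry and the HOG
  dimensionality is comparable across variants.

## HOG

Defaults: gamma 2.2 applied compressively (v → v^(1/2.2); the direction is
not dictated by the 2.2 value itself, compressive is the standard
illumination-flattening choice and `hog.gamma_mode` exposes the alternative),
[-1, 0, 1] centered differences (one-sided at borders), signed orientations
in [0, 360) — forced by 8 bins × 45° — hard bin assignment without bilinear
voting, 6×6 px cells (a 256×256 face gives 42×42 cells; remainder pixels at
the right/bottom edges are dropped), 2×2-cell blocks at stride 1 with
L2 normalization (‖·‖ + 1e-6, so zero blocks stay zero), row-major
concatenation: 41·41·2·2·8 = 53 792 features for a dense 256×256 face.
Every element carries (cell, bin) or block provenance until PCA discards it.

PCA is ordinary centered PCA; the component count is the smallest k reaching
an explained-variance target (default 0.95), capped at min(n−1, p). PCA is
always fitted on training subjects only and applied to held-out subjects.

## Eye weighting

The aligned face is tiled into a 6×6 grid (block side 256//6 = 42 px, the
remainder absorbed by the last row/column so the tiling is exact). HOG is
computed *per grid block* on this path, so provenance is exact, and every
element from a block whose rectangle intersects the ocular ROI with positive
area (config `weight.membership`) is multiplied by 4 (config
`weight.value`). Weighting acts on feature values before PCA and training —
it biases the representation, not the loss. The unweighted counterpart is
the identical representation with weight 1, which makes the weighted vs
unweighted comparison exactly paired.

## Classifiers

The BP network is a single hidden layer of 64 logistic units with softmax
output and cross-entropy loss, trained by SGD (learning rate 0.01, momentum
0.9, batch 32) for 50 epochs — "rounds" are read as epochs, the conventional
meaning for SGD training. Fits are deterministic given (data, config, seed).
Baselines (AdaBoost, ExtraTrees, random forest, XGBoost, KNN) use library
defaults with seeded determinism and the same prediction contract: three
class probabilities summing to one, zero-padded for classes absent from a
training fold. No class reweighting by default.

Cross-validation is stratified five-fold with shuffling; PCA and weighting
are fitted per training fold. Out-of-fold probabilities are pooled in the
original subject order, so two variants cross-validated with the same labels
and seed are paired subject by subject.

## Metrics and comparison tests

Sensitivity/specificity/PPV/NPV/accuracy are reported on the dichotomized
problem (malnourished-or-worse vs normal); undefined ratios are NaN, never
zero. AUC is micro-averaged: the one-vs-rest (label, score) pairs of all
three classes are pooled into one ROC, ties handled by midranks. CIs are
percentile bootstrap with B = 1000 (seeded; resamples on which a statistic
is undefined are redrawn and counted).

DeLong's test uses midrank structural components; degenerate variance
returns p = 1. NRI is categorical over the dichotomized risk with category
cut points at 1/3 and 2/3 of predicted risk and an asymptotic z-test; IDI is
the discrimination-slope difference with a paired z-test. The "risk" used by
all three is P(malnourished or severe), the dichotomized positive-class
probability — the natural scalar risk in a three-class screening setting.

## Synthetic cohorts

The generator emulates exactly the features the pipeline consumes:

* procedural faces (head ellipse, brow arcs, hexagonal eye contours, nose
  polyline, mouth ellipse) drawn at a randomized rotation (±12°), scale
  (±5%) and offset (±2%), with landmarks exactly on the drawn primitives;
* a periorbital signal: the intensity inside the ocular ROI drops by
  `effect_size × severity` (severity latent in [0, 1]). The signal is
  intensity-based, not shape-based, because HOG responds to the gradient
  step at the ROI boundary; that is sufficient to make ocular-vs-rest and
  weighted-vs-unweighted comparisons meaningful;
* label-independent nuisance a real photograph always carries: mouth
  openness/position (expression), two or three soft shadow blobs on the
  lower face, a linear illumination tilt, and Gaussian pixel noise
  (default sd 0.05). Without nuisance outside the eyes, every variant
  saturates and region weighting has nothing to suppress;
* questionnaire scores: PG-SGA SF = round(20·severity + ε), ε ~ N(0, 1.5);
  NRS2002 = round(7·(ρ·severity + √(1−ρ²)·u)) with u uniform, so the
  sample Pearson correlation between the scales tracks `target_r`
  (default 0.8, a strong but imperfect agreement between two screening
  instruments).

Severity is drawn case-control style by default ("balanced"): the three
classes are sampled with equal probability and severity uniformly within
each class's preimage ([0, 0.1), [0.1, 0.25), [0.25, 1] on the severity
scale). A chance-level classifier then scores micro-AUC ≈ 0.5, which makes
null calibration interpretable; with `severity_dist="uniform"` the cohort is
dominated by severe cases and the pooled one-vs-rest AUC of even a
prior-only predictor rises to ≈ 0.86 — a known property of micro-averaged
AUC under imbalance, worth remembering when reading clinical reports too.

What passing tests show: the pipeline recovers a periorbital intensity
signal of 0.3 under mild geometric and photometric nuisance at n = 200, and
the ocular/weighted design decisions help under eye-confined signal. What
they do not show: performance on real skin texture, demographic variation,
occlusion (glasses, hair), or landmark-detector noise — landmarks here are
exact by construction.

## Study sizes

The acceptance study uses 200-subject cohorts: sign tests over 10 seeds for
the paired variant comparisons, 5 seeds for AUC level and null calibration,
1000 simulations for DeLong type-I error, 500 replications for bootstrap
coverage. These sizes give stable means while keeping the whole suite
runnable on a laptop CPU in well under half an hour.

## Known limitations

* The crop anchoring places the eye centers on the crop's top edge; half of
  each eye contour is outside the 256×256 face. The darkened band below the
  eye line plus the ROI boundary carry the signal, but alternative anchors
  (`crop.anchor="face_center"`) keep more of the orbit visible.
* Hard orientation binning makes the descriptor slightly anisotropic
  relative to bilinear-voted HOG; all tests use the hard-assignment
  definition consistently.
* NRI category cut points (1/3, 2/3) are arbitrary in the absence of
  clinically validated risk bands for this score; they are configurable.
* The BP network is intentionally small; no architecture search is done.
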