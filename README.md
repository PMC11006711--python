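# nutriface

Screening for malnutrition from facial photographs. Clinically, loss of
periorbital fat is one of the few facial signs a dietitian scores during a
PG-SGA physical exam: as the orbital fat pads shrink, the eye region takes on
a sunken, darker appearance. `nutriface` implements an image pipeline that
exploits exactly that sign:

1. **Geometry** — given a photograph and 68 facial landmarks, rotate the image
   so the eye centers are horizontal (angle θ of the eye line, rotation about
   the landmark centroid), then crop a square of side D — the distance from
   the eye midpoint to the mouth centroid — split into 30%/40%/30% vertical
   bands, and resample to 256×256.
2. **Features** — Histogram of Oriented Gradients: gamma correction
   (γ = 2.2), centered-difference gradients, 6×6 px cells, 8 signed
   orientation bins of 45° each, L2 block normalization, optional PCA.
3. **Eye weighting** — the aligned face is partitioned into a 6×6 block grid;
   every block that intersects the ocular region of interest (brows down to
   the third nose landmark) has its HOG features multiplied by 4.
4. **Classification** — a back-propagation network (one hidden layer of 64
   logistic units, softmax output, SGD, 50 epochs) predicts three nutrition
   classes derived from the PG-SGA Short Form score: normal (< 2),
   malnourished (2 ≤ s < 5), severe (≥ 5). AdaBoost, ExtraTrees, random
   forest, XGBoost and KNN baselines share the same contract.
5. **Evaluation** — accuracy, sensitivity, specificity, PPV, NPV (on the
   dichotomized problem) and micro-averaged multiclass AUC, each with 95%
   bootstrap CIs; paired model comparison via the DeLong test on correlated
   AUCs, categorical NRI and IDI.

Because clinical photographs cannot ship with a library, a first-class
synthetic generator draws procedural faces with exact landmark annotations, a
periorbital darkening proportional to a latent severity, and correlated
NRS2002 / PG-SGA SF scores — every stage is testable end to end without any
download.

Intended users: researchers in clinical nutrition and medical image analysis
who want a transparent, dependency-light reference implementation of
landmark-normalized HOG screening with region weighting and honest paired
model statistics.

## Worked example

```sh
python examples/05_compare_models.py
```

```
weighted   micro-AUC: 0.818
unweighted micro-AUC: 0.798
delta AUC (dichotomized risk): -0.003, DeLong p = 0.919
NRI: +0.266 (p = 0.0598)
IDI: +0.087 (p = 0.00994)
```

On a 120-subject synthetic cohort the eye-weighted features cross-validate at
micro-AUC 0.818 versus 0.798 unweighted. The IDI of +0.087 says the weighted
model widens the mean predicted-risk gap between malnourished and normal
subjects by about 9 percentage points (p ≈ 0.01); the NRI of +0.266 says a
net quarter of subjects move toward the correct risk category. The DeLong
test on the dichotomized risk is inconclusive at this n — the three tests
measure different things and can disagree on small cohorts.

Other examples: `01_simulate_cohort.py` (cohort and scale-score correlation),
`02_align_and_crop.py` (geometry), `03_feature_variants.py` (descriptors),
`04_crossvalidate.py` (five-fold CV with bootstrap CIs).

A thin CLI wraps the same library calls:

```sh
nutriface simulate --n 60 --seed 3 --out workspace/cohort
nutriface crossval --cohort workspace/cohort --features weighted --out report.json
nutriface compare --cohort workspace/cohort --new weighted --old unweighted --out cmp.json
```

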