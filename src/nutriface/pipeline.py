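"""End-to-end pipelines: preprocess, featurize (per variant), cross-validate.

Three feature variants mirror the model-comparison design:

``ocular``
    the eye ROI (brows to third nose point) cropped from the aligned face,
    resampled to a fixed 48x144 patch, dense HOG;
``face_minus_eyes``
    the aligned face with the eye ROI zeroed, dense HOG on 256x256;
``weighted`` / ``unweighted``
    block-grid HOG over the 6x6 partition, with eye blocks scaled 4x
    (``weighted``) or left at 1x (``unweighted``);
``full``
    plain dense HOG on the aligned face.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from .evaluation import ComparisonResult, compare_models
from .features import HOGConfig, hog_descriptor
from .geometry import AlignedFace, FaceImage, LandmarkSet, align_and_crop, crop_roi, eye_roi, mask_eye_region
from .models import CrossValResult, TrainConfig, cross_validate
from .synthetic import SimSample
from .weighting import weighted_face_features

__all__ = [
    "FEATURE_VARIANTS",
    "OCULAR_PATCH",
    "preprocess",
    "extract_features",
    "featurize_cohort",
    "crossval_cohort",
    "compare_variants",
]

FEATURE_VARIANTS = ("ocular", "face_minus_eyes", "weighted", "unweighted", "full")

OCULAR_PATCH = (48, 144)  # (rows, cols) the ocular crop is resampled to


def preprocess(image: FaceImage, landmarks: LandmarkSet) -> AlignedFace:
    """Rotate to horizontal eyes, crop the 30/40/30 square, resample to 256."""
    return align_and_crop(image, landmarks)


def extract_features(
    face: AlignedFace,
    variant: str = "weighted",
    hog_config: HOGConfig = HOGConfig(),
    eye_weight: float = 4.0,
    grid: int = 6,
) -> np.ndarray:
    """Feature vector for one aligned face under the chosen variant."""
    if variant not in FEATURE_VARIANTS:
        raise ValueError(f"unknown feature variant {variant!r}")
    if variant == "ocular":
        roi = eye_roi(face.landmarks)
        patch = crop_roi(face, roi)
        patch = resize(patch, OCULAR_PATCH, order=1, mode="constant",
                       anti_aliasing=False, preserve_range=True)
        return hog_descriptor(patch, hog_config).values
    if variant == "face_minus_eyes":
        masked = mask_eye_region(face, eye_roi(face.landmarks))
        return hog_descriptor(masked.image, hog_config).values
    if variant == "full":
        return hog_descriptor(face.image, hog_config).values
    w = eye_weight if variant == "weighted" else 1.0
    return weighted_face_features(face, weight=w, n_per_side=grid,
                                  hog_config=hog_config).values


def featurize_cohort(
    samples: list[SimSample],
    variant: str = "weighted",
    hog_config: HOGConfig = HOGConfig(),
    eye_weight: float = 4.0,
    grid: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """(X, y): stacked variant features and three-class labels for a cohort."""
    rows, labels = [], []
    for s in samples:
        face = preprocess(s.image, s.landmarks)
        rows.append(extract_features(face, variant, hog_config, eye_weight, grid))
        labels.append(int(s.label))
    return np.vstack(rows), np.asarray(labels)


def featurize_cohort_pair(
    samples: list[SimSample],
    hog_config: HOGConfig = HOGConfig(),
    eye_weight: float = 4.0,
    grid: int = 6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X_unweighted, X_weighted, y) sharing one block-grid HOG pass.

    The weighted representation is the unweighted one with eye-block
    elements scaled, so computing the block HOG once per face is exact.
    """
    from .weighting import apply_face_eye_weights, block_grid_hog, partition_blocks

    unw, wtd, labels = [], [], []
    for s in samples:
        face = preprocess(s.image, s.landmarks)
        g = partition_blocks(face.image.shape[0], grid)
        fv = block_grid_hog(face, g, hog_config)
        unw.append(fv.values)
        wtd.append(apply_face_eye_weights(fv, g, eye_roi(face.landmarks),
                                          eye_weight).values)
        labels.append(int(s.label))
    return np.vstack(unw), np.vstack(wtd), np.asarray(labels)


def crossval_cohort(
    samples: list[SimSample],
    variant: str = "weighted",
    train_config: TrainConfig | None = None,
    pca_variance: float | None = 0.95,
    bootstrap_B: int = 200,
    features: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> CrossValResult:
    """Stratified five-fold CV of one variant/model combination.

    Precomputed (features, labels) may be passed to avoid re-extracting
    when several models run on the same representation.
    """
    if features is None or labels is None:
        features, labels = featurize_cohort(samples, variant)
    return cross_validate(features, labels, train_config,
                          pca_variance=pca_variance, bootstrap_B=bootstrap_B)


def compare_variants(
    samples: list[SimSample],
    variant_new: str = "weighted",
    variant_old: str = "unweighted",
    train_config: TrainConfig | None = None,
    pca_variance: float | None = 0.95,
) -> tuple[ComparisonResult, CrossValResult, CrossValResult]:
    """Paired DeLong/NRI/IDI between two feature variants.

    Both variants are cross-validated with identical fold assignments
    (same labels, same seed), so the pooled out-of-fold probabilities are
    paired subject by subject.
    """
    cv_new = crossval_cohort(samples, variant_new, train_config, pca_variance)
    cv_old = crossval_cohort(samples, variant_old, train_config, pca_variance)
    cmp = compare_models(cv_new.pooled_probabilities, cv_old.pooled_probabilities,
                         cv_new.labels)
    return cmp, cv_new, cv_old
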