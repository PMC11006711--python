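"""HOG descriptor and PCA dimensionality reduction.

The descriptor follows the classical recipe: gamma correction (default
2.2), centered-difference gradients, orientation histograms over 6x6-pixel
cells with 8 signed bins of 45 degrees each, L2 block normalization over
2x2-cell sliding blocks, row-major concatenation.  Each feature element
carries provenance (cell row, cell column, bin) until PCA discards it, so
downstream block weighting can scale exactly the elements that came from a
given image region.

PCA is ordinary centered principal component analysis; the model is fitted
on training data only and serialized as plain JSON for portability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "HOGConfig",
    "FeatureVector",
    "PCAModel",
    "FeatureError",
    "gamma_normalize",
    "pixel_gradients",
    "cell_histograms",
    "block_normalize_concat",
    "hog_descriptor",
    "hog_length",
    "pca_fit",
    "pca_transform",
]


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class HOGConfig:
    gamma: float = 2.2
    cell_px: int = 6
    n_bins: int = 8
    bin_width_deg: float = 45.0
    block_cells: int = 2
    block_eps: float = 1e-6
    block_stride_cells: int = 1

    def __post_init__(self):
        if self.gamma <= 0:
            raise FeatureError("gamma must be positive")
        if self.cell_px < 2:
            raise FeatureError("cell side must be at least 2 px")
        if abs(self.n_bins * self.bin_width_deg - 360.0) > 1e-9:
            raise FeatureError("n_bins * bin_width_deg must equal 360")
        if self.block_stride_cells < 1 or self.block_cells < 1:
            raise FeatureError("block geometry must be positive")


@dataclass
class FeatureVector:
    """Flat descriptor with optional per-element provenance.

    ``provenance`` is an integer array parallel to ``values``; its meaning
    depends on the producer (dense HOG stores flat cell indices, the
    block-grid extractor stores grid-block ids).
    """

    values: np.ndarray
    provenance: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise FeatureError("feature values must be finite")
        if self.provenance is not None:
            self.provenance = np.asarray(self.provenance)
            if self.provenance.shape != self.values.shape:
                raise FeatureError("provenance must parallel values")

    def __len__(self) -> int:
        return self.values.size


def gamma_normalize(image: np.ndarray, gamma: float = 2.2) -> np.ndarray:
    """Compressive gamma correction ``v -> v**(1/gamma)``, range-preserving."""
    if gamma <= 0:
        raise FeatureError("gamma must be positive")
    img = np.asarray(image, dtype=float)
    return np.power(np.clip(img, 0.0, 1.0), 1.0 / gamma)


def pixel_gradients(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel gradient magnitude and orientation.

    Uses the [-1, 0, 1] centered-difference kernel (one-sided at borders).
    Orientation is the signed angle of (gx, gy) mapped to [0, 360); y grows
    downward, so 90 degrees points down the image.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise FeatureError("gradients require a single-channel image")
    gx = np.empty_like(img)
    gx[:, 1:-1] = img[:, 2:] - img[:, :-2]
    gx[:, 0] = img[:, 1] - img[:, 0]
    gx[:, -1] = img[:, -1] - img[:, -2]
    gy = np.empty_like(img)
    gy[1:-1, :] = img[2:, :] - img[:-2, :]
    gy[0, :] = img[1, :] - img[0, :]
    gy[-1, :] = img[-1, :] - img[-2, :]
    magnitude = np.hypot(gx, gy)
    orientation = np.degrees(np.arctan2(gy, gx)) % 360.0
    return magnitude, orientation


def cell_histograms(
    magnitudes: np.ndarray,
    orientations: np.ndarray,
    config: HOGConfig = HOGConfig(),
) -> np.ndarray:
    """Orientation histograms per cell, shape (rows, cols, n_bins).

    Each pixel votes its full magnitude into the single bin containing its
    orientation (hard assignment).  Remainder pixels beyond the last whole
    cell at the right/bottom edges are dropped.
    """
    if magnitudes.shape != orientations.shape:
        raise FeatureError("magnitude and orientation arrays must share shape")
    h, w = magnitudes.shape
    cp = config.cell_px
    nr, nc = h // cp, w // cp
    if nr == 0 or nc == 0:
        raise FeatureError("image smaller than one cell")
    mag = magnitudes[: nr * cp, : nc * cp]
    ori = orientations[: nr * cp, : nc * cp]
    bins = np.floor_divide(ori, config.bin_width_deg).astype(int) % config.n_bins

    # accumulate with bincount over a combined (cell, bin) index
    cell_r = np.repeat(np.arange(nr), cp)[:, None]
    cell_c = np.repeat(np.arange(nc), cp)[None, :]
    flat_idx = ((cell_r * nc + cell_c) * config.n_bins + bins).ravel()
    hist = np.bincount(flat_idx, weights=mag.ravel(),
                       minlength=nr * nc * config.n_bins)
    return hist.reshape(nr, nc, config.n_bins)


def block_normalize_concat(
    hist: np.ndarray,
    config: HOGConfig = HOGConfig(),
) -> FeatureVector:
    """L2-normalize sliding cell blocks and concatenate them row-major.

    For a (R, C, B) cell grid with ``k``-cell blocks and stride ``s`` the
    output length is ``((R-k)//s + 1) * ((C-k)//s + 1) * k^2 * B``.
    Provenance records, per element, the flat index ``r * C + c`` of the
    cell the element's histogram came from.
    """
    R, C, B = hist.shape
    k, s = config.block_cells, config.block_stride_cells
    if R < k or C < k:
        raise FeatureError("cell grid smaller than one block")
    nbr = (R - k) // s + 1
    nbc = (C - k) // s + 1

    # gather blocks: shape (nbr, nbc, k, k, B)
    r_idx = (np.arange(nbr) * s)[:, None] + np.arange(k)[None, :]
    c_idx = (np.arange(nbc) * s)[:, None] + np.arange(k)[None, :]
    blocks = hist[r_idx[:, None, :, None], c_idx[None, :, None, :], :]
    flat = blocks.reshape(nbr, nbc, -1)
    norms = np.linalg.norm(flat, axis=-1, keepdims=True)
    normalized = flat / (norms + config.block_eps)

    cell_ids = (r_idx[:, None, :, None] * C + c_idx[None, :, None, :])
    prov = np.broadcast_to(cell_ids[..., None], blocks.shape).reshape(-1)
    return FeatureVector(values=normalized.ravel(), provenance=prov.copy())


def hog_descriptor(image: np.ndarray, config: HOGConfig = HOGConfig()) -> FeatureVector:
    """Full dense HOG pipeline: gamma -> gradients -> cells -> blocks."""
    img = gamma_normalize(image, config.gamma)
    mag, ori = pixel_gradients(img)
    hist = cell_histograms(mag, ori, config)
    return block_normalize_concat(hist, config)


def hog_length(height: int, width: int, config: HOGConfig = HOGConfig()) -> int:
    """Closed-form descriptor length for an image of the given size."""
    nr, nc = height // config.cell_px, width // config.cell_px
    k, s = config.block_cells, config.block_stride_cells
    if nr < k or nc < k:
        raise FeatureError("image too small for one block")
    nbr = (nr - k) // s + 1
    nbc = (nc - k) // s + 1
    return nbr * nbc * k * k * config.n_bins


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAModel:
    """Serializable PCA: mean, orthonormal components, variance fractions."""

    mean: np.ndarray
    components: np.ndarray  # (n_components, n_features)
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "mean": self.mean.tolist(),
                    "components": self.components.tolist(),
                    "explained_variance_ratio": self.explained_variance_ratio.tolist(),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "PCAModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            mean=np.asarray(d["mean"], dtype=float),
            components=np.asarray(d["components"], dtype=float),
            explained_variance_ratio=np.asarray(d["explained_variance_ratio"], dtype=float),
        )


def pca_fit(
    features: np.ndarray,
    variance_target: float | None = 0.95,
    n_components: int | None = None,
) -> PCAModel:
    """Fit PCA on a (n_samples, n_features) matrix.

    With ``variance_target`` (default 0.95) the number of components is the
    smallest k whose cumulative explained-variance fraction reaches the
    target, capped at min(n_samples - 1, n_features).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise FeatureError("PCA needs a 2-D matrix with at least 2 samples")
    if not np.any(np.std(X, axis=0) > 0):
        raise FeatureError("degenerate data: zero variance in every feature")
    cap = min(X.shape[0] - 1, X.shape[1])
    p = PCA(n_components=cap, svd_solver="full")
    p.fit(X)
    if n_components is not None:
        k = min(n_components, cap)
    else:
        cum = np.cumsum(p.explained_variance_ratio_)
        k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
        k = min(k, cap)
    return PCAModel(
        mean=p.mean_.copy(),
        components=p.components_[:k].copy(),
        explained_variance_ratio=p.explained_variance_ratio_[:k].copy(),
    )


def pca_transform(model: PCAModel, features: np.ndarray) -> np.ndarray:
    """Project (n, p) or (p,) features onto the model's components."""
    X = np.asarray(features, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.mean.size:
        raise FeatureError(
            f"feature length {X.shape[1]} does not match model ({model.mean.size})"
        )
    out = (X - model.mean) @ model.components.T
    return out[0] if single else out
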