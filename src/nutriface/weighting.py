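"""Face-eye weighted features: 6x6 block partition and 4x eye weighting.

The weighted variant partitions the aligned 256x256 face into a 6x6 grid,
extracts HOG features per grid block (block-local cells, so provenance is
exact), and multiplies every feature element originating from a block that
overlaps the ocular ROI by a weight (default 4); all other elements keep
weight 1.  Weighting happens on feature values, before PCA and training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .features import FeatureVector, HOGConfig, hog_descriptor
from .geometry import AlignedFace, Rect, eye_roi

__all__ = [
    "BlockGrid",
    "WeightMap",
    "partition_blocks",
    "block_is_eye",
    "apply_face_eye_weights",
    "block_grid_hog",
    "weighted_face_features",
]

DEFAULT_EYE_WEIGHT = 4.0
DEFAULT_GRID = 6


@dataclass(frozen=True)
class BlockGrid:
    """n x n rectangular tiling of a square image, row-major block order."""

    image_side: int
    n_per_side: int
    blocks: tuple[Rect, ...]

    def __len__(self) -> int:
        return len(self.blocks)


@dataclass(frozen=True)
class WeightMap:
    """Per-block multiplicative weights (eye blocks vs. the rest)."""

    grid: BlockGrid
    block_weights: np.ndarray  # (n_blocks,) positive floats

    def __post_init__(self):
        w = np.asarray(self.block_weights, dtype=float)
        if w.shape != (len(self.grid),):
            raise ValueError("one weight per block required")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        object.__setattr__(self, "block_weights", w)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "image_side": self.grid.image_side,
                    "n_per_side": self.grid.n_per_side,
                    "block_weights": self.block_weights.tolist(),
                },
                fh,
            )


def partition_blocks(image_side: int, n_per_side: int = DEFAULT_GRID) -> BlockGrid:
    """Tile a square image into n x n near-equal blocks.

    Block side is ``image_side // n``; remainder pixels are absorbed by the
    last row/column so the tiling is exact (disjoint, covering).
    """
    if n_per_side <= 0:
        raise ValueError("n_per_side must be positive")
    if image_side < n_per_side:
        raise ValueError("image smaller than the block grid")
    step = image_side // n_per_side
    edges = [i * step for i in range(n_per_side)] + [image_side]
    blocks = []
    for r in range(n_per_side):
        for c in range(n_per_side):
            blocks.append(Rect(edges[c], edges[r], edges[c + 1], edges[r + 1]))
    return BlockGrid(image_side=image_side, n_per_side=n_per_side, blocks=tuple(blocks))


def block_is_eye(block: Rect, roi: Rect) -> bool:
    """Eye membership: any positive-area intersection with the ocular ROI."""
    return block.intersects(roi)


def make_weight_map(grid: BlockGrid, roi: Rect, weight: float = DEFAULT_EYE_WEIGHT) -> WeightMap:
    w = np.array([weight if block_is_eye(b, roi) else 1.0 for b in grid.blocks])
    return WeightMap(grid=grid, block_weights=w)


def block_grid_hog(
    face: AlignedFace,
    grid: BlockGrid | None = None,
    hog_config: HOGConfig = HOGConfig(),
) -> FeatureVector:
    """HOG computed independently per grid block, concatenated row-major.

    Provenance stores the grid-block id of every element, so weighting can
    target exactly the elements derived from eye blocks.
    """
    if grid is None:
        grid = partition_blocks(face.image.shape[0])
    parts, provs = [], []
    for bid, rect in enumerate(grid.blocks):
        patch = face.image[int(rect.top):int(rect.bottom), int(rect.left):int(rect.right)]
        fv = hog_descriptor(patch, hog_config)
        parts.append(fv.values)
        provs.append(np.full(fv.values.size, bid, dtype=int))
    return FeatureVector(values=np.concatenate(parts), provenance=np.concatenate(provs))


def apply_face_eye_weights(
    features: FeatureVector,
    grid: BlockGrid,
    roi: Rect,
    weight: float = DEFAULT_EYE_WEIGHT,
) -> FeatureVector:
    """Scale feature elements from eye-overlapping blocks by ``weight``.

    Requires block provenance (as produced by :func:`block_grid_hog`).
    Length and element order are unchanged.
    """
    if features.provenance is None:
        raise ValueError("features lack block provenance; use block_grid_hog")
    wm = make_weight_map(grid, roi, weight)
    scaled = features.values * wm.block_weights[features.provenance]
    return FeatureVector(values=scaled, provenance=features.provenance.copy())


def weighted_face_features(
    face: AlignedFace,
    weight: float = DEFAULT_EYE_WEIGHT,
    n_per_side: int = DEFAULT_GRID,
    hog_config: HOGConfig = HOGConfig(),
) -> FeatureVector:
    """Convenience: block-grid HOG with eye blocks up-weighted.

    The ocular ROI comes from the face's own aligned landmarks; pass
    ``weight=1`` for the unweighted counterpart of the same representation.
    """
    grid = partition_blocks(face.image.shape[0], n_per_side)
    roi = eye_roi(face.landmarks)
    fv = block_grid_hog(face, grid, hog_config)
    if weight == 1.0:
        return fv
    return apply_face_eye_weights(fv, grid, roi, weight)
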