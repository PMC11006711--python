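"""Face alignment and cropping from 68-point landmarks.

The canonical preprocessing turns an arbitrary face photograph plus its
68 facial key points into an aligned, cropped, 256x256 grayscale face:

1. the eye centers (mean of each eye's six contour points) define a line
   whose angle with the horizontal is removed by rotating the image about
   the overall face center (mean of all 68 landmarks);
2. the crop is a square of side D, where D is the distance from the
   midpoint of the two eye centers to the mouth centroid, split into
   30% / 40% / 30% vertical bands with the middle band centered on that
   eye-to-mouth segment;
3. the crop is resampled to 256x256.

Coordinates are 0-based image coordinates: x = column, y = row, y grows
downward.  Rectangles are half-open ``[left, right) x [top, bottom)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import EuclideanTransform, resize, warp

__all__ = [
    "Landmark",
    "LandmarkSet",
    "FaceImage",
    "AlignedFace",
    "Rect",
    "ALIGNED_SIDE",
    "GeometryError",
    "DegenerateGeometryError",
    "eye_centers",
    "alignment_angle",
    "align_face",
    "crop_and_normalize",
    "align_and_crop",
    "eye_roi",
    "mask_eye_region",
    "load_landmarks",
    "save_landmarks",
]

ALIGNED_SIDE = 256

# 68-point scheme index groups (0-based)
CONTOUR = slice(0, 17)
LEFT_BROW = slice(17, 22)
RIGHT_BROW = slice(22, 27)
NOSE = slice(27, 36)
LEFT_EYE = slice(36, 42)
RIGHT_EYE = slice(42, 48)
MOUTH = slice(48, 68)

#: index of the "third point of the nose" used as the ocular ROI bottom
NOSE_THIRD_POINT = 29


class GeometryError(ValueError):
    """Structural problem with landmarks or image."""


class DegenerateGeometryError(GeometryError):
    """Geometry collapses (coincident eye centers, zero face height, ...)."""


@dataclass(frozen=True)
class Landmark:
    x: float
    y: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class LandmarkSet:
    """Exactly 68 facial key points in image coordinates."""

    points: np.ndarray  # (68, 2) float array, columns (x, y)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (68, 2):
            raise GeometryError(f"expected 68 (x, y) landmarks, got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise GeometryError("landmarks must be finite")
        if pts[LEFT_EYE, 0].mean() >= pts[RIGHT_EYE, 0].mean():
            raise GeometryError("left eye must lie left of right eye in image coordinates")
        object.__setattr__(self, "points", pts)

    def __getitem__(self, idx) -> np.ndarray:
        return self.points[idx]

    @property
    def face_center(self) -> np.ndarray:
        """Overall face center: unweighted mean of all 68 points."""
        return self.points.mean(axis=0)

    @property
    def mouth_center(self) -> np.ndarray:
        """Centroid of the 20 mouth landmarks (indices 48-67)."""
        return self.points[MOUTH].mean(axis=0)

    def transformed(self, fn) -> "LandmarkSet":
        return LandmarkSet(fn(self.points.copy()))


@dataclass(frozen=True)
class FaceImage:
    """Grayscale or RGB intensity image with values in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim == 3 and px.shape[2] not in (1, 3):
            raise GeometryError(f"expected 1 or 3 channels, got {px.shape[2]}")
        if px.ndim not in (2, 3):
            raise GeometryError("image must be HxW or HxWxC")
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise GeometryError("image must be at least 64x64")
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise GeometryError("intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", np.clip(px, 0.0, 1.0))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def to_gray(self) -> np.ndarray:
        """Single-channel luminance (Rec. 601 weights for RGB input)."""
        px = self.pixels
        if px.ndim == 2:
            return px
        if px.shape[2] == 1:
            return px[:, :, 0]
        return px @ np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class Rect:
    """Half-open axis-aligned rectangle [left, right) x [top, bottom)."""

    left: float
    top: float
    right: float
    bottom: float

    def __post_init__(self):
        if not (self.right > self.left and self.bottom > self.top):
            raise DegenerateGeometryError(
                f"degenerate rectangle: ({self.left}, {self.top}, {self.right}, {self.bottom})"
            )

    @property
    def width(self) -> float:
        return self.right - self.left

    @property
    def height(self) -> float:
        return self.bottom - self.top

    def intersects(self, other: "Rect") -> bool:
        """True iff the open intersection has positive area."""
        return (
            min(self.right, other.right) > max(self.left, other.left)
            and min(self.bottom, other.bottom) > max(self.top, other.top)
        )


@dataclass(frozen=True)
class AlignedFace:
    """Rotation-corrected 256x256 grayscale face plus transformed landmarks."""

    image: np.ndarray
    landmarks: LandmarkSet
    rotation_deg: float = 0.0
    crop_rect: Rect | None = None

    def __post_init__(self):
        img = np.asarray(self.image, dtype=float)
        if img.shape != (ALIGNED_SIDE, ALIGNED_SIDE):
            raise GeometryError(f"aligned face must be {ALIGNED_SIDE}x{ALIGNED_SIDE}")
        object.__setattr__(self, "image", np.clip(img, 0.0, 1.0))


def eye_centers(landmarks: LandmarkSet) -> tuple[Landmark, Landmark]:
    """Arithmetic mean of each eye's six contour points."""
    lc = landmarks[LEFT_EYE].mean(axis=0)
    rc = landmarks[RIGHT_EYE].mean(axis=0)
    return Landmark(*lc), Landmark(*rc)


def alignment_angle(left_center: Landmark, right_center: Landmark) -> float:
    """Signed angle (degrees) of the left-to-right eye line vs. horizontal.

    Positive when the right eye sits lower (larger y) than the left, i.e.
    the face is tilted clockwise on screen.  Range (-90, 90].
    """
    dx = right_center.x - left_center.x
    dy = right_center.y - left_center.y
    if dx == 0 and dy == 0:
        raise DegenerateGeometryError("coincident eye centers")
    theta = np.degrees(np.arctan2(dy, dx))
    if theta <= -90:
        theta += 180.0
    elif theta > 90:
        theta -= 180.0
    return float(theta)


def _rotation_matrix(theta_deg: float) -> np.ndarray:
    """Matrix applying rotation by -theta to (x, y) row vectors.

    With y growing downward, this sends the left->right eye vector at
    angle theta onto the horizontal axis.
    """
    t = np.radians(theta_deg)
    c, s = np.cos(t), np.sin(t)
    # column-vector form of R(-theta) in y-down coordinates: sends the
    # left->right eye vector at angle theta onto (+x, 0)
    return np.array([[c, s], [-s, c]])


def rotate_points(points: np.ndarray, theta_deg: float, center: np.ndarray) -> np.ndarray:
    """Rigid rotation of (n, 2) points by -theta about ``center``."""
    R = _rotation_matrix(theta_deg)
    return (points - center) @ R.T + center


def align_face(image: FaceImage, landmarks: LandmarkSet) -> tuple[FaceImage, LandmarkSet]:
    """Rotate image and landmarks so the eye centers become horizontal.

    The rotation center is the overall face center; pixels swept in from
    outside the canvas are zero-padded.
    """
    lc, rc = eye_centers(landmarks)
    theta = alignment_angle(lc, rc)
    center = landmarks.face_center
    gray = image.to_gray()

    new_pts = rotate_points(landmarks.points, theta, center)

    # warp() maps output coords through the given transform into the input,
    # so pass the inverse of the point rotation: p_in = R(theta) (p_out - c) + c
    t = np.radians(theta)
    c, s = np.cos(t), np.sin(t)
    fwd = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])  # R(-theta)
    shift = np.eye(3)
    shift[:2, 2] = -center
    unshift = np.eye(3)
    unshift[:2, 2] = center
    inverse = np.linalg.inv(unshift @ fwd @ shift)
    rotated = warp(gray, EuclideanTransform(matrix=inverse), order=1, cval=0.0,
                   preserve_range=True)
    return FaceImage(np.clip(rotated, 0, 1)), LandmarkSet(new_pts)


def crop_and_normalize(
    image: FaceImage,
    landmarks: LandmarkSet,
    rotation_deg: float = 0.0,
    anchor: str = "segment_midpoint",
) -> AlignedFace:
    """Crop the 30/40/30-band square around the face and resample to 256x256.

    Let D be the distance from the midpoint of the eye centers to the mouth
    centroid.  The crop is a DxD square: three vertical bands of heights
    0.3 D / 0.4 D / 0.3 D, the square centered horizontally on the face
    center.  Vertically, the middle band is centered on the midpoint of the
    eye-midpoint-to-mouth-centroid segment (``anchor="segment_midpoint"``),
    or the whole square on the face center (``anchor="face_center"``).
    Out-of-canvas pixels are zero-padded.
    """
    lc, rc = eye_centers(landmarks)
    eye_mid = (lc.as_array() + rc.as_array()) / 2.0
    mouth = landmarks.mouth_center
    D = float(np.linalg.norm(eye_mid - mouth))
    if D <= 0:
        raise DegenerateGeometryError("eye midpoint coincides with mouth centroid")

    cx = landmarks.face_center[0]
    if anchor == "segment_midpoint":
        anchor_y = (eye_mid[1] + mouth[1]) / 2.0  # center of the middle band
    elif anchor == "face_center":
        anchor_y = landmarks.face_center[1]
    else:
        raise GeometryError(f"unknown crop anchor {anchor!r}")
    left = cx - D / 2.0
    top = anchor_y - D / 2.0  # 0.2 D (half middle band) + 0.3 D (top band)
    rect = Rect(left, top, left + D, top + D)

    gray = image.to_gray()
    # sample the crop on a 256x256 grid directly (bilinear), zero outside
    side_px = max(int(round(D)), 1)
    r0, c0 = int(np.floor(top)), int(np.floor(left))
    pad_crop = np.zeros((side_px, side_px))
    rr = np.arange(r0, r0 + side_px)
    cc = np.arange(c0, c0 + side_px)
    rin = (rr >= 0) & (rr < gray.shape[0])
    cin = (cc >= 0) & (cc < gray.shape[1])
    pad_crop[np.ix_(rin, cin)] = gray[np.ix_(rr[rin], cc[cin])]
    out = resize(pad_crop, (ALIGNED_SIDE, ALIGNED_SIDE), order=1, mode="constant",
                 cval=0.0, anti_aliasing=False, preserve_range=True)

    scale = ALIGNED_SIDE / side_px
    new_pts = (landmarks.points - np.array([c0, r0])) * scale
    return AlignedFace(
        image=np.clip(out, 0, 1),
        landmarks=LandmarkSet(new_pts),
        rotation_deg=rotation_deg,
        crop_rect=rect,
    )


def align_and_crop(image: FaceImage, landmarks: LandmarkSet) -> AlignedFace:
    """Full canonicalization: rotate to horizontal eyes, then crop/resize."""
    lc, rc = eye_centers(landmarks)
    theta = alignment_angle(lc, rc)
    rot_img, rot_pts = align_face(image, landmarks)
    return crop_and_normalize(rot_img, rot_pts, rotation_deg=theta)


def eye_roi(landmarks: LandmarkSet, nose_point: int = NOSE_THIRD_POINT) -> Rect:
    """Ocular region of interest from brows and nose.

    Left edge: leftmost left-brow point; right edge: rightmost right-brow
    point; top: topmost brow point; bottom: y of the third nose landmark.
    """
    pts = landmarks.points
    left = float(pts[LEFT_BROW, 0].min())
    right = float(pts[RIGHT_BROW, 0].max())
    top = float(pts[17:27, 1].min())
    bottom = float(pts[nose_point, 1])
    if bottom <= top:
        raise DegenerateGeometryError("nose reference point lies above the brows")
    return Rect(left, top, right, bottom)


def mask_eye_region(face: AlignedFace, roi: Rect) -> AlignedFace:
    """Zero out the pixels inside the ocular ROI (full-face-minus-eyes variant).

    Masking (rather than removing rows) keeps the 256x256 grid so feature
    dimensionality is identical across variants.  Idempotent.
    """
    img = face.image.copy()
    t = max(int(np.floor(roi.top)), 0)
    b = min(int(np.ceil(roi.bottom)), ALIGNED_SIDE)
    l = max(int(np.floor(roi.left)), 0)
    r = min(int(np.ceil(roi.right)), ALIGNED_SIDE)
    img[t:b, l:r] = 0.0
    return replace(face, image=img)


def crop_roi(face: AlignedFace, roi: Rect) -> np.ndarray:
    """Extract the ROI pixels (clipped to the image) as a 2-D array."""
    t = max(int(np.floor(roi.top)), 0)
    b = min(int(np.ceil(roi.bottom)), ALIGNED_SIDE)
    l = max(int(np.floor(roi.left)), 0)
    r = min(int(np.ceil(roi.right)), ALIGNED_SIDE)
    return face.image[t:b, l:r]


# ---------------------------------------------------------------------------
# landmark file I/O

def load_landmarks(path) -> LandmarkSet:
    """Read a landmark file: JSON array of 68 [x, y] pairs, or CSV index,x,y."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            data = json.load(fh)
        pts = np.asarray(data, dtype=float)
    else:
        import pandas as pd

        df = pd.read_csv(path)
        required = {"index", "x", "y"}
        if not required.issubset(df.columns):
            raise GeometryError(f"landmark CSV must have columns {sorted(required)}")
        df = df.sort_values("index")
        if not np.array_equal(df["index"].to_numpy(), np.arange(68)):
            raise GeometryError("landmark CSV must contain indices 0..67 exactly once")
        pts = df[["x", "y"]].to_numpy(dtype=float)
    return LandmarkSet(pts)


def save_landmarks(landmarks: LandmarkSet, path) -> None:
    with open(path, "w") as fh:
        json.dump([[float(x), float(y)] for x, y in landmarks.points], fh)
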