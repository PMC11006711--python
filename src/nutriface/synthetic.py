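"""Synthetic face cohorts for end-to-end pipeline testing.

Each sample is a procedural face drawn from exact landmark geometry: a
filled head ellipse, brow arcs, hexagonal eye contours, a nose polyline
and a mouth ellipse, rendered at a randomized in-plane rotation, scale and
offset.  The malnutrition signal emulates periorbital volume loss as an
intensity decrease (darkening) of the ocular region, proportional to a
latent severity in [0, 1].  The questionnaire scores are driven by the
same severity: PG-SGA SF = round(20 * severity + noise) and NRS2002 =
round(7 * (rho * severity + sqrt(1 - rho^2) * u)), giving a controllable
Pearson correlation between the two scales.

The signal is intensity-based rather than shape-based: HOG responds to
the gradient step at the darkened region's boundary, which is what makes
ocular-vs-rest feature comparisons meaningful at synthetic scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import FaceImage, LandmarkSet, eye_roi, rotate_points
from .labeling import COHORT_COLUMNS, NutritionClass, assign_class

__all__ = ["SimConfig", "SimSample", "generate_face", "generate_cohort", "write_cohort"]


@dataclass(frozen=True)
class SimConfig:
    n: int = 200
    effect_size: float = 0.3      # periorbital darkening per unit severity
    noise_sd: float = 0.05        # Gaussian pixel noise
    target_r: float = 0.8         # Pearson target for (NRS2002, PG-SGA SF)
    image_side: int = 320
    seed: int = 0
    max_rotation_deg: float = 12.0
    jitter: float = 0.02          # translation jitter, fraction of side
    scale_jitter: float = 0.05    # +/- relative scale jitter
    score_noise_sd: float = 1.5   # PG-SGA SF score noise (score units)
    # label-independent nuisance outside the eye region (expression and
    # shading variation real photographs always carry)
    severity_dist: str = "balanced"  # "balanced" (case-control style) or "uniform"
    mouth_jitter: bool = True     # random mouth openness and vertical shift
    n_shadow_blobs: int = 3       # soft cheek/chin shadows per face
    shadow_amp: float = 0.15      # max shadow depth, intensity units
    illum_grad: float = 0.1       # max linear illumination tilt across the face

    def __post_init__(self):
        if self.n < 1 or self.effect_size < 0 or self.noise_sd < 0:
            raise ValueError("invalid simulation config")
        if not 0.0 <= self.target_r <= 1.0:
            raise ValueError("target_r must be in [0, 1]")


@dataclass
class SimSample:
    subject_id: str
    image: FaceImage
    landmarks: LandmarkSet
    severity: float
    nrs2002: int
    pgsga_sf: int
    group: str
    label: NutritionClass = field(init=False)

    def __post_init__(self):
        self.label = assign_class(self.pgsga_sf)


# ---------------------------------------------------------------------------
# canonical face template (unit coordinates, x right, y down)

_HEAD_CENTER = (0.50, 0.52)
_HEAD_AXES = (0.24, 0.30)

_EYE_RX, _EYE_RY = 0.035, 0.018
_LEFT_EYE_C = (0.42, 0.40)
_RIGHT_EYE_C = (0.58, 0.40)


def _template_landmarks() -> np.ndarray:
    pts = np.zeros((68, 2))
    # contour 0-16: lower half of the head ellipse, left ear -> chin -> right
    t = np.radians(np.linspace(180, 0, 17))
    pts[0:17, 0] = _HEAD_CENTER[0] + _HEAD_AXES[0] * np.cos(t)
    pts[0:17, 1] = _HEAD_CENTER[1] + _HEAD_AXES[1] * np.sin(t)
    # brows 17-21 / 22-26: shallow arcs above each eye
    for sl, cx in ((slice(17, 22), _LEFT_EYE_C[0]), (slice(22, 27), _RIGHT_EYE_C[0])):
        xs = np.linspace(cx - 0.06, cx + 0.06, 5)
        pts[sl, 0] = xs
        pts[sl, 1] = 0.345 - 0.012 * np.sin(np.linspace(0, np.pi, 5))
    # nose 27-35: bridge (27-30) then nostril row (31-35)
    pts[27:31, 0] = 0.50
    pts[27:31, 1] = np.linspace(0.41, 0.515, 4)
    pts[31:36, 0] = np.linspace(0.46, 0.54, 5)
    pts[31:36, 1] = 0.545
    # eyes 36-41 / 42-47: hexagonal contours (symmetric angles -> exact center)
    hexa = np.radians(np.array([180, 120, 60, 0, 300, 240]))
    for sl, (cx, cy) in ((slice(36, 42), _LEFT_EYE_C), (slice(42, 48), _RIGHT_EYE_C)):
        pts[sl, 0] = cx + _EYE_RX * np.cos(hexa)
        pts[sl, 1] = cy + _EYE_RY * np.sin(hexa)
    # mouth 48-67: 20-point ellipse (centroid = center exactly)
    a = 2 * np.pi * np.arange(20) / 20
    pts[48:68, 0] = 0.50 + 0.07 * np.cos(a)
    pts[48:68, 1] = 0.72 + 0.028 * np.sin(a)
    return pts


def _feature_segments(pts: np.ndarray) -> np.ndarray:
    """Line segments (n, 2, 2) for the drawn facial features."""
    segs = []

    def polyline(idx, closed=False):
        idx = list(idx)
        if closed:
            idx = idx + [idx[0]]
        for a, b in zip(idx[:-1], idx[1:]):
            segs.append((pts[a], pts[b]))

    polyline(range(17, 22))            # left brow
    polyline(range(22, 27))            # right brow
    polyline(range(27, 31))            # nose bridge
    polyline(range(31, 36))            # nostril row
    polyline(range(36, 42), closed=True)   # left eye
    polyline(range(42, 48), closed=True)   # right eye
    polyline(range(48, 68), closed=True)   # mouth
    return np.asarray(segs)


def _segment_distance(px: np.ndarray, py: np.ndarray, segs: np.ndarray) -> np.ndarray:
    """Min distance from each pixel to any segment (vectorized)."""
    P = np.stack([px.ravel(), py.ravel()], axis=1)  # (m, 2)
    best = np.full(P.shape[0], np.inf)
    for (a, b) in segs:
        ab = b - a
        denom = float(ab @ ab)
        ap = P - a
        t = np.clip((ap @ ab) / denom, 0.0, 1.0) if denom > 0 else 0.0
        proj = a + np.outer(t, ab) if denom > 0 else np.broadcast_to(a, P.shape)
        d = np.linalg.norm(P - proj, axis=1)
        np.minimum(best, d, out=best)
    return best.reshape(px.shape)


BACKGROUND = 0.15
FACE_TONE = 0.75
LINE_DELTA = 0.12
LINE_WIDTH = 1.5  # pixels


def generate_face(
    severity: float,
    config: SimConfig = SimConfig(),
    rng: np.random.Generator | None = None,
) -> tuple[FaceImage, LandmarkSet]:
    """Draw one face with its landmarks; darker eye region as severity grows.

    Deterministic given (severity, config, rng state).  Landmarks coincide
    exactly with the drawn primitives; the periorbital ROI (the region the
    geometry module derives from brows and nose) has its intensity lowered
    by ``effect_size * severity``.
    """
    if severity < 0:
        raise ValueError("severity must be non-negative")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    S = config.image_side

    pts = _template_landmarks()
    if config.mouth_jitter:
        # expression nuisance: mouth opens/closes and drifts vertically,
        # independent of severity
        mouth_c = pts[48:68].mean(axis=0)
        pts[48:68, 1] = mouth_c[1] + (pts[48:68, 1] - mouth_c[1]) * rng.uniform(0.6, 1.8)
        pts[48:68, 1] += rng.uniform(-0.02, 0.02)
    center = np.array([0.5, 0.52])
    scale = 1.0 + rng.uniform(-config.scale_jitter, config.scale_jitter)
    shift = rng.uniform(-config.jitter, config.jitter, size=2)
    pts = (pts - center) * scale + center + shift
    head_c = (np.asarray(_HEAD_CENTER) - center) * scale + center + shift
    head_ax = np.asarray(_HEAD_AXES) * scale

    pts_px = pts * S
    head_c_px, head_ax_px = head_c * S, head_ax * S
    roi = eye_roi(LandmarkSet(pts_px))  # canonical-frame signal region

    phi = rng.uniform(-config.max_rotation_deg, config.max_rotation_deg)
    face_center = pts_px.mean(axis=0)
    out_pts = rotate_points(pts_px, -phi, face_center)

    # render by inverse-mapping every output pixel into the canonical frame
    yy, xx = np.mgrid[0:S, 0:S]
    P_out = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
    P_can = rotate_points(P_out, phi, face_center)
    cx, cy = P_can[:, 0].reshape(S, S), P_can[:, 1].reshape(S, S)

    img = np.full((S, S), BACKGROUND)
    inside_head = (
        ((cx - head_c_px[0]) / head_ax_px[0]) ** 2
        + ((cy - head_c_px[1]) / head_ax_px[1]) ** 2
    ) <= 1.0
    img[inside_head] = FACE_TONE

    # feature lines only need evaluating near the head
    r0 = max(int(head_c_px[1] - head_ax_px[1] - 4), 0)
    r1 = min(int(head_c_px[1] + head_ax_px[1] + 4), S)
    segs = _feature_segments(pts_px)
    # restrict to pixels whose canonical y falls inside the head band
    band = (cy >= r0) & (cy <= r1) & inside_head
    d = np.full((S, S), np.inf)
    d[band] = _segment_distance(cx[band], cy[band], segs)
    img[d <= LINE_WIDTH / 2] -= LINE_DELTA

    # shading nuisance: soft shadow blobs on the lower face and a linear
    # illumination tilt, both independent of severity
    if config.n_shadow_blobs > 0 and config.shadow_amp > 0:
        for _ in range(config.n_shadow_blobs):
            bx = head_c_px[0] + rng.uniform(-0.6, 0.6) * head_ax_px[0]
            by = head_c_px[1] + rng.uniform(0.1, 0.8) * head_ax_px[1]
            sigma = rng.uniform(0.02, 0.05) * S
            amp = rng.uniform(0.0, config.shadow_amp)
            img -= amp * np.exp(-((cx - bx) ** 2 + (cy - by) ** 2) / (2 * sigma**2))
    if config.illum_grad > 0:
        gx, gy = rng.uniform(-config.illum_grad, config.illum_grad, size=2)
        img = img + gx * (cx - 0.5 * S) / S + gy * (cy - 0.5 * S) / S

    # periorbital darkening in the canonical ROI
    dark = (
        (cx >= roi.left) & (cx < roi.right) & (cy >= roi.top) & (cy < roi.bottom)
    )
    img[dark] -= config.effect_size * float(severity)

    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    return FaceImage(np.clip(img, 0.0, 1.0)), LandmarkSet(out_pts)


def _severity_to_scores(
    severity: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    rho = config.target_r
    e1 = rng.normal(0.0, config.score_noise_sd, size=severity.size)
    pgsga = np.clip(np.round(20.0 * severity + e1), 0, 20).astype(int)
    u = rng.uniform(0.0, 1.0, size=severity.size)
    latent = rho * severity + np.sqrt(max(1.0 - rho**2, 0.0)) * u
    nrs = np.clip(np.round(7.0 * latent), 0, 7).astype(int)
    return nrs, pgsga


def _draw_severity(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Latent severity sample.

    ``balanced`` (default) draws the three nutrition classes with equal
    probability and severity uniformly within each class's preimage under
    the PG-SGA SF mapping (cut points 2 and 5 on the 0-20 scale, i.e.
    severity 0.1 and 0.25) — a case-control style cohort in which chance
    discrimination corresponds to micro-AUC 0.5.  ``uniform`` draws
    severity ~ Uniform(0, 1), giving a cohort dominated by severe cases.
    """
    if config.severity_dist == "uniform":
        return rng.uniform(0.0, 1.0, size=config.n)
    if config.severity_dist != "balanced":
        raise ValueError(f"unknown severity_dist {config.severity_dist!r}")
    bounds = np.array([[0.0, 0.1], [0.1, 0.25], [0.25, 1.0]])
    cls = rng.integers(0, 3, size=config.n)
    lo, hi = bounds[cls, 0], bounds[cls, 1]
    return lo + rng.uniform(0.0, 1.0, size=config.n) * (hi - lo)


def generate_cohort(config: SimConfig = SimConfig()) -> list[SimSample]:
    """Simulate a cohort: faces, landmarks and correlated scale scores.

    Labels follow the 2.0/5.0 PG-SGA SF thresholds; images come from
    :func:`generate_face`.  Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    severity = _draw_severity(config, rng)
    nrs, pgsga = _severity_to_scores(severity, config, rng)
    groups = rng.choice(
        ["cancer_inpatient", "other_inpatient", "normal_control"],
        size=config.n,
        p=[0.5, 0.4, 0.1],
    )
    samples = []
    for i in range(config.n):
        img, lm = generate_face(float(severity[i]), config, rng)
        samples.append(
            SimSample(
                subject_id=f"S{i:04d}",
                image=img,
                landmarks=lm,
                severity=float(severity[i]),
                nrs2002=int(nrs[i]),
                pgsga_sf=int(pgsga[i]),
                group=str(groups[i]),
            )
        )
    return samples


def cohort_table(samples: list[SimSample], image_dir: str = "") -> pd.DataFrame:
    rows = []
    for s in samples:
        prefix = f"{image_dir}/" if image_dir else ""
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "nrs2002": s.nrs2002,
                "pgsga_sf": s.pgsga_sf,
                "image_path": f"{prefix}{s.subject_id}.png" if image_dir else "",
                "landmark_path": f"{prefix}{s.subject_id}.json" if image_dir else "",
            }
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort(samples: list[SimSample], out_dir, config: SimConfig | None = None) -> None:
    """Persist a cohort: PNG images, landmark JSONs, cohort CSV, manifest."""
    import json
    from pathlib import Path

    from PIL import Image

    from .geometry import save_landmarks

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "landmarks").mkdir(parents=True, exist_ok=True)
    for s in samples:
        arr = (s.image.to_gray() * 255).round().astype(np.uint8)
        Image.fromarray(arr).save(out / "images" / f"{s.subject_id}.png")
        save_landmarks(s.landmarks, out / "landmarks" / f"{s.subject_id}.json")
    df = cohort_table(samples)
    df["image_path"] = [f"images/{s.subject_id}.png" for s in samples]
    df["landmark_path"] = [f"landmarks/{s.subject_id}.json" for s in samples]
    df.to_csv(out / "cohort.csv", index=False)
    if config is not None:
        with open(out / "manifest.json", "w") as fh:
            json.dump({"config": config.__dict__, "n": len(samples)}, fh, indent=2)
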