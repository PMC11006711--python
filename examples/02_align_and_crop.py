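"""Align one face photograph: rotate to horizontal eyes, crop, normalize.

The crop side equals the eye-midpoint-to-mouth distance D, split into
30% / 40% / 30% vertical bands, then resampled to 256 x 256.
"""

import numpy as np

from nutriface.geometry import alignment_angle, eye_centers, eye_roi
from nutriface.pipeline import preprocess
from nutriface.synthetic import SimConfig, generate_face

image, landmarks = generate_face(severity=0.6, config=SimConfig(seed=3),
                                 rng=np.random.default_rng(3))
lc, rc = eye_centers(landmarks)
print(f"input image: {image.height} x {image.width}, "
      f"eye-line tilt {alignment_angle(lc, rc):+.2f} deg")

face = preprocess(image, landmarks)
lc2, rc2 = eye_centers(face.landmarks)
print(f"aligned face: {face.image.shape[0]} x {face.image.shape[1]}, "
      f"rotation applied {face.rotation_deg:+.2f} deg, "
      f"residual eye-height difference {abs(lc2.y - rc2.y):.2e} px")
print(f"crop square side (= D): {face.crop_rect.height:.1f} px, "
      f"middle band {0.4 * face.crop_rect.height:.1f} px")

roi = eye_roi(face.landmarks)
print(f"ocular ROI in crop coordinates: x [{roi.left:.0f}, {roi.right:.0f}), "
      f"y [{max(roi.top, 0):.0f}, {roi.bottom:.0f})")
# The residual eye-height difference being ~0 confirms the rotation; the
# ROI is the brow-to-nose band used for ocular features and eye weighting.
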