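"""Extract the four feature representations from one aligned face.

HOG uses gamma 2.2, 6 x 6 px cells, 8 signed orientation bins of 45 deg,
and L2 block normalization.  The weighted variant partitions the face
into a 6 x 6 block grid and scales eye-block features by 4.
"""

import numpy as np

from nutriface.pipeline import extract_features, preprocess
from nutriface.synthetic import SimConfig, generate_face

image, landmarks = generate_face(0.5, SimConfig(seed=8), np.random.default_rng(8))
face = preprocess(image, landmarks)

for variant in ("full", "ocular", "face_minus_eyes", "weighted", "unweighted"):
    v = extract_features(face, variant)
    print(f"{variant:>16}: {v.size:6d} features, L2 norm {np.linalg.norm(v):8.2f}")

# The weighted and unweighted vectors have identical length; the weighted
# norm is larger because eye-block elements are multiplied by 4.  The
# ocular variant is the brow-to-nose crop alone, hence far shorter.
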