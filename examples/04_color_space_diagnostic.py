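"""Compare color spaces for separating whitefly / thrips / card background.

Mean-color features of training crops are scored by silhouette on the
classic component pairs — (R, G), (H, S), (Cb, Cr), (a*, b*).  Brightness
varies between frames, which smears the correlated (R, G) scatter, while
saturation is a within-pixel ratio that survives; this is why the
classifier runs on HSV by default.
"""

import numpy as np

from trapscan.features import space_separability
from trapscan.pipeline import PipelineConfig, crop_feature
from trapscan.synth import generate_training_set

crops, labels = generate_training_set(80, seed=11)
features = {}
for space in ("RGB", "HSV", "YCbCr", "LAB"):
    config = PipelineConfig(color_space=space)
    features[space] = np.array([crop_feature(c, config).values for c in crops])

scores = space_separability(features, np.array(labels))
for space, score in sorted(scores.items(), key=lambda kv: kv[1]):
    print(f"{space:6s} silhouette = {score:.3f}")
print("higher = cleaner class separation; RGB mixes the classes most")
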