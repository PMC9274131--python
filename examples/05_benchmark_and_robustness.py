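"""Score the full pipeline on a multi-scene benchmark and a noise sweep.

The benchmark renders scenes with varying insect loads, detects with a
trained model, and reports per-class TPR/FPR/accuracy (mean +- SD over
images) plus the regression of automatic on manual counts.  The sweep
re-renders one layout under increasing glue degeneration to show the
graceful decline of detection.  Scaled down here for a quick run; the
acceptance script runs the full 18-scene version.
"""

import numpy as np

from trapscan import GroundTruth, SceneSpec, detect_image, noise_sweep, run_benchmark
from trapscan.evaluation import match_detections
from trapscan.pipeline import PipelineConfig, train_synthetic_model

config = PipelineConfig()
model = train_synthetic_model(n_per_class=150, config=config, seed=3)

report = run_benchmark(model, n_images=6, config=config, seed=3)
print("benchmark (6 scenes):")
print(report["summary"].round(3).to_string())
for cls, reg in report["count_regression"].items():
    print(f"  {cls} counts: slope={reg['slope']:.2f}  R^2={reg['r_squared']:.3f}")

print("\nnoise sweep (same layout, increasing degradation):")
base = SceneSpec(width=320, height=240, n_whitefly=7, n_thrips=7, seed=99)
for scale, image, ann in noise_sweep(base, [1.0, 2.5, 5.0]):
    ds, _ = detect_image(image, model, config, image_id="sweep")
    truth = GroundTruth(points=[(r.x, r.y, r.label) for r in ann.itertuples()],
                        image_id="sweep")
    res = match_detections(ds, truth, max_dist=config.match_dist)
    tp = sum(1 for d, t, _ in res.matches
             if ds.detections[d].label == truth.points[t][2])
    print(f"  noise x{scale:g}: {tp}/{len(truth.points)} insects recovered")
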