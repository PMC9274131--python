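"""Render one synthetic sticky-trap scene and inspect its ground truth.

The generator paints a yellow card on a dark background, places pale
whitefly and dark thrips ellipses (5-25 px area) without overlap, and
degrades the frame with glue spots, stripes, a bulk smear, an illumination
gradient and sensor noise.  The returned table is the exact ground truth
every later stage is scored against.
"""

from trapscan import SceneSpec, generate_scene

spec = SceneSpec(n_whitefly=10, n_thrips=8, seed=42)
image, annotations = generate_scene(spec)

print(f"scene: {image.width} x {image.height} px")
print(f"insects planted: {annotations.label.value_counts().to_dict()}")
print(f"rendered areas (px): min={annotations.area.min()} max={annotations.area.max()}")
print(annotations.head(5).to_string(index=False))
# each row is one insect: its center (x, y), rendered pixel area, and class
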