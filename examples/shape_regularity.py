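"""Score tumor-outline masks with the F-value regularity statistic.

F = (enclosing-circle area - tumor area) / enclosing-circle area: 0 for a
circle, 1 - b/a for an ellipse, 1 - 2/pi for a square.  Larger F means a
less regular outline.
"""

import math

from methmorph import generate_tumor_mask, shape_metrics, tumor_volume

shapes = {
    "circle r=50": ("circle", 128, {"radius": 50}),
    "ellipse 40x20": ("ellipse", 128, {"a": 40, "b": 20}),
    "square side 60": ("square", 160, {"side": 60}),
    "irregular blob": ("perturbed_blob", 128, {"radius": 40, "perturbation": 0.25}),
}
print(f"{'shape':<16} {'area_px':>8} {'long_axis':>10} {'F':>7}")
for label, (shape, size, params) in shapes.items():
    s = shape_metrics(generate_tumor_mask(shape, size, params, seed=7))
    print(f"{label:<16} {s.area_tumor:>8.0f} {s.long_axis:>10.1f} {s.f_value:>7.3f}")
print(f"analytic F for the ellipse: 1 - b/a = 0.500; for the square: 1 - 2/pi = {1 - 2 / math.pi:.4f}")
print(f"caliper volume of a 10 mm x 20 mm tumor: {tumor_volume(10, 20):.0f} mm^3 (w^2 * L / 2)")
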