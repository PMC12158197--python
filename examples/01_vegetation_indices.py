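"""Compute the four visible-band vegetation indices on a small scene.

Builds a synthetic canopy-over-soil image and prints, per index, the mean
value over vegetation and over soil pixels.  A usable index puts the two
class means far apart relative to their spread; note that RGRI runs the
other way (lower over vegetation).
"""

import numpy as np

from vegcover import INDEX_NAMES, SceneConfig, compute_index, generate_scene

scene = generate_scene(SceneConfig(rows=128, cols=128, seed=1))
veg = scene.truth_mask.vegetation
soil = scene.truth_mask.soil

print(f"scene: 128x128 px, realized cover {scene.realized_coverage_pct:.2f}%")
print(f"{'index':6s} {'veg mean':>9s} {'soil mean':>9s} {'polarity':>9s}")
for name in INDEX_NAMES:
    vi = compute_index(scene.image, name)
    print(f"{name:6s} {np.nanmean(vi.values[veg]):9.3f} "
          f"{np.nanmean(vi.values[soil]):9.3f} {vi.polarity.value:>9s}")
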