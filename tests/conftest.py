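import numpy as np
import pytest

from vegcover import RGBRaster, SceneConfig, generate_scene


@pytest.fixture
def gray_image():
    """4x4 raster of a single gray value (all bands equal)."""
    band = np.full((4, 4), 120, dtype=np.uint8)
    return RGBRaster(red=band, green=band.copy(), blue=band.copy(),
                     valid_mask=None, gsd_cm=1.0)


@pytest.fixture
def noiseless_scene():
    """Separable scene: zero colour noise, no shadows, no mixed pixels."""
    cfg = SceneConfig(
        rows=96, cols=96, target_coverage_pct=60.0,
        veg_rgb_mean=(60, 160, 60), soil_rgb_mean=(150, 120, 90),
        rgb_sd=(0.0, 0.0, 0.0), shadow_fraction=0.0,
        mixed_pixel_band_px=0, seed=7,
    )
    return generate_scene(cfg)


@pytest.fixture
def noisy_scene():
    """Default (moderate-noise) scene at 512x512 for distributional checks."""
    return generate_scene(SceneConfig(rows=512, cols=512, seed=11))
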