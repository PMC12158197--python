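"""Synthetic orthomosaic-like scenes with known vegetation/soil truth.

The generator emulates the statistical structure of a sunlit canopy-over-soil
orthomosaic at centimetre ground sample distance:

- vegetation occupies blob-shaped patches drawn from a thresholded smoothed
  Gaussian random field, so class boundaries are extended curves and mixed
  boundary pixels exist, as they do in real canopies;
- per-pixel colours are truncated Gaussians around distinct class mean
  colours, giving the high-low bimodal class-conditional vegetation-index
  histograms that the threshold method relies on;
- an optional fraction of vegetation pixels is darkened multiplicatively
  (factor 0.4) to mimic canopy shadow — still vegetation in truth;
- pixels within a configurable band of the class boundary get a linear
  colour blend of the two classes (mixed pixels), truth label unchanged.

The patch field is thresholded at the exact order statistic matching the
requested cover, so the realised coverage differs from the target only by
the sub-pixel rounding of ``target/100 * rows * cols``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, InputError
from .rasters import ClassificationMask, MaskSource, RGBRaster


@dataclass
class SceneConfig:
    """Generator settings.

    Defaults describe a moderately noisy, well-separated canopy/soil scene:
    green-dominated vegetation (60, 160, 60) over brownish soil
    (150, 120, 90), per-band Gaussian colour noise of 10 DN, a one-pixel
    mixed boundary band and a small shadowed fraction.
    """

    rows: int = 256
    cols: int = 256
    target_coverage_pct: float = 60.0
    veg_rgb_mean: tuple[float, float, float] = (60.0, 160.0, 60.0)
    soil_rgb_mean: tuple[float, float, float] = (150.0, 120.0, 90.0)
    rgb_sd: tuple[float, float, float] = (10.0, 10.0, 10.0)
    shadow_fraction: float = 0.05
    shadow_factor: float = 0.4
    mixed_pixel_band_px: int = 1
    blob_scale_px: float = 8.0
    gsd_cm: float = 0.83
    seed: int = 0

    def __post_init__(self):
        if self.rows <= 0 or self.cols <= 0:
            raise ConfigurationError("rows and cols must be positive")
        if not 0.0 < self.target_coverage_pct < 100.0:
            raise ConfigurationError("target_coverage_pct must be in (0, 100)")
        if not 0.0 <= self.shadow_fraction < 1.0:
            raise ConfigurationError("shadow_fraction must be in [0, 1)")
        if self.mixed_pixel_band_px < 0:
            raise ConfigurationError("mixed_pixel_band_px must be >= 0")
        if not self.gsd_cm > 0:
            raise ConfigurationError("gsd_cm must be > 0")
        if any(s < 0 for s in self.rgb_sd):
            raise ConfigurationError("rgb_sd must be non-negative")
        for m in (*self.veg_rgb_mean, *self.soil_rgb_mean):
            if not 0 <= m <= 255:
                raise ConfigurationError("class mean colors must lie in [0, 255]")
        if all(s == 0 for s in self.rgb_sd) and self.veg_rgb_mean == self.soil_rgb_mean:
            raise ConfigurationError(
                "noise-free classes must differ in at least one band"
            )


@dataclass
class SyntheticScene:
    image: RGBRaster
    truth_mask: ClassificationMask
    realized_coverage_pct: float
    config: SceneConfig | None = None


def generate_scene(cfg: SceneConfig) -> SyntheticScene:
    """Generate one scene; deterministic for a given config (incl. seed)."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.rows * cfg.cols

    # blob geometry: smoothed white noise thresholded at the order statistic
    # that realises the requested cover
    raw = rng.standard_normal((cfg.rows, cfg.cols))
    blobs = ndimage.gaussian_filter(raw, sigma=cfg.blob_scale_px)
    k = int(round(cfg.target_coverage_pct / 100.0 * n))
    k = min(max(k, 1), n - 1)
    cutoff = np.partition(blobs.ravel(), n - k)[n - k]
    veg = blobs >= cutoff
    # ties at the cutoff are measure-zero for a continuous field, but guard:
    realized = int(veg.sum())

    veg_draw = _class_colors(rng, cfg.veg_rgb_mean, cfg.rgb_sd, (cfg.rows, cfg.cols))
    soil_draw = _class_colors(rng, cfg.soil_rgb_mean, cfg.rgb_sd, (cfg.rows, cfg.cols))

    alpha = veg.astype(np.float64)  # vegetation colour weight per pixel
    if cfg.mixed_pixel_band_px > 0:
        band = cfg.mixed_pixel_band_px
        d_in = ndimage.distance_transform_edt(veg)      # veg px: dist to soil
        d_out = ndimage.distance_transform_edt(~veg)    # soil px: dist to veg
        in_band_veg = veg & (d_in <= band)
        in_band_soil = ~veg & (d_out <= band)
        alpha[in_band_veg] = 0.5 + 0.5 * d_in[in_band_veg] / (band + 1)
        alpha[in_band_soil] = 0.5 - 0.5 * d_out[in_band_soil] / (band + 1)

    img = alpha[..., None] * veg_draw + (1.0 - alpha[..., None]) * soil_draw

    if cfg.shadow_fraction > 0:
        vr, vc = np.nonzero(veg)
        n_shadow = int(round(cfg.shadow_fraction * vr.size))
        if n_shadow > 0:
            idx = rng.choice(vr.size, size=n_shadow, replace=False)
            img[vr[idx], vc[idx], :] *= cfg.shadow_factor

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    image = RGBRaster(
        red=img[..., 0],
        green=img[..., 1],
        blue=img[..., 2],
        valid_mask=np.ones((cfg.rows, cfg.cols), dtype=bool),
        gsd_cm=cfg.gsd_cm,
    )
    truth = ClassificationMask(labels=veg.astype(np.uint8), source=MaskSource.TRUTH)
    return SyntheticScene(
        image=image,
        truth_mask=truth,
        realized_coverage_pct=100.0 * realized / n,
        config=cfg,
    )


def _class_colors(rng, mean, sd, shape) -> np.ndarray:
    out = np.empty((*shape, 3), dtype=np.float64)
    for i in range(3):
        out[..., i] = np.clip(rng.normal(mean[i], sd[i], size=shape), 0.0, 255.0)
    return out


def resample_scene(scene: SyntheticScene, factor: int) -> SyntheticScene:
    """Coarsen a scene by block-averaging ``factor`` x ``factor`` pixel blocks.

    The truth mask is majority-voted per block, vegetation winning exact
    ties; the ground sample distance scales by ``factor``.
    """
    if factor < 1 or int(factor) != factor:
        raise InputError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return scene
    rows, cols = scene.image.shape
    if rows % factor or cols % factor:
        raise InputError(
            f"factor {factor} does not divide scene dimensions {rows}x{cols}"
        )
    r2, c2 = rows // factor, cols // factor

    def _block_mean(band):
        return band.astype(np.float64).reshape(r2, factor, c2, factor).mean(axis=(1, 3))

    bands = [np.clip(np.rint(_block_mean(b)), 0, 255).astype(np.uint8)
             for b in (scene.image.red, scene.image.green, scene.image.blue)]
    veg_frac = (
        scene.truth_mask.vegetation.astype(np.float64)
        .reshape(r2, factor, c2, factor)
        .mean(axis=(1, 3))
    )
    veg = veg_frac >= 0.5  # vegetation wins ties
    image = RGBRaster(
        red=bands[0],
        green=bands[1],
        blue=bands[2],
        valid_mask=np.ones((r2, c2), dtype=bool),
        gsd_cm=scene.image.gsd_cm * factor,
    )
    truth = ClassificationMask(labels=veg.astype(np.uint8), source=MaskSource.TRUTH)
    cfg = None
    if scene.config is not None:
        cfg = replace(scene.config, rows=r2, cols=c2, gsd_cm=scene.config.gsd_cm * factor)
    return SyntheticScene(
        image=image,
        truth_mask=truth,
        realized_coverage_pct=100.0 * float(veg.mean()),
        config=cfg,
    )
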