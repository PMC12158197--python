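"""Visible-band vegetation indices.

Four indices computed per pixel from the raw RGB digital numbers r, g, b:

- ``EXG``   excess green, ``2g - r - b``; range [-510, 510] for 8-bit input
- ``VDVI``  visible-band difference index, ``(2g - r - b) / (2g + r + b)``;
  range [-1, 1]
- ``RGRI``  red-green ratio, ``r / g``; >= 0, LOWER over vegetation than soil
- ``RGBVI`` ``(g^2 - r*b) / (g^2 + r*b)``; range [-1, 1]

Live vegetation reflects strongly in green and absorbs red and blue, so EXG,
VDVI and RGBVI rise over canopy while RGRI falls; the polarity of each index
is attached to the output raster so downstream thresholding applies the
decision rule in the right direction.

Pixels where an index's denominator vanishes are flagged invalid rather than
clamped.  EXG has no denominator; by default all-zero (black, typically
nodata-fill) pixels are flagged invalid there too so the four index masks
agree on degenerate input.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError
from .rasters import Polarity, RGBRaster, VIRaster

INDEX_NAMES = ("EXG", "VDVI", "RGRI", "RGBVI")

#: Side of the threshold on which vegetation lies, per index.
DEFAULT_POLARITY = {
    "EXG": Polarity.VEG_HIGH,
    "VDVI": Polarity.VEG_HIGH,
    "RGRI": Polarity.VEG_LOW,
    "RGBVI": Polarity.VEG_HIGH,
}

#: Histogram bin widths matching the precision at which thresholds for each
#: index are usually quoted (integer DN arithmetic for EXG, two decimals for
#: the normalised/ratio indices).
DEFAULT_BIN_WIDTH = {"EXG": 1.0, "VDVI": 0.01, "RGRI": 0.01, "RGBVI": 0.01}


def compute_index(
    image: RGBRaster,
    index_name: str,
    *,
    rgbvi_scale: float = 1.0,
    exg_mask_black: bool = True,
) -> VIRaster:
    """Compute one vegetation index over a raster.

    Parameters
    ----------
    image
        Input RGB raster (raw digital numbers, no calibration).
    index_name
        One of ``EXG``, ``VDVI``, ``RGRI``, ``RGBVI`` (case-insensitive).
    rgbvi_scale
        Optional linear factor applied to RGBVI values (default 1.0, i.e. the
        normalised definition with range [-1, 1]).
    exg_mask_black
        Flag all-zero pixels invalid for EXG so its validity mask matches the
        ratio indices, whose denominators vanish there.

    Returns
    -------
    VIRaster
        Same dimensions as the input; invalid where the input is invalid or
        the denominator is zero.
    """
    name = str(index_name).upper()
    if name not in INDEX_NAMES:
        raise ConfigurationError(
            f"unknown index {index_name!r}; expected one of {INDEX_NAMES}"
        )
    r = image.red.astype(np.float64)
    g = image.green.astype(np.float64)
    b = image.blue.astype(np.float64)
    valid = image.valid_mask.copy()

    with np.errstate(divide="ignore", invalid="ignore"):
        if name == "EXG":
            values = 2.0 * g - r - b
            if exg_mask_black:
                valid &= (r + g + b) > 0
        elif name == "VDVI":
            denom = 2.0 * g + r + b
            values = np.where(denom != 0, (2.0 * g - r - b) / np.where(denom == 0, 1, denom), np.nan)
            valid &= denom != 0
        elif name == "RGRI":
            values = np.where(g != 0, r / np.where(g == 0, 1, g), np.nan)
            valid &= g != 0
        else:  # RGBVI
            denom = g * g + r * b
            values = np.where(denom != 0, (g * g - r * b) / np.where(denom == 0, 1, denom), np.nan)
            values = values * rgbvi_scale
            valid &= denom != 0

    values = np.where(valid, values, np.nan)
    return VIRaster(
        index_name=name,
        values=values,
        valid_mask=valid,
        polarity=DEFAULT_POLARITY[name],
        gsd_cm=image.gsd_cm,
    )


def compute_all_indices(image: RGBRaster, **kwargs) -> dict[str, VIRaster]:
    """Convenience: all four indices keyed by name."""
    return {name: compute_index(image, name, **kwargs) for name in INDEX_NAMES}
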