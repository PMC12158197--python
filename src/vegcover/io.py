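"""Raster, mask, label and report readers/writers.

GeoTIFF-style rasters go through ``tifffile`` (3-band uint8 in, single-band
float32 with NaN nodata out); PNG through Pillow.  Label sets and reports are
plain CSV with 0-based, row-major pixel coordinates, origin at the top-left
corner.  All writes are atomic: content is written to a temporary sibling
file and renamed into place, so a failed write never leaves a partial
artifact.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import ConfigurationError, FormatError, InputError
from .rasters import (
    NODATA_LABEL,
    ClassificationMask,
    LabeledPixelSet,
    MaskSource,
    RGBRaster,
    VIRaster,
)

CSV_COORD_HEADER = "# pixel coordinates: 0-based, row-major, origin top-left"


def _atomic_write(path: str | Path, writer) -> None:
    """Write via a temp file + rename so partial outputs never appear."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_rgb_raster(
    path: str | Path,
    gsd_cm: float | None = None,
    nodata: float | None = None,
) -> RGBRaster:
    """Read a 3-band 8-bit raster from GeoTIFF/TIFF or PNG.

    Bands are taken as red, green, blue in order.  With ``nodata`` set,
    pixels where all three bands equal that value are flagged invalid.  The
    ground sample distance is read from the TIFF resolution tags when
    present (written by :func:`write_rgb_raster`); otherwise ``gsd_cm`` must
    be supplied.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    suffix = path.suffix.lower()
    tag_gsd = None
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if xres is not None and unit is not None and unit.value == 3:  # centimetre
                num, den = xres.value
                if num:
                    tag_gsd = den / num  # cm per pixel
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3 and arr.shape[0] in (3, 4) and arr.shape[0] < arr.shape[-1]:
        arr = np.moveaxis(arr, 0, -1)  # planar -> interleaved
    if arr.ndim != 3 or arr.shape[-1] < 3:
        raise FormatError(f"{path} has fewer than 3 bands")
    gsd = gsd_cm if gsd_cm is not None else tag_gsd
    if gsd is None:
        raise ConfigurationError(
            f"{path} carries no resolution metadata; pass gsd_cm explicitly"
        )
    r, g, b = (arr[..., i] for i in range(3))
    if nodata is not None:
        valid = ~((r == nodata) & (g == nodata) & (b == nodata))
    else:
        valid = np.ones(r.shape, dtype=bool)
    return RGBRaster(red=r, green=g, blue=b, valid_mask=valid, gsd_cm=float(gsd))


def write_rgb_raster(path: str | Path, image: RGBRaster) -> None:
    """Write a 3-band uint8 TIFF, recording the GSD in the resolution tags."""
    arr = np.stack(
        [image.red, image.green, image.blue], axis=-1
    ).astype(np.uint8)
    ppcm = 1.0 / image.gsd_cm  # pixels per centimetre

    def _w(tmp):
        tifffile.imwrite(
            tmp, arr, photometric="rgb",
            resolution=(ppcm, ppcm), resolutionunit="CENTIMETER",
        )

    _atomic_write(path, _w)


def write_vi_raster(path: str | Path, vi: VIRaster) -> None:
    """Write a VI raster as single-band float32 TIFF with NaN nodata."""
    values = np.where(vi.valid_mask, vi.values, np.nan).astype(np.float32)
    _atomic_write(path, lambda tmp: tifffile.imwrite(tmp, values))


def read_vi_raster(path: str | Path, index_name: str) -> VIRaster:
    from .indices import DEFAULT_POLARITY

    values = tifffile.imread(path)
    valid = ~np.isnan(values)
    return VIRaster(
        index_name=index_name.upper(),
        values=values.astype(np.float64),
        valid_mask=valid,
        polarity=DEFAULT_POLARITY[index_name.upper()],
    )


def write_mask(path: str | Path, mask: ClassificationMask) -> None:
    """Write a mask as single-band uint8 (1 veg, 0 soil, 255 nodata)."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        _atomic_write(path, lambda tmp: Image.fromarray(mask.labels, mode="L").save(tmp, format="PNG"))
    else:
        _atomic_write(path, lambda tmp: tifffile.imwrite(tmp, mask.labels))


def read_mask(path: str | Path, source: MaskSource = MaskSource.CLASSIFIER) -> ClassificationMask:
    path = Path(path)
    if path.suffix.lower() == ".png":
        labels = np.asarray(Image.open(path))
    else:
        labels = tifffile.imread(path)
    if labels.ndim != 2:
        raise FormatError(f"{path} is not a single-band mask")
    return ClassificationMask(labels=labels.astype(np.uint8), source=source)


def read_labels(path: str | Path) -> LabeledPixelSet:
    """Read a label CSV with columns row, col, label, split."""
    df = pd.read_csv(path, comment="#")
    required = {"row", "col", "label"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path} must have columns row, col, label[, split]")
    split = df["split"].to_numpy() if "split" in df.columns else None
    return LabeledPixelSet(
        rows=df["row"].to_numpy(),
        cols=df["col"].to_numpy(),
        labels=df["label"].to_numpy(),
        split=split,
    )


def write_labels(path: str | Path, labels: LabeledPixelSet) -> None:
    df = pd.DataFrame(
        {"row": labels.rows, "col": labels.cols, "label": labels.labels, "split": labels.split}
    )

    def _w(tmp):
        with open(tmp, "w") as fh:
            fh.write(CSV_COORD_HEADER + "\n")
            df.to_csv(fh, index=False)

    _atomic_write(path, _w)


def write_json(path: str | Path, obj) -> None:
    _atomic_write(path, lambda tmp: Path(tmp).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n"))


def write_text(path: str | Path, text: str) -> None:
    _atomic_write(path, lambda tmp: Path(tmp).write_text(text))


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
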