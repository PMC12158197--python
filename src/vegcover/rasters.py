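"""In-memory raster containers.

Pixel coordinates are 0-based, row-major, origin at the top-left corner.
Band values are 8-bit digital numbers (DN) straight off the sensor; no
radiometric calibration is applied anywhere in the package.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InputError

NODATA_LABEL = 255  # uint8 mask encoding: 1 = vegetation, 0 = soil


class Polarity(enum.Enum):
    """Direction of the vegetation decision rule relative to the threshold."""

    VEG_HIGH = "veg_high"  # vegetation iff VI >= threshold
    VEG_LOW = "veg_low"  # vegetation iff VI <= threshold


class MaskSource(enum.Enum):
    CLASSIFIER = "classifier"
    THRESHOLD = "threshold"
    TRUTH = "truth"


@dataclass
class RGBRaster:
    """3-band 8-bit image with a validity mask and a ground sample distance.

    Parameters
    ----------
    red, green, blue
        2-D arrays of identical shape holding digital numbers in [0, 255].
    valid_mask
        Boolean array, ``False`` where the pixel is nodata.
    gsd_cm
        Ground sample distance in centimetres per pixel (> 0).
    """

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    valid_mask: np.ndarray
    gsd_cm: float

    def __post_init__(self):
        self.red = np.asarray(self.red)
        self.green = np.asarray(self.green)
        self.blue = np.asarray(self.blue)
        if not (self.red.shape == self.green.shape == self.blue.shape):
            raise InputError("red/green/blue bands must share dimensions")
        if self.red.ndim != 2:
            raise InputError("bands must be 2-D arrays")
        if self.red.size == 0:
            raise InputError("empty raster")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.red.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.red.shape:
                raise InputError("valid_mask must match band dimensions")
        if not self.gsd_cm > 0:
            raise ConfigurationError("gsd_cm must be > 0")
        for name, band in (("red", self.red), ("green", self.green), ("blue", self.blue)):
            vals = band[self.valid_mask]
            if vals.size and (vals.min() < 0 or vals.max() > 255):
                raise InputError(f"{name} band has valid values outside [0, 255]")

    @property
    def rows(self) -> int:
        return self.red.shape[0]

    @property
    def cols(self) -> int:
        return self.red.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    def bands(self) -> np.ndarray:
        """Stacked float64 bands, shape (rows, cols, 3) in r, g, b order."""
        return np.stack(
            [b.astype(np.float64) for b in (self.red, self.green, self.blue)], axis=-1
        )


@dataclass
class VIRaster:
    """Per-pixel values of one vegetation index.

    ``valid_mask`` is ``False`` where the source pixel was invalid or the
    index denominator vanished.  ``polarity`` records on which side of a
    threshold vegetation lies for this index.
    """

    index_name: str
    values: np.ndarray
    valid_mask: np.ndarray
    polarity: Polarity
    gsd_cm: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise InputError("values and valid_mask must share dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]


@dataclass
class ClassificationMask:
    """Per-pixel vegetation/soil labels with nodata.

    ``labels`` is a uint8 array: 1 = vegetation, 0 = soil, 255 = nodata.
    """

    labels: np.ndarray
    source: MaskSource

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        bad = ~np.isin(self.labels, (0, 1, NODATA_LABEL))
        if bad.any():
            raise InputError("mask labels must be 0, 1 or 255 (nodata)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def vegetation(self) -> np.ndarray:
        return self.labels == 1

    @property
    def soil(self) -> np.ndarray:
        return self.labels == 0

    @property
    def valid(self) -> np.ndarray:
        return self.labels != NODATA_LABEL


@dataclass
class LabeledPixelSet:
    """Hand-labelled (row, col) samples for training/validation.

    ``labels`` holds ``"vegetation"`` or ``"soil"`` per coordinate, ``split``
    holds ``"train"`` or ``"validate"``.
    """

    rows: np.ndarray
    cols: np.ndarray
    labels: np.ndarray
    split: np.ndarray = field(default=None)

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=np.intp)
        self.cols = np.asarray(self.cols, dtype=np.intp)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.split is None:
            self.split = np.full(self.rows.shape, "train", dtype=object)
        else:
            self.split = np.asarray(self.split, dtype=object)
        n = len(self.rows)
        if not (len(self.cols) == len(self.labels) == len(self.split) == n):
            raise InputError("labeled pixel arrays must have equal length")
        unknown = set(np.unique(self.labels)) - {"vegetation", "soil"}
        if unknown:
            raise InputError(f"unknown class labels: {sorted(unknown)}")
        unknown = set(np.unique(self.split)) - {"train", "validate"}
        if unknown:
            raise InputError(f"unknown split values: {sorted(unknown)}")
        train = {(r, c) for r, c in zip(self.rows[self.split == "train"], self.cols[self.split == "train"])}
        val = {(r, c) for r, c in zip(self.rows[self.split == "validate"], self.cols[self.split == "validate"])}
        if train & val:
            raise InputError("train and validate pixel sets overlap")

    def __len__(self) -> int:
        return len(self.rows)

    def subset(self, split: str) -> "LabeledPixelSet":
        m = self.split == split
        return LabeledPixelSet(self.rows[m], self.cols[m], self.labels[m], self.split[m])

    def is_vegetation(self) -> np.ndarray:
        return self.labels == "vegetation"

    def check_inside(self, shape: tuple[int, int], valid_mask: np.ndarray | None = None):
        """Raise if any coordinate falls outside the raster or on nodata."""
        if len(self) == 0:
            return
        if (self.rows < 0).any() or (self.cols < 0).any() or (
            self.rows >= shape[0]
        ).any() or (self.cols >= shape[1]).any():
            raise InputError("labeled coordinates fall outside the raster")
        if valid_mask is not None and not valid_mask[self.rows, self.cols].all():
            raise InputError("labeled coordinates fall on invalid pixels")


def labels_from_mask(
    mask: ClassificationMask,
    n_per_class: int | None = None,
    rng: np.random.Generator | None = None,
    split: str = "train",
) -> LabeledPixelSet:
    """Turn a classification mask into a labelled pixel set.

    With ``n_per_class`` set, draws that many pixels per class without
    replacement (seeded by ``rng``); otherwise returns every valid pixel.
    """
    out_r, out_c, out_l = [], [], []
    for name, sel in (("vegetation", mask.vegetation), ("soil", mask.soil)):
        r, c = np.nonzero(sel)
        if r.size == 0:
            raise InputError(f"mask contains no {name} pixels")
        if n_per_class is not None and n_per_class < r.size:
            if rng is None:
                rng = np.random.default_rng()
            idx = rng.choice(r.size, size=n_per_class, replace=False)
            r, c = r[idx], c[idx]
        out_r.append(r)
        out_c.append(c)
        out_l.append(np.full(r.size, name, dtype=object))
    return LabeledPixelSet(
        np.concatenate(out_r),
        np.concatenate(out_c),
        np.concatenate(out_l),
        np.full(sum(a.size for a in out_r), split, dtype=object),
    )
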