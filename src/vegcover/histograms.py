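"""Class-conditional histograms and the intersection threshold.

The segmentation threshold for a vegetation index is read off the statistical
histograms of labelled vegetation and soil pixels: both class distributions
are binned on one shared grid, the two class modes are located, and the
threshold is placed in the intersection region between the modes where
dominance passes from one class to the other.  Among the candidate bin edges
between the modes the one minimising the total number of misclassified
labelled pixels (under the index's polarity rule) is selected; when the
classes are separated by an empty gap the midpoint of the gap is reported
instead of an arbitrary edge.

Binned counting is exact for bin-edge thresholds under the half-open bin
convention [low, high): a pixel equal to an edge lies in the bin starting at
that edge.  For veg_low polarity the mass of the bin starting at the
threshold is treated as above-threshold (exact-equality mass cannot be split
out of a histogram).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateSeparationError, InputError, NoSeparabilityError
from .rasters import LabeledPixelSet, Polarity, VIRaster


@dataclass
class ClassHistogramPair:
    """Vegetation and soil counts of one index on a shared bin grid.

    ``veg_counts``/``soil_counts`` are raw integer counts; when
    ``smoothing_window`` > 1 the zero-padded centred moving averages are kept
    alongside in ``veg_smoothed``/``soil_smoothed``.
    """

    index_name: str
    bin_edges: np.ndarray
    veg_counts: np.ndarray
    soil_counts: np.ndarray
    smoothing_window: int = 1
    veg_smoothed: np.ndarray = field(default=None)
    soil_smoothed: np.ndarray = field(default=None)

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.veg_counts = np.asarray(self.veg_counts)
        self.soil_counts = np.asarray(self.soil_counts)
        nbins = len(self.bin_edges) - 1
        if len(self.veg_counts) != nbins or len(self.soil_counts) != nbins:
            raise InputError("count arrays must have len(bin_edges) - 1 entries")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise InputError("bin_edges must be strictly increasing")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise InputError("smoothing_window must be an odd count >= 1")
        if self.veg_smoothed is None:
            self.veg_smoothed = moving_average(self.veg_counts, self.smoothing_window)
        if self.soil_smoothed is None:
            self.soil_smoothed = moving_average(self.soil_counts, self.smoothing_window)

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "veg_count": self.veg_counts,
                "soil_count": self.soil_counts,
            }
        )


@dataclass
class ThresholdResult:
    """Selected scalar threshold and the intersection interval it came from."""

    index_name: str
    intersection_interval: tuple[float, float]
    threshold: float
    polarity: Polarity
    misclassified_count: int

    def __post_init__(self):
        low, high = self.intersection_interval
        if not (low <= self.threshold <= high):
            raise InputError("threshold must lie inside the intersection interval")

    def to_dict(self) -> dict:
        return {
            "index_name": self.index_name,
            "intersection_low": float(self.intersection_interval[0]),
            "intersection_high": float(self.intersection_interval[1]),
            "threshold": float(self.threshold),
            "polarity": self.polarity.value,
            "misclassified_count": int(self.misclassified_count),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def moving_average(counts: np.ndarray, window: int) -> np.ndarray:
    """Zero-padded centred moving average; window must be odd, 1 = identity."""
    if window < 1 or window % 2 == 0:
        raise InputError("smoothing window must be an odd count >= 1")
    counts = np.asarray(counts, dtype=np.float64)
    if window == 1:
        return counts.copy()
    kernel = np.ones(window) / window
    return np.convolve(counts, kernel, mode="same")


def build_class_histograms(
    vi: VIRaster,
    labels: LabeledPixelSet,
    bin_width: float,
    smoothing_window: int = 1,
) -> ClassHistogramPair:
    """Bin labelled vegetation and soil VI values on one shared grid.

    The grid starts at ``floor(min/bin_width) * bin_width`` over the pooled
    values of both classes and extends far enough to cover the maximum, so
    corresponding bins of the two classes are directly comparable.
    """
    if not bin_width > 0:
        raise InputError("bin_width must be > 0")
    labels.check_inside(vi.shape)
    at_valid = vi.valid_mask[labels.rows, labels.cols]
    veg_sel = labels.is_vegetation() & at_valid
    soil_sel = (~labels.is_vegetation()) & at_valid
    veg_values = vi.values[labels.rows[veg_sel], labels.cols[veg_sel]]
    soil_values = vi.values[labels.rows[soil_sel], labels.cols[soil_sel]]
    return build_class_histograms_from_values(
        vi.index_name, veg_values, soil_values, bin_width, smoothing_window
    )


def build_class_histograms_from_values(
    index_name: str,
    veg_values: np.ndarray,
    soil_values: np.ndarray,
    bin_width: float,
    smoothing_window: int = 1,
) -> ClassHistogramPair:
    """Histogram pair from raw per-class value arrays (see build_class_histograms)."""
    veg_values = np.asarray(veg_values, dtype=np.float64)
    soil_values = np.asarray(soil_values, dtype=np.float64)
    for name, vals in (("vegetation", veg_values), ("soil", soil_values)):
        if vals.size == 0:
            raise InputError(f"no valid labeled {name} pixels")
    pooled_min = min(veg_values.min(), soil_values.min())
    pooled_max = max(veg_values.max(), soil_values.max())
    start = np.floor(pooled_min / bin_width) * bin_width
    # cover pooled_max with a half-open final bin
    n_bins = int(np.floor((pooled_max - start) / bin_width + 1e-9)) + 1
    edges = start + bin_width * np.arange(n_bins + 1)
    veg_counts, _ = np.histogram(veg_values, bins=edges)
    soil_counts, _ = np.histogram(soil_values, bins=edges)
    return ClassHistogramPair(
        index_name=index_name,
        bin_edges=edges,
        veg_counts=veg_counts,
        soil_counts=soil_counts,
        smoothing_window=smoothing_window,
    )


def _misclassification_at_edges(
    hist: ClassHistogramPair, polarity: Polarity
) -> np.ndarray:
    """Total misclassified labelled pixels for a threshold at every bin edge.

    Entry j corresponds to ``bin_edges[j]``.  veg_high: vegetation iff
    VI >= t, so errors = veg mass below edge j + soil mass at/above it;
    veg_low mirrors this.
    """
    veg = np.asarray(hist.veg_counts, dtype=np.float64)
    soil = np.asarray(hist.soil_counts, dtype=np.float64)
    cum_veg = np.concatenate([[0.0], np.cumsum(veg)])  # mass strictly below edge j
    cum_soil = np.concatenate([[0.0], np.cumsum(soil)])
    if polarity is Polarity.VEG_HIGH:
        return cum_veg + (soil.sum() - cum_soil)
    return (veg.sum() - cum_veg) + cum_soil


def find_intersection_threshold(
    hist: ClassHistogramPair, polarity: Polarity | None = None
) -> ThresholdResult:
    """Locate the histogram-intersection threshold between the class modes.

    Parameters
    ----------
    hist
        Shared-grid class histogram pair.  Mode finding and the dominance
        scan use the smoothed counts when smoothing is on; misclassification
        is always counted on the raw counts.
    polarity
        Decision-rule direction; defaults to the index's standard polarity.

    Raises
    ------
    NoSeparabilityError
        If the two class histograms are identical.
    DegenerateSeparationError
        If the class modes fall in the same bin (no interval between modes).
    """
    if polarity is None:
        from .indices import DEFAULT_POLARITY

        polarity = DEFAULT_POLARITY[hist.index_name.upper()]

    veg_c = np.asarray(hist.veg_smoothed, dtype=np.float64)
    soil_c = np.asarray(hist.soil_smoothed, dtype=np.float64)
    if np.array_equal(np.asarray(hist.veg_counts), np.asarray(hist.soil_counts)):
        raise NoSeparabilityError(
            "vegetation and soil histograms are identical; classes not separable"
        )
    veg_mode = int(np.argmax(veg_c))
    soil_mode = int(np.argmax(soil_c))
    if veg_mode == soil_mode:
        raise DegenerateSeparationError(
            "class histogram modes coincide; no intersection between modes",
            veg_mode_bin=veg_mode,
            soil_mode_bin=soil_mode,
        )

    edges = hist.bin_edges
    left_mode, right_mode = min(veg_mode, soil_mode), max(veg_mode, soil_mode)
    left_is_veg = veg_mode < soil_mode
    left_c = veg_c if left_is_veg else soil_c
    right_c = soil_c if left_is_veg else veg_c

    # Dominance scan strictly between the modes: the intersection interval
    # runs from the first bin no longer dominated by the left class to the
    # last bin not yet dominated by the right class.
    between = np.arange(left_mode + 1, right_mode)
    not_left_dom = [i for i in between if left_c[i] <= right_c[i]]
    not_right_dom = [i for i in between if right_c[i] <= left_c[i]]
    a = not_left_dom[0] if not_left_dom else right_mode
    b = not_right_dom[-1] if not_right_dom else left_mode
    low = float(edges[a])
    high = float(edges[b + 1])
    if high < low:  # single clean crossing inside one edge
        low, high = high, low

    # Candidate thresholds: every bin edge strictly between the mode bins.
    cand = np.arange(left_mode + 1, right_mode + 1)
    errors = _misclassification_at_edges(hist, polarity)[cand]
    min_err = errors.min()
    minimisers = cand[errors == min_err]

    if min_err == 0:
        # perfect separation: report the midpoint of the zero-error edge run
        j_lo, j_hi = int(minimisers.min()), int(minimisers.max())
        threshold = float((edges[j_lo] + edges[j_hi]) / 2.0)
    else:
        # tie-break toward the soil mode (fewest misclassified vegetation)
        pick = int(minimisers.max()) if soil_mode > veg_mode else int(minimisers.min())
        threshold = float(edges[pick])

    low = min(low, threshold)
    high = max(high, threshold)
    return ThresholdResult(
        index_name=hist.index_name,
        intersection_interval=(low, high),
        threshold=threshold,
        polarity=polarity,
        misclassified_count=int(round(float(min_err))),
    )


@dataclass
class IntersectionTable:
    """Per-index, per-vegetation-type threshold comparison."""

    per_result: pd.DataFrame
    per_index: pd.DataFrame

    def to_csv(self, path) -> None:
        self.per_result.to_csv(path, index=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_result": self.per_result.to_dict(orient="records"),
                "per_index": self.per_index.to_dict(orient="records"),
            },
            indent=2,
        )


def threshold_report(results: list[tuple[str, ThresholdResult]]) -> IntersectionTable:
    """Tabulate thresholds across vegetation types and flag the stablest index.

    Parameters
    ----------
    results
        ``(vegetation_type, ThresholdResult)`` pairs, possibly several
        vegetation types per index.

    Returns
    -------
    IntersectionTable
        ``per_result`` lists every threshold with its interval and polarity;
        ``per_index`` gives each index's threshold range (max - min) across
        vegetation types, with ``most_stable`` True on the smallest range.
    """
    if not results:
        raise InputError("threshold_report requires at least one result")
    rows = []
    for veg_type, res in results:
        rows.append(
            {
                "index_name": res.index_name,
                "vegetation_type": veg_type,
                "threshold": res.threshold,
                "intersection_low": res.intersection_interval[0],
                "intersection_high": res.intersection_interval[1],
                "polarity": res.polarity.value,
                "misclassified_count": res.misclassified_count,
            }
        )
    per_result = pd.DataFrame(rows)
    agg = (
        per_result.groupby("index_name")["threshold"]
        .agg(["min", "max", "count"])
        .reset_index()
    )
    agg["threshold_range"] = agg["max"] - agg["min"]
    agg["most_stable"] = agg["threshold_range"] == agg["threshold_range"].min()
    per_index = agg.rename(
        columns={"min": "threshold_min", "max": "threshold_max", "count": "n_types"}
    )
    return IntersectionTable(per_result=per_result, per_index=per_index)
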