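"""Threshold segmentation, fractional cover and the accuracy battery.

Fractional vegetation cover (FVC) is the percentage of valid pixels labelled
vegetation.  The threshold mask is scored against the classifier-derived
mask, which plays the role of an approximate true value:

- extraction error (signed, relative, %):
  ``100 * (threshold_cov - reference_cov) / reference_cov``
- absolute error (percentage points): ``|threshold_cov - reference_cov|``
- per-index spread: sample standard deviation (n - 1) of the absolute errors
  across vegetation types

Confusion-matrix statistics follow the standard remote-sensing accuracy
vocabulary: user's accuracy is row-wise (of the pixels predicted as a class,
how many are right), producer's accuracy is column-wise, and Cohen's Kappa
is the chance-corrected agreement (p_o - p_e) / (1 - p_e) with p_e from the
row/column marginals.

All statistics are computed in full precision; rounding to two decimals
happens only when a report is serialised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .rasters import (
    NODATA_LABEL,
    ClassificationMask,
    LabeledPixelSet,
    MaskSource,
    Polarity,
    VIRaster,
)
from .histograms import ThresholdResult


def binarize(vi: VIRaster, threshold: float, polarity: Polarity) -> ClassificationMask:
    """Binarise a VI raster at a scalar threshold.

    veg_high: vegetation iff value >= threshold (closed on the vegetation
    side); veg_low: vegetation iff value <= threshold.  Invalid pixels map to
    nodata.
    """
    with np.errstate(invalid="ignore"):
        if polarity is Polarity.VEG_HIGH:
            veg = vi.values >= threshold
        else:
            veg = vi.values <= threshold
    labels = np.where(vi.valid_mask, veg.astype(np.uint8), NODATA_LABEL).astype(np.uint8)
    return ClassificationMask(labels=labels, source=MaskSource.THRESHOLD)


def segment_by_threshold(vi: VIRaster, thr: ThresholdResult) -> ClassificationMask:
    """Binarise a VI raster at a selected threshold (see :func:`binarize`)."""
    if vi.index_name.upper() != thr.index_name.upper():
        raise ConfigurationError(
            f"index mismatch: VI raster is {vi.index_name}, threshold is {thr.index_name}"
        )
    return binarize(vi, thr.threshold, thr.polarity)


@dataclass
class CoverageResult:
    """Fractional cover of one mask: coverage_pct = 100 * n_veg / n_valid."""

    method: str  # "threshold" | "classifier" | "truth"
    coverage_pct: float
    n_veg: int
    n_valid: int
    index_name: str | None = None
    threshold: float | None = None


def coverage(
    mask: ClassificationMask,
    index_name: str | None = None,
    threshold: float | None = None,
) -> CoverageResult:
    """Fractional vegetation cover of a classification mask, in percent."""
    n_valid = int(mask.valid.sum())
    if n_valid == 0:
        raise InputError("mask has no valid pixels")
    n_veg = int(mask.vegetation.sum())
    return CoverageResult(
        method=mask.source.value,
        coverage_pct=100.0 * n_veg / n_valid,
        n_veg=n_veg,
        n_valid=n_valid,
        index_name=index_name,
        threshold=threshold,
    )


@dataclass
class ConfusionMatrix2x2:
    """Predicted x reference pixel counts for vegetation (v) and soil (s).

    ``n_vs`` = predicted vegetation, reference soil, and so on.
    """

    n_vv: int
    n_vs: int
    n_sv: int
    n_ss: int

    def __post_init__(self):
        counts = (self.n_vv, self.n_vs, self.n_sv, self.n_ss)
        if any(c < 0 for c in counts):
            raise InputError("confusion counts must be non-negative")
        if sum(counts) == 0:
            raise InputError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.n_vv + self.n_vs + self.n_sv + self.n_ss


def confusion_from_masks(
    predicted: ClassificationMask, reference: ClassificationMask
) -> ConfusionMatrix2x2:
    """Cross-tabulate two masks over their jointly valid pixels."""
    both = predicted.valid & reference.valid
    p = predicted.vegetation[both]
    r = reference.vegetation[both]
    return ConfusionMatrix2x2(
        n_vv=int(np.sum(p & r)),
        n_vs=int(np.sum(p & ~r)),
        n_sv=int(np.sum(~p & r)),
        n_ss=int(np.sum(~p & ~r)),
    )


def confusion_from_labels(
    predicted: ClassificationMask, labels: LabeledPixelSet
) -> ConfusionMatrix2x2:
    """Cross-tabulate a mask against labelled validation pixels."""
    sel = predicted.valid[labels.rows, labels.cols]
    p = predicted.vegetation[labels.rows[sel], labels.cols[sel]]
    r = labels.is_vegetation()[sel]
    return ConfusionMatrix2x2(
        n_vv=int(np.sum(p & r)),
        n_vs=int(np.sum(p & ~r)),
        n_sv=int(np.sum(~p & r)),
        n_ss=int(np.sum(~p & ~r)),
    )


@dataclass
class AccuracySummary:
    overall_accuracy: float
    users_accuracy_veg: float
    users_accuracy_soil: float
    producers_accuracy_veg: float
    producers_accuracy_soil: float
    kappa: float

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


def confusion_stats(cm: ConfusionMatrix2x2) -> AccuracySummary:
    """Overall/user's/producer's accuracy and Cohen's Kappa of a 2x2 matrix."""
    n = cm.total
    p_o = (cm.n_vv + cm.n_ss) / n
    row_v, row_s = cm.n_vv + cm.n_vs, cm.n_sv + cm.n_ss
    col_v, col_s = cm.n_vv + cm.n_sv, cm.n_vs + cm.n_ss
    p_e = (row_v * col_v + row_s * col_s) / (n * n)
    if p_e == 1.0:
        raise InputError("degenerate marginals (p_e = 1): Kappa undefined")

    def _ratio(num, den):
        return num / den if den > 0 else float("nan")

    return AccuracySummary(
        overall_accuracy=p_o,
        users_accuracy_veg=_ratio(cm.n_vv, row_v),
        users_accuracy_soil=_ratio(cm.n_ss, row_s),
        producers_accuracy_veg=_ratio(cm.n_vv, col_v),
        producers_accuracy_soil=_ratio(cm.n_ss, col_s),
        kappa=(p_o - p_e) / (1.0 - p_e),
    )


@dataclass
class ErrorReport:
    """Per-vegetation-type coverage errors of one index (or one resolution).

    ``table`` columns: vegetation_type, threshold_coverage_pct,
    reference_coverage_pct, extraction_error_pct, absolute_error_points.
    ``abs_error_sd`` is the sample SD of the absolute errors across types
    (NaN for a single type).
    """

    index_name: str
    table: pd.DataFrame
    abs_error_sd: float

    def to_csv(self, path_or_buf=None, decimals: int = 2):
        out = self.table.copy()
        num_cols = [c for c in out.columns if out[c].dtype.kind == "f"]
        out[num_cols] = out[num_cols].round(decimals)
        out["abs_error_sd"] = round(self.abs_error_sd, decimals)
        return out.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "ErrorReport":
        df = pd.read_csv(path_or_buf)
        sd = float(df["abs_error_sd"].iloc[0])
        idx = str(df["index_name"].iloc[0]) if "index_name" in df else ""
        keep = [c for c in df.columns if c not in ("abs_error_sd",)]
        return cls(index_name=idx, table=df[keep], abs_error_sd=sd)


def extraction_errors(
    pairs: list[tuple[str, float, float]], index_name: str = ""
) -> ErrorReport:
    """Extraction/absolute errors of threshold coverage against the reference.

    Parameters
    ----------
    pairs
        ``(vegetation_type, threshold_coverage_pct, reference_coverage_pct)``
        tuples; reference coverage must be positive (it is the denominator of
        the signed relative error).
    index_name
        Optional tag recorded in the report.
    """
    if not pairs:
        raise InputError("extraction_errors requires at least one pair")
    rows = []
    for veg_type, thr_cov, ref_cov in pairs:
        if not ref_cov > 0:
            raise InputError(f"reference coverage must be > 0 (got {ref_cov} for {veg_type})")
        rows.append(
            {
                "index_name": index_name,
                "vegetation_type": veg_type,
                "threshold_coverage_pct": float(thr_cov),
                "reference_coverage_pct": float(ref_cov),
                "extraction_error_pct": 100.0 * (thr_cov - ref_cov) / ref_cov,
                "absolute_error_points": abs(thr_cov - ref_cov),
            }
        )
    table = pd.DataFrame(rows)
    abs_err = table["absolute_error_points"].to_numpy()
    sd = float(np.std(abs_err, ddof=1)) if len(abs_err) > 1 else float("nan")
    return ErrorReport(index_name=index_name, table=table, abs_error_sd=sd)


def error_table(per_index_pairs: dict[str, list[tuple[str, float, float]]]) -> pd.DataFrame:
    """Stack per-index ErrorReports into one long table (one row per cell)."""
    frames = []
    for index_name, pairs in per_index_pairs.items():
        rep = extraction_errors(pairs, index_name=index_name)
        t = rep.table.copy()
        t["abs_error_sd"] = rep.abs_error_sd
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def resolution_analysis(
    scenes: list[tuple[float, "RGBRaster"]],
    index_name: str,
    labels: LabeledPixelSet,
    thr: ThresholdResult | None = None,
    classifier_config=None,
    bin_width: float | None = None,
) -> ErrorReport:
    """Coverage error as a function of ground sample distance.

    Runs the full pipeline at each resolution with ONE fixed index and ONE
    fixed threshold (determined on the finest scene when ``thr`` is None),
    trains the classifier per resolution in single-index feature mode, and
    scores every resolution against the mean of the per-resolution classifier
    coverages — the approximate true value when no single resolution is
    privileged.

    ``labels`` is defined on the finest scene; coordinates are mapped to the
    coarser grids by the GSD ratio.
    """
    from .classify import ClassifierConfig, classify_raster, train_classifier
    from .indices import DEFAULT_BIN_WIDTH, compute_index
    from .histograms import build_class_histograms, find_intersection_threshold

    if len(scenes) < 2:
        raise InputError("resolution analysis needs at least two resolutions")
    scenes = sorted(scenes, key=lambda t: t[0])
    gsd0 = scenes[0][0]
    shape0 = scenes[0][1].shape
    for gsd, img in scenes:
        factor = gsd / gsd0
        expect = (round(shape0[0] / factor), round(shape0[1] / factor))
        if img.shape != expect:
            raise InputError(
                f"scene at gsd {gsd} has shape {img.shape}, expected {expect} "
                f"for a consistent extent"
            )
    bin_width = bin_width or DEFAULT_BIN_WIDTH[index_name.upper()]
    cfg = classifier_config or ClassifierConfig(features=index_name)

    if thr is None:
        vi0 = compute_index(scenes[0][1], index_name)
        hist = build_class_histograms(vi0, labels, bin_width)
        thr = find_intersection_threshold(hist)

    per_res = []
    for gsd, img in scenes:
        factor = gsd / gsd0
        lab = _rescale_labels(labels, factor, img.shape)
        vi = compute_index(img, index_name)
        model = train_classifier(img, lab, cfg)
        ref_mask = classify_raster(model, img)
        thr_mask = segment_by_threshold(vi, thr)
        per_res.append(
            (gsd, coverage(thr_mask).coverage_pct, coverage(ref_mask).coverage_pct)
        )
    reference = float(np.mean([r[2] for r in per_res]))
    pairs = [(f"{gsd:g} cm", thr_cov, reference) for gsd, thr_cov, _ in per_res]
    return extraction_errors(pairs, index_name=index_name.upper())


def _rescale_labels(
    labels: LabeledPixelSet, factor: float, shape: tuple[int, int]
) -> LabeledPixelSet:
    """Map finest-grid label coordinates onto a coarser grid (deduplicated)."""
    r = np.floor(labels.rows / factor).astype(np.intp)
    c = np.floor(labels.cols / factor).astype(np.intp)
    r = np.clip(r, 0, shape[0] - 1)
    c = np.clip(c, 0, shape[1] - 1)
    seen: dict[tuple[int, int], int] = {}
    keep = []
    for i, (ri, ci) in enumerate(zip(r, c)):
        if (ri, ci) not in seen:
            seen[(ri, ci)] = i
            keep.append(i)
    keep = np.asarray(keep, dtype=np.intp)
    return LabeledPixelSet(r[keep], c[keep], labels.labels[keep], labels.split[keep])


@dataclass
class SensitivityReport:
    """Overall accuracy at the nominal and perturbed thresholds."""

    index_name: str
    threshold: float
    perturbation_pct: float
    accuracy_nominal: float
    accuracy_low: float
    accuracy_high: float

    @property
    def max_accuracy_change_pct(self) -> float:
        """Largest absolute change in overall accuracy, percentage points."""
        return 100.0 * max(
            abs(self.accuracy_low - self.accuracy_nominal),
            abs(self.accuracy_high - self.accuracy_nominal),
        )


def threshold_sensitivity(
    vi: VIRaster,
    thr: ThresholdResult,
    labels: LabeledPixelSet,
    perturbation_pct: float = 5.0,
) -> SensitivityReport:
    """Robustness of overall accuracy to a relative threshold perturbation.

    Evaluates the labelled pixels at thresholds ``t * (1 ± p/100)`` and
    reports the accuracies; perturbed thresholds outside the observed VI
    range are clipped with a warning.
    """
    if perturbation_pct < 0:
        raise InputError("perturbation_pct must be >= 0")

    vals = vi.valid_values()
    lo, hi = float(vals.min()), float(vals.max())

    def _clip(t: float) -> float:
        if t < lo or t > hi:
            warnings.warn(
                f"perturbed threshold {t:g} outside VI range [{lo:g}, {hi:g}]; clipped",
                stacklevel=2,
            )
            return min(max(t, lo), hi)
        return t

    def _accuracy(t: float) -> float:
        mask = binarize(vi, t, thr.polarity)
        cm = confusion_from_labels(mask, labels)
        return confusion_stats(cm).overall_accuracy

    delta = abs(thr.threshold) * perturbation_pct / 100.0
    t_low = _clip(thr.threshold - delta)
    t_high = _clip(thr.threshold + delta)
    return SensitivityReport(
        index_name=thr.index_name,
        threshold=thr.threshold,
        perturbation_pct=perturbation_pct,
        accuracy_nominal=_accuracy(thr.threshold),
        accuracy_low=_accuracy(t_low),
        accuracy_high=_accuracy(t_high),
    )
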