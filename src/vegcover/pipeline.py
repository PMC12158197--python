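"""End-to-end pipeline: classify -> histogram -> threshold -> segment ->
coverage -> validate.

The driver mirrors the standard workflow for visible-light coverage mapping:
a support-vector classifier trained on hand-labelled pixels produces the
reference mask; class-conditional histograms of the chosen vegetation index
are built from that mask; the intersection threshold is selected; the scene
is segmented at the threshold; fractional cover is computed for both masks;
and the threshold mask is validated against the reference (confusion matrix,
Kappa, extraction errors).

Every artifact is written atomically, and a run log records the config hash,
seed and input checksums so a run can be re-identified without external
tooling.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as vio
from .classify import ClassifierConfig, classify_raster, train_classifier
from .coverage import (
    confusion_from_masks,
    confusion_stats,
    coverage,
    extraction_errors,
    segment_by_threshold,
)
from .errors import ConfigurationError, PipelineStageError
from .histograms import build_class_histograms, find_intersection_threshold
from .indices import DEFAULT_BIN_WIDTH, DEFAULT_POLARITY, INDEX_NAMES, compute_index
from .rasters import LabeledPixelSet, Polarity, RGBRaster, labels_from_mask


@dataclass
class PipelineConfig:
    """Run settings; unknown keys in a config file are rejected.

    ``histogram_sample_per_class`` bounds how many classifier-labelled pixels
    per class seed the histograms (None = all valid pixels).
    """

    index_name: str = "VDVI"
    bin_width: float | None = None
    smoothing_window: int = 1
    polarity: str | None = None  # "veg_high" / "veg_low" override
    threshold_override: float | None = None
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    histogram_sample_per_class: int | None = None
    seed: int = 0
    gsd_cm: float | None = None
    nodata: float | None = None
    report_format: str = "csv"  # "csv" | "json"

    def __post_init__(self):
        self.index_name = self.index_name.upper()
        if self.index_name not in INDEX_NAMES:
            raise ConfigurationError(f"unknown index {self.index_name!r}")
        if self.polarity is not None and self.polarity not in ("veg_high", "veg_low"):
            raise ConfigurationError("polarity must be 'veg_high' or 'veg_low'")
        if self.report_format not in ("csv", "json"):
            raise ConfigurationError("report_format must be 'csv' or 'json'")
        if isinstance(self.classifier, dict):
            self.classifier = ClassifierConfig(**self.classifier)

    @property
    def effective_bin_width(self) -> float:
        return self.bin_width if self.bin_width is not None else DEFAULT_BIN_WIDTH[self.index_name]

    @property
    def effective_polarity(self) -> Polarity:
        if self.polarity is not None:
            return Polarity(self.polarity)
        return DEFAULT_POLARITY[self.index_name]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        vio.write_text(path, yaml.safe_dump(self.to_dict(), sort_keys=True))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    threshold_result: object
    threshold_coverage: object
    classifier_coverage: object
    accuracy: object
    extraction: object
    artifacts: dict


def run_pipeline(
    cfg: PipelineConfig,
    image: RGBRaster | None = None,
    labels: LabeledPixelSet | None = None,
    image_path: str | Path | None = None,
    labels_path: str | Path | None = None,
    out_dir: str | Path = "vegcover_out",
    vegetation_type: str = "scene",
) -> PipelineResult:
    """Run the full coverage-extraction pipeline on one scene.

    Inputs may be given in memory (``image``/``labels``) or as paths; paths
    are also checksummed into the run log.  Stage failures are re-raised as
    :class:`PipelineStageError` naming the stage.
    """
    out_dir = Path(out_dir)
    checksums = {}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineStageError(name, exc) from exc

    if image is None:
        if image_path is None:
            raise ConfigurationError("either image or image_path is required")
        image = _stage("read_raster", lambda: vio.read_rgb_raster(
            image_path, gsd_cm=cfg.gsd_cm, nodata=cfg.nodata))
        checksums[str(image_path)] = vio.sha256_of(image_path)
    if labels is None:
        if labels_path is None:
            raise ConfigurationError("either labels or labels_path is required")
        labels = _stage("read_labels", lambda: vio.read_labels(labels_path))
        checksums[str(labels_path)] = vio.sha256_of(labels_path)

    train = labels.subset("train")
    model = _stage("train", lambda: train_classifier(image, train, cfg.classifier))
    ref_mask = _stage("classify", lambda: classify_raster(model, image))

    vi = _stage("index", lambda: compute_index(image, cfg.index_name))

    def _histogram():
        rng = np.random.default_rng(cfg.seed)
        hist_labels = labels_from_mask(
            ref_mask, n_per_class=cfg.histogram_sample_per_class, rng=rng
        )
        return build_class_histograms(
            vi, hist_labels, cfg.effective_bin_width, cfg.smoothing_window
        )

    hist = _stage("histogram", _histogram)
    thr = _stage(
        "threshold",
        lambda: find_intersection_threshold(hist, polarity=cfg.effective_polarity),
    )
    if cfg.threshold_override is not None:
        thr = dataclasses.replace(
            thr,
            threshold=cfg.threshold_override,
            intersection_interval=(
                min(thr.intersection_interval[0], cfg.threshold_override),
                max(thr.intersection_interval[1], cfg.threshold_override),
            ),
        )

    thr_mask = _stage("segment", lambda: segment_by_threshold(vi, thr))
    thr_cov = _stage("coverage", lambda: coverage(
        thr_mask, index_name=cfg.index_name, threshold=thr.threshold))
    ref_cov = _stage("coverage", lambda: coverage(ref_mask))

    def _validate():
        cm = confusion_from_masks(thr_mask, ref_mask)
        stats = confusion_stats(cm)
        err = extraction_errors(
            [(vegetation_type, thr_cov.coverage_pct, ref_cov.coverage_pct)],
            index_name=cfg.index_name,
        )
        return cm, stats, err

    cm, stats, err = _stage("validate", _validate)

    artifacts = _stage("write", lambda: _write_artifacts(
        out_dir, cfg, image, vi, ref_mask, thr_mask, hist, thr,
        thr_cov, ref_cov, cm, stats, err, checksums))

    return PipelineResult(
        threshold_result=thr,
        threshold_coverage=thr_cov,
        classifier_coverage=ref_cov,
        accuracy=stats,
        extraction=err,
        artifacts=artifacts,
    )


def _write_artifacts(out_dir, cfg, image, vi, ref_mask, thr_mask, hist, thr,
                     thr_cov, ref_cov, cm, stats, err, checksums) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vi": out_dir / f"vi_{cfg.index_name.lower()}.tif",
        "classifier_mask": out_dir / "mask_classifier.png",
        "threshold_mask": out_dir / "mask_threshold.png",
        "histogram": out_dir / "histograms.csv",
        "threshold": out_dir / "threshold.json",
        "report": out_dir / f"report.{cfg.report_format}",
        "log": out_dir / "run_log.json",
    }
    vio.write_vi_raster(paths["vi"], vi)
    vio.write_mask(paths["classifier_mask"], ref_mask)
    vio.write_mask(paths["threshold_mask"], thr_mask)
    vio.write_text(
        paths["histogram"],
        vio.CSV_COORD_HEADER + "\n" + hist.to_frame().to_csv(index=False),
    )
    vio.write_text(paths["threshold"], thr.to_json() + "\n")
    summary = {
        "threshold_coverage_pct": round(thr_cov.coverage_pct, 2),
        "classifier_coverage_pct": round(ref_cov.coverage_pct, 2),
        "confusion": {"n_vv": cm.n_vv, "n_vs": cm.n_vs, "n_sv": cm.n_sv, "n_ss": cm.n_ss},
        "accuracy": {k: round(v, 4) for k, v in stats.to_dict().items()},
    }
    if cfg.report_format == "json":
        vio.write_json(paths["report"], summary)
    else:
        vio.write_text(paths["report"], err.to_csv())
    vio.write_json(
        paths["log"],
        {
            "config": cfg.to_dict(),
            "config_hash": cfg.content_hash(),
            "seed": cfg.seed,
            "input_checksums": checksums,
            "summary": summary,
        },
    )
    return {k: str(v) for k, v in paths.items()}
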