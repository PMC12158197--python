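"""Supervised pixel classification used as the approximate reference.

A maximum-margin (support-vector) classifier is trained on hand-labelled
vegetation/soil pixels and applied per pixel.  Its mask serves two roles:
it seeds the class-conditional histograms from which the index threshold is
read, and it stands in as the approximate truth when scoring the threshold
segmentation — a practical surrogate for field-measured cover at scene scale.

Features are the raw (r, g, b) digital numbers by default; a single
vegetation index can be used instead, which is the natural feature space when
comparing against a VI threshold rule.  The classifier is pluggable: anything
exposing ``fit(X, y)`` / ``predict(X)`` over pixel feature rows works.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .errors import ConfigurationError, InputError
from .indices import INDEX_NAMES, compute_index
from .rasters import (
    NODATA_LABEL,
    ClassificationMask,
    LabeledPixelSet,
    MaskSource,
    RGBRaster,
)


@dataclass
class ClassifierConfig:
    """Settings for the default support-vector pixel classifier.

    ``features`` is ``"rgb"`` or one of the index names (single-feature
    mode).  The linear kernel with C = 1.0 is the default; both are exposed
    because class overlap in shadowed or mixed scenes can warrant an RBF
    kernel or a different margin penalty.
    """

    kernel: str = "linear"
    c: float = 1.0
    gamma: str | float = "scale"
    features: str = "rgb"
    seed: int = 0

    def __post_init__(self):
        feat = self.features if self.features == "rgb" else str(self.features).upper()
        if feat != "rgb" and feat not in INDEX_NAMES:
            raise ConfigurationError(
                f"features must be 'rgb' or one of {INDEX_NAMES}, got {self.features!r}"
            )
        self.features = feat


@dataclass
class PixelClassifier:
    """A fitted per-pixel vegetation/soil classifier."""

    model: object
    config: ClassifierConfig

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.model.predict(X))


def extract_features(image: RGBRaster, features: str) -> np.ndarray:
    """Per-pixel feature array of shape (rows*cols, n_features), float64.

    Pixels that are invalid under the feature definition carry NaN rows;
    callers mask them out.
    """
    if features == "rgb":
        return image.bands().reshape(-1, 3)
    vi = compute_index(image, features)
    return vi.values.reshape(-1, 1)


def train_classifier(
    image: RGBRaster,
    train: LabeledPixelSet,
    config: ClassifierConfig | None = None,
    model: object | None = None,
) -> PixelClassifier:
    """Fit the pixel classifier on a labelled training set.

    Parameters
    ----------
    image
        Raster providing the features at the training coordinates.
    train
        Labelled pixels; must contain both classes and lie on valid pixels.
    config
        Classifier settings; defaults to a linear-kernel SVC with C = 1.0.
    model
        Optional substitute estimator with ``fit``/``predict``; overrides the
        default SVC but still uses ``config.features``.
    """
    config = config or ClassifierConfig()
    train.check_inside(image.shape, image.valid_mask)
    if len(train) == 0:
        raise InputError("empty training set")
    y = train.is_vegetation().astype(np.int8)
    if y.all() or not y.any():
        raise InputError("training set must contain both vegetation and soil pixels")
    X_all = extract_features(image, config.features)
    flat = train.rows * image.cols + train.cols
    X = X_all[flat]
    if np.isnan(X).any():
        raise InputError("training pixels fall on feature-invalid pixels")
    if model is None:
        model = SVC(
            kernel=config.kernel,
            C=config.c,
            gamma=config.gamma,
            random_state=config.seed,
        )
    model.fit(X, y)
    return PixelClassifier(model=model, config=config)


def classify_raster(classifier: PixelClassifier, image: RGBRaster) -> ClassificationMask:
    """Label every valid pixel of a raster with the fitted classifier.

    Nodata pixels (and pixels invalid under a single-index feature space)
    propagate to nodata in the output mask.
    """
    X = extract_features(image, classifier.config.features)
    valid = image.valid_mask.reshape(-1) & ~np.isnan(X).any(axis=1)
    labels = np.full(X.shape[0], NODATA_LABEL, dtype=np.uint8)
    if valid.any():
        pred = classifier.predict(X[valid])
        labels[valid] = pred.astype(np.uint8)
    return ClassificationMask(
        labels=labels.reshape(image.shape), source=MaskSource.CLASSIFIER
    )


def training_accuracy(
    classifier: PixelClassifier, image: RGBRaster, labels: LabeledPixelSet
) -> float:
    """Fraction of labelled pixels the classifier reproduces."""
    X = extract_features(image, classifier.config.features)
    flat = labels.rows * image.cols + labels.cols
    pred = classifier.predict(X[flat])
    return float(np.mean(pred == labels.is_vegetation().astype(np.int8)))
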