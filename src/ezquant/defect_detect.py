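"""Trainable binary pixel classification of en face thickness maps.

Defective EZ appears dark (thickness ~ 0) against bright intact EZ on the
en face map.  A bank of intensity/texture features (raw thickness,
multi-scale Gaussian smoothing, gradient magnitude, local variance, local
min/max) feeds a bagged ensemble of decision trees; the trained model
classifies each pixel as defect vs intact, restricted to the central
subfield.
"""

from __future__ import annotations

import hashlib
import json
import pickle
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import (
    gaussian_filter,
    gaussian_gradient_magnitude,
    maximum_filter,
    minimum_filter,
    uniform_filter,
)
from sklearn.ensemble import RandomForestClassifier

from .enface import CSFMask, EnFaceMap

__all__ = [
    "FeatureConfig",
    "PixelClassifierModel",
    "DefectMask",
    "compute_features",
    "train_classifier",
    "classify",
    "save_model",
    "load_model",
]

MODEL_VERSION = "ezquant-pixel-classifier-1"


class TrainingError(ValueError):
    """Raised for unusable training data (e.g. a single class)."""


class ModelMismatchError(ValueError):
    """Feature configuration at predict time differs from training time."""


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-bank settings (scales in en face pixels)."""

    smooth_sigmas: tuple[float, ...] = (1.0, 2.0, 4.0)
    gradient_sigma: float = 1.0
    variance_window: int = 5
    minmax_window: int = 5

    @property
    def n_features(self) -> int:
        # raw + smoothed scales + gradient + variance + min + max
        return len(self.smooth_sigmas) + 5

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "smooth_sigmas": list(self.smooth_sigmas),
                "gradient_sigma": self.gradient_sigma,
                "variance_window": self.variance_window,
                "minmax_window": self.minmax_window,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def compute_features(enface_map: EnFaceMap, config: FeatureConfig | None = None) -> np.ndarray:
    """Per-pixel feature stack of shape (n_bscans, n_ascans, n_features).

    Deterministic: raw thickness, Gaussian-smoothed thickness at each
    configured scale, gradient magnitude, local variance, and local
    min/max over a square neighborhood.
    """
    config = config or FeatureConfig()
    img = np.asarray(enface_map.thickness_um, dtype=np.float64)
    feats = [img]
    for sigma in config.smooth_sigmas:
        feats.append(gaussian_filter(img, sigma))
    feats.append(gaussian_gradient_magnitude(img, config.gradient_sigma))
    w = config.variance_window
    mean = uniform_filter(img, w)
    mean_sq = uniform_filter(img * img, w)
    feats.append(np.maximum(mean_sq - mean * mean, 0.0))
    feats.append(minimum_filter(img, size=config.minmax_window))
    feats.append(maximum_filter(img, size=config.minmax_window))
    stack = np.stack(feats, axis=-1)
    if not np.all(np.isfinite(stack)):
        raise ValueError("non-finite feature values")
    return stack


@dataclass
class PixelClassifierModel:
    """A trained bagged-tree pixel classifier with its feature config."""

    forest: RandomForestClassifier
    feature_config: FeatureConfig
    training_seed: int
    version: str = MODEL_VERSION
    oob_accuracy: float | None = None

    def model_hash(self) -> str:
        """Content hash over the fitted trees and configuration.

        Stable across serialization round-trips; identical
        seed/config/data give an identical hash.
        """
        h = hashlib.sha256()
        h.update(self.version.encode())
        h.update(self.feature_config.config_hash().encode())
        h.update(str(self.training_seed).encode())
        for est in self.forest.estimators_:
            tree = est.tree_
            for arr in (
                tree.children_left,
                tree.children_right,
                tree.feature,
                tree.threshold,
                tree.value,
            ):
                h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()


@dataclass
class DefectMask:
    """Classified defect mask restricted to the CSF."""

    mask: np.ndarray
    probability: np.ndarray
    csf: CSFMask


def train_classifier(
    labeled: list[tuple[EnFaceMap, np.ndarray]],
    config: FeatureConfig | None = None,
    seed: int = 0,
    n_estimators: int = 60,
    max_depth: int = 12,
    max_train_pixels: int = 200_000,
) -> PixelClassifierModel:
    """Train the defect/intact pixel classifier on labeled en face maps.

    Parameters
    ----------
    labeled
        (map, true defect mask) pairs; masks are boolean grids of the map's
        shape.  At least one pair and both classes are required.
    seed
        Seeds both the pixel subsample and the forest; identical
        seed/config/data give an identical model hash.
    max_train_pixels
        Upper bound on training pixels (uniform subsample across maps).

    Returns
    -------
    PixelClassifierModel
        With out-of-bag accuracy as the held-out performance estimate.
    """
    if not labeled:
        raise TrainingError("no labeled maps provided")
    config = config or FeatureConfig()
    xs, ys = [], []
    for emap, mask in labeled:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != emap.thickness_um.shape:
            raise TrainingError("label mask shape does not match its map")
        stack = compute_features(emap, config)
        xs.append(stack.reshape(-1, config.n_features))
        ys.append(mask.reshape(-1))
    X = np.concatenate(xs)
    y = np.concatenate(ys)
    if np.unique(y).size < 2:
        raise TrainingError("training labels contain a single class")
    rng = np.random.default_rng(seed)
    if X.shape[0] > max_train_pixels:
        idx = rng.choice(X.shape[0], size=max_train_pixels, replace=False)
        idx.sort()
        X, y = X[idx], y[idx]
        if np.unique(y).size < 2:  # pragma: no cover - extreme imbalance
            raise TrainingError("subsample lost one class; increase max_train_pixels")
    forest = RandomForestClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        oob_score=True,
        n_jobs=1,
        random_state=int(rng.integers(0, 2**31)),
    )
    forest.fit(X, y)
    return PixelClassifierModel(
        forest=forest,
        feature_config=config,
        training_seed=seed,
        oob_accuracy=float(forest.oob_score_),
    )


def classify(
    enface_map: EnFaceMap,
    model: PixelClassifierModel,
    csf: CSFMask,
    feature_config: FeatureConfig | None = None,
) -> DefectMask:
    """Classify each CSF pixel of a map as defect vs intact.

    If the caller supplies its own ``feature_config``, its hash must match
    the one embedded in the model (:class:`ModelMismatchError` otherwise);
    features are always computed with the model's own config.
    """
    if (
        feature_config is not None
        and feature_config.config_hash() != model.feature_config.config_hash()
    ):
        raise ModelMismatchError(
            "feature config hash differs from the model's training config"
        )
    stack = compute_features(enface_map, model.feature_config)
    if stack.shape[-1] != model.forest.n_features_in_:
        raise ModelMismatchError("feature count does not match the trained model")
    proba = model.forest.predict_proba(stack.reshape(-1, stack.shape[-1]))
    defect_col = list(model.forest.classes_).index(True)
    prob = proba[:, defect_col].reshape(enface_map.thickness_um.shape)
    prob = np.where(csf.mask, prob, 0.0)
    mask = (prob >= 0.5) & csf.mask
    return DefectMask(mask=mask, probability=prob, csf=csf)


def save_model(model: PixelClassifierModel, path) -> None:
    """Serialize a model (pickle with embedded feature config and version)."""
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path) -> PixelClassifierModel:
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, PixelClassifierModel):
        raise ModelMismatchError("file does not contain a pixel classifier model")
    return model
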