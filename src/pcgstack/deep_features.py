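"""Deep-feature extraction stage with a pluggable backbone interface.

The design mirrors transfer-learning pipelines that take a pretrained CNN
(ResNet50, DenseNet121, InceptionResNetV2), feed it the resized
spectrogram image, and read activations from the final pooling layer.
Those backbones require GPU-scale pretrained weights and a deep-learning
runtime, neither of which is part of this package's test surface;
requesting one raises :class:`UnavailableBackboneError` explicitly rather
than silently falling back.

The ``desk_default`` backbone is a deterministic, seed-defined stand-in:
a random-projection convolutional filter bank (zero-mean 5x5 filters),
absolute-value rectification, 4x4 average pooling per filter map, and a
seeded random projection down to ``output_dim``.  It is cheap, fully
deterministic given its seed, and sensitive to band-energy structure in
the spectrogram image — enough to exercise every downstream stage
(PCA, random forests, stacking) on synthetic data.  Different seeds play
the role of the three architecturally distinct CNNs.

PCA here is a thin, exactly-specified implementation (centered SVD,
minimal component count reaching the requested variance fraction) so the
"reduce then classify" step is reproducible to the digit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .errors import InvalidConfigError, InvalidInputError, NotFittedError, \
    UnavailableBackboneError

__all__ = [
    "TrainSettings",
    "BackboneSpec",
    "extract_features",
    "PCAModel",
    "fit_pca",
    "transform_pca",
]

_CNN_BACKBONES = ("resnet50", "densenet121", "inception_resnet_v2")


@dataclass(frozen=True)
class TrainSettings:
    """Fine-tuning settings carried as configuration for CNN backbones."""

    optimizer: str = "adam"
    batch_size: int = 16
    epochs: int = 120
    learning_rate: float = 1e-4
    early_stopping_patience: int = 10


@dataclass(frozen=True)
class BackboneSpec:
    name: str = "desk_default"
    output_dim: int = 64
    seed: int = 0
    fine_tune: bool = False
    train_settings: TrainSettings = field(default_factory=TrainSettings)

    def __post_init__(self) -> None:
        if self.name not in _CNN_BACKBONES + ("desk_default",):
            raise InvalidConfigError(f"unknown backbone: {self.name}")
        if self.output_dim < 1:
            raise InvalidConfigError("output_dim must be positive")


def _desk_features(images: np.ndarray, spec: BackboneSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    n_filters, ksize, grid = 16, 5, 4
    filters = rng.normal(size=(n_filters, ksize, ksize))
    filters -= filters.mean(axis=(1, 2), keepdims=True)
    proj = rng.normal(size=(n_filters * grid * grid, spec.output_dim))
    proj /= np.sqrt(proj.shape[0])
    rows = []
    for img in images:
        pooled = []
        for filt in filters:
            resp = np.abs(fftconvolve(img, filt, mode="valid"))
            h, w = resp.shape
            rb = np.array_split(np.arange(h), grid)
            cb = np.array_split(np.arange(w), grid)
            cells = [resp[np.ix_(r, c)].mean() for r in rb for c in cb]
            pooled.extend(cells)
        rows.append(np.asarray(pooled) @ proj)
    return np.vstack(rows)


def extract_features(images: np.ndarray | list[np.ndarray],
                     spec: BackboneSpec = BackboneSpec()) -> np.ndarray:
    """One feature row per image; rows align with input order.

    ``images`` is a (batch, H, W) stack or list of equal-size gray images.
    """
    imgs = np.asarray(images, dtype=float)
    if imgs.ndim == 2:
        imgs = imgs[None]
    if imgs.ndim != 3 or imgs.shape[0] == 0:
        raise InvalidInputError("images must be a non-empty (batch, H, W) stack "
                                "of uniform size")
    if spec.name in _CNN_BACKBONES:
        raise UnavailableBackboneError(
            f"backbone '{spec.name}' requires pretrained ImageNet weights and a "
            "deep-learning runtime, neither of which is available here; use "
            "name='desk_default' or provide a runtime with weights")
    F = _desk_features(imgs, spec)
    if not np.all(np.isfinite(F)):
        raise InvalidInputError("non-finite feature values")
    return F


@dataclass
class PCAModel:
    """Centered PCA retaining the minimal component count whose explained
    variance reaches the requested fraction."""

    mean_: np.ndarray | None = None
    components_: np.ndarray | None = None  # (n_components, dims)
    explained_variance_ratio_: np.ndarray | None = None
    variance_fraction: float = 0.95

    @property
    def n_components(self) -> int:
        if self.components_ is None:
            raise NotFittedError("PCA model is not fitted")
        return self.components_.shape[0]


def fit_pca(F: np.ndarray, variance_fraction: float = 0.95) -> PCAModel:
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[0] < 2:
        raise InvalidInputError("PCA needs at least 2 samples")
    if not (0 < variance_fraction <= 1):
        raise InvalidConfigError("variance_fraction must be in (0, 1]")
    mean = F.mean(axis=0)
    X = F - mean
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total <= 0:  # constant data: keep a single (arbitrary) direction
        ratios = np.zeros(1)
        k = 1
    else:
        ratios = var / total
        csum = np.cumsum(ratios)
        k = int(np.searchsorted(csum, variance_fraction - 1e-12) + 1)
        # drop numerically-null directions when full variance is requested
        k = min(k, int(np.sum(var > total * 1e-15)) or 1)
    model = PCAModel(mean_=mean, components_=Vt[:k],
                     explained_variance_ratio_=ratios[:k],
                     variance_fraction=variance_fraction)
    return model


def transform_pca(model: PCAModel, F: np.ndarray) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    if model.components_ is None:
        raise NotFittedError("PCA model is not fitted")
    if F.ndim != 2 or F.shape[1] != model.components_.shape[1]:
        raise InvalidInputError("feature dimension mismatch with fitted PCA")
    return (F - model.mean_) @ model.components_.T


def inverse_transform_pca(model: PCAModel, Z: np.ndarray) -> np.ndarray:
    if model.components_ is None:
        raise NotFittedError("PCA model is not fitted")
    return np.asarray(Z, dtype=float) @ model.components_ + model.mean_
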