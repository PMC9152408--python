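"""Per-pixel feature vectors from DTCWT subband energies, plus clustering.

Each pixel receives ``6 * levels + 1`` channels: for every scale and
orientation the locally smoothed subband magnitude (square-rooted, the
amplitude-compressing convention used throughout), nearest-neighbour
upsampled to the image grid, plus the coarse lowpass residual as an
intensity channel.  Pixels with equal features are grouped by k-means
(k-means++ start, channels standardized to unit variance), and each class
carries an energy value: the sum of squared feature-vector norms of its
member pixels.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .errors import ValidationError
from .transform import Pyramid

__all__ = [
    "FeatureMap",
    "FeatureClustering",
    "extract_features",
    "with_intensity_channel",
    "cluster",
    "class_energy",
]


@dataclass(frozen=True)
class FeatureMap:
    """Per-pixel feature vectors; ``vectors`` has shape ``(H, W, C)``."""

    vectors: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.vectors.shape[:2]

    @property
    def n_channels(self) -> int:
        return self.vectors.shape[2]


@dataclass(frozen=True)
class FeatureClustering:
    """K-means partition of the pixels of a :class:`FeatureMap`.

    ``centroids`` live in the original (unstandardized) feature space;
    ``energies[k]`` is the class-k feature energy (see :func:`class_energy`).
    """

    labels: np.ndarray
    centroids: np.ndarray
    energies: np.ndarray


def _upsample_to(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour upsample by the (integer) shape ratio, then crop."""
    fy = int(np.ceil(shape[0] / arr.shape[0]))
    fx = int(np.ceil(shape[1] / arr.shape[1]))
    up = np.repeat(np.repeat(arr, fy, axis=0), fx, axis=1)
    return up[: shape[0], : shape[1]]


def extract_features(pyramid: Pyramid) -> FeatureMap:
    """Subband-energy feature vectors on the source pixel grid.

    Per level and orientation: ``sqrt(smooth_3x3(|coefficient|))``, upsampled
    nearest-neighbour; the last channel is the upsampled lowpass residual.
    """
    shape = pyramid.source_shape
    channels = []
    for band in pyramid.highpasses:
        mag = np.abs(band)
        for k in range(band.shape[-1]):
            sm = ndimage.uniform_filter(mag[..., k], size=3, mode="reflect")
            channels.append(_upsample_to(np.sqrt(np.maximum(sm, 0.0)), shape))
    channels.append(_upsample_to(pyramid.lowpass, shape))
    return FeatureMap(vectors=np.stack(channels, axis=-1))


def with_intensity_channel(features: FeatureMap, image: np.ndarray) -> FeatureMap:
    """Replace the lowpass channel with a full-resolution intensity image.

    The upsampled coarse residual localizes region boundaries only to the
    coarse grid; substituting the (denoised) image itself keeps the
    intensity channel sharp at boundaries, which the MAP segmentation stage
    relies on.  Magnitude channels are untouched.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != features.shape:
        raise ValidationError(
            f"intensity shape {image.shape} does not match features {features.shape}"
        )
    v = features.vectors.copy()
    v[..., -1] = image
    return FeatureMap(vectors=v)


def cluster(features: FeatureMap, k: int, seed: int = 0, max_iter: int = 100) -> FeatureClustering:
    """K-means over pixels with unit-variance channel standardization.

    Deterministic for a fixed seed (single k-means++ initialization).
    """
    h, w, c = features.vectors.shape
    n = h * w
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of pixels ({n})")
    X = features.vectors.reshape(n, c)
    sd = X.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)
    Xs = X / scale
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=max_iter,
                random_state=seed)
    labels = km.fit_predict(Xs).astype(np.int32).reshape(h, w)
    centroids = km.cluster_centers_ * scale
    energies = np.array([class_energy(features, labels, i) for i in range(k)])
    return FeatureClustering(labels=labels, centroids=centroids, energies=energies)


def class_energy(features: FeatureMap, clustering, class_id: int) -> float:
    """Energy of one feature class: sum over member pixels of ||vector||^2.

    ``clustering`` may be a :class:`FeatureClustering` or a bare label map.
    An absent class has energy 0.
    """
    labels = clustering.labels if isinstance(clustering, FeatureClustering) else clustering
    member = labels == class_id
    if not member.any():
        return 0.0
    v = features.vectors[member]
    return float(np.sum(v * v))
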