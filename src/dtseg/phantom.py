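"""Synthetic brain-like phantom slices with ground-truth labels.

Real brain CT/MR slices show a bright skull ring enclosing smooth tissue
with one or a few tumor blobs of distinct mean intensity.  The phantom
reproduces exactly that geometry so every downstream stage (denoising,
clustering, MAP segmentation, RL refinement) can be validated against a
known truth without external data.

Class layout
------------
``0``  background (air), ``1``  skull ring (must be the brightest class when
``n_classes >= 3``), ``2``  brain tissue, ``3 ..``  tumor classes.  A
two-class phantom collapses to background + head disc.  Tumor shapes are
thresholded Gaussian-smoothed random fields intersected with ellipses:
irregular yet connected blobs with clear boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError

__all__ = ["PhantomSpec", "NoisySample", "generate_phantom", "add_noise", "make_dataset"]

#: Default class means by role for common class counts (background, skull,
#: tissue, tumors...).  Chosen to mimic CT contrast: dark air, bright bone,
#: mid-grey tissue, tumors offset from tissue.
_DEFAULT_MEANS = {
    2: [0.1, 0.7],
    3: [0.05, 0.95, 0.45],
    4: [0.05, 0.95, 0.45, 0.7],
    5: [0.05, 0.95, 0.45, 0.7, 0.25],
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic brain slice.

    ``class_means``/``class_texture_sd`` default to a CT-like palette for
    ``n_classes`` up to 5.  ``tumor_smooth_sd`` controls blob irregularity
    (larger = smoother, rounder tumors).
    """

    height: int = 128
    width: int = 128
    n_classes: int = 4
    tumor_count_range: tuple[int, int] = (1, 3)
    class_means: tuple[float, ...] | None = None
    class_texture_sd: tuple[float, ...] | None = None
    seed: int = 0
    tumor_smooth_sd: float = 3.0

    def resolved_means(self) -> np.ndarray:
        if self.class_means is not None:
            return np.asarray(self.class_means, dtype=float)
        if self.n_classes in _DEFAULT_MEANS:
            return np.asarray(_DEFAULT_MEANS[self.n_classes], dtype=float)
        base = list(_DEFAULT_MEANS[5])
        extra = np.linspace(0.6, 0.3, self.n_classes - 5)
        return np.asarray(base + list(extra), dtype=float)

    def resolved_texture_sd(self) -> np.ndarray:
        if self.class_texture_sd is not None:
            return np.asarray(self.class_texture_sd, dtype=float)
        return np.full(self.n_classes, 0.02)

    def validate(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValidationError(
                f"phantom size {self.height}x{self.width} too small (min 32x32)"
            )
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        means = self.resolved_means()
        if means.size != self.n_classes:
            raise ValidationError(
                f"class_means has {means.size} entries for {self.n_classes} classes"
            )
        if np.any(means < 0) or np.any(means > 1):
            raise ValidationError("class means must lie in [0, 1]")
        if np.unique(means).size != means.size:
            raise ValidationError("class means must be pairwise distinct")
        if self.n_classes >= 3 and means.argmax() != 1:
            raise ValidationError(
                "class 1 is the skull ring and must have the brightest mean"
            )
        sds = self.resolved_texture_sd()
        if sds.size != self.n_classes or np.any(sds < 0):
            raise ValidationError("class_texture_sd must be n_classes non-negative values")
        lo, hi = self.tumor_count_range
        if lo < 0 or hi < lo:
            raise ValidationError(f"invalid tumor_count_range {self.tumor_count_range}")
        if hi > 0 and self.n_classes < 4:
            raise ValidationError(
                "tumors require n_classes >= 4 (background, skull, tissue, tumor)"
            )

    @property
    def tumor_classes(self) -> tuple[int, ...]:
        return tuple(range(3, self.n_classes))


@dataclass(frozen=True)
class NoisySample:
    """A clean/noisy image pair with its ground-truth label map."""

    clean: np.ndarray
    noisy: np.ndarray
    truth: np.ndarray
    sigma: float

    def __post_init__(self):
        if not (self.clean.shape == self.noisy.shape == self.truth.shape):
            raise ValidationError("clean, noisy and truth must share one shape")


def _ellipse_mask(h, w, cy, cx, ry, rx, angle=0.0):
    yy, xx = np.mgrid[0:h, 0:w]
    ca, sa = np.cos(angle), np.sin(angle)
    y = (yy - cy) * ca + (xx - cx) * sa
    x = -(yy - cy) * sa + (xx - cx) * ca
    return (y / ry) ** 2 + (x / rx) ** 2 <= 1.0


def _place_tumors(rng, tissue, spec, labels):
    """Draw the requested number of tumor blobs strictly inside the tissue."""
    lo, hi = spec.tumor_count_range
    count = int(rng.integers(lo, hi + 1))
    if count == 0:
        return 0
    h, w = labels.shape
    interior = ndimage.binary_erosion(tissue, iterations=3)
    tumor_ids = spec.tumor_classes
    placed = 0
    occupied = np.zeros_like(tissue)
    for attempt in range(200):
        if placed == count:
            break
        ys, xs = np.nonzero(interior)
        if ys.size == 0:
            break
        i = int(rng.integers(ys.size))
        cy, cx = ys[i], xs[i]
        ry = rng.uniform(0.05, 0.12) * h
        rx = rng.uniform(0.05, 0.12) * w
        ell = _ellipse_mask(h, w, cy, cx, ry, rx, rng.uniform(0, np.pi))
        fld = ndimage.gaussian_filter(rng.normal(size=(h, w)), spec.tumor_smooth_sd)
        blob = ell & (fld > np.quantile(fld[ell], 0.3) if ell.any() else False)
        blob &= interior
        if not blob.any():
            continue
        # keep the largest connected component only
        lab, n = ndimage.label(blob)
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
            blob = lab == (1 + int(np.argmax(sizes)))
        if blob.sum() < 12:
            continue
        # keep blobs separated so component counts stay exact
        if (ndimage.binary_dilation(blob, iterations=2) & occupied).any():
            continue
        labels[blob] = tumor_ids[placed % len(tumor_ids)]
        occupied |= blob
        placed += 1
    if placed < count:
        raise ValidationError(
            f"could not place {count} tumors in a {h}x{w} phantom; "
            "enlarge the image or reduce tumor_count_range"
        )
    return placed


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate one clean phantom slice and its label map.

    Returns
    -------
    image : float array in [0, 1]; per-pixel class mean + texture noise.
    labels : integer label map (values in ``[0, n_classes)``).

    Deterministic for a fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    labels = np.zeros((h, w), dtype=np.int32)

    cy = h / 2 + rng.uniform(-0.02, 0.02) * h
    cx = w / 2 + rng.uniform(-0.02, 0.02) * w
    ry = rng.uniform(0.36, 0.42) * h
    rx = rng.uniform(0.36, 0.42) * w
    head = _ellipse_mask(h, w, cy, cx, ry, rx)
    ring_w = max(2, int(round(0.03 * min(h, w))))
    inner = ndimage.binary_erosion(head, iterations=ring_w)

    if spec.n_classes == 2:
        labels[head] = 1
    else:
        labels[head & ~inner] = 1  # skull ring
        labels[inner] = 2  # tissue
        _place_tumors(rng, inner, spec, labels)

    means = spec.resolved_means()
    sds = spec.resolved_texture_sd()
    image = means[labels] + rng.normal(size=(h, w)) * sds[labels]
    return np.clip(image, 0.0, 1.0), labels


def add_noise(image: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise of standard deviation ``sigma``.

    The result is intentionally not clipped: the wavelet-domain denoiser
    assumes true Gaussian statistics.
    """
    if sigma < 0:
        raise ValidationError(f"sigma must be >= 0, got {sigma}")
    image = np.asarray(image, dtype=float)
    if sigma == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    return image + rng.normal(0.0, sigma, size=image.shape)


def make_dataset(n: int, spec: PhantomSpec, sigma: float, seed: int) -> list[NoisySample]:
    """Generate ``n`` independent noisy phantom samples.

    Per-sample seeds derive deterministically from the master ``seed``, so
    the same call always returns bit-identical datasets.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    master = np.random.default_rng(seed)
    samples = []
    for _ in range(n):
        phantom_seed, noise_seed = (int(s) for s in master.integers(0, 2**31 - 1, 2))
        sub = PhantomSpec(
            height=spec.height,
            width=spec.width,
            n_classes=spec.n_classes,
            tumor_count_range=spec.tumor_count_range,
            class_means=spec.class_means,
            class_texture_sd=spec.class_texture_sd,
            seed=phantom_seed,
            tumor_smooth_sd=spec.tumor_smooth_sd,
        )
        clean, truth = generate_phantom(sub)
        noisy = add_noise(clean, sigma, noise_seed)
        samples.append(NoisySample(clean=clean, noisy=noisy, truth=truth, sigma=sigma))
    return samples
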