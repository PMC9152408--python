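"""Gaussian denoising by bivariate MAP shrinkage of DTCWT coefficients,
followed by an optional edge-preserving anisotropic diffusion step.

Model
-----
An observed wavelet coefficient is ``beta = alpha + delta`` with ``delta``
zero-mean Gaussian of SD ``sigma_n``.  A coefficient and its parent at the
next coarser scale share local signal energy; with the bivariate prior
``p(a1, a2) propto exp(-(sqrt(3)/sigma) * sqrt(a1^2 + a2^2))`` the MAP
estimate of the clean child is the closed-form shrinkage

    m = sqrt(|child|^2 + |parent|^2)
    alpha_hat = child * max(m - sqrt(3) * sigma_n^2 / sigma, 0) / m

a soft threshold on the joint child/parent magnitude.  One magnitude factor
scales real and imaginary parts alike, preserving phase.  ``sigma_n`` is
estimated by the robust median rule on the finest diagonal subbands;
``sigma`` by a local moment estimate per coefficient.

The diffusion step is an explicit 4-neighbour Perona-Malik iteration in
flux (divergence) form with reflecting boundaries, which conserves the mean
intensity exactly and smooths residual noise without blurring edges.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .transform import Pyramid, forward, inverse, parent_of

__all__ = [
    "NoiseModel",
    "DiffusionConfig",
    "estimate_sigma_n",
    "estimate_sigma_local",
    "shrink",
    "denoise_pyramid",
    "diffuse",
    "denoise_image",
]

logger = logging.getLogger(__name__)

#: Lower bound applied to the local signal SD before it divides anything.
SIGMA_FLOOR = 1e-8


@dataclass(frozen=True)
class NoiseModel:
    """Wavelet-domain noise description used by :func:`denoise_pyramid`.

    ``sigma_n`` is the coefficient-domain noise SD; ``window`` the odd side
    length of the neighbourhood used for the local signal-SD estimate.
    """

    sigma_n: float
    window: int = 7

    def __post_init__(self):
        if self.sigma_n < 0:
            raise ValidationError("sigma_n must be >= 0")
        if self.window < 3 or self.window % 2 == 0:
            raise ValidationError("window must be odd and >= 3")


@dataclass(frozen=True)
class DiffusionConfig:
    """Perona-Malik diffusion parameters.

    ``dt`` must lie in (0, 0.25] for stability of the explicit 4-neighbour
    scheme; ``kappa`` is the gradient-magnitude threshold (estimated as the
    90th percentile of gradient magnitudes when None); ``conductance``
    selects exp(-(g/kappa)^2) or 1/(1+(g/kappa)^2).
    """

    iterations: int = 10
    dt: float = 0.2
    kappa: float | None = None
    conductance: str = "exponential"

    def __post_init__(self):
        if self.iterations < 0:
            raise ValidationError("iterations must be >= 0")
        if not 0.0 < self.dt <= 0.25:
            raise ValidationError(f"dt={self.dt} outside the stable range (0, 0.25]")
        if self.kappa is not None and self.kappa <= 0:
            raise ValidationError("kappa must be positive")
        if self.conductance not in ("exponential", "rational"):
            raise ValidationError(f"unknown conductance {self.conductance!r}")


def estimate_sigma_n(pyramid: Pyramid) -> float:
    """Robust wavelet-domain noise SD: MAD of the finest diagonal subbands.

    ``median(|Re beta|) / 0.6745`` over the +/-45 degree subbands of level 1,
    the subbands most dominated by noise.  Invariant to constant image
    offsets (highpass filters annihilate DC).
    """
    if pyramid.levels < 1:
        raise ValidationError("pyramid has no highpass levels")
    finest = pyramid.highpasses[0]
    diag = np.concatenate(
        [finest[..., 1].real.ravel(), finest[..., 4].real.ravel()]
    )
    return float(np.median(np.abs(diag)) / 0.6745)


def estimate_sigma_local(subband: np.ndarray, sigma_n: float, window: int) -> np.ndarray:
    """Per-coefficient signal SD from the local second moment.

    ``sqrt(max(mean_{window x window}(|beta|^2) - sigma_n^2, 0))`` with
    reflected borders, floored at a small positive epsilon.
    """
    if window < 3 or window % 2 == 0:
        raise ValidationError("window must be odd and >= 3")
    power = np.abs(subband) ** 2
    local = ndimage.uniform_filter(power, size=window, mode="reflect")
    return np.sqrt(np.maximum(local - sigma_n**2, 0.0)).clip(min=SIGMA_FLOOR)


def shrink(child, parent, sigma_n, sigma_local):
    """Bivariate MAP shrinkage of a child coefficient given its parent.

    Accepts scalars or broadcastable arrays.  The magnitude factor
    ``g = max(m - sqrt(3) sigma_n^2 / sigma_local, 0) / m`` with
    ``m = sqrt(|child|^2 + |parent|^2)`` multiplies the complex child, so
    phase is preserved and ``|out| <= |in|`` everywhere.
    """
    child = np.asarray(child)
    parent = np.asarray(parent)
    if not (np.all(np.isfinite(child)) and np.all(np.isfinite(parent))):
        raise ValidationError("non-finite coefficients passed to shrink")
    sigma_local = np.maximum(np.asarray(sigma_local, dtype=float), SIGMA_FLOOR)
    m = np.sqrt(np.abs(child) ** 2 + np.abs(parent) ** 2)
    thresh = np.sqrt(3.0) * (np.asarray(sigma_n, dtype=float) ** 2) / sigma_local
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(m > 0, np.maximum(m - thresh, 0.0) / np.where(m > 0, m, 1.0), 0.0)
    out = g * child
    if out.ndim == 0:
        return complex(out) if np.iscomplexobj(child) else float(out)
    return out


def denoise_pyramid(pyramid: Pyramid, model: NoiseModel) -> Pyramid:
    """Apply bivariate shrinkage to every detail coefficient.

    Levels ``1..L-1`` use their true parents; the coarsest level (and every
    level of a depth-1 pyramid, with a logged warning) uses a zero parent.
    The lowpass residual is untouched.
    """
    if pyramid.levels < 2:
        logger.warning(
            "denoise_pyramid on a depth-%d pyramid: using zero parents", pyramid.levels
        )
    out = []
    for lev, band in enumerate(pyramid.highpasses):
        if lev < pyramid.levels - 1:
            par = parent_of(pyramid, lev)
        else:
            par = np.zeros_like(band)
        new = np.empty_like(band)
        for k in range(band.shape[-1]):
            sub = band[..., k]
            sigma_local = estimate_sigma_local(sub, model.sigma_n, model.window)
            new[..., k] = shrink(sub, par[..., k], model.sigma_n, sigma_local)
        out.append(new)
    return Pyramid(
        lowpass=pyramid.lowpass.copy(),
        highpasses=tuple(out),
        source_shape=pyramid.source_shape,
    )


def _conductance(g2, kappa, kind):
    if kind == "exponential":
        return np.exp(-g2 / kappa**2)
    return 1.0 / (1.0 + g2 / kappa**2)


def diffuse(image: np.ndarray, config: DiffusionConfig) -> np.ndarray:
    """Explicit Perona-Malik anisotropic diffusion.

    Flux form over the four pixel edges with zero flux across the image
    border (Neumann), so the image mean is conserved to machine precision.
    """
    image = np.asarray(image, dtype=float)
    if config.iterations == 0:
        return image.copy()
    kappa = config.kappa
    if kappa is None:
        gy, gx = np.gradient(image)
        mag = np.hypot(gy, gx)
        kappa = float(np.percentile(mag, 90))
        if kappa <= 0:
            return image.copy()  # flat image: nothing to diffuse
    u = image.copy()
    for _ in range(config.iterations):
        dv = np.diff(u, axis=0)  # u[i+1,:] - u[i,:]
        dh = np.diff(u, axis=1)
        cv = _conductance(dv**2, kappa, config.conductance)
        ch = _conductance(dh**2, kappa, config.conductance)
        fv = cv * dv
        fh = ch * dh
        div = np.zeros_like(u)
        div[:-1, :] += fv
        div[1:, :] -= fv
        div[:, :-1] += fh
        div[:, 1:] -= fh
        u += config.dt * div
    return u


def denoise_image(
    image: np.ndarray,
    levels: int = 4,
    diffusion: DiffusionConfig | None = None,
    sigma_n: float | None = None,
    window: int = 7,
) -> np.ndarray:
    """End-to-end denoiser: DTCWT -> bivariate shrinkage -> inverse -> diffusion.

    ``sigma_n`` overrides the median-based noise estimate when given;
    ``diffusion=None`` uses the default :class:`DiffusionConfig`, and
    ``DiffusionConfig(iterations=0)`` disables the diffusion stage.
    """
    pyr = forward(image, levels=levels)
    if sigma_n is None:
        sigma_n = estimate_sigma_n(pyr)
    model = NoiseModel(sigma_n=sigma_n, window=window)
    den = denoise_pyramid(pyr, model)
    rec = inverse(den)
    cfg = DiffusionConfig() if diffusion is None else diffusion
    return diffuse(rec, cfg)
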