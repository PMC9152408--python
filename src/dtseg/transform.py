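"""Dual-tree complex wavelet transform (DTCWT) for 2-D images.

The DTCWT runs two real wavelet trees whose filters are offset by half a
sample, producing six complex directional subbands per scale (orientations
near +/-15, +/-45 and +/-75 degrees).  Subband magnitudes are approximately
shift invariant — the property that makes the transform attractive for
denoising and texture features — while perfect reconstruction is retained.

Implementation notes
--------------------
Each of the four row/column tree combinations is a separable, critically
sampled DWT executed with :mod:`pywt` (``mode="periodization"``), so perfect
reconstruction is inherited from the per-tree filter banks.  Level 1 of
tree *b* equals tree *a* delayed by one input sample (realised as a circular
roll); levels >= 2 use an orthonormal quarter-shift ("Q-shift") filter in
tree *b* and its time reverse in tree *a*, giving the half-sample cumulative
delay offset between trees at every scale.

The Q-shift filter is designed in-package: an 18-tap orthonormal lowpass
filter with one vanishing moment and group delay 8.75 +/- 0.01 samples
(= (N-1)/2 + 1/4), obtained by shaping a symmetric length-36 prototype whose
even-indexed samples form the filter, under exact orthonormality
constraints.  ``scripts/design_qshift_filter.py`` regenerates the
coefficients below.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .errors import ValidationError

__all__ = [
    "Pyramid",
    "forward",
    "inverse",
    "parent_of",
    "pad_to_depth",
    "save_pyramid",
    "load_pyramid",
    "ORIENTATIONS",
    "ORIENTATION_PAIRS",
]

# Orientation (degrees) of each subband slice along the last axis.
ORIENTATIONS = (15, 45, 75, -75, -45, -15)
# Index pairs forming the +/- orientation couples.
ORIENTATION_PAIRS = {15: (0, 5), 45: (1, 4), 75: (2, 3)}

#: 18-tap orthonormal quarter-shift lowpass filter (tree b; tree a uses the
#: time reverse).  Group delay 8.75 samples, one vanishing moment, exact
#: conjugate-quadrature orthonormality.  See scripts/design_qshift_filter.py.
QSHIFT_LOWPASS = np.array(
    [
        0.004046781551803535,
        -0.002289979406676751,
        -0.0029487533987103184,
        -0.02459311506660269,
        0.054209791187525724,
        0.01415975866460143,
        -0.14412673696746447,
        0.04627091232478482,
        0.5664889076038478,
        0.7327457253441839,
        0.3025442704669351,
        -0.11319583177309168,
        -0.07901696267432862,
        0.06790719675832328,
        0.0047084164752957056,
        -0.016020374414878438,
        0.0012010669416430756,
        0.0021224887559036397,
    ]
)

#: Name of the pywt biorthogonal wavelet used at level 1 of both trees.
LEVEL1_WAVELET = "bior6.8"

_SQ2 = np.sqrt(0.5)
_COMBOS = (("a", "a"), ("a", "b"), ("b", "a"), ("b", "b"))


def _cqf_wavelet(h: np.ndarray) -> pywt.Wavelet:
    """Build a pywt Wavelet for an orthonormal lowpass filter ``h``."""
    n = np.arange(h.size)
    dec_lo = np.asarray(h, dtype=float)
    dec_hi = ((-1.0) ** n) * dec_lo[::-1]
    return pywt.Wavelet(
        "qshift",
        filter_bank=(
            dec_lo.tolist(),
            dec_hi.tolist(),
            dec_lo[::-1].tolist(),
            dec_hi[::-1].tolist(),
        ),
    )


_WAV_TREE_A = _cqf_wavelet(QSHIFT_LOWPASS[::-1])  # group delay (N-1)/2 - 1/4
_WAV_TREE_B = _cqf_wavelet(QSHIFT_LOWPASS)  # group delay (N-1)/2 + 1/4
_WAV_LEVEL1 = pywt.Wavelet(LEVEL1_WAVELET)


@dataclass(frozen=True)
class Pyramid:
    """DTCWT decomposition of a 2-D image.

    Attributes
    ----------
    lowpass:
        Real coarse residual.  The four tree combinations are interleaved on
        a twice-oversampled grid (row/column parity selects the tree pair),
        so the array is ``padded_shape / 2**(levels-1)``.
    highpasses:
        Tuple of complex arrays, finest level first.  Level ``l`` has shape
        ``(H/2**(l+1), W/2**(l+1), 6)`` of the padded input; the last axis
        runs over :data:`ORIENTATIONS`.
    source_shape:
        Shape of the original (unpadded) image, restored by :func:`inverse`.
    """

    lowpass: np.ndarray
    highpasses: tuple[np.ndarray, ...]
    source_shape: tuple[int, int]

    @property
    def levels(self) -> int:
        return len(self.highpasses)

    @property
    def padded_shape(self) -> tuple[int, int]:
        h, w = self.highpasses[0].shape[:2]
        return (2 * h, 2 * w)


def pad_to_depth(image: np.ndarray, levels: int) -> np.ndarray:
    """Pad by symmetric reflection (bottom/right) to a multiple of 2**levels."""
    m = 1 << levels
    h, w = image.shape
    ph = (-h) % m
    pw = (-w) % m
    if ph == 0 and pw == 0:
        return image
    return np.pad(image, ((0, ph), (0, pw)), mode="symmetric")


def _dwt_axis(x, tree, level, axis):
    if level == 0:
        if tree == "b":
            x = np.roll(x, 1, axis=axis)
        return pywt.dwt(x, _WAV_LEVEL1, mode="periodization", axis=axis)
    wav = _WAV_TREE_A if tree == "a" else _WAV_TREE_B
    return pywt.dwt(x, wav, mode="periodization", axis=axis)


def _idwt_axis(lo, hi, tree, level, axis):
    if level == 0:
        x = pywt.idwt(lo, hi, _WAV_LEVEL1, mode="periodization", axis=axis)
        if tree == "b":
            x = np.roll(x, -1, axis=axis)
        return x
    wav = _WAV_TREE_A if tree == "a" else _WAV_TREE_B
    return pywt.idwt(lo, hi, wav, mode="periodization", axis=axis)


def forward(image: np.ndarray, levels: int = 4) -> Pyramid:
    """Forward DTCWT of a 2-D image.

    Parameters
    ----------
    image:
        2-D real array.  Non-dyadic shapes are reflection-padded to the next
        multiple of ``2**levels`` (the inverse crops back).
    levels:
        Decomposition depth, >= 1.

    Returns
    -------
    Pyramid

    Notes
    -----
    The transform is linear in the image, coefficient-wise.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValidationError(f"expected a 2-D image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValidationError("image contains non-finite values")
    if levels < 1:
        raise ValidationError(f"levels must be >= 1, got {levels}")
    if min(image.shape) < (1 << levels):
        raise ValidationError(
            f"image of shape {image.shape} too small for {levels} levels "
            f"(needs min dimension >= {1 << levels})"
        )
    source_shape = image.shape
    x = pad_to_depth(image, levels)

    ll = {c: x for c in _COMBOS}
    highpasses = []
    for lev in range(levels):
        subs = {}
        for ti, tj in _COMBOS:
            lo0, hi0 = _dwt_axis(ll[(ti, tj)], ti, lev, 0)
            LL, LH = _dwt_axis(lo0, tj, lev, 1)
            HL, HH = _dwt_axis(hi0, tj, lev, 1)
            subs[(ti, tj)] = (LL, LH, HL, HH)
            ll[(ti, tj)] = LL
        bands = {}
        for name, si in (("LH", 1), ("HL", 2), ("HH", 3)):
            aa = subs[("a", "a")][si]
            ab = subs[("a", "b")][si]
            ba = subs[("b", "a")][si]
            bb = subs[("b", "b")][si]
            z_pos = ((aa - bb) + 1j * (ab + ba)) * _SQ2
            z_neg = ((aa + bb) + 1j * (ba - ab)) * _SQ2
            bands[name] = (z_pos, z_neg)
        # LH varies along columns -> near-vertical edges -> +/-15 degrees.
        highpasses.append(
            np.stack(
                [
                    bands["LH"][0],
                    bands["HH"][0],
                    bands["HL"][0],
                    bands["HL"][1],
                    bands["HH"][1],
                    bands["LH"][1],
                ],
                axis=-1,
            )
        )

    m, n = ll[("a", "a")].shape
    low = np.empty((2 * m, 2 * n))
    low[0::2, 0::2] = ll[("a", "a")]
    low[0::2, 1::2] = ll[("a", "b")]
    low[1::2, 0::2] = ll[("b", "a")]
    low[1::2, 1::2] = ll[("b", "b")]
    return Pyramid(lowpass=low, highpasses=tuple(highpasses), source_shape=source_shape)


def _check_structure(pyramid: Pyramid) -> None:
    if pyramid.levels < 1:
        raise ValidationError("pyramid has no highpass levels")
    h, w = pyramid.highpasses[0].shape[:2]
    for lev, band in enumerate(pyramid.highpasses):
        expect = (h >> lev, w >> lev, 6)
        if band.shape != expect:
            raise ValidationError(
                f"level {lev} subbands have shape {band.shape}, expected {expect}"
            )
    m, n = pyramid.highpasses[-1].shape[:2]
    if pyramid.lowpass.shape != (2 * m, 2 * n):
        raise ValidationError(
            f"lowpass has shape {pyramid.lowpass.shape}, expected {(2 * m, 2 * n)}"
        )


def inverse(pyramid: Pyramid) -> np.ndarray:
    """Inverse DTCWT; reconstructs the source image (cropped to source_shape).

    ``inverse(forward(x))`` recovers ``x`` to within 1e-8 maximum absolute
    error in float64.
    """
    _check_structure(pyramid)
    levels = pyramid.levels
    ll = {
        ("a", "a"): pyramid.lowpass[0::2, 0::2],
        ("a", "b"): pyramid.lowpass[0::2, 1::2],
        ("b", "a"): pyramid.lowpass[1::2, 0::2],
        ("b", "b"): pyramid.lowpass[1::2, 1::2],
    }
    for lev in range(levels - 1, -1, -1):
        hp = pyramid.highpasses[lev]
        z = {
            "LH": (hp[..., 0], hp[..., 5]),
            "HH": (hp[..., 1], hp[..., 4]),
            "HL": (hp[..., 2], hp[..., 3]),
        }
        rec = {}
        for ti, tj in _COMBOS:
            subs = {}
            for name in ("LH", "HL", "HH"):
                z_pos, z_neg = z[name]
                if (ti, tj) == ("a", "a"):
                    s = (z_pos.real + z_neg.real) * _SQ2
                elif (ti, tj) == ("b", "b"):
                    s = (z_neg.real - z_pos.real) * _SQ2
                elif (ti, tj) == ("a", "b"):
                    s = (z_pos.imag - z_neg.imag) * _SQ2
                else:  # ("b", "a")
                    s = (z_pos.imag + z_neg.imag) * _SQ2
                subs[name] = s
            lo0 = _idwt_axis(ll[(ti, tj)], subs["LH"], tj, lev, 1)
            hi0 = _idwt_axis(subs["HL"], subs["HH"], tj, lev, 1)
            rec[(ti, tj)] = _idwt_axis(lo0, hi0, ti, lev, 0)
        ll = rec
    out = sum(ll[c] for c in _COMBOS) / 4.0
    h, w = pyramid.source_shape
    return out[:h, :w]


def parent_of(pyramid: Pyramid, level: int) -> np.ndarray:
    """Parent coefficients of ``level``, upsampled to the child grid.

    The parent of child coefficient ``(r, c)`` at scale ``level`` is the
    coefficient ``(r // 2, c // 2)`` of the same orientation one scale
    coarser, replicated 2x2 (nearest neighbour) onto the child grid.
    """
    if not 0 <= level < pyramid.levels - 1:
        raise ValidationError(
            f"level {level} has no parent in a {pyramid.levels}-level pyramid"
        )
    child = pyramid.highpasses[level]
    parent = pyramid.highpasses[level + 1]
    up = np.repeat(np.repeat(parent, 2, axis=0), 2, axis=1)
    return up[: child.shape[0], : child.shape[1], :]


def save_pyramid(path, pyramid: Pyramid) -> None:
    """Serialize to an .npz container of named arrays (debugging aid)."""
    arrays = {f"highpass_{i}": b for i, b in enumerate(pyramid.highpasses)}
    np.savez(
        path,
        lowpass=pyramid.lowpass,
        source_shape=np.array(pyramid.source_shape),
        **arrays,
    )


def load_pyramid(path) -> Pyramid:
    with np.load(path) as data:
        n = sum(1 for k in data.files if k.startswith("highpass_"))
        return Pyramid(
            lowpass=data["lowpass"],
            highpasses=tuple(data[f"highpass_{i}"] for i in range(n)),
            source_shape=tuple(int(v) for v in data["source_shape"]),
        )
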