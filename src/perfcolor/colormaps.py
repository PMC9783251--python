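"""Analytic pseudo-color transfer functions for grayscale medical images.

Each color map is a triple of scalar functions ``(R(t), G(t), B(t))`` applied
pixel-wise to a normalized intensity ``t``.  Five maps are provided:

``wcm``
    Warm color map — a rotation of a chroma vector around the gray axis of the
    RGB cube, so equal intensity steps give equal color-space steps.  Runs
    dark blue → magenta → orange → light yellow.
``hcm``
    Hot color map — black through red, orange and yellow to white; emphasizes
    high intensities.
``scm``
    Sine color map — half-period sinusoids; blue background, red/orange
    targets.
``zcm``
    Piecewise-linear map running blue → turquoise → green → yellow → orange →
    red → white.
``jcm``
    Jet color map — the classical triangular R/G/B profile on a signed
    ``[-1, 1]`` domain; blue → turquoise → yellow → orange → red.

All maps except ``jcm`` take ``t`` in the unit interval ``[0, 1]``; ``jcm``
takes ``t`` in ``[-1, 1]``.  :func:`apply_colormap` performs the appropriate
affine range remapping from a *declared* input range (never the observed
per-image extremes, so that identical gray levels always receive identical
colors regardless of image content).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "VALUE_RANGES",
    "WCMParams",
    "ColorMapSpec",
    "COLORMAPS",
    "rescale_to_unit",
    "rescale_to_signed",
    "wcm_transfer",
    "hcm_transfer",
    "scm_transfer",
    "zcm_transfer",
    "jcm_transfer",
    "apply_colormap",
]

#: Named value ranges a grayscale image may declare.
VALUE_RANGES: dict[str, tuple[float, float]] = {
    "raw_8bit": (0.0, 255.0),
    "unit": (0.0, 1.0),
    "signed": (-1.0, 1.0),
}

_SQRT3 = math.sqrt(3.0)

#: Orthonormal basis taking (chroma1, chroma2, luminance) coordinates to RGB.
#: The third column is the gray axis (1,1,1)/sqrt(3); the first two columns
#: span the plane orthogonal to it and sum to zero channel-wise, so the
#: channel mean of any mapped color is carried by the luminance coordinate
#: alone.
WCM_BASIS = (1.0 / (2.0 * _SQRT3)) * np.array(
    [
        [1.0 + _SQRT3, 1.0 - _SQRT3, 2.0],
        [1.0 - _SQRT3, 1.0 + _SQRT3, 2.0],
        [-2.0, -2.0, 2.0],
    ]
)


def _resolve_range(value_range) -> tuple[float, float]:
    if isinstance(value_range, str):
        try:
            lo, hi = VALUE_RANGES[value_range]
        except KeyError:
            raise ValueError(
                f"unknown value range {value_range!r}; "
                f"expected one of {sorted(VALUE_RANGES)} or a (min, max) pair"
            ) from None
    else:
        lo, hi = float(value_range[0]), float(value_range[1])
    if hi <= lo:
        raise ValueError(f"degenerate value range ({lo}, {hi}): max must exceed min")
    return lo, hi


def rescale_to_unit(image, value_range="raw_8bit"):
    """Affinely remap ``image`` from its declared range to ``[0, 1]``.

    The declared container bounds are used — e.g. 0 and 255 for an 8-bit
    image — never the observed per-image min/max.

    Parameters
    ----------
    image : array_like
        Grayscale raster.
    value_range : str or (float, float)
        Declared range of the input: one of ``VALUE_RANGES`` keys or an
        explicit ``(min, max)`` pair with ``max > min``.

    Returns
    -------
    ndarray
        ``(image - min) / (max - min)``, same shape, float64.
    """
    lo, hi = _resolve_range(value_range)
    a = np.asarray(image, dtype=float)
    return (a - lo) / (hi - lo)


def rescale_to_signed(image, value_range="raw_8bit"):
    """Affinely remap ``image`` from its declared range to ``[-1, 1]``.

    For 8-bit input this is ``2*I/255 - 1``; for unit input ``2*u - 1``.
    A ``signed`` declaration is returned unchanged with a warning.
    """
    if value_range == "signed":
        warnings.warn("input already declared signed; rescale_to_signed is a no-op")
        return np.asarray(image, dtype=float)
    return 2.0 * rescale_to_unit(image, value_range) - 1.0


def _check_domain(t, lo: float, hi: float, name: str):
    t = np.asarray(t, dtype=float)
    if t.size and (np.min(t) < lo or np.max(t) > hi):
        raise ValueError(f"{name}: intensity t outside the [{lo}, {hi}] domain")
    return t


def _clip01(rgb: np.ndarray) -> np.ndarray:
    return np.clip(rgb, 0.0, 1.0)


@dataclass(frozen=True)
class WCMParams:
    """Parameters of the warm color map.

    Attributes
    ----------
    omega : float
        Angular rate of the chroma rotation, radians per unit ``t``.
    phi : float
        Phase offset in radians.  The defaults start the chroma vector at
        blue for small ``t`` and rotate it through magenta/red toward yellow
        as ``t`` approaches 1.
    basis : ndarray
        3x3 orthonormal matrix taking (chroma1, chroma2, luminance) to RGB;
        its third column must be the gray axis so the luminance coordinate
        ``sqrt(3)*t`` yields channel mean exactly ``t``.
    """

    omega: float = -math.pi
    phi: float = 5.0 * math.pi / 4.0
    basis: np.ndarray = field(default_factory=lambda: WCM_BASIS.copy())

    def __post_init__(self):
        b = np.asarray(self.basis, dtype=float)
        if b.shape != (3, 3):
            raise ValueError("basis must be 3x3")
        if not np.allclose(b.T @ b, np.eye(3), atol=1e-12):
            raise ValueError("basis columns must be orthonormal")
        gray = b[:, 2]
        if not np.allclose(gray, gray.mean(), atol=1e-12):
            raise ValueError("third basis column must lie on the gray axis (1,1,1)")
        object.__setattr__(self, "basis", b)


def wcm_transfer(t, params: WCMParams | None = None, clip: bool = True):
    """Warm color map: rotating chroma vector around the RGB gray axis.

    The color is ``basis @ (r(t)*sin(w*t+phi), r(t)*cos(w*t+phi), z(t))``
    with luminance ``z(t) = sqrt(3)*t`` and chroma radius ``r(t)`` a
    triangular profile peaking at ``t = 1/2``:
    ``r = (sqrt(3)/2)*t`` for ``t < 1/2`` and ``(sqrt(3)/2)*(1-t)`` after.
    Because the basis is orthonormal with the gray axis as third column, the
    channel mean of the (pre-clamp) color equals ``t`` exactly.

    Parameters
    ----------
    t : scalar or array in [0, 1]
    params : WCMParams, optional
    clip : bool
        Clamp channels to [0, 1] (the chroma circle can exit the RGB cube
        near mid-range ``t``).  Set False to inspect the raw vector.

    Returns
    -------
    ndarray, shape t.shape + (3,)
    """
    if params is None:
        params = WCMParams()
    t = _check_domain(t, 0.0, 1.0, "wcm")
    z = _SQRT3 * t
    r = (_SQRT3 / 2.0) * np.where(t < 0.5, t, 1.0 - t)
    angle = params.omega * t + params.phi
    coords = np.stack([r * np.sin(angle), r * np.cos(angle), z], axis=-1)
    rgb = coords @ params.basis.T
    return _clip01(rgb) if clip else rgb


def hcm_transfer(t):
    """Hot color map: black → red → orange/yellow → white.

    Each channel is a clamped linear ramp: ``R = min(2.7027*t, 1)``
    saturating near ``t = 0.37``, ``G = clip(2.7027*t - 1)`` ramping on
    roughly ``[0.37, 0.74]``, and ``B = clip(3.8461*t - 2.8461)`` ramping
    above ``t ~ 0.74``.  The clamp makes every channel continuous and
    non-decreasing; the nominal breakpoints land where each ramp crosses
    0 or 1 given the stated slopes.
    """
    t = _check_domain(t, 0.0, 1.0, "hcm")
    r = 2.7027 * t
    g = 2.7027 * t - 1.0
    b = 3.8461 * t - 2.8461
    return _clip01(np.stack([r, g, b], axis=-1))


def scm_transfer(t):
    """Sine color map: blue background to red/orange targets.

    ``R = -0.5*cos(pi*t) + 0.5``, ``G = sin(pi*t)``, ``B = 0.5*cos(pi*t) + 0.5``.
    """
    t = _check_domain(t, 0.0, 1.0, "scm")
    c = np.cos(np.pi * t)
    rgb = np.stack([-0.5 * c + 0.5, np.sin(np.pi * t), 0.5 * c + 0.5], axis=-1)
    return _clip01(rgb)


def zcm_transfer(t):
    """Piecewise-linear map: blue → turquoise → green → yellow → red → white.

    All channel segments are continuous except the blue channel, which (as
    defined) drops from 1/5 to 0 at ``t = 14/15`` before ramping back to 1.
    """
    t = _check_domain(t, 0.0, 1.0, "zcm")

    r = np.piecewise(
        t,
        [t <= 11 / 20, (t > 11 / 20) & (t < 4 / 5), t >= 4 / 5],
        [0.0, lambda x: 4.0 * x - 11.0 / 5.0, 1.0],
    )
    g = np.piecewise(
        t,
        [
            t <= 1 / 5,
            (t > 1 / 5) & (t < 7 / 20),
            (t >= 7 / 20) & (t <= 4 / 5),
            (t > 4 / 5) & (t < 14 / 15),
            (t >= 14 / 15) & (t < 19 / 20),
            t >= 19 / 20,
        ],
        [
            lambda x: 5.0 * x,
            lambda x: -(20.0 / 9.0) * x + 13.0 / 9.0,
            lambda x: (20.0 / 27.0) * x + 11.0 / 27.0,
            lambda x: -(15.0 / 2.0) * x + 7.0,
            lambda x: 60.0 * x - 56.0,
            1.0,
        ],
    )
    b = np.piecewise(
        t,
        [
            t <= 1 / 5,
            (t > 1 / 5) & (t < 2 / 5),
            (t >= 2 / 5) & (t <= 14 / 15),
            (t > 14 / 15) & (t < 19 / 20),
            t >= 19 / 20,
        ],
        [
            1.0,
            lambda x: -4.0 * x + 9.0 / 5.0,
            1.0 / 5.0,
            lambda x: 60.0 * x - 56.0,
            1.0,
        ],
    )
    return _clip01(np.stack([r, g, b], axis=-1))


def jcm_transfer(t):
    """Jet color map on the signed domain ``[-1, 1]``.

    Each channel is the unit clamp ``f(x) = min(max(x, 0), 1)`` of a
    triangular profile: ``R = f(1.5 - 2|t-1|)``, ``G = f(1.5 - 2|t|)``,
    ``B = f(1.5 - 2|t+1|)``.  Runs blue at ``t = -1`` through green at 0
    to red at ``t = +1``.
    """
    t = _check_domain(t, -1.0, 1.0, "jcm")
    r = 1.5 - 2.0 * np.abs(t - 1.0)
    g = 1.5 - 2.0 * np.abs(t)
    b = 1.5 - 2.0 * np.abs(t + 1.0)
    return _clip01(np.stack([r, g, b], axis=-1))


@dataclass(frozen=True)
class ColorMapSpec:
    """A named analytic transfer function with its domain convention."""

    name: str
    domain: str  # "unit" or "signed"
    transfer: Callable[..., np.ndarray]


COLORMAPS: dict[str, ColorMapSpec] = {
    "wcm": ColorMapSpec("wcm", "unit", wcm_transfer),
    "hcm": ColorMapSpec("hcm", "unit", hcm_transfer),
    "scm": ColorMapSpec("scm", "unit", scm_transfer),
    "zcm": ColorMapSpec("zcm", "unit", zcm_transfer),
    "jcm": ColorMapSpec("jcm", "signed", jcm_transfer),
}


def get_colormap(name: str) -> ColorMapSpec:
    try:
        return COLORMAPS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown color map {name!r}; expected one of {sorted(COLORMAPS)}"
        ) from None


def apply_colormap(
    image,
    cmap: str | ColorMapSpec,
    value_range="unit",
    wcm_params: WCMParams | None = None,
    use_lut: bool = False,
):
    """Pseudo-color a grayscale image pixel-wise.

    The image's *declared* range is remapped to the map's domain (unit for
    wcm/hcm/scm/zcm, signed for jcm) before the transfer function is applied.

    Parameters
    ----------
    image : array_like, 2-D
        Grayscale raster in the declared range.
    cmap : str or ColorMapSpec
        One of ``wcm, hcm, scm, zcm, jcm`` or an explicit spec.
    value_range : str or (min, max)
        Declared range of ``image``.
    wcm_params : WCMParams, optional
        Rotation parameters; only meaningful for the warm color map.
    use_lut : bool
        For ``raw_8bit`` integer images, evaluate the transfer once per gray
        level (256-entry lookup table) instead of per pixel.  Identical to
        direct evaluation; purely an evaluation strategy.

    Returns
    -------
    ndarray, shape (M, N, 3), channels in [0, 1].
    """
    spec = get_colormap(cmap) if isinstance(cmap, str) else cmap
    a = np.asarray(image, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {a.shape}")

    kwargs = {}
    if spec.name == "wcm" and wcm_params is not None:
        kwargs["params"] = wcm_params

    if use_lut:
        if value_range != "raw_8bit":
            raise ValueError("LUT evaluation requires a raw_8bit declared range")
        levels = np.arange(256, dtype=float)
        if not np.array_equal(a, np.rint(a)) or a.min() < 0 or a.max() > 255:
            raise ValueError("LUT evaluation requires integer gray levels in [0, 255]")
        t_levels = (
            rescale_to_signed(levels, "raw_8bit")
            if spec.domain == "signed"
            else rescale_to_unit(levels, "raw_8bit")
        )
        lut = spec.transfer(t_levels, **kwargs)
        return lut[a.astype(np.intp)]

    if spec.domain == "signed":
        t = a if value_range == "signed" else rescale_to_signed(a, value_range)
    else:
        if value_range == "signed":
            raise ValueError(
                f"{spec.name} expects a unit-domain image; got a signed declaration"
            )
        t = a if value_range == "unit" else rescale_to_unit(a, value_range)
    return spec.transfer(t, **kwargs)
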