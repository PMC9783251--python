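"""Synthetic short-axis myocardial perfusion phantoms.

On a short-axis SPECT slice the left-ventricular myocardium appears as a
bright annulus; a perfusion defect appears as a sector of reduced uptake.
This module generates such images at SPECT-like resolution (64x64 matrix by
default) so the denoise → colorize → assess pipeline can be exercised and
tested without any clinical data.

The clean phantom is a unit-intensity annulus between two radii, with an
optional angular sector scaled down by a defect severity, blurred by an
isotropic Gaussian (a crude stand-in for collimator/reconstruction
resolution) and renormalized to peak 1.  Noise is Poisson counting noise:
each pixel's expected count is ``counts_scale * intensity``; the realized
counts are rescaled back to a unit-range image.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomParams",
    "PhantomSample",
    "generate_clean_phantom",
    "add_poisson_noise",
    "generate_corpus",
]

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, defect, blur and noise parameters of one phantom.

    Attributes
    ----------
    matrix : int
        Image side in pixels; 64 matches a typical cardiac SPECT matrix.
    center : (float, float), optional
        Annulus center (row, col); defaults to the image center.
    inner_radius, outer_radius : float
        Myocardial annulus radii in pixels (0 < inner < outer < matrix/2).
    defect_angle_start, defect_angle_extent : float
        Perfusion-defect sector in degrees (counter-clockwise from +x).
    defect_severity : float in [0, 1]
        Fractional uptake reduction inside the sector; 0 disables the defect.
    blur_sigma : float
        Isotropic Gaussian blur in pixels, emulating system resolution.
    counts_scale : float
        Expected counts at unit intensity; lower values mean noisier images.
    seed : int, optional
        RNG seed for the Poisson noise.
    """

    matrix: int = 64
    center: tuple[float, float] | None = None
    inner_radius: float = 9.0
    outer_radius: float = 16.0
    defect_angle_start: float = 30.0
    defect_angle_extent: float = 60.0
    defect_severity: float = 0.0
    blur_sigma: float = 1.5
    counts_scale: float = 100.0
    seed: int | None = None

    def validate(self) -> "PhantomParams":
        if self.matrix < 4:
            raise ValueError(f"matrix side too small: {self.matrix}")
        if not (0 < self.inner_radius < self.outer_radius < self.matrix / 2):
            raise ValueError(
                "need 0 < inner_radius < outer_radius < matrix/2, got "
                f"{self.inner_radius}, {self.outer_radius}, {self.matrix}"
            )
        if not (0.0 <= self.defect_severity <= 1.0):
            raise ValueError(f"defect_severity must be in [0, 1], got {self.defect_severity}")
        if self.counts_scale <= 0:
            raise ValueError(f"counts_scale must be positive, got {self.counts_scale}")
        return self

    def resolved_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        c = (self.matrix - 1) / 2.0
        return (c, c)


def generate_clean_phantom(params: PhantomParams) -> np.ndarray:
    """Noise-free annulus phantom, unit range with peak 1.

    A defect of severity 1 zeroes the sector; severity 0 leaves the annulus
    rotationally symmetric about its center.  A vanishingly small
    ``inner_radius`` yields an (effectively) filled disk.
    """
    params.validate()
    m = params.matrix
    cr, cc = params.resolved_center()
    rows, cols = np.mgrid[0:m, 0:m].astype(float)
    dy, dx = rows - cr, cols - cc
    radius = np.hypot(dy, dx)
    img = ((radius >= params.inner_radius) & (radius <= params.outer_radius)).astype(
        float
    )
    if params.defect_severity > 0:
        angle = np.degrees(np.arctan2(dy, dx)) % 360.0
        in_sector = (angle - params.defect_angle_start) % 360.0 < params.defect_angle_extent
        img[in_sector] *= 1.0 - params.defect_severity
    if params.blur_sigma > 0:
        img = gaussian_filter(img, sigma=params.blur_sigma, mode="constant")
    peak = img.max()
    if peak > 0:
        img = img / peak
    return img


def add_poisson_noise(image, counts_scale: float, seed=None) -> np.ndarray:
    """Apply Poisson counting noise at a given count level.

    Each pixel draws ``Poisson(counts_scale * intensity)``; the counts are
    renormalized by the expected peak count (``counts_scale`` itself, since
    the clean image peaks at 1) and clipped to [0, 1].  Normalizing by the
    *expected* rather than the observed maximum keeps the image on the same
    intensity scale as the clean truth — dividing by the noisy maximum
    would shrink the whole image by a random factor and dominate any
    error-to-truth comparison with a scale bias.  Deterministic under a
    fixed seed (also accepts a Generator).

    Parameters
    ----------
    image : array_like, unit range
    counts_scale : float > 0
        Expected counts at intensity 1; reconstructed cardiac SPECT slices
        sit in the tens-to-hundreds range.
    seed : int, Generator or None
    """
    a = np.asarray(image, dtype=float)
    if counts_scale <= 0:
        raise ValueError(f"counts_scale must be positive, got {counts_scale}")
    if a.size and (a.min() < 0 or a.max() > 1):
        raise ValueError("input image must be unit range")
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(counts_scale * a).astype(float) / counts_scale
    return np.clip(noisy, 0.0, 1.0)


@dataclass(frozen=True)
class PhantomSample:
    """A corpus member: the noisy image, its clean truth, and the parameters."""

    noisy: np.ndarray
    clean: np.ndarray
    params: PhantomParams


def generate_corpus(
    n: int,
    base: PhantomParams | None = None,
    jitter: dict | None = None,
    seed=None,
) -> list[PhantomSample]:
    """Generate ``n`` reproducible phantoms with randomized defects.

    Parameters
    ----------
    n : int >= 1
    base : PhantomParams
        Template parameters; per-image seeds are derived from ``seed``.
    jitter : dict, optional
        Randomization ranges, any of ``severity`` (lo, hi), ``angle``
        (lo, hi) degrees for the defect start, ``extent`` (lo, hi) degrees.
        ``None`` disables jitter (all clean phantoms identical pre-noise).
    seed : int or None
        Master seed; the same seed reproduces the corpus exactly.
    """
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    if base is None:
        base = PhantomParams()
    jitter = jitter or {}
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n):
        updates: dict = {"seed": int(rng.integers(_SEED_MOD))}
        if "severity" in jitter:
            lo, hi = jitter["severity"]
            updates["defect_severity"] = float(rng.uniform(lo, hi))
        if "angle" in jitter:
            lo, hi = jitter["angle"]
            updates["defect_angle_start"] = float(rng.uniform(lo, hi))
        if "extent" in jitter:
            lo, hi = jitter["extent"]
            updates["defect_angle_extent"] = float(rng.uniform(lo, hi))
        p = replace(base, **updates)
        clean = generate_clean_phantom(p)
        noisy = add_poisson_noise(clean, p.counts_scale, seed=p.seed)
        samples.append(PhantomSample(noisy=noisy, clean=clean, params=p))
    return samples
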