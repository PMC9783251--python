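"""Full-reference quality indices for pseudo-colored images.

The reference is the grayscale image replicated into three identical RGB
channels; the test image is its pseudo-colored version.  Four indices are
computed:

MSE
    Mean of squared per-channel differences (divisor ``3*M*N``).
PSNR
    ``10*log10(Imax^2 / MSE)`` in decibels, with ``Imax = 1`` for unit-range
    data.
NCD
    Normalized color difference in CIELAB: the summed squared L/a/b
    differences divided by the summed squared L/a/b magnitude of the colored
    image (default), or the classical per-pixel Euclidean-root form.
SSIM
    Structural similarity over a sliding window (default 8x8, uniform,
    population moments), computed per channel then averaged.

Also provides the one-way ANOVA used to compare maps across an image corpus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.ndimage import uniform_filter
from skimage.color import rgb2lab

from .colormaps import WCMParams, apply_colormap, get_colormap

__all__ = [
    "SSIMParams",
    "MetricReport",
    "gray_to_rgb",
    "mse",
    "psnr",
    "rgb_to_lab",
    "ncd",
    "ssim_window",
    "ssim_image",
    "metric_report",
    "anova_oneway",
]


def gray_to_rgb(image):
    """Replicate a grayscale image into three identical RGB channels."""
    a = np.asarray(image, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {a.shape}")
    return np.repeat(a[..., None], 3, axis=-1)


def _check_pair(reference, test):
    x = np.asarray(reference, dtype=float)
    y = np.asarray(test, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def mse(reference, test) -> float:
    """Mean squared per-channel difference between two RGB images."""
    x, y = _check_pair(reference, test)
    return float(np.mean((x - y) ** 2))


def psnr(mse_value: float, imax: float = 1.0) -> float:
    """Peak signal-to-noise ratio ``10*log10(imax^2 / mse)`` in dB."""
    if mse_value < 0:
        raise ValueError(f"MSE must be nonnegative, got {mse_value}")
    if mse_value == 0:
        return float("inf")
    return float(10.0 * np.log10(imax**2 / mse_value))


def rgb_to_lab(image):
    """Convert a unit-range RGB image to CIELAB (sRGB primaries, D65 white).

    L lies in [0, 100]; a and b are signed opponent axes.
    """
    a = np.asarray(image, dtype=float)
    if a.ndim != 3 or a.shape[-1] != 3:
        raise ValueError(f"expected an (M, N, 3) RGB image, got shape {a.shape}")
    if a.min() < -1e-9 or a.max() > 1 + 1e-9:
        raise ValueError("RGB channels must lie in [0, 1]")
    return rgb2lab(np.clip(a, 0.0, 1.0))


def ncd(gray, colored, form: str = "printed") -> float:
    """Normalized color difference between a gray image and its colored version.

    Both images are taken to CIELAB — the gray one after replication into
    equal RGB channels — and compared over the L, a, b channels.

    Parameters
    ----------
    gray : array_like, 2-D, unit range
    colored : array_like, (M, N, 3), unit range
    form : {"printed", "classic"}
        ``printed``: ratio of the summed squared channel differences to the
        summed squared channel magnitudes of the colored image.
        ``classic``: per-pixel Euclidean distances, i.e.
        ``sum ||dLab|| / sum ||Lab_colored||``.

    Returns
    -------
    float
        Nonnegative; 0 iff the colored image reproduces the replicated gray.
    """
    g = np.asarray(gray, dtype=float)
    c = np.asarray(colored, dtype=float)
    if c.shape[:2] != g.shape:
        raise ValueError(f"shape mismatch: gray {g.shape} vs colored {c.shape[:2]}")
    glab = rgb_to_lab(gray_to_rgb(g))
    clab = rgb_to_lab(c)
    if form == "printed":
        num = float(np.sum((glab - clab) ** 2))
        den = float(np.sum(clab**2))
    elif form == "classic":
        num = float(np.sum(np.sqrt(np.sum((glab - clab) ** 2, axis=-1))))
        den = float(np.sum(np.sqrt(np.sum(clab**2, axis=-1))))
    else:
        raise ValueError(f"unknown NCD form {form!r}; expected 'printed' or 'classic'")
    if den == 0:
        raise ValueError("NCD undefined: colored image has zero Lab magnitude")
    return num / den


@dataclass(frozen=True)
class SSIMParams:
    """SSIM configuration.

    window_size : side of the square sliding window (default 8, uniform
    weights, stride 1).  dynamic_range : value range L of the data (1 for
    unit images).  c1, c2 : stabilization constants; default to
    ``(0.01*L)^2`` and ``(0.03*L)^2``.
    """

    window_size: int = 8
    dynamic_range: float = 1.0
    c1: float | None = None
    c2: float | None = None

    def constants(self) -> tuple[float, float]:
        c1 = (0.01 * self.dynamic_range) ** 2 if self.c1 is None else self.c1
        c2 = (0.03 * self.dynamic_range) ** 2 if self.c2 is None else self.c2
        if c1 <= 0 or c2 <= 0:
            raise ValueError("SSIM constants c1, c2 must be positive")
        return c1, c2


def ssim_window(x, y, params: SSIMParams | None = None) -> float:
    """SSIM between two equally shaped windows (population moments)."""
    if params is None:
        params = SSIMParams()
    x, y = _check_pair(x, y)
    c1, c2 = params.constants()
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = float(np.mean((x - mx) * (y - my)))
    return float(
        ((2 * mx * my + c1) * (2 * cov + c2))
        / ((mx**2 + my**2 + c1) * (vx + vy + c2))
    )


def _ssim_channel(x: np.ndarray, y: np.ndarray, w: int, c1: float, c2: float) -> float:
    # sliding-window moments via uniform filtering; only windows fully inside
    # the image contribute (count (M-w+1)*(N-w+1), matching a naive loop)
    def win_mean(a):
        f = uniform_filter(a, size=w, mode="constant")
        lo0, lo1 = w // 2, w // 2
        return f[lo0 : lo0 + x.shape[0] - w + 1, lo1 : lo1 + x.shape[1] - w + 1]

    mx, my = win_mean(x), win_mean(y)
    vx = win_mean(x * x) - mx * mx
    vy = win_mean(y * y) - my * my
    cov = win_mean(x * y) - mx * my
    ssim_map = ((2 * mx * my + c1) * (2 * cov + c2)) / (
        (mx**2 + my**2 + c1) * (vx + vy + c2)
    )
    return float(ssim_map.mean())


def ssim_image(reference, test, params: SSIMParams | None = None) -> float:
    """Mean SSIM over a sliding window per channel, averaged over channels."""
    if params is None:
        params = SSIMParams()
    x, y = _check_pair(reference, test)
    if x.ndim == 2:
        x, y = x[..., None], y[..., None]
    if x.ndim != 3:
        raise ValueError(f"expected (M, N[, C]) images, got shape {x.shape}")
    w = int(params.window_size)
    if w > x.shape[0] or w > x.shape[1]:
        raise ValueError(f"window {w} larger than image {x.shape[:2]}")
    c1, c2 = params.constants()
    return float(
        np.mean(
            [_ssim_channel(x[..., c], y[..., c], w, c1, c2) for c in range(x.shape[-1])]
        )
    )


@dataclass(frozen=True)
class MetricReport:
    """One row of the per-image quality table: a map and its four indices."""

    map_name: str
    mse: float
    psnr_db: float
    ncd: float
    ssim: float


def metric_report(
    gray,
    map_names: Sequence[str] = ("wcm", "hcm", "scm", "zcm", "jcm"),
    ssim_params: SSIMParams | None = None,
    ncd_form: str = "printed",
    wcm_params: WCMParams | None = None,
) -> list[MetricReport]:
    """Colorize a unit-range gray image with each map and score the result.

    The reference for MSE/PSNR/SSIM is the gray image replicated into equal
    RGB channels; NCD compares the two in CIELAB.  Rows follow the requested
    map order.
    """
    g = np.asarray(gray, dtype=float)
    reference = gray_to_rgb(g)
    rows = []
    for name in map_names:
        spec = get_colormap(name)  # raises on unknown names before any work
        colored = apply_colormap(g, spec, value_range="unit", wcm_params=wcm_params)
        m = mse(reference, colored)
        rows.append(
            MetricReport(
                map_name=spec.name,
                mse=m,
                psnr_db=psnr(m, imax=1.0),
                ncd=ncd(g, colored, form=ncd_form),
                ssim=ssim_image(reference, colored, ssim_params),
            )
        )
    return rows


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA across k groups.

    F = MS_between / MS_within with (k-1, N-k) degrees of freedom; the
    p-value is the upper tail of the F distribution.  Degenerate cases get
    sentinels: zero within-group variance yields ``F = inf, p = 0`` when the
    group means differ and ``F = 0, p = 1`` when they do not.

    Returns
    -------
    (F, p) : tuple of float
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    n = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    grand = float(np.concatenate(arrays).mean())
    ss_between = float(np.sum(n * (means - grand) ** 2))
    ss_within = float(sum(np.sum((a - m) ** 2) for a, m in zip(arrays, means)))
    df_between = len(arrays) - 1
    df_within = int(n.sum()) - len(arrays)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        return (float("inf"), 0.0) if ms_between > 0 else (0.0, 1.0)
    f = ms_between / ms_within
    return f, float(stats.f.sf(f, df_between, df_within))
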