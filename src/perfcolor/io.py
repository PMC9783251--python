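"""Image readers and writers for the pipeline.

Grayscale input: 8- or 16-bit PNG/TIFF, or a raw ``.npy`` array; everything
is normalized to a unit-range float raster on read.  Color output: 8-bit
PNG/TIFF with channels quantized by round-half-up of ``255 * v``.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_gray", "write_rgb"]


def read_gray(path, value_range=None, force_gray: bool = False) -> np.ndarray:
    """Read a grayscale image and normalize it to unit range.

    8-bit integer data are divided by 255, 16-bit by 65535.  Float data
    (e.g. from ``.npy``) are assumed unit-range unless ``value_range``
    gives explicit ``(min, max)`` bounds.  Multi-channel input is rejected
    unless ``force_gray`` requests the channel mean.
    """
    path = Path(path)
    if path.suffix.lower() == ".npy":
        a = np.load(path)
    else:
        a = iio.imread(path)
    if np.issubdtype(a.dtype, np.integer):
        info = np.iinfo(a.dtype)
        out = a.astype(float) / (255.0 if info.max <= 255 else 65535.0)
    else:
        out = a.astype(float)
        if value_range is not None:
            lo, hi = float(value_range[0]), float(value_range[1])
            if hi <= lo:
                raise ValueError(f"degenerate value range ({lo}, {hi})")
            out = (out - lo) / (hi - lo)
    if out.ndim == 3:
        if out.shape[-1] == 1:
            out = out[..., 0]
        elif force_gray:
            out = out.mean(axis=-1)
        else:
            raise ValueError(
                f"{path}: multi-channel image; pass force_gray to average channels"
            )
    if out.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image, got shape {out.shape}")
    if out.min() < 0 or out.max() > 1:
        raise ValueError(
            f"{path}: values outside [0, 1] after normalization; "
            "pass value_range=(min, max) for raw float data"
        )
    return out


def write_rgb(image, path) -> None:
    """Write a unit-range RGB image as an 8-bit PNG/TIFF.

    Quantization is round-half-up of ``255 * v`` per channel, so a
    write-then-read round trip changes each channel by at most 1/510.
    """
    a = np.asarray(image, dtype=float)
    if a.ndim != 3 or a.shape[-1] != 3:
        raise ValueError(f"expected an (M, N, 3) RGB image, got shape {a.shape}")
    if a.min() < -1e-9 or a.max() > 1 + 1e-9:
        raise ValueError("RGB channels must lie in [0, 1]")
    quantized = np.floor(255.0 * np.clip(a, 0.0, 1.0) + 0.5).astype(np.uint8)
    iio.imwrite(Path(path), quantized)


def write_gray16(image, path) -> None:
    """Write a unit-range grayscale image as a 16-bit PNG/TIFF."""
    a = np.asarray(image, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {a.shape}")
    quantized = np.floor(65535.0 * np.clip(a, 0.0, 1.0) + 0.5).astype(np.uint16)
    iio.imwrite(Path(path), quantized)
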