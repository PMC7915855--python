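"""Image reading/writing with a fixed in-memory convention.

Every image in this package is a float64 array: grayscale images are 2-D
with values in [0, 1]; RGB images are (H, W, 3) in [0, 1].  Files on disk
are 8- or 16-bit PNG/TIFF; conversion happens only here.
"""

from __future__ import annotations

import os

import numpy as np
import imageio.v3 as iio
import tifffile

LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def to_gray(img: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) array to single-channel luminance."""
    if img.ndim == 2:
        return img
    return img[..., :3] @ LUMA_WEIGHTS


def normalize(raw: np.ndarray) -> np.ndarray:
    """Map integer sample values onto [0, 1] by the dtype's full scale."""
    if np.issubdtype(raw.dtype, np.integer):
        info = np.iinfo(raw.dtype)
        return raw.astype(np.float64) / float(info.max)
    out = raw.astype(np.float64)
    if out.size and out.max() > 1.0 + 1e-9:
        out = out / out.max()
    return np.clip(out, 0.0, 1.0)


def read_gray(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/TIFF as a grayscale float image in [0, 1]."""
    raw = iio.imread(path)
    return np.clip(to_gray(normalize(raw)), 0.0, 1.0)


def read_rgb(path: str | os.PathLike) -> np.ndarray:
    raw = iio.imread(path)
    img = normalize(raw)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return np.clip(img[..., :3], 0.0, 1.0)


def write_gray(path: str | os.PathLike, img: np.ndarray, bits: int = 8) -> None:
    """Write a [0, 1] grayscale image as 8-bit PNG or 16-bit PNG/TIFF."""
    img = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    if bits == 8:
        data = np.round(img * 255).astype(np.uint8)
    elif bits == 16:
        data = np.round(img * 65535).astype(np.uint16)
    else:
        raise ValueError(f"unsupported bit depth: {bits}")
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def write_rgb(path: str | os.PathLike, img: np.ndarray) -> None:
    img = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(os.fspath(path), np.round(img * 255).astype(np.uint8))


def check_gray(img: np.ndarray, name: str = "image") -> np.ndarray:
    """Validate the grayscale contract: 2-D, finite, within [0, 1]."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError(f"{name} contains non-finite values")
    if img.min() < -1e-9 or img.max() > 1.0 + 1e-9:
        raise ValueError(f"{name} must lie in [0, 1]")
    return img
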