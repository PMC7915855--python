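"""Baseline smoothers: windowed median and local adaptive Wiener filter.

Both operate on grayscale float images with replicate boundary handling,
matching the gradient convention used by the RTV module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

__all__ = ["WindowSpec", "median_filter", "wiener_filter"]


@dataclass(frozen=True)
class WindowSpec:
    """Square odd-sided sliding window."""

    size: int = 3

    def __post_init__(self) -> None:
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError("window size must be odd and >= 3")


def median_filter(I: np.ndarray, w: WindowSpec | int = 3) -> np.ndarray:
    """Replace each pixel by the median of its w x w neighborhood.

    Replicate padding at the boundary.  The window has an odd pixel count,
    so the median is always a member of the window.
    """
    if isinstance(w, int):
        w = WindowSpec(w)
    I = np.asarray(I, dtype=np.float64)
    return ndi.median_filter(I, size=w.size, mode="nearest")


def wiener_filter(
    I: np.ndarray,
    w: WindowSpec | int = 5,
    noise_var: float | str = "auto",
) -> np.ndarray:
    """Local adaptive (pixel-wise) Wiener filter.

    Per pixel, with mu and sigma^2 the mean and population variance of the
    w x w window and eta^2 the noise variance:

        S = mu + max(sigma^2 - eta^2, 0) / sigma^2 * (I - mu)

    The filter shrinks each pixel toward its local mean in proportion to
    how much of the local variance is attributable to noise; where the
    local variance is entirely noise the output is the local mean, and
    where eta = 0 the image passes through unchanged.  ``noise_var="auto"``
    estimates eta^2 as the mean of all local variances (the conventional
    plug-in when the noise floor is unknown).
    """
    if isinstance(w, int):
        w = WindowSpec(w)
    I = np.asarray(I, dtype=np.float64)

    mu = ndi.uniform_filter(I, size=w.size, mode="nearest")
    mu2 = ndi.uniform_filter(I * I, size=w.size, mode="nearest")
    var = np.maximum(mu2 - mu * mu, 0.0)

    if isinstance(noise_var, str):
        if noise_var != "auto":
            raise ValueError(f"unknown noise_var mode: {noise_var!r}")
        eta2 = float(var.mean())
    else:
        eta2 = float(noise_var)
        if eta2 < 0:
            raise ValueError("noise_var must be >= 0")

    gain = np.zeros_like(I)
    nz = var > 0
    gain[nz] = np.maximum(var[nz] - eta2, 0.0) / var[nz]
    return mu + gain * (I - mu)
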