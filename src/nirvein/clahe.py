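"""Contrast-limited adaptive histogram equalization (CLAHE).

The image is divided into a grid of tiles; each tile's histogram is
clipped at a limit, the clipped excess is redistributed uniformly over all
bins (iterating the redistribution until no bin materially exceeds the
limit), and the tile's monotone mapping is the rescaled cumulative
distribution of the clipped histogram.  Pixels are mapped by bilinear
interpolation between the mappings of the four surrounding tile centers,
which removes tile-boundary artifacts.  Clipping bounds the slope of the
equalization map and hence the noise amplification in flat regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import check_gray

__all__ = ["CLAHEParams", "clip_redistribute", "tile_lut", "apply_clahe"]

_REDISTRIBUTE_CAP = 1000


@dataclass(frozen=True)
class CLAHEParams:
    """CLAHE parameters.

    clip_limit is expressed as a fraction of the tile pixel count; the
    absolute per-bin ceiling used for a tile of N pixels is
    ``max(clip_limit * N, N / n_bins)`` (the flat histogram is always
    feasible).
    """

    tiles_y: int = 8
    tiles_x: int = 8
    clip_limit: float = 0.01
    n_bins: int = 256

    def __post_init__(self) -> None:
        if self.tiles_y < 1 or self.tiles_x < 1:
            raise ValueError("tile counts must be >= 1")
        if not (0 < self.clip_limit <= 1):
            raise ValueError("clip_limit must lie in (0, 1]")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def clip_redistribute(hist: np.ndarray, clip: float) -> np.ndarray:
    """Clip a histogram at ``clip`` and redistribute the excess uniformly.

    The redistribution itself can push bins back over the limit, so it is
    repeated until no bin exceeds ``clip + 1`` (or an iteration cap).  The
    total count is conserved exactly: each round spreads ``excess // n_bins``
    to every bin and the remainder to the lowest-index bins.

    Raises
    ------
    ValueError
        if ``clip`` is smaller than the flat histogram level (total /
        n_bins), in which case no clipped histogram can exist.
    """
    hist = np.asarray(hist)
    if clip <= 0:
        raise ValueError("clip must be > 0")
    if np.any(hist < 0):
        raise ValueError("histogram counts must be nonnegative")
    counts = hist.astype(np.int64)
    total = int(counts.sum())
    n_bins = counts.size
    if total == 0:
        return counts
    if clip * n_bins < total:
        raise ValueError(
            f"infeasible clip: clip={clip} but total/n_bins={total / n_bins:.2f}"
        )
    clip_i = int(np.floor(clip))
    for _ in range(_REDISTRIBUTE_CAP):
        if counts.max() <= clip_i + 1:
            break
        excess = int(np.sum(np.maximum(counts - clip_i, 0)))
        counts = np.minimum(counts, clip_i)
        share, rem = divmod(excess, n_bins)
        counts += share
        counts[:rem] += 1
    else:
        raise ValueError("redistribution failed to settle within the iteration cap")
    assert int(counts.sum()) == total
    return counts


def tile_lut(
    hist_clipped: np.ndarray, out_range: tuple[float, float] = (0.0, 1.0)
) -> np.ndarray:
    """Monotone lookup table from a (clipped) histogram.

    LUT(b) = out_min + (out_max - out_min) * CDF(b) with the CDF taken over
    the normalized histogram.
    """
    hist_clipped = np.asarray(hist_clipped, dtype=np.float64)
    total = hist_clipped.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    lo, hi = out_range
    cdf = np.cumsum(hist_clipped) / total
    return lo + (hi - lo) * cdf


def _tile_edges(n: int, tiles: int) -> np.ndarray:
    """Pixel boundaries of ``tiles`` contiguous, near-equal tiles."""
    return np.round(np.linspace(0, n, tiles + 1)).astype(int)


def apply_clahe(I: np.ndarray, params: CLAHEParams | None = None) -> np.ndarray:
    """Apply CLAHE to a [0, 1] grayscale image.

    Each pixel's output is the bilinear blend of the LUTs of the four
    nearest tile centers (clamped at the image border, so corner and edge
    pixels use one or two tiles).
    """
    if params is None:
        params = CLAHEParams()
    I = check_gray(I, "input")
    H, W = I.shape
    ty, tx, nb = params.tiles_y, params.tiles_x, params.n_bins
    if ty > H or tx > W:
        raise ValueError(f"tile grid {ty}x{tx} larger than image {H}x{W}")

    bins = np.minimum((I * nb).astype(int), nb - 1)
    ye = _tile_edges(H, ty)
    xe = _tile_edges(W, tx)

    luts = np.empty((ty, tx, nb))
    centers_y = np.empty(ty)
    centers_x = np.empty(tx)
    for i in range(ty):
        centers_y[i] = 0.5 * (ye[i] + ye[i + 1]) - 0.5
        for j in range(tx):
            tile_bins = bins[ye[i] : ye[i + 1], xe[j] : xe[j + 1]]
            hist = np.bincount(tile_bins.ravel(), minlength=nb)
            npix = tile_bins.size
            clip = max(params.clip_limit * npix, npix / nb)
            luts[i, j] = tile_lut(clip_redistribute(hist, clip))
    for j in range(tx):
        centers_x[j] = 0.5 * (xe[j] + xe[j + 1]) - 0.5

    # Fractional tile-grid coordinates of every pixel, clamped so border
    # pixels extrapolate flatly from the outermost tile centers.
    rows = np.arange(H, dtype=np.float64)
    cols = np.arange(W, dtype=np.float64)
    fy = np.interp(rows, centers_y, np.arange(ty, dtype=np.float64))
    fx = np.interp(cols, centers_x, np.arange(tx, dtype=np.float64))

    i0 = np.minimum(fy.astype(int), ty - 1)
    i1 = np.minimum(i0 + 1, ty - 1)
    wy = (fy - i0)[:, None]
    j0 = np.minimum(fx.astype(int), tx - 1)
    j1 = np.minimum(j0 + 1, tx - 1)
    wx = (fx - j0)[None, :]

    def lut_at(ti: np.ndarray, tj: np.ndarray) -> np.ndarray:
        # Per-pixel LUT lookup for one corner of the interpolation cell.
        return luts[ti[:, None], tj[None, :], bins]

    out = (
        (1 - wy) * (1 - wx) * lut_at(i0, j0)
        + (1 - wy) * wx * lut_at(i0, j1)
        + wy * (1 - wx) * lut_at(i1, j0)
        + wy * wx * lut_at(i1, j1)
    )
    return np.clip(out, 0.0, 1.0)
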