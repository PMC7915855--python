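"""Intensity k-means segmentation of enhanced vein images.

The enhanced NIR image is clustered on pixel intensity alone into k
classes (k = 3 by default: background, tissue, subcutaneous veins).
Because veins absorb more NIR light than surrounding tissue, the vein
class is the cluster with the darkest centroid.  The resulting binary
mask can be blended into a co-registered optical (RGB) image for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClusterResult",
    "VeinMask",
    "kmeans_1d",
    "extract_vein_mask",
    "centroid_image",
    "blend",
]

_MAX_ITER = 300


@dataclass(frozen=True)
class ClusterResult:
    """Outcome of Lloyd's algorithm on a flat array of values.

    objective_trace holds the within-cluster sum of squares after every
    assignment step; it is non-increasing by construction.
    """

    labels: np.ndarray
    centroids: np.ndarray
    objective: float
    n_iter: int
    objective_trace: tuple[float, ...] = field(default=())


@dataclass(frozen=True)
class VeinMask:
    mask: np.ndarray
    vein_cluster: int


def _kmeanspp_init(values: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centroids by squared distance."""
    centroids = np.empty(k)
    centroids[0] = values[rng.integers(values.size)]
    d2 = (values - centroids[0]) ** 2
    for i in range(1, k):
        total = d2.sum()
        if total <= 0:
            # All remaining mass at already-chosen points: pick any distinct value.
            remaining = np.setdiff1d(np.unique(values), centroids[:i])
            centroids[i] = remaining[0]
        else:
            centroids[i] = values[rng.choice(values.size, p=d2 / total)]
        d2 = np.minimum(d2, (values - centroids[i]) ** 2)
    return centroids


def kmeans_1d(values: np.ndarray, k: int = 3, seed: int = 0) -> ClusterResult:
    """Cluster scalar values into k groups by Lloyd's EM alternation.

    Assignment (E): each value joins its nearest centroid.  Update (M):
    each centroid becomes the mean of its members.  Iterates until the
    assignment is stable or 300 iterations; the within-cluster sum of
    squares never increases across iterations.  An emptied cluster is
    reseeded at the point farthest from its current centroid.  Fully
    deterministic for a given seed.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if np.unique(values).size < k:
        raise ValueError(f"need >= {k} distinct values, got {np.unique(values).size}")
    rng = np.random.default_rng(seed)
    centroids = np.sort(_kmeanspp_init(values, k, rng))

    labels = np.zeros(values.size, dtype=np.intp)
    trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, _MAX_ITER + 1):
        dist2 = (values[:, None] - centroids[None, :]) ** 2
        new_labels = np.argmin(dist2, axis=1)
        obj = float(dist2[np.arange(values.size), new_labels].sum())
        trace.append(obj)
        if n_iter > 1 and np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
        for ci in range(k):
            members = values[labels == ci]
            if members.size:
                centroids[ci] = members.mean()
            else:
                # Reseed an emptied cluster at the worst-fit point.
                far = np.argmax((values - centroids[labels]) ** 2)
                centroids[ci] = values[far]

    dist2 = (values[:, None] - centroids[None, :]) ** 2
    labels = np.argmin(dist2, axis=1)
    obj = float(dist2[np.arange(values.size), labels].sum())
    return ClusterResult(
        labels=labels,
        centroids=centroids.copy(),
        objective=obj,
        n_iter=n_iter,
        objective_trace=tuple(trace),
    )


def segment_image(I: np.ndarray, k: int = 3, seed: int = 0) -> ClusterResult:
    """Run intensity k-means on a 2-D image; labels keep the image shape."""
    I = np.asarray(I, dtype=np.float64)
    res = kmeans_1d(I.ravel(), k=k, seed=seed)
    return ClusterResult(
        labels=res.labels.reshape(I.shape),
        centroids=res.centroids,
        objective=res.objective,
        n_iter=res.n_iter,
        objective_trace=res.objective_trace,
    )


def extract_vein_mask(result: ClusterResult, polarity: str = "dark") -> VeinMask:
    """Pick the vein cluster by centroid rank (darkest for NIR) and build its mask."""
    if result.centroids.size < 2:
        raise ValueError("need k >= 2 clusters to separate veins from tissue")
    cs = np.sort(result.centroids)
    if np.min(np.diff(cs)) < 1e-12:
        raise ValueError("degenerate clustering: two centroids coincide")
    if polarity == "dark":
        vein_cluster = int(np.argmin(result.centroids))
    elif polarity == "bright":
        vein_cluster = int(np.argmax(result.centroids))
    else:
        raise ValueError(f"unknown polarity: {polarity!r}")
    return VeinMask(mask=result.labels == vein_cluster, vein_cluster=vein_cluster)


def centroid_image(result: ClusterResult) -> np.ndarray:
    """Render a segmentation as a grayscale image of cluster centroids.

    Each pixel takes the intensity of its cluster's centroid — the
    piecewise-constant 'cleaned' view of the segmentation used for COV
    and profile evaluation.
    """
    return result.centroids[result.labels]


def blend(
    mask: VeinMask | np.ndarray,
    optical: np.ndarray,
    color: tuple[float, float, float] = (0.0, 0.8, 0.2),
    alpha: float = 0.6,
) -> np.ndarray:
    """Overlay the vein mask on the optical image.

    out = optical outside the mask; inside,
    out = (1 - alpha) * optical + alpha * color.
    """
    m = mask.mask if isinstance(mask, VeinMask) else np.asarray(mask, dtype=bool)
    optical = np.asarray(optical, dtype=np.float64)
    if optical.ndim != 3 or optical.shape[2] != 3:
        raise ValueError("optical image must be (H, W, 3)")
    if m.shape != optical.shape[:2]:
        raise ValueError(f"shape mismatch: mask {m.shape} vs optical {optical.shape[:2]}")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    out = optical.copy()
    out[m] = (1.0 - alpha) * optical[m] + alpha * np.asarray(color, dtype=np.float64)
    return np.clip(out, 0.0, 1.0)
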