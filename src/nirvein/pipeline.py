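"""The end-to-end vein recognition pipeline.

Stage order: smoothing (none / median / Wiener / RTV) -> contrast
enhancement (CLAHE on the min-max renormalized smoothed image) ->
intensity k-means (k = 3: background, tissue, veins) -> vein mask
(darkest cluster) -> optional blend into the co-registered optical image.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from . import io
from .clahe import CLAHEParams, apply_clahe
from .filters import WindowSpec, median_filter, wiener_filter
from .rtv import RTVParams, rtv_smooth
from .segment import (
    ClusterResult,
    VeinMask,
    blend,
    centroid_image,
    extract_vein_mask,
    segment_image,
)

__all__ = ["PipelineParams", "PipelineResult", "METHODS", "process", "run_pipeline"]

METHODS = ("none", "median", "wiener", "rtv")


@dataclass(frozen=True)
class PipelineParams:
    """All tunables of one pipeline run."""

    method: str = "rtv"
    rtv: RTVParams = field(default_factory=RTVParams)
    median_size: int = 3
    wiener_size: int = 5
    wiener_noise_var: float | str = "auto"
    clahe: CLAHEParams = field(default_factory=CLAHEParams)
    k: int = 3
    kmeans_seed: int = 0
    polarity: str = "dark"
    blend_color: tuple[float, float, float] = (0.0, 0.8, 0.2)
    blend_alpha: float = 0.6

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")


@dataclass(frozen=True)
class PipelineResult:
    smoothed: np.ndarray
    enhanced: np.ndarray
    clusters: ClusterResult
    vein: VeinMask
    segmentation: np.ndarray  # centroid-rendered grayscale segmentation
    rtv_energy_trace: tuple[float, ...] = ()
    stage_seconds: dict = field(default_factory=dict)


def _renormalize(I: np.ndarray) -> np.ndarray:
    """Min-max stretch to [0, 1]; constant images map to 0."""
    lo, hi = float(I.min()), float(I.max())
    if hi - lo < 1e-12:
        return np.zeros_like(I)
    return (I - lo) / (hi - lo)


def smooth(I: np.ndarray, params: PipelineParams) -> tuple[np.ndarray, tuple[float, ...]]:
    """Run the configured smoothing stage; returns (image, rtv energy trace)."""
    if params.method == "none":
        return np.asarray(I, dtype=np.float64).copy(), ()
    if params.method == "median":
        return median_filter(I, WindowSpec(params.median_size)), ()
    if params.method == "wiener":
        return wiener_filter(I, WindowSpec(params.wiener_size), params.wiener_noise_var), ()
    S, trace = rtv_smooth(I, params.rtv, return_trace=True)
    return S, tuple(trace)


def process(I: np.ndarray, params: PipelineParams | None = None) -> PipelineResult:
    """Run smoothing -> CLAHE -> k-means -> vein mask on one grayscale image."""
    if params is None:
        params = PipelineParams()
    I = io.check_gray(I, "input")
    times: dict[str, float] = {}

    t0 = time.perf_counter()
    smoothed, trace = smooth(I, params)
    times["smooth"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    enhanced = apply_clahe(_renormalize(smoothed), params.clahe)
    times["clahe"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    clusters = segment_image(enhanced, k=params.k, seed=params.kmeans_seed)
    vein = extract_vein_mask(clusters, polarity=params.polarity)
    times["kmeans"] = time.perf_counter() - t0

    return PipelineResult(
        smoothed=smoothed,
        enhanced=enhanced,
        clusters=clusters,
        vein=vein,
        segmentation=centroid_image(clusters),
        rtv_energy_trace=trace,
        stage_seconds=times,
    )


def _params_record(params: PipelineParams) -> dict:
    rec = asdict(params)
    rec["rtv"] = asdict(params.rtv)
    rec["clahe"] = asdict(params.clahe)
    return rec


def run_pipeline(
    input_path: str | os.PathLike,
    out_dir: str | os.PathLike,
    params: PipelineParams | None = None,
    optical_path: str | os.PathLike | None = None,
) -> dict:
    """File-level pipeline: read, process, write artifacts + provenance.

    Writes 16-bit TIFF intermediates (smoothed, enhanced), an 8-bit PNG
    mask and segmentation, an optional blended RGB PNG, and a JSON
    provenance record sufficient to reproduce the run.  On any stage
    failure, partial outputs are removed.
    """
    if params is None:
        params = PipelineParams()
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    def _w(name: str, writer, *args) -> str:
        path = os.path.join(out_dir, name)
        writer(path, *args)
        written.append(path)
        return path

    try:
        I = io.read_gray(input_path)
        result = process(I, params)
        _w("smoothed.tiff", io.write_gray, result.smoothed, 16)
        _w("enhanced.tiff", io.write_gray, result.enhanced, 16)
        _w("mask.png", io.write_gray, result.vein.mask.astype(np.float64), 8)
        _w("segmentation.png", io.write_gray, result.segmentation, 8)
        if optical_path is not None:
            optical = io.read_rgb(optical_path)
            blended = blend(result.vein, optical, params.blend_color, params.blend_alpha)
            _w("blended.png", io.write_rgb, blended)
        provenance = {
            "input": os.fspath(input_path),
            "optical": os.fspath(optical_path) if optical_path else None,
            "params": _params_record(params),
            "rtv_energy_trace": list(result.rtv_energy_trace),
            "kmeans": {
                "centroids": result.clusters.centroids.tolist(),
                "objective": result.clusters.objective,
                "n_iter": result.clusters.n_iter,
                "objective_trace": list(result.clusters.objective_trace),
            },
            "vein_cluster": result.vein.vein_cluster,
            "stage_seconds": result.stage_seconds,
            "outputs": [os.path.basename(p) for p in written],
        }
        ppath = os.path.join(out_dir, "provenance.json")
        with open(ppath, "w") as fh:
            json.dump(provenance, fh, indent=2)
        provenance["provenance_path"] = ppath
        return provenance
    except Exception as exc:
        for p in written:
            if os.path.exists(p):
                os.remove(p)
        raise RuntimeError(f"pipeline failed at stage output {len(written)}: {exc}") from exc
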