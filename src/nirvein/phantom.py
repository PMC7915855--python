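"""Synthetic NIR hand-vein phantoms with ground truth.

Veins absorb more near-infrared light than the surrounding tissue, so a
dorsal-hand NIR image shows dark, smoothly curving tubular dips on a
brighter tissue background, modulated by low-frequency illumination
inhomogeneity and corrupted by fine hairs (thin dark curvilinear
distractors of similar contrast), stationary fine-scale texture, and
sensor noise.  This module renders that generative model:

    nir = clip( tissue * illum * (1 - sum vein_dips - sum hair_dips)
                + texture + noise, 0, 1 )

where each vein dip has a Gaussian cross-section of depth
``vein_contrast`` around a smooth spline centerline.  A co-registered
skin-toned RGB rendering of the same scene omits the vein dips (veins are
invisible in visible light), and the ground truth records the vein mask
(pixels within 2 sigma of a centerline), the centerlines themselves, and
the hair mask.

All randomness flows from the spec's seed; identical spec implies
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom",
    "render_phantom",
    "make_two_vein_phantom",
    "standard_phantom_suite",
]

_SKIN_TONE = np.array([0.85, 0.62, 0.48])
_CENTERLINE_STEP = 0.25  # px spacing of sampled centerline points


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one phantom scene.

    vein_contrast is the fractional depth of the vein dip below the local
    tissue intensity; vein_width_range bounds the Gaussian cross-section
    sigma in pixels.  The seed is mandatory: generation without one would
    break the reproducibility contract.
    """

    height: int = 256
    width: int = 256
    n_veins: int = 3
    vein_width_range: tuple[float, float] = (2.5, 4.5)
    vein_contrast: float = 0.45
    tissue_level: float = 0.55
    illumination_amplitude: float = 0.12
    n_hairs: int = 4
    hair_contrast: float = 0.35
    texture_amplitude: float = 0.02
    noise_sigma: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.seed is None:
            raise ValueError("a seed is required (reproducibility contract)")
        if self.n_veins < 0 or self.n_hairs < 0:
            raise ValueError("counts must be nonnegative")
        if not (0 < self.tissue_level < 1):
            raise ValueError("tissue_level must lie in (0, 1)")
        if not (0 <= self.vein_contrast <= 1):
            raise ValueError("vein_contrast must lie in [0, 1]")
        if self.tissue_level * (1 - self.vein_contrast) <= 0:
            raise ValueError("vein dip would drive intensity non-positive")
        lo, hi = self.vein_width_range
        if not (0 < lo <= hi):
            raise ValueError("vein_width_range must be 0 < lo <= hi")
        for name in ("illumination_amplitude", "hair_contrast",
                     "texture_amplitude", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class PhantomTruth:
    vein_mask: np.ndarray
    vein_centerlines: list[np.ndarray]  # each (N, 2) float (row, col)
    hair_mask: np.ndarray
    vein_sigmas: tuple[float, ...] = ()


def _spline_path(
    control_rc: np.ndarray, n_out: int
) -> np.ndarray:
    """Cubic-spline interpolation through control points, arc-parametrized."""
    t = np.linspace(0.0, 1.0, control_rc.shape[0])
    cs_r = CubicSpline(t, control_rc[:, 0])
    cs_c = CubicSpline(t, control_rc[:, 1])
    tt = np.linspace(0.0, 1.0, n_out)
    return np.column_stack([cs_r(tt), cs_c(tt)])


def _random_vein_path(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """A smooth curve crossing the full image with bounded wiggle."""
    H, W = spec.height, spec.width
    vertical = bool(rng.integers(2))
    n_ctrl = int(rng.integers(4, 7))
    span = H if vertical else W
    cross = W if vertical else H
    main = np.linspace(-0.05 * span, 1.05 * span, n_ctrl)
    center = rng.uniform(0.2, 0.8) * cross
    # Cumulative bounded jitter keeps curvature gentle (vein-like).
    offsets = center + np.cumsum(rng.uniform(-0.08, 0.08, n_ctrl) * cross)
    offsets = np.clip(offsets, 0.05 * cross, 0.95 * cross)
    ctrl = np.column_stack([main, offsets] if vertical else [offsets, main])
    n_out = int(1.4 * span / _CENTERLINE_STEP)
    return _spline_path(ctrl, n_out)


def _random_hair_path(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Random-walk polyline: a thin hair lying across the skin."""
    H, W = spec.height, spec.width
    pos = rng.uniform([0.1 * H, 0.1 * W], [0.9 * H, 0.9 * W])
    angle = rng.uniform(0, 2 * np.pi)
    length = rng.uniform(0.25, 0.6) * min(H, W)
    n_steps = max(int(length / _CENTERLINE_STEP), 2)
    # Direction diffuses slowly -> gently curving strand.
    turns = rng.normal(0.0, 0.02, n_steps)
    angles = angle + np.cumsum(turns)
    steps = _CENTERLINE_STEP * np.column_stack([np.sin(angles), np.cos(angles)])
    return pos + np.cumsum(steps, axis=0)


def _distance_to_path(shape: tuple[int, int], path: np.ndarray) -> np.ndarray:
    """Per-pixel Euclidean distance to the sampled centerline."""
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W]
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    d, _ = cKDTree(path).query(pts, k=1)
    return d.reshape(H, W)


def _illumination(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 + a*f with max|f| = 1."""
    H, W = spec.height, spec.width
    if spec.illumination_amplitude == 0:
        return np.ones((H, W))
    yy, xx = np.mgrid[0:H, 0:W] / max(H, W)
    f = np.zeros((H, W))
    for _ in range(3):
        ky, kx = rng.uniform(0.5, 1.5, 2)
        ph = rng.uniform(0, 2 * np.pi, 2)
        f += rng.uniform(0.3, 1.0) * np.cos(2 * np.pi * ky * yy + ph[0]) * np.cos(
            2 * np.pi * kx * xx + ph[1]
        )
    f /= np.abs(f).max()
    return 1.0 + spec.illumination_amplitude * f


def _texture(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Band-limited stationary texture: smoothed white noise, zero mean."""
    from scipy.ndimage import gaussian_filter

    if spec.texture_amplitude == 0:
        return np.zeros((spec.height, spec.width))
    raw = rng.standard_normal((spec.height, spec.width))
    sm = gaussian_filter(raw, sigma=1.5, mode="wrap")
    sm -= sm.mean()
    rms = np.sqrt(np.mean(sm**2))
    return spec.texture_amplitude * sm / rms


def _render(
    spec: PhantomSpec,
    vein_paths: list[np.ndarray],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, PhantomTruth]:
    H, W = spec.height, spec.width
    shape = (H, W)
    lo, hi = spec.vein_width_range
    sigmas = tuple(float(rng.uniform(lo, hi)) for _ in vein_paths)

    vein_dip = np.zeros(shape)
    vein_mask = np.zeros(shape, dtype=bool)
    kept_paths: list[np.ndarray] = []
    for path, sigma in zip(vein_paths, sigmas):
        d = _distance_to_path(shape, path)
        vein_dip += spec.vein_contrast * np.exp(-(d**2) / (2 * sigma**2))
        vein_mask |= d <= 2.0 * sigma
        kept_paths.append(path)

    hair_dip = np.zeros(shape)
    hair_mask = np.zeros(shape, dtype=bool)
    for _ in range(spec.n_hairs):
        path = _random_hair_path(spec, rng)
        d = _distance_to_path(shape, path)
        hair_sigma = float(rng.uniform(0.5, 0.8))
        hair_dip += spec.hair_contrast * np.exp(-(d**2) / (2 * hair_sigma**2))
        hair_mask |= d <= 2.0 * hair_sigma

    illum = _illumination(spec, rng)
    texture = _texture(spec, rng)
    noise = (
        spec.noise_sigma * rng.standard_normal(shape)
        if spec.noise_sigma > 0
        else np.zeros(shape)
    )

    base = spec.tissue_level * illum
    nir = np.clip(base * (1.0 - vein_dip - hair_dip) + texture + noise, 0.0, 1.0)

    # Optical rendering: same illumination and hairs, no vein dips (veins
    # do not show in visible light), lightly textured skin tone.
    shade = np.clip(illum * (1.0 - hair_dip) + texture / spec.tissue_level, 0.0, None)
    rgb = np.clip(shade[..., None] * _SKIN_TONE[None, None, :], 0.0, 1.0)

    truth = PhantomTruth(
        vein_mask=vein_mask,
        vein_centerlines=kept_paths,
        hair_mask=hair_mask,
        vein_sigmas=sigmas,
    )
    return nir, rgb, truth


def make_phantom(
    spec: PhantomSpec,
) -> tuple[np.ndarray, np.ndarray, PhantomTruth]:
    """Generate one random phantom scene from its spec (deterministic in seed)."""
    rng = np.random.default_rng(spec.seed)
    vein_paths = [_random_vein_path(spec, rng) for _ in range(spec.n_veins)]
    return _render(spec, vein_paths, rng)


def render_phantom(
    spec: PhantomSpec, vein_paths: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, PhantomTruth]:
    """Render a phantom with caller-supplied vein centerlines.

    Each path is an (N, 2) float array of (row, col) points sampled densely
    along the curve.  Everything else (cross-section widths, hairs,
    illumination, texture, noise) still derives from the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    return _render(spec, [np.asarray(p, dtype=np.float64) for p in vein_paths], rng)


def make_two_vein_phantom(
    spec: PhantomSpec,
) -> tuple[np.ndarray, np.ndarray, PhantomTruth]:
    """Two roughly parallel near-vertical veins for profile analysis.

    The horizontal midline row crosses exactly two vein-mask runs, so an
    intensity profile along it shows exactly two vein dips — the scene
    used to count spurious profile responses.
    """
    if spec.n_veins != 2:
        spec = replace(spec, n_veins=2)
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    paths = []
    for frac in (0.35, 0.65):
        n_ctrl = 5
        main = np.linspace(-0.05 * H, 1.05 * H, n_ctrl)
        offsets = frac * W + rng.uniform(-0.03, 0.03, n_ctrl) * W
        ctrl = np.column_stack([main, offsets])
        paths.append(_spline_path(ctrl, int(1.4 * H / _CENTERLINE_STEP)))
    return _render(spec, paths, rng)


def standard_phantom_suite(
    n: int,
    seed: int = 0,
    *,
    height: int = 256,
    width: int = 256,
    noise_sigma: float = 0.05,
) -> list[tuple[np.ndarray, np.ndarray, PhantomTruth]]:
    """The fixed phantom family used by the evaluation harness.

    Member 0 is always the two-vein profile scene; members 1..n-1 are
    generic three-vein scenes with per-member seeds derived from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = []
    base = dict(height=height, width=width, noise_sigma=noise_sigma)
    two_vein = PhantomSpec(n_veins=2, seed=seed * 1_000_003 % (2**31), **base)
    out.append(make_two_vein_phantom(two_vein))
    for i in range(1, n):
        member = PhantomSpec(
            n_veins=3, seed=(seed * 1_000_003 + i) % (2**31), **base
        )
        out.append(make_phantom(member))
    return out
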