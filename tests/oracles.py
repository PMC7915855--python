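"""Independent reference implementations used to validate the package.

Everything here is written the slow, obvious way — explicit loops, dense
matrices, exhaustive search — and never calls into the code paths it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# RTV energy via naive summation, and a gradient-descent minimizer
# ---------------------------------------------------------------------------

def window_matrix(shape: tuple[int, int], h: float) -> np.ndarray:
    """Dense matrix M so that (M f) is the Gaussian-windowed sum of f.

    Built by brute-force double loop: output pixel p accumulates
    exp(-d^2 / 2h^2) * f(q) over window offsets truncated at ceil(3h),
    with replicate (clamped-index) boundary handling.
    """
    H, W = shape
    r = math.ceil(3.0 * h)
    n = H * W
    M = np.zeros((n, n))
    for i in range(H):
        for j in range(W):
            p = i * W + j
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    w = math.exp(-(di * di + dj * dj) / (2.0 * h * h))
                    qi = min(max(i + di, 0), H - 1)
                    qj = min(max(j + dj, 0), W - 1)
                    M[p, qi * W + qj] += w
    return M


def diff_matrices(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Dense forward-difference operators (zero gradient on last col/row)."""
    H, W = shape
    n = H * W
    Gx = np.zeros((n, n))
    Gy = np.zeros((n, n))
    for i in range(H):
        for j in range(W):
            p = i * W + j
            if j + 1 < W:
                Gx[p, p + 1] = 1.0
                Gx[p, p] = -1.0
            if i + 1 < H:
                Gy[p, p + W] = 1.0
                Gy[p, p] = -1.0
    return Gx, Gy


def rtv_energy_naive(
    S: np.ndarray, I: np.ndarray, lam: float, h: float, eps: float
) -> float:
    """RTV energy by explicit per-pixel summation (no shared code)."""
    H, W = S.shape
    M = window_matrix((H, W), h)
    Gx, Gy = diff_matrices((H, W))
    s = S.ravel()
    fidelity = float(np.sum((s - I.ravel()) ** 2))
    pen = 0.0
    for G in (Gx, Gy):
        g = G @ s
        D = M @ np.abs(g)
        L = np.abs(M @ g)
        pen += float(np.sum(D / (L + eps)))
    return fidelity + lam * pen


class RTVDescent:
    """Sub-gradient descent with backtracking line search on the RTV energy.

    Uses the dense-matrix formulation above; the search direction is the
    analytic (sub)gradient and steps are only accepted when the true
    energy decreases, so the trajectory is monotone.
    """

    def __init__(self, I: np.ndarray, lam: float, h: float, eps: float):
        self.shape = I.shape
        self.I = I.ravel().copy()
        self.lam = lam
        self.eps = eps
        self.M = window_matrix(I.shape, h)
        self.Gx, self.Gy = diff_matrices(I.shape)

    def energy(self, s: np.ndarray, delta: float = 0.0) -> float:
        """RTV energy; ``delta`` smooths |x| -> sqrt(x^2 + delta^2)."""

        def _abs(x: np.ndarray) -> np.ndarray:
            return np.abs(x) if delta == 0 else np.sqrt(x * x + delta * delta)

        val = float(np.sum((s - self.I) ** 2))
        for G in (self.Gx, self.Gy):
            g = G @ s
            D = self.M @ _abs(g)
            L = _abs(self.M @ g)
            val += self.lam * float(np.sum(D / (L + self.eps)))
        return val

    def grad(self, s: np.ndarray, delta: float = 0.0) -> np.ndarray:
        def _abs(x: np.ndarray) -> np.ndarray:
            return np.abs(x) if delta == 0 else np.sqrt(x * x + delta * delta)

        def _dabs(x: np.ndarray) -> np.ndarray:
            return np.sign(x) if delta == 0 else x / np.sqrt(x * x + delta * delta)

        out = 2.0 * (s - self.I)
        for G in (self.Gx, self.Gy):
            g = G @ s
            m = self.M @ g
            D = self.M @ _abs(g)
            denom = _abs(m) + self.eps
            dP_dg = _dabs(g) * (self.M.T @ (1.0 / denom)) - self.M.T @ (
                D * _dabs(m) / denom**2
            )
            out += self.lam * (G.T @ dP_dg)
        return out

    def _descend(
        self, s: np.ndarray, delta: float, max_iter: int, step0: float
    ) -> np.ndarray:
        e = self.energy(s, delta)
        step = step0
        stall = 0
        for _ in range(max_iter):
            d = self.grad(s, delta)
            nd = np.linalg.norm(d)
            if nd < 1e-12:
                break
            d = d / nd
            accepted = False
            for _ in range(60):
                cand = s - step * d
                ec = self.energy(cand, delta)
                if ec < e - 1e-14:
                    s, e = cand, ec
                    step *= 1.5
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                step = step0
                stall += 1
                if stall > 3:
                    break
            else:
                stall = 0
        return s

    def minimize_from(
        self,
        s0: np.ndarray,
        max_iter: int = 3000,
        delta: float = 1e-10,
        step0: float = 1e-2,
    ) -> tuple[np.ndarray, float]:
        """Monotone descent from one starting image; returns (S, true energy).

        delta smooths the |x| kinks just enough for the sub-gradient to be
        usable; it is kept 5 orders below the objective's eps so the
        smoothed and true energies agree to ~1e-5 relative.
        """
        s = self._descend(np.asarray(s0, dtype=np.float64).ravel().copy(),
                          delta, max_iter, step0)
        return s.reshape(self.shape), self.energy(s)

    def minimize(
        self,
        extra_starts: tuple[np.ndarray, ...] = (),
        max_iter: int = 3000,
    ) -> float:
        """Best energy over descent runs from several independent starts.

        The objective is nonconvex with ~1/eps-conditioned valleys, so a
        single cold start cannot be trusted; the canonical multi-start set
        is the input image, two box-blurred versions of it, and the flat
        (mean) image.  Callers may supply further starts — e.g. a candidate
        minimizer whose local optimality is in question; descent dynamics
        remain this class's own either way.
        """
        from scipy.ndimage import uniform_filter

        I2 = self.I.reshape(self.shape)
        starts = [
            I2,
            uniform_filter(I2, 3, mode="nearest"),
            uniform_filter(I2, 7, mode="nearest"),
            np.full(self.shape, I2.mean()),
            *extra_starts,
        ]
        return min(self.minimize_from(s0, max_iter=max_iter)[1] for s0 in starts)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def _pad_replicate(I: np.ndarray, r: int) -> np.ndarray:
    return np.pad(I, r, mode="edge")


def median_naive(I: np.ndarray, size: int) -> np.ndarray:
    """Sort-based sliding median with replicate padding."""
    r = size // 2
    P = _pad_replicate(I, r)
    out = np.empty_like(I, dtype=np.float64)
    H, W = I.shape
    for i in range(H):
        for j in range(W):
            win = np.sort(P[i : i + size, j : j + size].ravel())
            n = win.size
            out[i, j] = win[n // 2] if n % 2 else 0.5 * (win[n // 2 - 1] + win[n // 2])
    return out


def wiener_naive(I: np.ndarray, size: int, eta2: float) -> np.ndarray:
    """Element-wise local Wiener shrinkage, population variance."""
    r = size // 2
    P = _pad_replicate(I, r)
    out = np.empty_like(I, dtype=np.float64)
    H, W = I.shape
    for i in range(H):
        for j in range(W):
            win = P[i : i + size, j : j + size]
            mu = win.mean()
            var = ((win - mu) ** 2).mean()
            gain = max(var - eta2, 0.0) / var if var > 0 else 0.0
            out[i, j] = mu + gain * (I[i, j] - mu)
    return out


# ---------------------------------------------------------------------------
# CLAHE clip/redistribute
# ---------------------------------------------------------------------------

def clip_redistribute_naive(hist: list[int], clip: float, cap: int = 1000) -> list[int]:
    """Step-by-step iteration of the stated redistribution rule."""
    counts = [int(c) for c in hist]
    nb = len(counts)
    clip_i = int(math.floor(clip))
    for _ in range(cap):
        if max(counts) <= clip_i + 1:
            return counts
        excess = sum(max(c - clip_i, 0) for c in counts)
        counts = [min(c, clip_i) for c in counts]
        share, rem = divmod(excess, nb)
        counts = [c + share for c in counts]
        for b in range(rem):
            counts[b] += 1
    raise RuntimeError("did not settle")


# ---------------------------------------------------------------------------
# 1-D k-means global optimum by exhaustive contiguous partition
# ---------------------------------------------------------------------------

def kmeans_1d_optimum(values: np.ndarray, k: int) -> float:
    """Global optimum of 1-D k-means via exhaustive contiguous partitions.

    In 1-D every optimal clustering is contiguous in sorted order, so the
    global optimum is the best placement of k-1 cut points.
    """
    v = np.sort(np.asarray(values, dtype=np.float64))
    n = v.size
    best = math.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        sse = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg = v[a:b]
            sse += float(((seg - seg.mean()) ** 2).sum())
        best = min(best, sse)
    return best
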