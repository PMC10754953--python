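"""Dense optical flow by polynomial expansion (Farneback's algorithm).

Each image neighborhood is approximated by a quadratic polynomial
f(x) ≈ xᵀAx + bᵀx + c fitted under a Gaussian applicability; observing how
the polynomial coefficients move between two frames yields, per pixel, a
linear system A d ≈ Δb for the displacement d, which is solved in a least-
squares sense over an averaging window.  A coarse-to-fine image pyramid
handles displacements larger than a neighborhood, and the estimate is
refined by warping over a few iterations per level.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

__all__ = ["polynomial_expansion", "farneback_flow_pair"]


def _poly_basis(n: int, sigma: float):
    """Precompute the (pseudo)inverse metric for the 6-term basis
    {1, x, y, x², y², xy} under a Gaussian applicability of half-width n."""
    xs = np.arange(-n, n + 1, dtype=np.float64)
    a = np.exp(-(xs ** 2) / (2 * sigma ** 2))
    X, Y = np.meshgrid(xs, xs, indexing="xy")
    W = np.outer(a, a)
    basis = np.stack([np.ones_like(X), X, Y, X ** 2, Y ** 2, X * Y])
    G = np.einsum("iyx,jyx,yx->ij", basis, basis, W)
    Ginv = np.linalg.inv(G)
    return xs, a, basis, W, Ginv


def polynomial_expansion(img: np.ndarray, n: int = 2, sigma: float = 1.1):
    """Per-pixel quadratic coefficients (A 2x2 symmetric, b 2-vector, c).

    Returns (A11, A12, A22, b1, b2) arrays; the constant term is dropped as
    the displacement estimate never uses it.  Correlations are separable in
    x and y which keeps the expansion O(n) per pixel.
    """
    f = img.astype(np.float64)
    xs, a, _, _, Ginv = _poly_basis(n, sigma)
    # separable correlations of f with {1, x, x²} along each axis
    k0, k1, k2 = a, a * xs, a * xs ** 2

    def corr(fv, kx, ky):
        t = ndi.correlate1d(fv, ky, axis=0, mode="reflect")
        return ndi.correlate1d(t, kx, axis=1, mode="reflect")

    m00 = corr(f, k0, k0)   # <f, 1>
    m10 = corr(f, k1, k0)   # <f, x>
    m01 = corr(f, k0, k1)   # <f, y>
    m20 = corr(f, k2, k0)   # <f, x²>
    m02 = corr(f, k0, k2)   # <f, y²>
    m11 = corr(f, k1, k1)   # <f, xy>
    proj = np.stack([m00, m10, m01, m20, m02, m11])
    coef = np.einsum("ij,jyx->iyx", Ginv, proj)
    _, b1, b2, a11, a22, a12h = coef
    return a11, 0.5 * a12h, a22, b1, b2


def _solve_flow(A11, A12, A22, db1, db2, win: int):
    """Least-squares displacement from A d ≈ Δb averaged over a win×win box."""
    # normal equations: (AᵀA) d = Aᵀ Δb, accumulated over the window
    G11 = A11 * A11 + A12 * A12
    G12 = A11 * A12 + A12 * A22
    G22 = A12 * A12 + A22 * A22
    h1 = A11 * db1 + A12 * db2
    h2 = A12 * db1 + A22 * db2
    sm = lambda z: ndi.uniform_filter(z, size=win, mode="reflect")
    G11, G12, G22, h1, h2 = map(sm, (G11, G12, G22, h1, h2))
    det = G11 * G22 - G12 * G12
    det = np.where(np.abs(det) < 1e-9, 1e-9, det)
    dx = (G22 * h1 - G12 * h2) / det
    dy = (G11 * h2 - G12 * h1) / det
    return dy, dx


def _warp(img2_coeffs, flow_y, flow_x):
    """Sample each coefficient map of frame 2 at the flow-displaced position."""
    h, w = flow_y.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    sy = np.clip(yy + flow_y, 0, h - 1)
    sx = np.clip(xx + flow_x, 0, w - 1)
    return [ndi.map_coordinates(c, [sy, sx], order=1, mode="nearest") for c in img2_coeffs]


def farneback_flow_pair(img_a: np.ndarray, img_b: np.ndarray, levels: int = 6,
                        scale: float = 0.2, iterations: int = 3, poly_n: int = 5,
                        win: int = 30, poly_sigma: float = 1.2) -> np.ndarray:
    """Dense (dy, dx) displacement from img_a to img_b.

    ``poly_n`` is the neighborhood size of the polynomial expansion (an
    n×n window, so the half-width is n//2), ``win`` the side of the box
    filter that averages the normal equations, ``scale`` the pyramid
    downscaling ratio per level.  Levels that would shrink the image below
    a usable size are skipped.
    """
    if img_a.shape != img_b.shape:
        raise ValueError("slices must have the same shape")
    a = img_a.astype(np.float64)
    b = img_b.astype(np.float64)
    h, w = a.shape
    half = max(1, poly_n // 2)

    # build pyramid (finest first), dropping degenerate levels
    pyr = []
    for lvl in range(levels):
        s = scale ** lvl
        nh, nw = int(round(h * s)), int(round(w * s))
        if min(nh, nw) < max(16, 4 * poly_n):
            break
        if lvl == 0:
            pa, pb = a, b
        else:
            sig = 0.5 * np.sqrt(1.0 / s ** 2 - 1.0)
            pa = ndi.zoom(ndi.gaussian_filter(a, sig), (nh / h, nw / w), order=1)
            pb = ndi.zoom(ndi.gaussian_filter(b, sig), (nh / h, nw / w), order=1)
        pyr.append((pa, pb, s))

    flow_y = flow_x = None
    for pa, pb, s in reversed(pyr):
        nh, nw = pa.shape
        if flow_y is None:
            flow_y = np.zeros((nh, nw))
            flow_x = np.zeros((nh, nw))
        else:
            zy, zx = nh / flow_y.shape[0], nw / flow_y.shape[1]
            flow_y = ndi.zoom(flow_y, (zy, zx), order=1) * zy
            flow_x = ndi.zoom(flow_x, (zy, zx), order=1) * zx
        A11a, A12a, A22a, b1a, b2a = polynomial_expansion(pa, half, poly_sigma)
        cb = polynomial_expansion(pb, half, poly_sigma)
        lw = max(3, int(round(win * s)))
        for _ in range(iterations):
            A11b, A12b, A22b, b1b, b2b = _warp(cb, flow_y, flow_x)
            A11 = 0.5 * (A11a + A11b)
            A12 = 0.5 * (A12a + A12b)
            A22 = 0.5 * (A22a + A22b)
            # Δb = -(b₂(x+d) - b₁(x))/2 + A d  (d in (x, y) components)
            db1 = -0.5 * (b1b - b1a) + (A11 * flow_x + A12 * flow_y)
            db2 = -0.5 * (b2b - b2a) + (A12 * flow_x + A22 * flow_y)
            flow_y, flow_x = _solve_flow(A11, A12, A22, db1, db2, lw)
    return np.stack([flow_y, flow_x])
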