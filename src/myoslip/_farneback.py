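"""Dense two-frame motion estimation by polynomial expansion (Farnebäck).

Each local neighborhood of a frame is approximated by a quadratic
polynomial f(x) ~ x^T A x + b^T x + c, fitted by Gaussian-weighted least
squares (the "polynomial expansion").  For a pure translation d the
expansions of the two frames satisfy b2 = b1 - 2 A d, which is solved for d
per pixel by accumulating the normal equations over a weighting window;
iterating with warped coefficients and embedding the solver in a coarse-to-
fine image pyramid extends the estimate to displacements larger than the
expansion neighborhood.

Implementation is pure numpy/scipy (separable correlations +
map_coordinates); no claim of numeric equality with other implementations
of the same method.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.transform import resize


def _poly_expand(f: np.ndarray, n: int, sigma: float):
    """Quadratic polynomial expansion of a 2D image.

    Returns (A, b) where A is (H, W, 2, 2) and b is (H, W, 2), using the
    basis (1, x, y, x^2, y^2, xy) with x along columns, y along rows, and a
    Gaussian applicability of width ``sigma`` on a (2n+1)^2 neighborhood.
    """
    x = np.arange(-n, n + 1, dtype=np.float64)
    a = np.exp(-(x**2) / (2.0 * sigma**2))

    # normal matrix G = sum a(u) B(u) B(u)^T over the window (uniform certainty)
    ax, ay = np.meshgrid(x, x)  # ax varies along columns, ay along rows
    w2 = np.outer(a, a)
    basis = np.stack([np.ones_like(ax), ax, ay, ax**2, ay**2, ax * ay])
    G = np.einsum("kij,lij,ij->kl", basis, basis, w2)
    G_inv = np.linalg.inv(G)

    # projections v_i = sum a(u) B_i(u) f(p+u): separable correlations
    k0, k1, k2 = a, a * x, a * x**2
    fx0 = ndimage.correlate1d(f, k0, axis=1, mode="reflect")
    fx1 = ndimage.correlate1d(f, k1, axis=1, mode="reflect")
    fx2 = ndimage.correlate1d(f, k2, axis=1, mode="reflect")
    v = np.stack([
        ndimage.correlate1d(fx0, k0, axis=0, mode="reflect"),  # 1
        ndimage.correlate1d(fx1, k0, axis=0, mode="reflect"),  # x
        ndimage.correlate1d(fx0, k1, axis=0, mode="reflect"),  # y
        ndimage.correlate1d(fx2, k0, axis=0, mode="reflect"),  # x^2
        ndimage.correlate1d(fx0, k2, axis=0, mode="reflect"),  # y^2
        ndimage.correlate1d(fx1, k1, axis=0, mode="reflect"),  # xy
    ], axis=-1)

    r = v @ G_inv.T  # (H, W, 6)
    A = np.empty(f.shape + (2, 2))
    A[..., 0, 0] = r[..., 3]
    A[..., 1, 1] = r[..., 4]
    A[..., 0, 1] = A[..., 1, 0] = 0.5 * r[..., 5]
    b = r[..., 1:3]  # (dx, dy) order: coefficient of x then y
    return A, b


def _solve_displacement(A1, b1, A2, b2, d0, win_sigma: float, border_weight):
    """One update of the displacement field given expansions of both frames."""
    h, w = d0.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    # fetch frame-2 coefficients at warped positions (bilinear)
    px = np.clip(xx + d0[..., 0], 0, w - 1)
    py = np.clip(yy + d0[..., 1], 0, h - 1)
    coords = np.stack([py.ravel(), px.ravel()])

    def warp(field):
        return ndimage.map_coordinates(field, coords, order=1, mode="nearest").reshape(h, w)

    A = 0.5 * (A1 + np.stack(
        [warp(A2[..., i, j]) for i in range(2) for j in range(2)], axis=-1
    ).reshape(h, w, 2, 2))
    db = -0.5 * (np.stack([warp(b2[..., 0]), warp(b2[..., 1])], axis=-1) - b1)
    db = db + np.einsum("...ij,...j->...i", A, d0)

    # accumulate normal equations G d = h over a Gaussian window
    ATA = np.einsum("...ki,...kj->...ij", A, A)
    ATb = np.einsum("...ki,...k->...i", A, db)

    def smooth(img):
        return ndimage.gaussian_filter(img * border_weight, win_sigma, mode="constant")

    G = np.empty_like(ATA)
    hh = np.empty_like(ATb)
    for i in range(2):
        hh[..., i] = smooth(ATb[..., i])
        for j in range(2):
            G[..., i, j] = smooth(ATA[..., i, j])

    det = G[..., 0, 0] * G[..., 1, 1] - G[..., 0, 1] * G[..., 1, 0]
    det = np.where(np.abs(det) < 1e-12, 1e-12, det)
    d = np.empty_like(d0)
    d[..., 0] = (G[..., 1, 1] * hh[..., 0] - G[..., 0, 1] * hh[..., 1]) / det
    d[..., 1] = (G[..., 0, 0] * hh[..., 1] - G[..., 1, 0] * hh[..., 0]) / det
    return d


def farneback_flow(frame_a: np.ndarray, frame_b: np.ndarray, *,
                   pyramid_levels: int = 3, pyramid_scale: float = 0.5,
                   window_size: int = 15, iterations: int = 3,
                   poly_n: int = 5, poly_sigma: float = 1.1) -> np.ndarray:
    """Dense displacement field a -> b, shape (H, W, 2) with (dx, dy) in px."""
    if frame_a.shape != frame_b.shape:
        raise ValueError(f"frame shapes differ: {frame_a.shape} vs {frame_b.shape}")
    if frame_a.ndim != 2:
        raise ValueError("dense flow expects single-channel 2D frames")
    fa = np.ascontiguousarray(frame_a, dtype=np.float64)
    fb = np.ascontiguousarray(frame_b, dtype=np.float64)
    h, w = fa.shape
    win_sigma = max(window_size / 4.0, 1.0)
    n = max(poly_n // 2, 1)

    # build pyramids (coarsest first)
    shapes = [(h, w)]
    for _ in range(1, pyramid_levels):
        ph, pw = shapes[-1]
        nh, nw = int(round(ph * pyramid_scale)), int(round(pw * pyramid_scale))
        if min(nh, nw) < 4 * poly_n:
            break
        shapes.append((nh, nw))
    shapes = shapes[::-1]

    d = None
    for lev, shape in enumerate(shapes):
        if shape == (h, w):
            la, lb = fa, fb
        else:
            la = resize(fa, shape, anti_aliasing=True, preserve_range=True)
            lb = resize(fb, shape, anti_aliasing=True, preserve_range=True)
        if d is None:
            d = np.zeros(shape + (2,))
        else:
            prev = shapes[lev - 1]
            scale = np.array([shape[1] / prev[1], shape[0] / prev[0]])
            d = resize(d, shape + (2,), anti_aliasing=False, preserve_range=True) * scale
        A1, b1 = _poly_expand(la, n, poly_sigma)
        A2, b2 = _poly_expand(lb, n, poly_sigma)
        # down-weight the reflective border region in the window accumulation
        bw = np.ones(shape)
        m = n + 1
        bw[:m, :] = bw[-m:, :] = 0.0
        bw[:, :m] = bw[:, -m:] = 0.0
        for _ in range(iterations):
            d = _solve_displacement(A1, b1, A2, b2, d, win_sigma, bw)
    return d
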