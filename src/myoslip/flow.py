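"""Myosin-channel preparation and dense optical flow.

Pipeline order is fixed: denoise the 3D stacks, maximum-project over Z,
then compute dense flow between consecutive projected myosin frames.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable

import numpy as np
from scipy import ndimage

from ._farneback import farneback_flow


@dataclass
class FlowParams:
    """Farnebäck flow parameters (all logged with each run)."""

    pyramid_levels: int = 3
    pyramid_scale: float = 0.5
    window_size: int = 15
    iterations: int = 3
    poly_n: int = 5
    poly_sigma: float = 1.1


@dataclass
class FlowField:
    """Dense per-pixel displacement between two consecutive myosin frames.

    ``flow`` has shape (H, W, 2), components (dx, dy) in px per myosin
    frame interval; x along columns, y along rows.
    """

    flow: np.ndarray
    pair_index: int = 0
    pixel_size: float = 1.0  # µm/px
    myosin_interval: float = 60.0  # s

    def __post_init__(self) -> None:
        if self.flow.ndim != 3 or self.flow.shape[-1] != 2:
            raise ValueError(f"flow must have shape (H, W, 2), got {self.flow.shape}")
        if not np.all(np.isfinite(self.flow)):
            raise ValueError("flow field contains non-finite values")

    @property
    def um_per_min_factor(self) -> float:
        """px/frame -> µm/min."""
        return self.pixel_size * 60.0 / self.myosin_interval

    @property
    def magnitude_um_per_min(self) -> np.ndarray:
        return np.hypot(self.flow[..., 0], self.flow[..., 1]) * self.um_per_min_factor


# -- denoising --------------------------------------------------------------

_DENOISERS: dict[str, Callable[[np.ndarray], np.ndarray]] = {}


def register_denoiser(name: str, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register a plugin denoiser: receives a stack, returns a stack of the
    same shape.  External self-supervised denoisers attach here."""
    _DENOISERS[name] = fn


def denoise(frames: np.ndarray, method: str = "passthrough", sigma: float = 1.0) -> np.ndarray:
    """Optionally denoise a stack.

    ``passthrough`` returns the input unchanged (the default, so the core
    pipeline has no hidden smoothing); ``gaussian`` applies a Gaussian of
    width ``sigma`` px to the two trailing (image) axes; any other name is
    looked up in the plugin registry.
    """
    if method == "passthrough":
        return frames
    if method == "gaussian":
        sig = (0,) * (frames.ndim - 2) + (sigma, sigma)
        out = ndimage.gaussian_filter(frames.astype(np.float64), sig)
        return out.astype(frames.dtype) if np.issubdtype(frames.dtype, np.integer) else out
    if method in _DENOISERS:
        out = _DENOISERS[method](frames)
        if out.shape != frames.shape:
            raise ValueError(f"denoiser {method!r} changed the stack shape")
        return out
    known = ["passthrough", "gaussian", *sorted(_DENOISERS)]
    raise ValueError(f"unknown denoiser {method!r}; registered methods: {known}")


def max_project(volume: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection over the Z axis.

    Accepts (Z, H, W) or (T, Z, H, W); the Z axis is the third-from-last.
    A 2D input is returned unchanged.
    """
    volume = np.asarray(volume)
    if volume.ndim == 2:
        return volume
    if volume.shape[-3] == 0:
        raise ValueError("empty z-stack")
    return volume.max(axis=-3)


def dense_flow(frame_a: np.ndarray, frame_b: np.ndarray,
               params: FlowParams | None = None, *, pair_index: int = 0,
               pixel_size: float = 1.0, myosin_interval: float = 60.0) -> FlowField:
    """Dense displacement field estimating motion a -> b (Farnebäck)."""
    if params is None:
        params = FlowParams()
    d = farneback_flow(np.asarray(frame_a, dtype=np.float64),
                       np.asarray(frame_b, dtype=np.float64), **asdict(params))
    return FlowField(flow=d, pair_index=pair_index, pixel_size=pixel_size,
                     myosin_interval=myosin_interval)


def movie_flows(projected: np.ndarray, params: FlowParams | None = None, *,
                pixel_size: float = 1.0, myosin_interval: float = 60.0,
                pairs: list[int] | None = None) -> dict[int, FlowField]:
    """Flow for consecutive projected myosin frame pairs.

    ``pairs`` selects frame-pair indices (pair i is frames i -> i+1);
    default is every consecutive pair.
    """
    n = projected.shape[0]
    if pairs is None:
        pairs = list(range(n - 1))
    out = {}
    for i in pairs:
        out[i] = dense_flow(projected[i], projected[i + 1], params, pair_index=i,
                            pixel_size=pixel_size, myosin_interval=myosin_interval)
    return out
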