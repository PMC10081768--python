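"""Junction-fluorescence quantification by fixed-geometry line scans.

Mean intensity over a 50 px x 5 px rectangle drawn along a junction,
background-corrected with the same geometry placed off-specimen, normalized
to the group maximum, compared between paired embryos as ratios, and an
apical:basal enrichment ratio along a junction line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class LineScanSpec:
    """A line-scan rectangle: a segment of ``length`` px sampled at 1 px
    pitch, ``width`` px across (odd so the line is centered)."""

    start: tuple[float, float]  # (x, y), px
    end: tuple[float, float]
    length: int = 50
    width: int = 5

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"length must be > 0, got {self.length}")
        if self.width < 1 or self.width % 2 == 0:
            raise ValueError(f"width must be odd and >= 1, got {self.width}")

    def sample_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """(xs, ys) arrays of shape (length, width): bilinear sample points."""
        p0 = np.asarray(self.start, dtype=float)
        p1 = np.asarray(self.end, dtype=float)
        seg = p1 - p0
        norm = np.linalg.norm(seg)
        if norm == 0:
            raise ValueError("line scan endpoints coincide")
        u = seg / norm  # along the line
        v = np.array([-u[1], u[0]])  # across
        along = np.linspace(0.0, norm, self.length)
        across = np.arange(self.width) - (self.width - 1) / 2.0
        xs = p0[0] + np.outer(along, u[0]) + np.outer(np.ones_like(along), across * v[0])
        ys = p0[1] + np.outer(along, u[1]) + np.outer(np.ones_like(along), across * v[1])
        return xs, ys


def line_mean_intensity(image: np.ndarray, spec: LineScanSpec) -> float:
    """Mean of bilinearly-sampled intensities over the line-scan rectangle."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("line_mean_intensity expects a 2D image (project stacks first)")
    xs, ys = spec.sample_grid()
    h, w = image.shape
    if xs.min() < 0 or xs.max() > w - 1 or ys.min() < 0 or ys.max() > h - 1:
        raise ValueError("line scan exits the image")
    vals = ndimage.map_coordinates(image, np.stack([ys.ravel(), xs.ravel()]), order=1)
    return float(vals.mean())


def background_correct(junction_mean: float, background_mean: float
                       ) -> tuple[float, bool]:
    """Background-subtracted mean; the flag marks a (kept) negative result."""
    adjusted = junction_mean - background_mean
    return adjusted, adjusted < 0


def normalize_group(values) -> np.ndarray:
    """Divide each value by the group maximum (maps the max to exactly 1)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("normalize_group: empty group")
    vmax = v.max()
    if vmax <= 0:
        raise ValueError(f"normalize_group: group maximum must be > 0, got {vmax}")
    return v / vmax


def pair_ratio(pairs) -> dict:
    """Experimental/control intensity ratios for side-by-side embryo pairs.

    ``pairs`` is a sequence of (experimental, control) adjusted means.
    Pairs with control <= 0 are flagged and excluded from the summary.
    Returns per-pair ratios (NaN where flagged), the group mean and its 95%
    confidence half-width over valid pairs.
    """
    from .stats import _ci_halfwidth

    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (experimental, control)")
    valid = arr[:, 1] > 0
    ratios = np.full(len(arr), np.nan)
    ratios[valid] = arr[valid, 0] / arr[valid, 1]
    good = ratios[valid]
    return {
        "ratios": ratios,
        "flagged": np.nonzero(~valid)[0].tolist(),
        "mean": float(good.mean()) if len(good) else float("nan"),
        "ci95": _ci_halfwidth(good),
        "n": int(len(good)),
    }


def apical_basal_ratio(image: np.ndarray, junction: LineScanSpec,
                       split_fraction: float = 0.5) -> float:
    """Apical:basal intensity ratio along an apicobasal junction line.

    The line runs apical -> basal; the mean over the first
    ``split_fraction`` of its length is divided by the mean over the rest.
    """
    if not (0 < split_fraction < 1):
        raise ValueError(f"split_fraction must be in (0, 1), got {split_fraction}")
    image = np.asarray(image, dtype=np.float64)
    xs, ys = junction.sample_grid()
    h, w = image.shape
    if xs.min() < 0 or xs.max() > w - 1 or ys.min() < 0 or ys.max() > h - 1:
        raise ValueError("line scan exits the image")
    vals = ndimage.map_coordinates(
        image, np.stack([ys.ravel(), xs.ravel()]), order=1).reshape(xs.shape)
    n_apical = int(round(junction.length * split_fraction))
    n_apical = min(max(n_apical, 1), junction.length - 1)
    apical = vals[:n_apical].mean()
    basal = vals[n_apical:].mean()
    if basal == 0:
        raise ValueError("apical_basal_ratio: zero basal mean")
    return float(apical / basal)
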