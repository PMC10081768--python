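"""Centripetal-vector ("Spyderleg") coupling analysis.

For each membrane frame pair, rays are cast from the cell center to the
boundary at uniform angular spacing.  Optical-flow vectors falling inside a
2 µm window at the outer end of each ray are converted to µm/min, filtered
(slow vectors removed, only centripetally moving ones kept) and projected
onto the ray to give the myosin velocity; the sub-pixel displacement of the
boundary crossing along the same ray gives the membrane velocity.  Their
difference is the slippage rate: 0 means membrane and myosin move in
concert, positive means the myosin outruns the membrane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .flow import FlowField
from .segmentation import CentroidTrack, LabelMaskSeries

logger = logging.getLogger(__name__)


@dataclass
class CouplingConfig:
    """Geometry, filtering and unit parameters of the coupling analysis.

    ``speed_threshold`` is the minimum flow speed retained (µm/min); by
    default it applies to the raw flow-vector magnitude with a separate
    centripetal-positivity test, ``threshold_on="centripetal"`` applies it
    to the centripetal component instead.  ``pool_samples`` pools retained
    samples across the myosin frame pairs of one membrane interval (the
    default); ``False`` averages per-pair means instead.
    """

    window_depth: float = 2.0  # µm
    speed_threshold: float = 1.5  # µm/min
    legs_per_cell: int = 36
    pixel_size: float = 0.1  # µm/px
    myosin_interval: float = 5.7  # s
    membrane_stride: int = 6
    threshold_on: str = "magnitude"  # or "centripetal"
    pool_samples: bool = True

    def __post_init__(self) -> None:
        if self.speed_threshold < 0:
            raise ValueError(f"speed_threshold must be >= 0, got {self.speed_threshold}")
        if self.window_depth <= 0:
            raise ValueError(f"window_depth must be > 0, got {self.window_depth}")
        if self.legs_per_cell < 4:
            raise ValueError(f"legs_per_cell must be >= 4, got {self.legs_per_cell}")
        if self.threshold_on not in ("magnitude", "centripetal"):
            raise ValueError("threshold_on must be 'magnitude' or 'centripetal'")

    @property
    def um_per_min_factor(self) -> float:
        return self.pixel_size * 60.0 / self.myosin_interval

    @property
    def membrane_dt_min(self) -> float:
        return self.membrane_stride * self.myosin_interval / 60.0


@dataclass
class Spyderleg:
    """One centripetal vector: a boundary anchor, the unit direction toward
    the center, and the set of in-cell pixels within ``window_depth`` of the
    anchor along the leg axis (a wedge so legs tile the border band)."""

    cell: int
    pair_index: int
    leg_id: int
    center: np.ndarray  # (x, y) px
    anchor: np.ndarray  # (x, y) px, subpixel boundary crossing
    direction: np.ndarray  # unit (x, y), anchor -> center
    window_depth: float  # µm
    window_pixels: tuple[np.ndarray, np.ndarray]  # (ys, xs) int arrays


@dataclass
class SlippageRecord:
    """One (embryo, cell, leg, membrane-frame-pair) measurement."""

    embryo: str
    cell: int
    leg: int
    pair: int
    time_post_msxx: float  # min
    v_myo: float  # µm/min, positive toward center
    v_mem: float  # µm/min, positive toward center
    slippage: float  # = v_myo - v_mem
    n_flow_samples: int
    stage: str = "excluded"
    flag: str = ""  # "", "no-flow", "no-membrane-crossing"

    @property
    def valid(self) -> bool:
        return self.flag == ""


def _ray_crossing(mask_f: np.ndarray, center: np.ndarray, u_out: np.ndarray,
                  step: float = 0.25) -> float | None:
    """Distance from center to the sub-pixel 0.5-crossing of a binary mask
    along an outward ray; None if the ray leaves the image while inside."""
    h, w = mask_f.shape
    r_max = float(np.hypot(h, w))
    t = np.arange(0.0, r_max, step)
    xs = center[0] + t * u_out[0]
    ys = center[1] + t * u_out[1]
    inside_img = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
    n = int(inside_img.sum())
    if n < 2:
        return None
    vals = ndimage.map_coordinates(mask_f, np.stack([ys[:n], xs[:n]]), order=1)
    below = np.nonzero(vals < 0.5)[0]
    if len(below) == 0 or below[0] == 0:
        return None
    i = below[0]
    v0, v1 = vals[i - 1], vals[i]
    frac = (v0 - 0.5) / (v0 - v1)
    return float(t[i - 1] + frac * step)


def build_spyderlegs(mask: np.ndarray, center, config: CouplingConfig, *,
                     cell: int = 1, pair_index: int = 0) -> list[Spyderleg]:
    """Cast ``legs_per_cell`` rays from the center at uniform angular spacing.

    The anchor of each leg is the sub-pixel boundary crossing of the ray;
    the window is the set of in-cell pixels whose projection onto the leg
    axis lies within ``window_depth`` µm inward of the anchor, restricted to
    the leg's angular wedge so windows tile the border band.  Rays that fail
    to hit the boundary are skipped with a logged warning.
    """
    center = np.asarray(center, dtype=float)
    mask_b = mask > 0
    mask_f = mask_b.astype(np.float64)
    cx, cy = center
    if not (0 <= int(round(cy)) < mask.shape[0] and 0 <= int(round(cx)) < mask.shape[1]) \
            or not mask_b[int(round(cy)), int(round(cx))]:
        raise ValueError(f"center {tuple(center)} is not inside the cell label")

    ys, xs = np.nonzero(mask_b)
    psi = np.arctan2(ys - cy, xs - cx)  # pixel angle about the center
    depth_px = config.window_depth / config.pixel_size
    half_wedge = np.pi / config.legs_per_cell

    legs = []
    for k in range(config.legs_per_cell):
        phi = 2.0 * np.pi * k / config.legs_per_cell
        u_out = np.array([np.cos(phi), np.sin(phi)])
        r = _ray_crossing(mask_f, center, u_out)
        if r is None:
            logger.warning("leg %d (cell %d, pair %d): ray did not cross the boundary; skipped",
                           k, cell, pair_index)
            continue
        anchor = center + r * u_out
        direction = -u_out  # unit vector toward the center
        rel_x = xs - anchor[0]
        rel_y = ys - anchor[1]
        s = rel_x * direction[0] + rel_y * direction[1]  # inward distance along leg
        dpsi = np.angle(np.exp(1j * (psi - phi)))
        in_window = (s >= 0) & (s <= depth_px) & (np.abs(dpsi) <= half_wedge)
        legs.append(Spyderleg(
            cell=cell, pair_index=pair_index, leg_id=k, center=center,
            anchor=anchor, direction=direction, window_depth=config.window_depth,
            window_pixels=(ys[in_window], xs[in_window])))
    return legs


def centripetal_samples(flow: FlowField, leg: Spyderleg,
                        config: CouplingConfig) -> np.ndarray:
    """Retained centripetal speeds (µm/min) in the leg's window.

    A flow vector is retained iff it is faster than ``speed_threshold`` and
    its centripetal component (projection on the leg direction) is positive;
    the emitted sample is the centripetal component.
    """
    ys, xs = leg.window_pixels
    if len(ys) == 0:
        return np.empty(0)
    k = config.um_per_min_factor
    vx = flow.flow[ys, xs, 0] * k
    vy = flow.flow[ys, xs, 1] * k
    cent = vx * leg.direction[0] + vy * leg.direction[1]
    if config.threshold_on == "magnitude":
        fast = np.hypot(vx, vy) >= config.speed_threshold
    else:
        fast = cent >= config.speed_threshold
    return cent[fast & (cent > 0)]


def myosin_velocity(leg: Spyderleg, flows: list[FlowField],
                    config: CouplingConfig) -> tuple[float, int]:
    """Mean retained centripetal speed over the membrane interval.

    Returns (v_myo, n_samples); v_myo is NaN when no sample survives the
    filter (a "no-flow" outcome, excluded from aggregation downstream).
    """
    if not flows:
        raise ValueError("myosin_velocity needs at least one flow field")
    per_pair = [centripetal_samples(f, leg, config) for f in flows]
    n = int(sum(len(s) for s in per_pair))
    if n == 0:
        return float("nan"), 0
    if config.pool_samples:
        return float(np.concatenate(per_pair).mean()), n
    means = [s.mean() for s in per_pair if len(s)]
    return float(np.mean(means)), n


def membrane_velocity(mask_t0: np.ndarray, mask_t1: np.ndarray, leg: Spyderleg,
                      config: CouplingConfig) -> float | None:
    """Signed inward speed of the boundary crossing along the leg (µm/min).

    The same ray (center through anchor) is intersected with the boundary of
    the later mask; positive means the boundary moved toward the center.
    Returns None when the ray fails to cross the later boundary.
    """
    u_out = -leg.direction
    r0 = float(np.linalg.norm(leg.anchor - leg.center))
    r1 = _ray_crossing((mask_t1 > 0).astype(np.float64), leg.center, u_out)
    if r1 is None:
        return None
    return (r0 - r1) * config.pixel_size / config.membrane_dt_min


def slippage_records(masks: LabelMaskSeries, track: CentroidTrack,
                     flows: dict[int, FlowField], config: CouplingConfig, *,
                     msxx_birth_offset: float = 0.0, embryo_id: str = "embryo",
                     binning=None) -> list[SlippageRecord]:
    """One record per (cell, leg, membrane-frame-pair).

    Legs are rebuilt at every membrane frame pair from the earlier frame's
    mask and tracked center (boundaries shrink, so anchors must track the
    current boundary).  ``flows`` maps myosin frame-pair index j (frames
    j -> j+1) to its flow field; each membrane interval pools the myosin
    pairs it spans.  Records whose myosin or membrane measurement failed
    carry an explicit flag and NaN values.
    """
    from .stats import StageBinning, bin_stage

    if binning is None:
        binning = StageBinning()
    records: list[SlippageRecord] = []
    fidx = masks.frame_indices
    for cell, centers in track.centers.items():
        for i in range(len(masks) - 1):
            if i in masks.flagged or (i + 1) in masks.flagged:
                continue
            m0, m1 = int(fidx[i]), int(fidx[i + 1])
            mask0 = masks.masks[i] == track.labels[cell][i]
            mask1 = masks.masks[i + 1] == track.labels[cell][i + 1]
            pair_flows = [flows[j] for j in range(m0, m1) if j in flows]
            t_mid = msxx_birth_offset + 0.5 * (m0 + m1) * config.myosin_interval / 60.0
            stage = bin_stage(t_mid, binning)
            legs = build_spyderlegs(mask0, centers[i], config, cell=cell, pair_index=i)
            for leg in legs:
                v_myo, n = myosin_velocity(leg, pair_flows, config)
                v_mem = membrane_velocity(mask0, mask1, leg, config)
                flag = ""
                if n == 0:
                    flag = "no-flow"
                if v_mem is None:
                    flag = "no-membrane-crossing"
                    v_mem = float("nan")
                slip = v_myo - v_mem if flag == "" else float("nan")
                records.append(SlippageRecord(
                    embryo=embryo_id, cell=cell, leg=leg.leg_id, pair=i,
                    time_post_msxx=t_mid, v_myo=v_myo, v_mem=v_mem,
                    slippage=slip, n_flow_samples=n, stage=stage, flag=flag))
    return records


def records_to_frame(records: list[SlippageRecord]):
    """Tidy DataFrame, one row per record."""
    import pandas as pd

    return pd.DataFrame([{
        "embryo": r.embryo, "cell": r.cell, "leg": r.leg, "pair": r.pair,
        "time_post_msxx": r.time_post_msxx, "v_myo": r.v_myo, "v_mem": r.v_mem,
        "slippage": r.slippage, "n_flow_samples": r.n_flow_samples,
        "stage": r.stage, "flag": r.flag,
    } for r in records])
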