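"""Synthetic two-channel time-lapse generator with known ground truth.

Emulates the acquisition scheme used for coupling analysis: a punctate
myosin channel imaged every frame (interval ~5.7 s) and a membrane channel
imaged every ``membrane_stride``-th frame (~34.3 s at stride 6), each as a
short apical Z-stack (5 sections, 0.5 µm apart) with intensity falloff so
maximum projection is exercised.  The scene is a single apically
constricting cell: a closed circular membrane boundary contracting at a
configured speed while punctate myosin particles are advected centripetally
at a configured speed, conveyor-belt style (particles reaching the center
are respawned at the boundary).

Speeds may be piecewise-constant on the developmental clock (minutes post
MSxx birth) so one movie can span both the early and the late stage with
different membrane-contraction rates, mirroring the acceleration of inward
junction movement over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import TimeLapse

# Relative brightness of the 5 optical sections (apical surface first).
Z_WEIGHTS = np.array([1.0, 0.8, 0.55, 0.35, 0.2])
Z_STEP_UM = 0.5

MYOSIN_AMPLITUDE = 150.0
MEMBRANE_AMPLITUDE = 180.0
INTERIOR_HAZE = 25.0  # cytosolic pool of the membrane marker
BASELINE = 100.0  # camera offset

Rate = float | Sequence[tuple[float, float]]


def _as_schedule(rate: Rate, name: str) -> tuple[tuple[float, float], ...]:
    """Normalize a rate to ((t_min, value), ...) breakpoints on the MSxx clock."""
    if np.isscalar(rate):
        return ((-np.inf, float(rate)),)
    pts = tuple((float(t), float(v)) for t, v in rate)
    if not pts:
        raise ValueError(f"{name}: empty schedule")
    if any(pts[i][0] >= pts[i + 1][0] for i in range(len(pts) - 1)):
        raise ValueError(f"{name}: breakpoint times must be strictly increasing")
    return ((-np.inf, pts[0][1]),) + pts[1:]


def _rate_at(schedule: tuple[tuple[float, float], ...], t_min: float) -> float:
    value = schedule[0][1]
    for t0, v in schedule:
        if t_min >= t0:
            value = v
    return value


@dataclass
class SyntheticMovieSpec:
    """Parameters of a synthetic movie; defaults are the standard study
    conditions (pixel 0.1 µm, myosin every 5.7 s, membrane stride 6, myosin
    flow 1.8 µm/min, membrane contraction 0.3 µm/min early accelerating to
    1.0 µm/min from 13 min post MSxx birth)."""

    image_shape: tuple[int, int] = (256, 256)  # (H, W) pixels
    pixel_size: float = 0.1  # µm/px
    myosin_interval: float = 5.7  # s
    membrane_stride: int = 6
    n_myosin_frames: int = 43  # ~4 min
    v_myo_true: Rate = 1.8  # µm/min, centripetal
    v_mem_true: Rate = ((0.0, 0.3), (13.0, 1.0))  # µm/min, inward
    particle_density: float = 0.5  # particles/µm² of initial apical area
    particle_sigma: float = 0.15  # µm Gaussian spot width
    jitter_sigma: float = 0.03  # µm per frame, Brownian
    noise_model: str | tuple[str, float] = ("gaussian", 10.0)
    initial_radius: float = 10.0  # µm
    center: tuple[float, float] = (128.0, 128.0)  # (x, y) px
    msxx_birth_offset: float = 3.0  # min at frame 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size", "myosin_interval", "initial_radius", "particle_density",
                     "particle_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("jitter_sigma",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.membrane_stride < 1:
            raise ValueError(f"membrane_stride must be >= 1, got {self.membrane_stride}")
        if self.n_myosin_frames < 2:
            raise ValueError(f"n_myosin_frames must be >= 2, got {self.n_myosin_frames}")
        if any(s <= 0 for s in self.image_shape):
            raise ValueError(f"image_shape must be positive, got {self.image_shape}")
        self._v_myo = _as_schedule(self.v_myo_true, "v_myo_true")
        self._v_mem = _as_schedule(self.v_mem_true, "v_mem_true")
        if any(v < 0 for _, v in self._v_mem):
            raise ValueError("v_mem_true must be >= 0 (boundary radius non-increasing)")
        if self.radius_at_frame(self.n_myosin_frames - 1) <= 0.5:
            raise ValueError(
                "initial_radius too small for the movie duration: boundary would "
                "contract below 0.5 um before n_myosin_frames elapse")
        noise = self.noise_model
        if isinstance(noise, str):
            noise = (noise, 0.0)
        kind, param = noise
        if kind not in ("none", "gaussian", "poisson"):
            raise ValueError(f"noise_model kind must be none|gaussian|poisson, got {kind!r}")
        if kind != "none" and param <= 0:
            raise ValueError(f"noise_model parameter must be > 0, got {param}")
        self._noise = (kind, float(param))

    # -- ground-truth kinematics ------------------------------------------

    def minutes(self, frame: float) -> float:
        """Minutes post MSxx birth of a (possibly fractional) myosin frame."""
        return self.msxx_birth_offset + frame * self.myosin_interval / 60.0

    def v_myo_at(self, t_min: float) -> float:
        return _rate_at(self._v_myo, t_min)

    def v_mem_at(self, t_min: float) -> float:
        return _rate_at(self._v_mem, t_min)

    def radius_at_frame(self, frame: float) -> float:
        """Boundary radius (µm) at a myosin frame: initial radius minus the
        time-integral of the contraction speed since frame 0."""
        t0, t1 = self.minutes(0), self.minutes(frame)
        shrink = 0.0
        # integrate the piecewise-constant schedule
        knots = [t for t, _ in self._v_mem if t0 < t < t1]
        edges = [t0] + knots + [t1]
        for a, b in zip(edges[:-1], edges[1:]):
            shrink += self.v_mem_at(0.5 * (a + b)) * (b - a)
        return self.initial_radius - shrink

    @property
    def membrane_frames(self) -> np.ndarray:
        return np.arange(0, self.n_myosin_frames, self.membrane_stride)

    @property
    def n_particles(self) -> int:
        return int(round(self.particle_density * np.pi * self.initial_radius**2))


@dataclass
class GroundTruth:
    """Oracle container: true particle positions, boundary geometry, and the
    expected per-stage velocities implied by the movie spec."""

    spec: SyntheticMovieSpec
    particle_positions: np.ndarray  # (T, N, 2) µm, columns (x, y)
    boundary_radius: np.ndarray  # µm, per membrane frame

    @property
    def center_um(self) -> np.ndarray:
        return np.asarray(self.spec.center, dtype=float) * self.spec.pixel_size

    def mask(self, membrane_index: int) -> np.ndarray:
        """True binary cell mask (H, W) at a membrane frame."""
        h, w = self.spec.image_shape
        yy, xx = np.mgrid[0:h, 0:w]
        cx, cy = self.spec.center
        r_px = self.boundary_radius[membrane_index] / self.spec.pixel_size
        return (np.hypot(xx - cx, yy - cy) <= r_px)

    def expected_slippage_at(self, t_min: float) -> float:
        return self.spec.v_myo_at(t_min) - self.spec.v_mem_at(t_min)


def _render_spots(shape: tuple[int, int], pos_px: np.ndarray, sigma_px: float,
                  amplitude: float) -> np.ndarray:
    """Sum of Gaussian spots at subpixel positions, rendered on local patches."""
    h, w = shape
    img = np.zeros((h, w), dtype=np.float64)
    half = max(2, int(np.ceil(4 * sigma_px)))
    for x, y in pos_px:
        ix, iy = int(round(x)), int(round(y))
        x0, x1 = max(ix - half, 0), min(ix + half + 1, w)
        y0, y1 = max(iy - half, 0), min(iy + half + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        gx = np.exp(-0.5 * ((np.arange(x0, x1) - x) / sigma_px) ** 2)
        gy = np.exp(-0.5 * ((np.arange(y0, y1) - y) / sigma_px) ** 2)
        img[y0:y1, x0:x1] += amplitude * np.outer(gy, gx)
    return img


def _render_membrane(shape: tuple[int, int], center: tuple[float, float],
                     r_px: float, thickness_px: float = 3.0) -> np.ndarray:
    """Anti-aliased bright ring at radius r_px plus a dim interior haze."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    rho = np.hypot(xx - center[0], yy - center[1])
    ring = np.clip(thickness_px / 2.0 + 0.5 - np.abs(rho - r_px), 0.0, 1.0)
    interior = np.clip(r_px - rho + 0.5, 0.0, 1.0)
    return MEMBRANE_AMPLITUDE * ring + INTERIOR_HAZE * interior


def _apply_noise(img: np.ndarray, noise: tuple[str, float],
                 rng: np.random.Generator) -> np.ndarray:
    kind, param = noise
    if kind == "gaussian":
        img = img + rng.normal(0.0, param, size=img.shape)
    elif kind == "poisson":
        img = rng.poisson(np.clip(img, 0, None) * param).astype(np.float64) / param
    return img


def generate_movie(spec: SyntheticMovieSpec) -> tuple[TimeLapse, GroundTruth]:
    """Render the synthetic movie and its ground truth.

    The myosin channel contains ``spec.n_particles`` Gaussian spots advected
    toward the center at ``v_myo_true`` with Brownian jitter; particles
    within one spot-width of the center, or left outside the contracting
    boundary, are respawned on the boundary at a uniformly random angle so
    the particle count stays exact.  The membrane channel renders the
    contracting boundary as an anti-aliased ring on membrane frames only.
    Output is bit-identical for identical spec + seed.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    px = spec.pixel_size
    center_um = np.asarray(spec.center, dtype=float) * px
    n = spec.n_particles
    dt_min = spec.myosin_interval / 60.0

    # initial particle positions: uniform over the initial disk
    theta = rng.uniform(0, 2 * np.pi, n)
    rad = spec.initial_radius * np.sqrt(rng.uniform(0, 1, n))
    pos = center_um + np.column_stack([rad * np.cos(theta), rad * np.sin(theta)])

    positions = np.empty((spec.n_myosin_frames, n, 2))
    myosin = np.empty((spec.n_myosin_frames, len(Z_WEIGHTS), h, w), dtype=np.uint16)
    mem_frames = spec.membrane_frames
    membrane = np.empty((len(mem_frames), len(Z_WEIGHTS), h, w), dtype=np.uint16)
    radii = np.empty(len(mem_frames))

    sigma_px = spec.particle_sigma / px
    mem_i = 0
    for k in range(spec.n_myosin_frames):
        positions[k] = pos
        pos_px = pos / px
        spots = _render_spots((h, w), pos_px, sigma_px, MYOSIN_AMPLITUDE)
        for z, wz in enumerate(Z_WEIGHTS):
            frame = _apply_noise(spots * wz + BASELINE, spec._noise, rng)
            myosin[k, z] = np.clip(frame, 0, 65535).round().astype(np.uint16)

        if k in mem_frames:
            r_um = spec.radius_at_frame(k)
            radii[mem_i] = r_um
            ring = _render_membrane((h, w), spec.center, r_um / px)
            for z, wz in enumerate(Z_WEIGHTS):
                frame = _apply_noise(ring * wz + BASELINE, spec._noise, rng)
                membrane[mem_i, z] = np.clip(frame, 0, 65535).round().astype(np.uint16)
            mem_i += 1

        # advect to frame k+1
        t_mid = spec.minutes(k + 0.5)
        step = spec.v_myo_at(t_mid) * dt_min
        delta = center_um - pos
        dist = np.linalg.norm(delta, axis=1)
        safe = np.maximum(dist, 1e-9)
        pos = pos + delta / safe[:, None] * np.minimum(step, dist)[:, None]
        if spec.jitter_sigma > 0:
            pos = pos + rng.normal(0.0, spec.jitter_sigma, size=pos.shape)
        # respawn: reached center, or left behind by the contracting boundary
        r_next = spec.radius_at_frame(k + 1)
        dist = np.linalg.norm(center_um - pos, axis=1)
        respawn = (dist < spec.particle_sigma) | (dist > r_next)
        n_re = int(respawn.sum())
        if n_re:
            ang = rng.uniform(0, 2 * np.pi, n_re)
            rr = r_next - spec.particle_sigma
            pos[respawn] = center_um + rr * np.column_stack([np.cos(ang), np.sin(ang)])

    movie = TimeLapse(
        myosin=myosin,
        membrane=membrane,
        membrane_frames=mem_frames,
        pixel_size=px,
        myosin_interval=spec.myosin_interval,
        membrane_stride=spec.membrane_stride,
        z_step=Z_STEP_UM,
        msxx_birth_offset=spec.msxx_birth_offset,
        embryo_id=f"sim-{spec.seed}",
    )
    truth = GroundTruth(spec=spec, particle_positions=positions, boundary_radius=radii)
    return movie, truth


def ground_truth_records(spec: SyntheticMovieSpec, legs_per_cell: int = 36,
                         binning=None) -> list[dict]:
    """Expected slippage records: one per (leg, membrane-frame-pair).

    Each record carries the true myosin and membrane speeds at the pair's
    midpoint time and their difference (the expected slippage), plus the
    stage bin on the MSxx clock.
    """
    from .stats import StageBinning, bin_stage

    if binning is None:
        binning = StageBinning()
    mem_frames = spec.membrane_frames
    out = []
    for i in range(len(mem_frames) - 1):
        t_mid = spec.minutes(0.5 * (mem_frames[i] + mem_frames[i + 1]))
        v_myo = spec.v_myo_at(t_mid)
        v_mem = spec.v_mem_at(t_mid)
        for leg in range(legs_per_cell):
            out.append({
                "embryo": f"sim-{spec.seed}",
                "cell": 1,
                "leg": leg,
                "pair": i,
                "time_post_msxx": t_mid,
                "v_myo": v_myo,
                "v_mem": v_mem,
                "slippage": v_myo - v_mem,
                "stage": bin_stage(t_mid, binning),
            })
    return out
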