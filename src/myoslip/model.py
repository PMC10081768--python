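"""Core in-memory containers shared by the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TimeLapse:
    """A two-channel 4D fluorescence time-lapse plus acquisition metadata.

    The myosin channel is acquired every frame; the membrane channel only on
    every ``membrane_stride``-th myosin frame (the 1st, 7th, ... frame scheme
    of a stride of 6).  Both channels are stored as (T, Z, H, W) stacks; the
    membrane stack has one plane-set per membrane acquisition and
    ``membrane_frames`` records which myosin frame index each corresponds to.

    Attributes
    ----------
    myosin : np.ndarray
        (T, Z, H, W) myosin-channel stack.
    membrane : np.ndarray
        (Tm, Z, H, W) membrane-channel stack.
    membrane_frames : np.ndarray
        Myosin-frame indices at which the membrane was imaged (length Tm).
    pixel_size : float
        Lateral pixel size in µm/px.
    myosin_interval : float
        Time between consecutive myosin frames in seconds.
    membrane_stride : int
        Myosin frames per membrane frame.
    z_step : float
        Axial step between optical sections in µm.
    msxx_birth_offset : float
        Minutes post MSxx birth at myosin frame 0; maps frame index to the
        developmental clock used for early/late staging.
    embryo_id : str
        Replicate identifier carried through to slippage records.
    """

    myosin: np.ndarray
    membrane: np.ndarray
    membrane_frames: np.ndarray
    pixel_size: float
    myosin_interval: float
    membrane_stride: int
    z_step: float = 0.5
    msxx_birth_offset: float = 0.0
    embryo_id: str = "embryo"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.myosin_interval <= 0:
            raise ValueError(f"myosin_interval must be > 0, got {self.myosin_interval}")
        if self.membrane_stride < 1:
            raise ValueError(f"membrane_stride must be >= 1, got {self.membrane_stride}")
        self.membrane_frames = np.asarray(self.membrane_frames, dtype=int)
        if self.membrane.shape[0] != len(self.membrane_frames):
            raise ValueError("membrane stack and membrane_frames length differ")

    @property
    def n_frames(self) -> int:
        return int(self.myosin.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        """Image shape (H, W)."""
        return tuple(self.myosin.shape[-2:])

    def minutes_post_msxx(self, frame: int | np.ndarray) -> float | np.ndarray:
        """Developmental time (minutes post MSxx birth) of a myosin frame."""
        return self.msxx_birth_offset + np.asarray(frame) * self.myosin_interval / 60.0

    @property
    def um_per_min_factor(self) -> float:
        """Conversion factor from px/frame to µm/min."""
        return self.pixel_size * 60.0 / self.myosin_interval
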