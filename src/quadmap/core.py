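"""Core in-memory containers shared by the simulator and every analysis stage.

Conventions used throughout the package: grids are 0-based, row-major
``(row, col)``; distances are millimetres; within-burst trace times are
milliseconds; acquisition-clock times (FRET frames, burst starts) are seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError


@dataclass
class FrameStack:
    """One channel's movie: a (T, H, W) intensity array with timestamps.

    Parameters
    ----------
    values :
        Intensity grid per frame, shape ``(T, H, W)``.
    times :
        Acquisition time of each frame in seconds, strictly increasing.
    pixel_pitch_mm :
        Physical size of one pixel (mm/pixel).
    """

    values: np.ndarray
    times: np.ndarray
    pixel_pitch_mm: float = 0.1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 3:
            raise ConfigurationError(
                f"FrameStack values must be (T, H, W); got shape {self.values.shape}"
            )
        if self.times.shape != (self.values.shape[0],):
            raise ConfigurationError(
                "FrameStack times must have one entry per frame "
                f"({self.values.shape[0]}); got {self.times.shape}"
            )
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ConfigurationError("FrameStack times must be strictly increasing")
        if self.pixel_pitch_mm <= 0:
            raise ConfigurationError("pixel_pitch_mm must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]

    @property
    def sample_interval_ms(self) -> float:
        """Median inter-frame interval in milliseconds."""
        if self.n_frames < 2:
            raise ConfigurationError("need at least two frames for an interval")
        return float(np.median(np.diff(self.times)) * 1000.0)


@dataclass
class FretRecording:
    """Paired CFP/YFP movies of one heart plus the epicardial mask."""

    cfp: FrameStack
    yfp: FrameStack
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.cfp.values.shape != self.yfp.values.shape:
            raise ConfigurationError("CFP and YFP stacks must share shape")
        if not np.allclose(self.cfp.times, self.yfp.times):
            raise ConfigurationError("CFP and YFP stacks must share timestamps")
        if self.mask.shape != self.cfp.frame_shape:
            raise ConfigurationError("mask shape must match frame shape")
        if not self.mask.any():
            raise ConfigurationError("mask is empty")


@dataclass
class GroundTruth:
    """Simulator oracle: the per-pixel truths every analysis stage must recover.

    ``activation_time`` is ms within a beat (0 at the focal source);
    ``apd80_true`` / ``catd50_true`` are (n_bursts, H, W) in ms;
    ``delta_fret_true`` maps region name (or ``"default"``) to the ΔFRET time
    series sampled at the FRET frame times; ``heart_rate_true`` is bpm per burst.
    """

    activation_time: np.ndarray
    apd80_true: np.ndarray
    catd50_true: np.ndarray
    delta_fret_true: dict = field(default_factory=dict)
    heart_rate_true: np.ndarray = None
    fret_times: np.ndarray = None
    burst_times: np.ndarray = None
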