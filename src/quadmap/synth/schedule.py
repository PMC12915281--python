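"""Interleaved acquisition schedule: slow FRET frames with high-rate bursts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import instrument
from ..errors import ConfigurationError


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Timing of interleaved FRET frames and Vm/Ca bursts.

    A CFP/YFP frame is exposed every ``fret_period`` seconds for
    ``fret_exposure`` seconds; ``burst_offset`` seconds after each FRET frame
    start, both high-speed cameras record for ``burst_duration`` seconds at
    ``burst_rate`` samples/s. All times are seconds on the acquisition clock.
    """

    fret_period: float = instrument.FRET_PERIOD_S
    fret_exposure: float = instrument.FRET_EXPOSURE_S
    burst_rate: float = instrument.BURST_RATE_HZ
    burst_duration: float = instrument.BURST_DURATION_S
    total_duration: float = 120.0
    burst_offset: float = instrument.FRET_EXPOSURE_S

    def __post_init__(self) -> None:
        for name in ("fret_period", "fret_exposure", "burst_rate",
                     "burst_duration", "total_duration", "burst_offset"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.fret_exposure + self.burst_offset + self.burst_duration > self.fret_period:
            raise ConfigurationError(
                "fret_exposure + burst_offset + burst_duration must fit within fret_period"
            )
        if self.total_duration < self.fret_period:
            raise ConfigurationError("total_duration must cover at least one fret_period")

    @property
    def fret_times(self) -> np.ndarray:
        """FRET frame start times (s), including t = 0."""
        n = int(np.floor(self.total_duration / self.fret_period + 1e-9)) + 1
        return np.arange(n) * self.fret_period

    @property
    def burst_starts(self) -> np.ndarray:
        """Burst start times (s), one burst after every FRET frame."""
        return self.fret_times + self.burst_offset

    @property
    def n_slots(self) -> int:
        return len(self.fret_times)

    @property
    def burst_samples(self) -> int:
        return int(round(self.burst_rate * self.burst_duration))

    @property
    def sample_interval_ms(self) -> float:
        return 1000.0 / self.burst_rate
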