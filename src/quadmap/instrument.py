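"""Reference instrument geometry and timing.

Constants describing the tandem-lens macroscope configuration the package
models: a high-resolution sCMOS camera behind an image splitter for the
CFP/YFP FRET pair, and two high-speed CMOS cameras for the voltage- and
calcium-sensitive dyes. Pixel pitches follow from each camera's field of
view divided by its sensor resolution.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CameraSpec:
    """Sensor resolution and field of view of one detection path."""

    name: str
    rows: int
    cols: int
    fov_mm: tuple[float, float]  # (height, width) of the imaged field

    @property
    def pixel_pitch_mm(self) -> tuple[float, float]:
        """(row, col) pixel pitch in mm/pixel."""
        return self.fov_mm[0] / self.rows, self.fov_mm[1] / self.cols

    @property
    def pixel_pitch_um(self) -> float:
        """Row-direction pixel pitch in micrometres per pixel."""
        return self.pixel_pitch_mm[0] * 1000.0


#: sCMOS FRET camera: 1024 x 2048 px covering 7.24 mm x 14.5 mm (~7 um/px).
FRET_CAMERA = CameraSpec("fret_scmos", rows=1024, cols=2048, fov_mm=(7.24, 14.5))

#: High-speed CMOS mapping cameras: 100 x 100 px covering 10 mm x 10 mm (100 um/px).
MAPPING_CAMERA = CameraSpec("mapping_cmos", rows=100, cols=100, fov_mm=(10.0, 10.0))

#: Interleaved acquisition timing: one 100 ms CFP/YFP exposure every 10 s,
#: each immediately followed by a 2 s Vm/Ca burst sampled at 1 kHz.
FRET_PERIOD_S = 10.0
FRET_EXPOSURE_S = 0.1
BURST_RATE_HZ = 1000.0
BURST_DURATION_S = 2.0
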