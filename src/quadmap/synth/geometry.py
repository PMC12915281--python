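"""Synthetic heart geometry: mask, labelled regions, and the focal source.

Two presets mirror the two imaging views used for whole-heart work:
``ventricle_anterior`` (anterior view with RV-base / LV-apex / LA regions,
focal breakthrough near the base) and ``atria_posterior`` (posterior atrial
view with LA / RA regions and a sinoatrial-node patch in the intercaval
area that hosts the earliest activation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigurationError

PRESETS = ("ventricle_anterior", "atria_posterior")


@dataclass
class HeartGeometry:
    """Binary epicardial mask with labelled regions and wavefront parameters."""

    mask: np.ndarray
    region_labels: dict[str, np.ndarray] = field(default_factory=dict)
    focal_source: tuple[int, int] = (0, 0)
    conduction_velocity: float = 0.35  # mm/ms
    pixel_pitch: float = 0.1  # mm/pixel

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.conduction_velocity <= 0:
            raise ConfigurationError("conduction_velocity must be positive")
        if not self.mask[self.focal_source]:
            raise ConfigurationError("focal_source must lie inside the mask")
        covered = np.zeros_like(self.mask)
        for name, region in self.region_labels.items():
            region = np.asarray(region, dtype=bool)
            if (region & ~self.mask).any():
                raise ConfigurationError(f"region {name!r} extends outside the mask")
            if (region & covered).any():
                raise ConfigurationError(f"region {name!r} overlaps another region")
            covered |= region
            self.region_labels[name] = region

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def activation_delay_ms(self) -> np.ndarray:
        """Ground-truth activation delay (ms) from the focal source.

        Euclidean distance is used; the preset masks are convex (elliptical),
        where Euclidean and geodesic-in-mask distances coincide.
        """
        rr, cc = np.indices(self.shape)
        d_px = np.hypot(rr - self.focal_source[0], cc - self.focal_source[1])
        delay = d_px * self.pixel_pitch / self.conduction_velocity
        delay[~self.mask] = np.nan
        return delay


def _ellipse(shape, center, semi_axes) -> np.ndarray:
    rr, cc = np.indices(shape)
    return ((rr - center[0]) / semi_axes[0]) ** 2 + (
        (cc - center[1]) / semi_axes[1]
    ) ** 2 <= 1.0


def _disk(shape, center, radius) -> np.ndarray:
    rr, cc = np.indices(shape)
    return np.hypot(rr - center[0], cc - center[1]) <= radius


def build_geometry(
    rows: int,
    cols: int,
    preset: str,
    conduction_velocity: float = 0.35,
    pixel_pitch: float = 0.1,
) -> HeartGeometry:
    """Construct a preset heart geometry on a ``rows x cols`` grid.

    Raises
    ------
    ConfigurationError
        For unknown presets or grids smaller than 32 x 32.
    """
    if preset not in PRESETS:
        raise ConfigurationError(f"unknown preset {preset!r}; choose from {PRESETS}")
    if rows < 32 or cols < 32:
        raise ConfigurationError("grid must be at least 32 x 32")

    shape = (rows, cols)
    cr, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
    mask = _ellipse(shape, (cr, cc), (0.44 * rows, 0.38 * cols))
    r_small = max(2.0, 0.08 * min(rows, cols))

    if preset == "ventricle_anterior":
        # Anterior whole-heart view: atria at the top, ventricular apex at the
        # bottom. Focal breakthrough near the base (earliest epicardial site).
        regions = {
            "RV base": _disk(shape, (0.30 * rows, 0.34 * cols), 1.5 * r_small) & mask,
            "LV apex": _disk(shape, (0.78 * rows, 0.56 * cols), 1.5 * r_small) & mask,
            "LA": _disk(shape, (0.16 * rows, 0.62 * cols), r_small) & mask,
        }
        focal = (int(round(0.30 * rows)), int(round(0.50 * cols)))
    else:  # atria_posterior
        # Posterior atrial view: the SAN patch sits between the caval veins
        # (intercaval region, right-superior area) and is the focal source.
        san_center = (int(round(0.30 * rows)), int(round(0.62 * cols)))
        regions = {
            "SAN": _disk(shape, san_center, r_small) & mask,
            "LA": _disk(shape, (0.55 * rows, 0.30 * cols), 1.5 * r_small) & mask,
            "RA": _disk(shape, (0.55 * rows, 0.72 * cols), 1.5 * r_small) & mask,
        }
        focal = san_center

    for name, region in regions.items():
        if not region.any():
            raise ConfigurationError(f"preset region {name!r} is empty on this grid")

    return HeartGeometry(
        mask=mask,
        region_labels=regions,
        focal_source=focal,
        conduction_velocity=conduction_velocity,
        pixel_pitch=pixel_pitch,
    )
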