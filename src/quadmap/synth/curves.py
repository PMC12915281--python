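"""Pharmacological response curves driving the simulated physiology.

A :class:`ResponseCurve` is a piecewise-linear time course of one modulated
quantity. ``delta_fret`` curves are the true cAMP readout ΔFRET = R/R0;
``apd_scale`` / ``catd_scale`` / ``rate_scale`` multiply the baseline APD80,
CaTD50, and heart rate. Presets encode the stated drug responses:

* ``ne`` — norepinephrine bolus: ΔFRET rises to its peak at 40 s and returns
  to baseline by 120 s; APD is biphasic (prolonged to a maximum at ~40 s,
  back near baseline by ~60 s); CaTD decreases monotonically; heart rate
  rises alongside cAMP (300 → 500 bpm by default).
* ``tyramine`` — nerve-released norepinephrine: same kinetics with the
  strongest cAMP response in the left atrium.
* ``ach`` — acetylcholine: reversible ΔFRET reduction (values ≤ 1), mild
  rate slowing, durations unchanged.

Peak amplitudes (e.g. ΔFRET 1.2) are simulator defaults, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigurationError

APPLIES_TO = ("delta_fret", "apd_scale", "catd_scale", "rate_scale")

#: Key in a curve-set dict that covers mask pixels outside any labelled region
#: (and any labelled region without its own entry).
DEFAULT_REGION = "default"


@dataclass(frozen=True)
class ResponseCurve:
    """Piecewise-linear time course of one simulated quantity.

    ``knots`` are (time_s, value) pairs with strictly increasing times;
    evaluation clamps to the end values outside the knot range and returns
    ``baseline_value`` for times at or before the first knot.
    """

    knots: tuple
    applies_to: str
    baseline_value: float = 1.0

    def __post_init__(self) -> None:
        if self.applies_to not in APPLIES_TO:
            raise ConfigurationError(
                f"applies_to must be one of {APPLIES_TO}, got {self.applies_to!r}"
            )
        knots = tuple((float(t), float(v)) for t, v in self.knots)
        if len(knots) < 1:
            raise ConfigurationError("a ResponseCurve needs at least one knot")
        times = [t for t, _ in knots]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ConfigurationError("knot times must be strictly increasing")
        if times[0] < 0:
            raise ConfigurationError("knot times must be non-negative")
        if self.applies_to == "delta_fret" and knots[0][1] != 1.0:
            raise ConfigurationError("delta_fret curves must start at exactly 1.0")
        object.__setattr__(self, "knots", knots)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        times = np.array([k[0] for k in self.knots])
        values = np.array([k[1] for k in self.knots])
        out = np.interp(t, times, values)
        out = np.where(t <= times[0], self.baseline_value if len(times) == 1 else values[0], out)
        return out if out.ndim else float(out)


def camp_response(t, curve: ResponseCurve):
    """True ΔFRET at time ``t`` (s) for a ``delta_fret`` response curve."""
    if curve.applies_to != "delta_fret":
        raise ConfigurationError("camp_response requires a delta_fret curve")
    return curve(t)


def _df(knots):
    return ResponseCurve(knots=knots, applies_to="delta_fret")


def _scale(applies_to, knots):
    return ResponseCurve(knots=knots, applies_to=applies_to)


#: CurveSet type: {region name or "default": {applies_to: ResponseCurve}}.
CurveSet = dict


def preset_curves(name: str) -> CurveSet:
    """Return the per-region response-curve set for a drug preset."""
    flat = ((0.0, 1.0),)
    if name == "ne":
        return {
            DEFAULT_REGION: {
                "delta_fret": _df(((0.0, 1.0), (40.0, 1.2), (120.0, 1.0))),
                "apd_scale": _scale("apd_scale", ((0.0, 1.0), (40.0, 1.15), (60.0, 1.0))),
                "catd_scale": _scale("catd_scale", ((0.0, 1.0), (60.0, 0.85))),
                "rate_scale": _scale("rate_scale", ((0.0, 1.0), (40.0, 5.0 / 3.0), (120.0, 1.0))),
            },
            "LA": {"delta_fret": _df(((0.0, 1.0), (40.0, 1.1), (120.0, 1.0)))},
        }
    if name == "tyramine":
        return {
            DEFAULT_REGION: {
                "delta_fret": _df(((0.0, 1.0), (40.0, 1.12), (120.0, 1.0))),
                "apd_scale": _scale("apd_scale", ((0.0, 1.0), (40.0, 1.15), (60.0, 1.0))),
                "catd_scale": _scale("catd_scale", ((0.0, 1.0), (60.0, 0.85))),
                "rate_scale": _scale("rate_scale", ((0.0, 1.0), (40.0, 5.0 / 3.0), (120.0, 1.0))),
            },
            "LA": {"delta_fret": _df(((0.0, 1.0), (40.0, 1.25), (120.0, 1.0)))},
        }
    if name == "ach":
        return {
            DEFAULT_REGION: {
                "delta_fret": _df(((0.0, 1.0), (20.0, 0.9), (40.0, 0.9), (120.0, 1.0))),
                "apd_scale": _scale("apd_scale", flat),
                "catd_scale": _scale("catd_scale", flat),
                "rate_scale": _scale("rate_scale", ((0.0, 1.0), (20.0, 0.85), (120.0, 1.0))),
            },
        }
    raise ConfigurationError(f"unknown preset {name!r}; choose ne, tyramine, or ach")
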