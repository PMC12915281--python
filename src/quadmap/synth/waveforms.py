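"""Analytic action-potential and calcium-transient templates.

Both templates are linear-rise / exponential-shoulder pulses normalised to
[0, 1] and calibrated so the field's duration definitions hold exactly by
construction: measured from the upstroke's maximum-derivative time (the
onset, since the rise is linear), the action potential crosses 20% of its
amplitude exactly ``apd80`` ms later, and the calcium transient crosses 50%
exactly ``catd50`` ms later. Past a knee the decay is blended linearly to
zero so the diastolic baseline is exactly 0 before the next beat.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError

_LN5 = np.log(5.0)
_LN2 = np.log(2.0)


def _template(t_rel, rise_ms, tau_ms, knee_ms, zero_ms):
    """Piecewise pulse: linear rise, exponential decay, linear tail to zero."""
    t = np.asarray(t_rel, dtype=float)
    rise = np.asarray(rise_ms, dtype=float)
    tau = np.asarray(tau_ms, dtype=float)
    knee = np.asarray(knee_ms, dtype=float)
    zero = np.asarray(zero_ms, dtype=float)

    knee_v = np.exp(-(knee - rise) / tau)
    out = np.zeros(np.broadcast(t, rise, tau, knee, zero).shape)
    rising = (t >= 0) & (t < rise)
    decaying = (t >= rise) & (t <= knee)
    tail = (t > knee) & (t < zero)

    out = np.where(rising, t / rise, out)
    out = np.where(decaying, np.exp(-(t - rise) / tau), out)
    out = np.where(tail, knee_v * (zero - t) / (zero - knee), out)
    return out if out.ndim else float(out)


def _check(apd_like: float, rise: float, what: str) -> None:
    a = np.asarray(apd_like, dtype=float)
    r = np.asarray(rise, dtype=float)
    if np.any(a <= 0) or np.any(r <= 0):
        raise ConfigurationError(f"{what}: durations must be positive")
    if np.any(r >= a):
        raise ConfigurationError(f"{what}: upstroke/rise must be shorter than the duration")


def ap_waveform(t_rel, apd80, upstroke_ms=2.0):
    """Normalised action-potential deflection at ``t_rel`` ms after onset.

    The decay time constant is ``(apd80 - upstroke_ms) / ln 5``, so the value
    crosses 0.2 (80% repolarisation of the unit amplitude) exactly ``apd80``
    ms after the maximum-derivative time. All arguments broadcast.
    """
    _check(apd80, upstroke_ms, "ap_waveform")
    apd80 = np.asarray(apd80, dtype=float)
    up = np.asarray(upstroke_ms, dtype=float)
    tau = (apd80 - up) / _LN5
    return _template(t_rel, up, tau, apd80, apd80 + 0.4 * (apd80 - up))


def ca_waveform(t_rel, catd50, rise_ms=5.0):
    """Normalised calcium-transient deflection at ``t_rel`` ms after onset.

    The decay time constant is ``(catd50 - rise_ms) / ln 2``, so the value
    crosses 0.5 exactly ``catd50`` ms after the maximum-derivative time; the
    knee to the linear tail sits below the 0.5 crossing.
    """
    _check(catd50, rise_ms, "ca_waveform")
    catd50 = np.asarray(catd50, dtype=float)
    rise = np.asarray(rise_ms, dtype=float)
    tau = (catd50 - rise) / _LN2
    knee = rise + 1.5 * (catd50 - rise)
    zero = rise + 2.2 * (catd50 - rise)
    return _template(t_rel, rise, tau, knee, zero)
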