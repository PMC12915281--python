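"""Render synthetic quad-channel recordings with exact ground truth.

The renderer turns a heart geometry, an acquisition schedule, and a set of
per-region response curves into what the instrument would record: CFP/YFP
frame pairs every ``fret_period`` seconds and a high-rate Vm/Ca burst after
each frame, with channel gain, vignetting, spectral bleed-through, and
additive Gaussian noise applied. Every quantity the analysis stages estimate
(activation time, APD80, CaTD50, ΔFRET, heart rate) is returned exactly in a
:class:`~quadmap.core.GroundTruth`.

The CFP/YFP transduction is ``CFP = gain * ΔF^a`` and ``YFP = gain * ΔF^(-b)``
(ΔF the true ΔFRET), so the donor rises and the acceptor falls as cAMP rises
and, when ``a + b = 1``, the pixel ratio CFP/YFP normalised to baseline
reproduces ΔF exactly — the property the ratiometric oracle tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core import FrameStack, FretRecording, GroundTruth
from ..errors import ConfigurationError
from .curves import DEFAULT_REGION, ResponseCurve, camp_response
from .geometry import HeartGeometry
from .schedule import AcquisitionSchedule
from .waveforms import ap_waveform, ca_waveform

#: Onset of the first beat within each burst, ms after burst start.
FIRST_BEAT_MS = 40.0

#: Default regional baseline durations (ms); regions absent from a geometry
#: are ignored, mask pixels outside any labelled region use "default".
DEFAULT_APD80 = {"default": 50.0, "RV base": 55.0, "LV apex": 45.0}
DEFAULT_CATD50 = {"default": 40.0, "RV base": 45.0, "LV apex": 35.0}


@dataclass
class ChannelModel:
    """Detection-chain model shared by the four channels.

    ``bleedthrough`` is a 2x2 mixing matrix over the high-speed channels,
    rows = detected (Vm, Ca), cols = source; the diagonal must be 1 and
    off-diagonal fractions lie in [0, 0.5]. ``vm_polarity`` is the sign of
    the voltage-dye deflection on depolarisation (RH237-like dyes darken,
    hence -1 by default). ``cfp_response``/``yfp_response`` are the
    transduction exponents a and b described in the module docstring.
    ``vm_dye`` / ``ca_dye`` model which exogenous dyes are loaded.
    """

    gain: float = 1000.0
    offset: float = 0.0
    noise_sd: float = 0.0
    bleedthrough: np.ndarray = field(default_factory=lambda: np.eye(2))
    vignette_strength: float = 0.0
    vm_polarity: int = -1
    cfp_response: float = 0.5
    yfp_response: float = 0.5
    vm_dye: bool = True
    ca_dye: bool = True

    def __post_init__(self) -> None:
        self.bleedthrough = np.asarray(self.bleedthrough, dtype=float)
        if self.bleedthrough.shape != (2, 2):
            raise ConfigurationError("bleedthrough must be a 2x2 matrix (Vm, Ca)")
        if not np.allclose(np.diag(self.bleedthrough), 1.0):
            raise ConfigurationError("bleedthrough diagonal must be 1")
        off = self.bleedthrough[~np.eye(2, dtype=bool)]
        if np.any(off < 0) or np.any(off > 0.5):
            raise ConfigurationError("off-diagonal bleedthrough must be in [0, 0.5]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0.0 <= self.vignette_strength <= 1.0:
            raise ConfigurationError("vignette_strength must be in [0, 1]")
        if self.vm_polarity not in (-1, 1):
            raise ConfigurationError("vm_polarity must be +1 or -1")
        if self.cfp_response <= 0 or self.yfp_response <= 0:
            raise ConfigurationError("transduction constants must be positive")
        if self.gain <= 0:
            raise ConfigurationError("gain must be positive")


def _lookup_curve(curves, region: str, applies_to: str) -> ResponseCurve | None:
    for key in (region, DEFAULT_REGION):
        entry = curves.get(key, {})
        if applies_to in entry:
            return entry[applies_to]
    return None


def _region_map(geometry: HeartGeometry) -> dict[str, np.ndarray]:
    """Mask pixels per region plus the uncovered remainder under "default"."""
    out = {}
    covered = np.zeros_like(geometry.mask)
    for name, region in geometry.region_labels.items():
        out[name] = region
        covered |= region
    rest = geometry.mask & ~covered
    if rest.any():
        out[DEFAULT_REGION] = rest
    return out


def _base_duration_map(geometry: HeartGeometry, defaults: dict, overrides) -> np.ndarray:
    table = dict(defaults)
    if overrides:
        table.update(overrides)
    out = np.full(geometry.shape, float(table["default"]))
    for name, region in geometry.region_labels.items():
        out[region] = float(table.get(name, table["default"]))
    out[~geometry.mask] = np.nan
    return out


def vignette_map(geometry: HeartGeometry, strength: float) -> np.ndarray:
    """Radial cosine falloff: 1 at the mask centroid, 1 - strength at its edge."""
    if strength == 0:
        return np.ones(geometry.shape)
    rr, cc = np.indices(geometry.shape)
    r0 = rr[geometry.mask].mean()
    c0 = cc[geometry.mask].mean()
    d = np.hypot(rr - r0, cc - c0)
    dmax = d[geometry.mask].max()
    return (1.0 - strength) + strength * np.cos(0.5 * np.pi * np.clip(d / dmax, 0, 1))


def render_recording(
    geometry: HeartGeometry,
    schedule: AcquisitionSchedule,
    curves: dict,
    channels: ChannelModel | None = None,
    seed: int = 0,
    base_apd80: dict | None = None,
    base_catd50: dict | None = None,
    base_rate_bpm: float = 300.0,
    stimulus_onset_s: float = 0.0,
    upstroke_ms: float = 2.0,
    ca_rise_ms: float = 5.0,
    motion_jitter: bool = False,
):
    """Simulate one interleaved acquisition.

    Returns
    -------
    (FretRecording, list[(FrameStack, FrameStack)], GroundTruth)
        The CFP/YFP recording, the (Vm, Ca) stack pair for each burst, and
        the ground truth for every recovered quantity.

    Raises
    ------
    ConfigurationError
        If any labelled region (or uncovered mask area) lacks a
        ``delta_fret`` response curve.
    """
    channels = channels or ChannelModel()
    rng = np.random.default_rng(seed)
    regions = _region_map(geometry)
    for name in regions:
        if _lookup_curve(curves, name, "delta_fret") is None:
            raise ConfigurationError(f"no delta_fret curve covers region {name!r}")

    fret_times = schedule.fret_times
    burst_starts = schedule.burst_starts
    H, W = geometry.shape
    mask = geometry.mask
    vig = vignette_map(geometry, channels.vignette_strength)

    # --- FRET frames -------------------------------------------------------
    delta_true: dict[str, np.ndarray] = {}
    delta_map = np.full((len(fret_times), H, W), np.nan)
    for name, region in regions.items():
        curve = _lookup_curve(curves, name, "delta_fret")
        series = np.atleast_1d(camp_response(fret_times - stimulus_onset_s, curve))
        delta_true[name] = series
        delta_map[:, region] = series[:, None]

    a, b = channels.cfp_response, channels.yfp_response
    cfp = np.full((len(fret_times), H, W), channels.offset)
    yfp = np.full_like(cfp, channels.offset)
    cfp[:, mask] = channels.offset + channels.gain * delta_map[:, mask] ** a * vig[mask]
    yfp[:, mask] = channels.offset + channels.gain * delta_map[:, mask] ** (-b) * vig[mask]
    if motion_jitter:
        for i in range(len(fret_times)):
            dy, dx = rng.integers(-1, 2, size=2)
            cfp[i] = np.roll(cfp[i], (dy, dx), axis=(0, 1))
            yfp[i] = np.roll(yfp[i], (dy, dx), axis=(0, 1))
    if channels.noise_sd > 0:
        cfp += rng.normal(0.0, channels.noise_sd, cfp.shape)
        yfp += rng.normal(0.0, channels.noise_sd, yfp.shape)

    rec = FretRecording(
        cfp=FrameStack(cfp, fret_times, geometry.pixel_pitch),
        yfp=FrameStack(yfp, fret_times, geometry.pixel_pitch),
        mask=mask.copy(),
    )

    # --- Vm/Ca bursts ------------------------------------------------------
    delay = geometry.activation_delay_ms()
    delay_flat = delay[mask]
    apd_base = _base_duration_map(geometry, DEFAULT_APD80, base_apd80)
    catd_base = _base_duration_map(geometry, DEFAULT_CATD50, base_catd50)
    scale_maps = {"apd_scale": apd_base, "catd_scale": catd_base}

    n = schedule.burst_samples
    t_ms = np.arange(n) * schedule.sample_interval_ms
    M = channels.bleedthrough
    bursts = []
    apd_true = np.full((len(burst_starts), H, W), np.nan)
    catd_true = np.full_like(apd_true, np.nan)
    rates = np.zeros(len(burst_starts))

    def _scaled(applies_to, t_rel):
        base = scale_maps[applies_to]
        out = base.copy()
        for name, region in regions.items():
            curve = _lookup_curve(curves, name, applies_to)
            if curve is not None:
                out[region] = base[region] * float(curve(t_rel))
        return out

    rate_curve = _lookup_curve(curves, DEFAULT_REGION, "rate_scale")
    for k, tb in enumerate(burst_starts):
        t_rel = tb - stimulus_onset_s
        rate = base_rate_bpm * (float(rate_curve(t_rel)) if rate_curve else 1.0)
        period = 60000.0 / rate
        apd_k = _scaled("apd_scale", t_rel)
        catd_k = _scaled("catd_scale", t_rel)
        apd_true[k] = apd_k
        catd_true[k] = catd_k
        rates[k] = rate

        # Beat clock per pixel: wrap the within-burst time by the beat period
        # (beats never overlap; the leading partial wrap is the tail of a beat
        # "in progress" at burst start and carries no upstroke).
        t_wrap = (t_ms[:, None] - delay_flat[None, :] - FIRST_BEAT_MS) % period
        ap = ap_waveform(t_wrap, apd_k[mask][None, :], upstroke_ms)
        ca = ca_waveform(t_wrap, catd_k[mask][None, :], ca_rise_ms)
        own_vm = channels.vm_polarity * ap if channels.vm_dye else np.zeros_like(ap)
        own_ca = ca if channels.ca_dye else np.zeros_like(ca)

        det_vm = M[0, 0] * own_vm + M[0, 1] * own_ca
        det_ca = M[1, 0] * own_vm + M[1, 1] * own_ca

        vm_frames = np.full((n, H, W), channels.offset, dtype=np.float32)
        ca_frames = np.full((n, H, W), channels.offset, dtype=np.float32)
        vm_frames[:, mask] = channels.offset + channels.gain * (1.0 + det_vm) * vig[mask]
        ca_frames[:, mask] = channels.offset + channels.gain * (1.0 + det_ca) * vig[mask]
        if channels.noise_sd > 0:
            vm_frames += rng.normal(0.0, channels.noise_sd, vm_frames.shape).astype(np.float32)
            ca_frames += rng.normal(0.0, channels.noise_sd, ca_frames.shape).astype(np.float32)

        times_s = tb + t_ms / 1000.0
        bursts.append(
            (
                FrameStack(vm_frames, times_s, geometry.pixel_pitch),
                FrameStack(ca_frames, times_s, geometry.pixel_pitch),
            )
        )

    truth = GroundTruth(
        activation_time=delay,
        apd80_true=apd_true,
        catd50_true=catd_true,
        delta_fret_true=delta_true,
        heart_rate_true=rates,
        fret_times=fret_times,
        burst_times=burst_starts,
    )
    return rec, bursts, truth
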