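"""Optical-mapping analysis of transmembrane potential and calcium bursts.

The processing chain mirrors standard optical-mapping practice: a 3x3
spatial Gaussian filter, polarity normalisation (voltage dyes typically
darken on depolarisation), morphological top-hat baseline-drift correction,
beat detection on the maximum-upstroke derivative, and per-pixel maps of
activation time and of action-potential / calcium-transient duration
(APD80 from activation to 80% repolarisation, CaTD50 to 50% decay),
averaged over up to 10 consecutive beats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .core import FrameStack
from .errors import AnalysisError, ConfigurationError

# 3x3 Gaussian kernel, sigma = 1 px, normalised to sum 1.
_G1 = np.exp(-0.5 * np.arange(-1, 2) ** 2)
GAUSS3 = np.outer(_G1, _G1) / np.outer(_G1, _G1).sum()

#: Diastolic-baseline window: mean of this many ms immediately pre-upstroke.
BASELINE_MS = 10.0

#: Beat windows open this many ms before the detected trace-level upstroke.
PRE_WINDOW_MS = 40.0

#: Derivative samples within this relative tolerance of the maximum count as
#: ties (resolved to the earliest sample). A linear upstroke has an exactly
#: constant derivative; spatial filtering perturbs the tie by epsilon, which
#: would otherwise push the detected activation to the end of the rise.
DERIV_TIE_RTOL = 0.01


def _argmax_earliest(d: np.ndarray, rtol: float = DERIV_TIE_RTOL):
    """Earliest index whose value is within ``rtol`` of the column maximum."""
    dmax = d.max(axis=0)
    near = d >= dmax - rtol * np.abs(dmax)
    return near.argmax(axis=0)


@dataclass
class OpticalTrace:
    """A single fluorescence time series with uniform sampling.

    ``times`` are ms; ``polarity`` is the sign of the deflection on
    activation (+1 or -1). After :func:`normalize_polarity` upstrokes are
    positive.
    """

    times: np.ndarray
    values: np.ndarray
    polarity: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ConfigurationError("times and values must have equal length")
        if self.polarity not in (-1, 1):
            raise ConfigurationError("polarity must be +1 or -1")

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            raise ConfigurationError("trace needs at least two samples")
        return float(np.median(np.diff(self.times)))


@dataclass
class BeatSet:
    """Trace-level beats: activation times, index windows, and heart rate."""

    activation_times: np.ndarray
    beat_windows: list
    heart_rate: float | None

    @property
    def n_beats(self) -> int:
        return len(self.activation_times)


@dataclass
class DurationMap:
    """Per-pixel APD80 or CaTD50 (ms), averaged over beats; NaN outside mask."""

    kind: str
    values: np.ndarray
    n_beats_averaged: int
    level: float
    mask: np.ndarray = None


@dataclass
class ActivationMap:
    """Per-pixel activation time (ms) relative to the earliest pixel."""

    values: np.ndarray
    earliest_site: tuple


def pixel_trace(stack: FrameStack, pixel: tuple, polarity: int = 1) -> OpticalTrace:
    """Extract one pixel's time series as an :class:`OpticalTrace` (times in ms)."""
    t_ms = (stack.times - stack.times[0]) * 1000.0
    return OpticalTrace(t_ms, stack.values[:, pixel[0], pixel[1]].astype(float), polarity)


def normalize_polarity(trace: OpticalTrace) -> OpticalTrace:
    """Flip the trace if needed so that upstrokes are positive deflections."""
    return OpticalTrace(trace.times, trace.values * trace.polarity, 1)


def spatial_filter(stack: FrameStack) -> FrameStack:
    """Per-frame convolution with the normalised 3x3 Gaussian (sigma = 1 px)."""
    if stack.n_frames == 0:
        raise ConfigurationError("empty stack")
    out = ndimage.convolve(
        stack.values.astype(float), GAUSS3[None, :, :], mode="reflect"
    )
    return FrameStack(out, stack.times, stack.pixel_pitch_mm)


def _opening(values: np.ndarray, size: int, axis: int = -1) -> np.ndarray:
    """Grey opening with a flat structuring element: erosion then dilation."""
    eroded = ndimage.minimum_filter1d(values, size, axis=axis, mode="nearest")
    return ndimage.maximum_filter1d(eroded, size, axis=axis, mode="nearest")


def baseline_correct(trace: OpticalTrace, window_ms: float) -> OpticalTrace:
    """Top-hat baseline-drift correction.

    Subtracts the morphological opening (flat structuring element of
    ``window_ms``) of the polarity-normalised trace, leaving the diastolic
    baseline at ~0. ``window_ms`` must exceed the beat period so that entire
    beats are not eroded away.
    """
    norm = normalize_polarity(trace)
    size = int(round(window_ms / norm.dt))
    if size < 3:
        raise ConfigurationError("top-hat window must span at least 3 samples")
    corrected = norm.values - _opening(norm.values, size)
    return OpticalTrace(norm.times, corrected, 1)


def detect_beats(
    trace: OpticalTrace,
    min_separation_ms: float = 50.0,
    threshold_frac: float = 0.5,
    pre_window_ms: float = PRE_WINDOW_MS,
) -> BeatSet:
    """Detect beats as peaks of dV/dt above ``threshold_frac`` x max derivative.

    Returns an empty :class:`BeatSet` (no exception) when no upstroke exists.
    Beat windows run from ``pre_window_ms`` before each upstroke to the same
    point before the next one (the last window extends to the trace end).
    """
    v = trace.values * trace.polarity
    dt = trace.dt
    d = np.diff(v)
    if d.size == 0 or d.max() <= 0:
        return BeatSet(np.array([]), [], None)
    peaks, _ = signal.find_peaks(
        d,
        height=threshold_frac * d.max(),
        distance=max(1, int(round(min_separation_ms / dt))),
    )
    if peaks.size == 0:
        # A single monotone upstroke has no local maximum; take the argmax.
        peaks = np.array([int(np.argmax(d))])
    act_times = trace.times[peaks]
    pre = int(round(pre_window_ms / dt))
    starts = np.clip(peaks - pre, 0, None)
    ends = np.append(starts[1:], len(v))
    windows = [(int(s), int(e)) for s, e in zip(starts, ends)]
    rate = None
    if peaks.size >= 2:
        rate = 60000.0 / float(np.mean(np.diff(act_times)))
    return BeatSet(act_times, windows, rate)


def _complete_windows(beats: BeatSet, dt: float) -> list:
    """Windows long enough to contain a full beat (bounded by the next beat,
    or a trailing window at least ~0.9 of the median beat interval)."""
    if beats.n_beats == 0:
        return []
    if beats.n_beats == 1:
        return beats.beat_windows
    interval = np.median(np.diff(beats.activation_times)) / dt
    return [w for w in beats.beat_windows if (w[1] - w[0]) >= 0.9 * interval]


def _parabolic_refine(d: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Sub-sample offset of the derivative peak at index ``k`` (vectorised).

    Fits a parabola through d[k-1], d[k], d[k+1]; falls back to 0 at the
    ends or when the curvature is not concave.
    """
    k = np.atleast_1d(k)
    out = np.zeros(k.shape)
    ok = (k > 0) & (k < d.shape[0] - 1)
    if d.ndim == 1:
        dm = d[np.clip(k - 1, 0, None)]
        d0 = d[k]
        dp = d[np.clip(k + 1, 0, d.shape[0] - 1)]
    else:  # (T-1, P) with one k per column
        cols = np.arange(d.shape[1])
        dm = d[np.clip(k - 1, 0, None), cols]
        d0 = d[k, cols]
        dp = d[np.clip(k + 1, 0, d.shape[0] - 1), cols]
    denom = dm - 2 * d0 + dp
    ok &= denom < 0
    with np.errstate(divide="ignore", invalid="ignore"):
        off = (dm - dp) / (2.0 * denom)
    return np.where(ok, np.clip(off, -0.5, 0.5), 0.0)


def activation_time(
    trace: OpticalTrace, beat_window: tuple, refine: bool = False
) -> float | None:
    """Time (ms) of maximum forward-difference derivative within the window.

    Ties resolve to the earliest sample; returns None when the maximum
    derivative is not positive (no upstroke in the window). With
    ``refine=True`` the peak is localised to sub-sample precision by a
    parabolic fit through the three derivative samples around the maximum
    (the forward difference d[k] estimates the slope at k + 1/2, hence the
    half-sample shift).
    """
    i0, i1 = beat_window
    v = trace.values[i0:i1] * trace.polarity
    d = np.diff(v)
    if d.size == 0 or d.max() <= 0:
        return None
    k = int(_argmax_earliest(d[:, None])[0])
    off = float(_parabolic_refine(d, np.array([k]))[0]) + 0.5 if refine else 0.0
    return float(trace.times[i0 + k] + off * trace.dt)


def _beat_durations(
    seg: np.ndarray, dt: float, level: float, baseline_samples: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-pixel duration for one beat window.

    ``seg`` is (T, P), polarity-normalised and baseline-corrected. Returns
    (durations_ms, activation_idx) with NaN / -1 where undefined. The
    amplitude reference is peak minus the mean of ``baseline_samples``
    immediately preceding each pixel's upstroke; the crossing of
    ``peak - level * amplitude`` is linearly interpolated.
    """
    T, P = seg.shape
    d = np.diff(seg, axis=0)
    act = _argmax_earliest(d)
    act_valid = d.max(axis=0) > 0

    # Sub-sample upstroke foot: back-extrapolate the linear rise by the
    # partial first derivative sample, d[act-1]/d[act] of a full step.
    cur = np.take_along_axis(d, act[None, :], axis=0)[0]
    prev = np.take_along_axis(d, np.clip(act - 1, 0, None)[None, :], axis=0)[0]
    frac_foot = np.clip(np.where(cur > 0, prev / np.where(cur > 0, cur, 1.0), 0.0), 0, 1)
    foot = np.where(act > 0, act - frac_foot, act.astype(float))

    offs = np.clip(act[None, :] + np.arange(-baseline_samples, 0)[:, None], 0, T - 1)
    base = np.take_along_axis(seg, offs, axis=0).mean(axis=0)

    idx = np.arange(T)[:, None]
    after = idx >= act[None, :]
    masked = np.where(after, seg, -np.inf)
    peak_idx = masked.argmax(axis=0)
    peak_val = np.take_along_axis(seg, peak_idx[None, :], axis=0)[0]
    amp = peak_val - base
    thr = peak_val - level * amp

    # First post-peak crossing with 2-sample persistence (the next sample
    # must also be below threshold), which suppresses single-sample noise
    # dips; on a monotone noise-free decay it is the first crossing.
    below = seg < thr[None, :]
    persist = below & np.vstack([below[1:], np.ones((1, P), dtype=bool)])
    persist &= idx > peak_idx[None, :]
    has_cross = persist.any(axis=0)
    first = persist.argmax(axis=0)
    firstm1 = np.clip(first - 1, 0, T - 1)
    v_hi = np.take_along_axis(seg, firstm1[None, :], axis=0)[0]
    v_lo = np.take_along_axis(seg, first[None, :], axis=0)[0]
    denom = v_hi - v_lo
    frac = np.clip(
        np.where(denom > 0, (v_hi - thr) / np.where(denom > 0, denom, 1.0), 0.0), 0, 1
    )
    cross = (first - 1 + frac) * dt
    dur = cross - foot * dt

    valid = act_valid & has_cross & (amp > 0) & (dur > 0)
    return np.where(valid, dur, np.nan), np.where(act_valid, act, -1)


def apd(trace: OpticalTrace, beat_window: tuple, level: float = 0.8) -> float | None:
    """Action-potential duration (ms) at ``level`` repolarisation for one beat.

    Measured from the activation time (maximum upstroke derivative) to the
    linearly interpolated first post-peak crossing of
    ``peak - level * amplitude``; the amplitude references the mean of the
    10 ms preceding the upstroke. Returns None when undefined.
    """
    i0, i1 = beat_window
    v = (trace.values * trace.polarity)[i0:i1]
    if len(v) < 3:
        return None
    nb = max(1, int(round(BASELINE_MS / trace.dt)))
    dur, _ = _beat_durations(v[:, None], trace.dt, level, nb)
    return None if np.isnan(dur[0]) else float(dur[0])


def catd(trace: OpticalTrace, beat_window: tuple, level: float = 0.5) -> float | None:
    """Calcium-transient duration (ms) at ``level`` decay; see :func:`apd`."""
    return apd(trace, beat_window, level=level)


_KINDS = {"APD80": (0.8, -1), "CaTD50": (0.5, 1)}


def prepare_stack(
    stack: FrameStack,
    mask: np.ndarray,
    polarity: int,
    tophat_window_ms: float | None = None,
):
    """Filter, polarity-normalise and drift-correct a burst stack.

    Returns ``(values (T, P), reference OpticalTrace, BeatSet)`` where P runs
    over mask pixels in row-major order and the reference trace is the
    mask-mean. The top-hat window defaults to 1.5x the median beat interval,
    estimated from a first pass with a generous window.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise AnalysisError("empty mask")
    filtered = spatial_filter(stack)
    t_ms = (stack.times - stack.times[0]) * 1000.0
    dt = float(np.median(np.diff(t_ms)))
    V = filtered.values[:, mask].astype(float) * polarity

    def _correct(window_ms):
        size = max(3, int(round(window_ms / dt)))
        return V - _opening(V, size, axis=0)

    if tophat_window_ms is None:
        probe = _correct(min(600.0, t_ms[-1]))
        beats0 = detect_beats(OpticalTrace(t_ms, probe.mean(axis=1), 1))
        if beats0.n_beats >= 2:
            interval = float(np.median(np.diff(beats0.activation_times)))
            tophat_window_ms = 1.5 * interval
        else:
            tophat_window_ms = min(600.0, t_ms[-1])
    Vc = _correct(tophat_window_ms)
    ref = OpticalTrace(t_ms, Vc.mean(axis=1), 1)
    beats = detect_beats(ref)
    return Vc, ref, beats


def duration_map(
    stack: FrameStack,
    mask: np.ndarray,
    kind: str = "APD80",
    n_beats: int = 10,
    polarity: int | None = None,
    tophat_window_ms: float | None = None,
    prepared=None,
) -> DurationMap:
    """Per-pixel duration map averaged over the first ``n_beats`` complete beats.

    ``kind`` is ``"APD80"`` (level 0.8, polarity -1 by default) or
    ``"CaTD50"`` (level 0.5, polarity +1). Pixels with no valid beat are NaN.
    ``prepared`` may pass a precomputed ``prepare_stack`` result.

    Raises
    ------
    AnalysisError
        If no beats are detectable in the mask-mean reference trace.
    """
    if kind not in _KINDS:
        raise ConfigurationError(f"kind must be one of {sorted(_KINDS)}")
    level, default_pol = _KINDS[kind]
    polarity = default_pol if polarity is None else polarity
    V, ref, beats = prepared or prepare_stack(stack, mask, polarity, tophat_window_ms)
    if beats.n_beats == 0:
        raise AnalysisError("no beats detected in the reference trace")
    dt = ref.dt
    windows = _complete_windows(beats, dt)[:n_beats]
    if not windows:
        raise AnalysisError("no complete beats available")
    nb = max(1, int(round(BASELINE_MS / dt)))
    per_beat = np.stack(
        [_beat_durations(V[w[0] : w[1]], dt, level, nb)[0] for w in windows]
    )
    with np.errstate(invalid="ignore"):
        mean_dur = np.nanmean(per_beat, axis=0)
    mask = np.asarray(mask, dtype=bool)
    grid = np.full(mask.shape, np.nan)
    grid[mask] = mean_dur
    return DurationMap(kind, grid, len(windows), level, mask)


def activation_map(
    stack: FrameStack,
    mask: np.ndarray,
    beat_index: int = 0,
    polarity: int = -1,
    tophat_window_ms: float | None = None,
    refine: bool = True,
    prepared=None,
) -> ActivationMap:
    """Per-pixel activation time for one beat, relative to the earliest pixel.

    The earliest site (map minimum; row-major first on ties) functionally
    identifies the leading pacemaker in atrial preparations. Sub-sample
    parabolic refinement of the upstroke-derivative peak is on by default
    here: at typical sampling rates a whole disk of pixels around the
    source ties at the same activation sample, which would bias the
    earliest site toward the row-major-first pixel of that disk.

    Raises
    ------
    AnalysisError
        If ``beat_index`` is out of range or fewer than half of the mask
        pixels have a defined upstroke in the chosen beat.
    """
    V, ref, beats = prepared or prepare_stack(stack, mask, polarity, tophat_window_ms)
    if not 0 <= beat_index < beats.n_beats:
        raise AnalysisError(
            f"beat_index {beat_index} out of range ({beats.n_beats} beats)"
        )
    i0, i1 = beats.beat_windows[beat_index]
    seg = V[i0:i1]
    d = np.diff(seg, axis=0)
    act = _argmax_earliest(d)
    valid = d.max(axis=0) > 0
    if valid.mean() < 0.5:
        raise AnalysisError("beat defined in fewer than 50% of mask pixels")
    act_f = act.astype(float)
    if refine:
        act_f = act_f + _parabolic_refine(d, act) + 0.5
    act_ms = np.where(valid, act_f * ref.dt, np.nan)
    act_ms = act_ms - np.nanmin(act_ms)
    mask = np.asarray(mask, dtype=bool)
    grid = np.full(mask.shape, np.nan)
    grid[mask] = act_ms
    flat = np.where(np.isnan(grid), np.inf, grid)
    earliest = np.unravel_index(int(np.argmin(flat)), grid.shape)
    return ActivationMap(grid, (int(earliest[0]), int(earliest[1])))
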