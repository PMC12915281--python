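"""Ratiometric cAMP FRET analysis (CFP donor / YFP acceptor).

FRET is computed per pixel as R = CFP/YFP; changes are expressed relative
to the pre-stimulus baseline as ΔFRET = R/R0 with R0 the per-pixel mean of
R over a baseline frame window, which normalises away gain, illumination,
and curvature differences. ROI traces, cross-sectional intensity profiles,
and bolus-response metrics (Max R/R0 and 50% time to decay) follow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .core import FrameStack, FretRecording
from .errors import AnalysisError, ConfigurationError, RegistrationError

#: A response smaller than this above baseline leaves the bolus metrics undefined.
MIN_RESPONSE = 0.01


@dataclass
class RatioMovie:
    """Pixel-wise R, baseline R0 and ΔFRET = R/R0; NaN outside the mask."""

    r: np.ndarray
    r0: np.ndarray
    delta: np.ndarray
    baseline_window: tuple
    mask: np.ndarray
    times: np.ndarray
    pixel_pitch_mm: float = 0.1


@dataclass
class DeltaFretTrace:
    """ROI-mean ΔFRET time course with bolus-response metrics.

    ``max_ratio`` (Max R/R0), ``time_to_peak`` (s) and ``decay_t50`` (s; time
    from the peak to half-return toward baseline) are None when the trace
    shows no response above baseline.
    """

    roi_label: str
    times: np.ndarray
    values: np.ndarray
    max_ratio: float | None = None
    time_to_peak: float | None = None
    decay_t50: float | None = None


def _normalize_window(baseline_window, n_frames: int) -> tuple[int, int]:
    if isinstance(baseline_window, slice):
        start, stop = baseline_window.indices(n_frames)[:2]
    else:
        start, stop = baseline_window
    start, stop = int(start), int(stop)
    if not (0 <= start < stop <= n_frames):
        raise ConfigurationError(
            f"baseline_window ({start}, {stop}) must be a nonempty range within "
            f"[0, {n_frames})"
        )
    return start, stop


def register_split(
    cfp: FrameStack, yfp: FrameStack, max_shift: int = 8
) -> tuple[tuple[int, int], FrameStack]:
    """Estimate the integer (dy, dx) offset of the split YFP image vs CFP.

    The shift maximising the normalised cross-correlation of the
    time-averaged frames is found by exhaustive search over ±``max_shift``;
    ties resolve to the smallest |dy|+|dx|, then row-major order. Returns the
    displacement of YFP relative to CFP and the YFP stack shifted back into
    register (vacated borders zeroed).
    """
    if cfp.values.shape != yfp.values.shape:
        raise ConfigurationError("stacks must share shape")
    if max_shift < 0:
        raise ConfigurationError("max_shift must be >= 0")
    a = cfp.values.mean(axis=0)
    b = yfp.values.mean(axis=0)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise RegistrationError("cannot register featureless (constant) images")

    shifts = sorted(
        (
            (dy, dx)
            for dy in range(-max_shift, max_shift + 1)
            for dx in range(-max_shift, max_shift + 1)
        ),
        key=lambda s: (abs(s[0]) + abs(s[1]), s[0], s[1]),
    )
    H, W = a.shape
    best, best_ncc = (0, 0), -np.inf
    for dy, dx in shifts:
        # Overlap of a with b displaced by (dy, dx): b[r, c] ~ a[r - dy, c - dx].
        ay0, ay1 = max(0, -dy), min(H, H - dy)
        ax0, ax1 = max(0, -dx), min(W, W - dx)
        if ay1 - ay0 < 2 or ax1 - ax0 < 2:
            continue
        pa = a[ay0:ay1, ax0:ax1]
        pb = b[ay0 + dy : ay1 + dy, ax0 + dx : ax1 + dx]
        pa = pa - pa.mean()
        pb = pb - pb.mean()
        denom = np.sqrt((pa**2).sum() * (pb**2).sum())
        if denom == 0:
            continue
        ncc = float((pa * pb).sum() / denom)
        if ncc > best_ncc + 1e-12:
            best, best_ncc = (dy, dx), ncc
    if not np.isfinite(best_ncc):
        raise RegistrationError("registration failed: no valid overlap")

    dy, dx = best
    shifted = np.roll(yfp.values, (-dy, -dx), axis=(1, 2))
    if dy > 0:
        shifted[:, -dy:, :] = 0
    elif dy < 0:
        shifted[:, :-dy, :] = 0
    if dx > 0:
        shifted[:, :, -dx:] = 0
    elif dx < 0:
        shifted[:, :, :-dx] = 0
    return best, FrameStack(shifted, yfp.times, yfp.pixel_pitch_mm)


def compute_ratio(
    rec: FretRecording, baseline_window, yfp_floor: float = 0.0
) -> RatioMovie:
    """Pixel-wise R = CFP/YFP and ΔFRET = R/R0 over the recording.

    ``R0`` is the per-pixel mean of R over ``baseline_window`` (a
    ``(start, stop)`` frame range or slice). Pixels whose YFP ever drops to
    ``yfp_floor`` or below are removed from the mask to avoid ratio blow-up.

    Raises
    ------
    AnalysisError
        If no mask pixel survives the YFP floor.
    """
    start, stop = _normalize_window(baseline_window, rec.cfp.n_frames)
    mask = rec.mask & (rec.yfp.values.min(axis=0) > yfp_floor)
    if not mask.any():
        raise AnalysisError("mask is empty after applying the YFP floor")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(mask[None], rec.cfp.values / rec.yfp.values, np.nan)
    r0 = r[start:stop].mean(axis=0)
    delta = r / r0[None]
    return RatioMovie(
        r=r,
        r0=r0,
        delta=delta,
        baseline_window=(start, stop),
        mask=mask,
        times=rec.cfp.times.copy(),
        pixel_pitch_mm=rec.cfp.pixel_pitch_mm,
    )


def roi_trace(movie: RatioMovie, roi: np.ndarray, label: str = "ROI") -> DeltaFretTrace:
    """ROI-mean ΔFRET time course with response metrics filled in.

    ``roi`` is a boolean grid; only its intersection with the movie mask
    contributes (empty intersection raises :class:`AnalysisError`).
    """
    roi = np.asarray(roi, dtype=bool)
    sel = roi & movie.mask
    if not sel.any():
        raise AnalysisError(f"ROI {label!r} does not intersect the mask")
    values = movie.delta[:, sel].mean(axis=1)
    trace = DeltaFretTrace(label, movie.times.copy(), values)
    trace.max_ratio, trace.time_to_peak, trace.decay_t50 = response_metrics(
        trace, movie.baseline_window
    )
    return trace


def line_profile(
    map2d: np.ndarray,
    p_start: tuple,
    p_end: tuple,
    width: int = 1,
    pixel_pitch_mm: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-sectional profile of a map along a segment.

    Samples at 1-pixel steps between ``p_start`` and ``p_end`` (row, col),
    averaging perpendicular to the segment over ``width`` pixels. Returns
    ``(distance_mm, values)``.
    """
    map2d = np.asarray(map2d, dtype=float)
    for p in (p_start, p_end):
        if not (0 <= p[0] < map2d.shape[0] and 0 <= p[1] < map2d.shape[1]):
            raise ConfigurationError(f"endpoint {p} outside the grid")
    if tuple(p_start) == tuple(p_end):
        raise AnalysisError("zero-length profile segment")
    values = measure.profile_line(
        map2d, p_start, p_end, linewidth=width, order=1, mode="reflect",
        reduce_func=np.mean,
    )
    distances = np.arange(len(values)) * pixel_pitch_mm
    return distances, values


def response_metrics(
    trace: DeltaFretTrace, baseline_window, min_response: float = MIN_RESPONSE
):
    """Bolus-response metrics of a ΔFRET trace.

    ``max_ratio`` is the maximum after the baseline window (earliest frame on
    ties); ``decay_t50`` is the first post-peak time — linearly interpolated
    between frames — at which the trace falls to halfway between the peak and
    baseline (1.0), minus the peak time. All three are None when the peak
    does not exceed ``1 + min_response``.
    """
    start, stop = _normalize_window(baseline_window, len(trace.values))
    if len(trace.values) - stop < 1 or len(trace.values) < 3:
        raise ConfigurationError("need at least 3 frames and frames after baseline")
    post = trace.values[stop:]
    i_peak = int(np.argmax(post))
    max_ratio = float(post[i_peak])
    if max_ratio <= 1.0 + min_response:
        return None, None, None
    time_to_peak = float(trace.times[stop + i_peak])
    target = 1.0 + (max_ratio - 1.0) / 2.0
    decay_t50 = None
    for j in range(stop + i_peak + 1, len(trace.values)):
        if trace.values[j] <= target:
            v1, v2 = trace.values[j - 1], trace.values[j]
            t1, t2 = trace.times[j - 1], trace.times[j]
            frac = 0.0 if v1 == v2 else (v1 - target) / (v1 - v2)
            decay_t50 = float(t1 + frac * (t2 - t1) - time_to_peak)
            break
    return max_ratio, time_to_peak, decay_t50
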