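"""Electrophysiology analysis: filtering, drift correction, beats, durations,
activation maps, and invariance properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quadmap import electro, synth
from quadmap.core import FrameStack
from quadmap.errors import AnalysisError, ConfigurationError
from conftest import render_flat_burst


def _stack(values):
    values = np.asarray(values, dtype=float)
    return FrameStack(values, np.arange(values.shape[0]) / 1000.0)


def _trace(values, dt=1.0, polarity=1):
    values = np.asarray(values, dtype=float)
    return electro.OpticalTrace(np.arange(len(values)) * dt, values, polarity)


def brute_force_opening(v, size):
    """O(N*k) morphological opening oracle: min filter then max filter."""
    n = len(v)
    half_lo = size // 2
    half_hi = size - half_lo - 1

    def window(i):
        return slice(max(0, i - half_lo), min(n, i + half_hi + 1))

    eroded = np.array([v[window(i)].min() for i in range(n)])
    return np.array([eroded[window(i)].max() for i in range(n)])


class TestSpatialFilter:
    def test_constant_frame_unchanged(self):
        out = electro.spatial_filter(_stack(np.full((2, 10, 10), 5.0)))
        np.testing.assert_allclose(out.values, 5.0)

    def test_interior_impulse_conserves_mass(self):
        frame = np.zeros((1, 11, 11))
        frame[0, 5, 5] = 100.0
        out = electro.spatial_filter(_stack(frame))
        assert out.values.sum() == pytest.approx(100.0, abs=1e-9)

    def test_impulse_response_equals_explicit_kernel(self):
        """The kernel is the normalised outer product of exp(-{1,0,1}/2)."""
        g = np.exp(-0.5 * np.array([1.0, 0.0, 1.0]))
        expected = np.outer(g, g) / np.outer(g, g).sum()
        frame = np.zeros((1, 9, 9))
        frame[0, 4, 4] = 1.0
        out = electro.spatial_filter(_stack(frame))
        np.testing.assert_allclose(out.values[0, 3:6, 3:6], expected, atol=1e-12)
        assert out.values[0, 0, 0] == 0.0


class TestBaselineCorrect:
    def test_matches_brute_force_opening_oracle(self):
        rng = np.random.default_rng(0)
        t = np.arange(1000.0)
        pulses = synth.ap_waveform((t - 40) % 200.0, 50.0, 2.0)
        drift = 0.3 * t / 1000.0 + rng.normal(0, 0.01, 1000)
        v = pulses + drift
        corrected = electro.baseline_correct(_trace(v), 300.0)
        expected = v - brute_force_opening(v, 300)
        np.testing.assert_allclose(corrected.values, expected, atol=1e-12)

    def test_linear_drift_removed_from_diastole(self):
        t = np.arange(1200.0)
        pulses = synth.ap_waveform((t - 40) % 200.0, 50.0, 2.0)
        v = pulses + 0.5 * t / 1200.0
        corrected = electro.baseline_correct(_trace(v), 300.0)
        # boundary columns see a truncated structuring element; judge the
        # interior diastolic samples
        diastole = (((t - 40) % 200.0) > 150.0) & (t > 160) & (t < 1000)
        assert np.abs(corrected.values[diastole]).max() < 1e-3

    def test_window_1p5_beat_periods_preserves_amplitude(self):
        t = np.arange(1200.0)
        v = synth.ap_waveform((t - 40) % 200.0, 50.0, 2.0)
        corrected = electro.baseline_correct(_trace(v), 300.0)
        assert corrected.values.max() == pytest.approx(v.max(), rel=0.01)

    def test_negative_polarity_normalised_before_correction(self):
        t = np.arange(600.0)
        v = -synth.ap_waveform((t - 40) % 200.0, 50.0, 2.0)
        corrected = electro.baseline_correct(_trace(v, polarity=-1), 300.0)
        assert corrected.values.max() > 0.9

    def test_window_below_three_samples_rejected(self):
        with pytest.raises(ConfigurationError):
            electro.baseline_correct(_trace(np.zeros(100)), 2.0)


class TestDetectBeats:
    def test_pulses_every_100ms_give_600_bpm(self):
        t = np.arange(1000.0)
        v = synth.ap_waveform((t - 30) % 100.0, 40.0, 2.0)
        beats = electro.detect_beats(_trace(v))
        assert beats.heart_rate == pytest.approx(600.0, abs=1.0)
        assert beats.n_beats >= 9

    def test_flat_trace_has_no_beats(self):
        beats = electro.detect_beats(_trace(np.zeros(500)))
        assert beats.n_beats == 0
        assert beats.heart_rate is None

    def test_simulated_burst_rate_recovered(self, geom48):
        _, bursts, truth = render_flat_burst(geom48, 50.0, 40.0, rate_bpm=450.0)
        vm = bursts[0][0]
        _, _, beats = electro.prepare_stack(vm, geom48.mask, -1)
        assert beats.heart_rate == pytest.approx(450.0, abs=5.0)


class TestActivationTime:
    def test_linear_upstroke_ties_resolve_to_onset_sample(self):
        v = np.concatenate([np.zeros(20), np.linspace(0, 1, 11), np.ones(30)])
        t = electro.activation_time(_trace(v), (0, len(v)))
        assert t == pytest.approx(20.0)

    def test_sigmoid_upstroke_detected_at_inflection(self):
        x = np.arange(200.0)
        v = 1.0 / (1.0 + np.exp(-(x - 80.0) / 4.0))
        t = electro.activation_time(_trace(v), (0, 200))
        assert t == pytest.approx(80.0, abs=1.0)

    def test_no_upstroke_returns_none(self):
        v = np.linspace(1.0, 0.0, 50)
        assert electro.activation_time(_trace(v), (0, 50)) is None

    def test_parabolic_refinement_recovers_subsample_onset(self):
        x = np.arange(200.0)
        v = 1.0 / (1.0 + np.exp(-(x - 80.37) / 4.0))
        t = electro.activation_time(_trace(v), (0, 200), refine=True)
        assert t == pytest.approx(80.37, abs=0.1)


class TestDurations:
    @pytest.fixture()
    def trapezoid(self):
        # rise 0 -> 1 between 10 and 12 ms, plateau to 40 ms, fall to 0 at 100 ms
        t = np.arange(0.0, 140.0)
        v = np.interp(t, [0, 10, 12, 40, 100, 139], [0, 0, 1, 1, 0, 0])
        return _trace(v)

    def test_trapezoid_apd80_closed_form(self, trapezoid):
        # activation 10 ms; 0.2 crossing at 88 ms -> APD80 = 78 ms
        assert electro.apd(trapezoid, (0, 140), level=0.8) == pytest.approx(78.0, abs=1e-9)

    def test_trapezoid_half_level_closed_form(self, trapezoid):
        assert electro.apd(trapezoid, (0, 140), level=0.5) == pytest.approx(60.0, abs=1e-9)

    def test_template_apd_recovered_by_construction(self):
        t = np.arange(0.0, 200.0)
        v = synth.ap_waveform(t - 30.0, 50.0, 2.0)
        assert electro.apd(_trace(v), (0, 200)) == pytest.approx(50.0, abs=1.0)

    def test_never_recrossing_trace_undefined(self):
        v = np.concatenate([np.zeros(20), np.linspace(0, 1, 5), np.ones(50)])
        assert electro.apd(_trace(v), (0, len(v))) is None

    @given(st.integers(1, 40))
    @settings(max_examples=15, deadline=None)
    def test_time_shift_equivariance(self, k):
        t = np.arange(0.0, 300.0)
        base = synth.ap_waveform(t - 50.0, 60.0, 2.0)
        shifted = synth.ap_waveform(t - 50.0 - k, 60.0, 2.0)
        w = (0, 300)
        a0 = electro.activation_time(_trace(base), w)
        a1 = electro.activation_time(_trace(shifted), w)
        assert a1 - a0 == pytest.approx(k, abs=1e-9)
        d0 = electro.apd(_trace(base), w)
        d1 = electro.apd(_trace(shifted), w)
        assert d1 == pytest.approx(d0, abs=1e-9)

    @given(st.floats(0.01, 100.0))
    @settings(max_examples=15, deadline=None)
    def test_amplitude_invariance(self, c):
        t = np.arange(0.0, 300.0)
        v = synth.ap_waveform(t - 50.0, 60.0, 2.0)
        w = (0, 300)
        assert electro.activation_time(_trace(c * v), w) == electro.activation_time(
            _trace(v), w
        )
        assert electro.apd(_trace(c * v), w) == pytest.approx(
            electro.apd(_trace(v), w), abs=1e-6
        )


class TestDurationMap:
    def test_homogeneous_burst_recovers_uniform_map(self, geom48):
        _, bursts, _ = render_flat_burst(geom48, 50.0, 40.0)
        dm = electro.duration_map(bursts[0][0], geom48.mask, "APD80", 10)
        assert np.nanmax(np.abs(dm.values - 50.0)) < 1.0
        assert np.isnan(dm.values[~geom48.mask]).all()

    def test_base_apex_gradient_recovered(self, geom48, flat_curves):
        sch = synth.AcquisitionSchedule(total_duration=10.0)
        _, bursts, _ = synth.render_recording(
            geom48, sch, flat_curves, synth.ChannelModel(), seed=0,
            base_apd80={"default": 50.0, "RV base": 55.0, "LV apex": 45.0},
        )
        dm = electro.duration_map(bursts[0][0], geom48.mask, "APD80", 10)
        rv = np.nanmean(dm.values[geom48.region_labels["RV base"]])
        lv = np.nanmean(dm.values[geom48.region_labels["LV apex"]])
        assert rv == pytest.approx(55.0, abs=1.0)
        assert lv == pytest.approx(45.0, abs=1.0)

    def test_ten_of_twelve_beats_averaged(self, geom48):
        # 360 bpm for 2 s yields 12 upstrokes; only the first 10 count
        _, bursts, _ = render_flat_burst(geom48, 45.0, 35.0, rate_bpm=360.0)
        dm = electro.duration_map(bursts[0][0], geom48.mask, "APD80", n_beats=10)
        assert dm.n_beats_averaged == 10

    def test_recovery_grid_within_one_sample(self, recovery_grid):
        """Measured APD80/CaTD50 within one 1 kHz sample of truth, all pixels."""
        assert recovery_grid["apd"] <= 1.0
        assert recovery_grid["catd"] <= 1.0

    def test_apd_error_under_noise_within_3ms_for_95pct(self, geom48):
        """Additive noise at 5% of amplitude leaves APD80 within 3 ms almost
        everywhere (fixed seed)."""
        _, bursts, truth = render_flat_burst(geom48, 50.0, 40.0, noise_sd=50.0, seed=7)
        dm = electro.duration_map(bursts[0][0], geom48.mask, "APD80", 10)
        err = np.abs(dm.values - truth.apd80_true[0])[geom48.mask]
        assert np.mean(err <= 3.0) >= 0.95

    def test_unknown_kind_rejected(self, geom48):
        _, bursts, _ = render_flat_burst(geom48, 50.0, 40.0)
        with pytest.raises(ConfigurationError):
            electro.duration_map(bursts[0][0], geom48.mask, "APD90")

    def test_no_beats_rejected(self):
        flat = FrameStack(np.zeros((500, 8, 8)), np.arange(500) / 1000.0)
        with pytest.raises(AnalysisError):
            electro.duration_map(flat, np.ones((8, 8), bool), "APD80")


class TestActivationMap:
    def test_focal_source_is_earliest_site(self, geom48):
        _, bursts, _ = render_flat_burst(geom48, 50.0, 40.0)
        am = electro.activation_map(bursts[0][0], geom48.mask, 0)
        assert am.earliest_site == geom48.focal_source
        assert np.nanmin(am.values) == 0.0

    def test_wavefront_times_match_distance_over_velocity(self, geom48):
        """Activation differences equal geodesic distance / conduction
        velocity to within one sample at zero noise."""
        _, bursts, _ = render_flat_burst(geom48, 50.0, 40.0)
        am = electro.activation_map(bursts[0][0], geom48.mask, 0)
        expected = geom48.activation_delay_ms()
        err = np.abs(am.values - expected)
        assert np.nanmax(err) <= 1.0

    def test_planar_wave_has_linear_isochrones(self):
        t = np.arange(0.0, 600.0)
        cols = np.arange(24.0)
        delay = 2.0 * cols  # plane wave along columns, 2 ms per pixel
        v = synth.ap_waveform(
            ((t[:, None] - 40.0 - delay[None, :]) % 250.0), 50.0, 2.0
        )
        stack = FrameStack(
            np.repeat(v[:, None, :], 24, axis=1), t / 1000.0
        )
        am = electro.activation_map(stack, np.ones((24, 24), bool), 0, polarity=1)
        mid = am.values[12]
        slope = np.diff(mid[4:20])
        np.testing.assert_allclose(slope, 2.0, atol=1.0)

    def test_simultaneous_activation_ties_row_major(self):
        t = np.arange(0.0, 500.0)
        v = synth.ap_waveform((t - 40.0) % 250.0, 50.0, 2.0)
        stack = FrameStack(np.tile(v[:, None, None], (1, 10, 10)), t / 1000.0)
        mask = np.zeros((10, 10), bool)
        mask[2:8, 2:8] = True
        am = electro.activation_map(stack, mask, 0, polarity=1, refine=False)
        np.testing.assert_allclose(am.values[mask], 0.0)
        assert am.earliest_site == (2, 2)

    def test_out_of_range_beat_rejected(self, geom48):
        _, bursts, _ = render_flat_burst(geom48, 50.0, 40.0)
        with pytest.raises(AnalysisError):
            electro.activation_map(bursts[0][0], geom48.mask, 99)


def test_scalar_and_map_paths_agree(geom48):
    """Per-pixel scalar APD equals the vectorised map on the same data."""
    _, bursts, _ = render_flat_burst(geom48, 50.0, 40.0)
    vm = bursts[0][0]
    prep = electro.prepare_stack(vm, geom48.mask, -1)
    V, ref, beats = prep
    dm = electro.duration_map(vm, geom48.mask, "APD80", 3, prepared=prep)
    pix_ids = np.flatnonzero(geom48.mask.ravel())[[10, 200, 700]]
    flat_index = {p: i for i, p in enumerate(np.flatnonzero(geom48.mask.ravel()))}
    for p in pix_ids:
        col = flat_index[p]
        trace = electro.OpticalTrace(ref.times, V[:, col], 1)
        per_beat = [
            electro.apd(trace, w) for w in beats.beat_windows[:3]
        ]
        per_beat = [x for x in per_beat if x is not None]
        r, c = np.unravel_index(p, geom48.mask.shape)
        assert np.mean(per_beat) == pytest.approx(dm.values[r, c], abs=1e-9)
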