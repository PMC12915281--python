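"""Shared fixtures: rendered synthetic recordings reused across test modules.

The expensive renders are session-scoped so that oracle-equivalence, recovery
and acceptance tests share one computation each.
"""

from __future__ import annotations

import numpy as np
import pytest

from quadmap import crosstalk, electro, fret, synth
from quadmap.pipeline import biphasic_metrics


@pytest.fixture(scope="session")
def geom48():
    return synth.build_geometry(48, 48, "ventricle_anterior")


@pytest.fixture(scope="session")
def flat_curves():
    """No pharmacological response: ΔFRET pinned at 1, durations at baseline."""
    return {"default": {"delta_fret": synth.ResponseCurve(((0.0, 1.0),), "delta_fret")}}


def render_flat_burst(geom, apd0, catd0, noise_sd=0.0, seed=0, rate_bpm=300.0,
                      channels=None):
    """One short flat-response render with uniform true APD80/CaTD50."""
    sch = synth.AcquisitionSchedule(total_duration=10.0)
    curves = {"default": {"delta_fret": synth.ResponseCurve(((0.0, 1.0),), "delta_fret")}}
    channels = channels or synth.ChannelModel(noise_sd=noise_sd)
    uniform_a = {k: apd0 for k in ("default", "RV base", "LV apex")}
    uniform_c = {k: catd0 for k in ("default", "RV base", "LV apex")}
    return synth.render_recording(
        geom, sch, curves, channels, seed=seed,
        base_apd80=uniform_a, base_catd50=uniform_c, base_rate_bpm=rate_bpm,
    )


@pytest.fixture(scope="session")
def ne_zero48(geom48):
    """Full 120 s NE-preset render at zero noise, with its ratio movie."""
    sch = synth.AcquisitionSchedule(total_duration=120.0)
    rec, bursts, truth = synth.render_recording(
        geom48, sch, synth.preset_curves("ne"), synth.ChannelModel(), seed=11
    )
    movie = fret.compute_ratio(rec, (0, 1))
    return {"rec": rec, "bursts": bursts, "truth": truth, "movie": movie,
            "geom": geom48}


@pytest.fixture(scope="session")
def recovery_grid(geom48):
    """Worst-case |measured - true| over the APD80 x CaTD50 parameter grid.

    Zero noise; the full filter/detect/map pipeline at 1 kHz sampling.
    """
    worst_apd = worst_catd = 0.0
    for apd0 in (30.0, 50.0, 70.0):
        for catd0 in (25.0, 40.0, 55.0):
            _, bursts, _ = render_flat_burst(geom48, apd0, catd0)
            vm, ca = bursts[0]
            dm = electro.duration_map(vm, geom48.mask, "APD80", 10)
            cm = electro.duration_map(ca, geom48.mask, "CaTD50", 10)
            worst_apd = max(worst_apd, float(np.nanmax(np.abs(dm.values - apd0))))
            worst_catd = max(worst_catd, float(np.nanmax(np.abs(cm.values - catd0))))
    return {"apd": worst_apd, "catd": worst_catd}


@pytest.fixture(scope="session")
def ks_null_rate():
    """Fraction of p < 0.05 under the null: same generator, n = 200, 1000 reps."""
    rng = np.random.default_rng(123)
    rejections = 0
    reps = 1000
    for _ in range(reps):
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        if crosstalk.ks_compare(a, b).p_value < 0.05:
            rejections += 1
    return rejections / reps


@pytest.fixture(scope="session")
def bleed_recovery(geom48):
    """Recovered Ca->Vm bleed-through for a true mixing fraction of 0.08.

    Calcium dye only (no voltage dye), noise SD 5% of signal amplitude
    (SNR 20); the slope of the mask-mean Vm-channel trace on the Ca-channel
    trace after baseline correction.
    """
    channels = synth.ChannelModel(
        noise_sd=50.0,
        bleedthrough=np.array([[1.0, 0.08], [0.0, 1.0]]),
        vm_dye=False,
    )
    _, bursts, _ = render_flat_burst(geom48, 50.0, 40.0, channels=channels, seed=3)
    vm, ca = bursts[0]
    t_ms = (vm.times - vm.times[0]) * 1e3
    tr_vm = electro.OpticalTrace(t_ms, vm.values[:, geom48.mask].mean(1), 1)
    tr_ca = electro.OpticalTrace(t_ms, ca.values[:, geom48.mask].mean(1), 1)
    bc_vm = electro.baseline_correct(tr_vm, 300.0)
    bc_ca = electro.baseline_correct(tr_ca, 300.0)
    return crosstalk.bleedthrough_fraction(bc_ca.values, bc_vm.values)


@pytest.fixture(scope="session")
def ne_apd_course():
    """Whole-mask mean APD80 per burst for the default NE run.

    64x64 grid, bursts every 10 s for 120 s, noise SD 5% of amplitude,
    seed 1 — the study conditions for the biphasic-APD recovery check.
    """
    geom = synth.build_geometry(64, 64, "ventricle_anterior")
    sch = synth.AcquisitionSchedule(total_duration=120.0)
    _, bursts, truth = synth.render_recording(
        geom, sch, synth.preset_curves("ne"), synth.ChannelModel(noise_sd=50.0),
        seed=1,
    )
    means = []
    for vm, _ in bursts:
        dm = electro.duration_map(vm, geom.mask, "APD80", 10)
        means.append(float(np.nanmean(dm.values)))
    slot_times = truth.burst_times - sch.burst_offset
    peak_t, rec_t = biphasic_metrics(slot_times, means, n_baseline=1, tolerance=0.02)
    return {"times": slot_times, "means": np.array(means),
            "peak_time": peak_t, "recovery_time": rec_t, "truth": truth}
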