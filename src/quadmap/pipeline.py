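"""End-to-end orchestration: simulate to disk, run the full analysis, summarise.

``run_pipeline`` ties the stages together the way the instrument workflow
does: ΔFRET maps and ROI traces from the CFP/YFP pair, APD80/CaTD50 maps and
heart rate from each Vm/Ca burst, and a colocalised tidy table pairing each
burst with the immediately preceding FRET frame. Outputs are deterministic
given (config, seed), and every CSV embeds the config hash.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import electro, fret, io, synth
from .config import PathsConfig, RunConfig, ScheduleConfig
from .core import FretRecording
from .errors import AnalysisError, QuadmapError

__version__ = "0.1.0"


@dataclass
class PipelineResult:
    """Bundle returned by :func:`run_pipeline`."""

    ratio: fret.RatioMovie
    fret_traces: dict
    apd_maps: list
    catd_maps: list
    heart_rates: np.ndarray
    slot_times: np.ndarray
    summary: pd.DataFrame
    roi_table: pd.DataFrame
    config_hash: str
    log: dict = field(default_factory=dict)


def simulate_to_dir(
    out_dir,
    preset: str = "ne",
    geometry_preset: str = "ventricle_anterior",
    rows: int = 64,
    cols: int = 64,
    seed: int = 0,
    noise_sd: float = 0.0,
    vignette_strength: float = 0.0,
    bleedthrough_ca_to_vm: float = 0.0,
    total_duration: float = 120.0,
) -> RunConfig:
    """Render a synthetic recording, write it to ``out_dir``, return its config.

    Writes per-channel TIFF stacks (16-bit), the mask, default ROI file
    (the geometry's labelled regions), a ground-truth/metadata JSON sidecar,
    and ``config.json`` ready for :func:`run_pipeline`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geometry = synth.build_geometry(rows, cols, geometry_preset)
    schedule = synth.AcquisitionSchedule(total_duration=total_duration)
    bt = np.array([[1.0, bleedthrough_ca_to_vm], [0.0, 1.0]])
    channels = synth.ChannelModel(
        noise_sd=noise_sd, vignette_strength=vignette_strength, bleedthrough=bt
    )
    rec, bursts, truth = synth.render_recording(
        geometry, schedule, synth.preset_curves(preset), channels, seed=seed
    )

    def _quantize(stack):
        vals = np.clip(np.round(stack.values), 0, 65535).astype(np.uint16)
        return type(stack)(vals, stack.times, stack.pixel_pitch_mm)

    io.write_stack(_quantize(rec.cfp), out / "cfp.tif")
    io.write_stack(_quantize(rec.yfp), out / "yfp.tif")
    io.write_mask(geometry.mask, out / "mask.tif")
    io.write_rois(geometry.region_labels, out / "rois.json")
    vm_paths, ca_paths = [], []
    for k, (vm, ca) in enumerate(bursts):
        vm_paths.append(str(out / f"vm_{k:03d}.tif"))
        ca_paths.append(str(out / f"ca_{k:03d}.tif"))
        io.write_stack(_quantize(vm), vm_paths[-1])
        io.write_stack(_quantize(ca), ca_paths[-1])

    meta = {
        "preset": preset,
        "geometry_preset": geometry_preset,
        "seed": seed,
        "noise_sd": noise_sd,
        "heart_rate_true_bpm": truth.heart_rate_true.tolist(),
        "burst_times_s": truth.burst_times.tolist(),
        "fret_times_s": truth.fret_times.tolist(),
        "delta_fret_true": {k: v.tolist() for k, v in truth.delta_fret_true.items()},
        "focal_source": list(geometry.focal_source),
    }
    (out / "metadata.json").write_text(__import__("json").dumps(meta, indent=1))
    io.write_map(truth.activation_time, out / "truth_activation.tif")

    cfg = RunConfig(
        schedule=ScheduleConfig(total_duration=total_duration),
        paths=PathsConfig(
            cfp=str(out / "cfp.tif"),
            yfp=str(out / "yfp.tif"),
            mask=str(out / "mask.tif"),
            vm=vm_paths,
            ca=ca_paths,
            rois=str(out / "rois.json"),
        ),
        seed=seed,
    )
    (out / "config.json").write_text(cfg.model_dump_json(indent=1))
    return cfg


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, QuadmapError):
                raise type(exc)(f"stage {name!r}: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig, out_dir=None, n_beats: int | None = None) -> PipelineResult:
    """Run the full FRET + electrophysiology analysis described by ``config``.

    Returns one ΔFRET value per FRET frame (whole mask and per ROI) and one
    APD80/CaTD50/heart-rate triplet per burst, each burst paired with the
    immediately preceding FRET frame. When ``out_dir`` is given, maps are
    written as TIFF and tables as CSV (config hash embedded).
    """
    n_beats = config.n_beats if n_beats is None else n_beats
    chash = config.config_hash()

    with _stage("load"):
        config.check_paths()
        mask = io.read_mask(config.paths.mask)
        cfp = io.read_stack(config.paths.cfp)
        yfp = io.read_stack(config.paths.yfp)
        vm_stacks = [io.read_stack(p) for p in config.paths.vm]
        ca_stacks = [io.read_stack(p) for p in config.paths.ca]
        rois = (
            io.read_rois(config.paths.rois, mask.shape)
            if config.paths.rois
            else {}
        )

    with _stage("fret"):
        rec = FretRecording(cfp=cfp, yfp=yfp, mask=mask)
        movie = fret.compute_ratio(rec, config.baseline_window, config.yfp_floor)
        traces = {"whole heart": fret.roi_trace(movie, mask, "whole heart")}
        for label, roi in rois.items():
            traces[label] = fret.roi_trace(movie, roi, label)

    with _stage("electro"):
        apd_maps, catd_maps, rates = [], [], []
        for vm, ca in zip(vm_stacks, ca_stacks):
            prep_vm = electro.prepare_stack(
                vm, mask, config.polarity.get("vm", -1), config.tophat_window_ms
            )
            apd_maps.append(
                electro.duration_map(vm, mask, "APD80", n_beats, prepared=prep_vm)
            )
            catd_maps.append(
                electro.duration_map(
                    ca, mask, "CaTD50", n_beats,
                    polarity=config.polarity.get("ca", 1),
                    tophat_window_ms=config.tophat_window_ms,
                )
            )
            rates.append(prep_vm[2].heart_rate or np.nan)
        rates = np.asarray(rates, dtype=float)

    with _stage("summarize"):
        n_slots = min(len(vm_stacks), movie.delta.shape[0])
        slot_times = movie.times[:n_slots]
        rows = []
        for k in range(n_slots):
            rows.append(
                {
                    "slot": k,
                    "time_s": float(slot_times[k]),
                    "delta_fret": float(np.nanmean(movie.delta[k][movie.mask])),
                    "apd80_ms": float(np.nanmean(apd_maps[k].values)),
                    "catd50_ms": float(np.nanmean(catd_maps[k].values)),
                    "heart_rate_bpm": float(rates[k]),
                }
            )
        summary = pd.DataFrame(rows)

        roi_rows = []
        all_rois = {"whole heart": mask, **rois}
        for label, roi in all_rois.items():
            sel = np.asarray(roi, dtype=bool) & movie.mask
            if not sel.any():
                continue
            for k in range(n_slots):
                for metric, value in (
                    ("delta_fret", float(np.nanmean(movie.delta[k][sel]))),
                    ("apd80_ms", float(np.nanmean(apd_maps[k].values[sel]))),
                    ("catd50_ms", float(np.nanmean(catd_maps[k].values[sel]))),
                    ("heart_rate_bpm", float(rates[k])),
                ):
                    roi_rows.append(
                        {
                            "roi": label,
                            "slot": k,
                            "time_s": float(slot_times[k]),
                            "metric": metric,
                            "value": value,
                        }
                    )
        roi_table = pd.DataFrame(roi_rows)

    result = PipelineResult(
        ratio=movie,
        fret_traces=traces,
        apd_maps=apd_maps,
        catd_maps=catd_maps,
        heart_rates=rates,
        slot_times=slot_times,
        summary=summary,
        roi_table=roi_table,
        config_hash=chash,
        log={
            "version": __version__,
            "seed": config.seed,
            "n_beats": n_beats,
            "config_hash": chash,
            "n_slots": n_slots,
        },
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = f"# config_sha256={chash}\n# quadmap_version={__version__}\n# seed={config.seed}\n"
        for name, df in (("summary", summary), ("roi_table", roi_table)):
            with open(out / f"{name}.csv", "w") as fh:
                fh.write(header)
                df.to_csv(fh, index=False, float_format="%.9g", lineterminator="\n")
        for k in range(len(apd_maps)):
            io.write_map(apd_maps[k].values, out / f"apd80_{k:03d}.tif")
            io.write_map(catd_maps[k].values, out / f"catd50_{k:03d}.tif")
        for k in range(movie.delta.shape[0]):
            io.write_map(movie.delta[k], out / f"delta_fret_{k:03d}.tif")
    return result


def biphasic_metrics(
    times, values, n_baseline: int = 1, tolerance: float = 0.02
) -> tuple[float, float | None]:
    """Peak time and first post-peak return to within ``tolerance`` of baseline.

    ``baseline`` is the mean of the first ``n_baseline`` samples (the
    pre-stimulus slots). Returns ``(peak_time, recovery_time)`` with
    recovery None when the series never re-enters the tolerance band.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(values) < n_baseline + 2:
        raise AnalysisError("time course too short")
    baseline = values[:n_baseline].mean()
    i_peak = int(np.argmax(values))
    peak_time = float(times[i_peak])
    for j in range(i_peak + 1, len(values)):
        if abs(values[j] - baseline) <= tolerance * abs(baseline):
            return peak_time, float(times[j])
    return peak_time, None
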