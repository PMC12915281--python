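"""File formats: multi-page TIFF stacks with JSON sidecars, masks, and ROIs.

Stacks are written as multi-page TIFF (16-bit for raw counts, 32-bit float
for derived maps) with a ``<name>.json`` sidecar carrying per-frame
timestamps and pixel pitch, so a write/read round-trip is lossless for
16-bit data and exact to float32 precision for maps.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from skimage import draw

from .core import FrameStack
from .errors import FormatError


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_stack(stack: FrameStack, path) -> None:
    """Write a stack as multi-page TIFF plus a JSON timestamp sidecar.

    Integer-typed values are stored as uint16 (clipped), float values as
    float32.
    """
    path = Path(path)
    values = stack.values
    if np.issubdtype(values.dtype, np.integer):
        data = np.clip(values, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    else:
        data = values.astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "times_s": [float(t) for t in stack.times],
        "pixel_pitch_mm": stack.pixel_pitch_mm,
        "dtype": str(data.dtype),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_stack(path, expected_dtype=None, frame_interval_s: float | None = None) -> FrameStack:
    """Read a multi-page TIFF stack back into a :class:`FrameStack`.

    Timestamps come from the JSON sidecar, or from ``frame_interval_s`` when
    no sidecar exists.

    Raises
    ------
    FormatError
        For missing files, ragged or unreadable pages (the failing page
        index is named), dtype mismatches, or missing timestamps.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"stack not found: {path}")
    frames = []
    with tifffile.TiffFile(path) as tif:
        shape = None
        for i, page in enumerate(tif.pages):
            try:
                arr = page.asarray()
            except Exception as exc:  # corrupt page
                raise FormatError(f"{path}: cannot read page {i}: {exc}") from exc
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise FormatError(
                    f"{path}: ragged page {i}: shape {arr.shape} != {shape}"
                )
            frames.append(arr)
    if not frames:
        raise FormatError(f"{path}: no pages")
    values = np.stack(frames)
    if expected_dtype is not None and values.dtype != np.dtype(expected_dtype):
        raise FormatError(
            f"{path}: dtype {values.dtype} does not match expected {expected_dtype}"
        )

    sidecar = _sidecar_path(path)
    pitch = 0.1
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        times = np.asarray(meta["times_s"], dtype=float)
        pitch = float(meta.get("pixel_pitch_mm", pitch))
        if len(times) != len(frames):
            raise FormatError(
                f"{path}: sidecar has {len(times)} timestamps for {len(frames)} pages"
            )
    elif frame_interval_s is not None:
        times = np.arange(len(frames)) * float(frame_interval_s)
    else:
        raise FormatError(f"{path}: missing timestamps (no sidecar and no interval)")
    return FrameStack(values, times, pitch)


def write_map(map2d: np.ndarray, path, pixel_pitch_mm: float = 0.1) -> None:
    """Write a single 2-D map as float32 TIFF with a pitch sidecar."""
    tifffile.imwrite(Path(path), np.asarray(map2d, dtype=np.float32))
    _sidecar_path(path).write_text(json.dumps({"pixel_pitch_mm": pixel_pitch_mm}))


def read_map(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"map not found: {path}")
    return tifffile.imread(path)


def write_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(Path(path), np.asarray(mask, dtype=np.uint8))


def read_mask(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"mask not found: {path}")
    return tifffile.imread(path).astype(bool)


def read_rois(path, shape: tuple) -> dict[str, np.ndarray]:
    """Read ROI definitions from JSON into boolean grids.

    Each ROI is either ``{"pixels": [[r, c], ...]}`` or
    ``{"polygon": [[r, c], ...]}`` (vertices; filled by pixel-center
    rasterisation).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"ROI file not found: {path}")
    payload = json.loads(path.read_text())
    rois = {}
    for label, entry in payload.items():
        grid = np.zeros(shape, dtype=bool)
        if "pixels" in entry:
            pix = np.asarray(entry["pixels"], dtype=int)
            keep = (
                (pix[:, 0] >= 0) & (pix[:, 0] < shape[0])
                & (pix[:, 1] >= 0) & (pix[:, 1] < shape[1])
            )
            grid[pix[keep, 0], pix[keep, 1]] = True
        elif "polygon" in entry:
            poly = np.asarray(entry["polygon"], dtype=float)
            rr, cc = draw.polygon(poly[:, 0], poly[:, 1], shape=shape)
            grid[rr, cc] = True
        else:
            raise FormatError(f"ROI {label!r} needs 'pixels' or 'polygon'")
        rois[label] = grid
    return rois


def write_rois(rois: dict[str, np.ndarray], path) -> None:
    payload = {
        label: {"pixels": np.argwhere(np.asarray(grid, dtype=bool)).tolist()}
        for label, grid in rois.items()
    }
    Path(path).write_text(json.dumps(payload))
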