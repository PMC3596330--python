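"""On-disk formats: multi-page TIFF movies with a JSON metadata sidecar,
and ``time_ms,voltage_mV`` CSV traces.

The sidecar ``<name>.meta.json`` carries everything the analysis needs that
TIFF does not: ``sampling_interval_ms``, ``pixel_pitch_cm``,
``stim_times_ms``, an optional ``mask``, ``seed`` and, for synthetic
movies, the ``ground_truth`` block. Round trips are lossless (frames are
stored as float64).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .containers import INTRACELLULAR, OPTICAL, OpticalMovie, VoltageTrace
from .errors import FormatError, MetadataError

REQUIRED_META_KEYS = ("sampling_interval_ms", "pixel_pitch_cm")


def _meta_path(path: Path) -> Path:
    return path.parent / (path.stem + ".meta.json")


def write_movie(movie: OpticalMovie, path) -> Path:
    """Write ``path`` (TIFF stack) plus ``<stem>.meta.json``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, movie.frames.astype(np.float64), photometric="minisblack")
    meta = {
        "sampling_interval_ms": movie.sampling_interval_ms,
        "pixel_pitch_cm": movie.pixel_pitch_cm,
        "stim_times_ms": list(movie.stim_times_ms),
    }
    if not movie.mask.all():
        meta["mask"] = movie.mask.astype(int).tolist()
    if movie.ground_truth is not None:
        gt = dict(movie.ground_truth)
        fld = gt.get("activation_field_ms")
        if isinstance(fld, np.ndarray):
            gt["activation_field_ms"] = fld.tolist()
        meta["ground_truth"] = gt
        if "seed" in gt:
            meta["seed"] = gt["seed"]
    _meta_path(path).write_text(json.dumps(meta))
    return path


def read_movie(path) -> OpticalMovie:
    """Read a TIFF stack and its metadata sidecar into an
    :class:`~cardiomap.containers.OpticalMovie`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such movie: {path}")
    mpath = _meta_path(path)
    if not mpath.exists():
        raise MetadataError(
            f"missing metadata sidecar {mpath.name}; required keys: "
            + ", ".join(REQUIRED_META_KEYS)
        )
    meta = json.loads(mpath.read_text())
    missing = [k for k in REQUIRED_META_KEYS if k not in meta]
    if missing:
        raise MetadataError(f"metadata {mpath.name} missing required keys: {missing}")
    frames = tifffile.imread(path)
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.dtype == object:
        raise FormatError(f"{path.name}: pages have mismatched shapes")
    gt = meta.get("ground_truth")
    if gt is not None and "activation_field_ms" in gt:
        gt = dict(gt)
        gt["activation_field_ms"] = np.asarray(gt["activation_field_ms"], dtype=float)
    mask = meta.get("mask")
    return OpticalMovie(
        frames=frames.astype(float),
        sampling_interval_ms=meta["sampling_interval_ms"],
        pixel_pitch_cm=meta["pixel_pitch_cm"],
        mask=None if mask is None else np.asarray(mask, dtype=bool),
        stim_times_ms=list(meta.get("stim_times_ms", [])),
        ground_truth=gt,
    )


def write_trace(trace: VoltageTrace, path) -> Path:
    """Write a trace as ``time_ms,voltage_mV`` CSV (plus a sidecar with the
    stimulus times when present)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.column_stack([trace.times_ms, trace.samples])
    np.savetxt(path, data, delimiter=",", header="time_ms,voltage_mV", comments="")
    if trace.stim_times_ms or trace.modality != INTRACELLULAR:
        _meta_path(path).write_text(json.dumps({
            "stim_times_ms": list(trace.stim_times_ms),
            "modality": trace.modality,
        }))
    return path


def read_trace(path, stim_times_ms=None, modality: str | None = None) -> VoltageTrace:
    """Read a ``time_ms,voltage_mV`` CSV; the time column must be uniform."""
    path = Path(path)
    try:
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise FormatError(f"{path.name}: not a time_ms,voltage_mV CSV ({exc})") from exc
    if data.shape[1] < 2 or data.shape[0] < 2:
        raise FormatError(f"{path.name}: need two columns and >= 2 rows")
    t, v = data[:, 0], data[:, 1]
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise FormatError(f"{path.name}: time column is not uniformly sampled")
    mpath = _meta_path(path)
    if mpath.exists():
        meta = json.loads(mpath.read_text())
        if stim_times_ms is None:
            stim_times_ms = meta.get("stim_times_ms")
        if modality is None:
            modality = meta.get("modality")
    return VoltageTrace(
        samples=v,
        sampling_interval_ms=float(dt[0]),
        stim_times_ms=list(stim_times_ms or []),
        modality=modality or INTRACELLULAR,
    )
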