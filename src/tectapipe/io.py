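"""Readers and writers for the pipeline's on-disk formats.

Recordings travel as two-column CSV (t_seconds, voltage) with a JSON
sidecar holding the sampling rate; image stacks as multi-page TIFF
(z, y, x) with voxel sizes in a JSON sidecar; ground truth and results as
JSON.  Plain formats keep everything inspectable and round-trippable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError
from .synthetic import EventTruth, ImageStack, LFPRecording, TrueEvent

__all__ = [
    "write_recording",
    "read_recording",
    "write_stack",
    "read_stack",
    "write_truth",
    "read_truth",
]

log = logging.getLogger("tectapipe")

DEFAULT_Z_STEP_UM = 0.44  # confocal axial resolution assumed when missing


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_recording(rec: LFPRecording, path: str | Path) -> Path:
    """Write (t, v) CSV plus a JSON sidecar with fs/duration/label."""
    path = Path(path)
    df = pd.DataFrame({"t_seconds": rec.times, "voltage": rec.samples})
    df.to_csv(path, index=False)
    _sidecar(path).write_text(
        json.dumps(
            {"fs": rec.fs, "duration_s": rec.duration_s, "label": rec.label}
        )
    )
    return path


def read_recording(path: str | Path) -> LFPRecording:
    """Read a recording, checking sidecar fs against the time column (1%)."""
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FormatError(f"missing sidecar {side}")
    meta = json.loads(side.read_text())
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"unreadable recording {path}: {exc}") from exc
    if df.empty or df.shape[1] < 2:
        raise FormatError(f"{path} must have (t, v) columns and data rows")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: time column not strictly increasing")
    fs_obs = 1.0 / float(np.median(dt))
    fs = float(meta["fs"])
    if abs(fs_obs - fs) / fs > 0.01:
        raise FormatError(
            f"{path}: sidecar fs={fs} Hz but time step implies {fs_obs:.1f} Hz"
        )
    return LFPRecording(samples=v, fs=fs, label=str(meta.get("label", "")))


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a multi-page TIFF plus a JSON sidecar with voxel sizes."""
    path = Path(path)
    tifffile.imwrite(path, stack.voxels.astype(np.float32),
                     photometric="minisblack")
    _sidecar(path).write_text(
        json.dumps({"pixel_um": stack.pixel_um, "z_step_um": stack.z_step_um})
    )
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a TIFF stack; a missing sidecar falls back to a 0.44 um z-step
    and 1 um pixels with a logged warning."""
    path = Path(path)
    try:
        voxels = tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"unreadable TIFF {path}: {exc}") from exc
    if voxels.ndim == 2:
        voxels = voxels[None, ...]
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        pixel_um = float(meta.get("pixel_um", 1.0))
        z_step_um = float(meta.get("z_step_um", DEFAULT_Z_STEP_UM))
    else:
        log.warning(
            "%s: no metadata sidecar; assuming z-step %.2f um, 1 um pixels",
            path,
            DEFAULT_Z_STEP_UM,
        )
        pixel_um, z_step_um = 1.0, DEFAULT_Z_STEP_UM
    return ImageStack(voxels=voxels, pixel_um=pixel_um, z_step_um=z_step_um)


def write_truth(truth: EventTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_dict(), indent=2))
    return path


def read_truth(path: str | Path) -> EventTruth:
    data = json.loads(Path(path).read_text())
    return EventTruth(
        [
            TrueEvent(
                e["onset_s"], e["duration_s"], e["amp_factor"], e["has_hfo"]
            )
            for e in data["events"]
        ]
    )
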