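"""Reading and writing the pipeline's on-disk formats.

Images travel as multi-channel TIFF (planes = channels, or frames ×
channels for a time lapse) with a JSON sidecar carrying the pixel size,
channel roles and, for time lapses, per-frame timestamps. Manifests are
JSON; count, growth and dose tables are plain CSV handled with pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .core import SpindleImage, TimeLapse
from .synthetic_data import GroundTruthManifest


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def save_spindle_image(path: str | Path, image: SpindleImage) -> Path:
    """Write a multi-channel TIFF plus JSON sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(image.data, dtype=np.float32),
                     photometric="minisblack")
    sidecar = {
        "pixel_size_um": image.pixel_size_um,
        "channels": list(image.channels),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def load_spindle_image(path: str | Path) -> SpindleImage:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    sidecar = json.loads(_sidecar_path(path).read_text())
    return SpindleImage(data, tuple(sidecar["channels"]), float(sidecar["pixel_size_um"]))


def save_timelapse(path: str | Path, tl: TimeLapse) -> Path:
    """Write frames as a (T, C, rows, cols) TIFF with timestamps in the sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stack = np.stack([f.data for f in tl.frames]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {
        "pixel_size_um": tl.pixel_size_um,
        "channels": list(tl.frames[0].channels),
        "timestamps_s": [float(t) for t in tl.timestamps_s],
        "treatment_frame": tl.treatment_frame,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def load_timelapse(path: str | Path) -> TimeLapse:
    path = Path(path)
    stack = tifffile.imread(path).astype(float)
    sidecar = json.loads(_sidecar_path(path).read_text())
    channels = tuple(sidecar["channels"])
    px = float(sidecar["pixel_size_um"])
    timestamps = np.asarray(sidecar["timestamps_s"], dtype=float)
    frames = [SpindleImage(plane, channels, px, meta={"timestamp_s": float(t)})
              for plane, t in zip(stack, timestamps)]
    return TimeLapse(frames, timestamps, int(sidecar["treatment_frame"]))


def save_manifest(path: str | Path, manifest: GroundTruthManifest) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(manifest.to_json())
    return path


def load_manifest(path: str | Path) -> GroundTruthManifest:
    return GroundTruthManifest.from_json(Path(path).read_text())
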