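"""Reading and writing the pipeline's on-disk formats.

Image stacks and volumes travel as multi-page TIFF (via tifffile), scalar
metadata as JSON sidecars, ROI masks as integer-labelled single-page TIFF,
and metric tables as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .spectral import RoiSet, SpectralStack

__all__ = [
    "write_spectral_stack",
    "read_spectral_stack",
    "write_volume",
    "read_volume",
    "write_roi_labels",
    "read_roi_labels",
]


def write_spectral_stack(stack: SpectralStack, path: str | Path) -> Path:
    """Two-channel stack as interleaved multi-page TIFF + JSON sidecar."""
    path = Path(path)
    frames = np.stack([stack.channels[0], stack.channels[1]], axis=1)
    tifffile.imwrite(path, frames.reshape(-1, *stack.channels.shape[2:])
                     .astype(np.float32))
    meta = {
        "wavelengths_nm": list(stack.wavelengths_nm),
        "timestamps_s": stack.timestamps_s.tolist(),
        "baseline_window_s": list(stack.baseline_window_s),
        "interleaved": True,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))
    return path


def read_spectral_stack(path: str | Path) -> SpectralStack:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    raw = tifffile.imread(path).astype(float)
    nt = len(meta["timestamps_s"])
    frames = raw.reshape(nt, 2, *raw.shape[1:])
    channels = np.stack([frames[:, 0], frames[:, 1]])
    return SpectralStack(channels=channels,
                         timestamps_s=np.asarray(meta["timestamps_s"]),
                         baseline_window_s=tuple(meta["baseline_window_s"]),
                         wavelengths_nm=tuple(meta["wavelengths_nm"]))


def write_volume(volume: np.ndarray, path: str | Path,
                 metadata: dict | None = None) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(volume, dtype=np.float32))
    if metadata is not None:
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(metadata))
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    vol = tifffile.imread(path).astype(float)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return vol, meta


def write_roi_labels(rois: RoiSet, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, rois.labels.astype(np.int32))
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({str(k): v for k, v in rois.classes.items()}))
    return path


def read_roi_labels(path: str | Path) -> RoiSet:
    path = Path(path)
    labels = tifffile.imread(path).astype(int)
    classes = {int(k): v for k, v in json.loads(
        path.with_suffix(path.suffix + ".json").read_text()).items()}
    return RoiSet(labels=labels, classes=classes)
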