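"""Disk conventions: multi-page TIFF stacks with JSON sidecars, PNG masks.

Each stack is one TIFF per wavelength/condition plus a ``<stem>.json``
sidecar holding the sampling rate, condition, modulation and camera
descriptors, and seed, so a sequence round-trips losslessly (floats are
stored as 32-bit TIFF pages).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import tifffile

from .phantom_sim import FrameSequence, ModulationSpec

__all__ = ["save_sequence", "load_sequence", "save_mask", "load_mask"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_sequence(seq: FrameSequence, path) -> Path:
    """Write frames as a multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = seq.frames
    if frames.dtype not in (np.uint8, np.uint16):
        frames = frames.astype(np.float32)
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta = {
        "sampling_hz": seq.sampling_hz,
        "wavelength": seq.wavelength,
        "condition": seq.condition,
        "modulation": (
            dataclasses.asdict(seq.modulation) if seq.modulation else None
        ),
        "meta": {k: v for k, v in seq.meta.items() if _jsonable(v)},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def _jsonable(value) -> bool:
    try:
        json.dumps(value)
        return True
    except TypeError:
        return False


def load_sequence(path) -> FrameSequence:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads(_sidecar(path).read_text())
    modulation: Optional[ModulationSpec] = None
    if meta.get("modulation"):
        modulation = ModulationSpec(**meta["modulation"])
    return FrameSequence(
        frames=frames,
        sampling_hz=meta["sampling_hz"],
        wavelength=meta["wavelength"],
        condition=meta["condition"],
        modulation=modulation,
        meta=meta.get("meta", {}),
    )


def save_mask(mask: np.ndarray, path) -> Path:
    """Write a labeled mask as single-channel 8-bit PNG (labels <= 255)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mask = np.asarray(mask)
    if mask.max() > 255:
        raise ValueError("more than 255 labels cannot be stored as 8-bit PNG")
    iio.imwrite(path, mask.astype(np.uint8))
    return path


def load_mask(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))).astype(np.int32)
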