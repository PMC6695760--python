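"""Image containers and TIFF/CSV/JSON interchange.

Movies are time-ordered 2D frames with a physical pixel size and frame
interval; confocal volumes are z-ordered slices with a z-step. Both are
stored as multi-page TIFF with ImageJ-compatible metadata so the files open
with correct calibration in Fiji.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


@dataclass
class ImageStack:
    """A time-lapse movie: ``frames`` has shape (T, H, W)."""

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def save(self, path: str | Path) -> None:
        _write_stack(path, self.frames, self.pixel_size_um,
                     axes="TYX", finterval=self.frame_interval_s)

    @classmethod
    def load(cls, path: str | Path, pixel_size_um: float | None = None,
             frame_interval_s: float | None = None) -> "ImageStack":
        frames, px, interval = _read_stack(path)
        return cls(frames,
                   pixel_size_um if pixel_size_um is not None else (px or 0.1),
                   frame_interval_s if frame_interval_s is not None else (interval or 1.0))


@dataclass
class ZStack:
    """A confocal volume: ``slices`` has shape (Z, H, W), uniform z spacing."""

    slices: np.ndarray
    z_step_um: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3:
            raise ValueError("slices must be a (Z, H, W) array")
        if self.slices.shape[0] < 2:
            raise ValueError("a z-stack needs at least 2 slices")
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    def save(self, path: str | Path) -> None:
        _write_stack(path, self.slices, self.pixel_size_um,
                     axes="ZYX", spacing=self.z_step_um)

    @classmethod
    def load(cls, path: str | Path, z_step_um: float | None = None,
             pixel_size_um: float | None = None) -> "ZStack":
        slices, px, _ = _read_stack(path)
        spacing = None
        with tifffile.TiffFile(path) as tif:
            meta = tif.imagej_metadata or {}
            spacing = meta.get("spacing")
        return cls(slices,
                   z_step_um if z_step_um is not None else (spacing or 0.5),
                   pixel_size_um if pixel_size_um is not None else (px or 0.2))


def _write_stack(path, data, pixel_size_um, axes, finterval=None, spacing=None):
    data = np.asarray(data)
    if data.dtype not in (np.uint8, np.uint16, np.float32):
        data = data.astype(np.float32)
    meta = {"axes": axes, "unit": "um"}
    if finterval is not None:
        meta["finterval"] = finterval
    if spacing is not None:
        meta["spacing"] = spacing
    tifffile.imwrite(
        path, data, imagej=True,
        resolution=(1.0 / pixel_size_um, 1.0 / pixel_size_um),
        metadata=meta,
    )


def _read_stack(path):
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.imagej_metadata or {}
        interval = meta.get("finterval")
        px = None
        page = tif.pages[0]
        if "XResolution" in page.tags:
            num, den = page.tags["XResolution"].value
            if num:
                px = den / num
    if data.ndim == 2:
        data = data[None]
    return data, px, interval


def write_json(path: str | Path, obj) -> None:
    """JSON writer with stable key order (manifests must be reproducible)."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_table(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
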