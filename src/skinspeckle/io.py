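"""File I/O: speckle stacks, RGB patches, ROI tables, sidecar metadata.

Speckle stacks are stored as 8-bit multi-page TIFF (or a directory of
zero-padded, lexicographically ordered PNG/TIFF frames — the THSP depends on
frame order).  Patches are 8-bit PNG.  Every written artifact gets a JSON
sidecar with the generating parameters and seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .simulate import RGBPatch, SpeckleSequence

__all__ = [
    "write_speckle_stack",
    "read_speckle_stack",
    "write_patch",
    "read_patch",
    "read_roi_table",
    "load_rois",
    "write_sidecar",
]

_FRAME_SUFFIXES = {".png", ".tif", ".tiff"}


def write_sidecar(path: Path, params) -> Path:
    """Write simulation/acquisition parameters next to an image file."""
    meta = dataclasses.asdict(params) if dataclasses.is_dataclass(params) else dict(params)
    side = Path(path).with_suffix(Path(path).suffix + ".json")
    side.write_text(json.dumps(meta, indent=2, default=str))
    return side


def write_speckle_stack(seq: SpeckleSequence, path, params=None) -> Path:
    path = Path(path)
    if seq.frames.dtype != np.uint8:
        raise ValueError("only 8-bit stacks are written in v1")
    tifffile.imwrite(path, seq.frames, photometric="minisblack")
    meta = {"frame_rate": seq.frame_rate, "n_frames": seq.n_frames}
    if params is not None:
        meta["params"] = dataclasses.asdict(params)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))
    return path


def _read_frame_dir(path: Path) -> np.ndarray:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES)
    if len(files) < 2:
        raise FileNotFoundError(f"no frame sequence found in {path}")
    frames = [iio.imread(f) for f in files]
    return np.stack(frames)


def read_speckle_stack(path, frame_rate: float | None = None) -> SpeckleSequence:
    """Read a multi-page TIFF or a frame directory as a speckle sequence.

    ``frame_rate`` may come from the sidecar JSON written at save time;
    an explicit argument overrides it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"speckle stack not found: {path}")
    sidecar = Path(str(path) + ".json")
    if frame_rate is None and sidecar.exists():
        frame_rate = json.loads(sidecar.read_text()).get("frame_rate")
    if frame_rate is None:
        raise ValueError("frame_rate is required (no sidecar metadata found)")
    frames = _read_frame_dir(path) if path.is_dir() else tifffile.imread(path)
    frames = np.asarray(frames)
    if frames.ndim == 2:
        raise ValueError("a speckle stack needs multiple frames")
    if frames.ndim != 3:
        raise ValueError("expected monochrome frames (T, H, W)")
    if frames.dtype != np.uint8:
        raise ValueError("only 8-bit stacks are supported in v1")
    return SpeckleSequence(frames=frames, frame_rate=float(frame_rate))


def write_patch(patch: RGBPatch, path) -> Path:
    path = Path(path)
    iio.imwrite(path, patch.pixels)
    return path


def read_patch(path, label: str = "unknown") -> RGBPatch:
    pixels = np.asarray(iio.imread(path))
    if pixels.ndim == 2:
        pixels = np.repeat(pixels[:, :, None], 3, axis=2)
    if pixels.shape[2] == 4:
        pixels = pixels[:, :, :3]
    if pixels.dtype != np.uint8:
        raise ValueError("only 8-bit images are supported in v1")
    return RGBPatch(pixels=pixels, label=label)


def read_roi_table(path) -> pd.DataFrame:
    """ROI spec CSV with columns image_path, label, row, col, size."""
    table = pd.read_csv(path)
    required = {"image_path", "label", "row", "col", "size"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"ROI table is missing columns: {sorted(missing)}")
    return table


def load_rois(table: pd.DataFrame, base_dir=None) -> list[RGBPatch]:
    """Crop every ROI listed in the table from its source image."""
    base = Path(base_dir) if base_dir is not None else Path(".")
    patches = []
    for rec in table.itertuples():
        img_path = Path(rec.image_path)
        if not img_path.is_absolute():
            img_path = base / img_path
        pixels = np.asarray(iio.imread(img_path))
        if pixels.ndim == 2:
            pixels = np.repeat(pixels[:, :, None], 3, axis=2)
        r, c, s = int(rec.row), int(rec.col), int(rec.size)
        if r < 0 or c < 0 or r + s > pixels.shape[0] or c + s > pixels.shape[1]:
            raise ValueError(f"ROI at ({r},{c}) size {s} falls outside {img_path}")
        patches.append(
            RGBPatch(
                pixels=pixels[r : r + s, c : c + s, :3].astype(np.uint8),
                roi_origin=(r, c),
                label=str(rec.label),
            )
        )
    return patches
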