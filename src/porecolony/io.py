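"""Disk formats: masks and label maps as PNG, stacks as multi-page TIFF.

Conventions:

* pore masks — 8-bit single-channel PNG/TIFF, pore = 255, solid = 0
  (in memory: pore = 1/True, solid = 0/False);
* mapped masks (label maps) — 8-bit PNG with raw values 0 = solid/grain,
  1 = DEP, 2 = TP, plus a CSV of per-DEP records;
* image stacks — multi-page 16-bit TIFF, one file per channel, with a
  sidecar CSV of frame times (``frame,index_time_s``);
* velocity fields — two-channel 32-bit TIFF (u, v at cell centres, µm/s)
  plus a one-line CSV summary;
* ground truth and run manifests — JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .flow import VelocityField
from .geometry import PoreLabelMap, PoreMask
from .stacks import ImageStack

__all__ = [
    "write_mask",
    "read_mask",
    "write_label_map",
    "read_label_map",
    "write_stack",
    "read_stack",
    "write_velocity",
    "write_dep_records",
    "write_json",
    "read_yaml",
]


def write_mask(path: str | Path, mask: PoreMask) -> None:
    img = np.where(mask.grid, 255, 0).astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        iio.imwrite(path, img)


def read_mask(path: str | Path, pixel_size: float) -> PoreMask:
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    return PoreMask(grid=img > 127, pixel_size=pixel_size)


def write_label_map(path: str | Path, lmap: PoreLabelMap) -> None:
    iio.imwrite(Path(path), lmap.grid.astype(np.uint8))


def read_label_map(path: str | Path, pixel_size: float) -> PoreLabelMap:
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    return PoreLabelMap(grid=img.astype(np.uint8), pixel_size=pixel_size)


def write_stack(path: str | Path, stack: ImageStack) -> None:
    path = Path(path)
    frames = stack.frames
    if frames.dtype != np.uint16:
        frames = np.clip(frames, 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, frames, photometric="minisblack")
    sidecar = path.with_suffix(".times.csv")
    pd.DataFrame(
        {"frame": np.arange(stack.n_frames), "index_time_s": stack.times}
    ).to_csv(sidecar, index=False)


def read_stack(path: str | Path, channel: str, pixel_size: float) -> ImageStack:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = path.with_suffix(".times.csv")
    if sidecar.exists():
        times = pd.read_csv(sidecar)["index_time_s"].to_numpy(dtype=float)
    else:
        times = np.arange(len(frames), dtype=float)
    return ImageStack(frames=frames, times=times, channel=channel, pixel_size=pixel_size)


def write_velocity(path: str | Path, field: VelocityField, shear: float | None = None) -> None:
    path = Path(path)
    uv = np.stack([field.u_cell, field.v_cell]).astype(np.float32)
    tifffile.imwrite(path, uv, photometric="minisblack")
    summary = {
        "u_m": field.u_m,
        "divergence_max": field.divergence_max,
    }
    if shear is not None:
        summary["shear_rate"] = shear
    pd.DataFrame([summary]).to_csv(path.with_suffix(".summary.csv"), index=False)


def write_dep_records(path: str | Path, lmap: PoreLabelMap) -> None:
    rows = []
    for reg in lmap.dep_regions:
        ent = reg.entrance_pixels
        rows.append(
            {
                "dep_id": reg.dep_id,
                "entrance_x": float(ent[1].mean()) if len(ent[1]) else np.nan,
                "entrance_y": float(ent[0].mean()) if len(ent[0]) else np.nan,
                "depth_mm": reg.depth_mm,
                "area_px": reg.area_px,
            }
        )
    pd.DataFrame(
        rows, columns=["dep_id", "entrance_x", "entrance_y", "depth_mm", "area_px"]
    ).to_csv(path, index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, cls=_NumpyEncoder))


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
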