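"""Reading and writing of volumes (multi-page TIFF + JSON sidecar) and traces (CSV)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import VoxelVolume

__all__ = [
    "write_volume",
    "read_volume",
    "write_trace_csv",
    "read_trace_csv",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(volume: VoxelVolume, path, dtype: str = "uint16") -> Path:
    """Write a volume as a multi-page TIFF (z-pages) plus a JSON sidecar.

    Integer export clips to the 16-bit range; float32 export is lossless
    and used for intermediates (PSFs, deconvolved volumes).
    """
    path = Path(path)
    data = volume.data
    if dtype == "uint16":
        out = np.clip(np.rint(data), 0, 65535).astype(np.uint16)
    elif dtype == "float32":
        out = data.astype(np.float32)
    else:
        raise ValueError(f"unsupported export dtype {dtype!r}")
    tifffile.imwrite(path, out, photometric="minisblack")
    sidecar = {
        "voxel_size_nm": list(volume.voxel_size),
        "axes": "ZYX",
        "dtype": dtype,
        "meta": _jsonable(volume.meta),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    if volume.fibre_mask is not None:
        tifffile.imwrite(path.with_name(path.stem + "_fibre_mask.tif"),
                         volume.fibre_mask.astype(np.uint8), photometric="minisblack")
    return path


def read_volume(path) -> VoxelVolume:
    """Read a TIFF volume; voxel size and metadata come from the sidecar."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    voxel_size = (90.0, 90.0, 150.0)
    meta: dict = {}
    sc = _sidecar_path(path)
    if sc.exists():
        sidecar = json.loads(sc.read_text())
        voxel_size = tuple(sidecar.get("voxel_size_nm", voxel_size))
        meta = sidecar.get("meta", {})
    mask_path = path.with_name(path.stem + "_fibre_mask.tif")
    fibre_mask = tifffile.imread(mask_path).astype(bool) if mask_path.exists() else None
    return VoxelVolume(data=data.astype(np.float64), voxel_size=voxel_size,
                       fibre_mask=fibre_mask, meta=meta)


def write_trace_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_trace_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"time_s", "F"}
    if not required.issubset(df.columns):
        raise ValueError(f"trace CSV must have columns {sorted(required)}")
    return df


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
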