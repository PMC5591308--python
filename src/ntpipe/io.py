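"""Reading and writing pipeline artifacts.

Images travel as multi-page TIFF (grayscale, 16-bit unsigned by default)
with a JSON or YAML sidecar carrying acquisition metadata (pixel size,
frame rate, scan geometry, stimulus frame, seed); tables as CSV via
pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from ntpipe.deskew import DiagonalStack, Volume


def write_stack(path: str | Path, data: np.ndarray, meta: dict | None = None, dtype=np.uint16) -> Path:
    """Write an image stack as multi-page TIFF plus a JSON sidecar.

    Float data is scaled to the full dtype range when it would otherwise
    be clipped; the scale factor is recorded in the sidecar.
    """
    path = Path(path)
    arr = np.asarray(data)
    scale = 1.0
    if np.issubdtype(dtype, np.integer):
        top = np.iinfo(dtype).max
        amax = float(arr.max()) if arr.size else 0.0
        if amax > 0 and (np.issubdtype(arr.dtype, np.floating) or amax > top):
            scale = top / amax  # use the full dynamic range
        arr = np.clip(np.round(arr * scale), 0, top).astype(dtype)
    tifffile.imwrite(path, arr, photometric="minisblack")
    sidecar = dict(meta or {})
    sidecar["intensity_scale"] = scale
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=_jsonable))
    return path


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_meta(path: str | Path) -> dict:
    """Read a JSON or YAML metadata sidecar."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def read_stack(path: str | Path, meta_path: str | Path | None = None) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF and its sidecar; undoes the stored scale."""
    path = Path(path)
    if meta_path is None:
        meta_path = path.with_suffix(".json")
    meta = read_meta(meta_path) if Path(meta_path).exists() else {}
    arr = tifffile.imread(path).astype(float)
    scale = float(meta.get("intensity_scale", 1.0))
    if scale != 1.0:
        arr = arr / scale
    return arr, meta


def read_diagonal_stack(path: str | Path, meta_path: str | Path | None = None) -> DiagonalStack:
    arr, meta = read_stack(path, meta_path)
    return DiagonalStack(
        slices=arr,
        voxel_xy=meta.get("voxel_xy"),
        scan_step=meta.get("scan_step"),
        scan_angle=meta.get("scan_angle"),
        origin=tuple(meta.get("origin", (0.0, 0.0, 0.0))),
        meta=meta,
    )


def write_volume(path: str | Path, vol: Volume) -> Path:
    return write_stack(
        path,
        vol.voxels,
        meta={
            "spacing_zyx_um": list(vol.spacing),
            "origin_um": list(vol.origin),
            **{k: v for k, v in vol.provenance.items() if _is_plain(v)},
        },
    )


def read_volume(path: str | Path, meta_path: str | Path | None = None) -> Volume:
    arr, meta = read_stack(path, meta_path)
    return Volume(
        voxels=arr,
        spacing=tuple(meta["spacing_zyx_um"]),
        origin=tuple(meta.get("origin_um", (0.0, 0.0, 0.0))),
        provenance=meta,
    )


def _is_plain(v) -> bool:
    return isinstance(v, (str, int, float, bool, type(None)))


def read_seeds_csv(path: str | Path):
    """Seed pairs for tracing: columns path_id, xa, ya, za, xb, yb, zb (um)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"path_id", "xa", "ya", "za", "xb", "yb", "zb"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"seeds file missing columns: {sorted(missing)}")
    return df


def read_rois_json(path: str | Path) -> tuple[dict, list]:
    """ROI polygons with ids plus a connectivity table.

    Format: {"rois": {id: [[row, col], ...]}, "connections":
    [[roi_a, roi_b], ...]}.
    """
    spec = read_meta(path)
    rois = {k: np.asarray(v, dtype=float) for k, v in spec.get("rois", {}).items()}
    return rois, [tuple(c) for c in spec.get("connections", [])]
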