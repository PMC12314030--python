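"""Raster and table I/O.

Layers are stored as single-band TIFFs with the GDAL nodata convention
(ASCII tag 42113) so they open in GIS stacks; layer metadata (transform
state, uncertainty dialect, provenance) rides in the ImageDescription tag
as JSON.  Zone lookups and result tables are plain CSV.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import tifffile

from .layers import CellMask, RichnessLayer, UncertaintyLayer, ZoneMap

GDAL_NODATA_TAG = 42113
DEFAULT_NODATA = -9999.0


def _write_array(path, values: np.ndarray, nodata: float, description: dict) -> None:
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise ValueError("only single-band 2-D rasters are supported")
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.where(np.isfinite(arr), arr, nodata)
    tifffile.imwrite(
        path,
        arr,
        description=json.dumps(description, sort_keys=True),
        extratags=[(GDAL_NODATA_TAG, "s", 0, str(nodata), False)],
    )


def _read_array(path) -> tuple[np.ndarray, float | None, dict]:
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise ValueError(f"{path}: multi-page rasters are not supported")
        page = tif.pages[0]
        arr = page.asarray()
        if arr.ndim != 2:
            raise ValueError(f"{path}: multi-band rasters are not supported")
        nodata = None
        tag = page.tags.get(GDAL_NODATA_TAG)
        if tag is not None:
            nodata = float(tag.value)
        meta: dict = {}
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, json.JSONDecodeError):
                meta = {}
    if np.issubdtype(arr.dtype, np.floating):
        if nodata is None and np.isnan(arr).any():
            raise ValueError(f"{path}: NaNs present but no nodata tag")
        if nodata is not None:
            arr = np.where(arr == nodata, np.nan, arr)
    return arr, nodata, meta


def write_raster(layer, path, nodata: float = DEFAULT_NODATA) -> Path:
    """Write a RichnessLayer / UncertaintyLayer / CellMask / ZoneMap to TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(layer, RichnessLayer):
        desc = {"kind": "richness", "transform": layer.transform, "provenance": layer.provenance}
        _write_array(path, layer.values.astype(np.float64), nodata, desc)
    elif isinstance(layer, UncertaintyLayer):
        desc = {"kind": "uncertainty", "dialect": layer.dialect, "provenance": layer.provenance}
        _write_array(path, layer.values.astype(np.float64), nodata, desc)
    elif isinstance(layer, CellMask):
        desc = {"kind": "mask", "provenance": layer.provenance}
        tifffile.imwrite(path, layer.retained.astype(np.uint8),
                         description=json.dumps(desc, sort_keys=True))
    elif isinstance(layer, ZoneMap):
        desc = {"kind": "zones"}
        _write_array(path, layer.zones.astype(np.int32), -1, desc)
    else:
        raise TypeError(f"cannot write object of type {type(layer).__name__}")
    return path


def read_raster(path):
    """Read a raster written by :func:`write_raster`, restoring its type."""
    arr, nodata, meta = _read_array(path)
    kind = meta.get("kind")
    if kind == "richness":
        return RichnessLayer(arr, transform=meta.get("transform", "raw"),
                             provenance=meta.get("provenance", ""))
    if kind == "uncertainty":
        return UncertaintyLayer(arr, dialect=meta.get("dialect", "sd"),
                                provenance=meta.get("provenance", ""))
    if kind == "mask":
        return CellMask(arr.astype(bool), provenance=list(meta.get("provenance", [])))
    if kind == "zones":
        raise ValueError("zone rasters need their lookup CSV; use read_zonemap")
    # untagged file: return the bare array with NaN nodata applied
    return arr


def write_zonemap(zonemap: ZoneMap, raster_path, lookup_path) -> None:
    write_raster(zonemap, raster_path)
    lookup_path = Path(lookup_path)
    lookup_path.parent.mkdir(parents=True, exist_ok=True)
    with open(lookup_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ecoregion_id", "biome_id"])
        for eco in sorted(zonemap.biome_of):
            writer.writerow([eco, zonemap.biome_of[eco]])


def read_zonemap(raster_path, lookup_path) -> ZoneMap:
    arr, _, meta = _read_array(raster_path)
    if meta.get("kind") != "zones":
        raise ValueError(f"{raster_path} is not a zone raster")
    lookup: dict[int, int] = {}
    with open(lookup_path, newline="") as fh:
        for row in csv.DictReader(fh):
            lookup[int(row["ecoregion_id"])] = int(row["biome_id"])
    return ZoneMap(arr.astype(np.int64), lookup)
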