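"""File formats: multi-page TIFF fields with JSON sidecars, plate maps,
feature tables with a compartment-tag schema sidecar.

Fields are stored losslessly as 16-bit multi-page TIFF, one page per
channel, with a JSON sidecar recording channel order, pixel size and
provenance (seed, phenotype) so that channel access downstream stays
name-based.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import FieldImage


def write_field(image: FieldImage, path, extra_meta: dict | None = None) -> Path:
    """Write a field as multi-page TIFF plus a ``.json`` sidecar."""
    path = Path(path)
    names = list(image.channels)
    stack = np.stack([np.asarray(image.channels[n], dtype=np.uint16) for n in names])
    tifffile.imwrite(path, stack)
    meta = {
        "channels": names,
        "pixel_size_um": image.pixel_size_um,
        "field_id": image.field_id,
        "well_id": image.well_id,
        "site": image.site,
    }
    if extra_meta:
        meta.update(_jsonable(extra_meta))
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_field(path) -> FieldImage:
    """Read a field written by :func:`write_field`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    stack = tifffile.imread(path)
    channels = {name: stack[i] for i, name in enumerate(meta["channels"])}
    return FieldImage(
        channels=channels,
        pixel_size_um=meta["pixel_size_um"],
        field_id=meta.get("field_id", path.stem),
        well_id=meta.get("well_id", "A01"),
        site=meta.get("site", 1),
    )


def write_feature_table(table: pd.DataFrame, path, tags: dict | None = None) -> Path:
    """Write a feature table (Parquet by suffix, else CSV) with a tag sidecar."""
    path = Path(path)
    if path.suffix == ".parquet":
        table.to_parquet(path, index=False)
    else:
        table.to_csv(path, index=False)
    if tags is not None:
        path.with_suffix(".schema.json").write_text(json.dumps(tags, indent=1))
    return path


def read_feature_table(path) -> tuple[pd.DataFrame, dict | None]:
    path = Path(path)
    if path.suffix == ".parquet":
        table = pd.read_parquet(path)
    else:
        table = pd.read_csv(path)
    sidecar = path.with_suffix(".schema.json")
    tags = json.loads(sidecar.read_text()) if sidecar.exists() else None
    return table, tags


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
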