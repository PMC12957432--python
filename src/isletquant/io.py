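"""Interchange formats: CSV cell tables and GeoJSON annotation geometry.

Cell tables are CSV with one row per detected cell (``cell_id``, ``x_um``,
``y_um``, one intensity column per marker, plus any phenotype/assignment
columns added downstream).  Annotations travel as GeoJSON
FeatureCollections whose coordinates are micrometres on the section frame
(origin lower-left; not a geographic CRS), with properties ``islet_id``,
``area_um2`` and ``kind`` in {"islet", "periphery"}.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .config import MARKERS
from .geometry import IsletAnnotation, PeripheryBand

REQUIRED_CELL_COLUMNS = ("cell_id", "x_um", "y_um")


def read_cells(path, required_markers: tuple[str, ...] = MARKERS) -> pd.DataFrame:
    """Read and schema-validate a cell table.

    Fails naming the offending column/row on: missing required columns,
    duplicate cell ids, or non-finite coordinates.
    """
    cells = pd.read_csv(path)
    for col in REQUIRED_CELL_COLUMNS:
        if col not in cells.columns:
            raise ValueError(f"cell table {path} is missing required column {col!r}")
    for marker in required_markers:
        if marker not in cells.columns:
            raise ValueError(f"cell table {path} is missing intensity column {marker!r}")
    dup = cells["cell_id"][cells["cell_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate cell_id {dup.iloc[0]!r} in {path}")
    for col in ("x_um", "y_um"):
        values = pd.to_numeric(cells[col], errors="coerce")
        bad = ~np.isfinite(values.to_numpy(dtype=float))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"non-numeric {col} at row {row} of {path}")
        cells[col] = values.astype(float)
    return cells


def write_cells(cells: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cells.to_csv(path, index=False)


def _feature(geom, properties: dict) -> dict:
    return {"type": "Feature", "geometry": mapping(geom), "properties": properties}


def write_annotations(
    path, islets: list[IsletAnnotation], bands: list[PeripheryBand] | None = None
) -> None:
    """Write islets (and optionally their bands) as one FeatureCollection."""
    features = [
        _feature(i.polygon, {"islet_id": i.islet_id, "area_um2": i.area, "kind": "islet"})
        for i in islets
    ]
    for b in bands or []:
        features.append(
            _feature(b.region, {"islet_id": b.islet_id, "area_um2": b.area, "kind": "periphery"})
        )
    collection = {
        "type": "FeatureCollection",
        "crs_note": "coordinates in µm, origin lower-left",
        "features": features,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(collection, fh)


def read_annotations(path) -> tuple[list[IsletAnnotation], list[PeripheryBand]]:
    """Read a FeatureCollection back into islets and periphery bands.

    Features default to kind "islet"; multipolygon periphery features are
    kept as multipolygons (their area is the summed part area).  Non-polygon
    geometries or features without an ``islet_id`` are an error.
    """
    with open(path) as fh:
        collection = json.load(fh)
    islets: list[IsletAnnotation] = []
    bands: list[PeripheryBand] = []
    for k, feat in enumerate(collection.get("features", [])):
        geom = shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(
                f"feature {k} in {path} has geometry {geom.geom_type}; expected (Multi)Polygon"
            )
        props = feat.get("properties") or {}
        if "islet_id" not in props:
            raise ValueError(f"feature {k} in {path} lacks the islet_id property")
        islet_id = int(props["islet_id"])
        kind = props.get("kind", "islet")
        if kind == "periphery":
            bands.append(PeripheryBand(islet_id=islet_id, region=geom))
        else:
            if geom.geom_type != "Polygon":
                raise ValueError(f"islet feature {k} in {path} must be a simple Polygon")
            islets.append(IsletAnnotation(islet_id=islet_id, polygon=geom))
    return islets, bands
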