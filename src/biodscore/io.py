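"""Readers and writers for the external formats.

Conventions: coordinates in files are always µm (columns x_um, y_um),
caliper dimensions mm (length_mm, width_mm), volumes mm³, densities
cells/mm².  CSV is comma-separated, dot-decimal, UTF-8, header required.
The internal frame is Cartesian (y up); image-style exports with y
increasing downward are converted with ``y_down=True`` on the readers.

Boundaries travel as GeoJSON Polygon/MultiPolygon (in µm) or as a CSV
vertex list with columns ring_id, vertex_order, x_um, y_um (ring 0 is the
outer ring, further rings are holes).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .geometry import Polygon2D, ZoneMap
from .growth import tumor_volume

__all__ = [
    "read_boundary",
    "write_boundary",
    "read_cells",
    "write_cells",
    "read_growth",
    "write_zonemap",
    "write_json",
]

GROWTH_COLUMNS = ["animal", "group", "day", "length_mm", "width_mm"]


def read_boundary(path, y_down: bool = False) -> Polygon2D:
    """Read a boundary polygon from GeoJSON or the CSV vertex dialect.

    GeoJSON may be a bare geometry, a Feature, or a FeatureCollection; a
    MultiPolygon keeps the largest part with a warning.  Open rings (first
    vertex not repeated last) are accepted and auto-closed.
    """
    path = Path(path)
    if path.suffix.lower() in (".json", ".geojson"):
        poly = _boundary_from_geojson(json.loads(path.read_text()))
    else:
        poly = _boundary_from_csv(path)
    if y_down:
        poly = Polygon2D(
            outer_ring=np.column_stack([poly.outer_ring[:, 0], -poly.outer_ring[:, 1]]),
            holes=tuple(np.column_stack([h[:, 0], -h[:, 1]]) for h in poly.holes),
        )
    return poly


def _boundary_from_geojson(obj: dict) -> Polygon2D:
    if obj.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in obj["features"]]
    elif obj.get("type") == "Feature":
        geoms = [shape(obj["geometry"])]
    else:
        geoms = [shape(obj)]
    polys = []
    for g in geoms:
        if g.geom_type == "Polygon":
            polys.append(g)
        elif g.geom_type == "MultiPolygon":
            polys.extend(g.geoms)
        else:
            raise ValueError(f"unsupported geometry type {g.geom_type!r}")
    if not polys:
        raise ValueError("no polygon found in GeoJSON input")
    if len(polys) > 1:
        warnings.warn(
            f"{len(polys)} polygons in input; keeping the largest by area",
            stacklevel=3,
        )
        polys.sort(key=lambda p: p.area, reverse=True)
    g = polys[0]
    return Polygon2D(
        outer_ring=np.asarray(g.exterior.coords),
        holes=tuple(np.asarray(r.coords) for r in g.interiors),
    )


def _boundary_from_csv(path: Path) -> Polygon2D:
    df = pd.read_csv(path)
    required = {"ring_id", "vertex_order", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"boundary CSV is missing columns: {sorted(missing)}")
    rings = {}
    for rid, ring in df.sort_values("vertex_order").groupby("ring_id"):
        rings[rid] = ring[["x_um", "y_um"]].to_numpy(dtype=float)
    outer_id = min(rings)
    holes = tuple(rings[k] for k in sorted(rings) if k != outer_id)
    return Polygon2D(outer_ring=rings[outer_id], holes=holes)


def write_boundary(boundary: Polygon2D, path) -> None:
    """Write a boundary as a GeoJSON Polygon (rings closed, µm)."""
    from shapely.geometry import Polygon as _SP

    geom = _SP(boundary.outer_ring, [h for h in boundary.holes])
    Path(path).write_text(json.dumps(mapping(geom)))


def read_cells(path, y_down: bool = False) -> pd.DataFrame:
    """Read a cell coordinate table (x_um, y_um, marker)."""
    df = pd.read_csv(path)
    missing = {"x_um", "y_um", "marker"} - set(df.columns)
    if missing:
        raise ValueError(f"cells CSV is missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(df[["x_um", "y_um"]].to_numpy(dtype=float))):
        raise ValueError("non-finite cell coordinates")
    if y_down:
        df = df.assign(y_um=-df["y_um"])
    return df


def write_cells(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def read_growth(path) -> pd.DataFrame:
    """Read a long-format caliper study and derive volumes.

    Required columns: animal, group, day, length_mm, width_mm (genotype
    optional, default "wildtype").  Rows with width > length are rejected
    with their row numbers — length is defined as the longest dimension.
    A provided volume_mm3 column is cross-checked against (L·W²)/2 and a
    warning issued when any value disagrees by more than 1%.
    """
    df = pd.read_csv(path)
    missing = set(GROWTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"growth CSV is missing columns: {sorted(missing)}")
    bad = df.index[df["width_mm"] > df["length_mm"]].tolist()
    if bad:
        raise ValueError(
            f"width exceeds length in rows {bad}; length must be the longest dimension"
        )
    if "genotype" not in df.columns:
        df["genotype"] = "wildtype"
    v = tumor_volume(df["length_mm"].to_numpy(), df["width_mm"].to_numpy())
    if "volume_mm3" in df.columns:
        provided = df["volume_mm3"].to_numpy(dtype=float)
        rel = np.abs(provided - v) / np.maximum(v, 1e-12)
        if np.any(rel > 0.01):
            warnings.warn(
                f"{int((rel > 0.01).sum())} provided volumes disagree with "
                "(L*W^2)/2 by more than 1%; recomputed values are used",
                stacklevel=2,
            )
    df["volume_mm3"] = v
    return df


def write_zonemap(zonemap: ZoneMap, out_dir, stem: str = "zonemap") -> dict:
    """Write the zone label image (PNG) plus its JSON sidecar.

    The PNG stores the raw zone indices 0..K as 8-bit labels, flipped to
    image orientation (row 0 = top).  The sidecar carries everything needed
    to interpret it: origin, pixel size, thresholds and zone areas.
    """
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    png_path = out_dir / f"{stem}.png"
    Image.fromarray(zonemap.zone[::-1].astype(np.uint8), mode="L").save(png_path)
    sidecar = {
        "origin_um": list(zonemap.mask.origin),
        "pixel_size_um": zonemap.mask.pixel_size,
        "n_zones": zonemap.n_zones,
        "depth_thresholds_um": [float(t) for t in zonemap.depth_thresholds],
        "zone_areas_mm2": [float(a) for a in zonemap.zone_areas_mm2],
        "orientation": "png row 0 is the top (largest y)",
    }
    json_path = out_dir / f"{stem}.json"
    write_json(sidecar, json_path)
    return {"png": str(png_path), "json": str(json_path)}


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
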