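"""Grid-cell community matrices from range polygons, and per-cell PD maps.

Species range polygons (WGS84, decimal degrees) are rasterized onto a
regular lon/lat grid anchored at multiples of the resolution (cells are
half-open rectangles ``[x, x+res) x [y, y+res)``, indexed by their SW
corner).  A species is present in a cell when its polygon intersects the
cell with nonzero area (the default; a centroid-in-polygon rule is also
available).  No equal-area correction is applied: everything stays in
decimal degrees.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Tuple

import pandas as pd
from shapely.geometry import box, shape, Point
from shapely.geometry.base import BaseGeometry
from shapely.validation import explain_validity

from .diversity import subset_pd
from .treeio import TimeTree

__all__ = [
    "rasterize_ranges",
    "pd_per_cell",
    "export_map",
    "read_ranges_geojson",
    "GridCellPD",
]

Cell = Tuple[float, float]  # SW corner (lon, lat)

_AREA_EPS = 1e-12  # squared degrees; boundary-only contact is not presence


@dataclass
class GridCellPD:
    cell: Cell
    richness: int
    pd: float


def _validate_polygon(species: str, geom: BaseGeometry) -> None:
    if not geom.is_valid:
        raise ValueError(
            f"invalid range polygon for {species!r}: {explain_validity(geom)}"
        )
    minx, _, maxx, _ = geom.bounds
    if minx < -180.0 or maxx > 180.0:
        raise ValueError(
            f"range polygon for {species!r} has longitudes outside [-180, 180]"
        )


def rasterize_ranges(
    polygons: Mapping[str, BaseGeometry],
    resolution: float = 1.0,
    rule: str = "intersect",
) -> pd.DataFrame:
    """Presence/absence community matrix from species range polygons.

    Returns a DataFrame indexed by (lon, lat) SW cell corners with one 0/1
    column per species; cells occupied by no species are omitted.

    ``rule`` is ``"intersect"`` (presence iff the polygon overlaps the cell
    with nonzero area) or ``"centroid"`` (presence iff the cell's centroid
    falls inside the polygon).
    """
    if resolution <= 0 or abs(360.0 / resolution - round(360.0 / resolution)) > 1e-9:
        raise ValueError("resolution must be positive and divide 360 evenly")
    if rule not in ("intersect", "centroid"):
        raise ValueError(f"unknown presence rule: {rule!r}")
    presences: Dict[Cell, set] = {}
    for species, geom in polygons.items():
        _validate_polygon(species, geom)
        parts = list(getattr(geom, "geoms", [geom]))
        for part in parts:
            minx, miny, maxx, maxy = part.bounds
            i0 = math.floor(minx / resolution)
            i1 = math.ceil(maxx / resolution)
            j0 = math.floor(miny / resolution)
            j1 = math.ceil(maxy / resolution)
            for i in range(i0, i1 + 1):
                for j in range(j0, j1 + 1):
                    x, y = i * resolution, j * resolution
                    if rule == "intersect":
                        cell_geom = box(x, y, x + resolution, y + resolution)
                        hit = part.intersection(cell_geom).area > _AREA_EPS
                    else:
                        hit = part.contains(Point(x + resolution / 2, y + resolution / 2))
                    if hit:
                        presences.setdefault((x, y), set()).add(species)
    if not presences:
        raise ValueError("no cell contains any species")
    species_order = sorted(polygons)
    cells = sorted(presences)
    data = {
        sp: [1 if sp in presences[c] else 0 for c in cells] for sp in species_order
    }
    index = pd.MultiIndex.from_tuples(cells, names=["lon", "lat"])
    return pd.DataFrame(data, index=index)


def pd_per_cell(
    comm: pd.DataFrame, tree: TimeTree, include_root: bool = True
) -> List[GridCellPD]:
    """Faith's PD and species richness for every cell of a community matrix."""
    missing = sorted(set(comm.columns) - set(tree.tip_labels))
    if missing:
        raise ValueError(f"species absent from the tree: {missing}")
    out = []
    pd_cache: Dict[frozenset, float] = {}
    for cell, row in comm.iterrows():
        present = frozenset(comm.columns[row.values.astype(bool)])
        if not present:
            out.append(GridCellPD(cell, 0, 0.0))
            continue
        if present not in pd_cache:
            pd_cache[present] = subset_pd(tree, present, include_root=include_root)
        out.append(GridCellPD(cell, len(present), pd_cache[present]))
    return out


def export_map(cells: List[GridCellPD], path, format: str = "csv") -> None:
    """Write per-cell PD/richness as CSV (lon,lat,richness,PD_Ma) or GeoJSON
    (one 1-cell polygon feature per grid cell, same properties)."""
    if not cells:
        raise ValueError("no cells to export")
    if format == "csv":
        df = pd.DataFrame(
            {
                "lon": [c.cell[0] for c in cells],
                "lat": [c.cell[1] for c in cells],
                "richness": [c.richness for c in cells],
                "PD_Ma": [c.pd for c in cells],
            }
        )
        df.to_csv(path, index=False)
    elif format == "geojson":
        res = _infer_resolution(cells)
        features = []
        for c in cells:
            x, y = c.cell
            ring = [[x, y], [x + res, y], [x + res, y + res], [x, y + res], [x, y]]
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {
                        "lon": x,
                        "lat": y,
                        "richness": c.richness,
                        "PD_Ma": c.pd,
                    },
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)
    else:
        raise ValueError(f"unsupported format: {format!r}")


def _infer_resolution(cells: List[GridCellPD]) -> float:
    xs = sorted({c.cell[0] for c in cells})
    ys = sorted({c.cell[1] for c in cells})
    gaps = [b - a for a, b in zip(xs, xs[1:])] + [b - a for a, b in zip(ys, ys[1:])]
    return min(gaps) if gaps else 1.0


def read_ranges_geojson(path, species_field: str = "sci_name") -> Dict[str, BaseGeometry]:
    """Read a GeoJSON FeatureCollection of species ranges.

    Features sharing a species name (configurable attribute, default
    ``sci_name`` as in IUCN downloads) are unioned into one geometry.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    ranges: Dict[str, BaseGeometry] = {}
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        if species_field not in props:
            raise ValueError(f"feature missing species attribute {species_field!r}")
        name = str(props[species_field])
        geom = shape(feat["geometry"])
        ranges[name] = geom if name not in ranges else ranges[name].union(geom)
    return ranges
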