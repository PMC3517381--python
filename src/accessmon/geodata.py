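"""Spatial data model and I/O for the district analysis grid.

Everything works in projected metres on a regular north-up grid. Road
networks are vector polylines tagged with one of two surface classes
(``tarmac`` or ``track``); rasterisation assigns each grid cell the class
of the nearest road corridor within a buffer distance, with any remaining
cell classed ``other`` (settlements, crops, bare ground — traversed on
foot).

Raster convention: row 0 is the northernmost row, column 0 the westernmost.
The centre of cell ``(r, c)`` is ``(origin_x + (c + 0.5) * cell_size,
origin_y - (r + 0.5) * cell_size)``, i.e. the grid origin is the top-left
(north-west) corner.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path

import numpy as np
import shapely

ROAD_CLASSES = ("tarmac", "track")

#: integer codes used in rasters and their exports
CLASS_CODES = {"other": 0, "track": 1, "tarmac": 2}


class GeodataError(ValueError):
    """Raised for malformed spatial inputs."""


@dataclass(frozen=True)
class GridSpec:
    """Regular analysis grid in a projected (metric) coordinate system.

    ``origin_x``/``origin_y`` locate the north-west corner of the grid.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs_label: str = "local-metric"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise GeodataError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise GeodataError(
                f"grid must have at least one row and column, got "
                f"{self.n_rows}x{self.n_cols}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin_x + (col + 0.5) * self.cell_size,
            self.origin_y - (row + 0.5) * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """X and Y coordinates of every cell centre as 2-D arrays."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        xs = self.origin_x + (cols + 0.5) * self.cell_size
        ys = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def snap(self, x: float, y: float) -> tuple[int, int]:
        """Index of the cell containing (x, y); raises if outside the grid."""
        col = int(np.floor((x - self.origin_x) / self.cell_size))
        row = int(np.floor((self.origin_y - y) / self.cell_size))
        # points exactly on the east/south edge belong to the last cell
        if col == self.n_cols and x == self.origin_x + self.n_cols * self.cell_size:
            col -= 1
        if row == self.n_rows and y == self.origin_y - self.n_rows * self.cell_size:
            row -= 1
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise GeodataError(
                f"point ({x}, {y}) falls outside the analysis grid"
            )
        return row, col


@dataclass(frozen=True)
class RoadSegment:
    coords: tuple[tuple[float, float], ...]
    road_class: str

    def __post_init__(self) -> None:
        if self.road_class not in ROAD_CLASSES:
            raise GeodataError(
                f"unknown road class {self.road_class!r}; expected one of "
                f"{ROAD_CLASSES}"
            )
        if len(self.coords) < 2:
            raise GeodataError("a road polyline needs at least 2 vertices")


@dataclass(frozen=True)
class RoadNetwork:
    segments: tuple[RoadSegment, ...] = ()

    def __len__(self) -> int:
        return len(self.segments)

    def by_class(self, road_class: str) -> list[RoadSegment]:
        return [s for s in self.segments if s.road_class == road_class]


@dataclass(frozen=True)
class Village:
    village_id: str
    name: str
    x: float
    y: float
    population_weight: float

    def __post_init__(self) -> None:
        if self.population_weight < 0:
            raise GeodataError(
                f"village {self.village_id}: population weight must be >= 0"
            )


@dataclass(frozen=True)
class Clinic:
    clinic_id: str
    name: str
    x: float
    y: float
    opening_date: date


@dataclass
class ClassRaster:
    """Per-cell surface class on a grid, stored as integer codes."""

    grid: GridSpec
    codes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.shape != self.grid.shape:
            raise GeodataError(
                f"class raster shape {self.codes.shape} does not match grid "
                f"{self.grid.shape}"
            )
        if not np.isin(self.codes, list(CLASS_CODES.values())).all():
            raise GeodataError("class raster contains unknown class codes")


def _maybe_lonlat(points: list[tuple[float, float]]) -> bool:
    return bool(points) and all(
        abs(x) <= 180 and abs(y) <= 90 for x, y in points
    )


def _check_projected(points: list[tuple[float, float]], what: str,
                     allow_lonlat: bool) -> None:
    if not allow_lonlat and _maybe_lonlat(points):
        raise GeodataError(
            f"{what}: all coordinates lie within lon/lat bounds "
            "(|x|<=180, |y|<=90) — inputs must be projected metres. "
            "Pass allow_lonlat=True to override."
        )


def read_roads(path: str | Path, *, allow_lonlat: bool = False) -> RoadNetwork:
    """Read a road network from a GeoJSON FeatureCollection of LineStrings.

    Each feature must carry a ``road_class`` property equal to ``tarmac``
    or ``track``. Unknown classes are rejected with the feature index
    named in the error.
    """
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc.get("features", [])
    segments: list[RoadSegment] = []
    for i, feat in enumerate(feats):
        props = feat.get("properties") or {}
        cls = props.get("road_class")
        if cls not in ROAD_CLASSES:
            raise GeodataError(
                f"feature {i}: missing or invalid road_class {cls!r} "
                f"(expected one of {ROAD_CLASSES})"
            )
        geom = feat.get("geometry") or {}
        if geom.get("type") != "LineString":
            raise GeodataError(
                f"feature {i}: expected LineString geometry, got "
                f"{geom.get('type')!r}"
            )
        coords = tuple((float(x), float(y)) for x, y in geom["coordinates"])
        segments.append(RoadSegment(coords=coords, road_class=cls))
    all_pts = [pt for seg in segments for pt in seg.coords]
    _check_projected(all_pts, f"roads file {path}", allow_lonlat)
    return RoadNetwork(segments=tuple(segments))


def write_roads(roads: RoadNetwork, path: str | Path) -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {"road_class": seg.road_class},
            "geometry": {
                "type": "LineString",
                "coordinates": [[x, y] for x, y in seg.coords],
            },
        }
        for seg in roads.segments
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def _parse_date(text: str) -> date:
    return datetime.strptime(text.strip(), "%Y-%m-%d").date()


def read_villages(path: str | Path, *, allow_lonlat: bool = False) -> list[Village]:
    """Read villages from GeoJSON points or a CSV.

    CSV columns: ``village_id, name, x, y, population``.
    """
    path = Path(path)
    villages: list[Village] = []
    if path.suffix.lower() in {".geojson", ".json"}:
        with open(path) as fh:
            doc = json.load(fh)
        for feat in doc.get("features", []):
            p = feat.get("properties") or {}
            x, y = feat["geometry"]["coordinates"]
            villages.append(Village(
                village_id=str(p["village_id"]), name=str(p.get("name", "")),
                x=float(x), y=float(y),
                population_weight=float(p.get("population", 0.0)),
            ))
    else:
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                villages.append(Village(
                    village_id=str(row["village_id"]),
                    name=row.get("name", ""),
                    x=float(row["x"]), y=float(row["y"]),
                    population_weight=float(row["population"]),
                ))
    ids = [v.village_id for v in villages]
    if len(set(ids)) != len(ids):
        raise GeodataError(f"duplicate village_id in {path}")
    _check_projected([(v.x, v.y) for v in villages], f"villages file {path}",
                     allow_lonlat)
    return villages


def write_villages(villages: list[Village], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["village_id", "name", "x", "y", "population"])
        for v in villages:
            w.writerow([v.village_id, v.name, f"{v.x:.1f}", f"{v.y:.1f}",
                        f"{v.population_weight:.4f}"])


def read_clinics(path: str | Path, *, allow_lonlat: bool = False) -> list[Clinic]:
    """Read clinics from GeoJSON points or CSV.

    CSV columns: ``clinic_id, name, x, y, opening_date`` (ISO-8601 date).
    """
    path = Path(path)
    clinics: list[Clinic] = []
    if path.suffix.lower() in {".geojson", ".json"}:
        with open(path) as fh:
            doc = json.load(fh)
        for feat in doc.get("features", []):
            p = feat.get("properties") or {}
            x, y = feat["geometry"]["coordinates"]
            clinics.append(Clinic(
                clinic_id=str(p["clinic_id"]), name=str(p.get("name", "")),
                x=float(x), y=float(y),
                opening_date=_parse_date(p["opening_date"]),
            ))
    else:
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                clinics.append(Clinic(
                    clinic_id=str(row["clinic_id"]),
                    name=row.get("name", ""),
                    x=float(row["x"]), y=float(row["y"]),
                    opening_date=_parse_date(row["opening_date"]),
                ))
    ids = [c.clinic_id for c in clinics]
    if len(set(ids)) != len(ids):
        raise GeodataError(f"duplicate clinic_id in {path}")
    _check_projected([(c.x, c.y) for c in clinics], f"clinics file {path}",
                     allow_lonlat)
    return clinics


def write_clinics(clinics: list[Clinic], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["clinic_id", "name", "x", "y", "opening_date"])
        for c in clinics:
            w.writerow([c.clinic_id, c.name, f"{c.x:.1f}", f"{c.y:.1f}",
                        c.opening_date.isoformat()])


def rasterize_roads(roads: RoadNetwork, grid: GridSpec,
                    buffer_m: float = 75.0) -> ClassRaster:
    """Rasterise a road network onto the analysis grid.

    A cell is classed ``tarmac`` if its centre lies within ``buffer_m`` of
    any tarmac segment, else ``track`` if within ``buffer_m`` of any track
    segment, else ``other``. Tarmac takes precedence where the buffered
    corridors overlap (the faster surface dominates a mixed cell).

    Distances are exact point-to-polyline distances, so the result agrees
    with a brute-force distance check at every cell centre.
    """
    if buffer_m < 0:
        raise GeodataError(f"buffer_m must be >= 0, got {buffer_m}")
    codes = np.zeros(grid.shape, dtype=np.uint8)
    xs, ys = grid.cell_centers()
    pts = shapely.points(xs.ravel(), ys.ravel())
    # lower-precedence class first so tarmac overwrites track
    for cls in ("track", "tarmac"):
        segs = roads.by_class(cls)
        if not segs:
            continue
        lines = shapely.multilinestrings(
            [shapely.linestrings(np.asarray(s.coords)) for s in segs]
        )
        dist = shapely.distance(pts, lines).reshape(grid.shape)
        codes[dist <= buffer_m] = CLASS_CODES[cls]
    return ClassRaster(grid=grid, codes=codes)


def write_ascii_grid(values: np.ndarray, grid: GridSpec, path: str | Path,
                     *, nodata: float = -9999.0, fmt: str = "%.6g") -> None:
    """Write a raster as an ESRI ASCII grid (plain text)."""
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise GeodataError("raster shape does not match grid")
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin_x}\n")
        fh.write(f"yllcorner {grid.origin_y - grid.n_rows * grid.cell_size}\n")
        fh.write(f"cellsize {grid.cell_size}\n")
        fh.write(f"NODATA_value {nodata}\n")
        out = np.where(np.isfinite(values), values, nodata)
        np.savetxt(fh, out, fmt=fmt)


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid back into an array + GridSpec."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    cell = header["cellsize"]
    grid = GridSpec(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * cell,
        cell_size=cell, n_rows=n_rows, n_cols=n_cols,
    )
    values = np.loadtxt(lines[6:]).reshape(grid.shape)
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return values, grid
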