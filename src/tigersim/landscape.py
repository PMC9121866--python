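"""Gridded landscape layers: prey production, roads, and road-effect fields.

The simulation landscape is a regular grid (default 250 m cells) carrying a
static per-cell rate of prey biomass production (kg/month).  Transport
infrastructure is represented as a per-cell road class — ``none``,
``secondary`` or ``primary`` — rasterized from tagged polylines; a proposed
railway is treated as class primary.  Two derived fields drive the road
mechanisms: Euclidean distance-to-road per class, and a linear prey-depletion
multiplier that is 0 on infrastructure and recovers to 1 at a class-specific
distance (5 km for primary roads/railway, 2 km for secondary roads).

Grid convention: row-major, 0-based, cell (0, 0) at the northwest corner.
Geometry coordinates are projected meters; x grows east, y grows north, so
row ``r`` has cell-center ``y = yll + (nrows - r - 0.5) * cell_size``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, box, shape

__all__ = [
    "CLASS_NONE",
    "CLASS_SECONDARY",
    "CLASS_PRIMARY",
    "PreyGrid",
    "RoadLayer",
    "DepletionField",
    "read_ascii_grid",
    "write_ascii_grid",
    "load_prey_raster",
    "load_road_geojson",
    "rasterize_roads",
    "road_layer_from_raster",
    "distance_to_class",
    "depletion_multiplier",
    "depletion_field",
    "apply_depletion",
    "near_road_mask",
]

CLASS_NONE = 0
CLASS_SECONDARY = 1
CLASS_PRIMARY = 2

_CLASS_NAMES = {"secondary": CLASS_SECONDARY, "primary": CLASS_PRIMARY}

#: maximum depletion distance (m) per road class
DEPLETION_DISTANCE = {CLASS_PRIMARY: 5000.0, CLASS_SECONDARY: 2000.0}

#: sentinel distance used when a road class is absent from the landscape
DISTANCE_SENTINEL = np.inf


@dataclass
class PreyGrid:
    """Per-cell monthly prey biomass production (kg/month).

    ``production`` is zero outside ``mask``; both arrays share one shape.
    """

    production: np.ndarray
    mask: np.ndarray
    cell_size: float = 250.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    depleted: bool = False  # set once road depletion has been applied

    def __post_init__(self) -> None:
        self.production = np.asarray(self.production, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.production.shape != self.mask.shape:
            raise ValueError("production and mask shapes differ")
        if not np.isfinite(self.production).all():
            raise ValueError("prey production must be finite")
        if (self.production < 0).any():
            r, c = np.argwhere(self.production < 0)[0]
            raise ValueError(f"negative prey production at cell ({r}, {c})")
        self.production = np.where(self.mask, self.production, 0.0)

    @property
    def nrows(self) -> int:
        return self.production.shape[0]

    @property
    def ncols(self) -> int:
        return self.production.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.production.shape

    def copy(self) -> "PreyGrid":
        return PreyGrid(
            self.production.copy(),
            self.mask.copy(),
            self.cell_size,
            self.xllcorner,
            self.yllcorner,
            self.depleted,
        )

    def cell_center_xy(self, r: int, c: int) -> tuple[float, float]:
        x = self.xllcorner + (c + 0.5) * self.cell_size
        y = self.yllcorner + (self.nrows - r - 0.5) * self.cell_size
        return x, y


@dataclass
class RoadLayer:
    """Rasterized road classes plus (optionally) the source polylines."""

    class_grid: np.ndarray
    cell_size: float = 250.0
    geometries: list[tuple[LineString, str]] | None = None

    def __post_init__(self) -> None:
        self.class_grid = np.asarray(self.class_grid, dtype=np.uint8)
        bad = set(np.unique(self.class_grid)) - {CLASS_NONE, CLASS_SECONDARY, CLASS_PRIMARY}
        if bad:
            raise ValueError(f"unknown road class codes in raster: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.class_grid.shape

    def has_class(self, road_class: int) -> bool:
        return bool((self.class_grid == road_class).any())

    def length_km(self, road_class: int) -> float:
        """Total length per class: polyline length when geometries are known,
        otherwise rasterized cell count x cell size."""
        if self.geometries is not None:
            name = {CLASS_SECONDARY: "secondary", CLASS_PRIMARY: "primary"}[road_class]
            return sum(g.length for g, cls in self.geometries if cls == name) / 1000.0
        return float((self.class_grid == road_class).sum()) * self.cell_size / 1000.0


@dataclass
class DepletionField:
    """Combined per-cell prey-depletion multiplier in [0, 1]."""

    multiplier: np.ndarray
    max_distance: dict = field(default_factory=lambda: dict(DEPLETION_DISTANCE))


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Read a single-band ESRI ASCII grid; returns (array, header dict).

    NODATA cells are returned as NaN.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"malformed ESRI ASCII header in {path}: missing '{key}'")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    values = np.loadtxt(lines[i:].__iter__(), dtype=float)
    values = np.atleast_2d(values)
    if values.size != nrows * ncols:
        raise ValueError(
            f"malformed ESRI ASCII grid {path}: expected {nrows * ncols} values, "
            f"got {values.size}"
        )
    values = values.reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return values, header


def write_ascii_grid(path, values: np.ndarray, cell_size: float = 250.0,
                     xllcorner: float = 0.0, yllcorner: float = 0.0,
                     nodata: float = -9999.0, mask: np.ndarray | None = None) -> None:
    values = np.asarray(values, dtype=float)
    out = values.copy()
    if mask is not None:
        out[~np.asarray(mask, dtype=bool)] = nodata
    out = np.where(np.isnan(out), nodata, out)
    nrows, ncols = out.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {float(xllcorner)!r}\n")
        fh.write(f"yllcorner {float(yllcorner)!r}\n")
        fh.write(f"cellsize {float(cell_size)!r}\n")
        fh.write(f"NODATA_value {float(nodata)!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def load_prey_raster(path) -> PreyGrid:
    """Load a prey-production raster from an ESRI ASCII grid.

    NODATA cells become masked-out with production 0; in-mask values are
    preserved bit-exactly.  Negative production is rejected, naming the cell.
    """
    values, header = read_ascii_grid(path)
    mask = ~np.isnan(values)
    neg = np.argwhere(np.where(mask, values, 0.0) < 0)
    if neg.size:
        r, c = neg[0]
        raise ValueError(f"negative prey production at cell ({r}, {c}) in {path}")
    return PreyGrid(
        production=np.where(mask, values, 0.0),
        mask=mask,
        cell_size=header["cellsize"],
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
    )


# ---------------------------------------------------------------------------
# Roads
# ---------------------------------------------------------------------------


def load_road_geojson(path) -> list[tuple[LineString, str]]:
    """Read a GeoJSON FeatureCollection of LineStrings tagged "road_class"."""
    with open(path) as fh:
        data = json.load(fh)
    geoms: list[tuple[LineString, str]] = []
    for feat in data["features"]:
        cls = feat.get("properties", {}).get("road_class")
        if cls not in _CLASS_NAMES:
            raise ValueError(f"unknown road_class tag: {cls!r}")
        geom = shape(feat["geometry"])
        if not isinstance(geom, LineString):
            raise ValueError(f"road feature is not a LineString: {geom.geom_type}")
        geoms.append((geom, cls))
    return geoms


def write_road_geojson(path, geometries: list[tuple[LineString, str]]) -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {"road_class": cls},
            "geometry": {"type": "LineString", "coordinates": list(g.coords)},
        }
        for g, cls in geometries
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def _cell_bounds(grid: PreyGrid, r: int, c: int) -> tuple[float, float, float, float]:
    x0 = grid.xllcorner + c * grid.cell_size
    y1 = grid.yllcorner + (grid.nrows - r) * grid.cell_size
    return x0, y1 - grid.cell_size, x0 + grid.cell_size, y1


def rasterize_roads(geometries: list[tuple[LineString, str]], grid_spec: PreyGrid) -> RoadLayer:
    """Burn class-tagged polylines into a road-class raster.

    A cell is assigned a class when a line crosses its interior; where classes
    collide, primary wins.  Geometry outside grid bounds is clipped with a
    warning.
    """
    nrows, ncols = grid_spec.shape
    cell = grid_spec.cell_size
    xll, yll = grid_spec.xllcorner, grid_spec.yllcorner
    grid_box = box(xll, yll, xll + ncols * cell, yll + nrows * cell)
    class_grid = np.zeros((nrows, ncols), dtype=np.uint8)

    for geom, cls in geometries:
        if cls not in _CLASS_NAMES:
            raise ValueError(f"unknown road class tag: {cls!r}")
        code = _CLASS_NAMES[cls]
        if not geom.within(grid_box):
            warnings.warn("road geometry extends outside grid bounds; clipping")
        coords = np.asarray(geom.coords)
        for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
            seg = LineString([(x0, y0), (x1, y1)])
            cmin = int(np.floor((min(x0, x1) - xll) / cell)) - 1
            cmax = int(np.floor((max(x0, x1) - xll) / cell)) + 1
            rmin = int(np.floor((nrows - (max(y0, y1) - yll) / cell))) - 1
            rmax = int(np.floor((nrows - (min(y0, y1) - yll) / cell))) + 1
            for r in range(max(rmin, 0), min(rmax + 1, nrows)):
                for c in range(max(cmin, 0), min(cmax + 1, ncols)):
                    bx = box(*_cell_bounds(grid_spec, r, c))
                    # interior crossing: DE-9IM interior/interior intersection
                    if seg.relate(bx)[0] != "F":
                        class_grid[r, c] = max(class_grid[r, c], code)
    return RoadLayer(class_grid=class_grid, cell_size=cell, geometries=list(geometries))


def road_layer_from_raster(path_or_array, cell_size: float = 250.0) -> RoadLayer:
    """Build a RoadLayer from an integer raster {0,1,2} = {none, secondary, primary}."""
    if isinstance(path_or_array, (str, Path)):
        values, header = read_ascii_grid(path_or_array)
        values = np.where(np.isnan(values), 0, values)
        cell_size = header["cellsize"]
    else:
        values = np.asarray(path_or_array)
    return RoadLayer(class_grid=values.astype(np.uint8), cell_size=cell_size)


# ---------------------------------------------------------------------------
# Distance and depletion fields
# ---------------------------------------------------------------------------


def distance_to_class(road_layer: RoadLayer, road_class: int) -> np.ndarray:
    """Euclidean cell-center distance (m) to the nearest road cell of a class.

    Road cells are at distance 0; if the class is absent everywhere the field
    is +inf.
    """
    on_road = road_layer.class_grid == road_class
    if not on_road.any():
        return np.full(road_layer.shape, DISTANCE_SENTINEL)
    return ndimage.distance_transform_edt(~on_road, sampling=road_layer.cell_size)


def depletion_multiplier(distance, road_class: int):
    """Linear prey-depletion multiplier: 0 on the road, 1 at the class max
    distance (5 km primary/railway, 2 km secondary) and beyond."""
    d = np.asarray(distance, dtype=float)
    if (d[np.isfinite(d)] < 0).any() if d.ndim else (np.isfinite(d) and d < 0):
        raise ValueError("distance must be non-negative")
    m = np.minimum(d / DEPLETION_DISTANCE[road_class], 1.0)
    if np.ndim(distance) == 0:
        return float(m)
    return m


def depletion_field(road_layer: RoadLayer) -> DepletionField:
    """Combined multiplier: the minimum over road classes (most depleted wins)."""
    mult = np.ones(road_layer.shape)
    for cls in (CLASS_PRIMARY, CLASS_SECONDARY):
        if road_layer.has_class(cls):
            d = distance_to_class(road_layer, cls)
            mult = np.minimum(mult, depletion_multiplier(d, cls))
    return DepletionField(multiplier=mult)


def apply_depletion(prey: PreyGrid, road_layer: RoadLayer) -> PreyGrid:
    """Effective prey production under the depletion mechanism.

    Returns a new grid; the input is untouched.  Applying depletion to an
    already-depleted grid is a no-op (idempotent).
    """
    if prey.shape != road_layer.shape:
        raise ValueError(f"prey grid {prey.shape} and road layer {road_layer.shape} misaligned")
    if prey.depleted:
        return prey.copy()
    mult = depletion_field(road_layer).multiplier
    out = prey.copy()
    out.production = prey.production * mult
    out.depleted = True
    return out


def near_road_mask(road_layer: RoadLayer) -> np.ndarray:
    """True for cells within 2 km of a secondary road or 5 km of a primary
    road/railway — the road-effect zone used for occupancy stratification."""
    near = np.zeros(road_layer.shape, dtype=bool)
    for cls in (CLASS_PRIMARY, CLASS_SECONDARY):
        d = distance_to_class(road_layer, cls)
        near |= d <= DEPLETION_DISTANCE[cls]
    return near
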