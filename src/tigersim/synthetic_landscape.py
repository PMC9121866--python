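"""Synthetic Chitwan-like landscapes.

Generates a prey-production raster and a road network whose summary
statistics match the real model landscape: prey production between 0 and
10.46 kg/month with mean 3.78, ~198 km of primary roads (including a
railway corridor) and ~723 km of secondary roads on a ~1,700 km^2 grid of
250 m cells.  The prey field is low-pass-filtered noise shaped by a broad
"park core" envelope (high prey in the interior, poorer periphery);
secondary roads are routed preferentially through low-prey cells and kept to
the periphery, mirroring how real roads skirt the park core — this is what
makes the near-road prey deficit (2.89 vs 4.3 kg/month near/far) emerge.
The optional railway runs parallel and close (<2 km) to the main east-west
primary road, clipping the northern flank of the high-prey core: the
configuration argued to act as an ecological trap.

Everything is deterministic under the spec seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString
from shapely.ops import substring

from .landscape import PreyGrid, RoadLayer, rasterize_roads

__all__ = ["SynthSpec", "generate_prey", "generate_roads", "generate_landscape"]


@dataclass
class SynthSpec:
    """Generator settings; defaults emulate the Chitwan layers' printed
    statistics (grid area ~1,700 km^2 at 250 m; prey 0-10.46 mean 3.78;
    198 km primary incl. 25 km railway; 723 km secondary)."""

    nrows: int = 170
    ncols: int = 160
    cell_size: float = 250.0
    prey_max: float = 10.46
    prey_mean: float = 3.78
    autocorr_cells: float = 6.0
    primary_km: float = 198.0      # total primary incl. railway when present
    railway_km: float = 25.0
    secondary_km: float = 723.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prey_mean <= self.prey_max:
            raise ValueError("prey mean must lie within (0, prey_max]")
        if min(self.primary_km, self.railway_km, self.secondary_km) < 0:
            raise ValueError("road length targets must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "SynthSpec":
        return cls(**d)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def generate_prey(spec: SynthSpec, rng: np.random.Generator) -> PreyGrid:
    """Smoothed random prey field rescaled to the target range and mean.

    White noise is low-pass filtered at the autocorrelation length (length 0
    skips the filter), shaped by a smooth core-versus-periphery envelope, and
    mapped through a power transform u -> prey_max * u**gamma with gamma
    solved so the landscape mean hits the target exactly.
    """
    noise = rng.standard_normal((spec.nrows, spec.ncols))
    field = (ndimage.gaussian_filter(noise, spec.autocorr_cells)
             if spec.autocorr_cells > 0 else noise)
    u = field - field.min()
    u /= u.max()

    # core-versus-periphery envelope: a broad interior "park core" of high
    # prey, plus a narrower high-prey corridor reaching the northern edge
    # (the forest corridor the proposed railway would clip)
    rr, cc = np.indices((spec.nrows, spec.ncols))
    core = 0.85 * np.exp(
        -((rr - 0.58 * spec.nrows) ** 2 / (2 * (0.24 * spec.nrows) ** 2)
          + (cc - 0.50 * spec.ncols) ** 2 / (2 * (0.30 * spec.ncols) ** 2)))
    corridor = 0.8 * np.exp(
        -((rr - 0.15 * spec.nrows) ** 2 / (2 * (0.20 * spec.nrows) ** 2)
          + (cc - 0.45 * spec.ncols) ** 2 / (2 * (0.10 * spec.ncols) ** 2)))
    env = 0.38 + np.maximum(core, corridor)
    u = u * env
    u /= u.max()

    target = spec.prey_mean / spec.prey_max
    lo, hi = 0.01, 50.0
    for _ in range(200):
        gamma = 0.5 * (lo + hi)
        m = (u ** gamma).mean()
        if m > target:
            lo = gamma
        else:
            hi = gamma
    production = spec.prey_max * u ** gamma
    return PreyGrid(production=production, mask=np.ones_like(production, dtype=bool),
                    cell_size=spec.cell_size)


# ---------------------------------------------------------------------------
# Roads
# ---------------------------------------------------------------------------


def _path_to_line(path: list[tuple[int, int]], spec: SynthSpec) -> LineString:
    cell = spec.cell_size
    coords = [((c + 0.5) * cell, (spec.nrows - r - 0.5) * cell) for r, c in path]
    return LineString(coords)


def _meander_row(spec: SynthSpec, base_row: int, rng: np.random.Generator,
                 prey: np.ndarray | None = None,
                 max_drift: int = 3) -> list[tuple[int, int]]:
    """A west-east path around a base row.  With a prey field given, each
    column step drops to the lowest-prey neighboring row (low-prey routing);
    otherwise it wanders randomly within the drift band."""
    r = base_row
    path = [(r, 0)]
    for c in range(1, spec.ncols):
        lo = max(min(base_row - max_drift, r - 1), 0)
        hi = min(max(base_row + max_drift, r + 1), spec.nrows - 1)
        opts = [x for x in (r - 1, r, r + 1) if lo <= x <= hi]
        if prey is not None:
            vals = np.array([prey[x, c] for x in opts])
            vals = vals + rng.random(len(opts)) * 1e-3  # jitter breaks ties
            r = opts[int(np.argmin(vals))]
        else:
            r = opts[int(rng.integers(len(opts)))]
        path.append((r, c))
    return path


def _take_length(lines: list[LineString], target_m: float) -> list[LineString]:
    """Consume candidate lines until the cumulative length reaches the
    target, trimming the last one to land on it exactly."""
    out: list[LineString] = []
    total = 0.0
    for line in lines:
        if total >= target_m:
            break
        remaining = target_m - total
        if line.length <= remaining:
            out.append(line)
            total += line.length
        else:
            out.append(substring(line, 0, remaining))
            total = target_m
    if total < 0.95 * target_m:
        warnings.warn(
            f"road length target {target_m / 1000:.0f} km unreachable on this "
            f"grid; realized {total / 1000:.0f} km")
    return out


def generate_roads(spec: SynthSpec, prey: PreyGrid, rng: np.random.Generator,
                   railway: bool = False) -> list[tuple[LineString, str]]:
    """Synthesize tagged road polylines.

    Primary roads are a few long trunk lines (a northern and a southern
    east-west road plus western/eastern connectors); secondary roads are a
    denser set of low-prey-seeking lines confined to the peripheral bands.
    The railway (class primary) parallels the northern trunk road ~1.5 km to
    its south, through the high-prey corridor; its geometry is deterministic
    so the "existing" configuration is unchanged by toggling it.
    """
    nrows, ncols = spec.nrows, spec.ncols
    p = prey.production
    geoms: list[tuple[LineString, str]] = []

    # primary trunks hug the northern and southern peripheries (the real
    # network rings the park; the interior stays roadless), so the 5 km
    # road-effect zones stay clear of the core
    north_row = int(0.08 * nrows)
    candidates = [
        _path_to_line(_meander_row(spec, north_row, rng), spec),
        _path_to_line(_meander_row(spec, int(0.92 * nrows), rng), spec),
        _path_to_line(_meander_row(spec, int(0.035 * nrows), rng), spec),
        _path_to_line(_meander_row(spec, int(0.965 * nrows), rng), spec),
    ]
    # the railway is the proposed addition: existing primary roads total
    # primary_km - railway_km, so the railway configuration lands on the
    # printed total and toggling it leaves the existing network unchanged
    primary_target = (spec.primary_km - spec.railway_km) * 1000
    for line in _take_length(candidates, primary_target):
        geoms.append((line, "primary"))

    if railway and spec.railway_km > 0:
        rail_row = north_row + 6  # ~1.5 km south, toward the high-prey core
        start_col = int(0.15 * ncols)
        rail_path = [(rail_row, c) for c in range(start_col, ncols)]
        rail_line = _path_to_line(rail_path, spec)
        rail_line = substring(rail_line, 0, min(spec.railway_km * 1000, rail_line.length))
        geoms.append((rail_line, "primary"))

    # secondary network: low-prey routing confined to the peripheral bands,
    # inside the primary road-effect zones (real secondary roads serve the
    # same settled buffer the highways pass through)
    band_rows = list(range(int(0.02 * nrows), int(0.13 * nrows))) + \
        list(range(int(0.87 * nrows), int(0.98 * nrows)))
    candidates = []
    for _ in range(200):
        base = band_rows[int(rng.integers(len(band_rows)))]
        candidates.append(_path_to_line(_meander_row(spec, base, rng, prey=p), spec))
    for line in _take_length(candidates, spec.secondary_km * 1000):
        geoms.append((line, "secondary"))
    return geoms


def generate_landscape(spec: SynthSpec, railway: bool = False
                       ) -> tuple[PreyGrid, RoadLayer]:
    """Generate the full synthetic landscape (prey grid + rasterized roads),
    deterministically from the spec seed."""
    rng = np.random.default_rng(spec.seed)
    prey = generate_prey(spec, rng)
    geoms = generate_roads(spec, prey, rng, railway=railway)
    roads = rasterize_roads(geoms, prey)
    return prey, roads
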