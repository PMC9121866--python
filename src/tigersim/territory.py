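"""Female territories on the prey grid, and male ranges over females.

A territory is an exclusive, rook-connected set of grid cells owned by one
breeding female.  Females size territories against monthly prey requirements:
utilized prey is a fixed fraction (0.1) of the summed effective prey
production over the territory's cells, and a female keeps annexing the
richest frontier cell (up to 48 cells per month) while her utilized prey is
below the 76 kg/month minimum; she never grows past the 167.3 kg/month
maximum she could use.  Neighboring females may contest border patches: an
older (dominant) female takes a subordinate's patch with probability 0.25
when that patch is her best frontier candidate, after which the subordinate's
territory is repaired to the connected component containing her origin.

Males do not hold cells; a breeding male's range is the set of up to six
females whose territories lie within his 3 km search radius.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .agents import Params, Tiger
from .landscape import CLASS_NONE, CLASS_PRIMARY, CLASS_SECONDARY

__all__ = ["Territory", "MaleRange", "TerritoryMap", "find_settlement_site",
           "expand_territory", "contest_patch", "assemble_male_range",
           "is_rook_connected"]

_NEIGHBOR_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass
class Territory:
    """Cell set owned by one breeding female, with incrementally maintained
    prey and road-intersection bookkeeping."""

    owner_id: int
    origin: tuple[int, int]
    cells: set = field(default_factory=set)
    prey_sum: float = 0.0
    row_sum: int = 0
    col_sum: int = 0
    n_primary: int = 0     # road cells of each class inside the territory
    n_secondary: int = 0

    def utilized_prey(self, params: Params) -> float:
        return params.prey_utilization * self.prey_sum

    @property
    def centroid_cell(self) -> tuple[int, int]:
        n = max(len(self.cells), 1)
        return (int(round(self.row_sum / n)), int(round(self.col_sum / n)))

    def road_class(self) -> int:
        if self.n_primary > 0:
            return CLASS_PRIMARY
        if self.n_secondary > 0:
            return CLASS_SECONDARY
        return CLASS_NONE

    def copy(self) -> "Territory":
        t = Territory(self.owner_id, self.origin, set(self.cells), self.prey_sum,
                      self.row_sum, self.col_sum, self.n_primary, self.n_secondary)
        return t


@dataclass
class MaleRange:
    """A breeding male's set of associated females (at most six)."""

    male_id: int
    female_ids: list


def is_rook_connected(cells: set) -> bool:
    """True when the cell set forms one 4-connected component."""
    if not cells:
        return True
    start = next(iter(cells))
    seen = {start}
    stack = [start]
    while stack:
        r, c = stack.pop()
        for dr, dc in _NEIGHBOR_OFFSETS:
            nb = (r + dr, c + dc)
            if nb in cells and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == len(cells)


class TerritoryMap:
    """Owner grid plus the per-female territories, bound to the effective
    prey field they are scored against.

    ``owner`` holds 0 for unowned cells and the owning female's id elsewhere.
    ``set_effective_prey`` rebinds the prey field (used when the depletion
    mechanism rewrites it) and recomputes all prey sums deterministically.
    """

    def __init__(self, effective_prey: np.ndarray, mask: np.ndarray,
                 cell_size: float = 250.0, road_class: np.ndarray | None = None):
        self.effective_prey = np.asarray(effective_prey, dtype=float)
        self.mask = np.asarray(mask, dtype=bool)
        self.cell_size = float(cell_size)
        self.road_class = road_class
        self.owner = np.zeros(self.mask.shape, dtype=np.int32)
        self.territories: dict[int, Territory] = {}
        self._score: np.ndarray | None = None
        rows, cols = np.indices(self.mask.shape)
        self._rows, self._cols = rows, cols

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    # -- prey field -------------------------------------------------------

    def set_effective_prey(self, effective_prey: np.ndarray) -> None:
        self.effective_prey = np.asarray(effective_prey, dtype=float)
        self._score = None
        for tid in sorted(self.territories):
            terr = self.territories[tid]
            terr.prey_sum = sum(self.effective_prey[rc] for rc in sorted(terr.cells))

    def settlement_score(self, radius_m: float) -> np.ndarray:
        """Effective prey summed over a disk of the given radius around each
        cell (the score dispersing females maximize when settling)."""
        if self._score is None:
            n = int(np.floor(radius_m / self.cell_size))
            offs = np.arange(-n, n + 1)
            dr, dc = np.meshgrid(offs, offs, indexing="ij")
            kernel = (np.hypot(dr, dc) * self.cell_size) <= radius_m
            self._score = ndimage.convolve(
                self.effective_prey, kernel.astype(float), mode="constant", cval=0.0
            )
        return self._score

    # -- membership bookkeeping -------------------------------------------

    def settle(self, owner_id: int, origin: tuple[int, int]) -> Territory:
        if self.owner[origin] != 0:
            raise ValueError(f"cell {origin} already owned")
        terr = Territory(owner_id=owner_id, origin=origin)
        self.territories[owner_id] = terr
        self._annex(terr, origin)
        return terr

    def _annex(self, terr: Territory, cell: tuple[int, int]) -> None:
        self.owner[cell] = terr.owner_id
        terr.cells.add(cell)
        terr.prey_sum += self.effective_prey[cell]
        terr.row_sum += cell[0]
        terr.col_sum += cell[1]
        if self.road_class is not None:
            cls = self.road_class[cell]
            if cls == CLASS_PRIMARY:
                terr.n_primary += 1
            elif cls == CLASS_SECONDARY:
                terr.n_secondary += 1

    def _remove(self, terr: Territory, cell: tuple[int, int]) -> None:
        self.owner[cell] = 0
        terr.cells.remove(cell)
        terr.prey_sum -= self.effective_prey[cell]
        terr.row_sum -= cell[0]
        terr.col_sum -= cell[1]
        if self.road_class is not None:
            cls = self.road_class[cell]
            if cls == CLASS_PRIMARY:
                terr.n_primary -= 1
            elif cls == CLASS_SECONDARY:
                terr.n_secondary -= 1

    def release(self, owner_id: int) -> None:
        """Free all cells of a territory (owner died)."""
        terr = self.territories.pop(owner_id)
        for cell in terr.cells:
            self.owner[cell] = 0

    def repair_connectivity(self, terr: Territory) -> list:
        """Prune the territory to the connected component containing its
        origin; pruned cells become unowned.  If the origin itself was lost,
        the largest remaining component is kept (ties: the one holding the
        smallest cell) and the origin is reset."""
        if not terr.cells:
            return []
        if terr.origin not in terr.cells:
            comps = self._components(terr.cells)
            comps.sort(key=lambda comp: (-len(comp), min(comp)))
            keep = comps[0]
            terr.origin = min(keep)
        else:
            keep = self._component_of(terr.cells, terr.origin)
        pruned = sorted(terr.cells - keep)
        for cell in pruned:
            self._remove(terr, cell)
        return pruned

    @staticmethod
    def _component_of(cells: set, start: tuple[int, int]) -> set:
        seen = {start}
        stack = [start]
        while stack:
            r, c = stack.pop()
            for dr, dc in _NEIGHBOR_OFFSETS:
                nb = (r + dr, c + dc)
                if nb in cells and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return seen

    @classmethod
    def _components(cls, cells: set) -> list:
        remaining = set(cells)
        comps = []
        while remaining:
            comp = cls._component_of(remaining, min(remaining))
            comps.append(comp)
            remaining -= comp
        return comps

    def transfer_cell(self, from_terr: Territory, to_terr: Territory,
                      cell: tuple[int, int]) -> list:
        """Move one cell between territories, repairing the loser's
        connectivity; returns the cells pruned from the loser."""
        self._remove(from_terr, cell)
        pruned = self.repair_connectivity(from_terr)
        self._annex(to_terr, cell)
        return pruned

    def distance_to_owned(self) -> np.ndarray:
        """Euclidean distance (m) from each cell to the nearest owned cell."""
        if not self.territories:
            return np.full(self.shape, np.inf)
        return ndimage.distance_transform_edt(self.owner == 0, sampling=self.cell_size)

    def copy(self) -> "TerritoryMap":
        new = TerritoryMap.__new__(TerritoryMap)
        new.effective_prey = self.effective_prey.copy()
        new.mask = self.mask
        new.cell_size = self.cell_size
        new.road_class = self.road_class
        new.owner = self.owner.copy()
        new.territories = {tid: t.copy() for tid, t in self.territories.items()}
        new._score = self._score
        new._rows, new._cols = self._rows, self._cols
        return new


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def find_settlement_site(female: Tiger, tmap: TerritoryMap, params: Params,
                         rng: np.random.Generator,
                         occ_dist: np.ndarray | None = None,
                         natal_ok: np.ndarray | None = None) -> tuple[int, int] | None:
    """Pick a territory origin for a dispersing breeding female.

    Candidates lie within 33 km of her natal center, inside the landscape.
    The ideal pass requires no other female's territory cell within a 2 km
    radius; if nothing qualifies the requirement relaxes to 1 km.  Among
    qualifying cells the one maximizing effective prey summed within 1 km
    wins, ties broken uniformly at random.  Returns ``None`` when saturated.

    ``occ_dist`` (distance to the nearest owned cell) and ``natal_ok`` (the
    dispersal-cap mask) may be passed in when the caller has them cached.
    """
    if natal_ok is None:
        r0, c0 = female.natal_center
        natal_dist = np.hypot(tmap._rows - r0, tmap._cols - c0) * tmap.cell_size
        natal_ok = tmap.mask & (natal_dist <= params.max_dispersal_female)
    base = natal_ok
    if not base.any():
        return None
    if occ_dist is None:
        occ_dist = tmap.distance_to_owned()
    score = tmap.settlement_score(params.settlement_score_radius)
    for radius in (params.settlement_radius_ideal, params.settlement_radius_relaxed):
        cand = base & (occ_dist > radius)
        if not cand.any():
            continue
        vals = np.where(cand, score, -np.inf)
        best = vals.max()
        ties = np.argwhere(vals == best)
        pick = ties[rng.integers(len(ties))]
        return int(pick[0]), int(pick[1])
    return None


def _dominates(a: Tiger, b: Tiger) -> bool:
    """Female dominance: older wins; ties broken by lower id."""
    return (a.age, -a.id) > (b.age, -b.id)


def contest_patch(dominant: Tiger, subordinate: Tiger, cell: tuple[int, int],
                  tmap: TerritoryMap, params: Params,
                  rng: np.random.Generator) -> bool:
    """A dominant female's attempt to take a border patch from a subordinate.

    Only the dominant (older) female initiates; the patch transfers with
    probability 0.25, after which the subordinate's territory is repaired to
    the component containing her origin.  Returns True on transfer.
    """
    if not _dominates(dominant, subordinate):
        return False
    if rng.random() >= params.patch_takeover_prob:
        return False
    tmap.transfer_cell(tmap.territories[subordinate.id],
                       tmap.territories[dominant.id], cell)
    return True


def expand_territory(female: Tiger, tmap: TerritoryMap, params: Params,
                     rng: np.random.Generator,
                     tigers: dict | None = None) -> int:
    """Monthly territory adjustment by greedy annexation.

    While utilized prey is below the 76 kg/month minimum (and below the
    167.3 maximum), annex the frontier-adjacent cell with the highest
    effective prey, ties uniformly at random, at most 48 cells this step.
    Unowned cells are annexed outright; a cell owned by a younger female is
    taken only through :func:`contest_patch` (a failed contest forfeits that
    cell for the month).  Returns the number of cells annexed.
    """
    terr = tmap.territories[female.territory_id]
    ep = tmap.effective_prey
    nrows, ncols = tmap.shape
    heap: list = []
    queued: set = set()

    def push_neighbors(cell):
        r, c = cell
        for dr, dc in _NEIGHBOR_OFFSETS:
            nb = (r + dr, c + dc)
            if nb in queued or not (0 <= nb[0] < nrows and 0 <= nb[1] < ncols):
                continue
            if not tmap.mask[nb] or nb in terr.cells:
                continue
            queued.add(nb)
            heapq.heappush(heap, (-ep[nb], rng.random(), nb))

    for cell in sorted(terr.cells):
        push_neighbors(cell)

    added = 0
    while (added < params.max_cells_per_step
           and terr.utilized_prey(params) < params.prey_min_threshold
           and terr.utilized_prey(params) < params.prey_max_threshold):
        if not heap:
            break
        _, _, cell = heapq.heappop(heap)
        owner = int(tmap.owner[cell])
        if owner == female.id:
            continue
        if owner == 0:
            tmap._annex(terr, cell)
            added += 1
            push_neighbors(cell)
        else:
            if tigers is None or owner not in tigers:
                continue
            other = tigers[owner]
            if not _dominates(female, other):
                continue
            if contest_patch(female, other, cell, tmap, params, rng):
                added += 1
                push_neighbors(cell)
            # a failed contest forfeits the cell this step
    return added


def assemble_male_range(male: Tiger, tigers: dict, tmap: TerritoryMap,
                        params: Params) -> tuple[MaleRange, list]:
    """Associate a breeding male with nearby unassociated breeding females.

    Scans territory cells within the 3 km search radius of his location and
    associates with unassociated females nearest-first, up to six.  Females
    already held by another male are returned as challenge candidates
    (nearest-first) rather than taken silently.
    """
    challenge: list[tuple[float, int, int]] = []
    if male.location is None:
        return MaleRange(male.id, list(male.female_ids)), []
    r0, c0 = male.location
    n = int(np.floor(params.male_search_radius / tmap.cell_size))
    rlo, rhi = max(r0 - n, 0), min(r0 + n + 1, tmap.shape[0])
    clo, chi = max(c0 - n, 0), min(c0 + n + 1, tmap.shape[1])
    window = tmap.owner[rlo:rhi, clo:chi]
    rr, cc = np.indices(window.shape)
    dist = np.hypot(rr + rlo - r0, cc + clo - c0) * tmap.cell_size
    inside = (window > 0) & (dist <= params.male_search_radius)
    owners = np.unique(window[inside])
    cands = []
    for fid in owners:
        f = tigers.get(int(fid))
        if f is None or not f.alive or f.sex != "F":
            continue
        d = float(dist[inside & (window == fid)].min())
        cands.append((d, int(fid)))
    cands.sort()
    for d, fid in cands:
        f = tigers[fid]
        holder = tigers.get(f.associated_male_id) if f.associated_male_id is not None else None
        if holder is not None and not holder.alive:
            holder = None
        if holder is None:
            f.associated_male_id = None
            if len(male.female_ids) < params.max_females_per_male:
                male.female_ids.append(fid)
                f.associated_male_id = male.id
        elif f.associated_male_id != male.id:
            challenge.append((d, fid, f.associated_male_id))
    return MaleRange(male.id, list(male.female_ids)), challenge


def male_dispersal_target(male: Tiger, tigers: dict, tmap: TerritoryMap,
                          params: Params) -> tuple[tuple[int, int], str, int] | None:
    """Where a dispersing male jumps next: the nearest settled unassociated
    female (her territory centroid), or — only when no unassociated female is
    reachable — the nearest challengeable breeding male, subject to the 66 km
    cap on distance from his natal center.  Returns (cell, kind, target_id)
    or None.  Unassociated females are strictly preferred so that challenges
    (and the infanticide they bring) arise from genuine male surplus rather
    than from males bypassing free mates."""
    r0, c0 = male.location if male.location is not None else male.natal_center
    rn, cn = male.natal_center
    cap = params.max_dispersal_male / tmap.cell_size
    best = None
    for tid in sorted(tigers):
        t = tigers[tid]
        if not t.alive or t.id == male.id:
            continue
        if t.sex == "F" and t.territory_id is not None and t.associated_male_id is None:
            cell, kind = tmap.territories[t.territory_id].centroid_cell, "female"
        elif t.sex == "M" and t.female_ids and t.location is not None:
            cell, kind = t.location, "male"
        else:
            continue
        if np.hypot(cell[0] - rn, cell[1] - cn) > cap:
            continue
        d = np.hypot(cell[0] - r0, cell[1] - c0)
        key = (0 if kind == "female" else 1, d, t.id)
        if best is None or key < best[0]:
            best = (key, cell, kind, t.id)
    if best is None:
        return None
    return best[1], best[2], best[3]
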