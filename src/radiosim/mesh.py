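"""3-D discretising mesh and the mechanical (second-scan) rules.

The tumor lives on a cubic lattice of geometrical cells (GCs).  Each
occupied GC nominally holds NBC biological cells (cell density x voxel
volume); the second mesh scan of every hour keeps the per-GC load inside
the band [(1-margin) NBC, (1+margin) NBC] by pushing excess cells to
26-neighbourhood GCs with free space (expansion) or emptying depleted GCs
into their surroundings with inward chain shifts (shrinkage), and repairs
the two artefacts this can create: detached fragments and enclosed holes.
Cells are only ever moved, never created or destroyed, and unloading draws
proportionally from every subclass of the source GC.
"""

from __future__ import annotations

import itertools
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .cytokinetics import CompartmentState
from .params import ModelParameters

__all__ = [
    "TumorMesh",
    "SimulationDomainError",
    "second_scan",
    "rebalance_overloaded",
    "rebalance_underloaded",
    "repair_fragmentation",
    "color_necrotic",
    "tumor_volume",
]

Coord = Tuple[int, int, int]

# 26-neighbourhood offsets and the 6 face directions
NEIGH26: List[Coord] = [
    (dx, dy, dz)
    for dx, dy, dz in itertools.product((-1, 0, 1), repeat=3)
    if (dx, dy, dz) != (0, 0, 0)
]
NEIGH6: List[Coord] = [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                       (0, -1, 0), (0, 0, 1), (0, 0, -1)]

#: occupancy threshold: GC totals below this count as empty
_EMPTY_TOL = 1e-9


class SimulationDomainError(RuntimeError):
    """The tumor reached the boundary of the discretising mesh."""


class TumorMesh:
    """Lattice of GCs backed by one vectorised :class:`CompartmentState`.

    Rows of ``state`` correspond to lattice sites that have ever been
    occupied; ``coords[i]`` is the (x, y, z) index of row i.  Region labels
    (proliferating/necrotic) are fixed at initialisation.
    """

    def __init__(self, dims: Coord, params: ModelParameters,
                 rng: Optional[np.random.Generator] = None):
        self.dims = tuple(int(d) for d in dims)
        self.params = params
        self.voxel_edge = params.voxel_edge
        self.NBC = params.NBC
        self.margin = params.margin_percent
        self.rng = rng or np.random.default_rng(params.rng_seed)
        self.state = CompartmentState(0, params)
        self.coords = np.zeros((0, 3), dtype=int)
        self._index: dict[Coord, int] = {}
        self.region: List[str] = []
        self.fallback_log: List[dict] = []
        #: GCs created below the band by an expansion fallback; they are
        #: exempt from the band invariant until they refill
        self.fallback_created: set = set()
        self._tot_cache: Optional[np.ndarray] = None
        self._tot_version = -1

    # -- site bookkeeping ----------------------------------------------------
    def row_at(self, coord: Coord) -> Optional[int]:
        return self._index.get(tuple(coord))

    def in_bounds(self, coord: Coord) -> bool:
        return all(0 <= c < d for c, d in zip(coord, self.dims))

    def ensure_row(self, coord: Coord, region: str = "proliferating") -> int:
        coord = tuple(int(c) for c in coord)
        row = self._index.get(coord)
        if row is not None:
            return row
        if not self.in_bounds(coord):
            raise SimulationDomainError(
                f"tumor reached the mesh boundary at {coord}; "
                "re-run with larger dims")
        self.state.append_rows(1)
        row = self.state.n - 1
        self.coords = np.vstack([self.coords, np.array(coord)])
        self._index[coord] = row
        self.region.append(region)
        return row

    def totals(self) -> np.ndarray:
        if self._tot_version != self.state.version:
            self._tot_cache = self.state.total()
            self._tot_version = self.state.version
        return self._tot_cache

    def band_violations(self) -> List[Coord]:
        """Occupied GCs violating the density band.

        Above-band loads are violations anywhere.  Below-band loads are
        violations only in the tumor interior (all six face neighbours
        occupied): partially filled GCs are inherent to the growth frontier
        and to sites freshly freed by the expansion fallback, which refill
        from their overloaded neighbours over the following steps.
        """
        lo = (1.0 - self.margin) * self.NBC
        hi = (1.0 + self.margin) * self.NBC
        tot = self.totals()
        out = []
        for row in self.occupied_rows():
            coord = tuple(self.coords[row])
            if tot[row] > hi:
                out.append(coord)
                continue
            if tot[row] < lo:
                if coord in self.fallback_created:
                    continue
                interior = all(
                    self.is_occupied(tuple(np.add(coord, o))) for o in NEIGH6
                    if self.in_bounds(tuple(np.add(coord, o))))
                if interior:
                    out.append(coord)
            elif coord in self.fallback_created:
                self.fallback_created.discard(coord)
        return out

    def occupied_rows(self) -> np.ndarray:
        return np.flatnonzero(self.totals() > _EMPTY_TOL)

    def occupied_coords(self) -> np.ndarray:
        return self.coords[self.occupied_rows()]

    def is_occupied(self, coord: Coord) -> bool:
        row = self.row_at(coord)
        return row is not None and self.totals()[row] > _EMPTY_TOL

    def center_of_mass(self) -> np.ndarray:
        tot = self.totals()
        rows = self.occupied_rows()
        w = tot[rows]
        return (self.coords[rows] * w[:, None]).sum(axis=0) / w.sum()

    # -- ray helpers ----------------------------------------------------------
    def _ray(self, start: Coord, direction: Coord) -> List[Coord]:
        """Lattice sites from start (exclusive) along direction to the edge."""
        out = []
        c = np.array(start)
        d = np.array(direction)
        while True:
            c = c + d
            if not self.in_bounds(tuple(c)):
                break
            out.append(tuple(c))
        return out

    def outermost_occupied(self, start: Coord, direction: Coord) -> Optional[Coord]:
        last = None
        for c in self._ray(start, direction):
            if self.is_occupied(c):
                last = c
        return last


def tumor_volume(mesh: TumorMesh) -> float:
    """Occupied-GC count times the voxel volume, mm^3."""
    return len(mesh.occupied_rows()) * mesh.voxel_edge**3


def color_necrotic(mesh: TumorMesh, color_criterion: Optional[float] = None) -> np.ndarray:
    """Label volume: 0 background, 1 tumor, 2 necrotic GC.

    A GC is painted necrotic when its dead fraction reaches the criterion.
    """
    crit = mesh.params.color_criterion if color_criterion is None else color_criterion
    if not 0.9 <= crit <= 0.999:
        raise ValueError("color_criterion must lie in [0.9, 0.999]")
    labels = np.zeros(mesh.dims, dtype=np.int8)
    tot = mesh.totals()
    dead = mesh.state.dead()
    for row in mesh.occupied_rows():
        x, y, z = mesh.coords[row]
        labels[x, y, z] = 2 if dead[row] / tot[row] >= crit else 1
    return labels


def _free_space(mesh: TumorMesh, row: int) -> float:
    return mesh.NBC - mesh.totals()[row]


def _neighbor_rows(mesh: TumorMesh, coord: Coord,
                   offsets: Sequence[Coord] = NEIGH26) -> List[Coord]:
    return [tuple(np.add(coord, d)) for d in offsets
            if mesh.in_bounds(tuple(np.add(coord, d)))]


def _unload_to_neighbors(mesh: TumorMesh, row: int, amount: float,
                         require_occupied: bool = True) -> float:
    """Push up to ``amount`` cells to 26-neighbours with free space.

    Receivers are visited in order of decreasing free space; equal free
    space is broken by the mesh's seeded generator.  Returns the amount
    that could not be placed.
    """
    coord = tuple(mesh.coords[row])
    cands = []
    for nc in _neighbor_rows(mesh, coord):
        nrow = mesh.row_at(nc)
        if nrow is None:
            continue
        if require_occupied and mesh.totals()[nrow] <= _EMPTY_TOL:
            continue
        free = _free_space(mesh, nrow)
        if free > _EMPTY_TOL:
            cands.append((free, mesh.rng.random(), nrow))
    cands.sort(key=lambda t: (-t[0], t[1]))
    remaining = amount
    for free, _, nrow in cands:
        if remaining <= _EMPTY_TOL:
            break
        give = min(free, remaining)
        mesh.state.transfer(row, nrow, give)
        remaining -= give
    return max(remaining, 0.0)


def _shift_chain_outward(mesh: TumorMesh, start: Coord, direction: Coord) -> Coord:
    """Free the GC adjacent to ``start`` along ``direction``.

    The contents of the chain of GCs beginning at that adjacent site are
    pushed one GC outward; the first empty site along the ray (created if
    beyond the current tumor surface) terminates the chain.  Returns the
    freed adjacent coordinate.
    """
    ray = mesh._ray(start, direction)
    if not ray:
        raise SimulationDomainError(
            f"no room to expand from {start} along {direction}")
    # chain = leading run of occupied sites
    chain: List[Coord] = []
    for c in ray:
        if mesh.is_occupied(c):
            chain.append(c)
        else:
            break
    else:
        raise SimulationDomainError(
            f"tumor reached the mesh boundary expanding along {direction}")
    # receiving site just beyond the chain
    target = tuple(np.add(chain[-1], direction)) if chain else ray[0]
    mesh.ensure_row(target)
    for c in reversed(chain):
        mesh.state.move_all(mesh.row_at(c), mesh.row_at(target))
        if tuple(c) in mesh.fallback_created:
            mesh.fallback_created.discard(tuple(c))
            mesh.fallback_created.add(tuple(target))
        target = c
    return ray[0]


def _shift_chain_inward(mesh: TumorMesh, target: Coord, direction: Coord) -> None:
    """Slide the ray of GC contents along ``direction`` one step toward
    ``target`` (which receives the adjacent GC's contents)."""
    ray = mesh._ray(target, direction)
    outermost = None
    for i, c in enumerate(ray):
        if mesh.is_occupied(c):
            outermost = i
    if outermost is None:
        return
    mesh.ensure_row(target)
    prev = target
    for c in ray[: outermost + 1]:
        row = mesh.row_at(c)
        if row is not None and mesh.totals()[row] > _EMPTY_TOL:
            mesh.state.move_all(row, mesh.ensure_row(prev))
            if tuple(c) in mesh.fallback_created:
                mesh.fallback_created.discard(tuple(c))
                mesh.fallback_created.add(tuple(prev))
        prev = c


def rebalance_overloaded(mesh: TumorMesh, row: int) -> None:
    """Resolve a GC above the occupancy band.

    The excess above NBC is unloaded to 26-neighbours with free space
    (largest free space first); if excess remains, an adjacent GC along a
    randomly selected direction is freed by an outward chain shift and
    receives it (differential expansion).
    """
    excess = mesh.totals()[row] - mesh.NBC
    if mesh.totals()[row] <= (1.0 + mesh.margin) * mesh.NBC:
        return
    remaining = _unload_to_neighbors(mesh, row, excess)
    if remaining > _EMPTY_TOL:
        coord = tuple(mesh.coords[row])
        # random direction; directions blocked by the mesh boundary are
        # redrawn, and only when every direction is blocked has the tumor
        # truly outgrown the simulation domain
        order = mesh.rng.permutation(len(NEIGH26))
        last_err: Optional[SimulationDomainError] = None
        for i in order:
            direction = NEIGH26[i]
            try:
                freed = _shift_chain_outward(mesh, coord, direction)
            except SimulationDomainError as e:
                last_err = e
                continue
            mesh.state.transfer(row, mesh.ensure_row(freed), remaining)
            mesh.fallback_created.add(tuple(freed))
            mesh.fallback_log.append(
                {"event": "expansion-chain", "coord": coord,
                 "direction": direction})
            return
        raise last_err or SimulationDomainError(f"cannot expand from {coord}")


def _pick_inward_direction(mesh: TumorMesh, coord: Coord) -> Optional[Coord]:
    """Six random directions; keep the one whose outermost occupied GC has
    the most 6-neighbours inside the tumor (NGCT)."""
    dirs = [NEIGH26[i] for i in mesh.rng.choice(len(NEIGH26), size=6, replace=False)]
    best, best_ngct, best_tie = None, -1, 0.0
    for d in dirs:
        outer = mesh.outermost_occupied(coord, d)
        if outer is None:
            continue
        ngct = sum(mesh.is_occupied(tuple(np.add(outer, o))) for o in NEIGH6)
        tie = mesh.rng.random()
        if ngct > best_ngct or (ngct == best_ngct and tie > best_tie):
            best, best_ngct, best_tie = d, ngct, tie
    return best


def rebalance_underloaded(mesh: TumorMesh, row: int) -> None:
    """Resolve a GC below the occupancy band.

    All its cells are offered to 26-neighbours with free space; if the GC
    empties, a chain of GC contents is shifted inward to fill the vacuum
    (differential shrinkage).
    """
    tot = mesh.totals()[row]
    if not (0 < tot < (1.0 - mesh.margin) * mesh.NBC):
        return
    remaining = _unload_to_neighbors(mesh, row, tot)
    if remaining <= _EMPTY_TOL:
        coord = tuple(mesh.coords[row])
        direction = _pick_inward_direction(mesh, coord)
        if direction is not None:
            _shift_chain_inward(mesh, coord, direction)


def repair_fragmentation(mesh: TumorMesh, max_iter: int = 100) -> None:
    """Restore macroscopic cohesion after the mechanical rules.

    Iterates to a fixpoint: occupied GCs whose entire 6-neighbourhood is
    empty move one GC toward the center of mass along the coordinate axis
    with the smallest non-zero offset (ties broken by the seeded
    generator); empty GCs fully enclosed by occupied 6-neighbours are
    filled through the shrinkage chain shift.
    """
    for _ in range(max_iter):
        changed = False
        rows = mesh.occupied_rows()
        if len(rows) <= 1:
            return
        com = mesh.center_of_mass()
        # (I) detached GCs drift toward the center of mass
        for row in rows:
            coord = tuple(mesh.coords[row])
            if mesh.totals()[row] <= _EMPTY_TOL:
                continue
            if any(mesh.is_occupied(n) for n in _neighbor_rows(mesh, coord, NEIGH6)):
                continue
            offset = com - np.array(coord)
            axes = [a for a in range(3) if abs(offset[a]) >= 0.5]
            if not axes:
                continue
            dmin = min(abs(offset[a]) for a in axes)
            best = [a for a in axes if abs(offset[a]) == dmin]
            axis = best[mesh.rng.integers(len(best))] if len(best) > 1 else best[0]
            step = np.zeros(3, dtype=int)
            step[axis] = 1 if offset[axis] > 0 else -1
            target = tuple(np.array(coord) + step)
            trow = mesh.ensure_row(target)
            mesh.state.move_all(row, trow)
            # merging into an occupied site may overload it
            if mesh.totals()[trow] > (1.0 + mesh.margin) * mesh.NBC:
                rebalance_overloaded(mesh, trow)
            changed = True
        # (II) enclosed holes are filled by the shrinkage procedure
        occ = {tuple(c) for c in mesh.occupied_coords()}
        holes = set()
        for c in occ:
            for n in _neighbor_rows(mesh, c, NEIGH6):
                if n in occ or n in holes:
                    continue
                if all(mesh.is_occupied(tuple(np.add(n, o))) for o in NEIGH6
                       if mesh.in_bounds(tuple(np.add(n, o)))):
                    if all(mesh.in_bounds(tuple(np.add(n, o))) for o in NEIGH6):
                        holes.add(n)
        for hole in holes:
            direction = _pick_inward_direction(mesh, hole)
            if direction is not None:
                _shift_chain_inward(mesh, hole, direction)
                changed = True
        if not changed:
            return


def second_scan(mesh: TumorMesh) -> None:
    """Full mechanical pass: band rebalancing then cohesion repair.

    GCs are visited in lexicographic coordinate order starting from a
    random origin offset (avoids directional drift of the scan order).
    """
    rows = mesh.occupied_rows()
    if len(rows) == 0:
        return
    offset = mesh.rng.integers(0, np.maximum(mesh.dims, 1))
    keys = (mesh.coords[rows] + offset) % np.array(mesh.dims)
    order = rows[np.lexsort((keys[:, 2], keys[:, 1], keys[:, 0]))]
    lo = (1.0 - mesh.margin) * mesh.NBC
    hi = (1.0 + mesh.margin) * mesh.NBC
    for row in order:
        tot = mesh.totals()[row]
        if tot > hi:
            rebalance_overloaded(mesh, row)
        elif 0 < tot < lo:
            rebalance_underloaded(mesh, row)
    repair_fragmentation(mesh)
    # chain shifts can relocate a not-yet-visited overload into an
    # already-visited site; sweep until the upper band holds everywhere
    swept = False
    for _ in range(5):
        over = [r for r in mesh.occupied_rows()
                if mesh.totals()[r] > hi * (1 + 1e-12)]
        if not over:
            break
        swept = True
        for row in over:
            rebalance_overloaded(mesh, row)
    if swept:
        # the sweep's own chain shifts may detach GCs along diagonals
        repair_fragmentation(mesh)
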