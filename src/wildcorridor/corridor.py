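"""Least-cost corridor tracing on a composite cost surface.

The accumulated-cost surface is built by Dijkstra's algorithm over the
8-connected cell graph: moving between adjacent cells a and b costs the
mean of their cell costs times the step length (1 cell for orthogonal
moves, sqrt(2) for diagonal) — the standard GIS cost-distance convention.
The destination park supplies the Dijkstra sources; each start cell at the
other park's periphery is then traced back along the backlink grid,
yielding one least-cost path per start.

Downstream analyses annotate the traced paths: shared-segment
decomposition where multiple paths merge, weak-link flagging where the
forest narrows or fragmentation is severe, a variable-width corridor
buffer, and along-path water-gap analysis with proposed waterhole sites.

Determinism: neighbours are visited in the fixed order N, NE, E, SE, S,
SW, W, NW and the priority queue breaks ties by insertion order, so a
given cost surface always yields the same paths.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point
from shapely.ops import unary_union

from .raster_core import Grid, GridSpec, euclidean_distance

# neighbour offsets in deterministic visit order: N, NE, E, SE, S, SW, W, NW
NEIGHBOURS_8 = (
    (-1, 0),
    (-1, 1),
    (0, 1),
    (1, 1),
    (1, 0),
    (1, -1),
    (0, -1),
    (-1, -1),
)
NEIGHBOURS_4 = ((-1, 0), (0, 1), (1, 0), (0, -1))

# backlink codes: 0 = source/undefined, 1..8 index into NEIGHBOURS_8
# meaning "the previous cell on the optimal route lies in that direction".


@dataclass
class AccumulatedCost:
    """Minimal cumulative movement cost to any source cell, plus backlinks.

    ``acc`` is in cost-distance units (cell cost x cells travelled);
    ``backlink`` holds direction codes 0-8 (0 at sources and unreachable
    cells; 1-8 index the neighbour offsets N..NW pointing toward the
    predecessor on one optimal route).
    """

    acc: Grid
    backlink: Grid
    cost: Grid | None = None  # the cost surface the accumulation ran on


@dataclass
class WeakLink:
    """A fragile span of the corridor: forest too narrow or too fragmented."""

    span: list[tuple[int, int]]
    min_width_km: float
    cause: str  # "constriction" | "fragmentation"


@dataclass
class CorridorPath:
    """An ordered cell trace from a start cell back to the source cell."""

    cells: list[tuple[int, int]]
    length_km: float
    total_cost: float
    annotations: list[WeakLink] = field(default_factory=list)


def _step_lengths_km(cells: list[tuple[int, int]], cell_size: float) -> np.ndarray:
    if len(cells) < 2:
        return np.zeros(0)
    arr = np.asarray(cells, dtype=float)
    d = np.abs(np.diff(arr, axis=0))
    steps = np.where(d.sum(axis=1) == 2, math.sqrt(2.0), 1.0) * cell_size / 1000.0
    return steps


def path_length_km(cells: list[tuple[int, int]], cell_size: float) -> float:
    return float(_step_lengths_km(cells, cell_size).sum())


def accumulate(
    cm: Grid, sources: list[tuple[int, int]], connectivity: int = 8
) -> AccumulatedCost:
    """Dijkstra accumulation of movement cost from the source cells.

    Transition cost between adjacent cells a, b is
    ((cm[a] + cm[b]) / 2) * (1 orthogonal | sqrt(2) diagonal), in cell
    units. Unreachable / nodata cells hold +inf in ``acc``.
    """
    vals = np.asarray(cm.values, dtype=float)
    nodata = cm.spec.nodata
    valid = vals != nodata
    if not valid.any():
        raise ValueError("accumulate: all-nodata cost grid")
    if not sources:
        raise ValueError("accumulate: no source cells")
    if np.any(vals[valid] < 0):
        raise ValueError("accumulate: negative cost cells")
    n_rows, n_cols = cm.spec.shape
    offsets = NEIGHBOURS_8 if connectivity == 8 else NEIGHBOURS_4
    acc = np.full((n_rows, n_cols), np.inf)
    back = np.zeros((n_rows, n_cols), dtype=np.int8)
    done = np.zeros((n_rows, n_cols), dtype=bool)
    heap: list[tuple[float, int, int, int]] = []
    counter = 0
    for r, c in sources:
        if not (0 <= r < n_rows and 0 <= c < n_cols) or not valid[r, c]:
            raise ValueError(f"source cell ({r}, {c}) is off-grid or nodata")
        acc[r, c] = 0.0
        heapq.heappush(heap, (0.0, counter, r, c))
        counter += 1
    while heap:
        d, _, r, c = heapq.heappop(heap)
        if done[r, c]:
            continue
        done[r, c] = True
        here = vals[r, c]
        for code, (dr, dc) in enumerate(offsets, start=1):
            nr, nc = r + dr, c + dc
            if not (0 <= nr < n_rows and 0 <= nc < n_cols):
                continue
            if done[nr, nc] or not valid[nr, nc]:
                continue
            step = math.sqrt(2.0) if dr != 0 and dc != 0 else 1.0
            nd = d + 0.5 * (here + vals[nr, nc]) * step
            if nd < acc[nr, nc]:
                acc[nr, nc] = nd
                # backlink points from neighbour toward (r, c): opposite offset
                back[nr, nc] = _opposite_code(code, offsets)
                heapq.heappush(heap, (nd, counter, nr, nc))
                counter += 1
    return AccumulatedCost(
        Grid(cm.spec, acc, "accumulated"), Grid(cm.spec, back, "categorical"), cm
    )


def _opposite_code(code: int, offsets: tuple) -> int:
    dr, dc = offsets[code - 1]
    return offsets.index((-dr, -dc)) + 1


def trace(accres: AccumulatedCost, start: tuple[int, int]) -> CorridorPath:
    """Walk from a start cell down the accumulated-cost surface to a source.

    Each step picks the neighbour minimising acc + transition cost in the
    fixed N..NW order, comparing with a relative tolerance so that equal-cost
    alternatives resolve identically regardless of any positive scaling of
    the cost surface; on exact-cost plateaus (zero-cost regions) the stored
    backlink supplies the direction.
    """
    acc = np.asarray(accres.acc.values)
    back = np.asarray(accres.backlink.values).astype(int)
    cm = np.asarray(accres.cost.values) if accres.cost is not None else None
    offsets = NEIGHBOURS_8
    n_rows, n_cols = acc.shape
    r, c = start
    if not np.isfinite(acc[r, c]):
        raise ValueError(f"start cell {start} is unreachable")
    cells = [(r, c)]
    rel = 1e-9
    while back[r, c] != 0:
        step_to = None
        if cm is not None:
            best_val = math.inf
            for dr, dc in offsets:
                nr, nc = r + dr, c + dc
                if not (0 <= nr < n_rows and 0 <= nc < n_cols):
                    continue
                if not np.isfinite(acc[nr, nc]) or acc[nr, nc] >= acc[r, c]:
                    continue
                step = math.sqrt(2.0) if dr != 0 and dc != 0 else 1.0
                val = acc[nr, nc] + 0.5 * (cm[nr, nc] + cm[r, c]) * step
                if step_to is None or val < best_val - rel * max(1.0, abs(best_val)):
                    best_val = val
                    step_to = (nr, nc)
            # only accept a strictly descending, cost-consistent step
            if step_to is not None and not (
                best_val <= acc[r, c] + rel * max(1.0, acc[r, c])
            ):
                step_to = None
        if step_to is None:
            dr, dc = offsets[back[r, c] - 1]
            step_to = (r + dr, c + dc)
        r, c = step_to
        cells.append((r, c))
    cell_size = accres.acc.spec.cell_size
    return CorridorPath(
        cells=cells,
        length_km=path_length_km(cells, cell_size),
        total_cost=float(acc[start]),
    )


@dataclass
class PathSegment:
    """A maximal run of cells shared by a fixed set of paths."""

    cells: list[tuple[int, int]]
    members: frozenset[int]
    length_km: float

    @property
    def is_common(self) -> bool:
        return len(self.members) >= 2


def shared_segments(
    paths: list[CorridorPath], cell_size: float
) -> list[PathSegment]:
    """Decompose paths converging on one source into common and private segments.

    Paths traced on one Dijkstra backlink tree share suffixes: once two
    paths meet they run together to the source, so the shared structure is
    laminar. Working from the source end, the maximal suffix common to a
    group of paths becomes one segment; the group then splits at the
    divergence cell and each subgroup is decomposed recursively. A child
    segment's length includes its joining step to the parent segment, so
    each path's total length equals the sum of the lengths of the segments
    it belongs to.
    """
    if len(paths) < 2:
        raise ValueError("shared_segments needs at least two paths")
    rev = [list(reversed(p.cells)) for p in paths]
    segments: list[PathSegment] = []

    def recurse(group: list[int], depth: int, junction: tuple[int, int] | None) -> None:
        i = depth
        min_len = min(len(rev[k]) for k in group)
        while i < min_len and len({rev[k][i] for k in group}) == 1:
            i += 1
        run = rev[group[0]][depth:i]
        cells_for_len = ([junction] + run) if junction is not None else run
        segments.append(
            PathSegment(
                list(reversed(run)),
                frozenset(group),
                path_length_km(cells_for_len, cell_size),
            )
        )
        survivors = [k for k in group if len(rev[k]) > i]
        if not survivors:
            return
        subgroups: dict[tuple[int, int], list[int]] = {}
        for k in survivors:
            subgroups.setdefault(rev[k][i], []).append(k)
        new_junction = rev[group[0]][i - 1] if i > depth else junction
        for _, sub in sorted(subgroups.items()):
            recurse(sub, i, new_junction)

    recurse(list(range(len(paths))), 0, None)
    return segments


def forest_width_km(forest: Grid) -> Grid:
    """Forest width at each cell: twice the distance to the nearest non-forest cell, km."""
    vals = np.asarray(forest.values)
    nonforest = Grid(forest.spec, (vals == 0).astype(float), "categorical")
    if not (vals == 0).any():
        # infinite forest: no non-forest anywhere
        return Grid(forest.spec, np.full(forest.spec.shape, np.inf), "continuous")
    dist = euclidean_distance(nonforest, forest.spec)
    return Grid(forest.spec, 2.0 * dist.values / 1000.0, "continuous")


def weak_links(
    path: CorridorPath,
    forest: Grid,
    width_threshold_km: float = 4.0,
    edge_cost: Grid | None = None,
    fragmentation_cost: float = 8.0,
) -> list[WeakLink]:
    """Flag spans of the path where the forest is too narrow.

    Width at a path cell is twice its distance to the nearest non-forest
    cell. Maximal runs of consecutive cells with width strictly below the
    threshold become weak links (cause ``constriction``); a run whose
    maximum hexagon edge cost reaches ``fragmentation_cost`` is instead
    attributed to ``fragmentation``.
    """
    width = np.asarray(forest_width_km(forest).values)
    ecost = np.asarray(edge_cost.values) if edge_cost is not None else None
    links: list[WeakLink] = []
    run: list[tuple[int, int]] = []

    def close_run() -> None:
        if not run:
            return
        w = min(width[r, c] for r, c in run)
        cause = "constriction"
        if ecost is not None and max(ecost[r, c] for r, c in run) >= fragmentation_cost:
            cause = "fragmentation"
        links.append(WeakLink(list(run), float(w), cause))
        run.clear()

    for r, c in path.cells:
        if width[r, c] < width_threshold_km:
            run.append((r, c))
        else:
            close_run()
    close_run()
    return links


def buffer_corridor(
    path: CorridorPath,
    spec: GridSpec,
    min_km: float,
    max_km: float,
    weak: list[WeakLink] | None = None,
):
    """Variable-width corridor polygon around the traced path.

    Union of per-cell discs: radius ``max_km`` where the forest is
    continuous, ``min_km`` inside weak-link spans, with a linear taper
    (1 km of radius per km along the path) at span boundaries.
    """
    if not (0 < min_km <= max_km):
        raise ValueError("require 0 < min_km <= max_km")
    n = len(path.cells)
    radius = np.full(n, max_km)
    if weak:
        index_of = {cell: i for i, cell in enumerate(path.cells)}
        steps = _step_lengths_km(path.cells, spec.cell_size)
        along = np.concatenate([[0.0], np.cumsum(steps)])
        weak_idx = [index_of[c] for wl in weak for c in wl.span if c in index_of]
        if weak_idx:
            weak_pos = along[weak_idx]
            # taper: radius limited by min_km + distance to nearest weak cell
            dist_to_weak = np.min(
                np.abs(along[:, None] - weak_pos[None, :]), axis=1
            )
            radius = np.minimum(max_km, min_km + dist_to_weak)
    discs = [
        Point(spec.cell_center(r, c)).buffer(radius[i] * 1000.0, quad_segs=32)
        for i, (r, c) in enumerate(path.cells)
    ]
    return unary_union(discs)


@dataclass
class WaterGap:
    """A corridor span farther from perennial water than the allowed maximum."""

    span: list[tuple[int, int]]
    length_km: float
    proposed_waterholes: list[tuple[int, int]]


def water_gaps(
    path: CorridorPath, water_distance: Grid, max_km: float
) -> list[WaterGap]:
    """Find path spans beyond ``max_km`` of water and propose waterhole cells.

    Waterholes are placed greedily from the midpoint of each gap outwards,
    spaced 2 x max_km along the path, so that afterwards no path cell is
    farther than ``max_km`` from water (existing or proposed).
    """
    if max_km <= 0:
        raise ValueError("max_km must be > 0")
    if not math.isfinite(max_km):
        return []
    dist = np.asarray(water_distance.values)
    cell_size = water_distance.spec.cell_size
    steps = _step_lengths_km(path.cells, cell_size)
    along = np.concatenate([[0.0], np.cumsum(steps)])
    far = [dist[r, c] > max_km * 1000.0 for r, c in path.cells]
    gaps: list[WaterGap] = []
    i = 0
    n = len(path.cells)
    while i < n:
        if not far[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and far[j + 1]:
            j += 1
        span = path.cells[i : j + 1]
        length = float(along[j] - along[i])
        holes = _place_waterholes(path.cells, along, i, j, max_km)
        gaps.append(WaterGap(span, length, holes))
        i = j + 1
    return gaps


def _place_waterholes(
    cells: list[tuple[int, int]],
    along: np.ndarray,
    i: int,
    j: int,
    max_km: float,
) -> list[tuple[int, int]]:
    """Greedy midpoint-outward placement along the gap span [i, j]."""
    lo, hi = along[i], along[j]
    mid = 0.5 * (lo + hi)
    positions = [mid]
    k = 1
    while mid - k * 2 * max_km > lo - max_km or mid + k * 2 * max_km < hi + max_km:
        left = mid - k * 2 * max_km
        right = mid + k * 2 * max_km
        placed = False
        if left > lo - max_km:
            positions.append(left)
            placed = True
        if right < hi + max_km:
            positions.append(right)
            placed = True
        if not placed:
            break
        k += 1
    holes = []
    for pos in sorted(positions):
        idx = int(np.argmin(np.abs(along[i : j + 1] - pos))) + i
        if cells[idx] not in holes:
            holes.append(cells[idx])
    return holes
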