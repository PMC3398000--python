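"""Hexagon tessellation and per-hexagon Total Edge (TE).

Fragmentation is scored by tessellating the landscape into hexagonal units
and computing, within each hexagon, the total length of boundary between
forest and non-forest. Edge is measured on the raster as rook-adjacency
class transitions multiplied by the cell edge length — the standard
raster-mode equivalent of the FRAGSTATS Total Edge metric. The landscape
boundary itself contributes no edge (boundary proportion fixed at 0).

Hexagons are flat-top, ``width`` being the flat-to-flat diameter; every
raster cell centre is assigned to exactly one hexagon by axial-coordinate
rounding, so the tessellation partitions the grid with no gaps or overlaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .raster_core import Grid, GridSpec

SQRT3 = math.sqrt(3.0)

# TE (metres) -> cost rank bins; half-open, last closed above. TE below the
# first bin's lower bound maps to the lowest cost for continuity.
TE_COST_BINS: list[tuple[float, float, int]] = [
    (0.0, 27_000.0, 0),
    (27_000.0, 35_000.0, 4),
    (35_000.0, 59_000.0, 6),
    (59_000.0, 77_000.0, 8),
    (77_000.0, float("inf"), 10),
]


@dataclass(frozen=True)
class HexCell:
    """One hexagonal landscape unit: id, centre, polygon and flat-to-flat width."""

    id: int
    centre: tuple[float, float]
    polygon: Polygon
    width: float


@dataclass(frozen=True)
class EdgeReport:
    hex_id: int
    total_edge: float
    category_cost: int


def _hex_polygon(cx: float, cy: float, side: float) -> Polygon:
    # flat-top: vertices at 0, 60, ..., 300 degrees
    pts = [
        (cx + side * math.cos(math.radians(a)), cy + side * math.sin(math.radians(a)))
        for a in range(0, 360, 60)
    ]
    return Polygon(pts)


def hex_assignment(spec: GridSpec, hex_width: float) -> tuple[np.ndarray, dict[tuple[int, int], int]]:
    """Assign every cell centre to a flat-top hexagon by cube rounding.

    Returns (assignment array of hex ids, axial-coordinate -> hex id map).
    """
    if hex_width < 3 * spec.cell_size:
        raise ValueError("hex_width must be at least 3 x cell_size")
    side = hex_width / SQRT3  # circumradius of a flat-top hex of flat-to-flat hex_width
    xs, ys = spec.cell_centers()
    # fractional axial coordinates (flat-top convention)
    q = (2.0 / 3.0) * xs / side
    r = (-1.0 / 3.0 * xs + SQRT3 / 3.0 * ys) / side
    # cube rounding
    x, z = q, r
    y = -x - z
    rx, ry, rz = np.round(x), np.round(y), np.round(z)
    dx, dy, dz = np.abs(rx - x), np.abs(ry - y), np.abs(rz - z)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    rx = np.where(fix_x, -ry - rz, rx)
    rz = np.where(fix_z, -rx - ry, rz)
    axial = np.stack([rx.astype(int), rz.astype(int)], axis=-1)
    ids: dict[tuple[int, int], int] = {}
    assign = np.empty(spec.shape, dtype=int)
    flat_ax = axial.reshape(-1, 2)
    flat_assign = assign.reshape(-1)
    for i, (aq, ar) in enumerate(map(tuple, flat_ax)):
        key = (aq, ar)
        if key not in ids:
            ids[key] = len(ids)
        flat_assign[i] = ids[key]
    return assign, ids


def tessellate(spec: GridSpec, hex_width: float) -> tuple[list[HexCell], np.ndarray]:
    """Tile the grid extent with flat-top hexagons.

    Returns the hexagons (only those owning at least one cell centre) and
    the per-cell assignment array of hexagon ids.
    """
    assign, ids = hex_assignment(spec, hex_width)
    side = hex_width / SQRT3
    hexes = []
    for (aq, ar), hid in ids.items():
        cx = side * 1.5 * aq
        cy = side * (SQRT3 / 2.0 * aq + SQRT3 * ar)
        hexes.append(HexCell(hid, (cx, cy), _hex_polygon(cx, cy, side), hex_width))
    hexes.sort(key=lambda h: h.id)
    return hexes, assign


def total_edge(
    forest: Grid, hexes: list[HexCell], assign: np.ndarray
) -> list[EdgeReport]:
    """Per-hexagon Total Edge on a binary forest raster.

    TE = number of rook-adjacent cell pairs with differing class x cell
    size. Pairs inside one hexagon count for it; pairs straddling two
    hexagons count once, for the hexagon of the lexicographically smaller
    cell. Landscape-boundary edges are not counted.
    """
    v = np.asarray(forest.values)
    uniq = np.unique(v)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError("total_edge: forest grid must be binary (0/1)")
    cs = forest.spec.cell_size
    n_hex = len(hexes)
    te = np.zeros(n_hex, dtype=float)
    # vertical pairs: (r, c)-(r+1, c); lexicographically smaller cell is (r, c)
    diff_v = v[:-1, :] != v[1:, :]
    owner_v = assign[:-1, :]
    np.add.at(te, owner_v[diff_v], cs)
    # horizontal pairs: (r, c)-(r, c+1)
    diff_h = v[:, :-1] != v[:, 1:]
    owner_h = assign[:, :-1]
    np.add.at(te, owner_h[diff_h], cs)
    return [
        EdgeReport(h.id, float(te[h.id]), _te_cost(float(te[h.id]))) for h in hexes
    ]


def _te_cost(te_metres: float) -> int:
    for lo, hi, cost in TE_COST_BINS:
        if lo <= te_metres < hi:
            return cost
    return TE_COST_BINS[-1][2]


def edge_cost_grid(
    reports: list[EdgeReport], hexes: list[HexCell], spec: GridSpec, assign: np.ndarray
) -> Grid:
    """Spread each hexagon's TE cost rank onto its raster cells."""
    by_id = {r.hex_id: r.category_cost for r in reports}
    missing = {h.id for h in hexes} - set(by_id)
    if missing:
        raise ValueError(f"edge_cost_grid: hexagons without report: {sorted(missing)}")
    lut = np.zeros(max(by_id) + 1, dtype=float)
    for hid, cost in by_id.items():
        lut[hid] = cost
    return Grid(spec, lut[assign], "cost")
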