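"""Raster primitives for cost-surface modelling.

Everything downstream (cost layers, composite movement cost, accumulated
cost, corridor tracing) operates on a single grid model: a 2D array of
values on a uniform planar-metre grid, row 0 being the northernmost row.
This module provides that grid model plus the four primitives every cost
surface is built from: rasterization of vector layers, table-driven
reclassification, the Euclidean distance transform, and kernel line/point
density.

Distances are measured cell-centre to cell-centre; sub-cell geometry is
ignored, matching the resolution at which least-cost paths are traced.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from shapely import STRtree, box
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

NODATA_DEFAULT = -9999.0

GRID_KINDS = ("categorical", "continuous", "cost", "accumulated")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster: shape, cell size and top-left origin in planar metres.

    All grids combined in one analysis must share an identical GridSpec.
    ``origin_x``/``origin_y`` locate the outer corner of cell (0, 0); row 0
    is the northernmost row, so y decreases with increasing row index.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata: float = NODATA_DEFAULT

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full raster footprint."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y - (row + 0.5) * self.cell_size
        return (x, y)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (xs, ys) of all cell centres, shape (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        xs = self.origin_x + (cols + 0.5) * self.cell_size
        ys = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        col = int(math.floor((x - self.origin_x) / self.cell_size))
        row = int(math.floor((self.origin_y - y) / self.cell_size))
        return (row, col)


@dataclass
class Grid:
    """A raster layer: values on a GridSpec, tagged by kind.

    kind is one of 'categorical', 'continuous', 'cost', 'accumulated'.
    Cells equal to ``spec.nodata`` are missing; NaN is not used except
    where it stands in for nodata internally.
    """

    spec: GridSpec
    values: np.ndarray
    kind: str = "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != spec shape {self.spec.shape}"
            )
        if self.kind not in GRID_KINDS:
            raise ValueError(f"unknown grid kind {self.kind!r}")

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.values == self.spec.nodata

    def copy_with(self, values: np.ndarray, kind: str | None = None) -> "Grid":
        return Grid(self.spec, values, kind or self.kind)


@dataclass
class VectorLayer:
    """Vector features in planar metres with per-feature attributes.

    geometry_type is 'point', 'polyline' or 'polygon'; features are
    (shapely geometry, attribute dict) pairs.
    """

    geometry_type: str
    features: list[tuple[BaseGeometry, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.geometry_type not in ("point", "polyline", "polygon"):
            raise ValueError(f"unknown geometry_type {self.geometry_type!r}")
        for geom, _ in self.features:
            if self.geometry_type == "polyline" and len(geom.coords) < 2:
                raise ValueError("polyline features need at least 2 vertices")

    def require_attribute(self, name: str) -> None:
        for i, (_, attrs) in enumerate(self.features):
            if name not in attrs:
                raise KeyError(f"feature {i} lacks required attribute {name!r}")

    def __len__(self) -> int:
        return len(self.features)


class CostTable:
    """Ordered mapping from category labels or half-open numeric ranges to cost ranks.

    Numeric entries are half-open intervals [lo, hi); the last interval is
    closed above (values >= its lower bound match), so densities beyond the
    observed range clamp to the top category. Category entries match labels
    exactly. ``default`` supplies the cost for unmatched values; without it
    an unmatched value is an error naming the value.
    """

    def __init__(
        self,
        name: str,
        entries: Sequence[tuple[object, int]],
        default: int | None = None,
    ) -> None:
        self.name = name
        self.default = default
        self.categorical_entries: dict[object, int] = {}
        self.interval_entries: list[tuple[float, float, int]] = []
        for match, cost in entries:
            if cost < 0:
                raise ValueError("cost ranks must be >= 0")
            if isinstance(match, (tuple, list)) and len(match) == 2:
                lo, hi = float(match[0]), float(match[1])
                self.interval_entries.append((lo, hi, int(cost)))
            else:
                self.categorical_entries[match] = int(cost)
        self.interval_entries.sort(key=lambda e: e[0])
        for (lo1, hi1, _), (lo2, _, _) in zip(
            self.interval_entries, self.interval_entries[1:]
        ):
            if lo2 < hi1:
                raise ValueError(f"overlapping intervals in cost table {name!r}")

    @property
    def is_numeric(self) -> bool:
        return bool(self.interval_entries)

    def lookup(self, value: object) -> int:
        if value in self.categorical_entries:
            return self.categorical_entries[value]
        if self.is_numeric and not isinstance(value, str):
            v = float(value)  # type: ignore[arg-type]
            for i, (lo, hi, cost) in enumerate(self.interval_entries):
                last = i == len(self.interval_entries) - 1
                if lo <= v < hi or (last and v >= lo):
                    return cost
        if self.default is not None:
            return self.default
        raise KeyError(f"value {value!r} not matched by cost table {self.name!r}")

    def apply(self, values: np.ndarray, nodata: float) -> np.ndarray:
        """Vectorised lookup; nodata propagates unchanged."""
        out = np.full(values.shape, nodata, dtype=float)
        valid = values != nodata
        if self.is_numeric:
            matched = np.zeros(values.shape, dtype=bool)
            v = values.astype(float)
            for i, (lo, hi, cost) in enumerate(self.interval_entries):
                last = i == len(self.interval_entries) - 1
                sel = valid & ~matched & (v >= lo) & ((v < hi) | last)
                out[sel] = cost
                matched |= sel
            unmatched = valid & ~matched
        else:
            matched = np.zeros(values.shape, dtype=bool)
            for label, cost in self.categorical_entries.items():
                sel = valid & (values == label)
                out[sel] = cost
                matched |= sel
            unmatched = valid & ~matched
        if unmatched.any():
            if self.default is not None:
                out[unmatched] = self.default
            else:
                r, c = np.argwhere(unmatched)[0]
                raise KeyError(
                    f"value {values[r, c]!r} at cell ({r}, {c}) not matched by "
                    f"cost table {self.name!r}"
                )
        return out


# ---------------------------------------------------------------------------
# operations


def _cell_boxes(spec: GridSpec) -> np.ndarray:
    """All cell footprints as shapely boxes, row-major order."""
    cols = np.arange(spec.n_cols)
    rows = np.arange(spec.n_rows)
    cgrid, rgrid = np.meshgrid(cols, rows)
    x0 = spec.origin_x + cgrid * spec.cell_size
    y1 = spec.origin_y - rgrid * spec.cell_size
    return box(
        x0.ravel(), (y1 - spec.cell_size).ravel(), (x0 + spec.cell_size).ravel(), y1.ravel()
    )


def rasterize(layer: VectorLayer, spec: GridSpec, mode: str = "presence") -> Grid:
    """Burn a vector layer onto the grid.

    presence mode: 1 where any feature geometry intersects the cell
    footprint, else 0.  attribute mode: ``mode`` is ``("attribute", name)``
    or use :func:`rasterize_attribute`; intersected cells carry the
    feature's attribute, others nodata.
    """
    if mode not in ("presence",):
        raise ValueError("use rasterize_attribute for attribute burning")
    out = np.zeros(spec.shape, dtype=float)
    if not layer.features:
        logger.warning("rasterize: empty layer -> all-zero grid")
        return Grid(spec, out, "categorical")
    boxes = _cell_boxes(spec)
    tree = STRtree(boxes)
    flat = out.ravel()
    for geom, _ in layer.features:
        idx = tree.query(geom, predicate="intersects")
        flat[idx] = 1.0
    return Grid(spec, flat.reshape(spec.shape), "categorical")


def rasterize_attribute(layer: VectorLayer, spec: GridSpec, attr: str) -> Grid:
    """Burn a numeric attribute into every cell a feature intersects; nodata elsewhere.

    Later features overwrite earlier ones where they overlap.
    """
    layer.require_attribute(attr)
    out = np.full(spec.shape, spec.nodata, dtype=float)
    if not layer.features:
        logger.warning("rasterize_attribute: empty layer -> all-nodata grid")
        return Grid(spec, out, "continuous")
    boxes = _cell_boxes(spec)
    tree = STRtree(boxes)
    flat = out.ravel()
    for geom, attrs in layer.features:
        idx = tree.query(geom, predicate="intersects")
        flat[idx] = float(attrs[attr])
    return Grid(spec, flat.reshape(spec.shape), "continuous")


def reclassify(grid: Grid, table: CostTable) -> Grid:
    """Map every non-nodata cell through the cost table; result is cost-kind."""
    values = table.apply(np.asarray(grid.values), grid.spec.nodata)
    return Grid(grid.spec, values, "cost")


def euclidean_distance(sources: Grid, spec: GridSpec | None = None) -> Grid:
    """Metres from each cell centre to the nearest source-cell centre.

    ``sources`` is a binary grid (nonzero = source). Exact Euclidean
    distance transform; 0 at source cells.
    """
    spec = spec or sources.spec
    mask = np.asarray(sources.values) != 0
    if not mask.any():
        raise ValueError("euclidean_distance: no source cells")
    dist = ndimage.distance_transform_edt(~mask, sampling=spec.cell_size)
    return Grid(spec, dist.astype(float), "continuous")


def _clipped_segment_length(
    p0: np.ndarray, p1: np.ndarray, cx: np.ndarray, cy: np.ndarray, radius: float
) -> np.ndarray:
    """Length of segment p0-p1 inside circles centred at (cx, cy).

    Closed-form quadratic clipping, vectorised over circle centres.
    """
    d = p1 - p0
    seg_len = math.hypot(d[0], d[1])
    if seg_len == 0:
        return np.zeros_like(cx)
    fx = p0[0] - cx
    fy = p0[1] - cy
    a = d[0] * d[0] + d[1] * d[1]
    b = 2.0 * (fx * d[0] + fy * d[1])
    c = fx * fx + fy * fy - radius * radius
    disc = b * b - 4.0 * a * c
    out = np.zeros_like(cx, dtype=float)
    ok = disc > 0
    if not np.any(ok):
        return out
    sq = np.sqrt(np.where(ok, disc, 0.0))
    t1 = np.clip((-b - sq) / (2.0 * a), 0.0, 1.0)
    t2 = np.clip((-b + sq) / (2.0 * a), 0.0, 1.0)
    out[ok] = (t2 - t1)[ok] * seg_len
    return out


def line_density(
    lines: VectorLayer, weight_attr: str | None, spec: GridSpec, radius: float
) -> Grid:
    """Kernel line density: weighted clipped segment length per unit search area.

    For each cell centre, sum over all line segments of
    (length of the segment clipped to the radius-circle) x weight,
    divided by pi * radius^2.  Units: weight-metres per square metre
    (pcu/m for PCU-weighted roads).
    """
    if radius <= 0:
        raise ValueError("line_density: radius must be > 0")
    if weight_attr is not None:
        lines.require_attribute(weight_attr)
    xs, ys = spec.cell_centers()
    acc = np.zeros(spec.shape, dtype=float)
    area = math.pi * radius * radius
    for geom, attrs in lines.features:
        w = float(attrs[weight_attr]) if weight_attr is not None else 1.0
        coords = np.asarray(geom.coords)
        for p0, p1 in zip(coords[:-1], coords[1:]):
            xmin, xmax = sorted((p0[0], p1[0]))
            ymin, ymax = sorted((p0[1], p1[1]))
            near = (
                (xs >= xmin - radius)
                & (xs <= xmax + radius)
                & (ys >= ymin - radius)
                & (ys <= ymax + radius)
            )
            if not near.any():
                continue
            clipped = _clipped_segment_length(
                np.asarray(p0), np.asarray(p1), xs[near], ys[near], radius
            )
            acc[near] += w * clipped
    return Grid(spec, acc / area, "continuous")


def point_density(
    points: VectorLayer, weight_attr: str | None, spec: GridSpec, radius: float
) -> Grid:
    """Kernel point density: sum of weights within radius / (pi * radius^2)."""
    if radius <= 0:
        raise ValueError("point_density: radius must be > 0")
    if weight_attr is not None:
        points.require_attribute(weight_attr)
    xs, ys = spec.cell_centers()
    acc = np.zeros(spec.shape, dtype=float)
    r2 = radius * radius
    for geom, attrs in points.features:
        w = float(attrs[weight_attr]) if weight_attr is not None else 1.0
        p = geom if isinstance(geom, Point) else geom.centroid
        d2 = (xs - p.x) ** 2 + (ys - p.y) ** 2
        acc[d2 <= r2] += w
    return Grid(spec, acc / (math.pi * r2), "continuous")
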