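"""End-to-end corridor runs: layers -> composite cost -> paths -> reports.

One :class:`RunConfig` drives the whole chain for one or more weight
schemes: build the six cost layers, combine them, accumulate cost from the
destination park, trace a least-cost path per start cell, decompose shared
segments, flag weak links, find water gaps and buffer the corridor. Stage
outputs are cached on disk keyed by a content hash of their inputs and
parameters, so reruns skip unchanged stages; every stage logs its
parameters, making a run reconstructible from its log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from . import io as wio
from .corridor import (
    AccumulatedCost,
    CorridorPath,
    accumulate,
    buffer_corridor,
    shared_segments,
    trace,
    water_gaps,
    weak_links,
)
from .cost_model import (
    CostStack,
    WeightScheme,
    build_habitat_cost,
    build_rail_cost,
    build_road_cost,
    build_settlement_cost,
    build_water_cost,
    composite_cost,
    scheme,
)
from .edge_metrics import edge_cost_grid, tessellate, total_edge
from .raster_core import Grid
from .synthetic_landscape import Landscape, LandscapeScenario, generate_landscape

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one corridor run needs.

    Either ``scenario`` (synthetic inputs) or pre-built layers supplied via
    ``landscape``. Exactly one source cell; at least one start cell (both
    default to the scenario's park peripheries).
    """

    scenario: LandscapeScenario | None = None
    landscape: Landscape | None = None
    schemes: tuple[str, ...] = ("RO1", "RO2", "RO3")
    density_radius_m: float = 1_000.0
    hex_width_m: float = 2_000.0
    start_cells: list[tuple[int, int]] | None = None
    source_cell: tuple[int, int] | None = None
    weak_link_threshold_km: float = 4.0
    water_max_km: float = 5.0
    buffer_min_km: float = 2.0
    buffer_max_km: float = 6.0
    out_dir: Path | None = None

    def validate(self) -> None:
        if self.scenario is None and self.landscape is None:
            raise ValueError("need a scenario or a pre-built landscape")
        if self.landscape is not None or self.scenario is not None:
            pass
        starts = self.start_cells
        if starts is not None and len(starts) == 0:
            raise ValueError("need at least one start cell")


@dataclass
class SchemeReport:
    """All corridor outputs for one weight scheme."""

    scheme: WeightScheme
    cm: Grid
    accumulated: AccumulatedCost
    paths: list[CorridorPath]
    segments: list
    weak: list
    gaps: list
    buffer_polygon: object


@dataclass
class RunReport:
    landscape: Landscape
    stack: CostStack
    water_distance: Grid
    by_scheme: dict[str, SchemeReport] = field(default_factory=dict)

    def comparison_table(self) -> pd.DataFrame:
        rows = []
        for name, rep in self.by_scheme.items():
            for i, p in enumerate(rep.paths):
                rows.append(
                    {
                        "scheme": name,
                        "start": i,
                        "length_km": p.length_km,
                        "total_cost": p.total_cost,
                        "n_weak_links": len(rep.weak[i]),
                        "n_water_gaps": len(rep.gaps[i]),
                    }
                )
        return pd.DataFrame(rows)


def _content_hash(*parts: object) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, np.ndarray):
            h.update(np.ascontiguousarray(p).tobytes())
        else:
            h.update(repr(p).encode())
    return h.hexdigest()[:16]


class _StageCache:
    """Content-hash sidecars: a stage whose inputs are unchanged is skipped."""

    def __init__(self, out_dir: Path | None):
        self.dir = out_dir / "cache" if out_dir else None
        if self.dir:
            self.dir.mkdir(parents=True, exist_ok=True)

    def fresh(self, stage: str, key: str) -> bool:
        if not self.dir:
            return False
        f = self.dir / f"{stage}.json"
        if f.exists() and json.loads(f.read_text()).get("key") == key:
            logger.info("stage %s: cache hit (key %s), skipped", stage, key)
            return True
        return False

    def mark(self, stage: str, key: str) -> None:
        if self.dir:
            (self.dir / f"{stage}.json").write_text(json.dumps({"key": key}))


def build_cost_stack(
    land: Landscape, density_radius_m: float, hex_width_m: float
) -> tuple[CostStack, Grid]:
    """The six cost layers for a landscape; returns (stack, water distance grid)."""
    spec = land.habitat.spec
    logger.info(
        "build_cost_stack: radius=%s m, hex_width=%s m, grid=%s", density_radius_m,
        hex_width_m, spec.shape,
    )
    h = build_habitat_cost(land.habitat_labels)
    ws, wdist = build_water_cost(land.streams, land.waterbodies, spec)
    rd = build_road_cost(land.roads, spec, density_radius_m)
    r = build_rail_cost(land.rail, spec)
    s = build_settlement_cost(land.settlements, spec, density_radius_m)
    hexes, assign = tessellate(spec, hex_width_m)
    reports = total_edge(land.forest, hexes, assign)
    te = edge_cost_grid(reports, hexes, spec, assign)
    stack = CostStack({"H": h, "S": s, "WS": ws, "TE": te, "RD": rd, "R": r})
    return stack, wdist


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline for every requested weight scheme."""
    config.validate()
    if config.start_cells is not None and len(config.start_cells) == 0:
        raise ValueError("run: zero start cells")
    land = config.landscape or generate_landscape(config.scenario)
    starts = config.start_cells or land.start_cells
    source = config.source_cell or land.source_cell
    if not starts:
        raise ValueError("run: zero start cells")
    cache = _StageCache(config.out_dir)

    stack, wdist = build_cost_stack(land, config.density_radius_m, config.hex_width_m)
    report = RunReport(land, stack, wdist)

    out = config.out_dir
    if out:
        out.mkdir(parents=True, exist_ok=True)
        key = _content_hash(
            land.habitat.values, config.density_radius_m, config.hex_width_m
        )
        if not cache.fresh("costs", key):
            for name, grid in stack.layers.items():
                wio.write_ascii_grid(grid, out / f"cost_{name}.asc")
            wio.write_ascii_grid(wdist, out / "water_distance.asc")
            cache.mark("costs", key)

    for name in config.schemes:
        ws = scheme(name) if isinstance(name, str) else name
        logger.info("scheme %s: weights=%s", ws.name, ws.weights)
        cm = composite_cost(stack, ws)
        accres = accumulate(cm, [source])
        paths = [trace(accres, s) for s in starts]
        segs = (
            shared_segments(paths, cm.spec.cell_size) if len(paths) >= 2 else []
        )
        weak = [
            weak_links(p, land.forest, config.weak_link_threshold_km)
            for p in paths
        ]
        gaps = [water_gaps(p, wdist, config.water_max_km) for p in paths]
        buffers = [
            buffer_corridor(
                p, cm.spec, config.buffer_min_km, config.buffer_max_km, weak[i]
            )
            for i, p in enumerate(paths)
        ]
        rep = SchemeReport(ws, cm, accres, paths, segs, weak, gaps, buffers)
        report.by_scheme[ws.name] = rep
        if out:
            _write_scheme_outputs(out, land, rep)

    if out:
        report.comparison_table().to_csv(out / "comparison.csv", index=False)
    return report


def _path_linestring(path: CorridorPath, spec) -> LineString:
    pts = [spec.cell_center(r, c) for r, c in path.cells]
    if len(pts) == 1:
        pts = pts * 2
    return LineString(pts)


def _write_scheme_outputs(out: Path, land: Landscape, rep: SchemeReport) -> None:
    spec = rep.cm.spec
    name = rep.scheme.name
    wio.write_ascii_grid(rep.cm, out / f"cm_{name}.asc")
    for i, p in enumerate(rep.paths):
        wio.write_geometry(
            _path_linestring(p, spec),
            out / f"path_{name}_{i}.geojson",
            {"run_option": name, "length_km": p.length_km, "total_cost": p.total_cost},
        )
        wio.write_geometry(
            rep.buffer_polygon[i],
            out / f"buffer_{name}_{i}.geojson",
            {"run_option": name},
        )
    weak_rows = [
        {
            "path": i,
            "min_width_km": wl.min_width_km,
            "cause": wl.cause,
            "n_cells": len(wl.span),
        }
        for i, links in enumerate(rep.weak)
        for wl in links
    ]
    pd.DataFrame(weak_rows).to_csv(out / f"weak_links_{name}.csv", index=False)
    gap_rows = [
        {
            "path": i,
            "length_km": g.length_km,
            "n_waterholes": len(g.proposed_waterholes),
        }
        for i, gaps in enumerate(rep.gaps)
        for g in gaps
    ]
    pd.DataFrame(gap_rows).to_csv(out / f"water_gaps_{name}.csv", index=False)
    seg_rows = [
        {
            "members": ",".join(map(str, sorted(s.members))),
            "common": s.is_common,
            "length_km": s.length_km,
            "n_cells": len(s.cells),
        }
        for s in rep.segments
    ]
    pd.DataFrame(seg_rows).to_csv(out / f"segments_{name}.csv", index=False)
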