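"""The six movement-cost layers and their weighted combination.

Movement resistance for a dispersing tiger is scored by six raster layers:

    H   habitat cost (prey-ranked vegetation classes)
    S   human-settlement cost (population point density)
    WS  water-source cost (distance to perennial water; water itself a barrier)
    TE  total-edge cost (forest fragmentation per hexagon unit)
    RD  road-density cost (PCU-weighted traffic line density)
    R   railway cost (presence/absence)

Each layer maps its raw quantity through a published cost-rank table.
The Composite Movement Cost is the weighted linear combination

    CM = W_H*H + W_S*S + W_WS*WS + W_TE*TE + W_RD*RD + W_R*R

with importance weights elicited from a panel of tiger experts. Three
run options bracket the elicited variability: RO1 weights all layers
equally; RO2 follows one expert's column directly; RO3 doubles the
weight of habitat, edge and water against a baseline of 1.

Numeric category boundaries follow a half-open [lo, hi) convention — a
density exactly on a boundary takes the higher-cost bin — and values
beyond the observed ranges clamp to the top category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster_core import (
    CostTable,
    Grid,
    GridSpec,
    VectorLayer,
    euclidean_distance,
    line_density,
    point_density,
    rasterize,
    reclassify,
)

LAYER_KEYS = ("H", "S", "WS", "TE", "RD", "R")
WEIGHT_KEYS = ("W_H", "W_S", "W_WS", "W_TE", "W_RD", "W_R")

HABITAT_CLASSES = (
    "Teak",
    "Miscellaneous",
    "Teak Mixed",
    "Bamboo Mixed",
    "Mixed Bamboo",
    "Non-Forest",
)

#: Habitat class -> movement cost rank (prey-abundance-derived ordering).
HABITAT_COST = CostTable(
    "habitat",
    [
        ("Teak", 4),
        ("Miscellaneous", 3),
        ("Teak Mixed", 2),
        ("Bamboo Mixed", 1),
        ("Mixed Bamboo", 2),
        ("Non-Forest", 10),
    ],
)

#: Distance to perennial water (metres) -> cost rank; cells on water get 10.
WATER_DISTANCE_COST = CostTable(
    "water_distance",
    [
        ((0.0, 1_000.0), 0),
        ((1_000.0, 2_000.0), 1),
        ((2_000.0, 3_000.0), 2),
        ((3_000.0, 4_000.0), 3),
        ((4_000.0, 5_000.0), 4),
        ((5_000.0, 6_000.0), 5),
        ((6_000.0, 7_000.0), 6),
        ((7_000.0, float("inf")), 7),
    ],
)
WATER_BODY_COST = 10

#: PCU-weighted road density (pcu/m) -> cost rank. Exact zero is Absent;
#: any positive density below 4 is Low; the top bin clamps upward.
ROAD_DENSITY_COST = CostTable(
    "road_density",
    [
        ((0.0, 0.0), 0),  # placeholder; exact zero handled in build_road_cost
        ((0.0, 4.0), 2),
        ((4.0, 6.0), 5),
        ((6.0, float("inf")), 10),
    ],
)

RAIL_PRESENT_COST = 10

#: Settlement population density (pop/m^2) -> cost rank; exact zero is Absent.
SETTLEMENT_DENSITY_COST = CostTable(
    "settlement_density",
    [
        ((0.0, 0.0), 0),  # placeholder; exact zero handled in build_settlement_cost
        ((0.0, 0.001), 3),
        ((0.001, 0.0015), 6),
        ((0.0015, float("inf")), 10),
    ],
)

#: Expert questionnaire: seven movement parameters rated 0-5 by five experts.
EXPERT_PARAMETERS = (
    "Cover",
    "Food availability/Prey base",
    "Water availability",
    "Presence of roads",
    "Human habitation",
    "Presence of railway track",
    "Slope",
)

EXPERT_RATINGS = pd.DataFrame(
    {
        "E1": [2, 2, 2, 1, 1, 1, 0],
        "E2": [5, 4, 2, 1, 3, 0, 0],
        "E3": [5, 3, 4, 0, 2, 0, 0],
        "E4": [4, 3, 1, 1, 4, 1, 0],
        "E5": [4, 5, 4, 3, 5, 2, 1],
    },
    index=EXPERT_PARAMETERS,
)

#: Questionnaire parameter -> model weight symbol. Cover (forest-cover
#: continuity) drives the edge weight, food/prey the habitat weight;
#: slope has no layer in the model and is dropped.
PARAMETER_TO_WEIGHT = {
    "Cover": "W_TE",
    "Food availability/Prey base": "W_H",
    "Water availability": "W_WS",
    "Presence of roads": "W_RD",
    "Human habitation": "W_S",
    "Presence of railway track": "W_R",
}


@dataclass(frozen=True)
class ExpertWeightMatrix:
    """Parameters x experts table of importance ratings on a 0-5 scale."""

    ratings: pd.DataFrame

    def __post_init__(self) -> None:
        if self.ratings.shape[1] < 1:
            raise ValueError("need at least one expert")
        vals = self.ratings.to_numpy()
        if ((vals < 0) | (vals > 5)).any():
            raise ValueError("ratings must be within [0, 5]")


@dataclass(frozen=True)
class WeightScheme:
    """One run option: the six importance weights for the CM combination."""

    name: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(WEIGHT_KEYS) - set(self.weights)
        if missing:
            raise ValueError(f"missing weights: {sorted(missing)}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        if not any(w > 0 for w in self.weights.values()):
            raise ValueError("at least one weight must be positive")

    def __getitem__(self, key: str) -> float:
        return self.weights[key]


@dataclass
class CostStack:
    """The six aligned cost layers keyed H, S, WS, TE, RD, R."""

    layers: dict[str, Grid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(LAYER_KEYS) - set(self.layers)
        if missing:
            raise ValueError(f"missing layers: {sorted(missing)}")
        specs = {id(g.spec): g.spec for g in self.layers.values()}
        first = next(iter(self.layers.values())).spec
        for g in self.layers.values():
            if g.spec != first:
                raise ValueError("cost layers do not share one GridSpec")

    def __getitem__(self, key: str) -> Grid:
        return self.layers[key]


# ---------------------------------------------------------------------------
# layer builders


def build_habitat_cost(habitat: Grid) -> Grid:
    """Categorical habitat raster -> habitat cost layer (H)."""
    return reclassify(habitat, HABITAT_COST)


def build_water_cost(
    streams: VectorLayer, waterbodies: VectorLayer, spec: GridSpec
) -> tuple[Grid, Grid]:
    """Water-source cost layer (WS) and the underlying distance grid.

    Distance to the nearest perennial water cell is binned per the water
    cost table; cells lying on a water feature are overridden to the
    barrier cost (open water impedes movement).
    Returns (cost grid, distance grid in metres).
    """
    if not streams.features and not waterbodies.features:
        raise ValueError("build_water_cost: no water features")
    present = np.zeros(spec.shape, dtype=float)
    for layer in (streams, waterbodies):
        if layer.features:
            present = np.maximum(present, rasterize(layer, spec).values)
    water_mask = Grid(spec, present, "categorical")
    dist = euclidean_distance(water_mask, spec)
    cost = reclassify(dist, WATER_DISTANCE_COST)
    vals = cost.values.copy()
    vals[present != 0] = WATER_BODY_COST
    return Grid(spec, vals, "cost"), dist


def _density_to_cost(density: Grid, table: CostTable) -> Grid:
    """Bin a density grid, keeping exact zero in the Absent category."""
    vals = np.asarray(density.values)
    out = np.full(vals.shape, density.spec.nodata, dtype=float)
    valid = vals != density.spec.nodata
    zero = valid & (vals == 0)
    pos = valid & (vals > 0)
    out[zero] = 0.0
    if pos.any():
        # skip the zero-width placeholder interval when binning positives
        positive_table = CostTable(
            table.name, [((lo, hi), c) for lo, hi, c in table.interval_entries if hi > lo]
        )
        out[pos] = positive_table.apply(vals[pos], density.spec.nodata)
    return Grid(density.spec, out, "cost")


def build_road_cost(roads: VectorLayer, spec: GridSpec, radius: float = 1_000.0) -> Grid:
    """Road-density cost layer (RD) from PCU-weighted line density."""
    density = line_density(roads, "pcu", spec, radius)
    return _density_to_cost(density, ROAD_DENSITY_COST)


def build_rail_cost(rail: VectorLayer, spec: GridSpec) -> Grid:
    """Railway cost layer (R): presence -> barrier cost, absence -> 0."""
    presence = rasterize(rail, spec)
    return Grid(spec, presence.values * RAIL_PRESENT_COST, "cost")


def build_settlement_cost(
    settlements: VectorLayer, spec: GridSpec, radius: float = 1_000.0
) -> Grid:
    """Settlement cost layer (S) from population-weighted point density."""
    density = point_density(settlements, "population", spec, radius)
    return _density_to_cost(density, SETTLEMENT_DENSITY_COST)


# ---------------------------------------------------------------------------
# weights


def average_expert_weights(matrix: ExpertWeightMatrix) -> pd.Series:
    """Arithmetic mean rating per parameter, rounded to one decimal."""
    return matrix.ratings.mean(axis=1).round(1)


def scheme(name: str) -> WeightScheme:
    """The three published run options.

    RO1: all six layers equally important. RO2: expert E2's column mapped
    onto the model variables (edge 5, habitat 4, settlement 3, water 2,
    roads 1, railway 0). RO3: habitat, edge and water twice as important
    as the rest (baseline weight 1).
    """
    name = name.upper()
    if name == "RO1":
        return WeightScheme("RO1", {k: 1.0 for k in WEIGHT_KEYS})
    if name == "RO2":
        return WeightScheme(
            "RO2",
            {"W_TE": 5.0, "W_H": 4.0, "W_S": 3.0, "W_WS": 2.0, "W_RD": 1.0, "W_R": 0.0},
        )
    if name == "RO3":
        return WeightScheme(
            "RO3",
            {"W_H": 2.0, "W_TE": 2.0, "W_WS": 2.0, "W_S": 1.0, "W_RD": 1.0, "W_R": 1.0},
        )
    raise ValueError(f"unknown run option {name!r}")


def composite_cost(stack: CostStack, weights: WeightScheme) -> Grid:
    """CM = W_H*H + W_S*S + W_WS*WS + W_TE*TE + W_RD*RD + W_R*R, cellwise.

    nodata in any layer propagates to CM.
    """
    spec = stack["H"].spec
    acc = np.zeros(spec.shape, dtype=float)
    nodata_mask = np.zeros(spec.shape, dtype=bool)
    for layer_key, weight_key in zip(LAYER_KEYS, ("W_H", "W_S", "W_WS", "W_TE", "W_RD", "W_R")):
        grid = stack[layer_key]
        vals = np.asarray(grid.values, dtype=float)
        nodata_mask |= vals == spec.nodata
        acc += weights[weight_key] * vals
    acc[nodata_mask] = spec.nodata
    return Grid(spec, acc, "cost")
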