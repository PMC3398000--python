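"""Seeded generators for every input the corridor pipeline consumes.

Real inputs for this kind of analysis (classified satellite imagery, Survey
of India base layers, traffic and census attributes, field pellet surveys)
are proprietary, so the pipeline is exercised on synthetic two-park
landscapes with known ground truth: a forested matrix built from thresholded
smoothed Gaussian random fields (the simplest generator with controllable
patchiness), a road network with per-segment traffic (PCU) attributes, one
railway line, clustered settlements with census-style populations, perennial
streams and tanks, and optionally a planted low-cost channel between the two
parks plus engineered forest-width constrictions ("necks").

The planted channel is the recovery ground truth: inside it every cost
layer scores its best value (best habitat class, water within a kilometre,
no roads, rail or settlements nearby) and the best habitat class is
withheld from the rest of the landscape, so every off-channel corridor is
strictly more expensive and a correct least-cost tracer must stay inside
the channel under any positive weight scheme.

Pellet surveys are drawn from negative-binomial counts with per-(habitat,
species) intensities, transects stratified over forest habitat classes in
proportion to their area — mirroring the field design of 79 transects of 5
plots each.

Everything is driven by one integer seed, deterministically split per
sub-generator: the same seed and scenario reproduce every output bit for
bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import LineString, Point, Polygon, box

from .prey_survey import PelletPlot, SurveyDesign, SPECIES
from .raster_core import Grid, GridSpec, VectorLayer

FOREST_CLASSES = ("Teak", "Miscellaneous", "Teak Mixed", "Bamboo Mixed", "Mixed Bamboo")

#: habitat class -> id used in categorical rasters (0 = Non-Forest)
CLASS_IDS = {name: i for i, name in enumerate(("Non-Forest",) + FOREST_CLASSES)}
ID_CLASSES = {i: name for name, i in CLASS_IDS.items()}

DEFAULT_FRACTIONS = {
    "Teak": 0.15,
    "Miscellaneous": 0.20,
    "Teak Mixed": 0.15,
    "Bamboo Mixed": 0.10,
    "Mixed Bamboo": 0.15,
    # remainder (0.25) is Non-Forest
}

#: default per-species pellet-group intensity (mean groups/plot) by habitat,
#: expressed as species base rate x habitat multiplier. The multiplier
#: ordering plants the ground-truth preference: bamboo-dominated classes
#: first, pure teak last.
HABITAT_MULTIPLIER = {
    "Bamboo Mixed": 2.5,
    "Mixed Bamboo": 1.6,
    "Teak Mixed": 1.0,
    "Miscellaneous": 0.6,
    "Teak": 0.3,
}
SPECIES_BASE_RATE = {
    "chital": 1.5,
    "sambar": 0.8,
    "wild_boar": 0.6,
    "gaur": 0.4,
    "nilgai": 0.2,
    "chowsingha": 0.15,
    "barking_deer": 0.08,
}


def _child_seed(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k) % (2**31)


@dataclass(frozen=True)
class LandscapeScenario:
    """Parameters of one synthetic two-park landscape."""

    seed: int = 0
    extent_km: tuple[float, float] = (30.0, 20.0)
    cell_size: float = 100.0
    park_margin_km: float = 2.0
    park_size_km: tuple[float, float] = (4.0, 8.0)
    habitat_fractions: dict = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    autocorr_km: float = 1.5
    n_roads: int = 4
    pcu_range: tuple[float, float] = (1_000.0, 12_000.0)
    with_rail: bool = True
    n_settlement_clusters: int = 6
    settlement_cluster_size: tuple[int, int] = (4, 10)
    population_range: tuple[int, int] = (50, 1_500)
    n_streams: int = 3
    n_tanks: int = 8
    planted_channel: bool = False
    channel_width_m: float = 1_000.0
    channel_clearance_m: float = 2_500.0
    necks: tuple[tuple[float, float], ...] = ()  # (fraction along channel, width_km)
    neck_length_km: float = 2.0

    def __post_init__(self) -> None:
        total = sum(self.habitat_fractions.values())
        if total > 1.0 + 1e-9:
            raise ValueError("habitat fractions sum beyond 1")

    @property
    def grid_spec(self) -> GridSpec:
        return GridSpec(
            n_rows=int(round(self.extent_km[1] * 1000 / self.cell_size)),
            n_cols=int(round(self.extent_km[0] * 1000 / self.cell_size)),
            cell_size=self.cell_size,
            origin_x=0.0,
            origin_y=self.extent_km[1] * 1000.0,
        )


@dataclass
class Landscape:
    """All generated layers for one scenario, plus corridor endpoints."""

    scenario: LandscapeScenario
    habitat: Grid  # categorical, class ids of CLASS_IDS
    roads: VectorLayer
    rail: VectorLayer
    settlements: VectorLayer
    streams: VectorLayer
    waterbodies: VectorLayer
    park_a: Polygon
    park_b: Polygon
    start_cells: list[tuple[int, int]]
    source_cell: tuple[int, int]
    channel_mask: np.ndarray | None = None
    channel_line: LineString | None = None

    @property
    def forest(self) -> Grid:
        vals = (np.asarray(self.habitat.values) != CLASS_IDS["Non-Forest"]).astype(float)
        return Grid(self.habitat.spec, vals, "categorical")

    @property
    def habitat_labels(self) -> Grid:
        labels = np.empty(self.habitat.spec.shape, dtype=object)
        vals = np.asarray(self.habitat.values).astype(int)
        for cid, name in ID_CLASSES.items():
            labels[vals == cid] = name
        return Grid(self.habitat.spec, labels, "categorical")


def _smooth_field(rng: np.random.Generator, spec: GridSpec, scale_m: float) -> np.ndarray:
    noise = rng.normal(size=spec.shape)
    sigma = max(scale_m / spec.cell_size, 0.5)
    return ndimage.gaussian_filter(noise, sigma=sigma)


def _quantile_classify(
    field_vals: np.ndarray, mask: np.ndarray, fractions: list[tuple[str, float]]
) -> np.ndarray:
    """Split cells of ``mask`` into classes by field quantiles at the target fractions."""
    out = np.zeros(field_vals.shape, dtype=int)
    sub = field_vals[mask]
    order = np.argsort(sub, kind="stable")
    n = sub.size
    ids = np.zeros(n, dtype=int)
    start = 0
    cum = 0.0
    for name, frac in fractions:
        cum += frac
        stop = int(round(cum * n))
        ids[order[start:stop]] = CLASS_IDS[name]
        start = stop
    if start < n:  # rounding remainder joins the last class
        ids[order[start:]] = CLASS_IDS[fractions[-1][0]]
    out[mask] = ids
    return out


def _channel_line(scn: LandscapeScenario, park_a: Polygon, park_b: Polygon) -> LineString:
    ax = park_a.bounds[2]  # east edge of park A
    bx = park_b.bounds[0]  # west edge of park B
    ay = 0.5 * (park_a.bounds[1] + park_a.bounds[3])
    by = 0.5 * (park_b.bounds[1] + park_b.bounds[3])
    return LineString([(ax, ay), (bx, by)])


def _distance_to_line(line: LineString, spec: GridSpec) -> np.ndarray:
    xs, ys = spec.cell_centers()
    pts = shapely.points(xs.ravel(), ys.ravel())
    return shapely.distance(pts, line).reshape(spec.shape)


def generate_landscape(scn: LandscapeScenario) -> Landscape:
    """Generate the full input bundle for one scenario (deterministic in seed)."""
    spec = scn.grid_spec
    width_m = scn.extent_km[0] * 1000.0
    height_m = scn.extent_km[1] * 1000.0
    pw, ph = scn.park_size_km[0] * 1000.0, scn.park_size_km[1] * 1000.0
    margin = scn.park_margin_km * 1000.0
    cy = height_m / 2.0
    park_a = box(margin, cy - ph / 2, margin + pw, cy + ph / 2)
    park_b = box(width_m - margin - pw, cy - ph / 2, width_m - margin, cy + ph / 2)
    channel = _channel_line(scn, park_a, park_b) if scn.planted_channel else None

    # --- habitat mosaic ---------------------------------------------------
    rng_hab = np.random.default_rng(_child_seed(scn.seed, 1))
    forest_field = _smooth_field(rng_hab, spec, scn.autocorr_km * 1000.0)
    class_field = _smooth_field(rng_hab, spec, scn.autocorr_km * 1000.0)
    forest_frac = sum(scn.habitat_fractions.values())
    thresh = np.quantile(forest_field, 1.0 - forest_frac)
    forest_mask = forest_field >= thresh

    xs, ys = spec.cell_centers()
    in_park = shapely.contains_xy(park_a, xs, ys) | shapely.contains_xy(park_b, xs, ys)
    forest_mask |= in_park

    habitat_ids = _quantile_classify(
        class_field,
        forest_mask,
        [(name, frac / forest_frac) for name, frac in scn.habitat_fractions.items()],
    )

    channel_mask = None
    if channel is not None:
        d_chan = _distance_to_line(channel, spec)
        channel_mask = d_chan <= scn.channel_width_m / 2.0
        # withhold the best class from the matrix, then plant it on the
        # channel and inside both parks (the corridor endpoints), so any
        # off-channel crossing of the matrix is strictly more expensive
        best = CLASS_IDS["Bamboo Mixed"]
        protected = channel_mask | in_park
        habitat_ids[(habitat_ids == best) & ~protected] = CLASS_IDS["Mixed Bamboo"]
        habitat_ids[protected] = best
        forest_mask |= protected

    # engineered forest necks perpendicular to the channel
    if scn.necks:
        if channel is None:
            raise ValueError("necks require a planted channel")
        d_chan = _distance_to_line(channel, spec)
        pts = shapely.points(xs.ravel(), ys.ravel())
        along = shapely.line_locate_point(channel, pts).reshape(spec.shape)
        for frac, width_km in scn.necks:
            pos = frac * channel.length
            half_len = scn.neck_length_km * 1000.0 / 2.0
            half_w = width_km * 1000.0 / 2.0
            strip = np.abs(along - pos) <= half_len
            cut = strip & (d_chan > half_w) & ~in_park
            habitat_ids[cut] = CLASS_IDS["Non-Forest"]
            forest_mask &= ~cut
            # the surviving band is forest, padded along the channel so the
            # nearest non-forest from the neck centre is the band edge itself
            band = (np.abs(along - pos) <= half_len + half_w) & (d_chan <= half_w)
            fill = band & (habitat_ids == CLASS_IDS["Non-Forest"])
            habitat_ids[fill] = CLASS_IDS["Miscellaneous"]
            forest_mask |= band

    habitat_ids[~forest_mask] = CLASS_IDS["Non-Forest"]
    habitat = Grid(spec, habitat_ids.astype(float), "categorical")

    # --- exclusion zone around the planted channel and parks ----------------
    exclusion = None
    if channel is not None:
        exclusion = shapely.unary_union(
            [channel.buffer(scn.channel_width_m / 2.0), park_a, park_b]
        ).buffer(scn.channel_clearance_m)

    def keep(geom) -> bool:
        return exclusion is None or not geom.intersects(exclusion)

    def clip(geom):
        return geom if exclusion is None else geom.difference(exclusion)

    # --- roads --------------------------------------------------------------
    rng_road = np.random.default_rng(_child_seed(scn.seed, 2))
    road_feats = []
    for _ in range(scn.n_roads):
        x0 = rng_road.uniform(0.1, 0.9) * width_m
        x1 = np.clip(x0 + rng_road.uniform(-0.2, 0.2) * width_m, 0, width_m)
        line = clip(LineString([(x0, 0.0), (x1, height_m)]))
        pcu = float(rng_road.uniform(*scn.pcu_range))
        if line.is_empty:
            continue
        parts = line.geoms if line.geom_type == "MultiLineString" else [line]
        for part in parts:
            road_feats.append((part, {"pcu": pcu}))
    roads = VectorLayer("polyline", road_feats)

    # --- rail ----------------------------------------------------------------
    rail_feats = []
    if scn.with_rail:
        rng_rail = np.random.default_rng(_child_seed(scn.seed, 3))
        x = rng_rail.uniform(0.3, 0.7) * width_m
        line = clip(LineString([(x, 0.0), (x * 0.9, height_m)]))
        if not line.is_empty:
            parts = line.geoms if line.geom_type == "MultiLineString" else [line]
            rail_feats = [(part, {}) for part in parts]
    rail = VectorLayer("polyline", rail_feats)

    # --- settlements ----------------------------------------------------------
    rng_set = np.random.default_rng(_child_seed(scn.seed, 4))
    settle_feats = []
    for _ in range(scn.n_settlement_clusters):
        cx = rng_set.uniform(0.05, 0.95) * width_m
        cyc = rng_set.uniform(0.05, 0.95) * height_m
        size = rng_set.integers(*scn.settlement_cluster_size, endpoint=True)
        for _ in range(size):
            p = Point(
                cx + rng_set.normal(scale=600.0), cyc + rng_set.normal(scale=600.0)
            )
            if not keep(p):
                continue
            pop = int(rng_set.integers(*scn.population_range, endpoint=True))
            settle_feats.append((p, {"population": pop}))
    settlements = VectorLayer("point", settle_feats)

    # --- water ------------------------------------------------------------
    rng_wat = np.random.default_rng(_child_seed(scn.seed, 5))
    # open water must never sit on the channel itself (it is a movement
    # barrier), so streams and tanks keep a couple of cells clear of it
    water_zone = (
        channel.buffer(scn.channel_width_m / 2.0 + 2 * spec.cell_size)
        if channel is not None
        else None
    )
    stream_feats = []
    for _ in range(scn.n_streams):
        x = rng_wat.uniform(0.1, 0.9) * width_m
        wiggle = rng_wat.uniform(-0.1, 0.1) * width_m
        line = LineString([(x, 0.0), (x + wiggle, height_m)])
        if water_zone is not None:
            line = line.difference(water_zone)
        if line.is_empty:
            continue
        parts = line.geoms if line.geom_type == "MultiLineString" else [line]
        stream_feats.extend((part, {}) for part in parts)
    if channel is not None:
        # perennial streams hug both channel edges: water within a kilometre
        # of every channel cell without open water on the channel itself
        offset = scn.channel_width_m / 2.0 + spec.cell_size
        for side in (offset, -offset):
            edge = channel.offset_curve(side)
            if not edge.is_empty:
                parts = edge.geoms if edge.geom_type == "MultiLineString" else [edge]
                stream_feats.extend((part, {}) for part in parts)
    streams = VectorLayer("polyline", stream_feats)

    tank_feats = []
    for _ in range(scn.n_tanks):
        p = Point(rng_wat.uniform(0, width_m), rng_wat.uniform(0, height_m))
        if water_zone is None or not water_zone.intersects(p):
            tank_feats.append((p, {}))
    waterbodies = VectorLayer("point", tank_feats)

    # --- corridor endpoints -------------------------------------------------
    ax_edge = park_a.bounds[2] - spec.cell_size / 2.0
    ay_mid = 0.5 * (park_a.bounds[1] + park_a.bounds[3])
    start_cells = [
        spec.cell_of(ax_edge, ay_mid + dy)
        for dy in (ph * 0.4, 0.0, -ph * 0.4)
    ]
    bx_edge = park_b.bounds[0] + spec.cell_size / 2.0
    by_mid = 0.5 * (park_b.bounds[1] + park_b.bounds[3])
    source_cell = spec.cell_of(bx_edge, by_mid)

    return Landscape(
        scenario=scn,
        habitat=habitat,
        roads=roads,
        rail=rail,
        settlements=settlements,
        streams=streams,
        waterbodies=waterbodies,
        park_a=park_a,
        park_b=park_b,
        start_cells=start_cells,
        source_cell=source_cell,
        channel_mask=channel_mask,
        channel_line=channel,
    )


# ---------------------------------------------------------------------------
# pellet survey


@dataclass(frozen=True)
class SurveyScenario:
    """Parameters of one synthetic pellet survey (defaults: 79 x 5 = 395 plots)."""

    seed: int = 0
    design: SurveyDesign = field(default_factory=SurveyDesign)
    species: tuple[str, ...] = SPECIES
    intensities: dict | None = None  # (habitat, species) -> mean groups/plot
    dispersion: float = 2.0  # negative-binomial size; larger -> nearer Poisson

    def intensity(self, habitat: str, species: str) -> float:
        if self.intensities is not None:
            return float(self.intensities.get((habitat, species), 0.0))
        return SPECIES_BASE_RATE[species] * HABITAT_MULTIPLIER[habitat]


def generate_survey(scn: SurveyScenario, habitat: Grid) -> list[PelletPlot]:
    """Draw a habitat-stratified belt-transect pellet survey on a habitat raster.

    Transects are allocated to forest habitat classes proportionally to
    their cell counts (largest-remainder rounding), each placed at a random
    forest cell of its class; per-plot counts are negative binomial with
    the scenario's (habitat, species) intensity.
    """
    rng = np.random.default_rng(_child_seed(scn.seed, 11))
    vals = np.asarray(habitat.values).astype(int)
    areas = {
        name: int((vals == CLASS_IDS[name]).sum())
        for name in FOREST_CLASSES
        if (vals == CLASS_IDS[name]).any()
    }
    if not areas:
        raise ValueError("generate_survey: no forest cells in habitat raster")
    total_area = sum(areas.values())
    n_tr = scn.design.n_transects
    quotas = {h: n_tr * a / total_area for h, a in areas.items()}
    alloc = {h: int(math.floor(q)) for h, q in quotas.items()}
    remainder = n_tr - sum(alloc.values())
    for h, _ in sorted(
        quotas.items(), key=lambda kv: (kv[1] - math.floor(kv[1]), kv[0]), reverse=True
    )[:remainder]:
        alloc[h] += 1

    plots: list[PelletPlot] = []
    t = 0
    for hab in sorted(alloc):
        for _ in range(alloc[hab]):
            t += 1
            tid = f"T{t:03d}"
            for _plot in range(scn.design.plots_per_transect):
                counts = {}
                for sp in scn.species:
                    mu = scn.intensity(hab, sp)
                    if mu <= 0:
                        counts[sp] = 0
                        continue
                    size = scn.dispersion
                    p = size / (size + mu)
                    counts[sp] = int(rng.negative_binomial(size, p))
                plots.append(PelletPlot(tid, hab, counts))
    return plots
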