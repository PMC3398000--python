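import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Point

from wildcorridor import (
    CostStack,
    ExpertWeightMatrix,
    Grid,
    GridSpec,
    VectorLayer,
    WeightScheme,
    average_expert_weights,
    build_habitat_cost,
    build_rail_cost,
    build_road_cost,
    build_settlement_cost,
    build_water_cost,
    composite_cost,
    scheme,
)
from wildcorridor.cost_model import (
    EXPERT_RATINGS,
    HABITAT_COST,
    ROAD_DENSITY_COST,
    SETTLEMENT_DENSITY_COST,
    WATER_DISTANCE_COST,
    LAYER_KEYS,
)


class TestHabitatCost:
    @pytest.mark.parametrize(
        "label,cost",
        [
            ("Teak", 4),
            ("Miscellaneous", 3),
            ("Teak Mixed", 2),
            ("Bamboo Mixed", 1),
            ("Mixed Bamboo", 2),
            ("Non-Forest", 10),
        ],
    )
    def test_class_costs(self, label, cost):
        assert HABITAT_COST.lookup(label) == cost

    def test_all_nonforest_grid_uniform_10(self, spec10):
        grid = Grid(spec10, np.full(spec10.shape, "Non-Forest", dtype=object), "categorical")
        out = build_habitat_cost(grid)
        assert (out.values == 10).all()

    def test_unknown_class_raises(self, spec10):
        grid = Grid(spec10, np.full(spec10.shape, "Sal", dtype=object), "categorical")
        with pytest.raises(KeyError):
            build_habitat_cost(grid)


class TestWaterCost:
    @pytest.mark.parametrize(
        "metres,cost",
        [(500, 0), (1500, 1), (2500, 2), (3500, 3), (4500, 4), (5500, 5), (6500, 6), (7500, 7)],
    )
    def test_distance_bins(self, metres, cost):
        assert WATER_DISTANCE_COST.lookup(metres) == cost

    def test_cells_on_water_are_barriers(self):
        spec = GridSpec(5, 100, 100.0, 0.0, 500.0)
        stream = LineString([(50.0, 250.0), (450.0, 250.0)])  # crosses cols 0-4 of row 2
        ws, dist = build_water_cost(
            VectorLayer("polyline", [(stream, {})]), VectorLayer("point", []), spec
        )
        assert ws.values[2, 2] == 10  # on the stream
        assert ws.values[2, 9] == 0  # 500 m away
        assert ws.values[2, 80] == 7  # 7.55 km away
        assert dist.values[2, 2] == 0.0

    def test_no_water_features_raises(self, spec10):
        with pytest.raises(ValueError):
            build_water_cost(VectorLayer("polyline", []), VectorLayer("point", []), spec10)


class TestDensityCosts:
    @pytest.mark.parametrize("density,cost", [(8.0, 10), (5.0, 5), (2.0, 2), (0.05, 2), (20.0, 10)])
    def test_road_bins(self, density, cost):
        positive = [e for e in ROAD_DENSITY_COST.interval_entries if e[1] > e[0]]
        from wildcorridor.raster_core import CostTable

        table = CostTable("road+", [((lo, hi), c) for lo, hi, c in positive])
        assert table.lookup(density) == cost

    def test_road_absent_is_zero_cost(self, spec10):
        out = build_road_cost(VectorLayer("polyline", []), spec10, 1000.0)
        assert (out.values == 0).all()

    @pytest.mark.parametrize("density,cost", [(0.0018, 10), (0.0012, 6), (0.0005, 3), (0.01, 10)])
    def test_settlement_bins(self, density, cost):
        positive = [e for e in SETTLEMENT_DENSITY_COST.interval_entries if e[1] > e[0]]
        from wildcorridor.raster_core import CostTable

        table = CostTable("settle+", [((lo, hi), c) for lo, hi, c in positive])
        assert table.lookup(density) == cost

    def test_settlement_density_zero_is_absent(self):
        spec = GridSpec(40, 40, 100.0, 0.0, 4000.0)
        # one village of 4000 people: density 4000/(pi 1e6) ~ 0.0013 pop/m2 nearby
        pt = Point(spec.cell_center(20, 20))
        out = build_settlement_cost(
            VectorLayer("point", [(pt, {"population": 4000})]), spec, 1000.0
        )
        assert out.values[20, 20] == 6  # moderate bin
        assert out.values[0, 0] == 0  # far away: absent

    def test_rail_presence_absence(self, spec10):
        line = LineString([(10.0, 450.0), (480.0, 450.0)])
        out = build_rail_cost(VectorLayer("polyline", [(line, {})]), spec10)
        assert out.values[5, 2] == 10
        assert out.values[0, 0] == 0
        empty = build_rail_cost(VectorLayer("polyline", []), spec10)
        assert (empty.values == 0).all()


class TestExpertWeights:
    def test_reproduces_every_average(self):
        avg = average_expert_weights(ExpertWeightMatrix(EXPERT_RATINGS))
        expected = {
            "Cover": 4.0,
            "Food availability/Prey base": 3.4,
            "Water availability": 2.6,
            "Presence of roads": 1.2,
            "Human habitation": 3.0,
            "Presence of railway track": 0.8,
            "Slope": 0.2,
        }
        assert avg.to_dict() == expected

    def test_all_zero_ratings_average_zero(self):
        m = ExpertWeightMatrix(pd.DataFrame({"E1": [0, 0], "E2": [0, 0]}, index=["a", "b"]))
        assert (average_expert_weights(m) == 0.0).all()

    def test_out_of_range_ratings_rejected(self):
        with pytest.raises(ValueError):
            ExpertWeightMatrix(pd.DataFrame({"E1": [6]}, index=["a"]))


class TestSchemes:
    def test_ro1_all_equal(self):
        assert all(w == 1.0 for w in scheme("RO1").weights.values())

    def test_ro2_follows_expert_two_column(self):
        ws = scheme("RO2")
        assert ws.weights == {
            "W_TE": 5.0, "W_H": 4.0, "W_S": 3.0, "W_WS": 2.0, "W_RD": 1.0, "W_R": 0.0
        }

    def test_ro3_doubles_habitat_edge_water(self):
        ws = scheme("RO3")
        assert ws["W_H"] == ws["W_TE"] == ws["W_WS"] == 2.0
        assert ws["W_S"] == ws["W_RD"] == ws["W_R"] == 1.0

    def test_unknown_scheme_raises(self):
        with pytest.raises(ValueError):
            scheme("RO9")


def _stack(spec, arrays):
    return CostStack({k: Grid(spec, arrays[k], "cost") for k in LAYER_KEYS})


class TestCompositeCost:
    def test_uniform_ones_ro1_gives_six(self, spec10):
        stack = _stack(spec10, {k: np.ones(spec10.shape) for k in LAYER_KEYS})
        cm = composite_cost(stack, scheme("RO1"))
        assert (cm.values == 6.0).all()

    def test_ro3_weighted_sum(self, spec10):
        arrays = {k: np.zeros(spec10.shape) for k in LAYER_KEYS}
        for k in ("H", "TE", "WS"):
            arrays[k] = np.ones(spec10.shape)
        cm = composite_cost(_stack(spec10, arrays), scheme("RO3"))
        assert (cm.values == 6.0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_cell_dot_product_oracle(self, seed, spec10):
        rng = np.random.default_rng(seed)
        arrays = {k: rng.integers(0, 11, spec10.shape).astype(float) for k in LAYER_KEYS}
        weights = {
            "W_H": rng.uniform(0, 5), "W_S": rng.uniform(0, 5), "W_WS": rng.uniform(0, 5),
            "W_TE": rng.uniform(0, 5), "W_RD": rng.uniform(0, 5), "W_R": rng.uniform(0, 5),
        }
        ws = WeightScheme("custom", weights)
        cm = composite_cost(_stack(spec10, arrays), ws)
        for r in range(spec10.n_rows):
            for c in range(spec10.n_cols):
                want = (
                    weights["W_H"] * arrays["H"][r, c]
                    + weights["W_S"] * arrays["S"][r, c]
                    + weights["W_WS"] * arrays["WS"][r, c]
                    + weights["W_TE"] * arrays["TE"][r, c]
                    + weights["W_RD"] * arrays["RD"][r, c]
                    + weights["W_R"] * arrays["R"][r, c]
                )
                assert cm.values[r, c] == pytest.approx(want)

    def test_linear_in_weights(self, spec10):
        rng = np.random.default_rng(3)
        arrays = {k: rng.integers(0, 11, spec10.shape).astype(float) for k in LAYER_KEYS}
        base = scheme("RO3")
        doubled = WeightScheme("x2", {k: 2 * v for k, v in base.weights.items()})
        cm1 = composite_cost(_stack(spec10, arrays), base)
        cm2 = composite_cost(_stack(spec10, arrays), doubled)
        np.testing.assert_allclose(cm2.values, 2 * cm1.values)

    def test_nodata_propagates(self, spec10):
        arrays = {k: np.ones(spec10.shape) for k in LAYER_KEYS}
        arrays["WS"][4, 4] = spec10.nodata
        cm = composite_cost(_stack(spec10, arrays), scheme("RO1"))
        assert cm.values[4, 4] == spec10.nodata

    def test_nonnegative_and_zero_only_where_all_zero(self, spec10):
        rng = np.random.default_rng(11)
        arrays = {k: rng.integers(0, 3, spec10.shape).astype(float) for k in LAYER_KEYS}
        cm = composite_cost(_stack(spec10, arrays), scheme("RO1"))
        assert (cm.values >= 0).all()
        zero = cm.values == 0
        allzero = np.ones(spec10.shape, dtype=bool)
        for k in LAYER_KEYS:
            allzero &= arrays[k] == 0
        np.testing.assert_array_equal(zero, allzero)
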