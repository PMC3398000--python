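import math

import numpy as np
import pytest

from wildcorridor import (
    CorridorPath,
    Grid,
    GridSpec,
    accumulate,
    buffer_corridor,
    shared_segments,
    trace,
    water_gaps,
    weak_links,
)
from wildcorridor.corridor import NEIGHBOURS_8, path_length_km
from conftest import graph_dijkstra_acc


def _grid(values, cell_size=100.0):
    values = np.asarray(values, dtype=float)
    spec = GridSpec(values.shape[0], values.shape[1], cell_size, 0.0,
                    values.shape[0] * cell_size)
    return Grid(spec, values, "cost")


class TestAccumulate:
    def test_uniform_cost_closed_form(self):
        cm = _grid(np.full((6, 6), 2.0))
        res = accumulate(cm, [(0, 0)])
        assert res.acc.values[0, 5] == pytest.approx(10.0)
        assert res.acc.values[0, 0] == 0.0

    def test_all_zero_cost_gives_zero_everywhere(self):
        cm = _grid(np.zeros((5, 5)))
        res = accumulate(cm, [(2, 2)])
        assert (res.acc.values == 0).all()

    def test_source_on_nodata_rejected(self):
        vals = np.ones((4, 4))
        vals[1, 1] = -9999.0
        with pytest.raises(ValueError):
            accumulate(_grid(vals), [(1, 1)])

    def test_no_sources_rejected(self):
        with pytest.raises(ValueError):
            accumulate(_grid(np.ones((3, 3))), [])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_explicit_graph_dijkstra(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 16))
        vals = rng.uniform(0, 10, (n, n))
        src = [(int(rng.integers(n)), int(rng.integers(n)))]
        res = accumulate(_grid(vals), src)
        oracle = graph_dijkstra_acc(vals, src)
        np.testing.assert_allclose(res.acc.values, oracle, rtol=1e-10)

    def test_monotone_under_single_cell_perturbation(self):
        rng = np.random.default_rng(99)
        vals = rng.uniform(1, 5, (12, 12))
        base = accumulate(_grid(vals), [(0, 0)]).acc.values
        up = vals.copy()
        up[6, 6] += 3.0
        acc_up = accumulate(_grid(up), [(0, 0)]).acc.values
        assert (acc_up >= base - 1e-12).all()
        down = vals.copy()
        down[6, 6] = max(0.0, down[6, 6] - 3.0)
        acc_down = accumulate(_grid(down), [(0, 0)]).acc.values
        assert (acc_down <= base + 1e-12).all()


class TestTrace:
    def test_start_at_source_single_cell_path(self):
        cm = _grid(np.ones((5, 5)))
        res = accumulate(cm, [(2, 2)])
        p = trace(res, (2, 2))
        assert p.cells == [(2, 2)]
        assert p.length_km == 0.0
        assert p.total_cost == 0.0

    def test_straight_ten_step_path_is_one_km(self):
        cm = _grid(np.ones((1, 11)))
        res = accumulate(cm, [(0, 0)])
        p = trace(res, (0, 10))
        assert len(p.cells) == 11
        assert p.length_km == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_path_cost_resummation_equals_acc(self, seed):
        rng = np.random.default_rng(seed + 100)
        vals = rng.uniform(0, 10, (15, 15))
        cm = _grid(vals)
        res = accumulate(cm, [(14, 14)])
        p = trace(res, (0, 0))
        total = 0.0
        for (r1, c1), (r2, c2) in zip(p.cells, p.cells[1:]):
            step = math.sqrt(2) if (r1 != r2 and c1 != c2) else 1.0
            total += 0.5 * (vals[r1, c1] + vals[r2, c2]) * step
        assert total == pytest.approx(p.total_cost)
        assert p.cells[-1] == (14, 14)

    def test_unreachable_start_rejected(self):
        vals = np.ones((3, 5))
        vals[:, 2] = -9999.0  # nodata wall
        res = accumulate(_grid(vals), [(1, 0)])
        with pytest.raises(ValueError):
            trace(res, (1, 4))

    def test_route_invariant_under_positive_scaling(self):
        rng = np.random.default_rng(55)
        vals = rng.uniform(0.5, 9, (20, 20))
        p1 = trace(accumulate(_grid(vals), [(19, 19)]), (0, 0))
        p2 = trace(accumulate(_grid(vals * 3.7), [(19, 19)]), (0, 0))
        assert p1.cells == p2.cells


class TestSharedSegments:
    def _path(self, cells, cell_size=100.0):
        return CorridorPath(cells, path_length_km(cells, cell_size), 0.0)

    def test_identical_paths_one_common_segment(self):
        cells = [(0, 3), (0, 2), (0, 1), (0, 0)]
        segs = shared_segments([self._path(cells), self._path(cells)], 100.0)
        assert len(segs) == 1
        assert segs[0].is_common
        assert segs[0].cells == cells

    def test_disjoint_until_source_common_is_source_cell(self):
        a = [(2, 2), (1, 1), (0, 0)]
        b = [(0, 2), (0, 1), (0, 0)]
        segs = shared_segments([self._path(a), self._path(b)], 100.0)
        common = [s for s in segs if s.is_common]
        assert len(common) == 1
        assert common[0].cells == [(0, 0)]
        assert common[0].length_km == 0.0

    def test_lengths_sum_to_each_paths_total(self):
        # three paths engineered to merge midway at (0, 5)
        trunk = [(0, j) for j in range(5, -1, -1)]  # (0,5) .. (0,0)
        a = [(3, 8), (2, 7), (1, 6)] + trunk
        b = [(0, 8), (0, 7), (0, 6)] + trunk
        c = [(4, 7), (3, 7), (2, 6), (1, 5)] + trunk
        paths = [self._path(x) for x in (a, b, c)]
        segs = shared_segments(paths, 100.0)
        for k, p in enumerate(paths):
            total = sum(s.length_km for s in segs if k in s.members)
            assert total == pytest.approx(p.length_km)

    def test_segment_cells_partition_each_path(self):
        a = [(2, 2), (1, 1), (0, 0)]
        b = [(0, 2), (0, 1), (0, 0)]
        segs = shared_segments([self._path(a), self._path(b)], 100.0)
        for k, cells in enumerate((a, b)):
            covered = [cell for s in segs if k in s.members for cell in s.cells]
            assert sorted(covered) == sorted(cells)


class TestWeakLinks:
    def _path_row(self, row, n, cell_size=100.0):
        cells = [(row, c) for c in range(n)]
        return CorridorPath(cells, path_length_km(cells, cell_size), 0.0)

    def test_infinite_forest_no_weak_links(self):
        spec = GridSpec(20, 60, 100.0, 0.0, 2000.0)
        forest = Grid(spec, np.ones(spec.shape), "categorical")
        assert weak_links(self._path_row(10, 60), forest, 4.0) == []

    def test_known_neck_width_recovered(self):
        # forest band 40 cells (4 km) tall with a path along its centre;
        # non-forest above and below -> width 2 x 2000 m = 4 km
        spec = GridSpec(60, 100, 100.0, 0.0, 6000.0)
        vals = np.zeros(spec.shape)
        vals[10:50, :] = 1.0  # rows 10..49 forest
        forest = Grid(spec, vals, "categorical")
        links = weak_links(self._path_row(29, 100), forest, 5.0)
        assert len(links) == 1
        assert links[0].cause == "constriction"
        assert links[0].min_width_km == pytest.approx(4.0, abs=0.2)

    def test_zero_threshold_vacuous(self):
        spec = GridSpec(10, 10, 100.0, 0.0, 1000.0)
        vals = np.zeros(spec.shape)
        vals[5, :] = 1.0
        forest = Grid(spec, vals, "categorical")
        assert weak_links(self._path_row(5, 10), forest, 0.0) == []

    def test_fragmentation_cause_when_edge_cost_high(self):
        spec = GridSpec(20, 20, 100.0, 0.0, 2000.0)
        vals = np.zeros(spec.shape)
        vals[9:11, :] = 1.0  # narrow strip
        forest = Grid(spec, vals, "categorical")
        edge_cost = Grid(spec, np.full(spec.shape, 8.0), "cost")
        links = weak_links(self._path_row(9, 20), forest, 4.0, edge_cost=edge_cost)
        assert links and links[0].cause == "fragmentation"


class TestBufferCorridor:
    def test_straight_path_uniform_radius_area(self):
        spec = GridSpec(10, 101, 100.0, 0.0, 1000.0)
        cells = [(5, c) for c in range(101)]  # 10 km straight path
        p = CorridorPath(cells, path_length_km(cells, 100.0), 0.0)
        poly = buffer_corridor(p, spec, 2.0, 2.0)
        expected_km2 = 2 * 2.0 * 10.0 + math.pi * 2.0**2
        assert poly.area / 1e6 == pytest.approx(expected_km2, rel=0.05)

    def test_buffer_contains_every_path_cell(self):
        spec = GridSpec(20, 20, 100.0, 0.0, 2000.0)
        cells = [(i, i) for i in range(20)]
        p = CorridorPath(cells, path_length_km(cells, 100.0), 0.0)
        poly = buffer_corridor(p, spec, 2.0, 6.0)
        from shapely.geometry import Point

        assert all(poly.contains(Point(spec.cell_center(r, c))) for r, c in cells)

    def test_bad_radii_rejected(self):
        spec = GridSpec(5, 5, 100.0, 0.0, 500.0)
        p = CorridorPath([(0, 0)], 0.0, 0.0)
        with pytest.raises(ValueError):
            buffer_corridor(p, spec, 6.0, 2.0)


class TestWaterGaps:
    def _straight(self, n, cell_size=100.0):
        cells = [(0, c) for c in range(n)]
        return CorridorPath(cells, path_length_km(cells, cell_size), 0.0)

    def _distance_grid(self, n, water_cols, cell_size=100.0):
        spec = GridSpec(1, n, cell_size, 0.0, cell_size)
        cols = np.arange(n)
        d = np.min(
            [np.abs(cols - w) * cell_size for w in water_cols], axis=0
        ).reshape(1, n)
        return Grid(spec, d.astype(float), "continuous")

    def test_all_within_max_no_gaps(self):
        wd = self._distance_grid(50, [0, 25, 49])
        assert water_gaps(self._straight(50), wd, 5.0) == []

    def test_infinite_max_no_gaps(self):
        wd = self._distance_grid(50, [0])
        assert water_gaps(self._straight(50), wd, math.inf) == []

    def test_twenty_km_gap_covered_after_placement(self):
        # water only at both ends of a 30 km path -> one ~20 km waterless span
        n = 301
        wd = self._distance_grid(n, [0, 300])
        gaps = water_gaps(self._straight(n), wd, 5.0)
        assert len(gaps) == 1
        assert gaps[0].length_km == pytest.approx(20.0, abs=0.2)
        holes = gaps[0].proposed_waterholes
        assert len(holes) >= 1
        hole_cols = [c for _, c in holes]
        for _, c in gaps[0].span:
            nearest = min(
                min(abs(c - h) for h in hole_cols) * 0.1,
                min(abs(c - w) for w in (0, 300)) * 0.1,
            )
            assert nearest <= 5.0
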