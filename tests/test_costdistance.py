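import math
from datetime import date

import networkx as nx
import numpy as np
import pytest

from accessmon.costdistance import (CostDistanceError, cumulative_cost,
                                    least_cost_path, village_travel_times)
from accessmon.friction import FrictionSurface
from accessmon.geodata import Clinic, GridSpec, Village

WALK = 60.0 / 3500.0  # minutes per metre at 3.5 km/h


def _clinic(x, y, cid="C1"):
    return Clinic(clinic_id=cid, name=cid, x=x, y=y,
                  opening_date=date(2005, 7, 1))


def _uniform_surface(n_rows=5, n_cols=40, cell=100.0, mpm=WALK):
    grid = GridSpec(origin_x=0.0, origin_y=n_rows * cell, cell_size=cell,
                    n_rows=n_rows, n_cols=n_cols)
    return FrictionSurface(grid=grid,
                           cell_time_per_m=np.full((n_rows, n_cols), mpm))


def _oracle_field(friction, source_cells):
    """Independent oracle: networkx Dijkstra over an explicitly built
    8-neighbour graph with average-cost edges."""
    t = friction.cell_time_per_m
    nr, nc = t.shape
    cs = friction.grid.cell_size
    G = nx.Graph()
    for r in range(nr):
        for c in range(nc):
            for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < nr and 0 <= c2 < nc:
                    d = cs * math.sqrt(2) if dr and dc else cs
                    G.add_edge((r, c), (r2, c2),
                               weight=d * 0.5 * (t[r, c] + t[r2, c2]))
    out = np.full((nr, nc), np.inf)
    for src in source_cells:
        dist = nx.single_source_dijkstra_path_length(G, src)
        for (r, c), v in dist.items():
            out[r, c] = min(out[r, c], v)
    return out


class TestCumulativeCost:
    def test_uniform_walk_3500m_east_is_60_minutes(self):
        fric = _uniform_surface()
        field = cumulative_cost(fric, [_clinic(50.0, 250.0)])
        assert field.at(3550.0, 250.0) == pytest.approx(60.0, abs=1e-9)

    def test_single_diagonal_step(self):
        fric = _uniform_surface(n_rows=3, n_cols=3)
        field = cumulative_cost(fric, [_clinic(50.0, 250.0)])
        r, c = fric.grid.snap(150.0, 150.0)
        assert field.minutes[r, c] == pytest.approx(
            100.0 * math.sqrt(2) * WALK, abs=1e-9)

    def test_source_cells_are_zero(self):
        fric = _uniform_surface(10, 10)
        field = cumulative_cost(fric, [_clinic(450.0, 450.0)])
        assert field.at(450.0, 450.0) == 0.0
        assert (field.minutes >= 0).all()

    def test_empty_sources_rejected(self):
        with pytest.raises(CostDistanceError):
            cumulative_cost(_uniform_surface(3, 3), [])

    def test_source_outside_grid_rejected(self):
        with pytest.raises(CostDistanceError, match="outside"):
            cumulative_cost(_uniform_surface(3, 3),
                            [_clinic(-500.0, 150.0)])

    def test_matches_networkx_oracle_on_random_surfaces(self):
        rng = np.random.default_rng(2024)
        for trial in range(20):
            n = int(rng.integers(15, 21))
            grid = GridSpec(origin_x=0.0, origin_y=n * 100.0,
                            cell_size=100.0, n_rows=n, n_cols=n)
            fric = FrictionSurface(
                grid=grid,
                cell_time_per_m=rng.uniform(0.001, 0.05, size=(n, n)))
            n_src = int(rng.integers(1, 4))
            cells = [(int(rng.integers(n)), int(rng.integers(n)))
                     for _ in range(n_src)]
            clinics = [_clinic(*grid.cell_center(r, c), cid=f"C{i}")
                       for i, (r, c) in enumerate(cells)]
            field = cumulative_cost(fric, clinics)
            oracle = _oracle_field(fric, cells)
            np.testing.assert_allclose(field.minutes, oracle, atol=1e-9)

    def test_adding_a_source_never_increases_minutes(self):
        rng = np.random.default_rng(5)
        grid = GridSpec(origin_x=0.0, origin_y=1500.0, cell_size=100.0,
                        n_rows=15, n_cols=15)
        fric = FrictionSurface(
            grid=grid, cell_time_per_m=rng.uniform(0.001, 0.05, (15, 15)))
        one = cumulative_cost(fric, [_clinic(250.0, 250.0)])
        two = cumulative_cost(fric, [_clinic(250.0, 250.0),
                                     _clinic(1250.0, 1250.0, "C2")])
        assert (two.minutes <= one.minutes + 1e-12).all()

    def test_multisource_is_pointwise_minimum(self):
        rng = np.random.default_rng(6)
        grid = GridSpec(origin_x=0.0, origin_y=1200.0, cell_size=100.0,
                        n_rows=12, n_cols=12)
        fric = FrictionSurface(
            grid=grid, cell_time_per_m=rng.uniform(0.001, 0.05, (12, 12)))
        c1 = _clinic(150.0, 1050.0, "C1")
        c2 = _clinic(1050.0, 150.0, "C2")
        both = cumulative_cost(fric, [c1, c2])
        m1 = cumulative_cost(fric, [c1]).minutes
        m2 = cumulative_cost(fric, [c2]).minutes
        np.testing.assert_allclose(both.minutes, np.minimum(m1, m2),
                                   atol=1e-12)


class TestLeastCostPath:
    def test_origin_equals_source(self):
        fric = _uniform_surface(5, 5)
        field = cumulative_cost(fric, [_clinic(250.0, 250.0)])
        path = least_cost_path(field, fric, (250.0, 250.0))
        assert path.cells == [fric.grid.snap(250.0, 250.0)]
        assert path.total_minutes == 0.0
        assert path.total_metres == 0.0

    def test_cardinal_path_300m(self):
        fric = _uniform_surface(5, 10)
        field = cumulative_cost(fric, [_clinic(50.0, 250.0)])
        path = least_cost_path(field, fric, (350.0, 250.0))
        assert len(path.cells) == 4
        assert path.total_metres == pytest.approx(300.0)
        assert path.total_minutes == pytest.approx(300.0 * WALK, abs=1e-9)

    def test_backtracked_cost_equals_field_value(self):
        rng = np.random.default_rng(9)
        grid = GridSpec(origin_x=0.0, origin_y=2000.0, cell_size=100.0,
                        n_rows=20, n_cols=20)
        fric = FrictionSurface(
            grid=grid, cell_time_per_m=rng.uniform(0.001, 0.05, (20, 20)))
        field = cumulative_cost(fric, [_clinic(150.0, 1850.0)])
        for _ in range(10):
            x = float(rng.uniform(0, 2000))
            y = float(rng.uniform(0, 2000))
            path = least_cost_path(field, fric, (x, y))
            total = sum(
                _edge_total(fric, path.cells[i], path.cells[i + 1])
                for i in range(len(path.cells) - 1)
            )
            assert path.total_minutes == pytest.approx(field.at(x, y),
                                                       abs=1e-9)
            assert total == pytest.approx(path.total_minutes, abs=1e-9)

    def test_detour_onto_fast_corridor_pays_off(self):
        # a tarmac row along the top: walking origin far east should
        # route up to the corridor; cost must still match the field
        grid = GridSpec(origin_x=0.0, origin_y=1000.0, cell_size=100.0,
                        n_rows=10, n_cols=50)
        t = np.full((10, 50), WALK)
        t[0, :] = 60.0 / 35000.0
        fric = FrictionSurface(grid=grid, cell_time_per_m=t)
        field = cumulative_cost(fric, [_clinic(50.0, 950.0)])
        origin = (4950.0, 550.0)
        path = least_cost_path(field, fric, origin)
        rows = {r for r, _ in path.cells}
        assert 0 in rows  # enters the corridor
        assert path.total_minutes == pytest.approx(field.at(*origin),
                                                   abs=1e-9)


def _edge_total(fric, a, b):
    cs = fric.grid.cell_size
    d = cs * math.sqrt(2) if (a[0] != b[0] and a[1] != b[1]) else cs
    return d * 0.5 * (fric.cell_time_per_m[a] + fric.cell_time_per_m[b])


class TestVillageTravelTimes:
    def test_village_on_source_and_shared_cells(self):
        fric = _uniform_surface(5, 10)
        field = cumulative_cost(fric, [_clinic(50.0, 250.0)])
        villages = [
            Village("V1", "on-source", 50.0, 250.0, 10.0),
            Village("V2", "east-a", 520.0, 260.0, 10.0),
            Village("V3", "east-b", 540.0, 240.0, 10.0),
        ]
        tbl = village_travel_times(field, villages)
        assert tbl.loc[tbl.village_id == "V1", "minutes"].item() == 0.0
        a = tbl.loc[tbl.village_id == "V2", "minutes"].item()
        b = tbl.loc[tbl.village_id == "V3", "minutes"].item()
        assert a == b  # same cell

    def test_outside_village_listed_in_error(self):
        fric = _uniform_surface(5, 5)
        field = cumulative_cost(fric, [_clinic(250.0, 250.0)])
        with pytest.raises(CostDistanceError, match="V9"):
            village_travel_times(field, [
                Village("V9", "far", 99_999.0, 0.0, 1.0)])
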