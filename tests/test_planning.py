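"""Least-cost corridor and protected-area-expansion contracts, checked
against an explicit-graph Dijkstra oracle and a flood-fill oracle."""

import itertools
import math

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from shapely.geometry import box

import landintegrity as li
from landintegrity.lii import LiiSurface

from conftest import make_raster


def dijkstra_oracle(resistance, source_cells):
    """Shortest accumulated cost on the explicit 8-connected grid graph."""
    n_rows, n_cols = resistance.shape
    rows, cols, data = [], [], []
    for i, j in itertools.product(range(n_rows), range(n_cols)):
        for di, dj in itertools.product((-1, 0, 1), repeat=2):
            if di == dj == 0:
                continue
            ii, jj = i + di, j + dj
            if 0 <= ii < n_rows and 0 <= jj < n_cols:
                w = (resistance[i, j] + resistance[ii, jj]) / 2 * math.hypot(di, dj)
                rows.append(i * n_cols + j)
                cols.append(ii * n_cols + jj)
                data.append(w)
    graph = csr_matrix((data, (rows, cols)),
                       shape=(n_rows * n_cols, n_rows * n_cols))
    idx = [r * n_cols + c for r, c in source_cells]
    return dijkstra(graph, indices=idx).min(axis=0).reshape(n_rows, n_cols)


def lii_surface(values):
    return LiiSurface(values=make_raster(values))


class TestResistance:
    @pytest.mark.parametrize("lii_val,expected", [
        (1.0, li.planning.DEFAULT_RESISTANCE_FLOOR), (0.0, 1.0), (0.75, 0.25),
    ])
    def test_inverse_transform(self, lii_val, expected):
        out = li.resistance_from_lii(lii_surface(np.full((3, 3), lii_val)))
        assert np.allclose(out.values, expected)

    def test_literal_flag_uses_lii_directly(self):
        out = li.resistance_from_lii(lii_surface(np.full((2, 2), 0.75)),
                                     literal=True)
        assert np.allclose(out.values, 0.75)

    def test_monotone_decreasing_in_lii(self, rng):
        vals = rng.uniform(0, 1, (5, 5))
        res = li.resistance_from_lii(lii_surface(vals)).values
        order = np.argsort(vals.ravel())
        assert np.all(np.diff(res.ravel()[order]) <= 1e-15)


class TestCostDistance:
    def test_uniform_resistance_is_chamfer_distance(self):
        res = make_raster(np.ones((5, 5)))
        src = make_raster(np.eye(5)[:, :1] @ np.ones((1, 5)) * 0)
        src.values[0, 0] = 1
        cum = li.cost_distance(res, src).values
        for r in range(5):
            for c in range(5):
                expected = min(r, c) * math.sqrt(2) + abs(r - c)
                assert cum[r, c] == pytest.approx(expected, abs=1e-12)

    def test_source_cells_zero(self, rng):
        res = make_raster(rng.uniform(0.5, 2, (6, 6)))
        src_vals = np.zeros((6, 6))
        src_vals[2, 3] = src_vals[5, 0] = 1
        cum = li.cost_distance(res, make_raster(src_vals)).values
        assert cum[2, 3] == 0 and cum[5, 0] == 0

    def test_linearity_in_resistance(self, rng):
        vals = rng.uniform(0.5, 2, (7, 7))
        src_vals = np.zeros((7, 7))
        src_vals[0, 6] = 1
        c1 = li.cost_distance(make_raster(vals), make_raster(src_vals)).values
        c2 = li.cost_distance(make_raster(2 * vals), make_raster(src_vals)).values
        assert np.allclose(c2, 2 * c1, atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dijkstra_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0.1, 3.0, (10, 10))
        src_cells = [(0, 0), (7, 4)]
        src_vals = np.zeros((10, 10))
        for rc in src_cells:
            src_vals[rc] = 1
        cum = li.cost_distance(make_raster(vals), make_raster(src_vals)).values
        oracle = dijkstra_oracle(vals, src_cells)
        assert np.allclose(cum, oracle, atol=1e-10)

    def test_no_sources_rejected(self):
        with pytest.raises(ValueError, match="source"):
            li.cost_distance(make_raster(np.ones((3, 3))),
                             make_raster(np.zeros((3, 3))))

    def test_nonpositive_resistance_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            li.cost_distance(make_raster(np.zeros((3, 3))),
                             make_raster(np.ones((3, 3))))


class TestCorridorSurface:
    def _costs(self, resistance, a_cells, b_cells):
        def srcr(cells):
            v = np.zeros(resistance.shape)
            for rc in cells:
                v[rc] = 1
            return make_raster(v)
        res = make_raster(resistance)
        return (li.cost_distance(res, srcr(a_cells)),
                li.cost_distance(res, srcr(b_cells)))

    def test_minimum_is_zero(self, rng):
        ca, cb = self._costs(rng.uniform(0.5, 2, (8, 8)), [(0, 0)], [(7, 7)])
        corr = li.corridor_surface(ca, cb).values
        assert corr.min() == 0
        assert np.all(corr >= 0)

    def test_straight_line_between_row_endpoints(self):
        ca, cb = self._costs(np.ones((5, 9)), [(2, 0)], [(2, 8)])
        corr = li.corridor_surface(ca, cb).values
        zeros = set(zip(*np.nonzero(corr == 0)))
        assert zeros == {(2, c) for c in range(9)}

    def test_zero_along_reconstructed_path(self, rng):
        vals = rng.uniform(0.5, 2, (9, 9))
        ca, cb = self._costs(vals, [(0, 0)], [(8, 8)])
        corr = li.corridor_surface(ca, cb).values
        # greedy descent on cost_a from the B endpoint traces a least-cost
        # path; every cell on it must hold corridor value 0
        path = [(8, 8)]
        while path[-1] != (0, 0):
            r, c = path[-1]
            nbrs = [
                (r + di, c + dj)
                for di, dj in itertools.product((-1, 0, 1), repeat=2)
                if (di or dj) and 0 <= r + di < 9 and 0 <= c + dj < 9
            ]
            nxt = min(
                nbrs,
                key=lambda rc: ca.values[rc]
                + (vals[rc] + vals[r, c]) / 2 * math.hypot(rc[0] - r, rc[1] - c),
            )
            path.append(nxt)
        for rc in path:
            assert corr[rc] == pytest.approx(0.0, abs=1e-9)

    def test_scaling_resistance_scales_corridor(self, rng):
        vals = rng.uniform(0.5, 2, (7, 7))
        ca1, cb1 = self._costs(vals, [(0, 0)], [(6, 6)])
        ca2, cb2 = self._costs(3 * vals, [(0, 0)], [(6, 6)])
        c1 = li.corridor_surface(ca1, cb1).values
        c2 = li.corridor_surface(ca2, cb2).values
        assert np.allclose(c2, 3 * c1, atol=1e-9)


class TestSelectCorridors:
    def _setup(self, rng, shape=(20, 20)):
        vals = rng.uniform(0.2, 0.9, shape)
        surface = lii_surface(vals)
        res = li.resistance_from_lii(surface)
        pvals = np.zeros(shape)
        pvals[:3, :3] = 1
        pvals[-3:, -3:] = 1
        pmask = make_raster(pvals)
        src_a, src_b = make_raster((pvals * 0)), make_raster((pvals * 0))
        src_a.values[:3, :3] = 1
        src_b.values[-3:, -3:] = 1
        ca = li.cost_distance(res, src_a)
        cb = li.cost_distance(res, src_b)
        corr = li.corridor_surface(ca, cb)
        return corr, pmask

    def test_selected_fraction_matches_request(self, rng):
        corr, pmask = self._setup(rng)
        mask = li.select_corridors([corr], pmask, fraction=0.30)
        eligible = np.asarray(pmask.values) != 1
        frac = mask.values[eligible].sum() / eligible.sum()
        assert abs(frac - 0.30) <= 1.0 / eligible.sum()

    def test_fraction_near_one_selects_everything(self, rng):
        corr, pmask = self._setup(rng)
        mask = li.select_corridors([corr], pmask, fraction=0.999)
        eligible = np.asarray(pmask.values) != 1
        assert mask.values[eligible].sum() >= 0.99 * eligible.sum()

    def test_least_cost_path_always_selected(self, rng):
        corr, pmask = self._setup(rng)
        mask = li.select_corridors([corr], pmask, fraction=0.05)
        zero_cells = (corr.values == 0) & (np.asarray(pmask.values) != 1)
        assert np.all(mask.values[zero_cells] == 1)

    def test_nested_in_fraction(self, rng):
        corr, pmask = self._setup(rng)
        m1 = li.select_corridors([corr], pmask, fraction=0.1).values
        m2 = li.select_corridors([corr], pmask, fraction=0.4).values
        assert np.all(m2[m1 == 1] == 1)

    def test_priority_cells_never_selected(self, rng):
        corr, pmask = self._setup(rng)
        mask = li.select_corridors([corr], pmask, fraction=0.5)
        assert np.all(mask.values[np.asarray(pmask.values) == 1] == 0)

    def test_bad_fraction_rejected(self, rng):
        corr, pmask = self._setup(rng)
        for f in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                li.select_corridors([corr], pmask, fraction=f)


def flood_fill_oracle(high, pmask):
    """Components of supra-threshold cells reachable (8-conn) from cells
    adjacent to the priority mask."""
    n_rows, n_cols = high.shape
    seeds = set()
    for r, c in zip(*np.nonzero(high)):
        for di, dj in itertools.product((-1, 0, 1), repeat=2):
            rr, cc = r + di, c + dj
            if 0 <= rr < n_rows and 0 <= cc < n_cols and pmask[rr, cc]:
                seeds.add((r, c))
    keep = np.zeros_like(high, dtype=bool)
    stack = list(seeds)
    while stack:
        r, c = stack.pop()
        if keep[r, c]:
            continue
        keep[r, c] = True
        for di, dj in itertools.product((-1, 0, 1), repeat=2):
            rr, cc = r + di, c + dj
            if 0 <= rr < n_rows and 0 <= cc < n_cols and high[rr, cc] \
                    and not keep[rr, cc]:
                stack.append((rr, cc))
    return keep


class TestExpansionAreas:
    def test_all_below_threshold_empty(self):
        surface = lii_surface(np.full((6, 6), 0.5))
        pvals = np.zeros((6, 6))
        pvals[0, 0] = 1
        result = li.expansion_areas(surface, make_raster(pvals), threshold=0.7)
        assert result.total_area_km2 == 0 and not result.regions

    def test_touching_blob_kept_isolated_dropped(self):
        vals = np.full((10, 10), 0.2)
        vals[0:2, 1:3] = 0.9   # touches priority cell (0,0) diagonally
        vals[7:9, 7:9] = 0.9   # isolated
        pvals = np.zeros((10, 10))
        pvals[0, 0] = 1
        result = li.expansion_areas(lii_surface(vals), make_raster(pvals), 0.7)
        assert len(result.regions) == 1
        assert result.mask.values[1, 1] == 1
        assert result.mask.values[8, 8] == 0
        # area: 4 cells of 90 m
        assert result.total_area_km2 == pytest.approx(4 * 0.09 ** 2)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 1, (30, 30))
        pvals = np.zeros((30, 30))
        pvals[12:15, 12:15] = 1
        surface = lii_surface(vals)
        pmask = make_raster(pvals)
        result = li.expansion_areas(surface, pmask, threshold=0.7)
        high = (vals > 0.7) & (pvals != 1)
        oracle = flood_fill_oracle(high, pvals == 1)
        assert np.array_equal(result.mask.values.astype(bool), oracle)
        # every retained cell exceeds the threshold
        assert np.all(vals[result.mask.values == 1] > 0.7)

    def test_area_non_increasing_in_threshold(self, rng):
        vals = rng.uniform(0, 1, (25, 25))
        pvals = np.zeros((25, 25))
        pvals[10:13, 10:13] = 1
        surface = lii_surface(vals)
        pmask = make_raster(pvals)
        areas = [
            li.expansion_areas(surface, pmask, threshold=t).total_area_km2
            for t in (0.3, 0.5, 0.7, 0.9)
        ]
        assert all(a >= b for a, b in zip(areas, areas[1:]))


class TestPriorityArea:
    def test_gap_status_restricted(self):
        with pytest.raises(ValueError, match="GAP status"):
            li.PriorityArea("x", box(0, 0, 1, 1), gap_status=3)

    def test_pairwise_corridors_all_pairs(self, rng):
        vals = rng.uniform(0.2, 0.8, (15, 15))
        res = li.resistance_from_lii(lii_surface(vals))
        areas = [
            li.PriorityArea("a", box(0, 1200, 200, 1350), 1),
            li.PriorityArea("b", box(1100, 0, 1340, 200), 2),
            li.PriorityArea("c", box(1100, 1200, 1340, 1350), 1),
        ]
        results = li.pairwise_corridors(res, areas)
        assert {r.pair for r in results} == {("a", "b"), ("a", "c"), ("b", "c")}
        for r in results:
            finite = np.isfinite(r.corridor_value.values)
            assert r.corridor_value.values[finite].min() == 0
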