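"""Least-cost paths: masks, Dijkstra equivalence, distance matrices."""

import io
import itertools

import numpy as np
import pytest

import bathykit as bk
from bathykit.connectivity import NoPathError, SnapError

from conftest import oracle_shortest_path_km


class TestPassableMask:
    def test_all_ocean_window_everything_true(self):
        g = bk.generate(bk.SynthSpec("flat", params={"depth": -500.0}))
        m = bk.passable_mask(g, bk.DepthWindow(-12000, 0))
        assert m.mask.all()

    def test_avoid_shallower_than_1000m(self):
        # classic dispersal constraint: only water deeper than 1000 m passes
        g = bk.make_grid([0, 1], [0, 1], [[-500.0, -2000.0], [-1000.0, -999.9]])
        m = bk.passable_mask(g, bk.DepthWindow(-12000, -1000))
        assert not m.mask[0, 0]          # -500 m: too shallow
        assert m.mask[0, 1]              # -2000 m: passable
        assert m.mask[1, 0]              # exactly -1000 m: inclusive bound
        assert not m.mask[1, 1]

    def test_missing_cells_never_passable(self):
        g = bk.make_grid([0, 1], [0, 1], [[np.nan, -2000.0], [-2000.0, -2000.0]])
        m = bk.passable_mask(g, bk.DepthWindow(-12000, 0))
        assert not m.mask[0, 0]


def _open_grid(n=5, spacing=0.5, depth=-3000.0):
    ax = spacing * np.arange(n)
    return bk.make_grid(ax, ax, np.full((n, n), depth))


class TestLeastCostPath:
    def test_src_equals_dst_single_node(self):
        g = _open_grid()
        m = bk.passable_mask(g, bk.DepthWindow(-12000, 0))
        p = bk.least_cost_path(g, m, bk.GeoPoint(1.0, 1.0), bk.GeoPoint(1.0, 1.0))
        assert len(p.nodes) == 1 and p.length_km == 0.0

    @pytest.mark.parametrize("neighborhood", [4, 8, 16])
    def test_meridian_route_matches_haversine(self, neighborhood):
        g = _open_grid(9, 0.25)
        m = bk.passable_mask(g, bk.DepthWindow(-12000, 0))
        src, dst = bk.GeoPoint(1.0, 0.0), bk.GeoPoint(1.0, 2.0)
        p = bk.least_cost_path(g, m, src, dst, neighborhood=neighborhood)
        direct = bk.haversine_km(src, dst)
        cell = bk.haversine_km(bk.GeoPoint(1.0, 0.0), bk.GeoPoint(1.0, 0.25))
        assert direct - 1e-9 <= p.length_km <= direct + cell / 2

    def test_wall_with_gap_matches_brute_force(self):
        # 5x5, full-height wall at column 2 except a gap at row 4
        g = _open_grid(5)
        mask = np.ones((5, 5), dtype=bool)
        mask[:4, 2] = False
        pm = bk.PassableMask(mask)
        src, dst = g.node_point(0, 0), g.node_point(0, 4)
        for nb in (4, 8, 16):
            p = bk.least_cost_path(g, pm, src, dst, neighborhood=nb)
            ref = oracle_shortest_path_km(g, mask, (0, 0), (0, 4), nb)
            assert p.length_km == pytest.approx(ref, abs=1e-9)

    def test_paths_step_only_between_declared_neighbors(self):
        g = _open_grid(7)
        mask = np.ones((7, 7), dtype=bool)
        mask[2:5, 3] = False
        pm = bk.PassableMask(mask)
        for nb, max_step in [(4, 1), (8, 1), (16, 2)]:
            p = bk.least_cost_path(g, pm, g.node_point(3, 0), g.node_point(3, 6),
                                   neighborhood=nb)
            lons = np.array([q.lon for q in p.nodes])
            lats = np.array([q.lat for q in p.nodes])
            ji = np.rint(lons / 0.5).astype(int)
            ii = np.rint(lats / 0.5).astype(int)
            for k in range(len(p.nodes) - 1):
                di, dj = abs(ii[k + 1] - ii[k]), abs(ji[k + 1] - ji[k])
                assert max(di, dj) <= max_step
                assert mask[ii[k], ji[k]] and mask[ii[k + 1], ji[k + 1]]

    def test_exhaustive_masks_on_5x5(self):
        """Implementation agrees with a first-principles Dijkstra on every
        mask with up to 3 blocked interior cells, all neighborhoods."""
        g = _open_grid(5)
        cells = [(i, j) for i in range(5) for j in range(5)
                 if (i, j) not in ((0, 0), (4, 4))]
        src, dst = g.node_point(0, 0), g.node_point(4, 4)
        combos = [()] + [c for r in (1, 2) for c in itertools.combinations(cells, r)]
        rng = np.random.default_rng(5)
        for r in (3, 4):  # sample deeper block counts
            all_r = list(itertools.combinations(cells, r))
            idx = rng.choice(len(all_r), size=60, replace=False)
            combos += [all_r[k] for k in idx]
        for blocked in combos:
            mask = np.ones((5, 5), dtype=bool)
            for ij in blocked:
                mask[ij] = False
            pm = bk.PassableMask(mask)
            for nb in (4, 8, 16):
                ref = oracle_shortest_path_km(g, mask, (0, 0), (4, 4), nb)
                if ref is None:
                    with pytest.raises(NoPathError):
                        bk.least_cost_path(g, pm, src, dst, neighborhood=nb)
                else:
                    p = bk.least_cost_path(g, pm, src, dst, neighborhood=nb)
                    assert p.length_km == pytest.approx(ref, abs=1e-9)

    def test_snap_failure_and_disconnection_are_distinct_errors(self):
        g = _open_grid(7)
        mask = np.ones((7, 7), dtype=bool)
        mask[:, 2:5] = False    # 3-wide wall: splits even with knight moves
        pm = bk.PassableMask(mask)
        with pytest.raises(NoPathError):
            bk.least_cost_path(g, pm, g.node_point(0, 0), g.node_point(0, 6))
        mask2 = np.zeros((7, 7), dtype=bool)
        mask2[6, 6] = True
        with pytest.raises(SnapError):
            bk.least_cost_path(g, bk.PassableMask(mask2),
                               g.node_point(0, 0), g.node_point(6, 6))

    def test_matches_networkx_on_random_masks(self):
        """Cross-check against networkx Dijkstra, a third independent
        implementation, on seeded random masks."""
        import networkx as nx

        g = _open_grid(6, 0.4)
        rng = np.random.default_rng(21)
        for _ in range(15):
            mask = rng.random((6, 6)) > 0.25
            mask[0, 0] = mask[5, 5] = True
            pm = bk.PassableMask(mask)
            G = nx.Graph()
            steps = [(0, 1), (1, 0), (1, 1), (1, -1),
                     (1, 2), (2, 1), (1, -2), (2, -1)]
            for i in range(6):
                for j in range(6):
                    if not mask[i, j]:
                        continue
                    for di, dj in steps:
                        ii, jj = i + di, j + dj
                        if 0 <= ii < 6 and 0 <= jj < 6 and mask[ii, jj]:
                            w = bk.haversine_km(g.node_point(i, j),
                                                g.node_point(ii, jj))
                            G.add_edge((i, j), (ii, jj), weight=w)
            try:
                ref = nx.dijkstra_path_length(G, (0, 0), (5, 5))
            except (nx.NetworkXNoPath, nx.NodeNotFound):
                ref = None
            if ref is None:
                with pytest.raises(NoPathError):
                    bk.least_cost_path(g, pm, g.node_point(0, 0),
                                       g.node_point(5, 5), neighborhood=16)
            else:
                p = bk.least_cost_path(g, pm, g.node_point(0, 0),
                                       g.node_point(5, 5), neighborhood=16)
                assert p.length_km == pytest.approx(ref, abs=1e-9)

    def test_deterministic_across_runs(self):
        g = _open_grid(7)
        m = bk.passable_mask(g, bk.DepthWindow(-12000, 0))
        a = bk.least_cost_path(g, m, g.node_point(0, 0), g.node_point(6, 6))
        b = bk.least_cost_path(g, m, g.node_point(0, 0), g.node_point(6, 6))
        assert a.length_km == b.length_km
        assert [(p.lon, p.lat) for p in a.nodes] == [(p.lon, p.lat) for p in b.nodes]


class TestDistanceMatrix:
    def test_identical_sites_zero_matrix(self):
        g = _open_grid()
        p = bk.GeoPoint(1.0, 1.0)
        mat = bk.lc_distance_matrix(g, bk.DepthWindow(-12000, 0), [p, p])
        assert np.array_equal(mat, np.zeros((2, 2)))

    def test_open_ocean_lower_bounded_by_haversine(self):
        g = _open_grid(9, 0.25)
        sites = [g.node_point(0, 0), g.node_point(8, 8), g.node_point(0, 8),
                 g.node_point(4, 2)]
        mat = bk.lc_distance_matrix(g, bk.DepthWindow(-12000, 0), sites)
        for i in range(4):
            for j in range(4):
                assert mat[i, j] >= bk.haversine_km(sites[i], sites[j]) - 1e-9

    def test_matches_per_pair_path_calls(self, two_basins_grid):
        g = two_basins_grid
        win = bk.DepthWindow(-12000, -1000)
        sites = [bk.GeoPoint(-1.4, 1.4), bk.GeoPoint(1.4, 1.4), bk.GeoPoint(1.4, -1.4)]
        mat = bk.lc_distance_matrix(g, win, sites)
        m = bk.passable_mask(g, win)
        for i in range(3):
            for j in range(i + 1, 3):
                p = bk.least_cost_path(g, m, sites[i], sites[j])
                assert mat[i, j] == pytest.approx(p.length_km, abs=1e-9)
        assert np.allclose(mat, mat.T) and np.all(np.diag(mat) == 0)

    def test_unreachable_pairs_are_inf_with_warning(self):
        g = _open_grid(7)
        vals = g.values.copy()
        vals[:, 2:5] = -100.0  # 3-wide shallow wall
        g2 = bk.make_grid(g.lon_axis, g.lat_axis, vals)
        sites = [g2.node_point(3, 0), g2.node_point(3, 6)]
        with pytest.warns(UserWarning, match="unreachable"):
            mat = bk.lc_distance_matrix(g2, bk.DepthWindow(-12000, -1000), sites)
        assert np.isinf(mat[0, 1])

    def test_snap_error_names_site_index(self):
        g = _open_grid(5)
        vals = g.values.copy()
        vals[0, 0] = -100.0
        vals[0, 1] = -100.0
        vals[1, 0] = -100.0
        vals[1, 1] = -100.0
        g2 = bk.make_grid(g.lon_axis, g.lat_axis, vals)
        with pytest.raises(SnapError, match="site 0"):
            bk.lc_distance_matrix(g2, bk.DepthWindow(-12000, -1000),
                                  [g2.node_point(0, 0), g2.node_point(4, 4)])

    def test_triangle_inequality_over_fixed_mask(self, two_basins_grid):
        win = bk.DepthWindow(-12000, -1000)
        sites = bk.generate_sites(two_basins_grid, 6,
                                  bk.DepthWindow(-4500, -3500), seed=2)
        pts = [bk.GeoPoint(r.lon, r.lat) for r in sites.itertuples()]
        mat = bk.lc_distance_matrix(two_basins_grid, win, pts)
        n = len(pts)
        for i, j, k in itertools.permutations(range(n), 3):
            assert mat[i, j] <= mat[i, k] + mat[k, j] + 1e-6


class TestExportImport:
    def test_long_csv_row_count(self):
        mat = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        buf = io.StringIO()
        rows = bk.export_distances(mat, ["a", "b", "c"], buf, format="long_csv")
        assert rows == 3
        lines = buf.getvalue().strip().splitlines()
        assert lines[0] == "site_i,site_j,km" and len(lines) == 4

    def test_square_csv_round_trip(self):
        rng = np.random.default_rng(1)
        mat = rng.uniform(0, 1000, (4, 4))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0.0)
        labels = ["s1", "s2", "s3", "s4"]
        buf = io.StringIO()
        bk.export_distances(mat, labels, buf)
        buf.seek(0)
        back, lab2 = bk.import_distances(buf)
        assert lab2 == labels
        assert np.array_equal(back, mat)

    def test_infinite_entries_serialize_as_Inf(self):
        mat = np.array([[0.0, np.inf], [np.inf, 0.0]])
        buf = io.StringIO()
        bk.export_distances(mat, ["a", "b"], buf)
        assert "Inf" in buf.getvalue()
        buf.seek(0)
        back, _ = bk.import_distances(buf)
        assert np.isinf(back[0, 1])

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bk.export_distances(np.zeros((2, 2)), ["a"], io.StringIO())
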