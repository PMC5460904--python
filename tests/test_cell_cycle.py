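"""Growth law, node insertion, mitosis entry and division tests."""

import math

import numpy as np
import pytest

from episem import cell_cycle as cc
from episem.cell_cycle import GrowthConfig, advance_cycle, divide_cell, enter_mitosis, long_axis
from episem.metrics import polygon_area
from episem.tissue import initialize_tissue


@pytest.fixture
def lone_cell(full_cfg):
    ts = initialize_tissue(1, full_cfg, seed=13)
    return ts.cell(0)


class TestGrowthRate:
    def test_base_rate_drawn_within_configured_bounds(self, coarse_cfg):
        ts = initialize_tissue(7, coarse_cfg, seed=0)
        g0 = ts.cell_g0
        assert np.all(g0 >= 2.0e-3) and np.all(g0 <= 4.0e-3)
        # independent draws across cells
        assert len(np.unique(g0)) == 7

    def test_exponential_decay_factor(self, lone_cell):
        cfg = GrowthConfig()
        g0 = cc.growth_rate(lone_cell, 0.0, cfg)
        g1 = cc.growth_rate(lone_cell, 1.0 / cfg.k_g, cfg)
        assert g1 == pytest.approx(g0 / math.e)

    def test_zero_decay_gives_constant_rate(self, lone_cell):
        cfg = GrowthConfig(k_g=0.0)
        assert cc.growth_rate(lone_cell, 0.0, cfg) == cc.growth_rate(lone_cell, 5e4, cfg)


class TestAdvanceCycle:
    def test_internal_nodes_track_cycle_progress(self, full_cfg):
        # 20 internal nodes at CP=0 growing to 40 at CP=1: +1 per 1/20 of CP
        ts = initialize_tissue(1, full_cfg, seed=1)
        cell = ts.cell(0)
        cfg = GrowthConfig(k_g=0.0, T_mit=1e-6)  # effectively no M phase here
        assert cell.n_internal == 20
        while cell.CP < 0.5:
            advance_cycle(cell, dt=10.0, t=0.0, cfg=cfg)
        assert cell.n_internal == 20 + int(cell.CP * 20)
        assert abs(cell.n_internal - 30) <= 1

    def test_count_is_nondecreasing_step_function(self, full_cfg):
        ts = initialize_tissue(1, full_cfg, seed=2)
        cell = ts.cell(0)
        cfg = GrowthConfig(k_g=0.0, T_mit=1e-6)
        counts = [cell.n_internal]
        for _ in range(300):
            advance_cycle(cell, dt=1.0, t=0.0, cfg=cfg)
            counts.append(cell.n_internal)
        d = np.diff(counts)
        assert np.all(d >= 0)
        assert counts[0] == 20 and counts[-1] <= 40

    def test_division_due_fires_exactly_once(self, full_cfg):
        ts = initialize_tissue(1, full_cfg, seed=3)
        cell = ts.cell(0)
        cfg = GrowthConfig(k_g=0.0)
        fired = 0
        for _ in range(2000):
            if "division_due" in advance_cycle(cell, dt=1.0, t=0.0, cfg=cfg):
                fired += 1
                break
        assert fired == 1
        assert cell.CP == pytest.approx(1.0)

    def test_mitosis_entry_duration_close_to_t_mit(self, full_cfg):
        # with constant g the wall time from entry to division is exactly
        # (1 - CP_mit)/g = T_mit
        ts = initialize_tissue(1, full_cfg, seed=4)
        cell = ts.cell(0)
        cfg = GrowthConfig(k_g=0.0, T_mit=30.0)
        t, dt = 0.0, 0.05
        t_entry = None
        while cell.CP < 1.0:
            ev = advance_cycle(cell, dt=dt, t=t, cfg=cfg)
            t += dt
            if "mitosis_entry" in ev:
                t_entry = t
            if "division_due" in ev:
                break
        assert t_entry is not None
        assert (t - t_entry) == pytest.approx(cfg.T_mit, rel=0.1)


class TestInsertInternalNode:
    def test_placement_within_fifth_of_cell_radius(self, lone_cell):
        c0 = lone_cell.centroid()
        rc = lone_cell.radius()
        for _ in range(15):
            if lone_cell.n_internal >= lone_cell.tissue.n_internal_max:
                break
            cc.insert_internal_node(lone_cell)
            new = lone_cell.internal[-1]
            assert np.hypot(*(new - c0)) <= 0.2 * rc + 1e-12

    def test_count_increments_by_one(self, full_cfg):
        ts = initialize_tissue(1, full_cfg, seed=5)
        cell = ts.cell(0)
        n0 = cell.n_internal
        cc.insert_internal_node(cell)
        assert cell.n_internal == n0 + 1

    def test_identical_seed_identical_placement(self, full_cfg):
        a = initialize_tissue(1, full_cfg, seed=6)
        b = initialize_tissue(1, full_cfg, seed=6)
        cc.insert_internal_node(a.cell(0))
        cc.insert_internal_node(b.cell(0))
        np.testing.assert_array_equal(a.pos, b.pos)

    def test_insertion_at_max_warns_and_noops(self, full_cfg):
        ts = initialize_tissue(1, full_cfg, seed=7)
        cell = ts.cell(0)
        while cell.n_internal < ts.n_internal_max:
            cc.insert_internal_node(cell)
        with pytest.warns(UserWarning):
            cc.insert_internal_node(cell)
        assert cell.n_internal == ts.n_internal_max


class TestInsertMembraneNode:
    def test_relaxed_ring_unchanged(self, full_cfg):
        ts = initialize_tissue(1, full_cfg, seed=8)
        cell = ts.cell(0)
        n0 = cell.n_membrane
        assert cc.insert_membrane_node(cell) == 0
        assert cell.n_membrane == n0

    def test_long_segment_split_at_midpoint_preserves_perimeter(self, full_cfg):
        ts = initialize_tissue(1, full_cfg, seed=9)
        cell = ts.cell(0)
        ring = cell.ring
        # stretch one segment artificially by pushing a node outward
        seg = np.roll(ring, -1, axis=0) - ring
        perim0 = np.sum(np.hypot(seg[:, 0], seg[:, 1]))
        rest = ts.current_rest_length(0)
        ring[0] = ring[0] + 3.0 * rest * (ring[0] / np.hypot(*ring[0]))
        seg = np.roll(ring, -1, axis=0) - ring
        perim_stretched = np.sum(np.hypot(seg[:, 0], seg[:, 1]))
        n0 = cell.n_membrane
        added = cc.insert_membrane_node(cell)
        assert added >= 1
        assert cell.n_membrane == n0 + added
        ring2 = cell.ring
        seg2 = np.roll(ring2, -1, axis=0) - ring2
        perim_after = np.sum(np.hypot(seg2[:, 0], seg2[:, 1]))
        assert perim_after == pytest.approx(perim_stretched, rel=1e-12)
        assert perim_after > perim0


class TestLongAxisAndMitosisEntry:
    def test_ellipse_long_axis_matches_eigen_oracle(self):
        th = np.linspace(0, 2 * math.pi, 60, endpoint=False)
        pts = np.stack([2.0 * np.cos(th), 1.0 * np.sin(th)], axis=1)
        rot = math.radians(30)
        R = np.array([[math.cos(rot), -math.sin(rot)], [math.sin(rot), math.cos(rot)]])
        pts = pts @ R.T
        v = long_axis(pts)
        # independent oracle: eigen-decomposition of the covariance
        cov = np.cov(pts.T, bias=True)
        evals, evecs = np.linalg.eigh(cov)
        want = evecs[:, np.argmax(evals)]
        assert abs(abs(v @ want) - 1.0) < 1e-9

    def test_circular_ring_tie_break_is_x_axis(self):
        th = np.linspace(0, 2 * math.pi, 64, endpoint=False)
        pts = np.stack([np.cos(th), np.sin(th)], axis=1)
        np.testing.assert_allclose(long_axis(pts), [1.0, 0.0], atol=1e-6)

    def test_axis_frozen_at_entry(self, full_cfg):
        ts = initialize_tissue(1, full_cfg, seed=10)
        cell = ts.cell(0)
        ts.cell_cp[0] = 0.95
        enter_mitosis(cell, t=0.0, cfg=GrowthConfig(), cp_mit=0.95)
        axis0 = cell.division_axis.copy()
        # deform the ring afterwards; the stored axis must not move
        ts.pos[: cell.n_membrane, 1] *= 3.0
        np.testing.assert_array_equal(cell.division_axis, axis0)

    def test_double_entry_rejected(self, full_cfg):
        ts = initialize_tissue(1, full_cfg, seed=11)
        cell = ts.cell(0)
        ts.cell_cp[0] = 0.95
        enter_mitosis(cell, 0.0, GrowthConfig(), cp_mit=0.95)
        with pytest.raises(ValueError):
            enter_mitosis(cell, 0.0, GrowthConfig(), cp_mit=0.95)


class TestDivideCell:
    @pytest.fixture
    def mitotic_cell(self, full_cfg):
        ts = initialize_tissue(1, full_cfg, seed=12)
        cell = ts.cell(0)
        while cell.n_internal < ts.n_internal_max:
            cc.insert_internal_node(cell)
        ts.cell_cp[0] = 1.0
        enter_mitosis(cell, 0.0, GrowthConfig(), cp_mit=0.95)
        return cell

    def test_partition_conserves_internal_nodes_and_area(self, mitotic_cell):
        ts = mitotic_cell.tissue
        ni = mitotic_cell.n_internal
        area = polygon_area(mitotic_cell.ring)
        da, db, _ = divide_cell(mitotic_cell)
        assert da.n_internal + db.n_internal == ni
        a_sum = polygon_area(da.ring) + polygon_area(db.ring)
        assert a_sum == pytest.approx(area, rel=0.05)

    def test_daughters_reset_to_interphase(self, mitotic_cell):
        da, db, _ = divide_cell(mitotic_cell)
        for d in (da, db):
            assert d.CP == 0.0
            assert d.phase == "interphase"
            assert d.division_axis is None
            assert 2.0e-3 <= d.g0 <= 4.0e-3

    def test_cleavage_perpendicular_to_stored_axis(self, mitotic_cell):
        axis = mitotic_cell.division_axis.copy()
        centroid = mitotic_cell.centroid()
        da, db, _ = divide_cell(mitotic_cell)
        # the daughters' centroids separate along the stored long axis
        sep = da.centroid() - db.centroid()
        sep /= np.hypot(*sep)
        cross = abs(sep[0] * axis[1] - sep[1] * axis[0])
        assert cross < 0.2  # separation direction aligned with long axis
        # every new cleavage-line node of daughter A lies on the +axis side
        side_a = (da.ring - centroid) @ axis
        side_b = (db.ring - centroid) @ axis
        assert np.all(side_a > -1e-9)
        assert np.all(side_b < 1e-9)

    def test_only_mitotic_cells_divide(self, full_cfg):
        ts = initialize_tissue(1, full_cfg, seed=14)
        with pytest.raises(ValueError):
            divide_cell(ts.cell(0))
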