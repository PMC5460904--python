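"""Integrator and neighbor-search tests, including the all-pairs force
oracle."""

import numpy as np
import pytest

from episem import dynamics as dyn
from episem import mechanics as mech
from episem.dynamics import IntegratorConfig, euler_step, neighbor_candidates, net_forces
from episem.io import SimConfig
from episem.mechanics import AdhesionParams, CortexParams, MorseParams, params_from_vector
from episem.tissue import initialize_tissue


class TestNeighborCandidates:
    def test_close_pair_present_far_pair_absent(self):
        pos = np.array([[0.0, 0.0], [0.5, 0.0], [10.0, 10.0]])
        pairs = {tuple(p) for p in neighbor_candidates(pos, 1.0)}
        assert (0, 1) in pairs
        assert (0, 2) not in pairs and (1, 2) not in pairs

    def test_superset_of_brute_force_and_distance_bound(self):
        rng = np.random.default_rng(42)
        pos = rng.uniform(0, 10, (200, 2))
        cutoff = 0.9
        pairs = {tuple(p) for p in neighbor_candidates(pos, cutoff)}
        d = np.hypot(pos[:, None, 0] - pos[None, :, 0], pos[:, None, 1] - pos[None, :, 1])
        want = {(i, j) for i in range(200) for j in range(i + 1, 200) if d[i, j] <= cutoff}
        assert want <= pairs
        for i, j in pairs:
            assert d[i, j] <= cutoff * np.sqrt(8) + 1e-12

    def test_rejects_bad_cutoff(self):
        with pytest.raises(ValueError):
            neighbor_candidates(np.zeros((3, 2)), 0.0)


def _morse(prm, prefix, repulsive_only=False):
    return MorseParams(U=prm[f"{prefix}_U"], W=prm[f"{prefix}_W"],
                       xi=prm[f"{prefix}_xi"], gamma=max(prm[f"{prefix}_gamma"], 1e-9),
                       L=prm[f"{prefix}_L"], repulsive_only=repulsive_only)


def oracle_forces(ts):
    """Naive O(N^2) evaluation composed from the pure potential functions
    (cytoplasm-membrane and cross-cell exclusion act on membrane segments,
    enumerated here exhaustively)."""
    P = ts.resolve_params()
    n = ts.n_nodes
    forces = np.zeros((n, 2))
    pos = ts.pos
    mem_idx = ts.membrane_indices()
    L_max = max(params_from_vector(P[c])["adh_L_max"] for c in range(ts.n_cells))
    local = mech.pair_membranes(pos[mem_idx], ts.node_cell[mem_idx], L_max)
    partner = np.full(n, -1, dtype=int)
    ok = local >= 0
    partner[mem_idx[ok]] = mem_idx[local[ok]]

    def segments(c):
        s, nm = int(ts.cell_start[c]), int(ts.cell_nm[c])
        return [(s + a, s + (a + 1) % nm) for a in range(nm)]

    for c in range(ts.n_cells):
        prm = params_from_vector(P[c])
        s, nm, ni = int(ts.cell_start[c]), int(ts.cell_nm[c]), int(ts.cell_ni[c])
        ring = pos[s: s + nm]
        forces[s: s + nm] += mech.cortex_forces(
            ring, CortexParams(prm["k_stiff"], prm["L_stiff"], prm["k_tor"]))
        internal = range(s + nm, s + nm + ni)
        for a in internal:
            for b in internal:
                if b <= a:
                    continue
                f = mech.morse_force(pos[a], pos[b], _morse(prm, "ii"))
                forces[a] += f
                forces[b] -= f
        for a in internal:
            for (u, v) in segments(c):
                fp, fu, fv = mech.morse_segment_force(pos[a], pos[u], pos[v],
                                                      _morse(prm, "mi"))
                forces[a] += fp
                forces[u] += fu
                forces[v] += fv

    for i in mem_idx:
        ci = ts.node_cell[i]
        pi = params_from_vector(P[ci])
        for cj in range(ts.n_cells):
            if cj == ci:
                continue
            pj = params_from_vector(P[cj])
            mmd = MorseParams(
                U=0.5 * (pi["mmd_U"] + pj["mmd_U"]), W=0.5 * (pi["mmd_W"] + pj["mmd_W"]),
                xi=0.5 * (pi["mmd_xi"] + pj["mmd_xi"]),
                gamma=0.5 * (pi["mmd_gamma"] + pj["mmd_gamma"]),
                L=0.5 * (pi["mmd_L"] + pj["mmd_L"]))
            for (u, v) in segments(cj):
                fp, fu, fv = mech.morse_segment_force(pos[i], pos[u], pos[v], mmd)
                forces[i] += fp
                forces[u] += fu
                forces[v] += fv
        j = partner[i]
        if j > i:
            cj = ts.node_cell[j]
            pj = params_from_vector(P[cj])
            d = float(np.hypot(*(pos[i] - pos[j])))
            lmin = 0.5 * (pi["adh_L_min"] + pj["adh_L_min"])
            lmax = 0.5 * (pi["adh_L_max"] + pj["adh_L_max"])
            if lmin <= d <= lmax:
                k = 0.5 * (pi["k_adh"] + pj["k_adh"])
                f = -k * (d - lmin) * (pos[i] - pos[j]) / d
                forces[i] += f
                forces[j] -= f
    return forces


class TestNetForces:
    @pytest.fixture(scope="class")
    def three_cell_tissue(self, coarse_cfg):
        from dataclasses import replace

        cfg = replace(coarse_cfg, initial_gap=0.25)
        ts = initialize_tissue(3, cfg, seed=5)
        for _ in range(2000):  # brief relax into adhesive contact
            f, _ = dyn.net_forces_and_virial(ts)
            euler_step(ts, f, cfg.integrator)
        return ts

    def test_matches_all_pairs_oracle(self, three_cell_tissue):
        got = net_forces(three_cell_tissue)
        want = oracle_forces(three_cell_tissue)
        np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-11)

    def test_total_internal_force_vanishes(self, three_cell_tissue):
        f = net_forces(three_cell_tissue)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-9)

    def test_fused_step_equals_forces_plus_euler(self, coarse_cfg):
        ts_a = initialize_tissue(3, coarse_cfg, seed=9)
        ts_b = initialize_tissue(3, coarse_cfg, seed=9)
        icfg = coarse_cfg.integrator
        for _ in range(50):
            dyn.step_tissue(ts_a, ts_a.resolve_params(), icfg)
            f, _ = dyn.net_forces_and_virial(ts_b)
            euler_step(ts_b, f, icfg)
        np.testing.assert_array_equal(ts_a.pos, ts_b.pos)

    def test_equilibrium_cell_has_negligible_forces(self, relaxed_single_cell):
        f = net_forces(relaxed_single_cell)
        assert np.max(np.hypot(f[:, 0], f[:, 1])) < 0.05


class TestEulerStep:
    def _free_node_tissue(self, cfg):
        ts = initialize_tissue(1, cfg, seed=0)
        return ts

    def test_closed_form_displacement(self, full_cfg):
        ts = self._free_node_tissue(full_cfg)
        forces = np.zeros((ts.n_nodes, 2))
        forces[0] = [3.6, -7.2]
        before = ts.pos[0].copy()
        icfg = IntegratorConfig(eta=36.0, dt=0.003)
        euler_step(ts, forces, icfg)
        np.testing.assert_allclose(ts.pos[0] - before,
                                   np.array([3.6, -7.2]) * 0.003 / 36.0, rtol=1e-12)

    def test_zero_force_leaves_positions_unchanged(self, full_cfg):
        ts = self._free_node_tissue(full_cfg)
        before = ts.pos.copy()
        euler_step(ts, np.zeros_like(before), full_cfg.integrator)
        np.testing.assert_array_equal(ts.pos, before)

    def test_doubling_damping_halves_displacement(self, full_cfg):
        ts1 = self._free_node_tissue(full_cfg)
        ts2 = self._free_node_tissue(full_cfg)
        f = np.zeros((ts1.n_nodes, 2))
        f[:, 0] = 1.0
        p0 = ts1.pos.copy()
        euler_step(ts1, f, IntegratorConfig(eta=36.0, dt=0.003))
        euler_step(ts2, f, IntegratorConfig(eta=72.0, dt=0.003))
        # up to one ulp of the absolute coordinate from the position update
        np.testing.assert_allclose(ts2.pos - p0, (ts1.pos - p0) / 2.0, atol=1e-15)

    def test_halved_step_converges_to_first_order(self, full_cfg):
        # relaxing two-node system: one dt step vs two dt/2 steps differ at
        # O(dt^2), a small fraction of the O(dt) displacement itself
        p = mech.MorseParams(U=0.49, W=0.15, xi=0.31, gamma=1.25, L=1.56)
        x0 = np.array([[0.0, 0.0], [0.8, 0.0]])
        eta, dt = 36.0, 0.05

        def force(x):
            f = mech.morse_force(x[0], x[1], p)
            return np.array([f, -f])

        x_full = x0 + force(x0) * dt / eta
        x_half = x0 + force(x0) * (dt / 2) / eta
        x_half = x_half + force(x_half) * (dt / 2) / eta
        disp = np.abs(x_full - x0).max()
        mismatch = np.abs(x_full - x_half).max()
        assert mismatch < 0.05 * disp

    def test_instability_aborts_with_diagnostic(self, full_cfg):
        ts = self._free_node_tissue(full_cfg)
        forces = np.zeros((ts.n_nodes, 2))
        forces[0] = [1e6, 0.0]
        with pytest.raises(dyn.IntegratorInstability):
            euler_step(ts, forces, full_cfg.integrator)

    def test_step_is_deterministic(self, coarse_cfg):
        ts1 = initialize_tissue(3, coarse_cfg, seed=2)
        ts2 = initialize_tissue(3, coarse_cfg, seed=2)
        for _ in range(20):
            dyn.step_tissue(ts1, ts1.resolve_params(), coarse_cfg.integrator)
            dyn.step_tissue(ts2, ts2.resolve_params(), coarse_cfg.integrator)
        np.testing.assert_array_equal(ts1.pos, ts2.pos)


def test_cluster_relaxation_force_declines(small_cluster, coarse_cfg):
    """After the initial adhesion transient a resting cluster's peak force
    keeps dropping (stability smoke test)."""
    ts = small_cluster.copy()
    f0, _ = dyn.net_forces_and_virial(ts)
    m0 = np.max(np.hypot(f0[:, 0], f0[:, 1]))
    for _ in range(3000):
        dyn.step_tissue(ts, ts.resolve_params(), coarse_cfg.integrator)
    f1, _ = dyn.net_forces_and_virial(ts)
    m1 = np.max(np.hypot(f1[:, 0], f1[:, 1]))
    assert m1 < m0
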