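"""Unit and property tests for the potential families."""

import math

import numpy as np
import pytest
from scipy.optimize import bisect

from episem import mechanics as mech
from episem.mechanics import (AdhesionParams, CortexParams, MorseParams,
                              adhesion_energy, adhesion_force, cortex_energy,
                              cortex_forces, morse_energy, morse_force,
                              morse_radial_force, pair_membranes,
                              phase_interpolate)

II_INTER = MorseParams(U=0.49, W=0.15, xi=0.31, gamma=1.25, L=1.56)


class TestMorse:
    def test_known_value_interphase_cytoplasm(self):
        # scalar hand evaluation: 0.49 e^{-1/0.31} - 0.15 e^{-1/1.25}
        assert morse_energy(1.0, II_INTER) == pytest.approx(-0.0479, abs=5e-5)

    def test_zero_beyond_cutoff(self):
        assert morse_energy(II_INTER.L + 1e-9, II_INTER) == 0.0
        assert morse_radial_force(II_INTER.L + 1e-9, II_INTER) == 0.0

    def test_pure_repulsion_when_no_attractive_term(self):
        p = MorseParams(U=0.78, W=0.0, xi=0.13, gamma=1.0, L=1.56)
        r = np.linspace(0.05, p.L, 200)
        e = morse_energy(r, p)
        assert np.all(e > 0)
        assert np.all(np.diff(e) < 0)  # monotone decreasing

    def test_negative_separation_rejected(self):
        with pytest.raises(ValueError):
            morse_energy(-0.1, II_INTER)
        with pytest.raises(ValueError):
            morse_radial_force(-0.1, II_INTER)

    def test_zero_force_separation_matches_bisection_oracle(self):
        # independent root-find of dE/dr on the analytic energy
        def dEdr(r):
            return (-II_INTER.U / II_INTER.xi * math.exp(-r / II_INTER.xi)
                    + II_INTER.W / II_INTER.gamma * math.exp(-r / II_INTER.gamma))

        r_star = bisect(dEdr, 0.5, 1.5, xtol=1e-12)
        assert r_star == pytest.approx(1.063, abs=1e-3)
        assert morse_radial_force(r_star, II_INTER) == pytest.approx(0.0, abs=1e-12)
        assert II_INTER.zero_force_separation() == pytest.approx(r_star, abs=1e-10)

    def test_repulsive_below_equilibrium_and_antisymmetric(self):
        x_j = np.array([0.0, 0.0])
        for r in (0.3, 0.8, 1.02):
            x_i = np.array([r, 0.0])
            f_i = morse_force(x_i, x_j, II_INTER)
            f_j = morse_force(x_j, x_i, II_INTER)
            np.testing.assert_allclose(f_i, -f_j, atol=1e-15)
            assert f_i[0] > 0  # points away from j: repulsive

    def test_force_is_negative_gradient_of_energy(self):
        rng = np.random.default_rng(0)
        h = 1e-7
        for p in (II_INTER,
                  MorseParams(U=0.78, W=0.0, xi=0.13, gamma=1.0, L=1.56),
                  MorseParams(U=3.9, W=3.9, xi=0.13, gamma=1.6, L=0.78, repulsive_only=True)):
            cut = min(p.L, p.zero_force_separation())
            for r in rng.uniform(0.05, 0.95 * cut, 30):
                num = -(morse_energy(r + h, p) - morse_energy(r - h, p)) / (2 * h)
                assert morse_radial_force(r, p) == pytest.approx(num, rel=1e-6, abs=1e-9)

    def test_repulsive_only_family_never_attracts_and_energy_continuous(self):
        p = MorseParams(U=3.9, W=3.9, xi=0.13, gamma=1.6, L=0.78, repulsive_only=True)
        r = np.linspace(0.01, 1.0, 500)
        assert np.all(morse_radial_force(r, p) >= 0.0)
        r0 = p.zero_force_separation()
        assert morse_energy(r0 - 1e-9, p) == pytest.approx(0.0, abs=1e-7)

    def test_coincident_node_force_capped(self):
        cap = morse_radial_force(mech.MORSE_CAP_FRACTION * II_INTER.xi, II_INTER)
        assert morse_radial_force(0.0, II_INTER) == pytest.approx(cap)
        f = morse_force(np.zeros(2), np.zeros(2), II_INTER)
        assert np.hypot(*f) == pytest.approx(abs(cap))


class TestSegmentMorse:
    MI = MorseParams(U=0.78, W=0.0, xi=0.13, gamma=1.0, L=1.56)

    def test_force_is_negative_gradient_of_segment_energy(self):
        rng = np.random.default_rng(8)
        h = 1e-7
        for _ in range(20):
            a = rng.uniform(-1, 1, 2)
            b = a + rng.uniform(0.2, 0.8) * np.array(
                [math.cos(x := rng.uniform(0, 2 * math.pi)), math.sin(x)])
            p = rng.uniform(-1, 1, 2)
            d, _, _ = mech.point_segment_distance(p, a, b)
            if d < 0.05 or d > 0.9 * self.MI.L:
                continue
            f_p, f_a, f_b = mech.morse_segment_force(p, a, b, self.MI)
            for k in range(2):
                pp = p.copy()
                pp[k] += h
                ep = mech.morse_segment_energy(pp, a, b, self.MI)
                pp[k] -= 2 * h
                em = mech.morse_segment_energy(pp, a, b, self.MI)
                assert f_p[k] == pytest.approx(-(ep - em) / (2 * h), rel=1e-5, abs=1e-8)

    def test_reaction_balances_force_and_torque(self):
        p = np.array([0.3, 0.4])
        a = np.array([0.0, 0.0])
        b = np.array([1.0, 0.0])
        f_p, f_a, f_b = mech.morse_segment_force(p, a, b, self.MI)
        np.testing.assert_allclose(f_p + f_a + f_b, 0.0, atol=1e-14)
        torque = (np.cross(p, f_p) + np.cross(a, f_a) + np.cross(b, f_b))
        assert torque == pytest.approx(0.0, abs=1e-14)
        # closest point interior: reaction split by the lever rule
        assert f_a[1] != 0.0 and f_b[1] != 0.0

    def test_endpoint_projection_reduces_to_node_pair(self):
        p = np.array([-0.3, 0.2])  # beyond endpoint a
        a = np.array([0.0, 0.0])
        b = np.array([1.0, 0.0])
        f_p, f_a, f_b = mech.morse_segment_force(p, a, b, self.MI)
        np.testing.assert_allclose(f_p, mech.morse_force(p, a, self.MI), atol=1e-14)
        np.testing.assert_allclose(f_b, 0.0, atol=1e-14)

    def test_zero_beyond_cutoff(self):
        f_p, f_a, f_b = mech.morse_segment_force(
            np.array([0.0, 2.0]), np.array([-1.0, 0.0]), np.array([1.0, 0.0]), self.MI)
        assert not f_p.any() and not f_a.any() and not f_b.any()


class TestCortex:
    P = CortexParams(k_stiff=200.0, L_stiff=0.060, k_tor=6.0)

    @staticmethod
    def _regular_ring(n, radius=1.0):
        th = 2 * math.pi * np.arange(n) / n
        return radius * np.stack([np.cos(th), np.sin(th)], axis=1)

    def test_rest_configuration_is_force_free(self):
        n = 40
        # radius such that every segment is exactly at rest length
        radius = self.P.L_stiff / (2 * math.sin(math.pi / n))
        ring = self._regular_ring(n, radius)
        np.testing.assert_allclose(cortex_forces(ring, self.P), 0.0, atol=1e-10)

    def test_stretched_segment_pulls_with_k_delta(self):
        # isolate the linear springs with a negligible torsion constant
        p = CortexParams(k_stiff=200.0, L_stiff=0.060, k_tor=1e-15)
        n = 6
        radius = p.L_stiff / (2 * math.sin(math.pi / n))
        ring = self._regular_ring(n, radius)
        stretched = ring.copy()
        # displace node 0 radially so each adjacent segment stretches
        stretched[0] *= (radius + 0.01) / radius
        f = cortex_forces(stretched, p)
        expected = np.zeros(2)
        for nb in (1, n - 1):
            d = stretched[nb] - stretched[0]
            ell = np.linalg.norm(d)
            expected += p.k_stiff * (ell - p.L_stiff) * d / ell
        np.testing.assert_allclose(f[0], expected, atol=1e-9)
        # a segment stretched by 0.01 um at 200 nN/um pulls with 2 nN
        assert p.k_stiff * 0.01 == pytest.approx(2.0)

    def test_internal_forces_sum_and_torque_to_zero(self):
        rng = np.random.default_rng(3)
        ring = self._regular_ring(25, 0.3) + rng.normal(0, 0.03, (25, 2))
        f = cortex_forces(ring, self.P)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-10)
        torque = np.sum(ring[:, 0] * f[:, 1] - ring[:, 1] * f[:, 0])
        assert torque == pytest.approx(0.0, abs=1e-9)

    def test_force_is_negative_gradient(self):
        rng = np.random.default_rng(5)
        ring = self._regular_ring(12, 0.25) + rng.normal(0, 0.02, (12, 2))
        f = cortex_forces(ring, self.P)
        h = 1e-7
        for (i, k) in [(0, 0), (3, 1), (7, 0), (11, 1)]:
            perturbed = ring.copy()
            perturbed[i, k] += h
            e_plus = cortex_energy(perturbed, self.P)
            perturbed[i, k] -= 2 * h
            e_minus = cortex_energy(perturbed, self.P)
            num = -(e_plus - e_minus) / (2 * h)
            assert f[i, k] == pytest.approx(num, rel=1e-5, abs=1e-7)

    def test_degenerate_segment_rejected(self):
        ring = np.array([[0.0, 0.0], [0.0, 0.0], [0.1, 0.1]])
        with pytest.raises(ValueError):
            cortex_forces(ring, self.P)


class TestAdhesion:
    P = AdhesionParams(k_adh=20.0, L_min=0.062, L_max=0.40)

    def test_rest_length_and_cutoffs(self):
        assert adhesion_force(self.P.L_min, self.P) == 0.0
        assert adhesion_force(self.P.L_max + 1e-9, self.P) == 0.0  # detached
        assert adhesion_force(0.03, self.P) == 0.0  # below L_min: MMD's job

    def test_engaged_bond_value(self):
        # k (d - L_min) at the engagement cutoff: 20 * (0.40 - 0.062)
        assert adhesion_force(0.40, self.P) == pytest.approx(6.76)

    def test_force_is_negative_gradient(self):
        # sign convention: positive = attractive (pulling d down), so the
        # scalar force equals +dE/dd
        h = 1e-7
        for d in (0.1, 0.2, 0.35):
            num = (adhesion_energy(d + h, self.P) - adhesion_energy(d - h, self.P)) / (2 * h)
            assert adhesion_force(d, self.P) == pytest.approx(num, rel=1e-6)


def brute_force_pairing(pos, cell_of, L_max):
    """Independent all-pairs reimplementation of the pairing policy."""
    n = len(pos)
    cands = []
    for i in range(n):
        best, bd = -1, np.inf
        for j in range(n):
            if j == i or cell_of[j] == cell_of[i]:
                continue
            d = float(np.hypot(*(pos[i] - pos[j])))
            if d <= L_max and d < bd:
                best, bd = j, d
        if best >= 0:
            cands.append((bd, i, best))
    partner = np.full(n, -1, dtype=int)
    for d, i, j in sorted(cands):
        if partner[i] < 0 and partner[j] < 0:
            partner[i], partner[j] = j, i
    return partner


class TestAdhesionPairing:
    def test_far_cells_make_no_pairs(self):
        pos = np.array([[0.0, 0.0], [0.1, 0.0], [5.0, 0.0], [5.1, 0.0]])
        cell = np.array([0, 0, 1, 1])
        assert np.all(pair_membranes(pos, cell, 0.4) == -1)

    def test_parallel_membranes_pair_one_to_one(self):
        n = 8
        top = np.stack([np.arange(n) * 0.1, np.full(n, 0.15)], axis=1)
        bot = np.stack([np.arange(n) * 0.1, np.zeros(n)], axis=1)
        pos = np.vstack([top, bot])
        cell = np.array([0] * n + [1] * n)
        partner = pair_membranes(pos, cell, 0.4)
        np.testing.assert_array_equal(partner[:n], np.arange(n) + n)
        np.testing.assert_array_equal(partner[n:], np.arange(n))

    def test_never_pairs_within_a_cell_and_symmetric(self):
        rng = np.random.default_rng(11)
        pos = rng.uniform(0, 2, (60, 2))
        cell = rng.integers(0, 4, 60)
        partner = pair_membranes(pos, cell, 0.4)
        for i, j in enumerate(partner):
            if j >= 0:
                assert cell[i] != cell[j]
                assert partner[j] == i

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 1.5, (50, 2))
        cell = rng.integers(0, 4, 50)
        expected = brute_force_pairing(pos, cell, 0.4)
        np.testing.assert_array_equal(pair_membranes(pos, cell, 0.4), expected)


class TestPhaseInterpolate:
    def test_boundaries_and_midpoint(self):
        assert phase_interpolate(2.0, 10.0, 0.9, 0.9) == pytest.approx(2.0)
        assert phase_interpolate(2.0, 10.0, 1.0, 0.9) == pytest.approx(10.0)
        assert phase_interpolate(2.0, 10.0, 0.95, 0.9) == pytest.approx(6.0)

    def test_out_of_range_progress_rejected(self):
        with pytest.raises(ValueError):
            phase_interpolate(1.0, 2.0, 0.5, 0.9)
        with pytest.raises(ValueError):
            phase_interpolate(1.0, 2.0, 1.2, 0.9)

    def test_invariant_parameter_stays_constant(self):
        for cp in (0.9, 0.93, 0.99, 1.0):
            assert phase_interpolate(3.9, 3.9, cp, 0.9) == pytest.approx(3.9)


class TestParamValidation:
    def test_morse_invariants(self):
        with pytest.raises(ValueError):
            MorseParams(U=-1, W=0, xi=0.1, gamma=1, L=1)
        with pytest.raises(ValueError):
            MorseParams(U=1, W=0, xi=0, gamma=1, L=1)

    def test_adhesion_window_ordering(self):
        with pytest.raises(ValueError):
            AdhesionParams(k_adh=1.0, L_min=0.5, L_max=0.4)

    def test_cortex_positivity(self):
        with pytest.raises(ValueError):
            CortexParams(k_stiff=0.0, L_stiff=0.06, k_tor=6.0)
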