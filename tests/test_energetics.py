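"""Energetics oracles: HB counting, cooperativity, vdW, volume, enthalpy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydropore.energetics import (
    ModelParams,
    ThermoState,
    VolumeState,
    count_cooperative,
    count_hbonds,
    count_shell_hbonds,
    enthalpy,
    full_breakdown,
    hb_permitted,
    pair_potential,
    sigma_move_enthalpy_delta,
    total_volume,
    vdw_energy,
)
from hydropore.lattice import (
    WATER,
    GridSpec,
    empty_occupancy,
    hydration_shell,
    minimum_image_distance,
    water_pair_distance_counts,
)


class TestModelParams:
    def test_standard_defaults(self, params):
        assert params.J_rel == 0.3
        assert params.Jsigma_rel == 0.05
        assert params.vHB_rel == 0.5
        assert params.dJphi_rel == 0.83
        assert params.q == 6
        assert params.eps_rel == 0.25
        assert params.dJphi_abs == pytest.approx(0.249)

    def test_validation(self):
        with pytest.raises(ValueError):
            ModelParams(J_rel=-0.1)
        with pytest.raises(ValueError):
            ModelParams(q=1)
        with pytest.raises(ValueError):
            ModelParams(cutoff_rel=0.5)


class TestVolumeState:
    def test_hard_core(self):
        with pytest.raises(ValueError):
            VolumeState(0.99)

    def test_hb_switch(self):
        assert hb_permitted(VolumeState(1.0)) == 1
        assert hb_permitted(VolumeState(1.999)) == 1
        assert hb_permitted(VolumeState(2.0)) == 0  # boundary is non-bonding
        assert hb_permitted(VolumeState(2.5)) == 0

    def test_spacing(self):
        assert VolumeState(8.0).l_rel == pytest.approx(2.0)

    def test_thermo_validation(self):
        with pytest.raises(ValueError):
            ThermoState(T_star=0.0)


class TestHBCounting:
    def _uniform_system(self, L=10):
        spec = GridSpec(L=L, wall_row=None)
        occ = empty_occupancy(spec)
        sigma = np.zeros((L, L, 4), dtype=np.int8)
        return spec, occ, sigma

    def test_all_matched_torus(self):
        spec, occ, sigma = self._uniform_system(10)
        # every NN pair bonds: 2 L^2 pairs
        assert count_hbonds(sigma, occ, VolumeState(1.0)) == 200

    def test_volume_switch_kills_bonds(self):
        spec, occ, sigma = self._uniform_system(10)
        assert count_hbonds(sigma, occ, VolumeState(2.0)) == 0
        assert count_shell_hbonds(
            sigma, np.ones((10, 10), dtype=bool), occ, VolumeState(2.0)
        ) == 0

    def test_single_mismatch(self):
        spec, occ, sigma = self._uniform_system(10)
        sigma[3, 3, 0] = 1  # break the bond on the +x face of (3,3) only
        assert count_hbonds(sigma, occ, VolumeState(1.0)) == 199

    def test_shell_subset(self):
        occ = empty_occupancy(GridSpec(L=10))  # wall at row 0
        sigma = np.zeros((10, 10, 4), dtype=np.int8)
        shell = hydration_shell(occ)
        vol = VolumeState(1.0)
        n_phi = count_shell_hbonds(sigma, shell, occ, vol)
        assert 0 < n_phi <= count_hbonds(sigma, occ, vol)
        # shell rows are y=1 and y=9; shell-shell bonds are the 10 horizontal
        # bonds within each row
        assert n_phi == 20

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_relabelling_invariance(self, seed):
        """Counts depend only on index coincidences, not on index values."""
        rng = np.random.default_rng(seed)
        L = 8
        occ = empty_occupancy(GridSpec(L=L))
        sigma = rng.integers(0, 6, size=(L, L, 4)).astype(np.int8)
        perm = rng.permutation(6).astype(np.int8)
        relabeled = perm[sigma]
        shell = hydration_shell(occ)
        vol = VolumeState(1.2)
        assert count_hbonds(sigma, occ, vol) == count_hbonds(relabeled, occ, vol)
        assert count_shell_hbonds(sigma, shell, occ, vol) == count_shell_hbonds(
            relabeled, shell, occ, vol
        )
        assert count_cooperative(sigma, occ) == count_cooperative(relabeled, occ)


class TestCooperative:
    def test_one_pair_per_cell(self):
        occ = np.full((8, 8), WATER, dtype=np.int8)
        sigma = np.tile(np.array([0, 0, 1, 2], dtype=np.int8), (8, 8, 1))
        assert count_cooperative(sigma, occ) == 64

    def test_all_equal_six_pairs(self):
        occ = np.full((8, 8), WATER, dtype=np.int8)
        sigma = np.zeros((8, 8, 4), dtype=np.int8)
        assert count_cooperative(sigma, occ) == 6 * 64

    def test_standard_box_all_equal(self):
        occ = np.full((40, 40), WATER, dtype=np.int8)
        sigma = np.zeros((40, 40, 4), dtype=np.int8)
        assert count_cooperative(sigma, occ) == 9600


class TestPairPotential:
    def test_zero_at_hard_core_contact(self, params):
        assert pair_potential(1.0, params) == 0.0

    def test_minimum_is_minus_eps(self, params):
        r_min = 2.0 ** (1.0 / 6.0)
        assert pair_potential(r_min, params) == pytest.approx(-0.25)  # -eps in 4 eps units

    def test_zero_beyond_cutoff(self, params):
        assert pair_potential(6.0, params) == 0.0
        assert pair_potential(7.0, params) == 0.0

    def test_hard_core_raises(self, params):
        with pytest.raises(ValueError, match="hard-core"):
            pair_potential(0.9, params)

    def test_vdw_table_matches_brute_force(self, params, rng):
        spec = GridSpec(L=12, wall_row=None)
        occ = empty_occupancy(spec)
        # carve some random non-water cells
        for _ in range(20):
            occ[rng.integers(12), rng.integers(12)] = 2
        pc = water_pair_distance_counts(occ, spec)
        vol = VolumeState(1.37)
        fast = vdw_energy(pc, vol, params)
        xs, ys = np.nonzero(occ == WATER)
        brute = 0.0
        for i in range(len(xs)):
            for j in range(i + 1, len(xs)):
                r = minimum_image_distance((xs[i], ys[i]), (xs[j], ys[j]), spec)
                if r <= 6.0:
                    brute += pair_potential(vol.l_rel * r, params)
        assert fast == pytest.approx(brute, abs=1e-12)


class TestVolumeAndEnthalpy:
    def test_total_volume_examples(self, params):
        th = ThermoState(0.3, 0.1)
        assert total_volume(1600, VolumeState(1.0), 100, 0, th, params) == 1650.0
        th2 = ThermoState(0.3, 0.2)
        assert total_volume(1600, VolumeState(1.0), 100, 100, th2, params) == 1640.0

    def test_enthalpy_hb_only(self, params):
        th = ThermoState(0.3, 0.0)
        assert enthalpy(0.0, 10, 0, 0, 0.0, th, params) == pytest.approx(-3.0)

    def test_sigma_move_deltas(self, params):
        th0 = ThermoState(0.3, 0.0)
        assert sigma_move_enthalpy_delta(1, 0, 0, th0, params) == pytest.approx(-0.3)
        assert sigma_move_enthalpy_delta(1, 1, 0, th0, params) == pytest.approx(-0.549)
        # at P* = 0.6 the PV work of the added HB volume cancels J exactly
        th6 = ThermoState(0.3, 0.6)
        assert sigma_move_enthalpy_delta(1, 0, 0, th6, params) == pytest.approx(0.0)

    def test_full_breakdown_consistent_fields(self, params, rng):
        spec = GridSpec(L=10)
        occ = empty_occupancy(spec)
        sigma = rng.integers(0, 6, size=(10, 10, 4)).astype(np.int8)
        shell = hydration_shell(occ).astype(np.uint8)
        pc = water_pair_distance_counts(occ, spec)
        th = ThermoState(0.3, 0.1)
        vol = VolumeState(1.1)
        b = full_breakdown(occ, sigma, shell, pc, vol, th, params)
        assert b.N_HB == count_hbonds(sigma, occ, vol)
        assert b.V_tot == total_volume(100, vol, b.N_HB, b.N_HB_phi, th, params)
        assert b.H == pytest.approx(
            enthalpy(b.U_vdw, b.N_HB, b.N_HB_phi, b.N_sigma, b.V_tot, th, params)
        )
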