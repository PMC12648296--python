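import numpy as np
import pytest

from excitonscope.ctstates import (
    CTAssignment,
    ExcitedStateRecord,
    FragmentPartition,
    NTOComponent,
    classify_state,
    ct_direction_series,
    ct_summary,
    density_difference,
    density_difference_from_orbitals,
    fragment_charges,
    homo_lumo_overlap,
)
from excitonscope.cube import DensityGrid, read_cube, write_cube
from excitonscope.synthetic import GeneratorConfig, make_density_pair
from excitonscope.tables import rc_pair_states


def _rec(weight, f, hole, particle, energy=2.0, snap="s0", idx=None):
    return ExcitedStateRecord(snap, energy, f, [NTOComponent(weight, hole, particle)],
                              state_index=idx)


class TestClassifyState:
    def test_dark_interfragment_state_is_pure_ct(self):
        rec = _rec(1.0, 0.00, "P_L", "B_L")
        assert classify_state(rec) == "pure_CT"
        assert rec.ct_direction == "P_L->B_L"

    def test_bright_delocalized_state_is_me(self):
        rec = _rec(0.93, 0.59, "P_M/P_L", "P_M/P_L")
        assert classify_state(rec) == "ME"

    def test_same_fragment_state_is_le(self):
        assert classify_state(_rec(1.0, 0.00, "A", "A")) == "LE"

    def test_bright_interfragment_state_is_mixed(self):
        assert classify_state(_rec(0.95, 0.30, "A", "B")) == "mixed"

    def test_boundary_values_included_in_pure_ct(self):
        assert classify_state(_rec(0.94, 0.01, "A", "B")) == "pure_CT"

    def test_two_local_components_on_different_pigments_stay_le(self):
        rec = ExcitedStateRecord(
            "s", 1.992, 0.15,
            [NTOComponent(0.56, "P_M", "P_M"), NTOComponent(0.28, "B_M", "B_M")],
        )
        assert classify_state(rec) == "LE"

    def test_empty_nto_list_rejected(self):
        rec = ExcitedStateRecord("s", 2.0, 0.0, [])
        with pytest.raises(ValueError, match="no NTO"):
            classify_state(rec)

    def test_classification_total_and_deterministic(self):
        from excitonscope.synthetic import make_state_table

        table = make_state_table(GeneratorConfig(seed=3), n_records=100)
        for rec, _ in table:
            first = classify_state(rec)
            assert first in {"pure_CT", "mixed", "ME", "LE"}
            assert classify_state(rec) == first


class TestDensityGrids:
    def test_identical_grids_zero_difference(self, gen_cfg):
        rg, _, _, _ = make_density_pair(gen_cfg, "LE")
        delta = density_difference(rg, rg)
        np.testing.assert_array_equal(delta.values, 0.0)

    def test_geometry_mismatch_rejected(self, gen_cfg):
        rg, _, _, _ = make_density_pair(gen_cfg, "LE")
        shifted = DensityGrid(rg.origin + 1.0, rg.axes, rg.values,
                              rg.atom_numbers, rg.atom_coords)
        with pytest.raises(ValueError, match="differ"):
            density_difference(rg, shifted)

    def test_difference_linearity(self, gen_cfg):
        rg, re_, _, _ = make_density_pair(gen_cfg, "pure_CT")
        d1 = density_difference(re_, rg)
        scaled = density_difference(
            DensityGrid(re_.origin, re_.axes, 3.0 * re_.values, re_.atom_numbers, re_.atom_coords),
            DensityGrid(rg.origin, rg.axes, 3.0 * rg.values, rg.atom_numbers, rg.atom_coords),
        )
        np.testing.assert_allclose(scaled.values, 3.0 * d1.values, rtol=1e-12)

    def test_charge_conservation_of_transfer_pair(self, gen_cfg):
        rg, re_, _, _ = make_density_pair(gen_cfg, "pure_CT")
        delta = density_difference(re_, rg)
        assert delta.integral() == pytest.approx(0.0, abs=1e-3)

    def test_cube_file_round_trip(self, tmp_path, rng):
        grid = DensityGrid(
            origin=np.array([-3.0, -2.5, -2.0]),
            axes=0.5 * np.eye(3),
            values=rng.normal(size=(12, 10, 8)),
            atom_numbers=(12, 6),
            atom_coords=np.array([[-1.0, 0.0, 0.0], [1.0, 0.2, -0.3]]),
        )
        path = tmp_path / "rho.cube"
        write_cube(path, grid)
        loaded = read_cube(path)
        assert loaded.shape == grid.shape
        np.testing.assert_allclose(loaded.values, grid.values, rtol=1e-5, atol=1e-6)
        np.testing.assert_allclose(loaded.atom_coords, grid.atom_coords, atol=1e-6)


class TestOrbitalDifference:
    def _orbital(self, grid_ref, center, sigma=1.5):
        centers = grid_ref.voxel_centers()
        d2 = ((centers - center) ** 2).sum(axis=1)
        psi = np.exp(-0.25 * d2 / sigma**2)
        psi /= np.sqrt((psi**2).sum() * grid_ref.voxel_volume)  # unit norm
        return DensityGrid(grid_ref.origin, grid_ref.axes,
                           psi.reshape(grid_ref.shape),
                           grid_ref.atom_numbers, grid_ref.atom_coords)

    @pytest.fixture()
    def ref_grid(self, gen_cfg):
        rg, _, _, _ = make_density_pair(gen_cfg, "LE")
        return rg

    def test_identical_orbitals_cancel(self, ref_grid):
        psi = self._orbital(ref_grid, np.array([-6.0, 0, 0]))
        delta = density_difference_from_orbitals([psi], [psi], [1.0])
        np.testing.assert_array_equal(delta.values, 0.0)

    def test_disjoint_lobes_transfer_one_electron(self, ref_grid):
        psi_i = self._orbital(ref_grid, np.array([-6.0, 0, 0]))
        psi_a = self._orbital(ref_grid, np.array([6.0, 0, 0]))
        delta = density_difference_from_orbitals([psi_i], [psi_a], [1.0])
        dq = fragment_charges(delta, FragmentPartition(("A", "B")))
        assert dq["A"] == pytest.approx(-1.0, abs=0.01)
        assert dq["B"] == pytest.approx(+1.0, abs=0.01)

    def test_pair_linearity(self, ref_grid):
        psi_i = self._orbital(ref_grid, np.array([-6.0, 0, 0]))
        psi_a = self._orbital(ref_grid, np.array([6.0, 0, 0]))
        psi_b = self._orbital(ref_grid, np.array([6.0, 0, 2.0]))
        single1 = density_difference_from_orbitals([psi_i], [psi_a], [1.0])
        single2 = density_difference_from_orbitals([psi_i], [psi_b], [1.0])
        combo = density_difference_from_orbitals(
            [psi_i, psi_i], [psi_a, psi_b], [0.5, 0.5]
        )
        np.testing.assert_allclose(
            combo.values, 0.5 * (single1.values + single2.values), atol=1e-12
        )

    def test_no_coefficients_rejected(self):
        with pytest.raises(ValueError, match="no coefficient"):
            density_difference_from_orbitals([], [], [])


class TestFragmentCharges:
    def test_zero_difference_zero_charges(self, gen_cfg):
        rg, _, part, _ = make_density_pair(gen_cfg, "LE")
        zero = density_difference(rg, rg)
        dq = fragment_charges(zero, part)
        assert all(v == 0.0 for v in dq.values())

    def test_pure_ct_recovers_unit_transfer(self, gen_cfg):
        rg, re_, part, truth = make_density_pair(gen_cfg, "pure_CT")
        dq = fragment_charges(density_difference(re_, rg), part)
        assert dq["A"] == pytest.approx(truth["A"], abs=0.02)
        assert dq["B"] == pytest.approx(truth["B"], abs=0.02)

    def test_local_excitation_moves_no_charge(self, gen_cfg):
        rg, re_, part, _ = make_density_pair(gen_cfg, "LE")
        dq = fragment_charges(density_difference(re_, rg), part)
        assert abs(dq["A"]) <= 0.05 and abs(dq["B"]) <= 0.05

    def test_fragment_sums_partition_total_integral(self, gen_cfg):
        rg, re_, part, _ = make_density_pair(gen_cfg, "ME")
        delta = density_difference(re_, rg)
        dq = fragment_charges(delta, part)
        assert sum(dq.values()) == pytest.approx(delta.integral(), abs=1e-12)

    def test_grid_without_atoms_rejected(self, gen_cfg):
        rg, re_, part, _ = make_density_pair(gen_cfg, "pure_CT")
        bare = DensityGrid(rg.origin, rg.axes, rg.values)
        with pytest.raises(ValueError, match="no atoms"):
            fragment_charges(bare, part)


class TestHomoLumoOverlap:
    def _orbital(self, ref, center, sigma=1.5):
        centers = ref.voxel_centers()
        d2 = ((centers - center) ** 2).sum(axis=1)
        psi = np.exp(-0.25 * d2 / sigma**2)
        psi /= np.sqrt((psi**2).sum() * ref.voxel_volume)
        return DensityGrid(ref.origin, ref.axes, psi.reshape(ref.shape),
                           ref.atom_numbers, ref.atom_coords)

    @pytest.fixture()
    def ref_grid(self, gen_cfg):
        rg, _, _, _ = make_density_pair(gen_cfg, "LE")
        return rg

    def test_disjoint_orbitals_have_vanishing_product(self, ref_grid):
        part = FragmentPartition(("A", "B"))
        homo = self._orbital(ref_grid, np.array([-6.0, 0, 0]))
        lumo = self._orbital(ref_grid, np.array([6.0, 0, 0]))
        pop_h, pop_l, product = homo_lumo_overlap(homo, lumo, part)
        assert pop_h["A"] == pytest.approx(1.0, abs=0.01)
        assert pop_l["B"] == pytest.approx(1.0, abs=0.01)
        assert product < 1e-3

    def test_identical_orbitals_product_is_norm(self, ref_grid):
        part = FragmentPartition(("A", "B"))
        psi = self._orbital(ref_grid, np.array([-6.0, 0, 0]))
        _, _, product = homo_lumo_overlap(psi, psi, part)
        assert product == pytest.approx(1.0, abs=0.01)

    def test_delocalized_pair_has_significant_product(self, ref_grid):
        part = FragmentPartition(("A", "B"))
        centers = ref_grid.voxel_centers()

        def deloc(sign):
            d2a = ((centers - [-6.0, 0, 0]) ** 2).sum(axis=1)
            d2b = ((centers - [6.0, 0, 0]) ** 2).sum(axis=1)
            psi = np.exp(-0.25 * d2a / 1.5**2) + sign * np.exp(-0.25 * d2b / 1.5**2)
            psi /= np.sqrt((psi**2).sum() * ref_grid.voxel_volume)
            return DensityGrid(ref_grid.origin, ref_grid.axes,
                               psi.reshape(ref_grid.shape),
                               ref_grid.atom_numbers, ref_grid.atom_coords)

        _, _, product = homo_lumo_overlap(deloc(+1), deloc(-1), part)
        assert product > 0.2


class TestDirectionSeries:
    def _assign(self, snap, donor, acceptor):
        return CTAssignment(snap, 2.2, donor, acceptor)

    def test_alternating_directions_count_three_flips(self):
        # inactive-branch pattern across the 50-200 ns snapshots
        assigns = [
            self._assign("50ns", "P_M", "B_M"),
            self._assign("100ns", "B_M", "P_M"),
            self._assign("150ns", "P_M", "B_M"),
            self._assign("200ns", "B_M", "P_M"),
        ]
        signs, flips = ct_direction_series(assigns, pair_order=("P_M", "B_M"))
        assert signs == [1, -1, 1, -1]
        assert flips == 3

    def test_constant_direction_no_flips(self):
        assigns = [self._assign(s, "P_L", "B_L") for s in "abc"]
        assert ct_direction_series(assigns)[1] == 0

    def test_single_snapshot_no_flips(self):
        assert ct_direction_series([self._assign("a", "X", "Y")])[1] == 0

    def test_mixed_pairs_rejected(self):
        assigns = [self._assign("a", "P_L", "B_L"), self._assign("b", "P_M", "B_M")]
        with pytest.raises(ValueError, match="more than one"):
            ct_direction_series(assigns)

    def test_invalid_assignment_sign_convention(self):
        with pytest.raises(ValueError, match="donor"):
            CTAssignment("a", 2.0, "X", "X")
        with pytest.raises(ValueError, match="Δq"):
            CTAssignment("a", 2.0, "X", "Y", delta_q={"X": 0.5, "Y": -0.5})


class TestCTSummary:
    def test_reference_pair_ranges_match_brute_force(self):
        pairs = rc_pair_states()
        for pair, recs in pairs.items():
            summ = ct_summary(recs, pair)
            # independent scan over the same records
            energies = [r.energy_ev for r in recs if classify_state(r) == "pure_CT"]
            assert summ.min_ev == pytest.approx(min(energies))
            assert summ.max_ev == pytest.approx(max(energies))

    def test_inactive_branch_energy_range(self):
        summ = ct_summary(rc_pair_states()["P_M/B_M"], "P_M/B_M")
        assert summ.min_ev == pytest.approx(2.175)
        assert summ.max_ev == pytest.approx(2.471)

    def test_special_pair_50ns_has_no_low_ct(self):
        summ = ct_summary(rc_pair_states()["P_M/P_L"], "P_M/P_L")
        assert "50ns" in summ.snapshots_without_ct

    def test_single_pure_ct_record(self):
        rec = _rec(1.0, 0.0, "A", "B", energy=2.1)
        summ = ct_summary([rec], "A/B")
        assert summ.min_ev == summ.max_ev == 2.1
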