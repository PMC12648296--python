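import numpy as np
import pytest

from excitonscope.constants import KE_EV_ANG
from excitonscope.hamiltonian import (
    ExcitonHamiltonian,
    build_hamiltonian,
    coupling_matrix,
    diagonalize,
    point_dipole_coupling,
    site_dipoles,
    tresp_coupling,
)
from excitonscope.structures import PigmentGeometry, TransitionChargeSet, transition_dipole


def _pig(pid, coords, charges):
    coords = np.atleast_2d(np.asarray(coords, float))
    return (
        PigmentGeometry(pid, ("C",) * len(coords), coords),
        TransitionChargeSet(pid, np.atleast_1d(np.asarray(charges, float))),
    )


def brute_force_coulomb(gm, qm, gn, qn, f):
    """Independent oracle: explicit double loop over atom pairs."""
    total = 0.0
    for qi, ri in zip(qm.charges, gm.coords):
        for qj, rj in zip(qn.charges, gn.coords):
            total += qi * qj / np.linalg.norm(ri - rj)
    return f * KE_EV_ANG * total


class TestTrespCoupling:
    def test_single_atom_hand_value(self):
        gm, qm = _pig("m", [0, 0, 0], [0.1])
        gn, qn = _pig("n", [10, 0, 0], [0.1])
        v = tresp_coupling(gm, qm, gn, qn, screening_f=0.69)
        assert v == pytest.approx(0.69 * KE_EV_ANG * 0.01 / 10.0, rel=1e-12)
        assert v == pytest.approx(9.936e-3, abs=5e-7)

    def test_zero_screening_kills_coupling(self, rng):
        gm, qm = _pig("m", rng.normal(size=(4, 3)), rng.normal(size=4))
        gn, qn = _pig("n", rng.normal(size=(4, 3)) + 20, rng.normal(size=4))
        assert tresp_coupling(gm, qm, gn, qn, screening_f=0.0) == 0.0

    def test_matches_brute_force_double_sum(self, rng):
        gm, qm = _pig("m", rng.normal(size=(8, 3)), rng.normal(size=8))
        gn, qn = _pig("n", rng.normal(size=(8, 3)) + 15, rng.normal(size=8))
        v = tresp_coupling(gm, qm, gn, qn)
        assert v == pytest.approx(brute_force_coulomb(gm, qm, gn, qn, 0.69), abs=1e-12)

    def test_symmetric_under_exchange(self, rng):
        gm, qm = _pig("m", rng.normal(size=(5, 3)), rng.normal(size=5))
        gn, qn = _pig("n", rng.normal(size=(5, 3)) + 12, rng.normal(size=5))
        assert tresp_coupling(gm, qm, gn, qn) == pytest.approx(
            tresp_coupling(gn, qn, gm, qm), rel=1e-14
        )

    def test_far_field_matches_point_dipole_formula(self):
        # extended neutral charge sets separated by 50x the molecular extent
        ext = 2.0
        coords = np.array([[ext, 0, 0], [-ext, 0, 0], [0, ext, 0], [0, -ext, 0]])
        qm = np.array([0.3, -0.3, 0.1, -0.1])
        qn = np.array([0.25, -0.25, -0.15, 0.15])
        sep = np.array([100.0 * ext, 37.0, 12.0])
        gm, qsm = _pig("m", coords, qm)
        gn, qsn = _pig("n", coords + sep, qn)
        v = tresp_coupling(gm, qsm, gn, qsn)
        v_pd = point_dipole_coupling(
            transition_dipole(gm, qsm), gm.center,
            transition_dipole(gn, qsn), gn.center,
        )
        assert v == pytest.approx(v_pd, rel=0.01)

    def test_far_field_decay_slope_is_minus_three(self):
        gm, qm = _pig("m", [[1, 0, 0], [-1, 0, 0]], [0.3, -0.3])
        dists = np.logspace(2, 3, 12)  # one decade, far field
        vs = []
        for d in dists:
            gn, qn = _pig("n", [[1, 0, d], [-1, 0, d]], [0.3, -0.3])
            vs.append(abs(tresp_coupling(gm, qm, gn, qn)))
        slope = np.polyfit(np.log(dists), np.log(vs), 1)[0]
        assert slope == pytest.approx(-3.0, abs=0.05)

    def test_overlapping_geometries_rejected(self):
        gm, qm = _pig("m", [0, 0, 0], [0.1])
        gn, qn = _pig("n", [0.05, 0, 0], [0.1])
        with pytest.raises(ValueError, match="overlapping"):
            tresp_coupling(gm, qm, gn, qn)

    def test_self_coupling_rejected(self):
        gm, qm = _pig("m", [0, 0, 0], [0.1])
        with pytest.raises(ValueError, match="distinct"):
            tresp_coupling(gm, qm, gm, qm)


class TestBuildHamiltonian:
    def test_symmetric_dimer_splitting(self):
        ham = build_hamiltonian({"a": 2.0, "b": 2.0}, {("a", "b"): 0.05})
        evals = np.linalg.eigvalsh(ham.matrix)
        np.testing.assert_allclose(evals, [1.95, 2.05], atol=1e-14)

    def test_single_site(self):
        ham = build_hamiltonian({"only": 1.9}, {})
        assert ham.matrix.shape == (1, 1)
        assert ham.matrix[0, 0] == 1.9

    def test_full_complex_matrix(self, assembly):
        energies = {p.pigment_id: 1.9 for p in assembly.pigments}
        ham = build_hamiltonian(energies, couplings=None, assembly=assembly)
        assert ham.matrix.shape == (38, 38)
        np.testing.assert_allclose(ham.matrix, ham.matrix.T, atol=1e-12)

    def test_missing_site_energy_rejected(self):
        with pytest.raises(ValueError, match="missing site energy"):
            build_hamiltonian({"a": 2.0, "b": None}, {})

    def test_asymmetric_couplings_rejected(self):
        with pytest.raises(ValueError, match="[Aa]symmetric"):
            build_hamiltonian(
                {"a": 2.0, "b": 2.0}, {("a", "b"): 0.05, ("b", "a"): 0.06}
            )

    def test_text_round_trip(self, tmp_path):
        ham = build_hamiltonian({"a": 2.0, "b": 1.9}, {("a", "b"): 0.031})
        path = tmp_path / "h.txt"
        ham.to_text(path)
        loaded = ExcitonHamiltonian.from_text(path)
        assert loaded.labels == ham.labels
        np.testing.assert_allclose(loaded.matrix, ham.matrix, atol=1e-9)


class TestDiagonalize:
    def test_diagonal_hamiltonian_identity_eigenvectors(self):
        ham = ExcitonHamiltonian(("a", "b", "c"), np.diag([1.8, 1.9, 2.0]))
        mu = np.eye(3)
        states = diagonalize(ham, mu)
        np.testing.assert_allclose(np.abs(states.eigenvectors), np.eye(3), atol=1e-12)
        np.testing.assert_allclose(np.abs(states.dipoles), mu, atol=1e-12)

    def test_dimer_dipole_redistribution(self):
        # equal site dipoles: one exciton carries sqrt(2)*mu, the other zero
        ham = ExcitonHamiltonian(("a", "b"), np.array([[2.0, 0.05], [0.05, 2.0]]))
        mu = np.array([[1.0, 0, 0], [1.0, 0, 0]])
        states = diagonalize(ham, mu)
        mags = np.sort(np.linalg.norm(states.dipoles, axis=1))
        np.testing.assert_allclose(mags, [0.0, np.sqrt(2.0)], atol=1e-12)
        assert states.dipole_strengths.sum() == pytest.approx(2.0, rel=1e-12)

    def test_eigendecomposition_reconstructs_random_hamiltonian(self, rng):
        m = rng.normal(size=(10, 10))
        h = 0.5 * (m + m.T) + 10 * np.eye(10)  # positive diagonal
        ham = ExcitonHamiltonian(tuple(f"s{i}" for i in range(10)), h)
        states = diagonalize(ham, rng.normal(size=(10, 3)))
        rebuilt = states.eigenvectors @ np.diag(states.eigenvalues) @ states.eigenvectors.T
        np.testing.assert_allclose(rebuilt, h, atol=1e-10)

    def test_trace_conservation(self, rng):
        h = rng.normal(size=(6, 6))
        h = 0.5 * (h + h.T) + 5 * np.eye(6)
        ham = ExcitonHamiltonian(tuple("abcdef"), h)
        states = diagonalize(ham, rng.normal(size=(6, 3)))
        assert states.eigenvalues.sum() == pytest.approx(np.trace(h), rel=1e-10)

    def test_dipole_strength_sum_rule(self, assembly):
        energies = {p.pigment_id: 1.9 for p in assembly.pigments}
        ham = build_hamiltonian(energies, couplings=coupling_matrix(assembly))
        mu = site_dipoles(assembly)
        states = diagonalize(ham, mu)
        site_strength = np.einsum("mi,mi->", mu, mu)
        assert states.dipole_strengths.sum() == pytest.approx(site_strength, rel=1e-8)

    def test_eigenvalues_ascend(self, rng):
        h = rng.normal(size=(8, 8))
        h = 0.5 * (h + h.T) + 6 * np.eye(8)
        states = diagonalize(
            ExcitonHamiltonian(tuple(f"s{i}" for i in range(8)), h),
            rng.normal(size=(8, 3)),
        )
        assert (np.diff(states.eigenvalues) >= 0).all()
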