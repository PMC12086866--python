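"""Normal modes and PED against closed-form and GF-method oracles."""

import numpy as np
import pytest

from twodir.ped import (
    InternalCoordinate,
    InternalCoordinateSet,
    MolecularSystem,
    WAVENUMBER_FACTOR,
    atomic_mass,
    normal_modes,
    ped_table,
    read_hessian,
    read_xyz,
    wilson_b_matrix,
    write_hessian,
    write_xyz,
)


def spring_hessian(n_atoms, springs, coords):
    """Cartesian Hessian of pairwise bond springs (harmonic, at equilibrium):
    k (e e^T) blocks along the bond direction."""
    H = np.zeros((3 * n_atoms, 3 * n_atoms))
    for a, b, k in springs:
        d = coords[a] - coords[b]
        e = d / np.linalg.norm(d)
        blk = k * np.outer(e, e)
        H[3 * a : 3 * a + 3, 3 * a : 3 * a + 3] += blk
        H[3 * b : 3 * b + 3, 3 * b : 3 * b + 3] += blk
        H[3 * a : 3 * a + 3, 3 * b : 3 * b + 3] -= blk
        H[3 * b : 3 * b + 3, 3 * a : 3 * a + 3] -= blk
    return H


def co_system(k=None, freq=2100.0):
    mC, mO = atomic_mass("C"), atomic_mass("O")
    mu = mC * mO / (mC + mO)
    if k is None:
        k = (freq / WAVENUMBER_FACTOR["hartree/bohr^2"]) ** 2 * mu
    coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.128]])
    H = spring_hessian(2, [(0, 1, k)], coords)
    return MolecularSystem(["C", "O"], coords, H), k, mu


class TestNormalModes:
    def test_diatomic_matches_reduced_mass_formula(self):
        """nu = (1/2 pi c) sqrt(k/mu) to 0.1 cm^-1."""
        system, k, mu = co_system(freq=2100.0)
        freqs, _ = normal_modes(system)
        assert freqs.size == 1
        closed_form = WAVENUMBER_FACTOR["hartree/bohr^2"] * np.sqrt(k / mu)
        assert freqs[0] == pytest.approx(closed_form, abs=0.1)
        assert freqs[0] == pytest.approx(2100.0, abs=0.1)

    def test_translation_invariance(self):
        system, _, _ = co_system()
        shifted = MolecularSystem(
            system.symbols, system.coords + np.array([5.0, -3.0, 2.0]), system.hessian
        )
        f0, _ = normal_modes(system)
        f1, _ = normal_modes(shifted)
        assert np.allclose(f0, f1, atol=1e-9)

    def test_zero_hessian_all_zero_frequencies(self):
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        system = MolecularSystem(["O", "C", "O"], coords, np.zeros((9, 9)))
        freqs, _ = normal_modes(system)
        assert np.allclose(freqs, 0.0, atol=1e-8)

    def test_asymmetric_hessian_rejected(self):
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        H = np.zeros((6, 6))
        H[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            MolecularSystem(["C", "O"], coords, H)


class TestPED:
    def test_diatomic_single_stretch_is_unity(self):
        system, _, _ = co_system()
        ics = InternalCoordinateSet([InternalCoordinate("stretch", (0, 1), "CO")])
        table = ped_table(system, ics)
        assert table.fractions[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_triatomic_half_half(self):
        """Equal masses and force constants: both stretch modes carry 0.5
        from each bond coordinate."""
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.2], [0.0, 0.0, 2.4]])
        H = spring_hessian(3, [(0, 1, 0.5), (1, 2, 0.5)], coords)
        m = np.array([16.0, 16.0, 16.0])
        system = MolecularSystem(["O", "O", "O"], coords, H, masses=m)
        ics = InternalCoordinateSet(
            [
                InternalCoordinate("stretch", (0, 1), "r1"),
                InternalCoordinate("stretch", (1, 2), "r2"),
            ]
        )
        freqs, _ = normal_modes(system)
        stretch_modes = [k for k, f in enumerate(freqs) if f > 1.0]
        table = ped_table(system, ics, mode_selection=stretch_modes)
        assert np.allclose(table.fractions, 0.5, atol=1e-6)

    def test_asymmetric_triatomic_matches_gf_oracle(self):
        """Unequal end masses: fractions agree with an independent
        internal-coordinate GF-method calculation."""
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.2], [0.0, 0.0, 2.5]])
        k1, k2 = 0.55, 0.40
        masses = np.array([12.0, 31.97, 15.999])
        H = spring_hessian(3, [(0, 1, k1), (1, 2, k2)], coords)
        system = MolecularSystem(["C", "S", "O"], coords, H, masses=masses)
        ics = InternalCoordinateSet(
            [
                InternalCoordinate("stretch", (0, 1), "r1"),
                InternalCoordinate("stretch", (1, 2), "r2"),
            ]
        )
        freqs, _ = normal_modes(system)
        stretch_modes = [k for k, f in enumerate(freqs) if f > 1.0]
        table = ped_table(system, ics, mode_selection=stretch_modes)

        # GF oracle in pure internal coordinates: G from the s-vectors of two
        # collinear bonds, F exactly diagonal for bond springs
        e1 = (coords[0] - coords[1]) / np.linalg.norm(coords[0] - coords[1])
        e2 = (coords[2] - coords[1]) / np.linalg.norm(coords[2] - coords[1])
        G = np.array(
            [
                [1 / masses[0] + 1 / masses[1], (e1 @ e2) / masses[1]],
                [(e1 @ e2) / masses[1], 1 / masses[2] + 1 / masses[1]],
            ]
        )
        F = np.diag([k1, k2])
        lam, L = np.linalg.eig(G @ F)
        order = np.argsort(lam)
        lam, L = lam[order], L[:, order]
        ped_oracle = (np.diag(F)[:, None] * L**2) / (
            (np.diag(F)[:, None] * L**2).sum(axis=0)
        )
        # frequencies must agree between the Cartesian and GF routes
        nu_oracle = WAVENUMBER_FACTOR["hartree/bohr^2"] * np.sqrt(lam)
        assert np.allclose(np.sort(table.frequencies), np.sort(nu_oracle), atol=1e-6)
        assert np.allclose(table.fractions, ped_oracle.T, atol=1e-9)

    def test_rotation_invariance(self):
        """PED unchanged under a rigid rotation of geometry and Hessian."""
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.2], [0.0, 0.0, 2.5]])
        masses = np.array([12.0, 31.97, 15.999])
        H = spring_hessian(3, [(0, 1, 0.55), (1, 2, 0.40)], coords)
        system = MolecularSystem(["C", "S", "O"], coords, H, masses=masses)
        ics = InternalCoordinateSet(
            [
                InternalCoordinate("stretch", (0, 1), "r1"),
                InternalCoordinate("stretch", (1, 2), "r2"),
            ]
        )
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("zyx", [31.0, -47.0, 112.0], degrees=True).as_matrix()
        coords_rot = coords @ R.T
        Rb = np.kron(np.eye(3), R)
        H_rot = Rb @ H @ Rb.T
        system_rot = MolecularSystem(["C", "S", "O"], coords_rot, H_rot, masses=masses)
        freqs, _ = normal_modes(system)
        sel = [k for k, f in enumerate(freqs) if f > 1.0]
        t0 = ped_table(system, ics, mode_selection=sel)
        freqs_r, _ = normal_modes(system_rot)
        sel_r = [k for k, f in enumerate(freqs_r) if f > 1.0]
        t1 = ped_table(system_rot, ics, mode_selection=sel_r)
        assert np.allclose(t0.frequencies, t1.frequencies, atol=1e-6)
        assert np.allclose(t0.fractions, t1.fractions, atol=1e-8)

    def test_redundant_set_requires_flag(self):
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.2]])
        H = spring_hessian(2, [(0, 1, 0.5)], coords)
        system = MolecularSystem(["C", "O"], coords, H)
        ics = InternalCoordinateSet(
            [
                InternalCoordinate("stretch", (0, 1), "r1"),
                InternalCoordinate("stretch", (1, 0), "r1b"),
            ]
        )
        with pytest.raises(ValueError, match="rank"):
            ped_table(system, ics)
        table = ped_table(system, ics, redundant=True)
        assert table.fractions.shape[1] == 2


class TestFileFormats:
    def test_xyz_round_trip(self, tmp_path):
        symbols = ["Fe", "C", "O"]
        coords = np.array([[0.0, 0.0, 0.0], [1.8, 0.0, 0.0], [2.95, 0.0, 0.0]])
        p = tmp_path / "geom.xyz"
        write_xyz(p, symbols, coords, comment="test")
        s2, c2 = read_xyz(p)
        assert s2 == symbols
        assert np.allclose(c2, coords)

    def test_hessian_round_trip_with_units(self, tmp_path):
        rng = np.random.default_rng(5)
        H = rng.normal(size=(6, 6))
        H = (H + H.T) / 2
        p = tmp_path / "hess.txt"
        write_hessian(p, H, units="mdyn/angstrom")
        H2, units = read_hessian(p)
        assert units == "mdyn/angstrom"
        assert np.allclose(H2, H, atol=1e-10)

    def test_hessian_missing_header_rejected(self, tmp_path):
        p = tmp_path / "hess.txt"
        p.write_text("1.0\n")
        with pytest.raises(ValueError, match="header"):
            read_hessian(p)

    def test_mdyn_units_diatomic_frequency(self):
        """The mdyn/angstrom conversion agrees with the closed form:
        k = 19.0 mdyn/A for CO gives ~2170 cm^-1."""
        mC, mO = atomic_mass("C"), atomic_mass("O")
        mu = mC * mO / (mC + mO)
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.128]])
        k = 19.0
        H = spring_hessian(2, [(0, 1, k)], coords)
        system = MolecularSystem(
            ["C", "O"], coords, H, hessian_units="mdyn/angstrom"
        )
        freqs, _ = normal_modes(system)
        expected = WAVENUMBER_FACTOR["mdyn/angstrom"] * np.sqrt(k / mu)
        assert freqs[0] == pytest.approx(expected, abs=0.1)
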