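"""Coupled local-mode solver against an independent operator-algebra oracle."""

import itertools

import numpy as np
import pytest

from twodir.ladder import anharmonicities_from_table
from twodir.localmode import (
    AssignmentError,
    LocalModeModel,
    exciton_product_basis,
    localization,
    one_quantum_block,
    solve_ladder,
    sweep_models,
    two_quantum_block,
)


def oracle_hamiltonian(model, n_max=3):
    """Dense Hamiltonian from explicit bosonic ladder operators.

    Independent construction: per-site number operators give the local
    anharmonic ladder E_i(n) = w_i n - chi_i n(n+1), couplings enter as
    beta_ij (a_i^+ a_j + a_j^+ a_i) via Kronecker products.  Truncating each
    site at n_max quanta is exact for the <= 2-quantum sector because the
    Hamiltonian conserves total quanta.
    """
    n = model.n
    dim = n_max + 1
    a = np.diag(np.sqrt(np.arange(1, dim)), k=1)  # annihilation
    num = a.T @ a

    def embed(op, site):
        mats = [np.eye(dim)] * n
        mats[site] = op
        out = mats[0]
        for m in mats[1:]:
            out = np.kron(out, m)
        return out

    H = np.zeros((dim**n, dim**n))
    for i in range(n):
        ni = embed(num, i)
        H += model.site_freqs[i] * ni - model.local_anh[i] * (ni @ ni + ni)
    for i, j in itertools.combinations(range(n), 2):
        H += model.couplings[i][j] * (
            embed(a.T, i) @ embed(a, j) + embed(a.T, j) @ embed(a, i)
        )
    # total-quanta labels of the product basis
    occs = np.array(list(itertools.product(range(dim), repeat=n)))
    total = occs.sum(axis=1)
    return H, occs, total


def oracle_sector_eigs(model, quanta):
    H, occs, total = oracle_hamiltonian(model)
    idx = np.flatnonzero(total == quanta)
    return np.sort(np.linalg.eigvalsh(H[np.ix_(idx, idx)]))


class TestBlocks:
    def test_one_quantum_sector_matches_operator_oracle(self):
        model = LocalModeModel.dimer((2000.0, 2000.0), 12.0, 15.0)
        ladder, _ = solve_ladder(model)
        assert np.allclose(ladder.freqs1, oracle_sector_eigs(model, 1), atol=1e-9)

    def test_two_quantum_sector_matches_operator_oracle(self):
        model = LocalModeModel.dimer((2000.0, 2000.0), 12.0, 15.0)
        ladder, _ = solve_ladder(model)
        assert np.allclose(
            np.sort(ladder.energies2), oracle_sector_eigs(model, 2), atol=1e-9
        )

    def test_three_site_sectors_match_oracle(self):
        beta = ((0.0, 8.0, 3.0), (8.0, 0.0, 5.0), (3.0, 5.0, 0.0))
        model = LocalModeModel((1980.0, 2000.0, 2030.0), (10.0, 12.0, 14.0), beta)
        ladder, _ = solve_ladder(model)
        assert np.allclose(ladder.freqs1, oracle_sector_eigs(model, 1), atol=1e-9)
        assert np.allclose(
            np.sort(ladder.energies2), oracle_sector_eigs(model, 2), atol=1e-9
        )

    def test_exciton_product_basis_is_orthogonal(self):
        model = LocalModeModel.dimer((1990.0, 2005.0), 12.0, 9.0)
        _, v1 = np.linalg.eigh(one_quantum_block(model))
        T, pairs = exciton_product_basis(v1)
        assert np.allclose(T.T @ T, np.eye(T.shape[1]), atol=1e-9)


class TestLimits:
    def test_uncoupled_limit(self):
        """beta = 0: fundamentals at w - 2 chi, intramode exactly 2 chi,
        no intermode coupling."""
        model = LocalModeModel.dimer((1980.0, 2010.0), 12.0, 0.0)
        ladder, table = solve_ladder(model)
        anh = anharmonicities_from_table(table)
        assert sorted(table._fund.values()) == [1956.0, 1986.0]
        assert anh.get("low", "low") == pytest.approx(24.0, abs=1e-9)
        assert anh.get("high", "high") == pytest.approx(24.0, abs=1e-9)
        assert anh.get("low", "high") == pytest.approx(0.0, abs=1e-9)

    def test_harmonic_limit_all_zero(self):
        """chi = 0: bilinearly coupled harmonic oscillators stay harmonic."""
        for beta in (5.0, 15.0, 40.0):
            model = LocalModeModel.dimer((2000.0, 2000.0), 0.0, beta)
            _, table = solve_ladder(model)
            anh = anharmonicities_from_table(table)
            assert np.max(np.abs(anh.values)) < 1e-9

    def test_localized_limit_monotone(self):
        """Detuning >> coupling recovers the uncoupled observables."""
        chi, beta = 12.0, 8.0
        prev_inter = np.inf
        for det in (50.0, 150.0, 500.0):
            model = LocalModeModel.dimer((2000.0 - det / 2, 2000.0 + det / 2), chi, beta)
            _, table = solve_ladder(model)
            anh = anharmonicities_from_table(table)
            inter = abs(anh.get("low", "high"))
            assert inter < prev_inter
            prev_inter = inter
        assert anh.get("low", "low") == pytest.approx(2 * chi, abs=0.1)
        assert inter < 0.5


class TestTraceConservation:
    @pytest.mark.parametrize("beta", [0.0, 7.0, 15.0])
    def test_one_and_two_quantum_traces(self, beta):
        model = LocalModeModel.dimer((1985.0, 2004.0), (11.0, 13.0), beta)
        ladder, _ = solve_ladder(model)
        expected1 = sum(w - 2 * c for w, c in zip(model.site_freqs, model.local_anh))
        assert ladder.freqs1.sum() == pytest.approx(expected1, abs=1e-9)
        assert ladder.energies2.sum() == pytest.approx(
            np.trace(two_quantum_block(model)), abs=1e-9
        )


class TestDarlingDennison:
    def test_asymmetry_requires_two_quantum_mixing(self):
        """For identical sites the intramode anharmonicities of the two
        eigenmodes differ only through two-quantum state mixing."""
        model = LocalModeModel.dimer((2000.0, 2000.0), 12.0, 15.0)
        _, table = solve_ladder(model)
        anh = anharmonicities_from_table(table)
        d = anh.values.diagonal()
        assert abs(d[0] - d[1]) > 1.0  # resonance splits them
        assert d[0] > d[1]  # lower eigenmode softened more
        _, table0 = solve_ladder(model, two_quantum_mixing=False)
        anh0 = anharmonicities_from_table(table0)
        d0 = anh0.values.diagonal()
        assert d0[0] == pytest.approx(d0[1], abs=1e-9)

    def test_degenerate_dimer_reference_values(self):
        """Frozen oracle values for (w, w, chi=12, beta=15) from dense
        diagonalization of the 2x2 / 3x3 blocks."""
        model = LocalModeModel.dimer((2000.0, 2000.0), 12.0, 15.0)
        ladder, table = solve_ladder(model)
        anh = anharmonicities_from_table(table)
        assert ladder.freqs1 == pytest.approx([1961.0, 1991.0])
        assert np.sort(ladder.energies2) == pytest.approx(
            [3907.689011, 3928.0, 3972.310989], abs=1e-6
        )
        assert anh.get("low", "high") == pytest.approx(24.0, abs=1e-9)


class TestLocalization:
    def test_symmetric_dimer_half_half(self):
        model = LocalModeModel.dimer((2000.0, 2000.0), 12.0, 15.0)
        ladder, _ = solve_ladder(model)
        for mode, site in itertools.product(range(2), range(2)):
            assert localization(ladder, mode, site) == pytest.approx(0.5)

    def test_uncoupled_detuned_fully_localized(self):
        model = LocalModeModel.dimer((1995.0, 2005.0), 12.0, 0.0)
        ladder, _ = solve_ladder(model)
        assert localization(ladder, 0, 0) == pytest.approx(1.0)
        assert localization(ladder, 1, 1) == pytest.approx(1.0)

    def test_matches_analytic_two_level_mixing(self):
        """(1995, 2005, chi=12, beta=8): weight from the closed-form 2x2
        mixing angle of the one-quantum block."""
        model = LocalModeModel.dimer((1995.0, 2005.0), 12.0, 8.0)
        ladder, _ = solve_ladder(model)
        delta, beta = 5.0, 8.0  # half detuning of the diagonal, coupling
        theta = 0.5 * np.arctan2(2 * beta, 2 * delta)
        expected_low_on_site0 = np.cos(theta) ** 2
        assert localization(ladder, 0, 0) == pytest.approx(
            expected_low_on_site0, abs=1e-12
        )
        assert localization(ladder, 0, 0) + localization(ladder, 0, 1) == pytest.approx(
            1.0
        )

    def test_index_errors(self):
        model = LocalModeModel.dimer((1995.0, 2005.0), 12.0, 8.0)
        ladder, _ = solve_ladder(model)
        with pytest.raises(IndexError):
            localization(ladder, 2, 0)


class TestSweep:
    def test_parabolic_endpoints_and_minimum(self):
        base = LocalModeModel.dimer((1982.0, 2007.0), 12.5, 10.0)
        recs = sweep_models(base, np.linspace(-40, 40, 21), [10.0])
        d_low = [r.anharmonicities.values[0, 0] for r in recs]
        loc = [r.localizations["low"] for r in recs]
        mid = int(np.argmin(np.abs(np.array(loc) - 0.5)))
        assert d_low[0] == max(d_low) or d_low[-1] == max(d_low)
        assert d_low[mid] == min(d_low)

    def test_zero_coupling_sweep_has_zero_intermode(self):
        base = LocalModeModel.dimer((1982.0, 2007.0), 12.5, 0.0)
        recs = sweep_models(base, np.linspace(-30, 30, 7), [0.0])
        assert all(
            abs(r.anharmonicities.values[0, 1]) < 1e-9 for r in recs
        )

    def test_intra_inter_negative_rank_correlation(self):
        from scipy.stats import spearmanr

        base = LocalModeModel.dimer((1982.0, 2007.0), 12.5, 10.0)
        recs = sweep_models(base, np.linspace(-40, 40, 21), [10.0])
        intra = [r.anharmonicities.values[0, 0] for r in recs]
        inter = [r.anharmonicities.values[0, 1] for r in recs]
        rho = spearmanr(intra, inter).statistic
        assert rho < 0

    def test_deterministic(self):
        base = LocalModeModel.dimer((1982.0, 2007.0), 12.5, 10.0)
        a = sweep_models(base, [-10.0, 10.0], [8.0])
        b = sweep_models(base, [-10.0, 10.0], [8.0])
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.anharmonicities.values, rb.anharmonicities.values)


class TestValidation:
    def test_asymmetric_couplings_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            LocalModeModel((2000.0, 2010.0), (12.0, 12.0), ((0.0, 5.0), (6.0, 0.0)))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            LocalModeModel((2000.0, 2010.0), (12.0, 12.0), ((1.0, 5.0), (5.0, 0.0)))

    def test_sweep_empty_grid_rejected(self):
        base = LocalModeModel.dimer((1982.0, 2007.0), 12.5, 10.0)
        with pytest.raises(ValueError, match="non-empty"):
            sweep_models(base, [], [10.0])
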