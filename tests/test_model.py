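"""Cluster presets and Hamiltonian builders against closed-form oracles."""

from itertools import permutations

import numpy as np
import pytest

from spinblock import (
    ClusterModel,
    SiteOrdering,
    build_hamiltonian_csf,
    build_hamiltonian_sd,
    determinant_basis,
    make_cumulative_blocked_model,
    make_preset,
    spin_operator_matrices,
)


def kambe_pair_energy(J, S, s_a, s_b):
    """Closed-form two-spin exchange energy, E = -J/2 [S(S+1) - s_a(s_a+1)
    - s_b(s_b+1)] under the J<0-antiferromagnetic convention."""
    return -J / 2 * (S * (S + 1) - s_a * (s_a + 1) - s_b * (s_b + 1))


class TestPresets:
    def test_isosceles_coupling_map(self):
        m = make_preset("isosceles", 3, {"J_AB": -150.0, "J_AC": -20.0})
        assert m.couplings == {(0, 1): -150.0, (0, 2): -20.0, (1, 2): -20.0}
        assert m.labels == ("A", "B", "C")
        assert m.n_open == 9

    def test_square_topology(self):
        m = make_preset("square_2J", 3, {"J_short": -1.0, "J_long": -0.4})
        edges = {k for k, v in m.couplings.items() if v == -1.0}
        diags = {k for k, v in m.couplings.items() if v == -0.4}
        assert edges == {(0, 1), (1, 2), (2, 3), (0, 3)}
        assert diags == {(0, 2), (1, 3)}

    def test_periodic_3_chain_equals_equilateral(self):
        chain = make_preset("chain_periodic", 3, {"J": -1.0, "n_sites": 3})
        tri = make_preset("equilateral", 3, {"J": -1.0})
        assert chain.couplings == tri.couplings

    def test_open_3_chain_is_isosceles_with_zero_far_coupling(self):
        chain = make_preset("chain_open", 3, {"J": -1.0, "n_sites": 3})
        assert chain.coupling(0, 1) == chain.coupling(1, 2) == -1.0
        assert chain.coupling(0, 2) == 0.0

    def test_tetrahedron_all_pairs(self):
        m = make_preset("tetrahedron", 1, {"J": -2.0})
        assert len(m.couplings) == 6
        assert set(m.couplings.values()) == {-2.0}

    def test_unknown_preset_and_missing_params(self):
        with pytest.raises(ValueError, match="unknown preset"):
            make_preset("pentagon", 1, {})
        with pytest.raises(ValueError, match="requires params"):
            make_preset("isosceles", 3, {"J_AB": -1.0})

    def test_model_validation(self):
        with pytest.raises(ValueError, match="self-coupling"):
            ClusterModel((1, 1), {(0, 0): -1.0})
        with pytest.raises(ValueError, match="non-negative"):
            ClusterModel((1, 1), {(0, 1): -1.0}, j_hund=-2.0)


class TestCumulativeBlockedModel:
    def test_full_depth_three_sites_is_isosceles_shaped(self):
        m = make_cumulative_blocked_model((3, 3, 3), [-150.0, -20.0])
        assert m.coupling(0, 1) == -150.0
        assert m.coupling(0, 2) == m.coupling(1, 2) == -20.0

    def test_depth_two_square_like(self):
        m = make_cumulative_blocked_model(
            (1, 1, 1, 1), [-0.4, -1.0, -1.0], m=2, extra_couplings={(2, 3): -0.4}
        )
        # sites 3 and 4 couple uniformly to the first two; pair (3,4) is free
        assert m.coupling(0, 2) == m.coupling(1, 2) == -1.0
        assert m.coupling(0, 3) == m.coupling(1, 3) == -1.0
        assert m.coupling(2, 3) == -0.4

    def test_extra_coupling_cannot_break_shell(self):
        with pytest.raises(ValueError, match="conflicts"):
            make_cumulative_blocked_model(
                (1, 1, 1), [-1.0, -1.0], extra_couplings={(0, 2): -0.5}
            )


class TestDeterminantHamiltonian:
    def test_spin_half_dimer_sectors(self):
        m = make_preset("dimer", 1, {"J": -1.0})
        H = build_hamiltonian_sd(m, SiteOrdering.identity(2), 0).toarray()
        assert np.allclose(np.sort(np.linalg.eigvalsh(H)), [-0.75, 0.25])

    def test_s32_dimer_singlet_sector_kambe(self):
        """M=0 sector of the s=3/2 dimer holds one level per total spin S,
        each at the Kambe pair energy, with multiplicity one per multiplet."""
        m = make_preset("dimer", 3, {"J": -1.0})
        H = build_hamiltonian_sd(m, SiteOrdering.identity(2), 0).toarray()
        ev = np.sort(np.linalg.eigvalsh(H))
        expected = []
        # M=0 intersects every (S_A, S_B, S) multiplet once
        for t_a in (1, 3):
            mult_a = 2 if t_a == 1 else 1
            for t_b in (1, 3):
                mult_b = 2 if t_b == 1 else 1
                for tS in range(abs(t_a - t_b), t_a + t_b + 1, 2):
                    E = kambe_pair_energy(-1.0, tS / 2, t_a / 2, t_b / 2)
                    expected += [E] * (mult_a * mult_b)
        assert np.allclose(ev, np.sort(expected), atol=1e-9)

    def test_hund_sector_eigenvalues(self):
        """Restricting to local spins 3/2: singlet at -15/4 above the
        exchange-only Hund levels; the four lowest M=0 Kambe energies."""
        m = make_preset("dimer", 3, {"J": -1.0}, j_hund=100.0)
        H = build_hamiltonian_sd(m, SiteOrdering.identity(2), 0).toarray()
        ev = np.sort(np.linalg.eigvalsh(H))
        hund_shift = -100.0 * 2 * 0.5 * (15 / 4 - 9 / 4)
        kambe = sorted(
            kambe_pair_energy(-1.0, S, 1.5, 1.5) + hund_shift for S in range(4)
        )
        assert np.allclose(ev[:4], kambe[:4], atol=1e-8)

    @pytest.mark.parametrize("preset,params", [
        ("scalene", {"J_AB": -150.0, "J_AC": -50.0, "J_BC": -20.0}),
        ("square_2J", {"J_short": -1.0, "J_long": -0.4}),
    ])
    def test_commutes_with_total_s2(self, preset, params):
        m = make_preset(preset, 1, params)
        tM = m.n_open % 2
        H = build_hamiltonian_sd(m, SiteOrdering.identity(m.n_sites), tM)
        ops = spin_operator_matrices(
            m.n_open, [[k] for k in range(m.n_open)], tM
        )
        S2 = ops.total_spin_squared()
        comm = (S2 @ H - H @ S2).toarray()
        assert np.linalg.norm(comm) < 1e-10


class TestSpinAdaptedHamiltonian:
    def test_dimer_site_separated_is_diagonal(self, dimer_singlet):
        H = dimer_singlet.matrix
        off = H - np.diag(np.diag(H))
        assert np.abs(off).max() < 1e-10 * np.abs(H).max()
        assert np.allclose(
            np.sort(np.diag(H)), [-3.75, -0.75, -0.75, -0.75, -0.75], atol=1e-9
        )

    def test_dimer_scrambled_orbitals_dense_but_isospectral(self, dimer_singlet):
        m = dimer_singlet.model
        H2 = build_hamiltonian_csf(
            m, SiteOrdering.identity(2), 0, orbital_permutation=[0, 4, 5, 1, 2, 3]
        )
        assert np.all(np.abs(H2.matrix) > 1e-12)  # fully dense
        assert np.allclose(
            np.sort(np.linalg.eigvalsh(H2.matrix)),
            np.sort(np.diag(dimer_singlet.matrix)),
            atol=1e-9,
        )

    def test_quartet_dimension(self, quartet_abc):
        assert quartet_abc.dim == 48

    def test_isospectrality_under_site_permutations(self):
        """All six site orderings of a scalene triangle give the same
        spin-adapted spectrum."""
        m = make_preset("scalene", 3, {"J_AB": -150.0, "J_AC": -50.0, "J_BC": -20.0})
        ref = None
        for perm in permutations(range(3)):
            H = build_hamiltonian_csf(m, SiteOrdering(perm), 3)
            ev = np.sort(np.linalg.eigvalsh(H.matrix))
            if ref is None:
                ref = ev
            else:
                assert np.allclose(ev, ref, rtol=1e-9, atol=1e-9)

    def test_equilateral_closed_form(self):
        """Equilateral s=1/2 triangle at J=-1: doublets at -3/4 (twice),
        quartet at +3/4 — E = ½[S(S+1) − 9/4]."""
        m = make_preset("equilateral", 1, {"J": -1.0})
        H2 = build_hamiltonian_csf(m, SiteOrdering.identity(3), 1)
        assert np.allclose(np.sort(np.linalg.eigvalsh(H2.matrix)), [-0.75, -0.75])
        H4 = build_hamiltonian_csf(m, SiteOrdering.identity(3), 3)
        assert np.allclose(np.linalg.eigvalsh(H4.matrix), [0.75])

    def test_hund_penalty_shifts_are_linear(self, isosceles_model):
        """J_Hund commutes with H (local spins are conserved), so raising it
        by Δ shifts each eigenvalue by −Δ·Σ_i⟨Σ_{p<q∈i} s_p·s_q⟩ exactly."""
        m0 = isosceles_model
        delta = 37.0
        m1 = ClusterModel(
            m0.site_twice_spins, m0.couplings, j_hund=delta, labels=m0.labels
        )
        o = SiteOrdering.identity(3)
        H0 = build_hamiltonian_csf(m0, o, 3)
        H1 = build_hamiltonian_csf(m1, o, 3)
        w0, V = np.linalg.eigh(H0.matrix)
        # Hund operator in the CSF basis
        hund = (H1.matrix - H0.matrix) / (-delta)
        shift = -delta * np.einsum("ij,jk,ki->i", V.T, hund, V)
        assert np.allclose(
            np.sort(w0 + shift), np.sort(np.linalg.eigvalsh(H1.matrix)), atol=1e-8
        )
        # doubling Δ doubles every gap change
        m2 = ClusterModel(
            m0.site_twice_spins, m0.couplings, j_hund=2 * delta, labels=m0.labels
        )
        H2 = build_hamiltonian_csf(m2, o, 3)
        assert np.allclose(
            np.sort(w0 + 2 * shift),
            np.sort(np.linalg.eigvalsh(H2.matrix)),
            atol=1e-8,
        )


def test_site_ordering_parsing(isosceles_model):
    o1 = SiteOrdering.from_labels("ACB", isosceles_model)
    o2 = SiteOrdering.from_labels("A,C,B", isosceles_model)
    assert o1 == o2 == SiteOrdering((0, 2, 1))
    assert o1.labels_for(isosceles_model) == "ACB"
    with pytest.raises(KeyError):
        SiteOrdering.from_labels("AXB", isosceles_model)
    with pytest.raises(ValueError):
        SiteOrdering((0, 0, 1))


def test_determinant_basis_sector_sizes():
    assert len(determinant_basis(6, 0)) == 20
    assert len(determinant_basis(9, 3)) == 84
    with pytest.raises(ValueError, match="infeasible"):
        determinant_basis(4, 1)
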