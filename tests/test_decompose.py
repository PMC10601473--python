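import numpy as np
import pytest

from edascan import GridSpec, asm_decompose, decompose_scan
from edascan.decompose import (
    DecompositionError,
    eda_decompose,
    elstat_interaction,
    homo_lumo_overlap,
    pauli_intermediate_density,
    pauli_repulsion,
)
from edascan.geometry import Geometry
from edascan.scan import run_rigid_scan
from edascan.units import HARTREE_TO_KCAL


class TestASM:
    def test_defining_identities(self):
        res = asm_decompose(-10.0, -4.0, -5.0, -4.5, -5.2, scale=1.0)
        assert res.dE_strain_A == pytest.approx(0.5)
        assert res.dE_strain_B == pytest.approx(0.2)
        assert res.dE_int == pytest.approx(-1.0)
        assert res.dE == pytest.approx(-0.3)
        assert res.dE == pytest.approx(res.dE_strain + res.dE_int)

    def test_noninteracting_limit_all_zero(self):
        res = asm_decompose(-7.7, -4.5, -3.2, -4.5, -3.2, scale=1.0)
        for v in (res.dE, res.dE_strain, res.dE_int):
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_kcal_scale(self):
        res = asm_decompose(-1.0, -0.25, -0.65, -0.25, -0.65)
        assert res.dE_int == pytest.approx(-0.1 * HARTREE_TO_KCAL)

    def test_mixed_provenance_rejected(self):
        with pytest.raises(DecompositionError):
            asm_decompose(-1, -0.5, -0.5, -0.5, -0.5,
                          provenance=["rhf:aaaa", "rhf:bbbb", "rhf:aaaa",
                                      "rhf:aaaa", "rhf:aaaa"])


def _fragment_setup(engine, gA, gB):
    """Dimer matrices plus fragment solutions at in-complex geometries."""
    comp = Geometry(
        gA.atoms + gB.atoms,
        np.vstack([gA.coords, gB.coords]),
        charge=gA.charge + gB.charge,
    )
    mats = engine.matrices(comp)
    solA = engine.compute_scf(gA)
    solB = engine.compute_scf(gB)
    idx_a = list(range(gA.natoms))
    idx_b = list(range(gA.natoms, comp.natoms))
    return comp, mats, solA, solB, idx_a, idx_b


class TestElstat:
    def test_point_charge_limit(self, rhf_engine):
        """Bare proton against hydride at 20 A: the frozen-density
        electrostatic interaction must approach q1 q2 / r."""
        gA = Geometry(["H"], [[0.0, 0.0, 0.0]], charge=1)       # no electrons
        gB = Geometry(["H"], [[0.0, 0.0, 20.0]], charge=-1)     # 2 electrons
        _, mats, solA, solB, ia, ib = _fragment_setup(rhf_engine, gA, gB)
        e = elstat_interaction(solA, solB, mats, ia, ib)
        from edascan.units import ang_to_bohr
        oracle = (1.0) * (-1.0) / ang_to_bohr(20.0)
        assert e * HARTREE_TO_KCAL == pytest.approx(
            oracle * HARTREE_TO_KCAL, abs=0.05
        )

    def test_neutral_fragments_vanish_at_long_range(self, rhf_engine):
        gA = Geometry(["He"], [[0.0, 0.0, 0.0]])
        gB = Geometry(["He"], [[0.0, 0.0, 30.0]])
        _, mats, solA, solB, ia, ib = _fragment_setup(rhf_engine, gA, gB)
        assert abs(elstat_interaction(solA, solB, mats, ia, ib)) < 1e-10

    def test_fragment_swap_symmetry(self, rhf_engine):
        gA = Geometry(["He"], [[0.0, 0.0, 0.0]])
        gB = Geometry(["H", "H"], [[0.0, 0.0, 2.8], [0.0, 0.0, 3.54]])
        _, mats, solA, solB, ia, ib = _fragment_setup(rhf_engine, gA, gB)
        e1 = elstat_interaction(solA, solB, mats, ia, ib)
        e2 = elstat_interaction(solB, solA, mats, ib, ia)
        assert e1 == pytest.approx(e2, abs=1e-10)
        p1 = pauli_repulsion(solA, solB, mats, rhf_engine, ia, ib)
        p2 = pauli_repulsion(solB, solA, mats, rhf_engine, ib, ia)
        assert p1 == pytest.approx(p2, abs=1e-10)


class TestPauli:
    def test_positive_for_overlapping_closed_shells(self, rhf_engine):
        d = 3.0 * 0.529177210903
        gA = Geometry(["He"], [[0.0, 0.0, 0.0]])
        gB = Geometry(["He"], [[0.0, 0.0, d]])
        _, mats, solA, solB, ia, ib = _fragment_setup(rhf_engine, gA, gB)
        assert pauli_repulsion(solA, solB, mats, rhf_engine, ia, ib) > 0.0

    def test_vanishes_at_long_range(self, rhf_engine):
        gA = Geometry(["He"], [[0.0, 0.0, 0.0]])
        gB = Geometry(["He"], [[0.0, 0.0, 50.0]])
        _, mats, solA, solB, ia, ib = _fragment_setup(rhf_engine, gA, gB)
        assert abs(
            pauli_repulsion(solA, solB, mats, rhf_engine, ia, ib)
        ) < 1e-8

    def test_intermediate_energy_against_determinant_oracle(self, rhf_engine):
        """E[Psi0] for He...He from an explicit Slater determinant:
        transform integrals to the orthonormalized occupied MO space and
        apply the closed-shell determinant energy expression directly."""
        d = 3.0 * 0.529177210903
        gA = Geometry(["He"], [[0.0, 0.0, 0.0]])
        gB = Geometry(["He"], [[0.0, 0.0, d]])
        _, mats, solA, solB, ia, ib = _fragment_setup(rhf_engine, gA, gB)
        D0 = pauli_intermediate_density(solA, solB, mats, ia, ib)
        e_engine = rhf_engine.energy_of_density(mats, D0)

        # independent route: explicit MO-basis contraction
        nao = mats.basis.nao
        CA = np.zeros((nao, 1))
        CA[[0], 0] = solA.orbital_coefficients[:, 0]
        CB = np.zeros((nao, 1))
        CB[[1], 0] = solB.orbital_coefficients[:, 0]
        C = np.hstack([CA, CB])
        Socc = C.T @ mats.S @ C
        w, U = np.linalg.eigh(Socc)
        C0 = C @ (U / np.sqrt(w)) @ U.T
        h_mo = C0.T @ mats.hcore @ C0
        eri_mo = np.einsum(
            "pqrs,pi,qj,rk,sl->ijkl", mats.eri, C0, C0, C0, C0,
            optimize=True,
        )
        nocc = 2
        e_det = 2.0 * np.trace(h_mo[:nocc, :nocc]) + mats.enuc
        for i in range(nocc):
            for j in range(nocc):
                e_det += 2.0 * eri_mo[i, i, j, j] - eri_mo[i, j, j, i]
        assert e_engine == pytest.approx(e_det, abs=1e-8)

    def test_singular_occupied_metric_rejected(self, rhf_engine):
        """Linearly dependent occupied blocks (the fused-fragment limit)
        must raise instead of silently orthonormalizing noise."""
        gA = Geometry(["He"], [[0.0, 0.0, 0.0]])
        gB = Geometry(["He"], [[0.0, 0.0, 5.0]])
        _, mats, solA, solB, ia, ib = _fragment_setup(rhf_engine, gA, gB)
        with pytest.raises(DecompositionError):
            pauli_intermediate_density(solA, solA, mats, ia, ia)


class TestEDA:
    def test_noninteracting_duplicate_fragments(self, rhf_engine):
        gA = Geometry(["He"], [[0.0, 0.0, 0.0]])
        gB = Geometry(["He"], [[0.0, 0.0, 100.0]])
        comp, mats, solA, solB, ia, ib = _fragment_setup(rhf_engine, gA, gB)
        solC = rhf_engine.compute_scf(comp, mats=mats)
        eda = eda_decompose(solA, solB, solC, mats, rhf_engine, ia, ib)
        tol = 1e-6 * HARTREE_TO_KCAL
        for v in (eda.dV_elstat, eda.dE_Pauli, eda.dE_oi, eda.dE_int):
            assert abs(v) < tol

    def test_closure_is_exact_and_oi_stabilizing(self, rhf_engine):
        d = 3.0 * 0.529177210903
        gA = Geometry(["He"], [[0.0, 0.0, 0.0]])
        gB = Geometry(["He"], [[0.0, 0.0, d]])
        comp, mats, solA, solB, ia, ib = _fragment_setup(rhf_engine, gA, gB)
        D0 = pauli_intermediate_density(solA, solB, mats, ia, ib)
        solC = rhf_engine.compute_scf(comp, guess=D0, mats=mats)
        eda = eda_decompose(solA, solB, solC, mats, rhf_engine, ia, ib)
        assert abs(
            eda.dV_elstat + eda.dE_Pauli + eda.dE_oi - eda.dE_int
        ) < 1e-10
        assert eda.dE_oi <= 1e-6 * HARTREE_TO_KCAL

    def test_unconverged_inputs_rejected(self, rhf_engine):
        gA = Geometry(["He"], [[0.0, 0.0, 0.0]])
        gB = Geometry(["He"], [[0.0, 0.0, 5.0]])
        _, mats, solA, solB, ia, ib = _fragment_setup(rhf_engine, gA, gB)
        solA.converged = False
        with pytest.raises(DecompositionError):
            elstat_interaction(solA, solB, mats, ia, ib)


class TestOverlap:
    def test_orbital_with_itself_is_one(self, rhf_engine):
        g = Geometry(["He"], [[0.0, 0.0, 0.0]])
        mats = rhf_engine.matrices(g)
        sol = rhf_engine.compute_scf(g, mats=mats)
        idx = np.arange(mats.basis.nao)
        res = homo_lumo_overlap(sol, sol, mats.S, idx, idx,
                                orbital_A=0, orbital_B=0)
        assert res.S == pytest.approx(1.0, abs=1e-10)

    def test_distant_fragments_vanishing_overlap(self, rhf_engine):
        gA = Geometry(["H", "H"], [[0, 0, 0], [0, 0, 0.74]])
        gB = Geometry(["H", "H"], [[0, 0, 50.0], [0, 0, 50.74]])
        _, mats, solA, solB, ia, ib = _fragment_setup(rhf_engine, gA, gB)
        aoA = mats.ao_indices_of_atoms(ia)
        aoB = mats.ao_indices_of_atoms(ib)
        res = homo_lumo_overlap(solA, solB, mats.S, aoA, aoB)
        assert res.S < 1e-10

    def test_bad_orbital_index(self, rhf_engine):
        g = Geometry(["He"], [[0.0, 0.0, 0.0]])
        mats = rhf_engine.matrices(g)
        sol = rhf_engine.compute_scf(g, mats=mats)
        idx = np.arange(mats.basis.nao)
        with pytest.raises(DecompositionError):
            homo_lumo_overlap(sol, sol, mats.S, idx, idx,
                              orbital_A=0, orbital_B=5)


class TestMockModeEquality:
    def test_terms_equal_mock_partial_sums(self, mock_pair, mock_engine):
        spec = GridSpec(2.2, 3.0, 0.4, 90.0, 120.0, 15.0)
        scan = run_rigid_scan(mock_pair, spec, mock_engine)
        table = decompose_scan(scan, mock_engine, analyses=("asm", "eda"))
        for row in table.itertuples(index=False):
            p = scan.point_at(row.r_angstrom, row.theta_deg)
            fp = scan.pair_template.with_geometry(p.geometry)
            t = mock_engine.interaction_terms(
                fp.complex_geometry, fp.fragment_A_indices,
                fp.fragment_B_indices,
            )
            assert row.V_elstat == pytest.approx(t.coulomb, rel=1e-12)
            assert row.E_pauli == pytest.approx(t.repulsion, rel=1e-12)
            assert row.E_oi == pytest.approx(t.attraction, rel=1e-12)
            # both closure identities
            assert row.dE == pytest.approx(
                row.dE_strain + row.dE_int, abs=1e-9
            )
            assert row.E_int == pytest.approx(
                row.V_elstat + row.E_pauli + row.E_oi, abs=1e-9
            )
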