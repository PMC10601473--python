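import math

import numpy as np
import pytest

from edascan.engine import EngineError, EngineSettings, MockEngine, RHFEngine
from edascan.engine.basis import STO3G, build_basis
from edascan.geometry import Geometry
from edascan.units import ANGSTROM_PER_BOHR


def h2(distance_bohr=1.4):
    return Geometry(
        ["H", "H"], [[0, 0, 0], [0, 0, distance_bohr * ANGSTROM_PER_BOHR]]
    )


class TestRHFEnergies:
    """Total energies against independent references.

    H2 (R = 1.4 bohr) and the He atom in this minimal basis are classic
    worked examples with well-known restricted Hartree-Fock energies;
    formaldehyde exercises s+p shells on three elements at once.
    """

    def test_h2_textbook_energy(self, rhf_engine):
        sol = rhf_engine.compute_scf(h2())
        assert sol.converged
        assert sol.energy == pytest.approx(-1.1167, abs=2e-4)

    def test_he_closed_form_oracle(self, rhf_engine):
        """One doubly occupied s function: E = 2 h11 + (11|11), where both
        integrals have closed forms for same-center s Gaussians."""
        _, exps, coefs = None, *STO3G["He"][0][1:]
        # normalized contraction coefficients (primitive norm (2a/pi)^{3/4})
        c = np.array([ci * (2 * ai / math.pi) ** 0.75
                      for ai, ci in zip(exps, coefs)])
        s = sum(
            ci * cj * (math.pi / (ai + aj)) ** 1.5
            for ai, ci in zip(exps, c) for aj, cj in zip(exps, c)
        )
        c /= math.sqrt(s)
        T = sum(
            ci * cj * 3.0 * ai * aj / (ai + aj)
            * (math.pi / (ai + aj)) ** 1.5
            for ai, ci in zip(exps, c) for aj, cj in zip(exps, c)
        )
        V = sum(
            ci * cj * (-2.0) * 2.0 * math.pi / (ai + aj)
            for ai, ci in zip(exps, c) for aj, cj in zip(exps, c)
        )
        J = sum(
            ci * cj * ck * cl
            * 2.0 * math.pi ** 2.5
            / ((ai + aj) * (ak + al) * math.sqrt(ai + aj + ak + al))
            for ai, ci in zip(exps, c) for aj, cj in zip(exps, c)
            for ak, ck in zip(exps, c) for al, cl in zip(exps, c)
        )
        e_oracle = 2.0 * (T + V) + J
        sol = rhf_engine.compute_scf(Geometry(["He"], [[0, 0, 0]]))
        assert sol.energy == pytest.approx(e_oracle, abs=1e-10)

    def test_h2_bound(self, rhf_engine):
        sol = rhf_engine.compute_scf(h2(1.4))
        assert sol.converged and sol.energy < 0.0

    def test_determinism(self, rhf_engine):
        g = h2(1.5)
        e1 = rhf_engine.compute_scf(g).energy
        e2 = rhf_engine.compute_scf(g.copy()).energy
        assert e1 == e2

    def test_open_shell_rejected(self, rhf_engine):
        with pytest.raises(EngineError):
            rhf_engine.compute_scf(Geometry(["H"], [[0, 0, 0]]))

    def test_translation_rotation_invariance(self, rhf_engine, rng):
        g = Geometry(
            ["O", "H", "H"],
            [[0, 0, 0.1], [0, 0.76, -0.5], [0, -0.7, -0.55]],
        )
        e0 = rhf_engine.compute_scf(g).energy
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        g2 = g.copy()
        g2.coords = g.coords @ q.T + np.array([3.0, -1.0, 2.0])
        assert rhf_engine.compute_scf(g2).energy == pytest.approx(e0, abs=1e-8)

    def test_variational_bound_for_trial_density(self, rhf_engine):
        """Any idempotent closed-shell trial density has E[D] >= E_SCF."""
        g = h2(1.6)
        mats = rhf_engine.matrices(g)
        sol = rhf_engine.compute_scf(g, mats=mats)
        # trial: occupy the core-guess orbital instead of the SCF one
        h = mats.hcore
        sval, svec = np.linalg.eigh(mats.S)
        X = svec / np.sqrt(sval)
        _, C = np.linalg.eigh(X.T @ h @ X)
        C = X @ C
        D_trial = 2.0 * np.outer(C[:, 0], C[:, 0])
        assert rhf_engine.energy_of_density(mats, D_trial) >= sol.energy - 1e-12


class TestMatrices:
    def test_overlap_normalized_diagonal(self, rhf_engine):
        g = Geometry(["C", "O"], [[0, 0, 0], [1.2, 0, 0]])
        mats = rhf_engine.matrices(g)
        np.testing.assert_allclose(np.diag(mats.S), 1.0, atol=1e-10)

    def test_overlap_limits(self, rhf_engine):
        near = rhf_engine.matrices(
            Geometry(["H", "H"], [[0, 0, 0], [0, 0, 0.31]])
        ).S[0, 1]
        far = rhf_engine.matrices(
            Geometry(["H", "H"], [[0, 0, 0], [0, 0, 40.0]])
        ).S[0, 1]
        assert near > 0.9
        assert abs(far) < 1e-12

    def test_h_1s_overlap_quadrature_oracle(self, rhf_engine):
        """Contracted 1s-1s overlap at 1.4 bohr against numerical
        quadrature of the orbital product on a radial-z grid."""
        d = 1.4 * ANGSTROM_PER_BOHR
        mats = rhf_engine.matrices(
            Geometry(["H", "H"], [[0, 0, 0], [0, 0, d]])
        )
        _, exps, coefs = None, *STO3G["H"][0][1:]
        c = np.array([ci * (2 * ai / math.pi) ** 0.75
                      for ai, ci in zip(exps, coefs)])
        norm = sum(
            ci * cj * (math.pi / (ai + aj)) ** 1.5
            for ai, ci in zip(exps, c) for aj, cj in zip(exps, c)
        )
        c /= math.sqrt(norm)

        def phi(z, rho, center_z):
            r2 = rho ** 2 + (z - center_z) ** 2
            return sum(ci * np.exp(-ai * r2) for ai, ci in zip(exps, c))

        z = np.linspace(-10, 12, 901)
        rho = np.linspace(0, 8, 401)
        Z, RHO = np.meshgrid(z, rho, indexing="ij")
        integrand = 2 * math.pi * RHO * phi(Z, RHO, 0.0) * phi(Z, RHO, 1.4)
        val = np.trapezoid(np.trapezoid(integrand, rho, axis=1), z)
        assert mats.S[0, 1] == pytest.approx(val, abs=5e-5)

    def test_overlap_spd(self, rhf_engine):
        g = Geometry(["C", "O"], [[0, 0, 0], [1.2, 0, 0]])
        S = rhf_engine.matrices(g).S
        np.testing.assert_allclose(S, S.T, atol=1e-12)
        assert np.linalg.eigvalsh(S).min() > 0

    def test_eri_permutation_symmetry(self, rhf_engine):
        g = Geometry(["C", "O"], [[0, 0, 0], [1.2, 0, 0]])
        eri = rhf_engine.matrices(g).eri
        rng = np.random.default_rng(7)
        for _ in range(30):
            i, j, k, l = rng.integers(0, eri.shape[0], 4)
            v = eri[i, j, k, l]
            assert eri[j, i, k, l] == pytest.approx(v, rel=1e-10, abs=1e-14)
            assert eri[k, l, i, j] == pytest.approx(v, rel=1e-10, abs=1e-14)


class TestGradient:
    def test_matches_finite_differences(self, rhf_engine):
        g = Geometry(
            ["O", "H", "H"],
            [[0, 0, 0.1], [0, 0.76, -0.5], [0, -0.7, -0.55]],
        )
        grad = rhf_engine.gradient(g)
        h = 2e-4
        for (i, d) in [(0, 2), (1, 1), (2, 0)]:
            gp, gm = g.copy(), g.copy()
            gp.coords[i, d] += h
            gm.coords[i, d] -= h
            num = (
                rhf_engine.compute_scf(gp).energy
                - rhf_engine.compute_scf(gm).energy
            ) / (2 * h) * ANGSTROM_PER_BOHR
            assert grad[i, d] == pytest.approx(num, abs=5e-7)

    def test_zero_net_force(self, rhf_engine):
        g = Geometry(
            ["O", "H", "H"],
            [[0, 0, 0.1], [0, 0.76, -0.5], [0, -0.7, -0.55]],
        )
        grad = rhf_engine.gradient(g)
        np.testing.assert_allclose(grad.sum(axis=0), 0.0, atol=1e-9)


class TestMockEngine:
    def test_pure_repulsion_closed_form(self, mock_engine):
        from edascan.engine.mock import MockParams

        eng = MockEngine(MockParams.from_dict({"He": (0.0, 50.0, 0.0)}))
        g = Geometry(["He", "He"], [[0, 0, 0], [0, 0, 2.0]])
        assert eng.energy(g) == pytest.approx(50.0 / 2.0 ** 12, rel=1e-12)

    def test_coulomb_law(self):
        from edascan.engine.mock import MockParams

        eng = MockEngine(MockParams.from_dict({
            "H": (1.0, 0.0, 0.0), "O": (-1.0, 0.0, 0.0),
        }))
        g = Geometry(["H", "O"], [[0, 0, 0], [0, 0, 10.0]])
        t = eng.interaction_terms(g, [0], [1])
        assert t.coulomb == pytest.approx(-0.1, rel=1e-12)
        assert t.repulsion == 0.0 and t.attraction == 0.0

    def test_brute_force_pair_sum(self, mock_engine, rng):
        atoms = ["H", "C", "N", "O", "H"]
        coords = rng.uniform(-3, 3, size=(5, 3))
        coords += np.arange(5)[:, None] * 2.0  # keep atoms apart
        g = Geometry(atoms, coords)
        table = mock_engine.params.as_dict()
        expected = 0.0
        for i in range(5):
            for j in range(i + 1, 5):
                qi, Ai, Bi = table[atoms[i]]
                qj, Aj, Bj = table[atoms[j]]
                d = np.linalg.norm(coords[i] - coords[j])
                expected += (
                    qi * qj / d
                    + math.sqrt(Ai * Aj) / d ** 12
                    - math.sqrt(Bi * Bj) / d ** 6
                )
        assert mock_engine.energy(g) == pytest.approx(expected, rel=1e-12)

    def test_partial_sums_reconstruct_total(self, mock_engine):
        g = Geometry(
            ["C", "N", "O", "H"],
            [[0, 0, 0], [0, 0, 1.2], [3, 0, 0], [3, 0, 1.0]],
        )
        t = mock_engine.interaction_terms(g, [0, 1], [2, 3])
        e_ab = mock_engine.energy(g)
        ga = Geometry(["C", "N"], [[0, 0, 0], [0, 0, 1.2]])
        gb = Geometry(["O", "H"], [[3, 0, 0], [3, 0, 1.0]])
        e_a = mock_engine.energy(ga)
        e_b = mock_engine.energy(gb)
        assert t.total == pytest.approx(e_ab - e_a - e_b, rel=1e-12)

    def test_invariance(self, mock_engine, rng):
        g = Geometry(
            ["C", "N", "O"], [[0, 0, 0], [0, 0, 1.2], [2.5, 0, 0]]
        )
        e0 = mock_engine.energy(g)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        g2 = g.copy()
        g2.coords = g.coords @ q.T + 5.0
        assert mock_engine.energy(g2) == pytest.approx(e0, abs=1e-10)

    def test_gradient_matches_finite_differences(self, mock_engine):
        g = Geometry(
            ["C", "N", "O"], [[0, 0, 0], [0, 0, 1.3], [2.2, 0.4, 0]]
        )
        grad = mock_engine.gradient(g)
        h = 1e-6
        for (i, d) in [(0, 0), (1, 2), (2, 1)]:
            gp, gm = g.copy(), g.copy()
            gp.coords[i, d] += h
            gm.coords[i, d] -= h
            num = (mock_engine.energy(gp) - mock_engine.energy(gm)) / (2 * h)
            assert grad[i, d] == pytest.approx(num, abs=1e-6)

    def test_missing_element_parameters(self, mock_engine):
        with pytest.raises(EngineError):
            mock_engine.energy(Geometry(["Kr"], [[0, 0, 0]]))


class TestBasis:
    def test_ao_counts(self):
        basis = build_basis(Geometry(["C", "O"], [[0, 0, 0], [1.2, 0, 0]]))
        assert basis.nao == 10  # 5 per first-row heavy atom

    def test_unknown_basis(self):
        from edascan.engine.basis import BasisError

        with pytest.raises(BasisError):
            build_basis(h2(), "cc-pvqz")

    def test_settings_validation(self):
        with pytest.raises(EngineError):
            EngineSettings(scf_tolerance=-1.0)
        with pytest.raises(EngineError):
            RHFEngine(EngineSettings(method="dft"))
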