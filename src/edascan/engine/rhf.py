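"""Built-in restricted Hartree-Fock engine.

Closed-shell RHF over contracted Gaussians with a GWH starting guess,
Pulay DIIS acceleration (damping + level-shift fallback), and analytic
nuclear gradients from the density-contracted derivative integrals.

The engine exposes, besides ``compute_scf``, the raw matrices (overlap, core
Hamiltonian, two-electron tensor, per-fragment nuclear attraction) required
by the energy decomposition layer, and a non-self-consistent energy
functional used for the antisymmetrized intermediate state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..geometry import Geometry
from ..units import ang_to_bohr
from .base import EngineError, EngineSettings, SCFSolution
from .basis import BasisSet, build_basis
from .integrals import IntegralContext

_GWH_K = 1.75
_S_LINDEP = 1e-8


@dataclass
class EngineMatrices:
    """Molecular integrals for one geometry (atomic units)."""

    geometry: Geometry
    basis: BasisSet
    S: np.ndarray
    T: np.ndarray
    V: np.ndarray
    eri: np.ndarray
    enuc: float
    _context: IntegralContext = None

    @property
    def hcore(self) -> np.ndarray:
        return self.T + self.V

    def coulomb(self, D: np.ndarray) -> np.ndarray:
        return np.einsum("ijkl,kl->ij", self.eri, D, optimize=True)

    def exchange(self, D: np.ndarray) -> np.ndarray:
        return np.einsum("ikjl,kl->ij", self.eri, D, optimize=True)

    def fock(self, D: np.ndarray) -> np.ndarray:
        return self.hcore + self.coulomb(D) - 0.5 * self.exchange(D)

    def nuclear_attraction_subset(self, atom_indices) -> np.ndarray:
        """Attraction matrix generated by a subset of this geometry's nuclei."""
        g = self.geometry
        idx = list(atom_indices)
        xyz = ang_to_bohr(g.coords[idx])
        Z = g.atomic_numbers[idx].astype(float)
        return self._context.nuclear_attraction(xyz, Z)

    def ao_indices_of_atoms(self, atom_indices) -> np.ndarray:
        wanted = set(int(i) for i in atom_indices)
        return np.array(
            [k for k, a in enumerate(self.basis.ao_atom) if int(a) in wanted],
            dtype=int,
        )


def _nuclear_repulsion(xyz_bohr: np.ndarray, Z: np.ndarray) -> float:
    e = 0.0
    n = len(Z)
    for i in range(n):
        for j in range(i):
            e += Z[i] * Z[j] / np.linalg.norm(xyz_bohr[i] - xyz_bohr[j])
    return float(e)


def _nuclear_repulsion_grad(xyz_bohr: np.ndarray, Z: np.ndarray) -> np.ndarray:
    n = len(Z)
    g = np.zeros((n, 3))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            rij = xyz_bohr[i] - xyz_bohr[j]
            g[i] -= Z[i] * Z[j] * rij / np.linalg.norm(rij) ** 3
    return g


class RHFEngine:
    """Restricted Hartree-Fock engine over the built-in Gaussian basis."""

    def __init__(self, settings: EngineSettings | None = None):
        self.settings = settings or EngineSettings()
        if self.settings.method.lower() not in ("rhf", "hf"):
            raise EngineError(
                f"built-in engine implements RHF, not {self.settings.method!r}"
            )
        self._mat_cache_key = None
        self._mat_cache = None
        self.ncalls = 0  # compute_scf/gradient invocations (cache audits)

    @property
    def hash(self) -> str:
        return "rhf:" + self.settings.hash()

    # -- integrals ---------------------------------------------------------

    def matrices(self, geometry: Geometry) -> EngineMatrices:
        key = (geometry.coords.tobytes(), tuple(geometry.atoms),
               self.settings.basis)
        if key == self._mat_cache_key:
            return self._mat_cache
        basis = build_basis(geometry, self.settings.basis)
        ctx = IntegralContext(basis)
        S, T = ctx.overlap_kinetic()
        xyz = ang_to_bohr(geometry.coords)
        Z = geometry.atomic_numbers.astype(float)
        V = ctx.nuclear_attraction(xyz, Z)
        eri = ctx.eri()
        mats = EngineMatrices(
            geometry=geometry, basis=basis, S=S, T=T, V=V, eri=eri,
            enuc=_nuclear_repulsion(xyz, Z), _context=ctx,
        )
        self._mat_cache_key = key
        self._mat_cache = mats
        return mats

    def overlap_matrix(self, geometry: Geometry):
        """Dimer overlap matrix and basis only (no two-electron work);
        sufficient for fragment-orbital overlap diagnostics."""
        basis = build_basis(geometry, self.settings.basis)
        ctx = IntegralContext(basis)
        S, _ = ctx.overlap_kinetic()
        return S, basis

    # -- SCF ---------------------------------------------------------------

    def compute_scf(
        self,
        geometry: Geometry,
        guess: np.ndarray | None = None,
        mats: EngineMatrices | None = None,
    ) -> SCFSolution:
        if geometry.n_electrons % 2 != 0 or geometry.multiplicity != 1:
            raise EngineError(
                "restricted closed-shell engine requires an even electron "
                "count and singlet multiplicity"
            )
        self.ncalls += 1
        mats = mats if mats is not None else self.matrices(geometry)
        nocc = geometry.n_electrons // 2
        if nocc > mats.basis.nao:
            raise EngineError("more occupied orbitals than basis functions")

        out = self._scf_loop(mats, nocc, guess, damping=0.2, shift=0.0)
        if not out["converged"]:
            out = self._scf_loop(
                mats, nocc, out["D"], damping=0.5, shift=0.3
            )
        C, eps, D = out["C"], out["eps"], out["D"]
        occ = np.zeros(len(eps))
        occ[:nocc] = 2.0
        return SCFSolution(
            energy=out["energy"],
            converged=out["converged"],
            orbital_coefficients=C,
            orbital_energies=eps,
            occupations=occ,
            basis_labels=list(mats.basis.ao_labels),
            engine_hash=self.hash,
            extras={"enuc": mats.enuc, "nao": mats.basis.nao},
        )

    def _scf_loop(self, mats, nocc, guess, damping, shift):
        S, h = mats.S, mats.hcore
        sval, svec = np.linalg.eigh(S)
        keep = sval > _S_LINDEP
        X = svec[:, keep] / np.sqrt(sval[keep])
        tol = self.settings.scf_tolerance
        err_tol = max(1e-7, 100.0 * tol)

        if guess is not None:
            D = guess.copy()
        else:
            hd = np.diag(h)
            F0 = 0.5 * _GWH_K * (hd[:, None] + hd[None, :]) * S
            np.fill_diagonal(F0, hd)
            D = self._density_from_fock(F0, X, nocc)

        e_old = 0.0
        diis_F, diis_E = [], []
        converged = False
        energy = 0.0
        C = eps = None
        for it in range(self.settings.max_scf_cycles):
            F = mats.fock(D)
            energy = 0.5 * np.einsum("ij,ij->", D, h + F) + mats.enuc
            err = X.T @ (F @ D @ S - S @ D @ F) @ X
            err_max = np.abs(err).max()
            if it > 0 and abs(energy - e_old) < tol and err_max < err_tol:
                converged = True
            e_old = energy

            diis_F.append(F.copy())
            diis_E.append(err.copy())
            if len(diis_F) > 8:
                diis_F.pop(0)
                diis_E.pop(0)
            if len(diis_F) >= 2 and err_max < 1.0:
                F_eff = self._diis_extrapolate(diis_F, diis_E)
            else:
                F_eff = F
            if shift > 0.0:
                # level shift on virtual space via density projector
                F_eff = F_eff + shift * (S - 0.5 * S @ D @ S / max(nocc, 1))
            C, eps = self._solve_fock(F_eff, X)
            D_new = 2.0 * C[:, :nocc] @ C[:, :nocc].T
            if converged:
                D = D_new
                break
            D = (1.0 - damping) * D_new + damping * D if it < 4 else D_new

        # final canonical orbitals/energies from the unshifted Fock operator
        F = mats.fock(D)
        C, eps = self._solve_fock(F, X)
        D_fin = 2.0 * C[:, :nocc] @ C[:, :nocc].T
        energy = 0.5 * np.einsum("ij,ij->", D_fin, h + mats.fock(D_fin)) \
            + mats.enuc
        return {
            "energy": float(energy), "converged": converged,
            "C": C, "eps": eps, "D": D_fin,
        }

    @staticmethod
    def _solve_fock(F, X):
        Fp = X.T @ F @ X
        eps, Cp = np.linalg.eigh(Fp)
        return X @ Cp, eps

    def _density_from_fock(self, F, X, nocc):
        C, _ = self._solve_fock(F, X)
        return 2.0 * C[:, :nocc] @ C[:, :nocc].T

    @staticmethod
    def _diis_extrapolate(Fs, Es):
        n = len(Fs)
        B = -np.ones((n + 1, n + 1))
        B[n, n] = 0.0
        for i in range(n):
            for j in range(n):
                B[i, j] = np.einsum("ij,ij->", Es[i], Es[j])
        rhs = np.zeros(n + 1)
        rhs[n] = -1.0
        try:
            c = np.linalg.solve(B, rhs)[:n]
        except np.linalg.LinAlgError:
            return Fs[-1]
        return sum(ci * Fi for ci, Fi in zip(c, Fs))

    # -- derived quantities ------------------------------------------------

    def energy_of_density(self, mats: EngineMatrices, D: np.ndarray) -> float:
        """Non-self-consistent HF energy functional of an idempotent density."""
        F = mats.fock(D)
        return float(0.5 * np.einsum("ij,ij->", D, mats.hcore + F) + mats.enuc)

    def gradient(
        self,
        geometry: Geometry,
        sol: SCFSolution | None = None,
        mats: EngineMatrices | None = None,
        skip_atoms=None,
    ) -> np.ndarray:
        """Analytic nuclear gradient in hartree/bohr, one row per atom.

        ``skip_atoms`` marks atoms whose force the caller does not need
        (pinned or symmetry-slaved); their rows are not fully accumulated.
        """
        self.ncalls += 1
        mats = mats if mats is not None else self.matrices(geometry)
        if sol is None:
            sol = self.compute_scf(geometry, mats=mats)
        if not sol.converged:
            raise EngineError("gradient requested for unconverged SCF")
        C = sol.orbital_coefficients
        occ = sol.occupations
        D = (C * occ) @ C.T
        W = (C * (occ * sol.orbital_energies)) @ C.T
        xyz = ang_to_bohr(geometry.coords)
        Z = geometry.atomic_numbers.astype(float)
        skip = None
        if skip_atoms is not None:
            skip = np.zeros(geometry.natoms, dtype=bool)
            skip[list(skip_atoms)] = True
        grad = mats._context.gradient(xyz, Z, D, W, skip=skip)
        grad += _nuclear_repulsion_grad(xyz, Z)
        return grad
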