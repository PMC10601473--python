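"""Activation-strain and energy decomposition analyses.

Two nested decompositions are implemented.

Strain/interaction split of the total energy change relative to relaxed,
infinitely separated fragments:

    dE = dE_strain + dE_int,
    dE_strain = [E_A(distorted) - E_A(relaxed)] + [E_B(distorted) - E_B(relaxed)],
    dE_int    = E_complex - E_A(distorted) - E_B(distorted).

Ziegler-Rauk-type split of the interaction energy:

    dE_int = dV_elstat + dE_Pauli + dE_oi,

where dV_elstat is the quasi-classical electrostatic interaction of the
frozen, unrelaxed fragment charge distributions; dE_Pauli is the energy rise
upon antisymmetrizing and renormalizing the product of fragment determinants
(built here by symmetric Loewdin orthonormalization of the union of occupied
fragment orbitals, evaluated non-self-consistently); and dE_oi, the orbital
interaction, is defined as the closure remainder so any decomposition error
appears in the reported residual rather than silently in a term.

Sign convention: stabilizing contributions are negative.  Public results are
in kcal/mol (mock-engine results stay in the mock's own energy unit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine.base import EngineError, SCFSolution
from .engine.mock import MockEngine
from .geometry import FragmentPair
from .scan import ScanResult
from .units import HARTREE_TO_KCAL, ang_to_bohr

__all__ = [
    "ASMResult",
    "EDAResult",
    "OverlapResult",
    "asm_decompose",
    "elstat_interaction",
    "pauli_repulsion",
    "eda_decompose",
    "homo_lumo_overlap",
    "decompose_scan",
]


class DecompositionError(RuntimeError):
    pass


@dataclass
class ASMResult:
    """Strain/interaction split, kcal/mol (or mock units for the mock engine)."""

    dE: float
    dE_strain_A: float
    dE_strain_B: float
    dE_strain: float
    dE_int: float


@dataclass
class EDAResult:
    """Interaction-energy decomposition, kcal/mol.

    closure_residual = dV_elstat + dE_Pauli + dE_oi - dE_int; identically
    ~0 because dE_oi is the closure remainder, reported as a diagnostic.
    """

    dV_elstat: float
    dE_Pauli: float
    dE_oi: float
    dE_int: float
    closure_residual: float


@dataclass
class OverlapResult:
    S: float
    orbital_A_label: str
    orbital_B_label: str


def asm_decompose(
    E_complex: float,
    E_A_distorted: float,
    E_B_distorted: float,
    E_A_relaxed: float,
    E_B_relaxed: float,
    scale: float = HARTREE_TO_KCAL,
    provenance=None,
) -> ASMResult:
    """Strain/interaction split of five total energies (input hartree).

    ``provenance``, if given, is a sequence of engine hashes for the five
    energies; mixing engines is rejected.
    """
    if provenance is not None:
        tags = {t for t in provenance if t}
        if len(tags) > 1:
            raise DecompositionError(
                f"energies from different engines cannot be mixed: {tags}"
            )
    sA = E_A_distorted - E_A_relaxed
    sB = E_B_distorted - E_B_relaxed
    dint = E_complex - E_A_distorted - E_B_distorted
    dE = E_complex - E_A_relaxed - E_B_relaxed
    return ASMResult(
        dE=dE * scale,
        dE_strain_A=sA * scale,
        dE_strain_B=sB * scale,
        dE_strain=(sA + sB) * scale,
        dE_int=dint * scale,
    )


def _padded_density(sol: SCFSolution, ao_idx: np.ndarray, nao: int) -> np.ndarray:
    D = np.zeros((nao, nao))
    D[np.ix_(ao_idx, ao_idx)] = sol.density
    return D


def _padded_coeff(sol: SCFSolution, cols, ao_idx: np.ndarray,
                  nao: int) -> np.ndarray:
    C = np.zeros((nao, len(np.atleast_1d(cols))))
    C[ao_idx, :] = sol.orbital_coefficients[:, np.atleast_1d(cols)]
    return C


def _require_converged(*sols):
    for s in sols:
        if not s.converged:
            raise DecompositionError(
                "unconverged fragment/complex solution passed to EDA"
            )


def _cross_nuclear(geom, idx_a, idx_b) -> float:
    xyz = ang_to_bohr(geom.coords)
    Z = geom.atomic_numbers.astype(float)
    e = 0.0
    for i in idx_a:
        for j in idx_b:
            e += Z[i] * Z[j] / np.linalg.norm(xyz[i] - xyz[j])
    return float(e)


def elstat_interaction(
    solA: SCFSolution,
    solB: SCFSolution,
    mats,
    idx_a,
    idx_b,
) -> float:
    """Quasi-classical electrostatic interaction of frozen fragment densities.

    Returns hartree:  V_nn(cross) + <rho_A|v_nuc,B> + <rho_B|v_nuc,A>
    + J(rho_A, rho_B), symmetric under A<->B exchange.
    """
    _require_converged(solA, solB)
    idx_a = sorted(int(i) for i in idx_a)
    idx_b = sorted(int(i) for i in idx_b)
    nao = mats.basis.nao
    aoA = mats.ao_indices_of_atoms(idx_a)
    aoB = mats.ao_indices_of_atoms(idx_b)
    DA = _padded_density(solA, aoA, nao)
    DB = _padded_density(solB, aoB, nao)
    VA = mats.nuclear_attraction_subset(idx_a)
    VB = mats.nuclear_attraction_subset(idx_b)
    e = _cross_nuclear(mats.geometry, idx_a, idx_b)
    e += float(np.einsum("ij,ij->", DA, VB))
    e += float(np.einsum("ij,ij->", DB, VA))
    e += float(np.einsum("ij,ij->", DA, mats.coulomb(DB)))
    return e


def pauli_intermediate_density(solA, solB, mats, idx_a, idx_b) -> np.ndarray:
    """Density of the antisymmetrized, renormalized fragment determinant.

    Occupied orbitals of both fragments, zero-padded onto the dimer AO
    basis (exact: the fragments occupy disjoint atom sets), are symmetrically
    Loewdin-orthonormalized under the dimer overlap metric.
    """
    nao = mats.basis.nao
    aoA = mats.ao_indices_of_atoms(sorted(idx_a))
    aoB = mats.ao_indices_of_atoms(sorted(idx_b))
    CA = _padded_coeff(solA, range(solA.n_occupied), aoA, nao)
    CB = _padded_coeff(solB, range(solB.n_occupied), aoB, nao)
    C = np.hstack([CA, CB])
    Socc = C.T @ mats.S @ C
    w, U = np.linalg.eigh(Socc)
    if w.min() < 1e-10:
        g = mats.geometry
        raise DecompositionError(
            "occupied-orbital overlap numerically singular (fragments fused) "
            f"for complex with {g.natoms} atoms; smallest metric eigenvalue "
            f"{w.min():.3e}"
        )
    C0 = C @ (U / np.sqrt(w)) @ U.T
    return 2.0 * C0 @ C0.T


def pauli_repulsion(
    solA: SCFSolution,
    solB: SCFSolution,
    mats,
    engine,
    idx_a,
    idx_b,
    elstat: float | None = None,
) -> float:
    """Pauli (exchange) repulsion, hartree.

    E[Psi0] - E_A - E_B - dV_elstat, with E[Psi0] the full-system energy
    functional evaluated non-self-consistently on the idempotent density of
    the orthonormalized fragment-orbital determinant.
    """
    _require_converged(solA, solB)
    D0 = pauli_intermediate_density(solA, solB, mats, idx_a, idx_b)
    e0 = engine.energy_of_density(mats, D0)
    if elstat is None:
        elstat = elstat_interaction(solA, solB, mats, idx_a, idx_b)
    return float(e0 - solA.energy - solB.energy - elstat)


def eda_decompose(
    solA: SCFSolution,
    solB: SCFSolution,
    sol_complex: SCFSolution,
    mats,
    engine,
    idx_a,
    idx_b,
    scale: float = HARTREE_TO_KCAL,
) -> EDAResult:
    """Full interaction-energy decomposition for one geometry (kcal/mol)."""
    _require_converged(solA, solB, sol_complex)
    dint = sol_complex.energy - solA.energy - solB.energy
    elstat = elstat_interaction(solA, solB, mats, idx_a, idx_b)
    pauli = pauli_repulsion(solA, solB, mats, engine, idx_a, idx_b,
                            elstat=elstat)
    oi = dint - elstat - pauli
    residual = elstat + pauli + oi - dint
    return EDAResult(
        dV_elstat=elstat * scale,
        dE_Pauli=pauli * scale,
        dE_oi=oi * scale,
        dE_int=dint * scale,
        closure_residual=residual * scale,
    )


def homo_lumo_overlap(
    solA: SCFSolution,
    solB: SCFSolution,
    S_dimer: np.ndarray,
    ao_idx_a: np.ndarray,
    ao_idx_b: np.ndarray,
    orbital_A: int | None = None,
    orbital_B: int | None = None,
) -> OverlapResult:
    """|<phi_A| phi_B>| between fragment orbitals in the dimer basis.

    Defaults to HOMO of fragment A (nucleophile) against LUMO of fragment B
    (acceptor).  The magnitude is reported; the phase of either orbital is
    arbitrary.
    """
    _require_converged(solA, solB)
    nao = S_dimer.shape[0]
    ia = solA.homo_index if orbital_A is None else orbital_A
    ib = solB.lumo_index if orbital_B is None else orbital_B
    for sol, i in ((solA, ia), (solB, ib)):
        if not (0 <= i < sol.orbital_coefficients.shape[1]):
            raise DecompositionError(f"orbital index {i} out of range")
    cA = _padded_coeff(solA, [ia], ao_idx_a, nao)[:, 0]
    cB = _padded_coeff(solB, [ib], ao_idx_b, nao)[:, 0]
    S = float(abs(cA @ S_dimer @ cB))

    def _label(sol, i, name):
        if i == sol.homo_index:
            return f"HOMO({name})"
        if i == sol.lumo_index:
            return f"LUMO({name})"
        return f"MO{i}({name})"

    return OverlapResult(
        S=S,
        orbital_A_label=_label(solA, ia, "A"),
        orbital_B_label=_label(solB, ib, "B"),
    )


# ---------------------------------------------------------------------------
# scan-level driver


def _mock_point_eda(engine: MockEngine, pair: FragmentPair) -> EDAResult:
    t = engine.interaction_terms(
        pair.complex_geometry, pair.fragment_A_indices,
        pair.fragment_B_indices,
    )
    return EDAResult(
        dV_elstat=t.coulomb,
        dE_Pauli=t.repulsion,
        dE_oi=t.attraction,
        dE_int=t.total,
        closure_residual=0.0,
    )


def decompose_scan(
    scan: ScanResult,
    engine,
    analyses=("asm", "eda", "overlap"),
    progress=None,
) -> pd.DataFrame:
    """Per-point ASM/EDA/overlap table for a completed scan.

    Columns: r_angstrom, theta_deg plus dE, dE_strain_A/B, dE_strain, dE_int
    (kcal/mol), V_elstat, E_pauli, E_oi, E_int, closure_residual (kcal/mol)
    and S_homo_lumo.  Failed scan points yield NaN rows.
    """
    is_mock = isinstance(engine, MockEngine)
    rows = []
    for p in scan.points:
        row = {"r_angstrom": p.r, "theta_deg": p.theta, "status": p.status}
        if p.status == "converged":
            if "asm" in analyses:
                scale = 1.0 if is_mock else HARTREE_TO_KCAL
                asm = asm_decompose(
                    p.E_complex, p.E_A_dist, p.E_B_dist,
                    scan.E_A_relaxed, scan.E_B_relaxed, scale=scale,
                )
                row.update(
                    dE=asm.dE, dE_strain_A=asm.dE_strain_A,
                    dE_strain_B=asm.dE_strain_B, dE_strain=asm.dE_strain,
                    dE_int=asm.dE_int,
                )
            if ("eda" in analyses) or ("overlap" in analyses):
                pair = scan.pair_template.with_geometry(p.geometry)
                if is_mock:
                    if "eda" in analyses:
                        eda = _mock_point_eda(engine, pair)
                        row.update(
                            V_elstat=eda.dV_elstat, E_pauli=eda.dE_Pauli,
                            E_oi=eda.dE_oi, E_int=eda.dE_int,
                            closure_residual=eda.closure_residual,
                        )
                else:
                    try:
                        row.update(_rhf_point_analyses(
                            engine, pair, analyses
                        ))
                    except (DecompositionError, EngineError):
                        row["status"] = "failed"
        rows.append(row)
        if progress:
            progress(row)
    return pd.DataFrame(rows)


def _rhf_point_analyses(engine, pair: FragmentPair, analyses) -> dict:
    mats = engine.matrices(pair.complex_geometry)
    gA = pair.fragment_geometry("A")
    gB = pair.fragment_geometry("B")
    solA = engine.compute_scf(gA)
    solB = engine.compute_scf(gB)
    out = {}
    if "eda" in analyses:
        D0 = pauli_intermediate_density(
            solA, solB, mats, pair.fragment_A_indices, pair.fragment_B_indices
        )
        sol_c = engine.compute_scf(pair.complex_geometry, guess=D0, mats=mats)
        eda = eda_decompose(
            solA, solB, sol_c, mats, engine,
            pair.fragment_A_indices, pair.fragment_B_indices,
        )
        out.update(
            V_elstat=eda.dV_elstat, E_pauli=eda.dE_Pauli, E_oi=eda.dE_oi,
            E_int=eda.dE_int, closure_residual=eda.closure_residual,
        )
    if "overlap" in analyses:
        ov = homo_lumo_overlap(
            solA, solB, mats.S,
            mats.ao_indices_of_atoms(sorted(pair.fragment_A_indices)),
            mats.ao_indices_of_atoms(sorted(pair.fragment_B_indices)),
        )
        out["S_homo_lumo"] = ov.S
    return out
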