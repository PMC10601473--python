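"""Desk-scale study protocols for the cyanide/acetone model system.

These functions fix the problem sizes used for the reduced-level (RHF,
minimal basis) reproduction of the attack-trajectory analysis:

* a rigid survey grid, r = 1.45-2.95 A in 0.25 A steps by theta = 70-155
  deg in 5 deg steps (126 cells), dense enough in angle to resolve the
  saddle while staying desk scale;
* a relaxed survey grid, r = {1.55, 2.25, 2.95} A by theta = 90-140 deg
  in 10 deg steps (18 constrained optimizations), spanning the short/long
  distance and low/high angle extremes with the angular resolution the
  saddle and interaction-minimum analyses need; the three distance rows
  sample the product basin, the barrier ridge and the reactant basin;
* a fixed-distance orbital-overlap sweep at r = 1.95 A over the full
  70-155 deg range;
* a long-range probe at r = 8-12 A for the asymptotic behavior of the
  decomposition terms.

The relaxed survey uses the looser 'fast' optimizer preset
(max gradient 5e-3 hartree/bohr); the survey observables -- strain
energies of a few kcal/mol and angular positions on a >= 5 deg lattice --
are insensitive at that tolerance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .decompose import decompose_scan
from .engine import RHFEngine
from .geometry import Geometry, GridSpec
from .molecules import acetone, cyanide, cyanide_acetone_pair
from .optimize import OptSettings, relax
from .scan import ScanResult, run_relaxed_scan, run_rigid_scan

RIGID_SURVEY_GRID = GridSpec(1.45, 2.95, 0.25, 70.0, 155.0, 5.0)
RELAXED_SURVEY_GRID = GridSpec(1.55, 2.95, 0.70, 90.0, 140.0, 10.0)
OVERLAP_SWEEP_R = 1.95
OVERLAP_SWEEP_GRID = GridSpec(1.95, 1.95, 1.0, 70.0, 155.0, 5.0)
LONG_RANGE_GRID = GridSpec(8.0, 12.0, 2.0, 90.0, 150.0, 30.0)


def relaxed_fragment_pair(engine: RHFEngine | None = None):
    """Relax the built-in acetone and cyanide templates, return the pair."""
    engine = engine or RHFEngine()
    ac = relax(acetone(), engine).geometry
    cn = relax(cyanide(), engine).geometry
    return cyanide_acetone_pair(ac, cn)


def rigid_survey(pair, engine, cache=None, progress=None) -> ScanResult:
    """Frozen-fragment total-energy surface on the rigid survey grid."""
    return run_rigid_scan(
        pair, RIGID_SURVEY_GRID, engine,
        relax_fragments=False, cache=cache, progress=progress,
    )


def relaxed_survey(pair, engine, cache=None, progress=None) -> ScanResult:
    """Constrained relaxed scan on the coarse survey grid."""
    return run_relaxed_scan(
        pair, RELAXED_SURVEY_GRID, engine,
        opt_settings=OptSettings().fast(),
        relax_fragments=False, cache=cache, progress=progress,
    )


def overlap_sweep(pair, engine, fragments: str = "distorted") -> pd.DataFrame:
    """HOMO(nucleophile)/LUMO(acceptor) overlap along theta at r = 1.95 A.

    With ``fragments='distorted'`` (default) the acceptor is taken at its
    relaxed in-complex geometry from a constrained optimization at the
    transition-state-like cell (r = 1.95 A -- just inside the TS distance
    -- at the ~111 deg attack angle, on-lattice at 110): the
    pyramidalized carbonyl tilts its empty pi* orbital and that tilt is
    what the overlap diagnostic is probing.  ``fragments='idealized'``
    uses the isolated relaxed (planar) acceptor instead.

    The overlap needs only the fragment wavefunctions and the dimer
    overlap matrix, so no per-point complex SCF is run; the acceptor stays
    fixed in the aligned frame and its solution is computed once.
    """
    from .decompose import homo_lumo_overlap
    from .geometry import align_carbonyl, embed_nucleophile

    spec = OVERLAP_SWEEP_GRID
    A = pair.fragment_geometry("A")
    B = pair.fragment_geometry("B")
    idx_b = list(pair.fragment_B_indices)
    c_loc = idx_b.index(pair.carbonyl_C)
    o_loc = idx_b.index(pair.carbonyl_O)
    d = np.linalg.norm(B.coords - B.coords[c_loc], axis=1)
    plane_loc = next(
        int(i) for i in np.argsort(d) if int(i) not in (c_loc, o_loc)
    )
    B = align_carbonyl(B, c_loc, o_loc, plane_loc)
    attack_loc = list(pair.fragment_A_indices).index(pair.attack_atom_A)
    n_b = B.natoms
    if fragments == "distorted":
        from .optimize import OptSettings, pinned_relax
        from .scan import _canonical_pair

        comp = embed_nucleophile(B, A, OVERLAP_SWEEP_R, 110.0,
                                 attack_atom=attack_loc)
        cpair = _canonical_pair(pair, comp, n_b, A.natoms,
                                c_loc, o_loc, attack_loc)
        res = pinned_relax(cpair, OVERLAP_SWEEP_R, 110.0, engine,
                           OptSettings().fast())
        if res.converged:
            B = Geometry(list(B.atoms), res.geometry.coords[:n_b],
                         B.charge, B.multiplicity)
    elif fragments != "idealized":
        raise ValueError(f"unknown fragment mode {fragments!r}")
    solB = engine.compute_scf(B)
    rows = []
    for theta in spec.theta_values:
        row = {"r_angstrom": OVERLAP_SWEEP_R, "theta_deg": float(theta)}
        try:
            comp = embed_nucleophile(B, A, OVERLAP_SWEEP_R, float(theta),
                                     attack_atom=attack_loc)
            gA = Geometry(
                list(A.atoms), comp.coords[n_b:], A.charge, A.multiplicity
            )
            solA = engine.compute_scf(gA)
            S, basis = engine.overlap_matrix(comp)
            ao_a = np.array(
                [k for k, at in enumerate(basis.ao_atom) if at >= n_b]
            )
            ao_b = np.array(
                [k for k, at in enumerate(basis.ao_atom) if at < n_b]
            )
            res = homo_lumo_overlap(solA, solB, S, ao_a, ao_b)
            row.update(status="converged", S_homo_lumo=res.S)
        except Exception:
            row.update(status="failed", S_homo_lumo=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def long_range_probe(pair, engine, cache=None) -> pd.DataFrame:
    """Full decomposition at 8-12 A, where Pauli repulsion must vanish and
    the electrostatic term must follow the charge/multipole expectation."""
    scan = run_rigid_scan(
        pair, LONG_RANGE_GRID, engine,
        relax_fragments=False, cache=cache,
    )
    return decompose_scan(scan, engine, analyses=("asm", "eda"))


def mulliken_charges(geometry, engine) -> np.ndarray:
    """Mulliken atomic charges, used as an independent classical
    point-charge model for the long-range electrostatic expectation."""
    mats = engine.matrices(geometry)
    sol = engine.compute_scf(geometry, mats=mats)
    pop = np.einsum("ij,ji->i", sol.density, mats.S)
    charges = geometry.atomic_numbers.astype(float)
    for ao, a in enumerate(mats.basis.ao_atom):
        charges[a] -= pop[ao]
    return charges


def point_charge_elstat(acceptor_charges, acceptor_coords, nucleophile_charge,
                        nucleophile_position) -> float:
    """Classical ion/point-charge interaction energy in hartree
    (coordinates in angstrom)."""
    from .units import ang_to_bohr

    d = np.linalg.norm(
        ang_to_bohr(acceptor_coords - nucleophile_position[None, :]), axis=1
    )
    return float(np.sum(acceptor_charges * nucleophile_charge / d))
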