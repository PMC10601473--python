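"""Starting geometries for the cyanide/acetone model system.

Built from standard bond lengths and angles (C=O 1.22 A, C-C 1.52 A,
C-H 1.09 A, sp2 angles near 120 deg, tetrahedral methyls, C#N 1.18 A).
These are templates only: workflows relax them with the active engine, so
the exact starting values are not load bearing.
"""

from __future__ import annotations

import math

import numpy as np

from .geometry import FragmentPair, Geometry, align_carbonyl, embed_nucleophile


def acetone(co: float = 1.22, cc: float = 1.52, ch: float = 1.09) -> Geometry:
    """Acetone in the canonical carbonyl frame (C1 at origin, O on +x).

    Atom order: [C_carbonyl, O, C_methyl1, C_methyl2, 6 x H].
    """
    occ = math.radians(121.5)  # O=C-C angle
    coords = [
        [0.0, 0.0, 0.0],                                   # carbonyl C
        [co, 0.0, 0.0],                                    # O
        [cc * math.cos(occ), cc * math.sin(occ), 0.0],
        [cc * math.cos(occ), -cc * math.sin(occ), 0.0],
    ]
    atoms = ["C", "O", "C", "C"]
    # methyl hydrogens: one in the carbonyl plane, two above/below it; the
    # second methyl is the exact mirror image of the first across the
    # attack plane, so the molecule has the mirror symmetry of the
    # equilibrium structure
    c = np.array(coords[2])
    axis = c / np.linalg.norm(c)            # carbonyl C -> methyl C
    w_in = np.array([-axis[1], axis[0], 0.0])   # in-plane, perpendicular
    w_in /= np.linalg.norm(w_in)
    w_out = np.array([0.0, 0.0, 1.0])           # out of the sp2 plane
    tet = math.radians(180.0 - 109.5)
    methyl1 = []
    for phi in (0.0, 2.0 * math.pi / 3.0, -2.0 * math.pi / 3.0):
        d = (
            math.cos(tet) * axis
            + math.sin(tet) * (math.cos(phi) * w_in + math.sin(phi) * w_out)
        )
        methyl1.append(c + ch * d)
    mirror = np.array([1.0, -1.0, 1.0])
    for h in methyl1:
        coords.append(h.tolist())
        atoms.append("H")
    for h in methyl1:
        coords.append((h * mirror).tolist())
        atoms.append("H")
    g = Geometry(atoms, np.array(coords), charge=0, multiplicity=1)
    return align_carbonyl(g, c_index=0, o_index=1, plane_atom_index=2)


def cyanide(cn: float = 1.18) -> Geometry:
    """CN- with the carbon (attacking atom) first."""
    return Geometry(
        ["C", "N"], [[0.0, 0.0, 0.0], [0.0, 0.0, cn]],
        charge=-1, multiplicity=1,
    )


ACETONE_CARBONYL_C = 0
ACETONE_O = 1
ACETONE_PLANE_ATOM = 2  # a methyl carbon fixes the sp2 plane
CYANIDE_ATTACK_ATOM = 0


def cyanide_acetone_pair(
    acetone_geom: Geometry | None = None,
    cyanide_geom: Geometry | None = None,
    r: float = 2.0,
    theta: float = 110.0,
) -> FragmentPair:
    """A template complex: acetone atoms first, cyanide appended."""
    ace = acetone_geom if acetone_geom is not None else acetone()
    ace = align_carbonyl(ace, ACETONE_CARBONYL_C, ACETONE_O, ACETONE_PLANE_ATOM)
    cn = cyanide_geom if cyanide_geom is not None else cyanide()
    comp = embed_nucleophile(ace, cn, r=r, theta=theta,
                             attack_atom=CYANIDE_ATTACK_ATOM)
    na = ace.natoms
    return FragmentPair(
        complex_geometry=comp,
        fragment_A_indices=tuple(range(na, na + cn.natoms)),
        fragment_B_indices=tuple(range(na)),
        charge_A=cn.charge,
        multiplicity_A=cn.multiplicity,
        charge_B=ace.charge,
        multiplicity_B=ace.multiplicity,
        attack_atom_A=na + CYANIDE_ATTACK_ATOM,
        carbonyl_C=ACETONE_CARBONYL_C,
        carbonyl_O=ACETONE_O,
    )
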