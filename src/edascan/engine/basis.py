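"""Gaussian basis sets and their per-molecule array layout.

The built-in table is STO-3G for H, He, C, N and O -- sufficient for the
cyanide/acetone model chemistry and for dimer test systems.  Shells are
expanded into flat numpy arrays (one row per shell) so the numba integral
kernels can iterate without Python objects.  Atomic orbitals are ordered
atom by atom, shells in tabulated order, p components as (x, y, z).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..geometry import Geometry
from ..units import ang_to_bohr


class BasisError(ValueError):
    pass


# STO-3G: Hehre, Stewart & Pople least-squares fits; contraction coefficients
# are shared across first-row atoms, exponents are element specific.
_S_COEF = (0.1543289673, 0.5353281423, 0.4446345422)
_2S_COEF = (-0.09996722919, 0.3995128261, 0.7001154689)
_2P_COEF = (0.1559162750, 0.6076837186, 0.3919573931)

# element -> list of (l, exponents, coefficients)
STO3G = {
    "H": [(0, (3.425250914, 0.6239137298, 0.1688554040), _S_COEF)],
    "He": [(0, (6.362421394, 1.158922999, 0.3136497915), _S_COEF)],
    "C": [
        (0, (71.61683735, 13.04509632, 3.530512160), _S_COEF),
        (0, (2.941249355, 0.6834830964, 0.2222899159), _2S_COEF),
        (1, (2.941249355, 0.6834830964, 0.2222899159), _2P_COEF),
    ],
    "N": [
        (0, (99.10616896, 18.05231239, 4.885660238), _S_COEF),
        (0, (3.780455879, 0.8784966449, 0.2857143744), _2S_COEF),
        (1, (3.780455879, 0.8784966449, 0.2857143744), _2P_COEF),
    ],
    "O": [
        (0, (130.7093214, 23.80886605, 6.443608313), _S_COEF),
        (0, (5.033151319, 1.169596125, 0.3803889600), _2S_COEF),
        (1, (5.033151319, 1.169596125, 0.3803889600), _2P_COEF),
    ],
}

BASIS_TABLES = {"sto-3g": STO3G}


def _double_factorial(n: int) -> float:
    out = 1.0
    while n > 1:
        out *= n
        n -= 2
    return out


def _primitive_norm(a: float, l: int) -> float:
    """Norm of a Cartesian primitive with angular momentum along one axis."""
    return (
        (2.0 * a / math.pi) ** 0.75
        * (4.0 * a) ** (l / 2.0)
        / math.sqrt(_double_factorial(2 * l - 1))
    )


def _normalized_coefficients(l: int, exps, coefs) -> np.ndarray:
    c = np.array([ci * _primitive_norm(ai, l) for ai, ci in zip(exps, coefs)])
    # contracted self-overlap for the (l,0,0) component
    s = 0.0
    for ai, ci in zip(exps, c):
        for aj, cj in zip(exps, c):
            p = ai + aj
            s += (
                ci * cj
                * _double_factorial(2 * l - 1) / (2.0 * p) ** l
                * (math.pi / p) ** 1.5
            )
    return c / math.sqrt(s)


@dataclass
class BasisSet:
    """Flat per-shell arrays (atomic units) for the integral kernels."""

    name: str
    shell_atom: np.ndarray      # (nsh,) atom index
    shell_center: np.ndarray    # (nsh, 3) bohr
    shell_l: np.ndarray         # (nsh,)
    shell_nprim: np.ndarray     # (nsh,)
    shell_exp: np.ndarray       # (nsh, maxprim)
    shell_coef: np.ndarray      # (nsh, maxprim), normalized
    shell_ao: np.ndarray        # (nsh,) first AO index of the shell
    nao: int
    ao_atom: np.ndarray         # (nao,) atom index per AO
    ao_labels: list

    @property
    def nshells(self) -> int:
        return len(self.shell_l)


def build_basis(geometry: Geometry, name: str = "sto-3g") -> BasisSet:
    try:
        table = BASIS_TABLES[name.lower()]
    except KeyError as exc:
        raise BasisError(f"unknown basis set {name!r}") from exc

    atoms, centers, ls, nprims, exps, coefs, ao_first = [], [], [], [], [], [], []
    ao_atom, ao_labels = [], []
    nao = 0
    maxprim = max(
        len(e) for shells in table.values() for (_, e, _) in shells
    )
    for ia, (sym, xyz) in enumerate(zip(geometry.atoms, geometry.coords)):
        if sym not in table:
            raise BasisError(f"element {sym} not available in basis {name}")
        for ish, (l, e, c) in enumerate(table[sym]):
            atoms.append(ia)
            centers.append(ang_to_bohr(np.asarray(xyz, dtype=float)))
            ls.append(l)
            nprims.append(len(e))
            row_e = np.zeros(maxprim)
            row_c = np.zeros(maxprim)
            row_e[: len(e)] = e
            row_c[: len(e)] = _normalized_coefficients(l, e, c)
            exps.append(row_e)
            coefs.append(row_c)
            ao_first.append(nao)
            ncomp = (l + 1) * (l + 2) // 2
            for comp in range(ncomp):
                ao_atom.append(ia)
                tag = {0: ["s"], 1: ["px", "py", "pz"]}.get(l)
                label = tag[comp] if tag else f"l{l}c{comp}"
                ao_labels.append((ia, sym, ish, label))
            nao += ncomp

    return BasisSet(
        name=name.lower(),
        shell_atom=np.array(atoms, dtype=np.int64),
        shell_center=np.array(centers, dtype=np.float64),
        shell_l=np.array(ls, dtype=np.int64),
        shell_nprim=np.array(nprims, dtype=np.int64),
        shell_exp=np.array(exps, dtype=np.float64),
        shell_coef=np.array(coefs, dtype=np.float64),
        shell_ao=np.array(ao_first, dtype=np.int64),
        nao=nao,
        ao_atom=np.array(ao_atom, dtype=np.int64),
        ao_labels=ao_labels,
    )
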