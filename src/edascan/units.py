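"""Unit conventions and conversion factors.

External interfaces (files, CLI, result tables) use angstrom and degrees;
the electronic-structure engine works in atomic units (bohr, hartree).
All conversions go through this module so no factor is duplicated.
"""

import math

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903
ANGSTROM_PER_BOHR = 0.529177210903

HARTREE_TO_KCAL = 627.5094740631
KCAL_TO_HARTREE = 1.0 / HARTREE_TO_KCAL


def ang_to_bohr(x):
    return x * BOHR_PER_ANGSTROM


def bohr_to_ang(x):
    return x * ANGSTROM_PER_BOHR


def hartree_to_kcal(e):
    return e * HARTREE_TO_KCAL


def kcal_to_hartree(e):
    return e * KCAL_TO_HARTREE


def deg_to_rad(a):
    return a * math.pi / 180.0


def rad_to_deg(a):
    return a * 180.0 / math.pi
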