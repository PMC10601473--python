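"""Analytic pair-potential mock engine.

Energy model (consistent units: energies in 'mock hartree', distances in
angstrom):

    E = sum_{i<j} [ q_i q_j / r_ij + A_ij r_ij^-12 - B_ij r_ij^-6 ]

with per-element point charge q, repulsion strength A and attraction
strength B, and geometric-mean combination rules A_ij = sqrt(A_i A_j),
B_ij = sqrt(B_i B_j).  The model is smooth, deterministic and analytically
differentiable, and its cross-fragment Coulomb / repulsive / attractive
partial sums provide exactly known expected values for the decomposition
pipeline, so every orchestration layer can be tested without an SCF.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from ..geometry import Geometry
from .base import EngineError, SCFSolution

#: default per-element (charge q, repulsion A, attraction B) parameters;
#: loosely sized like van der Waals interactions so demo surfaces have a
#: long-range attractive well and a steep short-range wall.
DEFAULT_MOCK_PARAMS = {
    "H": (0.05, 20.0, 2.0),
    "C": (0.00, 800.0, 30.0),
    "N": (-0.15, 700.0, 25.0),
    "O": (-0.20, 600.0, 25.0),
    "He": (0.00, 50.0, 1.0),
}


@dataclass(frozen=True)
class MockParams:
    element_params: tuple = tuple(sorted(DEFAULT_MOCK_PARAMS.items()))

    @classmethod
    def from_dict(cls, d: dict) -> "MockParams":
        return cls(tuple(sorted((k, tuple(v)) for k, v in d.items())))

    def as_dict(self) -> dict:
        return {k: tuple(v) for k, v in self.element_params}


@dataclass
class MockInteraction:
    """Exact cross-fragment partial sums of the mock pair potential."""

    coulomb: float
    repulsion: float
    attraction: float

    @property
    def total(self) -> float:
        return self.coulomb + self.repulsion + self.attraction


class MockEngine:
    """Pair-potential engine satisfying the same calling surface as RHF."""

    def __init__(self, params: MockParams | None = None):
        self.params = params or MockParams()
        self._table = self.params.as_dict()
        self.ncalls = 0  # compute_scf/gradient invocations (cache audits)

    @property
    def hash(self) -> str:
        payload = json.dumps(self.params.as_dict(), sort_keys=True)
        return "mock:" + hashlib.sha256(payload.encode()).hexdigest()[:16]

    def _qab(self, geometry: Geometry):
        try:
            rows = [self._table[s] for s in geometry.atoms]
        except KeyError as exc:
            raise EngineError(
                f"no mock parameters for element {exc.args[0]!r}"
            ) from exc
        arr = np.array(rows, dtype=float)
        return arr[:, 0], arr[:, 1], arr[:, 2]

    @staticmethod
    def _pair_terms(coords, q, A, B, idx_a, idx_b):
        """(coulomb, repulsion, attraction) summed over pairs a in A, b in B."""
        d = np.linalg.norm(
            coords[idx_a][:, None, :] - coords[idx_b][None, :, :], axis=-1
        )
        if np.any(d < 1e-10):
            raise EngineError("coincident atoms in mock energy evaluation")
        qq = np.outer(q[idx_a], q[idx_b])
        Aab = np.sqrt(np.outer(A[idx_a], A[idx_b]))
        Bab = np.sqrt(np.outer(B[idx_a], B[idx_b]))
        return (
            float((qq / d).sum()),
            float((Aab / d**12).sum()),
            float(-(Bab / d**6).sum()),
        )

    def energy(self, geometry: Geometry) -> float:
        q, A, B = self._qab(geometry)
        n = geometry.natoms
        total = 0.0
        for i in range(n):
            idx_j = np.arange(i + 1, n)
            if len(idx_j) == 0:
                continue
            c, r, a = self._pair_terms(
                geometry.coords, q, A, B, np.array([i]), idx_j
            )
            total += c + r + a
        return total

    def compute_scf(self, geometry: Geometry, guess=None, mats=None) -> SCFSolution:
        """SCFSolution-shaped record; orbital fields are empty placeholders."""
        self.ncalls += 1
        e = self.energy(geometry)
        return SCFSolution(
            energy=e,
            converged=True,
            orbital_coefficients=np.zeros((0, 0)),
            orbital_energies=np.zeros(0),
            occupations=np.zeros(0),
            basis_labels=[],
            engine_hash=self.hash,
            extras={"mock": True},
        )

    def interaction_terms(
        self, geometry: Geometry, idx_a, idx_b
    ) -> MockInteraction:
        q, A, B = self._qab(geometry)
        c, r, a = self._pair_terms(
            geometry.coords, q, A, B,
            np.asarray(list(idx_a), dtype=int),
            np.asarray(list(idx_b), dtype=int),
        )
        return MockInteraction(coulomb=c, repulsion=r, attraction=a)

    def gradient(self, geometry: Geometry, sol=None, mats=None) -> np.ndarray:
        """Analytic gradient of the mock energy, per atom, energy/angstrom."""
        self.ncalls += 1
        q, A, B = self._qab(geometry)
        coords = geometry.coords
        n = geometry.natoms
        grad = np.zeros((n, 3))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                rij = coords[i] - coords[j]
                d = np.linalg.norm(rij)
                Aij = np.sqrt(A[i] * A[j])
                Bij = np.sqrt(B[i] * B[j])
                # dE/dd for the (i, j) pair counted once
                dEdd = (
                    -q[i] * q[j] / d**2
                    - 12.0 * Aij / d**13
                    + 6.0 * Bij / d**7
                )
                grad[i] += dEdd * rij / d
        return grad
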