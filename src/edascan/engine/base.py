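"""Engine contract: settings, SCF solutions, and the interface every
backend must satisfy so the scan/decomposition layers never see
backend-specific objects."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np


class EngineError(RuntimeError):
    """Engine failure (basis construction, SCF breakdown, bad input)."""


@dataclass(frozen=True)
class EngineSettings:
    """Settings for an electronic-structure calculation.

    method: energy model name ('rhf' for the built-in engine, 'mock' for the
        analytic pair-potential engine).
    basis: basis-set name ('sto-3g' built in).
    scf_tolerance: SCF energy-change convergence threshold in hartree.
    max_scf_cycles: hard iteration cap; exceeding it yields converged=False.
    grid_quality: free label mapped by each backend (unused by HF).
    """

    method: str = "rhf"
    basis: str = "sto-3g"
    scf_tolerance: float = 1e-8
    max_scf_cycles: int = 128
    grid_quality: str = "default"

    def __post_init__(self):
        if self.scf_tolerance <= 0:
            raise EngineError("scf_tolerance must be positive")
        if self.max_scf_cycles < 1:
            raise EngineError("max_scf_cycles must be >= 1")

    def hash(self) -> str:
        payload = json.dumps(
            {
                "method": self.method.lower(),
                "basis": self.basis.lower(),
                "tol": self.scf_tolerance,
                "cycles": self.max_scf_cycles,
                "grid": self.grid_quality,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SCFSolution:
    """Converged (or not) mean-field solution for one geometry.

    orbital_coefficients columns are MOs over the system's AO basis;
    occupations are per-MO electron counts (0 or 2 for closed shells).
    """

    energy: float
    converged: bool
    orbital_coefficients: np.ndarray
    orbital_energies: np.ndarray
    occupations: np.ndarray
    basis_labels: list
    engine_hash: str = ""
    extras: dict = field(default_factory=dict)

    @property
    def n_electrons(self) -> float:
        return float(self.occupations.sum())

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.occupations > 0))

    @property
    def homo_index(self) -> int:
        if self.n_occupied == 0:
            raise EngineError("no occupied orbitals")
        return self.n_occupied - 1

    @property
    def lumo_index(self) -> int:
        if self.n_occupied >= len(self.occupations):
            raise EngineError("no virtual orbitals in this basis")
        return self.n_occupied

    @property
    def density(self) -> np.ndarray:
        """Total AO density matrix D = C diag(occ) C^T."""
        C = self.orbital_coefficients
        return (C * self.occupations) @ C.T
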