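"""Molecular geometries, the carbonyl attack frame, and (r, theta) grids.

The attack of a nucleophile on a carbonyl carbon is parametrized by two
coordinates: the distance r between the nucleophile's attacking atom and the
carbonyl carbon, and the attack angle theta measured as the
Nu-C-O angle at the carbonyl carbon.  The carbonyl fragment is placed in a
canonical frame (C at the origin, O on +x, the sp2 plane equal to the xy
plane); the nucleophile is then embedded at

    p(r, theta) = (r cos(theta), 0, r sin(theta))

i.e. in the xz plane that contains the C=O axis and is perpendicular to the
carbonyl plane -- the standard Buergi-Dunitz trajectory plane.  An in-plane
(xy) alternative is available for non-standard scans.

All coordinates in this module are in angstrom, angles in degrees.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ATOMIC_NUMBERS",
    "Geometry",
    "FragmentPair",
    "GridSpec",
    "GridPoint",
    "build_grid",
    "align_carbonyl",
    "embed_nucleophile",
    "measure_rc",
    "read_xyz",
    "write_xyz",
]

# Elements through Kr cover all organic nucleophile/electrophile use cases;
# the engine restricts further to the elements its basis set tabulates.
ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Sc": 21, "Ti": 22,
    "V": 23, "Cr": 24, "Mn": 25, "Fe": 26, "Co": 27, "Ni": 28, "Cu": 29,
    "Zn": 30, "Ga": 31, "Ge": 32, "As": 33, "Se": 34, "Br": 35, "Kr": 36,
}

MIN_INTERATOMIC = 0.3  # angstrom; closer atoms are considered fused
CLASH_DISTANCE = 0.5   # angstrom; cross-fragment contacts below this flag a clash


class GeometryError(ValueError):
    """Invalid molecular geometry or frame specification."""


@dataclass
class Geometry:
    """A molecule or fragment: element symbols, Cartesian coordinates (A),
    total charge (e) and spin multiplicity."""

    atoms: list[str]
    coords: np.ndarray
    charge: int = 0
    multiplicity: int = 1
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.validate()

    def validate(self) -> None:
        if len(self.atoms) != len(self.coords):
            raise GeometryError(
                f"{len(self.atoms)} atoms but {len(self.coords)} coordinates"
            )
        for sym in self.atoms:
            if sym not in ATOMIC_NUMBERS:
                raise GeometryError(f"unknown element symbol {sym!r}")
        if self.multiplicity < 1:
            raise GeometryError("multiplicity must be a positive integer")
        n = len(self.atoms)
        if n > 1:
            d = np.linalg.norm(
                self.coords[:, None, :] - self.coords[None, :, :], axis=-1
            )
            np.fill_diagonal(d, np.inf)
            if d.min() <= MIN_INTERATOMIC:
                i, j = np.unravel_index(np.argmin(d), d.shape)
                raise GeometryError(
                    f"atoms {i} and {j} are fused ({d[i, j]:.3f} A apart)"
                )

    @property
    def natoms(self) -> int:
        return len(self.atoms)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBERS[s] for s in self.atoms], dtype=int)

    @property
    def n_electrons(self) -> int:
        return int(self.atomic_numbers.sum()) - self.charge

    def copy(self) -> "Geometry":
        return Geometry(
            list(self.atoms), self.coords.copy(), self.charge,
            self.multiplicity, dict(self.info),
        )

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coords[i] - self.coords[j]))

    def angle(self, i: int, j: int, k: int) -> float:
        """Included angle i-j-k in degrees, in [0, 180]."""
        u = self.coords[i] - self.coords[j]
        v = self.coords[k] - self.coords[j]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-12 or nv < 1e-12:
            raise GeometryError("zero-length vector in angle measurement")
        c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
        return math.degrees(math.acos(c))

    def distance_matrix(self) -> np.ndarray:
        return np.linalg.norm(
            self.coords[:, None, :] - self.coords[None, :, :], axis=-1
        )


@dataclass
class FragmentPair:
    """A complex partitioned into nucleophile (A) and carbonyl acceptor (B)."""

    complex_geometry: Geometry
    fragment_A_indices: tuple
    fragment_B_indices: tuple
    charge_A: int
    multiplicity_A: int
    charge_B: int
    multiplicity_B: int
    attack_atom_A: int
    carbonyl_C: int
    carbonyl_O: int

    def __post_init__(self):
        self.fragment_A_indices = tuple(self.fragment_A_indices)
        self.fragment_B_indices = tuple(self.fragment_B_indices)
        n = self.complex_geometry.natoms
        a, b = set(self.fragment_A_indices), set(self.fragment_B_indices)
        if a & b:
            raise GeometryError("fragment index sets overlap")
        if a | b != set(range(n)):
            raise GeometryError("fragment index sets do not partition the complex")
        if self.charge_A + self.charge_B != self.complex_geometry.charge:
            raise GeometryError("fragment charges do not sum to complex charge")
        if self.attack_atom_A not in a:
            raise GeometryError("attack atom must belong to fragment A")
        if self.carbonyl_C not in b or self.carbonyl_O not in b:
            raise GeometryError("carbonyl atoms must belong to fragment B")

    def fragment_geometry(self, which: str) -> Geometry:
        """Extract fragment 'A' or 'B' at its in-complex coordinates."""
        idx = self.fragment_A_indices if which == "A" else self.fragment_B_indices
        chg = self.charge_A if which == "A" else self.charge_B
        mult = self.multiplicity_A if which == "A" else self.multiplicity_B
        g = self.complex_geometry
        return Geometry([g.atoms[i] for i in idx], g.coords[list(idx)], chg, mult)

    def with_geometry(self, geom: Geometry) -> "FragmentPair":
        return FragmentPair(
            geom, self.fragment_A_indices, self.fragment_B_indices,
            self.charge_A, self.multiplicity_A, self.charge_B,
            self.multiplicity_B, self.attack_atom_A, self.carbonyl_C,
            self.carbonyl_O,
        )


@dataclass(frozen=True)
class GridSpec:
    """Rectangular (r, theta) lattice: r in angstrom, theta in degrees."""

    r_min: float
    r_max: float
    r_step: float
    theta_min: float
    theta_max: float
    theta_step: float

    LATTICE_TOL = 1e-9

    def __post_init__(self):
        if self.r_min <= 0:
            raise GeometryError("r_min must be positive")
        if self.r_max < self.r_min:
            raise GeometryError("r_max must be >= r_min")
        if not (0.0 < self.theta_min <= 180.0 and 0.0 < self.theta_max <= 180.0):
            raise GeometryError("theta must lie in (0, 180] degrees")
        if self.theta_max < self.theta_min:
            raise GeometryError("theta_max must be >= theta_min")
        if self.r_step <= 0 or self.theta_step <= 0:
            raise GeometryError("steps must be positive")
        for lo, hi, step, name in (
            (self.r_min, self.r_max, self.r_step, "r"),
            (self.theta_min, self.theta_max, self.theta_step, "theta"),
        ):
            span = hi - lo
            k = round(span / step)
            if abs(span - k * step) > self.LATTICE_TOL * max(1.0, abs(span)):
                raise GeometryError(
                    f"{name} range {span} is not an integer multiple of step {step}"
                )

    @property
    def n_r(self) -> int:
        return round((self.r_max - self.r_min) / self.r_step) + 1

    @property
    def n_theta(self) -> int:
        return round((self.theta_max - self.theta_min) / self.theta_step) + 1

    @property
    def r_values(self) -> np.ndarray:
        return self.r_min + self.r_step * np.arange(self.n_r)

    @property
    def theta_values(self) -> np.ndarray:
        return self.theta_min + self.theta_step * np.arange(self.n_theta)

    @property
    def size(self) -> int:
        return self.n_r * self.n_theta

    def index_of(self, r: float, theta: float, tol: float = 1e-6) -> tuple[int, int]:
        """(i_r, i_theta) of an on-lattice point; raises if off-lattice."""
        ir = round((r - self.r_min) / self.r_step)
        it = round((theta - self.theta_min) / self.theta_step)
        if not (0 <= ir < self.n_r and 0 <= it < self.n_theta):
            raise GeometryError(f"({r}, {theta}) outside grid")
        if (abs(r - (self.r_min + ir * self.r_step)) > tol
                or abs(theta - (self.theta_min + it * self.theta_step)) > tol):
            raise GeometryError(f"({r}, {theta}) is not on the grid lattice")
        return ir, it


@dataclass
class GridPoint:
    """One (r, theta) cell; carries a geometry once embedded or optimized."""

    r: float
    theta: float
    geometry: Geometry | None = None
    status: str = "stub"

    STATUSES = ("stub", "embedded", "converged", "failed")

    def __post_init__(self):
        if self.status not in self.STATUSES:
            raise GeometryError(f"unknown status {self.status!r}")
        if (self.geometry is None) != (self.status == "stub"):
            raise GeometryError("geometry must be present iff status != stub")


def build_grid(spec: GridSpec) -> list[GridPoint]:
    """All lattice cells as stubs, ordered by ascending theta then ascending r."""
    return [
        GridPoint(r=float(r), theta=float(t))
        for t in spec.theta_values
        for r in spec.r_values
    ]


def _rotation_onto(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a onto unit vector b (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    s = np.linalg.norm(v)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        K = np.array([
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ])
        return np.eye(3) + 2.0 * (K @ K)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K * ((1 - c) / (s * s))


def align_carbonyl(
    g: Geometry, c_index: int, o_index: int, plane_atom_index: int
) -> Geometry:
    """Rigid transform into the canonical carbonyl frame.

    Carbonyl C at the origin, O on the +x axis, and the third reference atom
    in the xy plane with positive y, so the sp2 plane of the carbonyl is the
    xy plane.  Purely rigid: all internal distances preserved.
    """
    if len({c_index, o_index, plane_atom_index}) != 3:
        raise GeometryError("alignment reference indices must be distinct")
    C = g.coords[c_index]
    ex = g.coords[o_index] - C
    nex = np.linalg.norm(ex)
    if nex < 1e-10:
        raise GeometryError("carbonyl C and O coincide")
    ex = ex / nex
    v = g.coords[plane_atom_index] - C
    ey = v - np.dot(v, ex) * ex
    ney = np.linalg.norm(ey)
    if ney < 1e-8:
        raise GeometryError("alignment reference atoms are collinear")
    ey = ey / ney
    ez = np.cross(ex, ey)
    R = np.vstack([ex, ey, ez])  # rows: new basis in old coordinates
    out = g.copy()
    out.coords = (g.coords - C) @ R.T
    return out


def embed_nucleophile(
    acceptor_aligned: Geometry,
    nucleophile: Geometry,
    r: float,
    theta: float,
    attack_atom: int = 0,
    orientation: str = "away",
    plane: str = "perpendicular",
) -> Geometry:
    """Place the nucleophile at (r, theta) around an aligned carbonyl.

    The attacking atom goes to (r cos t, 0, r sin t) for the default
    ``plane='perpendicular'`` (the Buergi-Dunitz trajectory plane: contains
    the C=O axis, perpendicular to the carbonyl sp2 plane) or to
    (r cos t, r sin t, 0) for ``plane='in-plane'``.

    ``orientation='away'`` points the nucleophile's principal axis (attack
    atom -> centroid of its remaining atoms) away from the carbonyl carbon
    along the attack vector; ``orientation='keep'`` retains the input
    orientation.  Cross-fragment contacts closer than 0.5 A set
    ``info['clash']`` rather than failing: short-distance, high-angle cells
    of the repulsive region are intentionally sampled.
    """
    if not (0.0 < theta <= 180.0):
        raise GeometryError(f"theta={theta} outside (0, 180] degrees")
    if r <= 0:
        raise GeometryError("r must be positive")
    t = math.radians(theta)
    if plane == "perpendicular":
        p = np.array([r * math.cos(t), 0.0, r * math.sin(t)])
    elif plane == "in-plane":
        p = np.array([r * math.cos(t), r * math.sin(t), 0.0])
    else:
        raise GeometryError(f"unknown attack plane {plane!r}")

    nu = nucleophile.copy()
    rel = nu.coords - nu.coords[attack_atom]
    if orientation == "away" and nu.natoms > 1:
        centroid = np.delete(rel, attack_atom, axis=0).mean(axis=0)
        if np.linalg.norm(centroid) > 1e-8:
            rel = rel @ _rotation_onto(centroid, p).T
    elif orientation not in ("away", "keep"):
        raise GeometryError(f"unknown orientation rule {orientation!r}")
    nu_coords = rel + p

    atoms = list(acceptor_aligned.atoms) + list(nu.atoms)
    coords = np.vstack([acceptor_aligned.coords, nu_coords])
    cross = np.linalg.norm(
        acceptor_aligned.coords[:, None, :] - nu_coords[None, :, :], axis=-1
    )
    out = Geometry.__new__(Geometry)  # bypass fused-atom validation for clashes
    out.atoms = atoms
    out.coords = coords
    out.charge = acceptor_aligned.charge + nucleophile.charge
    out.multiplicity = 1
    out.info = {"r": r, "theta": theta, "clash": bool(cross.min() < CLASH_DISTANCE)}
    if len(out.atoms) != len(out.coords):
        raise GeometryError("internal embedding error")
    return out


def measure_rc(fp: FragmentPair) -> tuple[float, float]:
    """(C-C distance in A, Nu-C-O angle in degrees) of a fragment pair."""
    g = fp.complex_geometry
    r = g.distance(fp.attack_atom_A, fp.carbonyl_C)
    if r < 1e-12:
        raise GeometryError("attack atom coincides with carbonyl carbon")
    theta = g.angle(fp.attack_atom_A, fp.carbonyl_C, fp.carbonyl_O)
    return r, theta


# ---------------------------------------------------------------------------
# XYZ files: count line, comment line with optional "key=value" metadata,
# then "El x y z" rows in angstrom.

_KV_RE = re.compile(r"(\w+)\s*=\s*([-+0-9.eE]+)")


def write_xyz(g: Geometry, path, comment: str = "") -> None:
    meta = dict(g.info)
    meta.pop("clash", None)
    parts = [comment.strip()] if comment.strip() else []
    for key in ("r", "theta"):
        if key in meta:
            parts.append(f"{key}={meta[key]:g}")
    parts.append(f"charge={g.charge}")
    parts.append(f"mult={g.multiplicity}")
    lines = [str(g.natoms), " ".join(parts)]
    for sym, (x, y, z) in zip(g.atoms, g.coords):
        lines.append(f"{sym:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_xyz(path) -> Geometry:
    with open(path) as fh:
        raw = [line.rstrip("\n") for line in fh]
    if not raw:
        raise GeometryError(f"empty XYZ file {path}")
    try:
        n = int(raw[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise GeometryError(f"bad atom-count line in {path}") from exc
    comment = raw[1] if len(raw) > 1 else ""
    meta = {k: float(v) for k, v in _KV_RE.findall(comment)}
    charge = int(meta.pop("charge", 0))
    mult = int(meta.pop("mult", 1))
    atoms, coords = [], []
    for line in raw[2: 2 + n]:
        parts = line.split()
        if len(parts) < 4:
            raise GeometryError(f"malformed coordinate line {line!r} in {path}")
        atoms.append(parts[0].capitalize())
        coords.append([float(x) for x in parts[1:4]])
    if len(atoms) != n:
        raise GeometryError(f"expected {n} atoms, found {len(atoms)} in {path}")
    return Geometry(atoms, np.array(coords), charge, mult, info=meta)
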