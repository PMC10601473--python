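"""Scalar fields over the (r, theta) grid and their analyses.

Surfaces are stored as n_r x n_theta arrays with a validity mask (failed
scan points stay masked and never enter a statistic).  The transition
state of the sampled landscape is located as the discrete minimax saddle:
the cell realizing the minimum over all 4-neighbor connecting paths of the
maximum energy along the path, computed by threshold union-find over cells
sorted by energy.  A 3x3-stencil detector is provided as an independent
cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import GridSpec
from .scan import ScanResult

FIELD_NAMES = (
    "E", "E_strain", "E_strain_A", "E_strain_B", "E_int",
    "V_elstat", "E_pauli", "E_oi", "S_overlap", "closure_residual",
)

_TABLE_COLUMNS = {
    "E": "dE",
    "E_strain": "dE_strain",
    "E_strain_A": "dE_strain_A",
    "E_strain_B": "dE_strain_B",
    "E_int": "dE_int",
    "V_elstat": "V_elstat",
    "E_pauli": "E_pauli",
    "E_oi": "E_oi",
    "S_overlap": "S_homo_lumo",
    "closure_residual": "closure_residual",
}


class SurfaceError(ValueError):
    pass


@dataclass
class SurfaceField:
    """A named scalar field over the grid; kcal/mol unless dimensionless."""

    name: str
    values: np.ndarray  # (n_r, n_theta)
    mask: np.ndarray    # True where valid
    gridspec: GridSpec

    def __post_init__(self):
        expect = (self.gridspec.n_r, self.gridspec.n_theta)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != expect or self.mask.shape != expect:
            raise SurfaceError(
                f"field shape {self.values.shape} does not match grid {expect}"
            )

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def value_at(self, r: float, theta: float) -> float:
        ir, it = self.gridspec.index_of(r, theta)
        if not self.mask[ir, it]:
            raise SurfaceError(f"cell ({r}, {theta}) is masked")
        return float(self.values[ir, it])


@dataclass
class CrossSection:
    fixed_r: float
    thetas: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    field: str
    interpolated: bool = False


@dataclass
class SaddleReport:
    r: float
    theta: float
    value: float
    barrier_height: float
    reactant_cell: tuple
    product_cell: tuple
    method: str = "discrete minimax"


def assemble_surface(
    scan: ScanResult,
    table: pd.DataFrame | None,
    field_name: str,
) -> SurfaceField:
    """Build one named field from a scan and its decomposition table.

    Energies follow the convention of the strain/interaction split: they are
    referenced to relaxed, infinitely separated fragments, in kcal/mol (mock
    units for mock scans); the orbital overlap field is dimensionless.
    """
    if field_name not in FIELD_NAMES:
        raise SurfaceError(f"unknown field {field_name!r}; "
                           f"choose from {FIELD_NAMES}")
    spec = scan.gridspec
    col = _TABLE_COLUMNS[field_name]
    if table is None:
        raise SurfaceError("a decomposition table is required")
    need = {"r_angstrom", "theta_deg", col}
    if not need.issubset(table.columns):
        missing = need - set(table.columns)
        raise SurfaceError(f"table lacks columns {sorted(missing)}")
    values = np.full((spec.n_r, spec.n_theta), np.nan)
    mask = np.zeros((spec.n_r, spec.n_theta), dtype=bool)
    for row in table.itertuples(index=False):
        ir, it = spec.index_of(row.r_angstrom, row.theta_deg)
        v = getattr(row, col)
        if getattr(row, "status", "converged") == "converged" \
                and np.isfinite(v):
            values[ir, it] = v
            mask[ir, it] = True
    return SurfaceField(field_name, values, mask, spec)


def surfaces_from_table(scan: ScanResult, table: pd.DataFrame) -> dict:
    """Every assemblable field present in the table, keyed by name."""
    out = {}
    for name in FIELD_NAMES:
        if _TABLE_COLUMNS[name] in table.columns:
            out[name] = assemble_surface(scan, table, name)
    return out


def cross_section(sf: SurfaceField, r0: float) -> CrossSection:
    """Fixed-distance angular slice; linear interpolation off-lattice."""
    spec = sf.gridspec
    if not (spec.r_min - 1e-9 <= r0 <= spec.r_max + 1e-9):
        raise SurfaceError(f"r={r0} outside grid range")
    pos = (r0 - spec.r_min) / spec.r_step
    i0 = int(np.floor(pos + 1e-9))
    frac = pos - i0
    if frac > 1.0 - 1e-9:
        i0 += 1
        frac = 0.0
    if abs(frac) < 1e-9 or i0 >= spec.n_r - 1:
        return CrossSection(
            fixed_r=float(spec.r_values[i0]),
            thetas=spec.theta_values.copy(),
            values=sf.values[i0].copy(),
            mask=sf.mask[i0].copy(),
            field=sf.name,
        )
    lo, hi = sf.values[i0], sf.values[i0 + 1]
    mask = sf.mask[i0] & sf.mask[i0 + 1]
    return CrossSection(
        fixed_r=float(r0),
        thetas=spec.theta_values.copy(),
        values=(1.0 - frac) * lo + frac * hi,
        mask=mask,
        field=sf.name,
        interpolated=True,
    )


def argmin_surface(sf: SurfaceField) -> tuple[float, float, float]:
    """(r, theta, value) of the global minimum over valid cells.

    Ties break toward smaller theta, then smaller r.
    """
    if sf.n_valid == 0:
        raise SurfaceError("fully masked surface")
    best = None
    spec = sf.gridspec
    for it in range(spec.n_theta):       # theta-major: tie rule
        for ir in range(spec.n_r):
            if not sf.mask[ir, it]:
                continue
            v = sf.values[ir, it]
            if best is None or v < best[0] - 1e-15:
                best = (v, ir, it)
    v, ir, it = best
    return float(spec.r_values[ir]), float(spec.theta_values[it]), float(v)


def argmax_surface(sf: SurfaceField) -> tuple[float, float, float]:
    neg = SurfaceField(sf.name, -sf.values, sf.mask, sf.gridspec)
    r, t, v = argmin_surface(neg)
    return r, t, -v


def default_basin_seeds(sf: SurfaceField) -> tuple[tuple, tuple]:
    """Reactant seed: lowest valid cell in the largest-distance rows;
    product seed: lowest valid cell in the smallest-distance rows."""
    spec = sf.gridspec

    def row_seed(order):
        for ir in order:
            if sf.mask[ir].any():
                it = int(np.nanargmin(
                    np.where(sf.mask[ir], sf.values[ir], np.nan)
                ))
                return (ir, it)
        raise SurfaceError("fully masked surface")

    reactant = row_seed(range(spec.n_r - 1, -1, -1))
    product = row_seed(range(spec.n_r))
    return reactant, product


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[ri] = rj


def locate_saddle(
    sf: SurfaceField,
    reactant_cell: tuple | None = None,
    product_cell: tuple | None = None,
) -> SaddleReport:
    """Minimax barrier between the reactant and product basins.

    Cells are activated in order of increasing energy; the first activation
    that connects the two seeds (through 4-neighbor adjacency on valid
    cells) is the saddle, and its energy is the lowest possible maximum
    over all connecting paths.
    """
    spec = sf.gridspec
    if reactant_cell is None or product_cell is None:
        r_def, p_def = default_basin_seeds(sf)
        reactant_cell = reactant_cell or r_def
        product_cell = product_cell or p_def
    for cell in (reactant_cell, product_cell):
        ir, it = cell
        if not sf.mask[ir, it]:
            raise SurfaceError(f"basin seed {cell} is masked")

    nr, nt = spec.n_r, spec.n_theta
    cells = [
        (sf.values[ir, it], it, ir)
        for ir in range(nr) for it in range(nt) if sf.mask[ir, it]
    ]
    cells.sort()
    uf = _UnionFind(nr * nt)
    active = np.zeros((nr, nt), dtype=bool)
    idx = lambda ir, it: ir * nt + it  # noqa: E731
    rs, ps = idx(*reactant_cell), idx(*product_cell)
    for v, it, ir in cells:
        active[ir, it] = True
        for dr, dt in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            jr, jt = ir + dr, it + dt
            if 0 <= jr < nr and 0 <= jt < nt and active[jr, jt]:
                uf.union(idx(ir, it), idx(jr, jt))
        if uf.find(rs) == uf.find(ps):
            return SaddleReport(
                r=float(spec.r_values[ir]),
                theta=float(spec.theta_values[it]),
                value=float(v),
                barrier_height=float(
                    v - sf.values[reactant_cell[0], reactant_cell[1]]
                ),
                reactant_cell=tuple(reactant_cell),
                product_cell=tuple(product_cell),
            )
    raise SurfaceError("basins are disconnected on the unmasked grid")


def stencil_saddles(sf: SurfaceField) -> list[tuple[float, float, float]]:
    """3x3-stencil saddle candidates (cross-check for the minimax finder).

    Interior valid cells that are maxima along one lattice direction and
    minima along the other.
    """
    spec = sf.gridspec
    out = []
    for ir in range(1, spec.n_r - 1):
        for it in range(1, spec.n_theta - 1):
            if not (sf.mask[ir - 1:ir + 2, it].all()
                    and sf.mask[ir, it - 1:it + 2].all()):
                continue
            v = sf.values[ir, it]
            along_r = (sf.values[ir - 1, it], sf.values[ir + 1, it])
            along_t = (sf.values[ir, it - 1], sf.values[ir, it + 1])
            max_r_min_t = v >= max(along_r) and v <= min(along_t)
            min_r_max_t = v <= min(along_r) and v >= max(along_t)
            if max_r_min_t or min_r_max_t:
                out.append((
                    float(spec.r_values[ir]),
                    float(spec.theta_values[it]),
                    float(v),
                ))
    return out


def to_view(sf: SurfaceField, view: str = "cartesian"):
    """Plottable cell positions: 'cartesian' places cells at
    (r cos t, r sin t) -- the nucleophile position around the carbonyl
    carbon -- while 'rectangular' uses the (theta, r) lattice axes.
    Values are untouched.

    Returns (X, Y, values, mask) arrays of shape (n_r, n_theta).
    """
    spec = sf.gridspec
    R, T = np.meshgrid(spec.r_values, spec.theta_values, indexing="ij")
    if view == "cartesian":
        X = R * np.cos(np.radians(T))
        Y = R * np.sin(np.radians(T))
    elif view == "rectangular":
        X, Y = T, R
    else:
        raise SurfaceError(f"unknown view {view!r}")
    return X, Y, sf.values.copy(), sf.mask.copy()
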