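"""Surface tables, run configuration, and analysis-only ingestion.

The canonical interchange format is a tidy CSV with one row per grid cell
and a commented header declaring units and provenance, so energies computed
with any quantum-chemistry program can be decomposed and analyzed here
without rerunning electronic-structure calculations.  Raw total energies
are in hartree; decomposition columns are in kcal/mol; distances in
angstrom; angles in degrees.  Angles and distances are never serialized in
any other unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import FragmentPair, Geometry, GridSpec
from .scan import ScanPoint, ScanResult

HEADER_MAGIC = "# edascan surface table v1"
UNITS_LINE = (
    "# units: r_angstrom=angstrom theta_deg=degree "
    "E_complex=hartree E_A_dist=hartree E_B_dist=hartree "
    "dE=kcal/mol dE_strain_A=kcal/mol dE_strain_B=kcal/mol "
    "dE_strain=kcal/mol dE_int=kcal/mol V_elstat=kcal/mol "
    "E_pauli=kcal/mol E_oi=kcal/mol closure_residual=kcal/mol "
    "S_homo_lumo=dimensionless"
)

_CORE_COLUMNS = ["r_angstrom", "theta_deg", "status",
                 "E_complex", "E_A_dist", "E_B_dist"]


class TableError(ValueError):
    pass


def write_surface_table(
    path,
    scan: ScanResult,
    table: pd.DataFrame | None = None,
) -> None:
    """Write the per-cell energy (and optional decomposition) table.

    Deterministic: fixed column order, fixed float format, rows in
    theta-major grid order.
    """
    df = scan.to_frame()
    if table is not None:
        extra = table.drop(
            columns=[c for c in ("status",) if c in table.columns]
        )
        df = df.merge(extra, on=["r_angstrom", "theta_deg"], how="left")
    cols = _CORE_COLUMNS + [
        c for c in df.columns if c not in _CORE_COLUMNS and c != "clash"
    ] + ["clash"]
    df = df[[c for c in cols if c in df.columns]]
    header = [
        HEADER_MAGIC,
        UNITS_LINE,
        f"# engine={scan.provenance.get('engine', 'unknown')} "
        f"mode={scan.mode}",
        f"# E_A_relaxed={scan.E_A_relaxed!r} "
        f"E_B_relaxed={scan.E_B_relaxed!r}",
        f"# grid={scan.gridspec.r_min},{scan.gridspec.r_max},"
        f"{scan.gridspec.r_step},{scan.gridspec.theta_min},"
        f"{scan.gridspec.theta_max},{scan.gridspec.theta_step}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        # %.17g guarantees exact float64 round trips through the reader
        df.to_csv(fh, index=False, float_format="%.17g", lineterminator="\n")


def read_surface_table(path) -> tuple[ScanResult, pd.DataFrame]:
    """Read a surface table into a (ScanResult, decomposition frame) pair.

    The grid is inferred from the header (or from the rows) and validated
    against the lattice rules; cells absent from the file are masked as
    failed points.  The returned ScanResult carries energies but no
    geometries, which is sufficient for every analysis that does not need
    wavefunctions.
    """
    path = Path(path)
    header: dict[str, str] = {}
    lines = path.read_text().splitlines()
    n_comment = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_comment += 1
        for tok in line[1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                header.setdefault(k, v)
    if not lines or lines[0].strip() != HEADER_MAGIC:
        raise TableError(f"{path} is not an edascan surface table")
    if "r_angstrom" not in header:
        raise TableError("table header does not declare units")
    df = pd.read_csv(path, comment="#")
    missing = {"r_angstrom", "theta_deg", "E_complex"} - set(df.columns)
    if missing:
        raise TableError(f"table lacks columns {sorted(missing)}")

    if "grid" in header:
        g = [float(x) for x in header["grid"].split(",")]
        spec = GridSpec(*g)
    else:
        spec = infer_gridspec(df["r_angstrom"].values, df["theta_deg"].values)

    seen = set()
    cells: dict[tuple[int, int], ScanPoint] = {}
    for row in df.itertuples(index=False):
        ir, it = spec.index_of(row.r_angstrom, row.theta_deg)
        if (ir, it) in seen:
            raise TableError(
                f"duplicate cell ({row.r_angstrom}, {row.theta_deg})"
            )
        seen.add((ir, it))
        status = getattr(row, "status", "converged")
        ok = status == "converged" and np.isfinite(row.E_complex)
        cells[(ir, it)] = ScanPoint(
            r=float(spec.r_values[ir]),
            theta=float(spec.theta_values[it]),
            status="converged" if ok else "failed",
            geometry=None,
            E_complex=float(row.E_complex) if ok else None,
            E_A_dist=float(getattr(row, "E_A_dist", np.nan)) if ok else None,
            E_B_dist=float(getattr(row, "E_B_dist", np.nan)) if ok else None,
            clash=bool(getattr(row, "clash", False)),
        )
    points = []
    for it in range(spec.n_theta):
        for ir in range(spec.n_r):
            points.append(cells.get((ir, it)) or ScanPoint(
                r=float(spec.r_values[ir]),
                theta=float(spec.theta_values[it]),
                status="failed",
            ))
    # placeholder two-atom pair: analysis-only results carry no geometries
    dummy = Geometry(["He", "He"], [[0.0, 0.0, 0.0], [0.0, 0.0, 3.0]])
    template = FragmentPair(
        dummy, (0,), (1,), 0, 1, 0, 1, 0, 1, 1
    )
    scan = ScanResult.__new__(ScanResult)
    scan.gridspec = spec
    scan.mode = header.get("mode", "external")
    scan.points = points
    scan.E_A_relaxed = float(header.get("E_A_relaxed", "nan"))
    scan.E_B_relaxed = float(header.get("E_B_relaxed", "nan"))
    scan.pair_template = template
    scan.provenance = {"engine": header.get("engine", "external"),
                       "source": str(path)}
    deco_cols = [c for c in df.columns if c not in _CORE_COLUMNS + ["clash"]]
    table = df[["r_angstrom", "theta_deg", "status", *deco_cols]] \
        if deco_cols else df[["r_angstrom", "theta_deg", "status"]].copy()
    if "status" not in df.columns:
        table = table.assign(status="converged")
    return scan, table


def infer_gridspec(r_values, theta_values) -> GridSpec:
    """Lattice parameters from scattered (r, theta) samples."""

    def axis(vals, name):
        u = np.unique(np.round(np.asarray(vals, dtype=float), 9))
        if len(u) == 1:
            return float(u[0]), float(u[0]), 1.0
        steps = np.diff(u)
        step = steps.min()
        if np.any(np.abs(steps / step - np.round(steps / step)) > 1e-6):
            raise TableError(f"{name} values are not on a regular lattice")
        return float(u[0]), float(u[-1]), float(step)

    rmin, rmax, rstep = axis(r_values, "r")
    tmin, tmax, tstep = axis(theta_values, "theta")
    return GridSpec(rmin, rmax, rstep, tmin, tmax, tstep)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Everything one pipeline run needs, loadable from YAML."""

    nucleophile_xyz: str | None = None
    acceptor_xyz: str | None = None
    nucleophile_charge: int = -1
    acceptor_charge: int = 0
    attack_atom: int = 0
    carbonyl_c: int = 0
    carbonyl_o: int = 1
    grid: tuple = (1.25, 2.95, 0.1, 70.0, 155.0, 5.0)
    engine: str = "rhf"
    basis: str = "sto-3g"
    scan_mode: str = "rigid"
    analyses: tuple = ("asm", "eda", "overlap")
    section_distances: tuple = (1.95,)
    output_dir: str = "edascan_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.scan_mode not in ("rigid", "relaxed"):
            raise TableError(f"unknown scan mode {self.scan_mode!r}")
        spec = self.gridspec  # validates lattice rules
        for d in self.section_distances:
            if not (spec.r_min - 1e-9 <= d <= spec.r_max + 1e-9):
                raise TableError(
                    f"section distance {d} outside grid range"
                )
        for p in (self.nucleophile_xyz, self.acceptor_xyz):
            if p is not None and not Path(p).exists():
                raise TableError(f"referenced file {p} does not exist")

    @property
    def gridspec(self) -> GridSpec:
        return GridSpec(*self.grid)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise TableError(f"unknown config keys {sorted(bad)}")
        for key in ("grid", "analyses", "section_distances"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)
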