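"""Grid scans: rigid embedding and constrained relaxed optimization.

A scan walks the (r, theta) lattice in a deterministic order -- for each
angle, distances descending, then the next angle -- so the nucleophile
approaches from afar and every point can warm-start from the nearest
previously converged neighbor (its SCF density in rigid mode, its geometry
in relaxed mode).  Failed points are masked and the scan continues;
short-distance, high-repulsion cells are expected to be the hard ones.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    FragmentPair,
    Geometry,
    GridPoint,
    GridSpec,
    align_carbonyl,
    embed_nucleophile,
)
from .optimize import OptSettings, pinned_relax, relax


class ScanError(RuntimeError):
    pass


@dataclass
class ScanPoint:
    """One evaluated lattice cell."""

    r: float
    theta: float
    status: str  # 'converged' | 'failed'
    geometry: Geometry | None = None
    E_complex: float | None = None
    E_A_dist: float | None = None
    E_B_dist: float | None = None
    clash: bool = False

    def as_grid_point(self) -> GridPoint:
        return GridPoint(self.r, self.theta, self.geometry,
                         "converged" if self.status == "converged" else "failed")


@dataclass
class ScanResult:
    """All per-point energies plus the relaxed fragment references."""

    gridspec: GridSpec
    mode: str  # 'rigid' | 'relaxed'
    points: list
    E_A_relaxed: float
    E_B_relaxed: float
    pair_template: FragmentPair
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.points) != self.gridspec.size:
            raise ScanError("scan must carry exactly one record per cell")

    def point_at(self, r: float, theta: float) -> ScanPoint:
        ir, it = self.gridspec.index_of(r, theta)
        return self.points[it * self.gridspec.n_r + ir]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            rows.append({
                "r_angstrom": p.r,
                "theta_deg": p.theta,
                "status": p.status,
                "E_complex": p.E_complex,
                "E_A_dist": p.E_A_dist,
                "E_B_dist": p.E_B_dist,
                "clash": p.clash,
            })
        return pd.DataFrame(rows)


def scan_order(spec: GridSpec) -> list[tuple[float, float]]:
    """(theta, r) visit order: angles ascending, distances descending."""
    return [
        (float(t), float(r))
        for t in spec.theta_values
        for r in spec.r_values[::-1]
    ]


class ScanCache:
    """Per-point JSON records keyed by (spec, engine, mode, r, theta)."""

    def __init__(self, directory):
        self.dir = Path(directory)
        self.dir.mkdir(parents=True, exist_ok=True)

    @staticmethod
    def _key(spec: GridSpec, engine_hash: str, mode: str,
             r: float | None = None, theta: float | None = None) -> str:
        payload = json.dumps(
            [spec.r_min, spec.r_max, spec.r_step, spec.theta_min,
             spec.theta_max, spec.theta_step, engine_hash, mode, r, theta]
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:24]

    def _path(self, *args) -> Path:
        return self.dir / (self._key(*args) + ".json")

    def load(self, *args):
        path = self._path(*args)
        if not path.exists():
            return None
        return json.loads(path.read_text())

    def store(self, record: dict, *args) -> None:
        self._path(*args).write_text(json.dumps(record))


def _fragment_prep(fp: FragmentPair, engine, opt_settings, relax_fragments):
    """Relax isolated fragments once and align the acceptor frame."""
    A = fp.fragment_geometry("A")
    B = fp.fragment_geometry("B")
    idx_b = list(fp.fragment_B_indices)
    c_loc = idx_b.index(fp.carbonyl_C)
    o_loc = idx_b.index(fp.carbonyl_O)
    idx_a = list(fp.fragment_A_indices)
    attack_loc = idx_a.index(fp.attack_atom_A)

    if relax_fragments:
        A = relax(A, engine, opt_settings).geometry
        B = relax(B, engine, opt_settings).geometry
    E_A = engine.compute_scf(A).energy
    E_B = engine.compute_scf(B).energy

    # sp2-plane reference: the heaviest non-carbonyl atom bound to the carbon
    dists = np.linalg.norm(B.coords - B.coords[c_loc], axis=1)
    order = np.argsort(dists)
    plane_loc = next(
        int(i) for i in order if i not in (c_loc, o_loc)
    )
    B_aligned = align_carbonyl(B, c_loc, o_loc, plane_loc)
    return A, B_aligned, E_A, E_B, c_loc, o_loc, attack_loc


def _canonical_pair(fp: FragmentPair, complex_geom: Geometry,
                    n_b: int, n_a: int, c_loc: int, o_loc: int,
                    attack_loc: int) -> FragmentPair:
    """Scan complexes store acceptor atoms first, nucleophile appended."""
    return FragmentPair(
        complex_geometry=complex_geom,
        fragment_A_indices=tuple(range(n_b, n_b + n_a)),
        fragment_B_indices=tuple(range(n_b)),
        charge_A=fp.charge_A,
        multiplicity_A=fp.multiplicity_A,
        charge_B=fp.charge_B,
        multiplicity_B=fp.multiplicity_B,
        attack_atom_A=n_b + attack_loc,
        carbonyl_C=c_loc,
        carbonyl_O=o_loc,
    )


def _provenance(engine, spec, mode, opt_settings=None) -> dict:
    return {
        "engine": engine.hash,
        "mode": mode,
        "grid": [spec.r_min, spec.r_max, spec.r_step,
                 spec.theta_min, spec.theta_max, spec.theta_step],
        "opt": None if opt_settings is None else {
            "max_gradient": opt_settings.max_gradient,
            "energy_change": opt_settings.energy_change,
            "max_iterations": opt_settings.max_iterations,
        },
        "timestamp": datetime.datetime.now(datetime.UTC).isoformat(),
    }


def run_rigid_scan(
    fp: FragmentPair,
    spec: GridSpec,
    engine,
    opt_settings: OptSettings | None = None,
    relax_fragments: bool = True,
    cache: ScanCache | None = None,
    progress=None,
) -> ScanResult:
    """Frozen-fragment scan: embed relaxed fragments at each (r, theta).

    Fragment strain is exactly zero by construction, so the total-energy
    surface equals the interaction-energy surface of the rigid approach.
    """
    opt_settings = opt_settings or OptSettings()
    mode = "rigid"
    refs = cache.load(spec, engine.hash, mode) if cache else None
    if refs is not None:
        A = _geom_from_record(refs["A"])
        B_aligned = _geom_from_record(refs["B"])
        E_A, E_B = refs["E_A"], refs["E_B"]
        c_loc, o_loc, attack_loc = refs["locs"]
    else:
        A, B_aligned, E_A, E_B, c_loc, o_loc, attack_loc = _fragment_prep(
            fp, engine, opt_settings, relax_fragments
        )
        if cache:
            cache.store(
                {"A": _geom_record(A), "B": _geom_record(B_aligned),
                 "E_A": E_A, "E_B": E_B,
                 "locs": [c_loc, o_loc, attack_loc]},
                spec, engine.hash, mode,
            )

    by_cell: dict[tuple[float, float], ScanPoint] = {}
    guess = None
    last_theta = None
    for theta, r in scan_order(spec):
        if theta != last_theta:
            guess = None  # new approach column
            last_theta = theta
        rec = cache.load(spec, engine.hash, mode, r, theta) if cache else None
        if rec is not None:
            by_cell[(r, theta)] = _point_from_record(rec)
            continue
        comp = embed_nucleophile(B_aligned, A, r, theta,
                                 attack_atom=attack_loc)
        point = ScanPoint(r=r, theta=theta, status="failed",
                          geometry=comp, clash=comp.info.get("clash", False))
        try:
            sol = engine.compute_scf(comp, guess=guess)
            if sol.converged:
                point.status = "converged"
                point.E_complex = sol.energy
                point.E_A_dist = E_A  # frozen fragments: zero strain exactly
                point.E_B_dist = E_B
                guess = getattr(sol, "density", None) \
                    if sol.occupations.size else None
        except Exception:
            point.status = "failed"
        if cache:
            cache.store(_point_record(point), spec, engine.hash, mode, r, theta)
        by_cell[(r, theta)] = point
        if progress:
            progress(point)

    points = [
        by_cell[(float(r), float(t))]
        for t in spec.theta_values for r in spec.r_values
    ]
    template = _canonical_pair(
        fp,
        points[0].geometry if points[0].geometry is not None
        else embed_nucleophile(B_aligned, A, spec.r_max, spec.theta_min,
                               attack_atom=attack_loc),
        B_aligned.natoms, A.natoms, c_loc, o_loc, attack_loc,
    )
    return ScanResult(
        gridspec=spec, mode=mode, points=points,
        E_A_relaxed=E_A, E_B_relaxed=E_B, pair_template=template,
        provenance=_provenance(engine, spec, mode),
    )


def run_relaxed_scan(
    fp: FragmentPair,
    spec: GridSpec,
    engine,
    opt_settings: OptSettings | None = None,
    relax_fragments: bool = True,
    cache: ScanCache | None = None,
    progress=None,
) -> ScanResult:
    """Constrained relaxed scan: optimize everything but (r, theta).

    Each point warm-starts from the nearest previously converged neighbor
    (previous distance in the same approach column, else the same distance
    in the previous column); a diverged optimization is retried from the
    rigid embedding before the point is marked failed.
    """
    opt_settings = opt_settings or OptSettings()
    mode = "relaxed"
    refs = cache.load(spec, engine.hash, mode) if cache else None
    if refs is not None:
        A = _geom_from_record(refs["A"])
        B_aligned = _geom_from_record(refs["B"])
        E_A, E_B = refs["E_A"], refs["E_B"]
        c_loc, o_loc, attack_loc = refs["locs"]
    else:
        A, B_aligned, E_A, E_B, c_loc, o_loc, attack_loc = _fragment_prep(
            fp, engine, opt_settings, relax_fragments
        )
        if cache:
            cache.store(
                {"A": _geom_record(A), "B": _geom_record(B_aligned),
                 "E_A": E_A, "E_B": E_B,
                 "locs": [c_loc, o_loc, attack_loc]},
                spec, engine.hash, mode,
            )
    n_b, n_a = B_aligned.natoms, A.natoms

    by_cell: dict[tuple[float, float], ScanPoint] = {}
    prev_in_column: Geometry | None = None
    prev_column: dict[float, Geometry] = {}
    this_column: dict[float, Geometry] = {}
    last_theta = None
    for theta, r in scan_order(spec):
        if theta != last_theta:
            prev_in_column = None
            prev_column = this_column
            this_column = {}
            last_theta = theta
        rec = cache.load(spec, engine.hash, mode, r, theta) if cache else None
        if rec is not None:
            point = _point_from_record(rec)
            by_cell[(r, theta)] = point
            if point.status == "converged":
                prev_in_column = point.geometry
                this_column[r] = point.geometry
            continue

        rigid = embed_nucleophile(B_aligned, A, r, theta,
                                  attack_atom=attack_loc)
        # nearest converged neighbor: the same distance in the previous
        # angle column is much closer in geometry than the previous (larger)
        # distance in this column
        start = prev_column.get(r)
        if start is None:
            start = prev_in_column
        starts = [] if start is None else [start]
        starts.append(rigid)
        point = ScanPoint(r=r, theta=theta, status="failed",
                          geometry=rigid, clash=rigid.info.get("clash", False))
        for start_geom in starts:
            try:
                g0 = rigid.copy()
                g0.coords = start_geom.coords.copy()
                pair = _canonical_pair(fp, g0, n_b, n_a, c_loc, o_loc,
                                       attack_loc)
                res = pinned_relax(pair, r, theta, engine, opt_settings)
            except Exception:
                continue
            if res.converged:
                point.status = "converged"
                point.geometry = res.geometry
                point.E_complex = res.energy
                frag_pair = _canonical_pair(
                    fp, res.geometry, n_b, n_a, c_loc, o_loc, attack_loc
                )
                point.E_A_dist = engine.compute_scf(
                    frag_pair.fragment_geometry("A")
                ).energy
                point.E_B_dist = engine.compute_scf(
                    frag_pair.fragment_geometry("B")
                ).energy
                prev_in_column = res.geometry
                this_column[r] = res.geometry
                break
        if cache:
            cache.store(_point_record(point), spec, engine.hash, mode, r, theta)
        by_cell[(r, theta)] = point
        if progress:
            progress(point)

    points = [
        by_cell[(float(r), float(t))]
        for t in spec.theta_values for r in spec.r_values
    ]
    template = _canonical_pair(
        fp,
        points[0].geometry if points[0].geometry is not None
        else embed_nucleophile(B_aligned, A, spec.r_max, spec.theta_min,
                               attack_atom=attack_loc),
        n_b, n_a, c_loc, o_loc, attack_loc,
    )
    return ScanResult(
        gridspec=spec, mode=mode, points=points,
        E_A_relaxed=E_A, E_B_relaxed=E_B, pair_template=template,
        provenance=_provenance(engine, spec, mode, opt_settings),
    )


# -- cache (de)serialization -------------------------------------------------

def _geom_record(g: Geometry) -> dict:
    return {
        "atoms": list(g.atoms),
        "coords": np.asarray(g.coords).tolist(),
        "charge": g.charge,
        "multiplicity": g.multiplicity,
    }


def _geom_from_record(d: dict) -> Geometry:
    return Geometry(d["atoms"], np.array(d["coords"]), d["charge"],
                    d["multiplicity"])


def _point_record(p: ScanPoint) -> dict:
    return {
        "r": p.r, "theta": p.theta, "status": p.status,
        "geometry": None if p.geometry is None else _geom_record(p.geometry),
        "E_complex": p.E_complex, "E_A_dist": p.E_A_dist,
        "E_B_dist": p.E_B_dist, "clash": p.clash,
    }


def _point_from_record(d: dict) -> ScanPoint:
    return ScanPoint(
        r=d["r"], theta=d["theta"], status=d["status"],
        geometry=None if d["geometry"] is None
        else _geom_from_record(d["geometry"]),
        E_complex=d["E_complex"], E_A_dist=d["E_A_dist"],
        E_B_dist=d["E_B_dist"], clash=d["clash"],
    )
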