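"""Geometry optimization: free relaxation and (r, theta)-constrained
relaxation of attack complexes.

Minimization runs in Cartesian coordinates with scipy; the two scan
coordinates (attacking-atom--carbonyl-carbon distance and Nu-C-O angle) are
imposed as smooth equality constraints with analytic Jacobians, mirroring a
constrained relaxed scan.  Convergence is judged on the projected gradient
(gradient with the constraint directions removed) so a point counts as
converged only when the unconstrained degrees of freedom are relaxed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .geometry import FragmentPair, Geometry
from .units import ANGSTROM_PER_BOHR

# gradient conversion: hartree/bohr -> hartree/angstrom
_PER_ANG = 1.0 / ANGSTROM_PER_BOHR


@dataclass(frozen=True)
class OptSettings:
    """Convergence thresholds for geometry optimization.

    max_gradient: hartree/bohr, on the (projected) nuclear gradient.
    energy_change: hartree, optimizer step-to-step objective tolerance.
    max_iterations: iteration cap; exceeding it marks the point unconverged.
    constraint_r_tol / constraint_theta_tol: allowed residual deviation of
    the constrained coordinates (angstrom / degrees).
    """

    max_gradient: float = 4.5e-4
    energy_change: float = 1e-6
    max_iterations: int = 100
    constraint_r_tol: float = 1e-4
    constraint_theta_tol: float = 1e-3

    def fast(self) -> "OptSettings":
        """Looser scan preset for coarse survey grids: residual forces up to
        ~3 kcal/mol/A on soft modes, which perturbs survey energies by well
        under a kcal/mol -- negligible against the tens of kcal/mol contrasts
        the survey grids resolve."""
        return replace(self, max_gradient=5e-3, energy_change=1e-5,
                       max_iterations=80)


@dataclass
class RelaxResult:
    geometry: Geometry
    energy: float
    converged: bool
    n_iterations: int
    max_gradient: float


def _energy_and_grad(engine, template: Geometry):
    """Objective closure over flattened angstrom coordinates."""

    def fun(x):
        g = template.copy()
        g.coords = x.reshape(-1, 3)
        mats = getattr(engine, "matrices", None)
        m = mats(g) if mats is not None else None
        sol = engine.compute_scf(g, mats=m)
        grad = engine.gradient(g, sol=sol, mats=m)
        if hasattr(engine, "matrices"):
            grad = grad * _PER_ANG  # hartree/bohr -> hartree/angstrom
        return sol.energy, grad.ravel()

    return fun


def relax(geometry: Geometry, engine,
          settings: OptSettings | None = None) -> RelaxResult:
    """Unconstrained minimization of an isolated fragment or complex."""
    settings = settings or OptSettings()
    fun = _energy_and_grad(engine, geometry)
    gtol_ang = settings.max_gradient * (
        _PER_ANG if hasattr(engine, "matrices") else 1.0
    )
    res = minimize(
        fun, geometry.coords.ravel(), jac=True, method="L-BFGS-B",
        options={
            "maxiter": settings.max_iterations,
            "gtol": gtol_ang,
            # L-BFGS-B ftol is relative to |f|; total energies are O(10^2)
            # hartree, so scale it down to keep the gradient test binding
            "ftol": settings.energy_change * 1e-3,
        },
    )
    out = geometry.copy()
    out.coords = res.x.reshape(-1, 3)
    grad = res.jac if getattr(res, "jac", None) is not None else fun(res.x)[1]
    gmax = float(np.abs(grad).max()) / (
        _PER_ANG if hasattr(engine, "matrices") else 1.0
    )
    return RelaxResult(
        geometry=out,
        energy=float(res.fun),
        converged=bool(gmax <= settings.max_gradient * 1.5 or res.success),
        n_iterations=int(res.nit),
        max_gradient=gmax,
    )


def _distance_constraint(i: int, j: int, r0: float):
    def val(x):
        c = x.reshape(-1, 3)
        return float(np.linalg.norm(c[i] - c[j]) - r0)

    def jac(x):
        c = x.reshape(-1, 3)
        d = c[i] - c[j]
        n = np.linalg.norm(d)
        out = np.zeros_like(c)
        out[i] = d / n
        out[j] = -d / n
        return out.ravel()

    return val, jac


def _angle_constraint(i: int, j: int, k: int, theta0_deg: float):
    """Angle i-j-k in radians relative to the target."""
    t0 = math.radians(theta0_deg)

    def _geom(x):
        c = x.reshape(-1, 3)
        u = c[i] - c[j]
        v = c[k] - c[j]
        nu = np.linalg.norm(u)
        nv = np.linalg.norm(v)
        cu = u / nu
        cv = v / nv
        cos_t = float(np.clip(cu @ cv, -1.0, 1.0))
        sin_t = math.sqrt(max(1.0 - cos_t * cos_t, 1e-14))
        return c, cu, cv, nu, nv, cos_t, sin_t

    def val(x):
        *_, cos_t, _ = _geom(x)
        return math.acos(cos_t) - t0

    def jac(x):
        c, cu, cv, nu, nv, cos_t, sin_t = _geom(x)
        out = np.zeros_like(c)
        di = -(cv - cos_t * cu) / (sin_t * nu)
        dk = -(cu - cos_t * cv) / (sin_t * nv)
        out[i] = di
        out[k] = dk
        out[j] = -di - dk
        return out.ravel()

    return val, jac


def _projected_gradient(grad: np.ndarray, jacs: list[np.ndarray]) -> np.ndarray:
    """Remove the constraint directions from a flattened gradient."""
    J = np.vstack(jacs)
    lam, *_ = np.linalg.lstsq(J.T, grad, rcond=None)
    return grad - J.T @ lam


def _mirror_pairs(atoms, coords, tol=0.12):
    """Atom pairing under the xz mirror (y -> -y); None if not symmetric.

    Returns (pairs, in_plane): pairs of (representative, partner) indices
    and the list of atoms lying in the mirror plane.
    """
    n = len(atoms)
    mirrored = coords * np.array([1.0, -1.0, 1.0])
    used = set()
    pairs = []
    in_plane = []
    for i in range(n):
        if i in used:
            continue
        if abs(coords[i, 1]) < tol:
            in_plane.append(i)
            used.add(i)
            continue
        partner = None
        for j in range(n):
            if j in used or j == i or atoms[j] != atoms[i]:
                continue
            if np.linalg.norm(coords[j] - mirrored[i]) < tol:
                partner = j
                break
        if partner is None:
            return None
        pairs.append((i, partner))
        used.add(i)
        used.add(partner)
    return pairs, in_plane


def pinned_relax(
    fp: FragmentPair,
    r0: float,
    theta0: float,
    engine,
    settings: OptSettings | None = None,
) -> RelaxResult:
    """Constrained relaxation via a constraint-eliminating parametrization.

    Valid for complexes prepared in the canonical attack frame (carbonyl C
    at the origin, O on +x, nucleophile in the xz plane): the scan
    constraints are imposed exactly by pinning the attacking atom at
    (r cos t, 0, r sin t), while the frame gauge pins the carbonyl carbon
    (translations), the O direction (two rotations) and the attack-atom
    y component (the rotation about the C=O axis) -- eight conditions for
    six rigid-body modes plus the two scan constraints, so every internal
    degree of freedom stays free.  The attack azimuth sits in the xz
    mirror plane, which is a symmetry plane of acetone-like complexes.

    When the starting structure is mirror-symmetric about the xz plane the
    optimization runs in the totally symmetric subspace: mirror partners
    are slaved to their representatives and in-plane atoms keep y = 0.
    That halves the variable count and keeps the relaxed scan on the
    symmetric branch; asymmetric systems fall back to the full space.
    Minimization is L-BFGS over the free Cartesians.
    """
    settings = settings or OptSettings()
    g0 = fp.complex_geometry
    n = g0.natoms
    i_att = fp.attack_atom_A
    i_c = fp.carbonyl_C
    i_o = fp.carbonyl_O

    t = math.radians(theta0)
    pin_pos = np.array([r0 * math.cos(t), 0.0, r0 * math.sin(t)])
    base = g0.coords.copy()
    # move the nucleophile rigidly so the attack atom sits on its pin
    shift = pin_pos - base[i_att]
    for i in fp.fragment_A_indices:
        base[i] += shift
    base[i_c] = 0.0
    base[i_o, 1] = 0.0
    base[i_o, 2] = 0.0

    free = np.ones((n, 3), dtype=bool)
    free[i_att] = False
    free[i_c] = False
    free[i_o, 1] = False
    free[i_o, 2] = False

    M = np.array([1.0, -1.0, 1.0])
    sym = _mirror_pairs(g0.atoms, base)
    if sym is not None:
        pairs, in_plane = sym
        for i in in_plane:
            base[i, 1] = 0.0
            free[i, 1] = False
        for i, j in pairs:
            base[j] = base[i] * M
            free[j] = False
    else:
        pairs = []

    # per-variable weight for the physical gradient norm: a pair variable
    # carries the force on both partners
    weight = np.ones((n, 3))
    for i, j in pairs:
        weight[i] = 2.0

    unit = _PER_ANG if hasattr(engine, "matrices") else 1.0
    last_density = [None]  # SCF warm start across optimizer steps

    def expand(x):
        coords = base.copy()
        coords[free] = x
        for i, j in pairs:
            coords[j] = coords[i] * M
        return coords

    # forces the optimizer never reads: fully pinned atoms and
    # symmetry-slaved mirror partners (their force is the mirrored force
    # of the representative)
    skip_atoms = [i_att, i_c] + [j for _, j in pairs]

    def fun(x):
        g = g0.copy()
        g.coords = expand(x)
        if hasattr(engine, "matrices"):
            m = engine.matrices(g)
            sol = engine.compute_scf(g, guess=last_density[0], mats=m)
            if sol.occupations.size:
                last_density[0] = sol.density
            grad = engine.gradient(g, sol=sol, mats=m,
                                   skip_atoms=skip_atoms) * unit
            for i, _ in pairs:
                grad[i] *= 2.0
        else:
            sol = engine.compute_scf(g)
            grad = engine.gradient(g, sol=sol) * unit
            for i, j in pairs:
                grad[i] += grad[j] * M
        return sol.energy, grad[free]

    res = minimize(
        fun, base[free], jac=True, method="L-BFGS-B",
        options={"maxiter": settings.max_iterations,
                 "maxcor": 30,  # stiff bonds + soft bends: keep history
                 "gtol": settings.max_gradient * unit,
                 "ftol": settings.energy_change * 1e-3},
    )
    out = g0.copy()
    out.coords = expand(res.x)
    grad = res.jac if getattr(res, "jac", None) is not None \
        else fun(res.x)[1]
    gmax = float(np.abs(grad / weight[free]).max()) / unit
    return RelaxResult(
        geometry=out,
        energy=float(res.fun),
        converged=bool(gmax <= settings.max_gradient * 1.5 or res.success),
        n_iterations=int(res.nit),
        max_gradient=gmax,
    )


def constrained_relax(
    fp: FragmentPair,
    r0: float,
    theta0: float,
    engine,
    settings: OptSettings | None = None,
) -> RelaxResult:
    """Relax all degrees of freedom except the (r, theta) scan coordinates."""
    settings = settings or OptSettings()
    g0 = fp.complex_geometry
    fun = _energy_and_grad(engine, g0)
    unit = _PER_ANG if hasattr(engine, "matrices") else 1.0

    rv, rj = _distance_constraint(fp.attack_atom_A, fp.carbonyl_C, r0)
    av, aj = _angle_constraint(fp.attack_atom_A, fp.carbonyl_C,
                               fp.carbonyl_O, theta0)
    res = minimize(
        fun, g0.coords.ravel(), jac=True, method="SLSQP",
        constraints=[
            {"type": "eq", "fun": rv, "jac": rj},
            {"type": "eq", "fun": av, "jac": aj},
        ],
        options={"maxiter": settings.max_iterations,
                 "ftol": settings.energy_change},
    )
    x = res.x
    e = float(res.fun)
    grad = res.jac if getattr(res, "jac", None) is not None else fun(x)[1]
    gproj = _projected_gradient(grad, [rj(x), aj(x)])
    gmax = float(np.abs(gproj).max()) / unit
    ok_constraints = (
        abs(rv(x)) <= settings.constraint_r_tol
        and abs(math.degrees(av(x))) <= settings.constraint_theta_tol
    )
    out = g0.copy()
    out.coords = x.reshape(-1, 3)
    converged = bool(
        ok_constraints and (gmax <= settings.max_gradient * 1.5 or res.success)
    )
    return RelaxResult(
        geometry=out,
        energy=float(e),
        converged=converged,
        n_iterations=int(res.nit),
        max_gradient=gmax,
    )
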