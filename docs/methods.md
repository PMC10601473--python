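# Methods

## The model

`edascan` maps how the energy of a nucleophile/carbonyl encounter complex
changes over a two-dimensional grid of approach geometries and splits that
change into physically interpretable pieces.  The two scan coordinates are
the distance r between the attacking atom of the nucleophile and the
carbonyl carbon, and the attack angle theta (attacking atom - carbonyl C -
carbonyl O).  The carbonyl fragment defines a canonical frame: carbonyl C
at the origin, the C=O bond along +x, the sp2 plane equal to the xy plane.
The nucleophile is placed in the xz plane,

    p(r, theta) = (r cos theta, 0, r sin theta),

i.e. on the plane that contains the C=O axis and is perpendicular to the
carbonyl plane -- the classic trajectory plane of nucleophilic attack, on
which the Buergi-Dunitz angle (~107 deg) is defined.  An in-plane (xy)
variant is available.

Two nested decompositions are computed at each grid point.

**Strain/interaction (distortion-interaction, activation-strain) split.**
With respect to relaxed, infinitely separated fragments A (nucleophile)
and B (carbonyl compound):

    dE(r, theta) = dE_strain + dE_int
    dE_strain    = [E_A(in-complex geometry) - E_A(relaxed)]
                 + [E_B(in-complex geometry) - E_B(relaxed)]
    dE_int       = E_complex - E_A(in-complex) - E_B(in-complex)

Both identities hold exactly by construction; the test suite asserts them
to better than 1e-6 hartree at every scanned point.

**Interaction-energy decomposition (Ziegler-Rauk type).**

    dE_int = dV_elstat + dE_Pauli + dE_oi

* `dV_elstat`: quasi-classical electrostatic interaction of the frozen,
  unrelaxed fragment charge distributions -- cross nuclear repulsion,
  each fragment density in the other fragment's nuclear potential, and the
  inter-fragment Coulomb term.  Symmetric under fragment exchange.
* `dE_Pauli`: the energy rise upon enforcing antisymmetry between the two
  frozen fragment wavefunctions.  The occupied orbitals of both fragments
  are zero-padded onto the dimer basis (exact, because the fragments
  occupy disjoint atom sets), symmetrically Loewdin-orthonormalized under
  the dimer overlap metric, and the full-system energy functional is
  evaluated non-self-consistently on the resulting idempotent density
  E[Psi0]; dE_Pauli = E[Psi0] - E_A - E_B - dV_elstat.
* `dE_oi`: orbital interaction (filled/empty mixing plus intra-fragment
  polarization), defined as the closure remainder
  dE_oi = dE_int - dV_elstat - dE_Pauli.  Defining it as the remainder
  makes the decomposition close exactly; any numerical defect would land
  in the reported `closure_residual` diagnostic instead of hiding inside a
  term.  Because the full SCF minimizes over all determinants including
  Psi0, dE_oi <= 0 up to SCF convergence; the complex SCF is seeded from
  the Psi0 density so both states sit on the same SCF branch.

Stabilizing terms are negative; public results are in kcal/mol
(1 hartree = 627.5094740631 kcal/mol); file formats carry angstrom and
degrees only.

**Orbital-overlap diagnostic.**  S = |c_HOMO(A)^T S_dimer c_LUMO(B)| with
fragment orbital coefficient vectors zero-padded into the dimer AO basis.
By default the acceptor is taken at its distorted in-complex geometry,
obtained from a constrained relaxation at the transition-state-like cell
of the sweep (r = 1.95 A, theta = 110 deg): pyramidalization tilts the
empty pi* orbital, and that tilt -- absent in the idealized planar
acceptor, selectable by flag -- is what shifts the overlap maximum above
90 deg.  The magnitude is reported because the phase of either orbital is
arbitrary.

## Electronic-structure engine

The built-in engine is restricted closed-shell Hartree-Fock over
contracted Cartesian Gaussians (STO-3G for H, He, C, N, O), with
McMurchie-Davidson integrals (Hermite expansion coefficients, Boys
function, Hermite Coulomb tensor) implemented as numba kernels:

* SCF: generalized Wolfsberg-Helmholz starting guess, Pulay DIIS with
  early-iteration damping, level-shifted damped fallback on
  non-convergence; energy-change threshold 1e-8 hartree and commutator
  residual 1e-6 (defaults).  Non-converged solutions are flagged and never
  used downstream.
* Analytic nuclear gradients via the angular-momentum increment identity
  per primitive, with translational invariance supplying operator-center
  and remaining-center derivatives; two-electron work is screened by
  Cauchy-Schwarz bounds weighted with shell-block density maxima
  (thresholds 1e-10 for shell quartets, 1e-13 per primitive), giving
  force noise orders of magnitude below the loosest optimizer threshold.
  Gradients are validated against central finite differences in the test
  suite (agreement ~1e-8 hartree/bohr).
* The engine contract (`compute_scf`, `matrices`, `gradient`,
  `energy_of_density`) is narrow so a higher-level method/basis is a
  configuration change, not a code path.  Open-shell systems are rejected
  explicitly.

The analytic mock engine implements
E = sum_pairs [ q_i q_j / r + A_ij r^-12 - B_ij r^-6 ] with per-element
parameters and geometric-mean combination rules.  Its cross-fragment
Coulomb / repulsive / dispersive partial sums are exact expected values
for the decomposition bookkeeping, so every orchestration layer (scans,
caching, tables, surfaces, CLI) is testable in seconds without an SCF.
In mock mode the three interaction components are those partial sums and
the closure identities are exact to machine precision.

## Scans

Grid points are visited angle column by angle column, distances
descending (approach from afar).  Rigid scans embed the frozen relaxed
fragments at each (r, theta); fragment strain is identically zero by
construction.  Relaxed scans minimize all degrees of freedom except the
two scan coordinates.  The constraints are imposed exactly through a
constraint-eliminating parametrization: the attacking atom is pinned at
p(r, theta) while the carbonyl carbon (translations), the O direction
(two rotations) and the attack-atom y component (rotation about the C=O
axis) fix the frame -- eight pinned coordinates for six rigid-body modes
plus the two scan constraints, so every internal degree of freedom stays
free.  Holding the attack azimuth in the xz plane uses the mirror
symmetry of the acetone-type complex (the attack plane is a Cs symmetry
plane); when the starting structure is mirror-symmetric the optimization
additionally runs in the totally symmetric subspace (mirror partners
slaved, in-plane atoms kept at y = 0), halving the variable count and
keeping the scan on the symmetric branch.  A general SLSQP path with
explicit equality constraints (distance + angle, analytic Jacobians) is
provided for acceptors without that symmetry.

Optimization is L-BFGS-B over the free Cartesians.  Defaults: maximum
residual gradient 4.5e-4 hartree/bohr, energy change 1e-6 hartree, 100
iterations.  The `fast()` survey preset loosens the gradient threshold to
5e-3 hartree/bohr (residual soft-mode forces of a few kcal/mol/A, which
move survey energies by well under a kcal/mol -- negligible against the
tens of kcal/mol contrasts the survey grids resolve).  Warm starts use the
converged geometry at the same distance in the previous angle column
(nearest neighbor in geometry), falling back to the previous distance in
the same column, then the rigid embedding; a failed optimization is
retried from the rigid embedding before the point is masked.  Failed
points are masked and the scan continues -- surfaces tolerate holes, and
short-distance high-repulsion cells are expected to be the hard ones.
Scan results can be cached per point (JSON records keyed by grid, engine
hash, mode and cell); a warm rerun replays without engine calls.

## Survey problem sizes

The desk-scale study of CN- + acetone runs at RHF/STO-3G:

* rigid survey: r = 1.45-2.95 A step 0.25 x theta = 70-155 deg step 5
  (126 points);
* relaxed survey: r = {1.55, 2.25, 2.95} x theta = 90-140 deg step 10
  (18 constrained optimizations, fast preset).  The three distance rows
  sample the product basin, the barrier ridge and the reactant basin; the
  angular window contains the landmark regions (saddle, interaction
  minimum);
* overlap sweep: r = 1.95 A, theta = 70-155 deg step 5 (18 points);
* long-range probe: r = {8, 10, 12} A x theta = {90, 120, 150} deg.

The saddle and the interaction-minimum angle are computed from the
relaxed survey by design: a frozen planar acetone cannot pyramidalize, so
a rigid scan has no adduct valley to connect to -- the strain release
that creates the product basin is exactly the physics the
strain/interaction split is meant to expose, and a minimax barrier is
only meaningful on the surface that contains both basins.

## Surface analyses

Named fields (E, E_strain, E_strain_A/B, E_int, V_elstat, E_pauli, E_oi,
S_overlap, closure_residual) are stored as n_r x n_theta arrays with
validity masks; masked cells never enter a statistic.  Cross-sections at
fixed r return the exact lattice row, or a flagged linear interpolation
between bracketing rows.  The global minimum breaks ties toward smaller
angle, then smaller distance.  The transition state of the sampled
landscape is the discrete minimax saddle: cells are activated in order of
increasing energy and merged with active 4-neighbors (union-find); the
activation that first connects the reactant-basin seed to the
product-basin seed realizes the minimum over connecting paths of the path
maximum.  Default seeds are the lowest valid cell in the largest-distance
row (reactant complex) and in the smallest-distance row (product),
overridable.  The finder is verified against exhaustive path enumeration
on small random fields, and a 3x3-stencil detector is provided as an
independent cross-check.  Barrier heights are reported relative to the
reactant seed and are invariant under constant shifts of the field.

## What the mock generator does and does not emulate

The mock pair potential produces smooth surfaces with a long-range
attractive well and a short-range repulsive wall, and exact decomposition
partial sums.  It has no electronic structure: no charge transfer, no
orbital overlap, no angular preference beyond geometry, and no
fragment-strain physics beyond bond-length relaxation.  Mock-mode tests
therefore establish the correctness of bookkeeping, orchestration,
serialization and surface analysis -- not chemistry.  Conclusions about
the attack-angle physics rest on the RHF surveys.

## Numerical choices and degenerate inputs

* Lattice membership tested to 1e-9 (relative); grids whose step does not
  divide the range are rejected.
* Alignment requires non-collinear reference atoms (sin of the frame
  angle > 1e-8); embedding rejects theta outside (0, 180] deg; contacts
  closer than 0.5 A set a clash flag instead of failing, because the
  short-distance repulsive region is intentionally sampled.
* The Loewdin orthonormalization refuses occupied-metric eigenvalues
  below 1e-10 (fused fragments) with an explicit error.
* Overlap-matrix eigenvalues below 1e-8 are projected out of the SCF
  orthogonalizer.
* Boys functions: converging series with downward recursion for T <= 35,
  asymptotic form with upward recursion beyond.
* scipy's L-BFGS-B `ftol` is relative to |f|; with total energies of
  order 100 hartree it is scaled by 1e-3 so the gradient criterion, not
  the energy criterion, terminates optimizations.

## Known limitations

* Minimal-basis restricted Hartree-Fock shifts landmark angles by several
  degrees relative to correlated, large-basis results; the survey grids
  resolve angles to their 5-10 deg spacing.  The package reports landmark
  positions, not absolute energetics, at this level.
* At this level the anion addition is nearly barrierless: the sampled
  total-energy surface crosses from the reactant basin to the adduct over
  a ridge only a fraction of a kcal/mol high, comparable to the residual
  of the fast optimizer preset.  The minimax saddle cell's angle is then
  decided by sub-kcal/mol differences and can move by one angular cell
  between equally defensible convergence settings, whereas the
  strain-driven angular structure (interaction minimum above the
  realized attack angle, steeply rising strain at high angles) is robust.
* Closed-shell fragments only; no solvation; no relativistic effects; no
  d functions in the built-in basis (elements H-O in practice).
* The relaxed-scan symmetry assumption (attack in the acceptor mirror
  plane) is correct for C2v-like acceptors such as acetone; for chiral or
  asymmetric acceptors use the general constrained path.
* dE_oi is a remainder: it absorbs basis-set superposition effects along
  with genuine orbital interaction, as in any fragment-based analysis
  without counterpoise correction.
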