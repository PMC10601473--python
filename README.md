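# edascan

Two-dimensional activation-strain and energy decomposition analysis of
nucleophilic attack trajectories on carbonyl compounds.

## The problem

When a nucleophile adds to a carbonyl group it does not approach
perpendicular to the C=O bond but along a trajectory tilted toward the
oxygen-opposed side -- the Buergi-Dunitz angle, near 107 deg.  Explaining
*why* requires more than locating a transition state: the preference is a
balance between how much the reactants must distort and how strongly they
interact, and that balance changes continuously with both the approach
distance and the approach angle.

`edascan` maps this balance.  It scans a grid of nucleophile positions
around the carbonyl carbon, parametrized by the attack distance r
(nucleophile atom to carbonyl C) and the attack angle theta
(Nu-C-O), and at every grid point splits the energy change into

    dE = dE_strain + dE_int                      (distortion-interaction /
                                                  activation-strain model)
    dE_int = dV_elstat + dE_Pauli + dE_oi        (Ziegler-Rauk-type
                                                  decomposition)

yielding a stack of surfaces -- total energy, fragment strain,
interaction, electrostatic, Pauli repulsion, orbital interaction, plus a
fragment HOMO/LUMO overlap diagnostic -- together with the analyses that
make them quantitative: fixed-distance cross-sections, masked extrema,
and a discrete minimax saddle finder that locates the transition state of
the sampled landscape.

It is aimed at computational organic chemists who want
trajectory-resolved strain/interaction analysis rather than
single-point comparisons.  Energies can come from the built-in
restricted Hartree-Fock engine (Gaussian basis, analytic gradients,
numba-accelerated integrals -- enough for desk-scale model systems such
as CN- + acetone), from the analytic mock engine (instant, exactly
decomposable pair potential for pipeline work), or from any external
quantum-chemistry program via the documented CSV surface-table format
(analysis-only mode).

## Worked example

The mock-engine demo runs the full pipeline -- fragment relaxation, a
rigid 18 x 18 scan over the default grid (r = 1.25-2.95 A by 0.1 A,
theta = 70-155 deg by 5 deg, 324 structures), both decompositions,
surface assembly and saddle analysis -- in about two seconds:

```bash
$ edascan demo --out demo_out
{"interaction_minimum": {"r": 1.9500000000000002, "theta": 110.0,
  "value": -0.7338031134148304},
 "points": 324,
 "saddle": {"barrier": 46.70239875720574, "r": 1.25, "theta": 125.0}}
```

`demo_out/surface_table.csv` holds one row per grid cell with the raw
energies (hartree) and every decomposition column (mock energy units for
the mock engine; kcal/mol for the RHF engine); `summary.json` repeats the
landmark analysis.  The numbers above are properties of the mock pair
potential -- useful for checking the bookkeeping (for example,
`V_elstat + E_pauli + E_oi` reproduces `E_int` to machine precision in
every row), not for chemistry.

The real study runs the same pipeline with the RHF engine:

```bash
edascan scan --engine rhf --mode relaxed --fast-opt \
    --grid "1.55:2.95:1.40,90:140:10" --out cn_acetone
edascan saddle --table cn_acetone/surface_table.csv --field E
edascan overlap --r 1.95          # HOMO/LUMO overlap angular sweep
```

or, from Python, through `edascan.workflows`, which fixes the survey
problem sizes used throughout the tests (see `docs/methods.md`).

## Layout

| module | contents |
| --- | --- |
| `edascan.geometry` | geometry/fragment types, carbonyl frame, embedding, grids, XYZ I/O |
| `edascan.engine` | engine contract, built-in RHF engine (integrals, SCF, gradients), mock engine |
| `edascan.scan` | rigid and relaxed scans, warm starts, per-point caching |
| `edascan.decompose` | strain/interaction split, electrostatic/Pauli/orbital decomposition, orbital overlap |
| `edascan.surface` | surface fields, cross-sections, extrema, minimax saddle |
| `edascan.io` / `edascan.cli` / `edascan.plotting` | surface tables, YAML config, command line, heatmaps |
| `edascan.workflows` | the desk-scale study protocols (survey grids, overlap sweep, long-range probe) |
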