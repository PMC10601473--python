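import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edascan import GridSpec, MockEngine, decompose_scan
from edascan.scan import run_rigid_scan
from edascan.surface import (
    SurfaceError,
    SurfaceField,
    argmin_surface,
    assemble_surface,
    cross_section,
    locate_saddle,
    stencil_saddles,
    surfaces_from_table,
    to_view,
)


def field_from(values, mask=None, spec=None):
    values = np.asarray(values, dtype=float)
    if spec is None:
        nr, nt = values.shape
        spec = GridSpec(1.0, 1.0 + 0.5 * (nr - 1), 0.5,
                        60.0, 60.0 + 10.0 * (nt - 1), 10.0)
    if mask is None:
        mask = np.ones_like(values, dtype=bool)
    return SurfaceField("E", values, mask, spec)


def brute_force_minimax(values, mask, start, goal):
    """Minimum over all 4-neighbor paths of the path maximum, by exhaustive
    depth-first enumeration of simple paths."""
    nr, nt = values.shape
    best = [np.inf]

    def neighbors(c):
        r, t = c
        for dr, dt in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, tt = r + dr, t + dt
            if 0 <= rr < nr and 0 <= tt < nt and mask[rr, tt]:
                yield (rr, tt)

    def dfs(cell, seen, cur_max):
        cur_max = max(cur_max, values[cell])
        if cur_max >= best[0]:
            return
        if cell == goal:
            best[0] = cur_max
            return
        for nb in neighbors(cell):
            if nb not in seen:
                dfs(nb, seen | {nb}, cur_max)

    dfs(start, {start}, -np.inf)
    return best[0]


@pytest.fixture(scope="module")
def mock_surfaces():
    from edascan.molecules import cyanide_acetone_pair

    eng = MockEngine()
    pair = cyanide_acetone_pair()
    spec = GridSpec(2.0, 3.0, 0.25, 80.0, 130.0, 10.0)
    scan = run_rigid_scan(pair, spec, eng)
    table = decompose_scan(scan, eng, analyses=("asm", "eda"))
    return scan, table


class TestAssemble:
    def test_rigid_strain_surface_is_zero(self, mock_surfaces):
        scan, table = mock_surfaces
        sf = assemble_surface(scan, table, "E_strain")
        assert sf.n_valid == scan.gridspec.size
        np.testing.assert_allclose(sf.values[sf.mask], 0.0, atol=1e-9)

    def test_strain_interaction_closure_field(self, mock_surfaces):
        scan, table = mock_surfaces
        E = assemble_surface(scan, table, "E").values
        Es = assemble_surface(scan, table, "E_strain").values
        Ei = assemble_surface(scan, table, "E_int").values
        np.testing.assert_allclose(E - (Es + Ei), 0.0, atol=1e-9)

    def test_eda_closure_field(self, mock_surfaces):
        scan, table = mock_surfaces
        sfs = surfaces_from_table(scan, table)
        resid = (
            sfs["V_elstat"].values + sfs["E_pauli"].values
            + sfs["E_oi"].values - sfs["E_int"].values
        )
        np.testing.assert_allclose(resid, 0.0, atol=1e-9)

    def test_unknown_field_rejected(self, mock_surfaces):
        scan, table = mock_surfaces
        with pytest.raises(SurfaceError):
            assemble_surface(scan, table, "enthalpy")

    def test_masked_cells_excluded_from_minima(self):
        vals = [[0.0, -5.0], [1.0, 2.0]]
        mask = [[True, False], [True, True]]
        sf = field_from(vals, mask)
        r, t, v = argmin_surface(sf)
        assert v == 0.0  # the -5 cell is masked out


class TestCrossSection:
    def test_on_lattice_row_identity(self):
        vals = np.arange(12.0).reshape(3, 4)
        sf = field_from(vals)
        cs = cross_section(sf, 1.5)
        np.testing.assert_array_equal(cs.values, vals[1])
        assert not cs.interpolated

    def test_midpoint_linear_interpolation(self):
        vals = np.array([[0.0, 2.0], [4.0, 6.0], [8.0, 10.0]])
        sf = field_from(vals)  # r lattice 1.0, 1.5, 2.0; linear in r
        cs = cross_section(sf, 1.25)
        np.testing.assert_allclose(cs.values, (vals[0] + vals[1]) / 2.0)
        assert cs.interpolated

    def test_outside_range_rejected(self):
        sf = field_from(np.zeros((3, 3)))
        with pytest.raises(SurfaceError):
            cross_section(sf, 5.0)


class TestArgmin:
    def test_paraboloid_minimum_cell(self):
        spec = GridSpec(1.0, 3.0, 0.5, 60.0, 140.0, 20.0)
        R, T = np.meshgrid(spec.r_values, spec.theta_values, indexing="ij")
        vals = (R - 2.0) ** 2 + ((T - 100.0) / 20.0) ** 2
        sf = SurfaceField("E", vals, np.ones_like(vals, bool), spec)
        r, t, v = argmin_surface(sf)
        assert (r, t) == (2.0, 100.0)

    def test_tie_breaks_to_smaller_theta_then_r(self):
        vals = np.array([[1.0, 0.0], [0.0, 1.0]])
        sf = field_from(vals)
        r, t, v = argmin_surface(sf)
        # equal minima at (r_idx 1, theta_idx 0) and (r_idx 0, theta_idx 1)
        assert t == sf.gridspec.theta_values[0]
        assert r == sf.gridspec.r_values[1]

    def test_fully_masked_rejected(self):
        sf = field_from(np.zeros((2, 2)), mask=np.zeros((2, 2), bool))
        with pytest.raises(SurfaceError):
            argmin_surface(sf)


class TestSaddle:
    def test_canonical_saddle_x2_minus_y2(self):
        spec = GridSpec(1.0, 3.0, 0.5, 60.0, 140.0, 20.0)
        R, T = np.meshgrid(spec.r_values, spec.theta_values, indexing="ij")
        x = R - 2.0
        y = (T - 100.0) / 20.0
        vals = x ** 2 - y ** 2
        sf = SurfaceField("E", vals, np.ones_like(vals, bool), spec)
        # basins of x^2 - y^2 lie along +-y; the pass between them is (0, 0)
        rep = locate_saddle(sf, reactant_cell=(2, 0), product_cell=(2, 4))
        assert (rep.r, rep.theta) == (2.0, 100.0)
        assert rep.value == pytest.approx(0.0, abs=1e-12)
        # the 3x3-stencil detector agrees on the clean analytic field
        assert (2.0, 100.0, 0.0) in [
            (r, t, round(v, 9)) for r, t, v in stencil_saddles(sf)
        ]

    def test_matches_exhaustive_path_enumeration(self, rng):
        for _ in range(25):
            vals = rng.normal(size=(5, 5))
            sf = field_from(vals)
            rep = locate_saddle(sf, reactant_cell=(0, 0),
                                product_cell=(4, 4))
            oracle = brute_force_minimax(
                vals, np.ones((5, 5), bool), (0, 0), (4, 4)
            )
            assert rep.value == pytest.approx(oracle, abs=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_minimax_property_random_fields(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(-10, 10, size=(4, 4))
        mask = rng.uniform(size=(4, 4)) > 0.15
        mask[0, 0] = mask[3, 3] = True
        sf = field_from(vals, mask)
        oracle = brute_force_minimax(vals, mask, (0, 0), (3, 3))
        if np.isinf(oracle):
            with pytest.raises(SurfaceError):
                locate_saddle(sf, (0, 0), (3, 3))
        else:
            rep = locate_saddle(sf, (0, 0), (3, 3))
            assert rep.value == pytest.approx(oracle, abs=1e-12)

    def test_barrier_shift_invariance(self, rng):
        vals = rng.normal(size=(5, 5))
        sf1 = field_from(vals)
        sf2 = field_from(vals + 7.5)
        b1 = locate_saddle(sf1, (0, 0), (4, 4)).barrier_height
        b2 = locate_saddle(sf2, (0, 0), (4, 4)).barrier_height
        assert b1 == pytest.approx(b2, abs=1e-12)

    def test_saddle_not_below_basins(self, rng):
        vals = rng.normal(size=(6, 6))
        sf = field_from(vals)
        rep = locate_saddle(sf, (0, 0), (5, 5))
        assert rep.value >= min(vals[0, 0], vals[5, 5]) - 1e-12

    def test_disconnected_basins_error(self):
        vals = np.zeros((3, 3))
        mask = np.ones((3, 3), bool)
        mask[1, :] = False  # cut the grid in two
        sf = field_from(vals, mask)
        with pytest.raises(SurfaceError):
            locate_saddle(sf, (0, 0), (2, 2))


class TestViews:
    def test_theta_90_column_on_z_axis(self):
        spec = GridSpec(1.0, 2.0, 0.5, 90.0, 110.0, 10.0)
        sf = SurfaceField("E", np.zeros((3, 3)), np.ones((3, 3), bool), spec)
        X, Y, V, m = to_view(sf, "cartesian")
        np.testing.assert_allclose(X[:, 0], 0.0, atol=1e-12)
        np.testing.assert_allclose(Y[:, 0], spec.r_values)

    def test_rectangular_axes_are_lattice(self):
        spec = GridSpec(1.0, 2.0, 0.5, 90.0, 110.0, 10.0)
        sf = SurfaceField("E", np.zeros((3, 3)), np.ones((3, 3), bool), spec)
        X, Y, V, m = to_view(sf, "rectangular")
        np.testing.assert_array_equal(X[0, :], spec.theta_values)
        np.testing.assert_array_equal(Y[:, 0], spec.r_values)

    def test_cartesian_positions_invert_to_cells(self):
        spec = GridSpec(1.0, 3.0, 0.25, 60.0, 150.0, 5.0)
        n = (spec.n_r, spec.n_theta)
        sf = SurfaceField("E", np.zeros(n), np.ones(n, bool), spec)
        X, Y, V, m = to_view(sf, "cartesian")
        r_back = np.hypot(X, Y)
        t_back = np.degrees(np.arctan2(Y, X))
        for ir, it in itertools.product(range(n[0]), range(n[1])):
            assert spec.index_of(
                round(r_back[ir, it], 9), round(t_back[ir, it], 9)
            ) == (ir, it)

    def test_unknown_view(self):
        sf = field_from(np.zeros((2, 2)))
        with pytest.raises(SurfaceError):
            to_view(sf, "polar3d")
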