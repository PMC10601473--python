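import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edascan.geometry import (
    Geometry,
    GeometryError,
    GridSpec,
    align_carbonyl,
    build_grid,
    embed_nucleophile,
    measure_rc,
    read_xyz,
    write_xyz,
)
from edascan.molecules import acetone, cyanide, cyanide_acetone_pair


def rotation_matrix(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestGridSpec:
    @pytest.mark.parametrize(
        "spec, n",
        [
            ((1.25, 2.95, 0.1, 70, 155, 5), 324),  # 18 x 18 survey lattice
            ((2.0, 2.0, 0.1, 90, 90, 5), 1),
            ((1.0, 2.0, 0.5, 90, 100, 5), 9),
        ],
    )
    def test_cell_count(self, spec, n):
        assert len(build_grid(GridSpec(*spec))) == n

    def test_count_formula(self):
        spec = GridSpec(1.25, 2.95, 0.1, 70, 155, 5)
        assert spec.n_r == 18 and spec.n_theta == 18
        assert spec.size == spec.n_r * spec.n_theta

    def test_ordering_and_uniqueness(self):
        grid = build_grid(GridSpec(1.0, 2.0, 0.5, 90, 100, 5))
        pairs = [(p.theta, p.r) for p in grid]
        assert pairs == sorted(pairs)  # angle-major, then distance ascending
        assert len(set(pairs)) == len(pairs)

    @pytest.mark.parametrize(
        "bad",
        [
            (1.0, 2.0, 0.3, 90, 100, 5),     # step does not divide r range
            (1.0, 2.0, 0.5, 90, 100, 3),     # step does not divide theta range
            (-1.0, 2.0, 0.5, 90, 100, 5),    # negative distance
            (1.0, 2.0, 0.5, 0.0, 100, 5),    # theta outside (0, 180]
            (2.0, 1.0, 0.5, 90, 100, 5),     # inverted range
        ],
    )
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(GeometryError):
            GridSpec(*bad)


class TestAlignCarbonyl:
    def test_canonical_frame(self):
        g = acetone(co=1.21)
        out = align_carbonyl(g, 0, 1, 2)
        np.testing.assert_allclose(out.coords[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(out.coords[1], [1.21, 0, 0], atol=1e-12)
        assert abs(out.coords[2][2]) < 1e-12 and out.coords[2][1] > 0

    def test_idempotent(self):
        g = align_carbonyl(acetone(), 0, 1, 2)
        again = align_carbonyl(g, 0, 1, 2)
        np.testing.assert_allclose(again.coords, g.coords, atol=1e-12)

    def test_rigid_body_only(self, rng):
        g = acetone()
        R = rotation_matrix(rng)
        rot = g.copy()
        rot.coords = g.coords @ R.T + rng.normal(size=3)
        out = align_carbonyl(rot, 0, 1, 2)
        np.testing.assert_allclose(
            out.distance_matrix(), g.distance_matrix(), atol=1e-10
        )

    def test_collinear_rejected(self):
        g = Geometry(["C", "O", "H"], [[0, 0, 0], [1.2, 0, 0], [2.4, 0, 0]])
        with pytest.raises(GeometryError):
            align_carbonyl(g, 0, 1, 2)
        with pytest.raises(GeometryError):
            align_carbonyl(g, 0, 1, 1)


class TestEmbed:
    def setup_method(self):
        self.ac = align_carbonyl(acetone(), 0, 1, 2)
        self.cn = cyanide()

    def test_perpendicular_attack_at_90(self):
        comp = embed_nucleophile(self.ac, self.cn, 2.0, 90.0)
        np.testing.assert_allclose(
            comp.coords[self.ac.natoms], [0, 0, 2.0], atol=1e-12
        )

    def test_collinear_attack_at_180(self):
        comp = embed_nucleophile(self.ac, self.cn, 2.5, 180.0)
        np.testing.assert_allclose(
            comp.coords[self.ac.natoms], [-2.5, 0, 0], atol=1e-9
        )

    def test_nucleophile_internal_geometry_unchanged(self):
        comp = embed_nucleophile(self.ac, self.cn, 1.8, 110.0)
        na = self.ac.natoms
        d_embedded = np.linalg.norm(comp.coords[na] - comp.coords[na + 1])
        assert abs(d_embedded - self.cn.distance(0, 1)) < 1e-10

    def test_orientation_points_away(self):
        comp = embed_nucleophile(self.ac, self.cn, 2.0, 110.0)
        na = self.ac.natoms
        c, n = comp.coords[na], comp.coords[na + 1]
        # N further from the carbonyl carbon (origin) than the attacking C
        assert np.linalg.norm(n) > np.linalg.norm(c)

    @given(
        r=st.floats(1.3, 3.0),
        theta=st.floats(40.0, 180.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_embed_measure_roundtrip(self, r, theta):
        comp = embed_nucleophile(self.ac, self.cn, r, theta)
        pair = cyanide_acetone_pair(self.ac, self.cn, r=2.0, theta=110.0)
        fp = pair.with_geometry(comp)
        rr, tt = measure_rc(fp)
        assert abs(rr - r) < 1e-9
        assert abs(tt - theta) < 1e-6

    def test_rigid_body_invariance(self, rng):
        """Aligning a rotated acceptor then embedding gives identical
        coordinates to embedding into the unrotated one."""
        ref = embed_nucleophile(self.ac, self.cn, 2.2, 105.0)
        R = rotation_matrix(rng)
        rot = self.ac.copy()
        rot.coords = self.ac.coords @ R.T + np.array([1.0, -2.0, 0.5])
        realigned = align_carbonyl(rot, 0, 1, 2)
        out = embed_nucleophile(realigned, self.cn, 2.2, 105.0)
        np.testing.assert_allclose(out.coords, ref.coords, atol=1e-8)

    def test_clash_flagged_not_fatal(self):
        comp = embed_nucleophile(self.ac, self.cn, 0.45, 150.0)
        assert comp.info["clash"] is True

    def test_invalid_theta(self):
        with pytest.raises(GeometryError):
            embed_nucleophile(self.ac, self.cn, 2.0, 0.0)
        with pytest.raises(GeometryError):
            embed_nucleophile(self.ac, self.cn, 2.0, 200.0)

    def test_in_plane_variant(self):
        comp = embed_nucleophile(self.ac, self.cn, 2.0, 90.0,
                                 plane="in-plane")
        np.testing.assert_allclose(
            comp.coords[self.ac.natoms], [0, 2.0, 0], atol=1e-12
        )


class TestMeasure:
    def test_right_angle(self):
        pair = cyanide_acetone_pair(r=2.0, theta=90.0)
        r, t = measure_rc(pair)
        assert abs(r - 2.0) < 1e-9 and abs(t - 90.0) < 1e-6

    def test_collinear(self):
        pair = cyanide_acetone_pair(r=1.0, theta=180.0)
        r, t = measure_rc(pair)
        assert abs(r - 1.0) < 1e-9 and abs(t - 180.0) < 1e-4


class TestGeometryType:
    def test_mismatched_lengths(self):
        with pytest.raises(GeometryError):
            Geometry(["H", "H"], [[0, 0, 0]])

    def test_unknown_element(self):
        with pytest.raises(GeometryError):
            Geometry(["Xx"], [[0, 0, 0]])

    def test_fused_atoms(self):
        with pytest.raises(GeometryError):
            Geometry(["H", "H"], [[0, 0, 0], [0.1, 0, 0]])

    def test_electron_count(self):
        assert cyanide().n_electrons == 14
        assert acetone().n_electrons == 32


class TestXYZ:
    def test_roundtrip_with_metadata(self, tmp_path):
        g = cyanide()
        g.info.update(r=1.95, theta=111.0)
        path = tmp_path / "cn.xyz"
        write_xyz(g, path, comment="cyanide fragment")
        back = read_xyz(path)
        assert back.atoms == g.atoms
        np.testing.assert_allclose(back.coords, g.coords, atol=1e-9)
        assert back.charge == -1 and back.multiplicity == 1
        assert back.info["r"] == 1.95 and back.info["theta"] == 111.0

    def test_tolerant_comment_parse(self, tmp_path):
        path = tmp_path / "h.xyz"
        path.write_text("1\nfree text, no keys\nH 0 0 0\n")
        g = read_xyz(path)
        assert g.atoms == ["H"] and g.charge == 0

    def test_malformed_rejected(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("2\ncomment\nH 0 0 0\n")
        with pytest.raises(GeometryError):
            read_xyz(path)
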