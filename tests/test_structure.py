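"""Structure-mapping tests: PDB ingestion, accessible volumes, inter-dye
distances, and the angle calibration."""

import warnings

import numpy as np
import pytest

from clampfret import structure as sm
from clampfret.alex import CorrectionFactors, fret_from_distance


def _structure_from_arrays(coords, chains=None, residues=None, names=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return sm.StructureAtoms(
        chains=np.asarray(chains if chains is not None else ["A"] * n),
        residues=np.asarray(residues if residues is not None else range(1, n + 1)),
        icodes=np.asarray([""] * n),
        names=np.asarray(names if names is not None else ["CA"] * n),
        elements=np.asarray(["C"] * n),
        coords=coords,
    )


class TestReadStructure:
    def test_two_atom_fixture(self, write_pdb):
        path = write_pdb(
            [
                dict(name="CA", resname="ALA", chain="A", resseq=1, x=0.0, y=0.0, z=0.0),
                dict(name="CA", resname="GLY", chain="B", resseq=2, x=0.0, y=0.0, z=73.0),
            ]
        )
        st = sm.read_structure(path)
        assert len(st) == 2
        np.testing.assert_allclose(st.coords[1], [0, 0, 73])
        assert sm.ca_distance(st, ("A", 1), ("B", 2)) == pytest.approx(73.0)

    def test_altloc_a_retained(self, write_pdb):
        path = write_pdb(
            [
                dict(name="CA", resname="ALA", chain="A", resseq=1,
                     x=1.0, y=0.0, z=0.0, altloc="A"),
                dict(name="CA", resname="ALA", chain="A", resseq=1,
                     x=9.0, y=0.0, z=0.0, altloc="B"),
            ]
        )
        st = sm.read_structure(path)
        assert len(st) == 1
        assert st.coords[0][0] == pytest.approx(1.0)

    def test_missing_attachment_named_in_error(self, write_pdb):
        path = write_pdb(
            [dict(name="CA", resname="ALA", chain="A", resseq=1, x=0.0, y=0.0, z=0.0)]
        )
        st = sm.read_structure(path)
        with pytest.raises(KeyError, match="chain B"):
            st.find_atom("B", 106)

    def test_hydrogens_dropped(self, write_pdb):
        path = write_pdb(
            [
                dict(name="CA", resname="ALA", chain="A", resseq=1,
                     x=0.0, y=0.0, z=0.0, element="C"),
                dict(name="HA", resname="ALA", chain="A", resseq=1,
                     x=1.0, y=0.0, z=0.0, element="H"),
            ]
        )
        assert len(sm.read_structure(path)) == 1


class TestAccessibleVolume:
    def test_unobstructed_point_dye_is_ball(self):
        st = _structure_from_arrays([[0.0, 0.0, 0.0]])
        dye = sm.DyeModel("toy", 10.0, 4.5, (0.1,), chain="A", residue=1)
        av = sm.compute_av(st, dye, grid_spacing=1.0)
        # mean position at the attachment (symmetric ball)
        np.testing.assert_allclose(av.mean_position, [0, 0, 0], atol=1e-9)
        # volume close to (4/3) pi L^3 in grid-cell units
        expect = 4.0 / 3.0 * np.pi * 10.0**3
        assert len(av) == pytest.approx(expect, rel=0.05)
        # hard geometric bound
        assert np.linalg.norm(av.points, axis=1).max() <= 10.0 + 1e-9

    def test_slab_displaces_mean_by_half_ball_centroid(self):
        """A slab under the attachment restricts the AV to a half-ball whose
        centroid sits 3L/8 above the attachment."""
        from conftest import make_slab_structure

        L = 10.0
        st = make_slab_structure(linker_length=L)
        dye = sm.DyeModel("toy", L, 4.5, (0.1,), chain="A", residue=1)
        av = sm.compute_av(st, dye, grid_spacing=0.5)
        assert av.points[:, 2].min() >= 0.0
        assert av.mean_position[2] == pytest.approx(3 * L / 8, abs=0.35)
        np.testing.assert_allclose(av.mean_position[:2], [0, 0], atol=1e-9)

    def test_grid_refinement_stable(self):
        st = _structure_from_arrays([[0.0, 0.0, 0.0], [0.0, 0.0, -3.0]])
        dye = sm.DyeModel("toy", 8.0, 4.5, (1.0,), chain="A", residue=1)
        coarse = sm.compute_av(st, dye, grid_spacing=1.0)
        fine = sm.compute_av(st, dye, grid_spacing=0.5)
        assert np.linalg.norm(coarse.mean_position - fine.mean_position) < 0.5

    def test_no_point_clashes_with_protein(self):
        rng = np.random.default_rng(0)
        coords = np.vstack([[0.0, 0.0, 0.0], rng.uniform(-12, 12, (200, 3))])
        st = _structure_from_arrays(coords)
        dye = sm.DyeModel("toy", 10.0, 4.5, (2.0,), chain="A", residue=1)
        av = sm.compute_av(st, dye, grid_spacing=1.0)
        from scipy.spatial.distance import cdist

        dmin = cdist(av.points, coords[1:]).min()
        assert dmin >= 2.0 + sm.DEFAULT_ATOM_RADIUS - 1e-9

    def test_buried_site_raises(self):
        # cage of atoms immediately around the attachment
        shell = []
        for dx in (-2.0, 0.0, 2.0):
            for dy in (-2.0, 0.0, 2.0):
                for dz in (-2.0, 0.0, 2.0):
                    if (dx, dy, dz) != (0, 0, 0):
                        shell.append([dx, dy, dz])
        st = _structure_from_arrays(np.vstack([[0.0, 0.0, 0.0], shell]))
        dye = sm.DyeModel("toy", 6.0, 4.5, (3.0,), chain="A", residue=1)
        with pytest.raises(ValueError, match="buried"):
            sm.compute_av(st, dye, grid_spacing=1.0)


class TestInterdyeDistance:
    def _point_av(self, xyz):
        return sm.AccessibleVolume(
            attachment=np.asarray(xyz, float), spacing=1.0,
            points=np.asarray([xyz], float),
        )

    def test_point_volumes(self):
        a = self._point_av([0, 0, 0])
        b = self._point_av([0, 0, 30])
        assert sm.mean_interdye_distance(a, b) == pytest.approx(30.0)

    def test_exact_matches_bruteforce_on_balls(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(-1, 1, (300, 3))
        q = rng.uniform(-1, 1, (300, 3)) + [0, 0, 40.0]
        av1 = sm.AccessibleVolume(np.zeros(3), 1.0, p)
        av2 = sm.AccessibleVolume(np.array([0, 0, 40.0]), 1.0, q)
        from scipy.spatial.distance import cdist

        brute = cdist(p, q).mean()
        assert sm.mean_interdye_distance(av1, av2) == pytest.approx(brute, abs=1e-9)
        # far-apart balls: mean approaches centre separation from above
        assert brute >= 40.0 - 1e-9

    def test_subsampled_close_to_exact(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(-5, 5, (2000, 3))
        q = rng.uniform(-5, 5, (2000, 3)) + [0, 0, 50.0]
        av1 = sm.AccessibleVolume(np.zeros(3), 1.0, p)
        av2 = sm.AccessibleVolume(np.array([0, 0, 50.0]), 1.0, q)
        exact = sm.mean_interdye_distance(av1, av2)
        sampled = sm.mean_interdye_distance(
            av1, av2, max_exact_pairs=1000, n_sample_pairs=2_000_000, seed=3
        )
        assert sampled == pytest.approx(exact, abs=0.1)

    def test_jensen_bound(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(-3, 3, (500, 3))
        q = rng.uniform(-3, 3, (500, 3)) + [0, 0, 20.0]
        av1 = sm.AccessibleVolume(np.zeros(3), 1.0, p)
        av2 = sm.AccessibleVolume(np.array([0, 0, 20.0]), 1.0, q)
        mean_pair = sm.mean_interdye_distance(av1, av2)
        centre_sep = np.linalg.norm(av1.mean_position - av2.mean_position)
        assert mean_pair >= centre_sep - 1e-9

    def test_point_dyes_tiny_linkers_reduce_to_ca_distance(self):
        st = _structure_from_arrays(
            [[0.0, 0.0, 0.0], [0.0, 0.0, 73.0]], chains=["A", "B"], residues=[1, 2]
        )
        donor = sm.DyeModel("d", 0.01, 0.01, (0.01,), chain="A", residue=1)
        acceptor = sm.DyeModel("a", 0.01, 0.01, (0.01,), chain="B", residue=2)
        r_av = sm.interdye_distance_av1(st, donor, acceptor, grid_spacing=1.0)
        assert r_av == pytest.approx(73.0, abs=1e-9)


class TestAngleCalibration:
    def test_linear_midpoint(self):
        cal = sm.calibrate_angle_curve([(0.0, 80.0), (16.0, 68.0)])
        assert cal.angle_from_distance(74.0) == pytest.approx(8.0)

    def test_exact_at_anchors(self):
        cal = sm.calibrate_angle_curve([(0.0, 80.0), (8.0, 74.0), (16.0, 68.0)])
        for angle, dist in [(0.0, 80.0), (8.0, 74.0), (16.0, 68.0)]:
            assert cal.angle_from_distance(dist) == pytest.approx(angle)

    def test_out_of_range_clamped_with_warning(self):
        cal = sm.calibrate_angle_curve([(0.0, 80.0), (16.0, 68.0)])
        with pytest.warns(UserWarning, match="outside calibration"):
            assert cal.angle_from_distance(90.0) == pytest.approx(0.0)
        with pytest.warns(UserWarning):
            assert cal.angle_from_distance(10.0) == pytest.approx(16.0)

    def test_non_monotone_curve_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            sm.calibrate_angle_curve([(0.0, 80.0), (8.0, 85.0), (16.0, 68.0)])


class TestAssignState:
    def _cal(self):
        return sm.calibrate_angle_curve([(0.0, 80.0), (16.0, 60.1)])

    def test_half_transfer_is_forster_radius(self):
        corr = CorrectionFactors(0.0, 0.0, 0.95, 60.1)
        r, angle = sm.assign_state(0.5, corr, self._cal())
        assert r == pytest.approx(60.1)
        assert angle == pytest.approx(16.0)

    def test_round_trip_at_anchors(self):
        corr = CorrectionFactors(0.0, 0.0, 0.95, 60.1)
        cal = self._cal()
        for theta in (0.0, 8.0, 16.0):
            r = cal.distance_from_angle(theta)
            e_a = fret_from_distance(r, corr.r0)
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                _, back = sm.assign_state(e_a, corr, cal)
            assert back == pytest.approx(theta, abs=1e-9)

    def test_monotone_composition(self):
        corr = CorrectionFactors(0.0, 0.0, 0.95, 60.1)
        cal = self._cal()
        rs, angles = zip(*(sm.assign_state(ea, corr, cal) for ea in (0.3, 0.4, 0.5)))
        assert rs[0] > rs[1] > rs[2]
        assert angles[0] < angles[1] < angles[2]


def test_rotate_selection_rigid():
    st = _structure_from_arrays([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0], [5.0, 3.0, 0.0]])
    sel = np.array([False, True, True])
    rot = sm.rotate_selection(st, sel, [0, 0, 0], [0, 0, 1], 90.0)
    np.testing.assert_allclose(rot.coords[1], [0, 5, 0], atol=1e-12)
    # internal distances preserved
    d0 = np.linalg.norm(st.coords[1] - st.coords[2])
    d1 = np.linalg.norm(rot.coords[1] - rot.coords[2])
    assert d1 == pytest.approx(d0)
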