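"""Trajectory observables: distances, dihedrals, RMSD, waters, unbinding."""
import numpy as np
import pytest

from fepkit.traj import (
    SeriesSummary,
    Trajectory,
    detect_unbinding,
    dihedral,
    dihedral_series,
    distance_series,
    per_residue_rmsd,
    rmsd,
    water_occupancy,
)

from conftest import random_rotation


def single_frame_traj(coords, names=None, **kw):
    coords = np.asarray(coords, dtype=float)
    names = names or [f"A{i}" for i in range(coords.shape[0])]
    return Trajectory(coords[None, :, :], names, **kw)


class TestDistance:
    def test_three_four_five(self):
        traj = single_frame_traj([[0, 0, 0], [3, 4, 0]])
        s = distance_series(traj, 0, 1)
        assert s.values[0] == pytest.approx(5.0)

    def test_constant_series_single_occupied_bin(self):
        coords = np.zeros((20, 2, 3))
        coords[:, 1, 0] = 3.5
        s = distance_series(Trajectory(coords, ["A", "B"]), "A", "B")
        assert np.allclose(s.values, 3.5)
        assert (s.counts > 0).sum() == 1

    def test_histogram_conserves_frame_count(self, rng):
        coords = np.zeros((250, 2, 3))
        coords[:, 1, 0] = rng.uniform(2, 8, 250)
        s = distance_series(Trajectory(coords, ["A", "B"]), "A", "B")
        assert s.counts.sum() == 250

    def test_unknown_atom_raises(self):
        traj = single_frame_traj([[0, 0, 0], [1, 0, 0]], names=["A", "B"])
        with pytest.raises(KeyError):
            distance_series(traj, "A", "Z")


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]) == pytest.approx(
            0.0, abs=1e-10
        )

    def test_planar_trans_is_180(self):
        assert abs(
            dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0])
        ) == pytest.approx(180.0)

    def test_right_angle_sign_convention(self):
        ang = dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 0, 1])
        assert abs(ang) == pytest.approx(90.0)

    def test_rotation_invariance(self, rng):
        pts = rng.normal(size=(4, 3))
        ref = dihedral(*pts)
        for _ in range(5):
            rot = random_rotation(rng)
            shift = rng.normal(size=3)
            moved = pts @ rot.T + shift
            assert dihedral(*moved) == pytest.approx(ref, abs=1e-6)

    def test_matches_mdanalysis(self, rng):
        from MDAnalysis.lib.distances import calc_dihedrals

        for _ in range(10):
            pts = rng.normal(size=(4, 3)).astype(np.float64)
            mine = dihedral(*pts)
            theirs = np.degrees(
                calc_dihedrals(pts[0][None], pts[1][None], pts[2][None], pts[3][None])
            )[0]
            assert mine == pytest.approx(theirs, abs=1e-4)

    def test_collinear_geometry_flagged_missing(self):
        coords = np.zeros((1, 4, 3))
        coords[0, :, 0] = [0.0, 1.0, 2.0, 3.0]  # all on the x axis
        s = dihedral_series(Trajectory(coords, list("abcd")), [0, 1, 2, 3])
        assert np.isnan(s.values[0])


class TestRMSD:
    def test_self_rmsd_zero(self, rng):
        x = rng.normal(size=(10, 3))
        assert rmsd(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_superposes_to_zero(self, rng):
        x = rng.normal(size=(25, 3))
        moved = x @ random_rotation(rng).T + rng.normal(size=3)
        assert rmsd(x, moved, superpose=True) < 1e-8
        assert rmsd(x, moved, superpose=False) > 0.1

    def test_one_angstrom_shift(self):
        x = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        shifted = x + np.array([1.0, 0, 0])
        assert rmsd(x, shifted, superpose=False) == pytest.approx(1.0)
        assert rmsd(x, shifted, superpose=True) == pytest.approx(0.0, abs=1e-9)

    def test_superposed_never_exceeds_raw(self, rng):
        for _ in range(10):
            a = rng.normal(size=(12, 3))
            b = a + rng.normal(scale=0.5, size=(12, 3))
            assert rmsd(a, b, superpose=True) <= rmsd(a, b, superpose=False) + 1e-12

    def test_matches_mdanalysis_reference(self, rng):
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        a = rng.normal(size=(15, 3))
        b = a + rng.normal(scale=0.3, size=(15, 3))
        assert rmsd(a, b, superpose=True) == pytest.approx(
            mda_rmsd(b, a, center=True, superposition=True), abs=1e-6
        )

    def test_empty_selection_rejected(self, rng):
        x = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            rmsd(x, x, selection=np.array([], dtype=int))


class TestPerResidueRMSD:
    def test_identical_structures_all_zero(self, rng):
        x = rng.normal(size=(12, 3))
        resids = np.repeat([1, 2, 3], 4)
        out = per_residue_rmsd(x, x, resids)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in out.values())

    def test_displaced_residue_stands_out(self, rng):
        x = rng.normal(size=(12, 3))
        resids = np.repeat([1, 2, 3], 4)
        y = x.copy()
        y[resids == 2] += np.array([4.0, 0.0, 0.0])
        fit_sel = np.where(resids != 2)[0]
        out = per_residue_rmsd(x, y, resids, fit_selection=fit_sel)
        assert out[2] == pytest.approx(4.0, abs=1e-6)
        assert out[1] < 1e-6 and out[3] < 1e-6

    def test_global_rigid_motion_fits_away(self, rng):
        x = rng.normal(size=(12, 3))
        resids = np.repeat([1, 2, 3], 4)
        y = x @ random_rotation(rng).T + np.array([1.0, 2.0, 3.0])
        out = per_residue_rmsd(x, y, resids)
        assert all(v < 1e-8 for v in out.values())


class TestWaterOccupancy:
    def _traj_with_waters(self, n_frames=5, positions=None):
        # site: 2 protein atoms at origin; 4 water oxygens nearby, 1 far
        prot = np.zeros((2, 3))
        near = np.array([[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]], dtype=float)
        far = np.array([[30.0, 0, 0]])
        coords = np.tile(
            np.vstack([prot, near, far])[None], (n_frames, 1, 1)
        )
        if positions is not None:
            coords = positions
        names = ["CA", "CB", "OW1", "OW2", "OW3", "OW4", "OW5"]
        resnames = ["PRO", "PRO", "WAT", "WAT", "WAT", "WAT", "WAT"]
        resids = np.array([1, 1, 2, 3, 4, 5, 6])
        return Trajectory(coords, names, resids=resids, resnames=resnames)

    def test_constant_four_waters(self):
        traj = self._traj_with_waters()
        counts, events = water_occupancy(traj, np.array([0, 1]), cutoff=5.0)
        assert np.all(counts == 4)
        assert events == []

    def test_identity_swap_at_constant_count(self):
        traj = self._traj_with_waters()
        coords = traj.coords.copy()
        # from frame 3 on, water resid 2 leaves and water resid 6 takes its place
        coords[3:, 2] = [30.0, 30.0, 0.0]
        coords[3:, 6] = [1.0, 0.0, 0.0]
        traj2 = Trajectory(coords, traj.names, resids=traj.resids, resnames=traj.resnames)
        counts, events = water_occupancy(traj2, np.array([0, 1]), cutoff=5.0)
        assert np.all(counts == 4)
        assert len(events) == 1
        frame, left, entered = events[0]
        assert frame == 3 and left == {2} and entered == {6}

    def test_zero_cutoff_zero_counts(self):
        traj = self._traj_with_waters()
        counts, _ = water_occupancy(traj, np.array([0, 1]), cutoff=0.0)
        assert np.all(counts == 0)

    def test_no_waters_warns(self):
        coords = np.zeros((2, 2, 3))
        traj = Trajectory(coords, ["CA", "CB"], resids=np.array([1, 1]),
                          resnames=["PRO", "PRO"])
        with pytest.warns(UserWarning, match="no water"):
            counts, _ = water_occupancy(traj, np.array([0]), cutoff=5.0)
        assert np.all(counts == 0)


class TestUnbinding:
    def test_persistent_crossing_found_at_onset(self):
        values = np.full(1000, 3.0)
        values[400:] = 20.0
        assert detect_unbinding(values, threshold=10.0, persistence=50) == 400

    def test_never_crossing_returns_none(self):
        assert detect_unbinding(np.full(500, 3.0), 10.0, 10) is None

    def test_short_spike_ignored(self):
        values = np.full(500, 3.0)
        values[100:110] = 20.0
        assert detect_unbinding(values, 10.0, persistence=50) is None

    def test_works_on_series_summary(self):
        values = np.full(300, 2.0)
        values[200:] = 25.0
        s = SeriesSummary.from_values(values)
        assert detect_unbinding(s, 10.0, 20) == 200
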