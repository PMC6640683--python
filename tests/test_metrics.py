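import numpy as np
import pytest
from MDAnalysis.analysis.rms import rmsd as mda_rmsd

from abtraj import (AbtrajError, AtomSet, FluctuationSpec, GroundTruth,
                    TimeSeries, Trajectory, mean_structure, rmsd_pair,
                    rmsd_series, rmsf_profile, select, simulate, window_stats)


class TestRmsdPair:
    def test_single_atom_345_triangle(self):
        assert rmsd_pair(np.array([[0.0, 0, 0]]),
                         np.array([[3.0, 4, 0]])) == pytest.approx(5.0)

    def test_two_atom_literal_value(self):
        a = np.array([[0.0, 0, 0], [2, 0, 0]])
        b = np.array([[0.0, 0, 0], [0, 2, 0]])
        assert rmsd_pair(a, b) == pytest.approx(2.0)

    def test_zero_for_identical_and_symmetry(self, rng):
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        assert rmsd_pair(a, a) == 0.0
        assert rmsd_pair(a, b) == pytest.approx(rmsd_pair(b, a))

    def test_superposed_rigid_copy_is_zero(self, rng):
        from scipy.spatial.transform import Rotation

        a = rng.normal(size=(10, 3)) * 5
        moved = a @ Rotation.random(random_state=3).as_matrix().T + [1, 2, 3]
        assert rmsd_pair(moved, a, superpose=True) < 1e-8

    def test_count_mismatch_rejected(self):
        with pytest.raises(AbtrajError):
            rmsd_pair(np.zeros((2, 3)), np.zeros((3, 3)))


class TestRmsdSeries:
    def test_rigid_tumble_is_zero_everywhere(self, rigid_tumble_traj):
        aset = AtomSet(np.arange(rigid_tumble_traj.n_atoms))
        series = rmsd_series(rigid_tumble_traj, 0, aset, aset)
        assert series.values.max() <= 1e-8
        assert series.units == "Å"

    def test_first_frame_reference_starts_at_zero(self, noisy_traj):
        aset = AtomSet(np.arange(noisy_traj.n_atoms))
        series = rmsd_series(noisy_traj, 0, aset, aset)
        assert series.values[0] == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_array_equal(series.times, noisy_traj.times)

    def test_matches_independent_per_frame_oracle(self, noisy_traj):
        """Every value equals MDAnalysis's superposed RMSD for that frame."""
        aset = select(noisy_traj.structure, "all")
        series = rmsd_series(noisy_traj, 0, aset, aset)
        ref = noisy_traj.coordinates[0]
        for f in range(0, noisy_traj.n_frames, 37):
            expected = mda_rmsd(noisy_traj.coordinates[f], ref,
                                center=True, superposition=True)
            assert series.values[f] == pytest.approx(expected, rel=1e-8)

    def test_domain_fit_never_exceeds_whole_fit_on_domain_atoms(
            self, toy, hinged_traj):
        """Fragment-local fitting removes relative motion; the residual can
        only shrink."""
        structure, dmap = toy
        whole = select(structure, "all")
        for region in ("fab_left", "fc"):
            aset = dmap.region_atomset(structure, region)
            local = rmsd_series(hinged_traj, 0, aset, aset)
            global_fit = rmsd_series(hinged_traj, 0, aset, whole)
            assert np.all(local.values <= global_fit.values + 1e-8)


class TestMeanStructure:
    def test_static_trajectory_mean_is_the_frame(self, toy_structure):
        coords = np.stack([toy_structure.positions] * 5)
        traj = Trajectory(toy_structure, coords, 0.1 * np.arange(1, 6))
        mean = mean_structure(traj)
        np.testing.assert_allclose(mean, toy_structure.positions, atol=1e-10)

    def test_two_symmetric_frames_average_to_midpoint(self, toy_structure):
        shift = np.array([1.0, -2.0, 0.5])
        coords = np.stack([toy_structure.positions - shift,
                           toy_structure.positions + shift])
        traj = Trajectory(toy_structure, coords, np.array([0.1, 0.2]))
        mean = mean_structure(traj)
        # pure translations are removed by the fit: mean == template shape
        d = mean - mean.mean(axis=0)
        t = toy_structure.positions - toy_structure.positions.mean(axis=0)
        np.testing.assert_allclose(d, t, atol=1e-8)

    def test_noisy_mean_recovers_template(self, toy):
        structure, dmap = toy
        sigma, n_frames = 0.5, 400
        truth = GroundTruth(fluctuation=FluctuationSpec(sigma=sigma), seed=21)
        traj = simulate(structure, dmap, truth, n_frames)
        mean = mean_structure(traj)
        fitted = rmsd_pair(mean, structure.positions, superpose=True)
        # standard error of the mean per coordinate is sigma/sqrt(n_frames)
        assert fitted < 3 * sigma / np.sqrt(n_frames) * np.sqrt(3)


class TestRmsfProfile:
    def test_rigid_tumble_rmsf_is_zero(self, rigid_tumble_traj):
        prof = rmsf_profile(rigid_tumble_traj,
                            select(rigid_tumble_traj.structure, "all"), "local")
        assert prof.rmsf.max() <= 1e-8

    def test_iid_noise_gives_sqrt3_sigma(self, toy):
        structure, dmap = toy
        truth = GroundTruth(fluctuation=FluctuationSpec(sigma=1.0), seed=9)
        traj = simulate(structure, dmap, truth, 1500)
        prof = rmsf_profile(traj, select(structure, "all"), "local")
        assert prof.rmsf.mean() == pytest.approx(np.sqrt(3.0), rel=0.05)

    def test_matches_direct_eq2_evaluation(self, noisy_traj):
        """Direct numpy evaluation of the fluctuation formula on the aligned
        frames reproduces the engine's profile."""
        from abtraj.metrics import _aligned_fragment_coords

        structure = noisy_traj.structure
        frag = select(structure, "chain A")
        prof = rmsf_profile(noisy_traj, frag, "local")
        coords = _aligned_fragment_coords(noisy_traj, frag, frag, 10, 1e-6)
        mean = coords.mean(axis=0)
        dev2 = np.sum((coords - mean) ** 2, axis=2)
        resids = structure.residue_numbers[frag.indices]
        expected = [np.sqrt(dev2[:, resids == r].mean(axis=1).mean())
                    for r in prof.residue_numbers]
        np.testing.assert_allclose(prof.rmsf, expected, rtol=1e-10)

    def test_whole_molecule_fit_inflates_hinged_domain_rmsf(self, toy,
                                                            hinged_traj):
        """Relative domain motion leaks into RMSF unless the fit is local —
        the reason fragment-focused alignment exists."""
        structure, dmap = toy
        fab = dmap.region_atomset(structure, "fab_left")
        whole = select(structure, "all")
        local = rmsf_profile(hinged_traj, fab, "local")
        inflated = rmsf_profile(hinged_traj, fab, whole)
        assert local.rmsf.mean() < 1.0     # noise level, sigma = 0.3
        assert inflated.rmsf.mean() > 2 * local.rmsf.mean()

    def test_profile_recovers_per_residue_amplitudes(self, toy):
        """RMSF correlates with sqrt(3)*sigma_k across a heterogeneous profile."""
        structure, dmap = toy
        res_keys = structure.residue_keys()
        rng = np.random.default_rng(4)
        sigma_k = {(c, r): float(s) for (c, r, _), s in
                   zip(res_keys, rng.uniform(0.3, 1.5, len(res_keys)))}
        truth = GroundTruth(
            fluctuation=FluctuationSpec(sigma=1.0, per_residue=sigma_k), seed=14)
        traj = simulate(structure, dmap, truth, 1500)
        prof = rmsf_profile(traj, select(structure, "all"), "local")
        expected = np.array([np.sqrt(3) * sigma_k[(c, r)]
                             for c, r in zip(prof.chain_ids,
                                             prof.residue_numbers)])
        rel_err = np.abs(prof.rmsf - expected) / expected
        assert np.median(rel_err) < 0.05
        assert np.corrcoef(prof.rmsf, expected)[0, 1] > 0.99

    def test_single_frame_rmsf_is_an_error(self, toy_structure):
        traj = Trajectory(toy_structure, toy_structure.positions[None],
                          np.array([0.1]))
        with pytest.raises(AbtrajError, match="single-frame"):
            rmsf_profile(traj, select(toy_structure, "all"), "local")


class TestWindowStats:
    def test_constant_series(self):
        s = TimeSeries("c", np.arange(1, 6) * 0.1, np.full(5, 5.0), "Å")
        ws = window_stats(s, 0.0, 1.0)
        assert ws.mean == pytest.approx(5.0)
        assert ws.sd == pytest.approx(0.0)

    def test_sample_sd_of_1_2_3(self):
        s = TimeSeries("x", np.array([0.1, 0.2, 0.3]),
                       np.array([1.0, 2.0, 3.0]), "Å")
        ws = window_stats(s, 0.0, 1.0)
        assert ws.mean == pytest.approx(2.0)
        assert ws.sd == pytest.approx(1.0)
        assert ws.n_points == 3

    def test_empty_window_rejected(self):
        s = TimeSeries("x", np.array([0.1, 0.2]), np.array([1.0, 2.0]), "Å")
        with pytest.raises(AbtrajError, match="no points"):
            window_stats(s, 5.0, 6.0)

    def test_enlarging_window_shifts_mean_at_most_by_added_range(self, rng):
        values = rng.normal(5, 2, 50)
        s = TimeSeries("x", np.arange(1, 51) * 0.1, values, "Å")
        small = window_stats(s, 2.0, 4.0)
        big = window_stats(s, 1.0, 5.0)
        added = values[(s.times >= 1.0) & (s.times <= 5.0)]
        assert abs(big.mean - small.mean) <= added.max() - added.min()
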