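import numpy as np
import pytest

from abtraj import (AbtrajError, AngleSchedule, FluctuationSpec, GroundTruth,
                    GlobalMotion, Hinge, TerminalRamp, angle_series,
                    make_toy_antibody, rmsf_profile, select, simulate)


class TestMakeToyAntibody:
    def test_default_layout(self, toy):
        structure, dmap = toy
        assert structure.chains() == ["A", "B", "C", "D"]
        assert set(dmap.regions) == {"fab_left", "fab_right", "fc"}
        # light chains 2 domains, heavy chains 4 domains + linker
        n_light = sum(1 for f in dmap.fragments.values() if f.chain_id == "A")
        n_heavy = sum(1 for f in dmap.fragments.values() if f.chain_id == "B")
        assert n_light == 2 and n_heavy == 5

    def test_smallest_valid_molecule(self):
        structure, dmap = make_toy_antibody(n_res_per_domain=4)
        dmap.validate(structure)
        for region in dmap.regions:
            assert len(dmap.region_atomset(structure, region)) >= 3

    def test_too_small_rejected(self):
        with pytest.raises(AbtrajError):
            make_toy_antibody(n_res_per_domain=3)

    def test_construction_angles_match_request(self):
        structure, dmap = make_toy_antibody(left_angle_deg=110.0,
                                            right_angle_deg=140.0)
        from abtraj import Trajectory

        traj = Trajectory(structure, structure.positions[None], np.array([0.1]))
        series = angle_series(traj, dmap)
        assert series["left"].values[0] == pytest.approx(110.0, abs=1e-9)
        assert series["right"].values[0] == pytest.approx(140.0, abs=1e-9)
        assert series["top"].values[0] == pytest.approx(110.0, abs=1e-9)

    def test_four_atom_variant_has_backbone(self):
        structure, _ = make_toy_antibody(atoms_per_residue=4)
        assert set(structure.atom_names) == {"N", "CA", "C", "O"}
        ca_only, _ = make_toy_antibody()
        assert structure.n_atoms == 4 * ca_only.n_atoms


class TestSchedules:
    def test_ramp_endpoints(self):
        s = AngleSchedule("ramp", start=10.0, end=40.0)
        assert s.delta(0, 100) == pytest.approx(10.0)
        assert s.delta(99, 100) == pytest.approx(40.0)

    def test_sinusoid_period(self):
        s = AngleSchedule("sinusoid", amplitude=5.0, period_frames=50)
        assert s.delta(0, 100) == pytest.approx(0.0)
        assert s.delta(50, 100) == pytest.approx(0.0, abs=1e-9)
        assert s.delta(12, 100) == pytest.approx(5 * np.sin(2 * np.pi * 12 / 50))

    def test_values_schedule_must_cover_run(self, toy):
        structure, dmap = toy
        truth = GroundTruth(hinges=[Hinge("left", AngleSchedule(
            "values", values=[0.0, 1.0]))])
        with pytest.raises(AbtrajError, match="2 values"):
            simulate(structure, dmap, truth, 5)


class TestSimulate:
    def test_zero_noise_constant_hinges_gives_identical_frames(self, toy):
        structure, dmap = toy
        truth = GroundTruth(fluctuation=FluctuationSpec(sigma=0.0), seed=0)
        traj = simulate(structure, dmap, truth, 5)
        assert np.all(traj.coordinates == traj.coordinates[0])
        np.testing.assert_array_equal(traj.coordinates[0], structure.positions)

    def test_same_seed_is_bit_identical(self, toy):
        structure, dmap = toy
        truth = GroundTruth(
            hinges=[Hinge("left", AngleSchedule("ramp", start=0, end=20))],
            fluctuation=FluctuationSpec(sigma=0.4),
            global_motion=GlobalMotion((0, 1, 0), 2.0, (0.1, 0, 0)), seed=42)
        a = simulate(structure, dmap, truth, 10)
        b = simulate(structure, dmap, truth, 10)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_different_seeds_differ(self, toy):
        structure, dmap = toy
        t1 = GroundTruth(fluctuation=FluctuationSpec(sigma=0.4), seed=1)
        t2 = GroundTruth(fluctuation=FluctuationSpec(sigma=0.4), seed=2)
        a = simulate(structure, dmap, t1, 3)
        b = simulate(structure, dmap, t2, 3)
        assert np.abs(a.coordinates - b.coordinates).max() > 0.01

    def test_zero_noise_hinging_keeps_domains_rigid(self, toy):
        structure, dmap = toy
        truth = GroundTruth(
            hinges=[Hinge("left", AngleSchedule("ramp", start=0, end=45))],
            fluctuation=FluctuationSpec(sigma=0.0), seed=0)
        traj = simulate(structure, dmap, truth, 8)
        for label in ("VH_B", "CH2_B", "VL_A"):
            idx = dmap.fragment_atomset(structure, label).indices
            ref = traj.coordinates[0][idx]
            ref_d = np.linalg.norm(ref[:, None] - ref[None], axis=-1)
            for f in range(1, traj.n_frames):
                cur = traj.coordinates[f][idx]
                cur_d = np.linalg.norm(cur[:, None] - cur[None], axis=-1)
                np.testing.assert_allclose(cur_d, ref_d, atol=1e-8)

    def test_terminal_ramp_elevates_terminal_rmsf(self, toy):
        """C-terminal amplitude ramps mimic terminal-loop unfolding."""
        structure, dmap = toy
        truth = GroundTruth(
            fluctuation=FluctuationSpec(
                sigma=0.4, ramps=[TerminalRamp("B", "C", length=6, peak=4.0)]),
            seed=77)
        traj = simulate(structure, dmap, truth, 600)
        prof = rmsf_profile(traj, select(structure, "chain B"), "local")
        body = prof.rmsf[:-6]
        terminus = prof.rmsf[-1]
        assert terminus > 2.5 * body.mean()
        # the ramp rises monotonically towards the terminus (noise-averaged)
        assert prof.rmsf[-1] > prof.rmsf[-4] > body[:10].mean()

    def test_ramp_longer_than_chain_rejected(self, toy):
        structure, dmap = toy
        truth = GroundTruth(fluctuation=FluctuationSpec(
            sigma=0.2, ramps=[TerminalRamp("A", "C", length=9999, peak=2.0)]))
        with pytest.raises(AbtrajError, match="exceeds chain"):
            simulate(structure, dmap, truth, 2)

    def test_global_motion_moves_molecule_not_shape(self, toy):
        structure, dmap = toy
        truth = GroundTruth(fluctuation=FluctuationSpec(sigma=0.0),
                            global_motion=GlobalMotion((1, 0, 0), 5.0,
                                                       (1.0, 0, 0)), seed=0)
        traj = simulate(structure, dmap, truth, 6)
        from abtraj import rmsd_pair

        moved = rmsd_pair(traj.coordinates[5], traj.coordinates[0])
        shape = rmsd_pair(traj.coordinates[5], traj.coordinates[0],
                          superpose=True)
        assert moved > 1.0
        assert shape < 1e-8


class TestGroundTruthSidecar:
    def test_yaml_round_trip(self, tmp_path, toy):
        structure, dmap = toy
        truth = GroundTruth(
            hinges=[Hinge("left", AngleSchedule("ramp", start=0, end=30)),
                    Hinge("right", AngleSchedule("sinusoid", amplitude=4.0,
                                                 period_frames=80))],
            fluctuation=FluctuationSpec(
                sigma=0.5, per_residue={("A", 1): 2.0},
                ramps=[TerminalRamp("B", "C", 5, 3.0)]),
            global_motion=GlobalMotion((0, 0, 1), 1.5, (0.1, 0.2, 0.0)),
            seed=99, dt=0.05)
        path = tmp_path / "truth.yaml"
        truth.to_yaml(path)
        back = GroundTruth.from_yaml(path)
        a = simulate(structure, dmap, truth, 6)
        b = simulate(structure, dmap, back, 6)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)
        np.testing.assert_array_equal(a.times, b.times)
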