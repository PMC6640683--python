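# abtraj

Analysis of antibody molecular-dynamics trajectories: rigid-body
superposition, RMSD/RMSF with fragment-local alignment, Fab/Fc hinge-angle
kinematics, implicit↔explicit time rescaling, solvation-box arithmetic, and a
synthetic hinged-antibody generator for validating all of it against known
ground truth.

## The problem

An IgG antibody is a Y-shaped four-chain molecule: two Fab arms (VH+CH1
paired with VL+CL) joined to an Fc stem (paired CH2+CH3) through a short
CH1–CH2 hinge linker. In MD simulations its dominant motions are large-scale
swings of the rigid Fab/Fc regions about that hinge, superimposed on
residue-level fluctuations. Quantifying both — and comparing how fast
implicit- versus explicit-solvent simulations explore them — requires a small
set of careful geometric tools:

* **RMSD** between index-matched structures after optimal rigid superposition
  (translations + proper rotations only, Kabsch/SVD):
  `RMSD = sqrt( (1/N_atoms) Σ_i |r_i(t1) − r_i(t2)|² )`.
* **RMSF** of residue *k* about the time-averaged structure of an aligned
  trajectory:
  `RMSF_k = sqrt( ⟨ (1/N_k) Σ_{i∈k} |r_i(t) − ⟨r_i⟩_T|² ⟩_T )`.
  Because relative re-orientation of two domains inflates both quantities,
  every engine supports *fragment-local* alignment — fitting on the analysed
  fragment itself so only internal flexibility remains.
* **Hinge angles**: three angles sharing a vertex anchor in the CH1–CH2
  linker — left (left-Fab tip/vertex/Fc tip), right (right-Fab
  tip/vertex/Fc tip) and top (the two Fab tips) — are rigid-motion invariant
  and track arm swings directly. Their sum is 360° only when the three arms
  are coplanar.
* **Sampling scale factor**: the time at which one trajectory best matches a
  reference conformation (minimum superposed RMSD), divided into the
  reference time. E.g. a conformation reached at 100 ns of explicit solvent
  and matched at 16.88 ns of an implicit run gives a factor of 5.92 ≈ 6.

Because production MD of a solvated antibody (~500k atoms, 100 ns) is not
desk-scale, the package ships a first-class synthetic generator
(`abtraj.synthetic`): a four-chain, twelve-domain toy Y with programmed hinge
rotations, per-residue Gaussian fluctuations, optional terminal amplitude
ramps and global tumbling — with all ground truth recorded so every metric
can be tested for exact recovery.

## Worked example

```python
import numpy as np
from abtraj import (AngleSchedule, FluctuationSpec, GroundTruth, Hinge,
                    angle_series, estimate_scale_factor, make_toy_antibody,
                    match_time, rmsd_series, rmsf_profile, select, simulate,
                    window_stats)

structure, dmap = make_toy_antibody()          # 154 CA atoms, chains A-D
truth = GroundTruth(
    hinges=[Hinge("left", AngleSchedule("ramp", start=0.0, end=30.0))],
    fluctuation=FluctuationSpec(sigma=0.5), seed=42, dt=0.1)
traj = simulate(structure, dmap, truth, 500)   # 50 ns synthetic trajectory

aset = select(structure, "all")
series = rmsd_series(traj, 0, aset, aset)      # whole-molecule fit
ws = window_stats(series, 25.0, 50.0)
ang = angle_series(traj, dmap)
prof = rmsf_profile(traj, select(structure, "chain A"), "local")
```

This prints (via f-strings over the objects above):

```
whole-molecule RMSD, 25-50 ns window: 8.46 +/- 1.62 A (n=251)
left angle: 125.2 -> 154.6 deg
chain A RMSF: mean 0.83 A (expected sqrt(3)*0.5 = 0.87 A)
```

The whole-molecule RMSD keeps growing because the left Fab sweeps 30° — the
left-angle series recovers exactly the programmed ramp on top of the 125°
construction angle — while the chain-A RMSF under fragment-local alignment
stays at the pure noise level √3·σ (the arm's swing has been removed by the
local fit). Matching the final conformation inside a second trajectory that
runs the same hinge program four times faster:

```python
fast = simulate(structure, dmap, GroundTruth(
    hinges=[Hinge("left", AngleSchedule("ramp", start=0.0, end=30.0))],
    fluctuation=FluctuationSpec(sigma=0.5), seed=43, dt=0.1), 125)
t, r = match_time(traj.coordinates[-1][aset.indices], fast, aset)
fit = estimate_scale_factor(traj.times[-1], t, r)
# matched at 12.1 ns of 50 ns -> factor 4.13 (~4)
```

## Command line

`abtraj` exposes subcommands `simulate`, `rmsd`, `rmsf`, `angles`,
`compare`, `setup-box`, `audit` and `run` (full pipeline from a YAML
config). Example:

```sh
abtraj simulate --out-prefix out/sim --frames 200 --left-ramp 0 30 --seed 1
abtraj angles --structure out/sim.pdb --traj out/sim.dcd \
              --map out/sim_map.yaml --out out/angles.csv
```

An example domain map for an intact IgG (PDB entry 1IGT: twelve domains, the
CH1–CH2 linkers, four anchors) ships as
`src/abtraj/data/igg_1igt_map.yaml`; read its header comments — the anchor
chain assignment is an assumption documented there.

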