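# Methods

## Superposition

`best_fit` implements least-squares rigid superposition via the SVD form of
the Kabsch algorithm: centre both clouds at their (weighted) centroids, take
the SVD of the weighted cross-covariance, and flip the sign of the smallest
singular direction whenever the naive product would be a reflection, so the
returned rotation always has determinant +1. Weights default to uniform
(mass-weighting is available but nothing in the analysis chain uses it).
Degenerate inputs — fewer than three points, or a collinear cloud (weighted
covariance of rank < 2) — are rejected rather than silently fitted, because
the rotation is not unique there. Tests cross-check the fitted RMSD against
MDAnalysis's independent implementation and against a brute-force oracle that
samples 10,000 random proper rotations.

## RMSD and RMSF

`rmsd_pair` is the literal root-mean-square distance; with `superpose=True`
it reports the Kabsch-minimised value. `rmsd_series` refits every frame to
the reference (first frame by default) on a fit set before evaluating on a
calc set. The defaults mirror standard practice for antibodies: the
whole-molecule series fits on the whole molecule; per-chain and per-domain
series fit on the chain/domain itself, so that each series measures internal
change rather than arm swing. A per-frame consequence, enforced as a test
invariant, is that fragment-local fitting never yields a larger residual
than evaluating the same atoms under a whole-molecule fit.

The RMSF reference ⟨r_i⟩_T is alignment-dependent, so `mean_structure`
makes it well defined by iteration: align all frames to the running mean,
recompute the mean, stop when the mean shifts by < 1e-6 Å RMS or after 10
iterations (non-convergence warns and returns the last iterate; in practice
two or three iterations suffice on every tested input). `rmsf_profile` then
aligns each frame to that converged mean (locally on the fragment, or on a
caller-supplied set), averages the squared atomic deviations within each
residue (N_k atoms), time-averages, and takes the square root. A
single-frame trajectory is an error, not zero: fluctuations about a
one-frame average are vacuous.

For iid isotropic noise of amplitude σ per coordinate the expected RMSF is
√3·σ, less two small, well-understood deflations: subtracting the sample
mean over T frames removes a 1/T share of the variance, and the 6
rigid-body degrees of freedom absorbed by the per-frame fit remove roughly
6/(3m) more for an m-atom fit set. At the scales used for validation
(m ≈ 200 atoms, T = 2000 frames) both effects are below one percent in
amplitude, which is why recovery is asserted at 5%.

## Hinge angles

Anchors resolve to a residue's CA atom by default (a residue centroid rule
is available); the three angles are plain arccosines of clamped normalised
dot products, so they are exactly invariant under global rigid motion and no
alignment is applied before measuring them. Clamping the cosine into
[−1, 1] protects the 0°/180° ends from round-off. The sum left+right+top
equals 360° precisely when the three arm directions are coplanar, and the
toy generator places its four anchor atoms exactly in a plane so this
identity is testable to 1e-6°.

## Cross-trajectory comparison

`match_time` scans a trajectory for the frame minimising superposed RMSD to
a query conformation and returns the earliest minimiser (an explicit,
reproducible objective in place of visual inspection; on real data the two
can disagree, and the matched RMSD is reported so the quality of the match
is never hidden). `estimate_scale_factor` is the ratio of the reference
time to the matched time, reported unrounded with a rounded convenience
value. Rescaling multiplies the time axis only, so value order statistics
are untouched; overlays linearly interpolate each series onto a shared grid
and leave cells outside a series' support empty rather than extrapolate.
Hardware cost ratios (core-hours) are user-supplied metadata in reports,
never computed here.

## Box arithmetic and audits

`padded_box` adds twice the padding to the axis-aligned extents of the
solute. `ion_pairs` treats ionic strength as concentration (exact for a 1:1
monovalent salt) and supports two documented conventions: volume-based
`round(c·N_A·V)` and water-ratio `round(c/55.345·n_waters)`. For a
147×197×196 Å box at 0.05 M the volume convention gives 171 pairs; published
systems of this size are sometimes reported with different counts (e.g. 161),
and since solvation tools do not document their exclusion rules the audit
report surfaces such gaps instead of matching them. Rounding is to the
nearest integer, and counts are electroneutral by construction.
`audit_system` classifies atoms by residue name (standard amino acids;
HOH/TIP3/WAT-type waters; NA/SOD cations; CL/CLA anions; everything else as
"other"). `place_ions` is seeded rejection sampling with a minimum
separation — plumbing for toy systems, with no claim of reproducing any MD
package's placement.

## The synthetic generator

`make_toy_antibody` builds a planar Y: the Fc stem along −y, the two Fab
arms at configurable angles to it (125° each by default, giving a 110° top
angle), four chains (A/C light: VL+CL; B/D heavy: VH+CH1+linker+CH2+CH3 —
twelve structured domains plus two linkers), one CA per residue at 3.8 Å
spacing (a 4-atom backbone variant exercises N_k > 1). Within each domain
the residues wiggle off-axis with two harmonics that vanish at the domain
ends, so every domain is non-collinear (fittable) while the four anchor
atoms — arm tips, Fc bottom, mid-linker vertex — sit exactly in the z = 0
plane. Light chains are offset out of plane, which also keeps whole-molecule
fits non-degenerate.

`simulate` applies, per frame: programmed rigid rotations of each Fab
region about the hinge-anchor pivot (axes are chosen so a positive schedule
value opens the arm away from the Fc), iid Gaussian displacement with
per-residue amplitude σ_k, then a deterministic global tumble/drift.
Schedules are constant, linear ramp, sinusoid, or an explicit per-frame
array (which must cover the run). Terminal ramps multiply σ over the last
(or first) few residues of a chain, rising linearly to a peak at the
terminus, emulating terminal-loop unfolding as elevated amplitudes. Noise
is iid per frame — a deliberate simplification with no autocorrelation,
sufficient for the fluctuation definition being tested but not a model of
real MD dynamics. One integer seed expands to child streams through
`SeedSequence(seed).spawn(3)` in a fixed order.

What passing the recovery suite shows: the analysis chain is unbiased and
correctly normalised on data that satisfy its own assumptions (rigid
domains, isotropic uncorrelated noise, a single dominant hinge motion). What
it does not show: behaviour under correlated solvent-driven dynamics,
anisotropic fluctuations, partial unfolding, or imperfect atom
correspondence — conclusions about real trajectories still require the real
data.

## Validation scales and numerical choices

Validation runs use a ~150–200 residue toy, 300–2000 frames, σ between 0.3
and 1.0 Å, chosen so closed-form expectations are sharp (Monte-Carlo error
well under the asserted tolerances) while the whole suite runs in seconds.
Scale-factor recovery uses a ×4 compressed 400-frame pair and asserts
agreement within one frame interval, the resolution limit of the matcher.
Defaults elsewhere: heavy-atom selections for metrics (robust to
present-or-absent hydrogens between solvent models), first-frame RMSD
reference, sample (n−1) standard deviation in window statistics, 0.1 ns per
frame when a trajectory format carries no time axis.

## Known limitations

* PDB/DCD only (via MDAnalysis); no PSF/topology or mmCIF support.
* Atom correspondence is positional — no sequence alignment; inputs must be
  index-matched.
* The shipped IgG example map's domain boundaries and anchor chain
  assignments are documented assumptions, not curated annotations.
* Single-scalar time rescaling only; no dynamic time warping.
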