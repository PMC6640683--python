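"""Synthetic hinged-antibody benchmark generator.

Builds a four-chain, Y-shaped toy molecule — two light chains (VL + CL) and
two heavy chains (VH + CH1 + linker + CH2 + CH3), twelve rigid domains
grouped into Fab-left, Fab-right and Fc — and simulates kinematic
trajectories over it: programmed hinge rotations of whole Fab arms about the
central linker, iid per-residue isotropic Gaussian fluctuations (optionally
ramped up towards chain termini to mimic terminal-loop unfolding), and a
global rigid tumble/drift.  Every input is recorded as ground truth so
analysis code can be tested for exact recovery.  This is a kinematic
benchmark, not an MD engine: no force field, no solvent, no autocorrelation
in the noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .domains import (ROLE_FAB_LEFT, ROLE_FAB_RIGHT, ROLE_FC, ROLE_HINGE,
                      Anchor, DomainMap, Fragment)
from .model import AbtrajError, Structure, Trajectory

_CA_SPACING = 3.8  # Å, consecutive CA-CA distance along a chain

#: fixed local offsets for the 4-atom-per-residue variant (Å)
_BACKBONE_OFFSETS = {"N": (-1.2, -0.5, 0.3), "CA": (0.0, 0.0, 0.0),
                     "C": (1.2, 0.5, 0.2), "O": (1.6, 1.6, -0.4)}


# --------------------------------------------------------------------------
# toy molecule construction
# --------------------------------------------------------------------------

def _arm_direction(angle_from_fc_deg: float, side: str) -> np.ndarray:
    """Unit in-plane direction making ``angle`` with the Fc stem (0,-1,0)."""
    a = np.radians(angle_from_fc_deg)
    sign = -1.0 if side == "left" else 1.0
    return np.array([sign * np.sin(a), -np.cos(a), 0.0])


def _domain_positions(origin: np.ndarray, direction: np.ndarray, n: int,
                      start_dist: float, towards_origin: bool, wiggle: float,
                      perp1: np.ndarray, perp2: np.ndarray) -> np.ndarray:
    """CA positions of one domain along an axis, with end residues on-axis."""
    dists = start_dist + _CA_SPACING * np.arange(n)
    if towards_origin:
        dists = dists[::-1]
    t = np.arange(n) / max(n - 1, 1)
    # both wiggle harmonics vanish at t = 0 and t = 1 -> domain ends on-axis
    off = (wiggle * np.sin(2 * np.pi * t)[:, None] * perp1
           + 0.5 * wiggle * np.sin(4 * np.pi * t)[:, None] * perp2)
    return origin + dists[:, None] * direction + off


def make_toy_antibody(n_res_per_domain: int = 12, left_angle_deg: float = 125.0,
                      right_angle_deg: float = 125.0, linker_len: int = 5,
                      atoms_per_residue: int = 1, wiggle: float = 1.2,
                      base_offset: float = 8.0, light_offset: float = 6.0,
                      ) -> tuple[Structure, DomainMap]:
    """Build the Y-shaped toy molecule and its matching domain map.

    ``left_angle_deg``/``right_angle_deg`` are the angles each Fab arm makes
    with the Fc stem at construction; the four anchor CA atoms are exactly
    coplanar (z = 0), so at frame zero left + right + top = 360° holds to
    machine precision.  Chains: A/C light (VL, CL), B/D heavy (VH, CH1,
    linker, CH2, CH3); one CA per residue by default
    (``atoms_per_residue=4`` adds N, C, O at fixed local offsets).
    """
    n = int(n_res_per_domain)
    if n < 4:
        raise AbtrajError("n_res_per_domain must be at least 4")
    if linker_len < 1:
        raise AbtrajError("linker_len must be at least 1")
    if atoms_per_residue not in (1, 4):
        raise AbtrajError("atoms_per_residue must be 1 or 4")
    for angle in (left_angle_deg, right_angle_deg):
        if not 10.0 <= angle <= 170.0:
            raise AbtrajError("arm angles must lie in [10, 170] degrees")

    origin = np.zeros(3)
    d_fc = np.array([0.0, -1.0, 0.0])
    z = np.array([0.0, 0.0, 1.0])
    s = _CA_SPACING
    d0 = float(base_offset)
    arm = {"left": _arm_direction(left_angle_deg, "left"),
           "right": _arm_direction(right_angle_deg, "right")}

    records: list[tuple[str, int, str, np.ndarray]] = []  # chain, resid, resname, CA

    def add_domain(chain: str, first_resid: int, positions: np.ndarray,
                   resname: str = "ALA") -> None:
        for j, pos in enumerate(positions):
            records.append((chain, first_resid + j, resname, pos))

    def heavy_chain(chain: str, side: str) -> dict[str, tuple[int, int]]:
        u = arm[side]
        perp2 = np.array([-u[1], u[0], 0.0])
        bounds = {}
        # VH: residue 1 at the arm tip, running inwards
        vh = _domain_positions(origin, u, n, d0 + n * s, True, wiggle, z, perp2)
        add_domain(chain, 1, vh)
        bounds["VH"] = (1, n)
        ch1 = _domain_positions(origin, u, n, d0, True, wiggle, z, perp2)
        add_domain(chain, n + 1, ch1)
        bounds["CH1"] = (n + 1, 2 * n)
        # linker: straight interpolation arm base -> stem top, mid residue at origin
        p_arm = u * (d0 - s)
        p_stem = d_fc * (d0 - s)
        mid = (linker_len + 1) // 2
        for k in range(1, linker_len + 1):
            t = k / (linker_len + 1)
            pos = origin if k == mid else (1 - t) * p_arm + t * p_stem
            records.append((chain, 2 * n + k, "ALA", np.asarray(pos, dtype=float)))
        bounds["linker"] = (2 * n + 1, 2 * n + linker_len)
        stem_perp = np.array([1.0, 0.0, 0.0])
        ch2 = _domain_positions(origin, d_fc, n, d0, False, wiggle, z, stem_perp)
        add_domain(chain, 2 * n + linker_len + 1, ch2)
        bounds["CH2"] = (2 * n + linker_len + 1, 3 * n + linker_len)
        ch3 = _domain_positions(origin, d_fc, n, d0 + n * s, False, wiggle, z,
                                stem_perp)
        add_domain(chain, 3 * n + linker_len + 1, ch3)
        bounds["CH3"] = (3 * n + linker_len + 1, 4 * n + linker_len)
        return bounds

    def light_chain(chain: str, side: str) -> dict[str, tuple[int, int]]:
        u = arm[side]
        perp2 = np.array([-u[1], u[0], 0.0])
        shift = light_offset * z
        vl = _domain_positions(origin + shift, u, n, d0 + n * s, True, wiggle,
                               z, perp2)
        add_domain(chain, 1, vl)
        cl = _domain_positions(origin + shift, u, n, d0, True, wiggle, z, perp2)
        add_domain(chain, n + 1, cl)
        return {"VL": (1, n), "CL": (n + 1, 2 * n)}

    light_a = light_chain("A", "left")
    heavy_b = heavy_chain("B", "left")
    light_c = light_chain("C", "right")
    heavy_d = heavy_chain("D", "right")

    # anchor residues at the region tips (heavy-chain CA atoms, exactly planar)
    hinge_resid = 2 * n + (linker_len + 1) // 2
    fc_resid = 4 * n + linker_len
    anchor_resnames = {("B", 1): "ASP", ("D", 1): "LYS",
                       ("B", hinge_resid): "CYS", ("B", fc_resid): "PHE"}
    records = [(c, r, anchor_resnames.get((c, r), rn), p)
               for c, r, rn, p in records]

    chains_arr, resids_arr, resnames_arr, names_arr, pos_list = [], [], [], [], []
    for c, r, rn, ca in records:
        names = ("CA",) if atoms_per_residue == 1 else ("N", "CA", "C", "O")
        for name in names:
            chains_arr.append(c)
            resids_arr.append(r)
            resnames_arr.append(rn)
            names_arr.append(name)
            pos_list.append(ca + np.asarray(_BACKBONE_OFFSETS[name]))
    n_atoms = len(pos_list)
    structure = Structure(
        atom_ids=np.arange(1, n_atoms + 1),
        atom_names=np.asarray(names_arr, dtype=object),
        residue_numbers=np.asarray(resids_arr, dtype=int),
        residue_names=np.asarray(resnames_arr, dtype=object),
        chain_ids=np.asarray(chains_arr, dtype=object),
        elements=np.asarray([nm[0] for nm in names_arr], dtype=object),
        positions=np.asarray(pos_list, dtype=float),
    )

    fragments = {}
    for chain, bounds in (("A", light_a), ("C", light_c)):
        for dom, (lo, hi) in bounds.items():
            label = f"{dom}_{chain}"
            fragments[label] = Fragment(label, chain, [(lo, hi)])
    for chain, bounds in (("B", heavy_b), ("D", heavy_d)):
        for dom, (lo, hi) in bounds.items():
            label = f"{dom}_{chain}"
            fragments[label] = Fragment(label, chain, [(lo, hi)])

    regions = {
        "fab_left": ["VL_A", "CL_A", "VH_B", "CH1_B"],
        "fab_right": ["VL_C", "CL_C", "VH_D", "CH1_D"],
        "fc": ["CH2_B", "CH3_B", "CH2_D", "CH3_D"],
    }
    anchors = {
        ROLE_FAB_LEFT: Anchor(ROLE_FAB_LEFT, "B", 1, "CA", "ASP"),
        ROLE_FAB_RIGHT: Anchor(ROLE_FAB_RIGHT, "D", 1, "CA", "LYS"),
        ROLE_HINGE: Anchor(ROLE_HINGE, "B", hinge_resid, "CA", "CYS"),
        ROLE_FC: Anchor(ROLE_FC, "B", fc_resid, "CA", "PHE"),
    }
    domain_map = DomainMap(fragments, regions, anchors)
    domain_map.validate(structure)
    return structure, domain_map


# --------------------------------------------------------------------------
# ground-truth programs
# --------------------------------------------------------------------------

@dataclass
class AngleSchedule:
    """Hinge rotation (degrees) as a function of frame index.

    kinds: ``constant`` (value), ``ramp`` (start -> end linearly over the
    trajectory), ``sinusoid`` (amplitude, period_frames, phase_deg), or
    ``values`` (an explicit per-frame array, which must cover the run).
    """

    kind: str = "constant"
    value: float = 0.0
    start: float = 0.0
    end: float = 0.0
    amplitude: float = 0.0
    period_frames: float = 100.0
    phase_deg: float = 0.0
    values: list[float] | None = None

    def delta(self, frame: int, n_frames: int) -> float:
        if self.kind == "constant":
            return self.value
        if self.kind == "ramp":
            if n_frames < 2:
                return self.start
            return self.start + (self.end - self.start) * frame / (n_frames - 1)
        if self.kind == "sinusoid":
            return self.amplitude * np.sin(
                2 * np.pi * frame / self.period_frames
                + np.radians(self.phase_deg))
        if self.kind == "values":
            if self.values is None or len(self.values) < n_frames:
                raise AbtrajError(
                    f"schedule provides {0 if self.values is None else len(self.values)} "
                    f"values but {n_frames} frames were requested")
            return float(self.values[frame])
        raise AbtrajError(f"unknown schedule kind {self.kind!r}")


_HINGE_REGION = {"left": "fab_left", "right": "fab_right"}
# Default axes chosen so a positive schedule value OPENS the arm away from
# the Fc stem (the toy is built in the z = 0 plane).
_DEFAULT_AXIS = {"left": (0.0, 0.0, -1.0), "right": (0.0, 0.0, 1.0)}


@dataclass
class Hinge:
    """One programmed hinge: which Fab rotates, about which axis, by how much."""

    label: str
    schedule: AngleSchedule
    axis: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.label not in _HINGE_REGION:
            raise AbtrajError(f"hinge label must be 'left' or 'right', "
                              f"got {self.label!r}")
        axis = np.asarray(self.axis if self.axis is not None
                          else _DEFAULT_AXIS[self.label], dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise AbtrajError("hinge axis must be nonzero")
        self.axis = tuple(float(x) for x in axis / norm)

    @property
    def region(self) -> str:
        return _HINGE_REGION[self.label]


@dataclass
class TerminalRamp:
    """Elevated fluctuation amplitudes at a chain terminus.

    The last (``terminal='C'``) or first (``'N'``) ``length`` residues of
    ``chain`` have their sigma multiplied by a linear ramp from 1 up to
    ``peak`` at the terminus — a stand-in for terminal-loop unfolding.
    """

    chain: str
    terminal: str = "C"
    length: int = 5
    peak: float = 3.0

    def __post_init__(self) -> None:
        if self.terminal not in ("N", "C"):
            raise AbtrajError("terminal must be 'N' or 'C'")
        if self.length < 1 or self.peak < 0:
            raise AbtrajError("ramp needs length >= 1 and peak >= 0")


@dataclass
class FluctuationSpec:
    """Per-residue isotropic Gaussian amplitudes (Å per coordinate)."""

    sigma: float = 0.5
    per_residue: dict | None = None  # {(chain, resid): sigma} overrides
    ramps: list[TerminalRamp] = field(default_factory=list)

    def resolve(self, structure: Structure) -> np.ndarray:
        """Per-atom sigma array in structure order."""
        if self.sigma < 0:
            raise AbtrajError("sigma must be nonnegative")
        res_keys = structure.residue_keys()
        sigma_res = {key: float(self.sigma) for key in res_keys}
        if self.per_residue:
            for (chain, resid), sig in self.per_residue.items():
                key = (chain, int(resid), "")
                if key in sigma_res:
                    sigma_res[key] = float(sig)
        for ramp in self.ramps:
            chain_keys = [k for k in res_keys if k[0] == ramp.chain]
            if ramp.length > len(chain_keys):
                raise AbtrajError(
                    f"terminal ramp length {ramp.length} exceeds chain "
                    f"{ramp.chain!r} length {len(chain_keys)}")
            targets = (chain_keys[-ramp.length:] if ramp.terminal == "C"
                       else chain_keys[:ramp.length][::-1])
            for j, key in enumerate(targets):
                # multiplier 1 at the ramp start, `peak` at the terminus
                frac = (j + 1) / ramp.length
                sigma_res[key] *= 1.0 + (ramp.peak - 1.0) * frac
        lookup = dict(sigma_res)
        return np.array([
            lookup[(c, r, i)]
            for c, r, i in zip(structure.chain_ids, structure.residue_numbers,
                               structure.insertion_codes)
        ])


@dataclass
class GlobalMotion:
    """Deterministic whole-molecule tumble and drift applied after hinging."""

    rotation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    rotation_rate_deg: float = 0.0   # degrees per frame, about the template centroid
    drift: tuple[float, float, float] = (0.0, 0.0, 0.0)  # Å per frame


@dataclass
class GroundTruth:
    """Everything that determines a synthetic trajectory, for recovery tests.

    The single integer ``seed`` expands into independent child streams via
    ``numpy.random.SeedSequence(seed).spawn(3)`` in the fixed order
    (noise, global-motion, placement); only the noise stream is currently
    consumed, but the rule keeps sidecars forward-compatible.
    """

    hinges: list[Hinge] = field(default_factory=list)
    fluctuation: FluctuationSpec = field(default_factory=FluctuationSpec)
    global_motion: GlobalMotion | None = None
    seed: int = 0
    dt: float = 0.1  # ns per frame

    # ---- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "dt": float(self.dt),
            "hinges": [
                {"label": h.label, "axis": list(h.axis),
                 "schedule": {k: v for k, v in vars(h.schedule).items()
                              if v not in (None,)}}
                for h in self.hinges
            ],
            "fluctuation": {
                "sigma": self.fluctuation.sigma,
                "per_residue": (
                    [[c, r, s] for (c, r), s in self.fluctuation.per_residue.items()]
                    if self.fluctuation.per_residue else None),
                "ramps": [vars(r) for r in self.fluctuation.ramps],
            },
            "global_motion": (None if self.global_motion is None else {
                "rotation_axis": list(self.global_motion.rotation_axis),
                "rotation_rate_deg": self.global_motion.rotation_rate_deg,
                "drift": list(self.global_motion.drift),
            }),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GroundTruth":
        hinges = [Hinge(h["label"], AngleSchedule(**h["schedule"]),
                        tuple(h["axis"])) for h in data.get("hinges", [])]
        flz = data.get("fluctuation", {})
        per_res = flz.get("per_residue")
        fluct = FluctuationSpec(
            sigma=flz.get("sigma", 0.5),
            per_residue=({(c, int(r)): float(s) for c, r, s in per_res}
                         if per_res else None),
            ramps=[TerminalRamp(**r) for r in flz.get("ramps", [])],
        )
        gm = data.get("global_motion")
        global_motion = None if gm is None else GlobalMotion(
            tuple(gm["rotation_axis"]), gm["rotation_rate_deg"],
            tuple(gm["drift"]))
        return cls(hinges, fluct, global_motion, int(data.get("seed", 0)),
                   float(data.get("dt", 0.1)))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# --------------------------------------------------------------------------
# the simulator
# --------------------------------------------------------------------------

def simulate(structure: Structure, domain_map: DomainMap, truth: GroundTruth,
             n_frames: int) -> Trajectory:
    """Generate a kinematic trajectory from a ground-truth program.

    Per frame, in order: (1) each hinged region is rotated rigidly about the
    hinge-anchor pivot by its scheduled angle, (2) iid Gaussian noise with the
    per-residue sigma is added to every coordinate, (3) the deterministic
    global tumble/drift is applied.  Bit-identical output for identical
    inputs and seed.
    """
    if n_frames < 1:
        raise AbtrajError("n_frames must be at least 1")
    # fail fast if an explicit-values schedule is too short
    for h in truth.hinges:
        h.schedule.delta(0, n_frames)
        h.schedule.delta(n_frames - 1, n_frames)

    template = structure.positions
    pivot_idx = domain_map.anchors[ROLE_HINGE].resolve(structure)
    pivot = template[pivot_idx].mean(axis=0)
    regions = {h.label: domain_map.region_atomset(structure, h.region).indices
               for h in truth.hinges}
    sigma_atom = truth.fluctuation.resolve(structure)

    noise_ss, _global_ss, _placement_ss = np.random.SeedSequence(
        truth.seed).spawn(3)
    rng = np.random.default_rng(noise_ss)

    centroid = template.mean(axis=0)
    gm = truth.global_motion
    coords = np.empty((n_frames, structure.n_atoms, 3))
    for f in range(n_frames):
        frame = template.copy()
        for h in truth.hinges:
            delta = h.schedule.delta(f, n_frames)
            rot = Rotation.from_rotvec(np.radians(delta) * np.asarray(h.axis))
            idx = regions[h.label]
            frame[idx] = rot.apply(frame[idx] - pivot) + pivot
        frame += rng.standard_normal(frame.shape) * sigma_atom[:, None]
        if gm is not None:
            axis = np.asarray(gm.rotation_axis, dtype=float)
            norm = np.linalg.norm(axis)
            if norm > 0 and gm.rotation_rate_deg != 0.0:
                rot = Rotation.from_rotvec(
                    np.radians(gm.rotation_rate_deg * f) * axis / norm)
                frame = rot.apply(frame - centroid) + centroid
            frame += np.asarray(gm.drift) * f
        coords[f] = frame
    times = (np.arange(n_frames) + 1) * truth.dt
    return Trajectory(structure, coords, times)
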