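"""Solvation-box arithmetic and solvated-system auditing.

Explicit-solvent antibody systems are built by padding the solute bounding box
(e.g. 30 Å on every side), then adding a 1:1 salt at a target ionic strength.
For monovalent ions the ionic strength equals the salt concentration, so the
pair count follows either from the box volume (``n = round(c * N_A * V)``) or
from the water count (``n = round(c / 55.345 * n_waters)``, the molarity of
pure water).  ``audit_system`` recounts an existing solvated PDB by residue
class.  Neither convention claims to reproduce any particular solvation tool's
internal placement rules; the audit report exists precisely to surface such
differences instead of hiding them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.constants import Avogadro

from .io import is_protein_residue
from .model import AbtrajError, Structure

WATER_RESNAMES = {"HOH", "TIP3", "TIP", "WAT", "SPC", "SOL", "H2O"}
CATION_RESNAMES = {"NA", "SOD", "NA+", "K", "POT", "K+"}
ANION_RESNAMES = {"CL", "CLA", "CL-"}

WATER_MOLARITY = 55.345  # mol/L, pure water at 25 °C
_A3_TO_L = 1e-27


@dataclass
class SolventSpec:
    """A padded-box + salt recipe (1:1 monovalent salt assumed)."""

    padding: float
    ionic_strength: float
    box: tuple[float, float, float]
    n_cation: int
    n_anion: int
    convention: str

    def __post_init__(self) -> None:
        if self.padding < 0 or self.ionic_strength < 0:
            raise AbtrajError("padding and ionic strength must be nonnegative")
        if min(self.box) <= 0:
            raise AbtrajError("box edges must be positive")
        if self.n_cation < 0 or self.n_anion < 0:
            raise AbtrajError("ion counts must be nonnegative")


def padded_box(structure: Structure, padding: float) -> tuple[float, float, float]:
    """Axis-aligned bounding-box extents of all atoms plus 2×padding per axis (Å)."""
    if padding < 0:
        raise AbtrajError("padding must be nonnegative")
    extents = structure.positions.max(axis=0) - structure.positions.min(axis=0)
    return tuple(float(e + 2.0 * padding) for e in extents)


def ion_pairs(box: tuple[float, float, float], ionic_strength: float,
              convention: str = "volume", n_waters: int | None = None
              ) -> tuple[int, int]:
    """Na+/Cl- pair counts for a box at a given ionic strength (mol/L).

    ``convention='volume'``: ``n = round(c * N_A * V_box)``.
    ``convention='water-ratio'``: ``n = round(c / 55.345 * n_waters)`` —
    requires ``n_waters``.
    Electroneutral by construction: returns equal cation and anion counts.
    """
    if ionic_strength < 0:
        raise AbtrajError("ionic strength must be nonnegative")
    if any(e <= 0 for e in box):
        raise AbtrajError("box edges must be positive")
    if convention == "volume":
        volume_l = float(np.prod(box)) * _A3_TO_L
        n = int(round(ionic_strength * Avogadro * volume_l))
    elif convention == "water-ratio":
        if n_waters is None:
            raise AbtrajError("water-ratio convention requires n_waters")
        if n_waters < 0:
            raise AbtrajError("n_waters must be nonnegative")
        n = int(round(ionic_strength / WATER_MOLARITY * n_waters))
    else:
        raise AbtrajError(f"unknown convention {convention!r}; "
                          "use 'volume' or 'water-ratio'")
    return n, n


def solvent_spec(structure: Structure, padding: float, ionic_strength: float,
                 convention: str = "volume",
                 n_waters: int | None = None) -> SolventSpec:
    box = padded_box(structure, padding)
    n_cat, n_an = ion_pairs(box, ionic_strength, convention, n_waters)
    return SolventSpec(padding, ionic_strength, box, n_cat, n_an, convention)


@dataclass
class CompositionReport:
    """Atom counts of a solvated system by residue class."""

    protein_atoms: int
    water_atoms: int
    water_molecules: int
    cations: int
    anions: int
    other_atoms: int
    total_atoms: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_text(self) -> str:
        return (
            f"total atoms:     {self.total_atoms}\n"
            f"  protein:       {self.protein_atoms}\n"
            f"  water:         {self.water_atoms} ({self.water_molecules} molecules)\n"
            f"  cations:       {self.cations}\n"
            f"  anions:        {self.anions}\n"
            f"  other:         {self.other_atoms}\n"
        )


def audit_system(structure: Structure) -> CompositionReport:
    """Count protein, water, cation, anion and other atoms in a loaded system."""
    protein = water = cat = an = other = 0
    water_res: set[tuple] = set()
    for resname, chain, resid, icode in zip(
            structure.residue_names, structure.chain_ids,
            structure.residue_numbers, structure.insertion_codes):
        name = str(resname).upper()
        if name in WATER_RESNAMES:
            water += 1
            water_res.add((chain, resid, icode))
        elif name in CATION_RESNAMES:
            cat += 1
        elif name in ANION_RESNAMES:
            an += 1
        elif is_protein_residue(name):
            protein += 1
        else:
            other += 1
    return CompositionReport(protein, water, len(water_res), cat, an, other,
                             structure.n_atoms)


def place_ions(box: tuple[float, float, float], n_cation: int, n_anion: int,
               solute_coords: np.ndarray | None = None, min_dist: float = 5.0,
               seed: int = 0, max_tries: int = 10000) -> np.ndarray:
    """Random non-overlapping ion positions inside the box (plumbing only).

    Positions are uniform in the box, rejected when closer than ``min_dist``
    Å to any solute atom or previously placed ion.  Deterministic given
    ``seed``.  Makes no claim of reproducing any MD package's ion placement.
    """
    rng = np.random.default_rng(seed)
    box_arr = np.asarray(box, dtype=float)
    placed: list[np.ndarray] = []
    solute = None if solute_coords is None else np.asarray(solute_coords, float)
    for _ in range(n_cation + n_anion):
        for _try in range(max_tries):
            p = rng.uniform(0, 1, 3) * box_arr
            if solute is not None and len(solute):
                if np.min(np.linalg.norm(solute - p, axis=1)) < min_dist:
                    continue
            if placed and np.min(
                    np.linalg.norm(np.asarray(placed) - p, axis=1)) < min_dist:
                continue
            placed.append(p)
            break
        else:
            raise AbtrajError("could not place ions without overlap; "
                              "increase the box or lower min_dist")
    return np.asarray(placed).reshape(-1, 3)
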