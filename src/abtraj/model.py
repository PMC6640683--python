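"""Core in-memory containers for structures, trajectories and analysis output.

A :class:`Structure` is a flat atom table (author residue numbering, per-chain)
holding one coordinate set; a :class:`Trajectory` binds a time-ordered stack of
coordinate frames to a Structure.  :class:`AtomSet` is an ordered, duplicate-free
index set into a Structure, and :class:`TimeSeries` carries the (time, value)
records that every per-frame metric produces.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class AbtrajError(ValueError):
    """Base class for domain errors raised by this package."""


class DegenerateGeometryError(AbtrajError):
    """Raised when a point set cannot support a rigid-body fit (n < 3 or collinear)."""


class SelectionError(AbtrajError):
    """Raised for malformed or empty atom selections."""


@dataclass
class Structure:
    """An atom table with one coordinate set.

    Parameters
    ----------
    atom_ids : (n,) int array — serial numbers.
    atom_names : (n,) str array — PDB atom names (``CA``, ``N`` ...).
    residue_numbers : (n,) int array — author residue numbering, per chain.
    residue_names : (n,) str array.
    chain_ids : (n,) str array — single-character chain identifiers.
    elements : (n,) str array — element symbols (may be guessed from names).
    positions : (n, 3) float array, Å.
    insertion_codes : (n,) str array — PDB insertion codes, ``''`` if absent.
    """

    atom_ids: np.ndarray
    atom_names: np.ndarray
    residue_numbers: np.ndarray
    residue_names: np.ndarray
    chain_ids: np.ndarray
    elements: np.ndarray
    positions: np.ndarray
    insertion_codes: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.atom_ids)
        if n == 0:
            raise AbtrajError("no atoms: a Structure must contain at least one atom")
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (n, 3):
            raise AbtrajError(
                f"positions shape {self.positions.shape} does not match {n} atoms"
            )
        if not np.all(np.isfinite(self.positions)):
            raise AbtrajError("non-finite coordinates in structure")
        if self.insertion_codes is None:
            self.insertion_codes = np.full(n, "", dtype=object)
        for name in ("atom_names", "residue_names", "chain_ids", "elements",
                     "insertion_codes"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=object))
        self.atom_ids = np.asarray(self.atom_ids, dtype=int)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        keys = list(zip(self.chain_ids, self.residue_numbers,
                        self.insertion_codes, self.atom_names))
        if len(set(keys)) != n:
            raise AbtrajError(
                "duplicate (chain, residue, insertion code, atom name) keys; "
                "altloc records must be resolved before constructing a Structure"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Unique (chain, residue_number, insertion_code) keys in atom order."""
        seen: dict[tuple[str, int, str], None] = {}
        for c, r, i in zip(self.chain_ids, self.residue_numbers, self.insertion_codes):
            seen.setdefault((c, r, i), None)
        return list(seen)

    def chains(self) -> list[str]:
        """Distinct chain ids in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c, None)
        return list(seen)

    def copy(self) -> "Structure":
        return Structure(
            self.atom_ids.copy(), self.atom_names.copy(),
            self.residue_numbers.copy(), self.residue_names.copy(),
            self.chain_ids.copy(), self.elements.copy(),
            self.positions.copy(), self.insertion_codes.copy(),
        )


@dataclass
class Trajectory:
    """Time-ordered coordinate frames bound to a :class:`Structure`.

    ``coordinates`` has shape (n_frames, n_atoms, 3) in Å; ``times`` is the
    per-frame time in ns, strictly increasing.
    """

    structure: Structure
    coordinates: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise AbtrajError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[0] < 1:
            raise AbtrajError("a trajectory needs at least one frame")
        if self.coordinates.shape[1] != self.structure.n_atoms:
            raise AbtrajError(
                f"frame atom count {self.coordinates.shape[1]} does not match "
                f"structure atom count {self.structure.n_atoms}; "
                "wrong structure/trajectory pairing?"
            )
        if len(self.times) != self.coordinates.shape[0]:
            raise AbtrajError("one time per frame required")
        if np.any(np.diff(self.times) <= 0):
            raise AbtrajError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coordinates[i]

    def copy(self) -> "Trajectory":
        return Trajectory(self.structure, self.coordinates.copy(), self.times.copy())


@dataclass
class AtomSet:
    """Ordered, duplicate-free atom indices into a Structure."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.ndim != 1:
            raise AbtrajError("AtomSet indices must be one-dimensional")
        if len(np.unique(self.indices)) != len(self.indices):
            raise AbtrajError("AtomSet indices must be duplicate-free")
        if len(self.indices) and self.indices.min() < 0:
            raise AbtrajError("negative atom index")

    def __len__(self) -> int:
        return len(self.indices)

    def validate(self, structure: Structure) -> None:
        if len(self.indices) and self.indices.max() >= structure.n_atoms:
            raise AbtrajError(
                f"AtomSet index {self.indices.max()} out of range for "
                f"{structure.n_atoms}-atom structure"
            )


@dataclass
class TimeSeries:
    """A labelled (time ns, value) series with units (Å or degrees)."""

    label: str
    times: np.ndarray
    values: np.ndarray
    units: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise AbtrajError("times and values must be 1-D and equally long")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise AbtrajError("TimeSeries times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "value": self.values})

    def to_csv(self, path, extra_comments: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            fh.write(f"# label: {self.label}\n# units: {self.units}\n")
            for line in extra_comments or []:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path, units: str | None = None) -> "TimeSeries":
        label, file_units = "", ""
        lines = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    body = line[1:].strip()
                    if body.startswith("label:"):
                        label = body.split(":", 1)[1].strip()
                    elif body.startswith("units:"):
                        file_units = body.split(":", 1)[1].strip()
                else:
                    lines.append(line)
        df = pd.read_csv(_io.StringIO("".join(lines)))
        return cls(label, df["time_ns"].to_numpy(), df["value"].to_numpy(),
                   units or file_units)


@dataclass
class WindowStats:
    """Mean and sample standard deviation of a series over a time window."""

    t_start: float
    t_end: float
    mean: float
    sd: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise AbtrajError("window requires t_start < t_end")
        if self.n_points < 1:
            raise AbtrajError("window must contain at least one point")
        if self.sd < 0:
            raise AbtrajError("sd must be nonnegative")


@dataclass
class RmsfProfile:
    """Per-residue root-mean-square fluctuation for one fragment.

    ``chain_ids``, ``residue_numbers`` and ``rmsf`` are parallel arrays with one
    entry per residue of the fragment; ``n_frames`` records the trajectory
    length used.
    """

    label: str
    chain_ids: np.ndarray
    residue_numbers: np.ndarray
    rmsf: np.ndarray
    n_frames: int
    insertion_codes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if np.any(self.rmsf < 0):
            raise AbtrajError("RMSF values must be nonnegative")
        if not (len(self.chain_ids) == len(self.residue_numbers) == len(self.rmsf)):
            raise AbtrajError("profile arrays must be parallel")

    def __len__(self) -> int:
        return len(self.rmsf)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chain": self.chain_ids,
            "resid": self.residue_numbers,
            "rmsf_A": self.rmsf,
        })

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# label: {self.label}\n# units: Å\n"
                     f"# n_frames: {self.n_frames}\n")
            self.to_frame().to_csv(fh, index=False)
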