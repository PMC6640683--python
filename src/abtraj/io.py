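"""Structure/trajectory readers and writers (PDB, DCD) built on MDAnalysis.

Reading preserves author residue numbering, chain ids and insertion codes, and
resolves alternate locations to the highest-occupancy record (ties: first
listed).  DCD files carry no absolute time, so trajectory times are assigned as
``(frame_index + 1) * dt`` with ``dt`` in ns per frame.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda
    from MDAnalysis.coordinates.DCD import DCDReader

from .model import AbtrajError, Structure, Trajectory

DEFAULT_DT_NS = 0.1

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "HID", "HIE", "HIP", "CYX", "MSE",
}


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    # Two-letter elements common in biomolecular PDB files.
    two = stripped[:2].upper()
    if two in {"CL", "NA", "MG", "ZN", "FE", "BR", "MN", "CA"} and len(atom_name.strip()) <= 2:
        return two.capitalize()
    return stripped[0].upper()


def _load_universe(path) -> "mda.Universe":
    path = Path(path)
    if not path.exists():
        raise AbtrajError(f"file not found: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # noqa: BLE001 - normalise reader errors
        raise AbtrajError(f"unreadable structure file {path}: {exc}") from exc
    if len(u.atoms) == 0:
        raise AbtrajError(f"no atoms in {path}")
    return u


def _attr(u: "mda.Universe", name: str, default):
    try:
        return np.asarray(getattr(u.atoms, name))
    except Exception:  # noqa: BLE001 - MDAnalysis NoDataError
        return np.full(len(u.atoms), default, dtype=object)


def _resolve_altlocs(order: np.ndarray, keys: list, altlocs: np.ndarray,
                     occupancies: np.ndarray) -> np.ndarray:
    """Indices keeping one atom per key: highest occupancy, ties first listed."""
    best: dict = {}
    for i in order:
        k = keys[i]
        if k not in best:
            best[k] = i
        elif occupancies[i] > occupancies[best[k]] + 1e-12:
            best[k] = i
    return np.array(sorted(best.values()), dtype=int)


def structure_from_universe(u: "mda.Universe") -> Structure:
    atoms = u.atoms
    n = len(atoms)
    names = np.asarray(atoms.names, dtype=object)
    resids = np.asarray(atoms.resids, dtype=int)
    resnames = _attr(u, "resnames", "UNK")
    chain_ids = _attr(u, "chainIDs", "")
    if np.all(chain_ids == ""):
        chain_ids = np.array([str(s)[:1] or "A" for s in _attr(u, "segids", "A")],
                             dtype=object)
    icodes = _attr(u, "icodes", "")
    altlocs = _attr(u, "altLocs", "")
    occ = _attr(u, "occupancies", 1.0).astype(float)
    try:
        elements = np.asarray(atoms.elements, dtype=object)
        if np.all(elements == ""):
            raise ValueError
    except Exception:  # noqa: BLE001
        elements = np.array([_guess_element(nm) for nm in names], dtype=object)

    keep = np.arange(n)
    if np.any(altlocs != ""):
        keys = list(zip(chain_ids, resids, icodes, names))
        keep = _resolve_altlocs(keep, keys, altlocs, occ)

    return Structure(
        atom_ids=np.asarray(atoms.ids, dtype=int)[keep],
        atom_names=names[keep],
        residue_numbers=resids[keep],
        residue_names=np.asarray(resnames, dtype=object)[keep],
        chain_ids=np.asarray(chain_ids, dtype=object)[keep],
        elements=elements[keep],
        positions=np.asarray(atoms.positions, dtype=float)[keep],
        insertion_codes=np.asarray(icodes, dtype=object)[keep],
    )


def load_structure(path) -> Structure:
    """Read a PDB file into a :class:`Structure` (first model only)."""
    return structure_from_universe(_load_universe(path))


def load_trajectory(path, structure: Structure, dt: float = DEFAULT_DT_NS) -> Trajectory:
    """Read a DCD or multi-model PDB trajectory bound to ``structure``.

    Times are assigned as ``(frame_index + 1) * dt`` ns.  The frame atom count
    must equal the structure atom count (a mismatch signals a wrong
    structure/trajectory pairing).
    """
    if dt <= 0:
        raise AbtrajError("dt must be positive (ns per frame)")
    path = Path(path)
    if not path.exists():
        raise AbtrajError(f"file not found: {path}")
    frames: list[np.ndarray] = []
    if path.suffix.lower() == ".dcd":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reader = DCDReader(str(path))
            for ts in reader:
                frames.append(ts.positions.astype(float).copy())
            reader.close()
    else:
        u = _load_universe(path)
        if len(u.atoms) != structure.n_atoms:
            raise AbtrajError(
                f"trajectory atom count {len(u.atoms)} != structure atom count "
                f"{structure.n_atoms}"
            )
        for _ in u.trajectory:
            frames.append(u.atoms.positions.astype(float).copy())
    if not frames:
        raise AbtrajError(f"zero frames in {path}")
    coords = np.stack(frames)
    if coords.shape[1] != structure.n_atoms:
        raise AbtrajError(
            f"trajectory atom count {coords.shape[1]} != structure atom count "
            f"{structure.n_atoms}"
        )
    times = (np.arange(coords.shape[0]) + 1) * dt
    return Trajectory(structure, coords, times)


def _universe_from_structure(structure: Structure) -> "mda.Universe":
    n = structure.n_atoms
    res_keys = structure.residue_keys()
    res_index = {k: i for i, k in enumerate(res_keys)}
    atom_resindex = np.array(
        [res_index[(c, r, i)] for c, r, i in
         zip(structure.chain_ids, structure.residue_numbers,
             structure.insertion_codes)],
        dtype=int,
    )
    chains = structure.chains()
    chain_index = {c: i for i, c in enumerate(chains)}
    residue_segindex = np.array([chain_index[k[0]] for k in res_keys], dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, n_residues=len(res_keys),
                               n_segments=len(chains),
                               atom_resindex=atom_resindex,
                               residue_segindex=residue_segindex,
                               trajectory=True)
        u.add_TopologyAttr("names", structure.atom_names.astype(str))
        u.add_TopologyAttr("chainIDs", structure.chain_ids.astype(str))
        u.add_TopologyAttr("elements", structure.elements.astype(str))
        u.add_TopologyAttr("resids", np.array([k[1] for k in res_keys]))
        u.add_TopologyAttr("icodes", np.array([k[2] for k in res_keys], dtype=str))
        first_atom = {}
        for i, k in enumerate(atom_resindex):
            first_atom.setdefault(k, i)
        u.add_TopologyAttr(
            "resnames",
            np.array([structure.residue_names[first_atom[i]]
                      for i in range(len(res_keys))], dtype=str))
        # PDB chain id lives on atoms; segids mirror them for writer fallback.
        u.add_TopologyAttr("segids", np.array([str(c) for c in chains]))
        u.atoms.positions = structure.positions
    return u


def write_pdb(structure: Structure, path, coordinates: np.ndarray | None = None) -> None:
    """Write a Structure (or a multi-model trajectory of it) as a PDB file.

    ``coordinates`` of shape (n_frames, n_atoms, 3) produces one MODEL per
    frame; ``None`` writes the structure's own coordinates as a single model.
    """
    u = _universe_from_structure(structure)
    frames = structure.positions[None] if coordinates is None else np.asarray(coordinates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=structure.n_atoms,
                        multiframe=len(frames) > 1) as w:
            for frame in frames:
                u.atoms.positions = frame
                w.write(u.atoms)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a Trajectory as DCD (``.dcd``) or multi-model PDB (anything else)."""
    path = Path(path)
    if path.suffix.lower() == ".dcd":
        u = _universe_from_structure(traj.structure)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.Writer(str(path), n_atoms=traj.n_atoms, format="DCD") as w:
                for frame in traj.coordinates:
                    u.atoms.positions = frame
                    w.write(u.atoms)
    else:
        write_pdb(traj.structure, path, traj.coordinates)


def is_protein_residue(resname: str) -> bool:
    return resname.upper() in _STANDARD_AA
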