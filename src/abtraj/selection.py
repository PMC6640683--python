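"""A small atom-selection grammar over :class:`~abtraj.model.Structure`.

Selections are conjunctions of clauses joined by ``and``:

* ``chain A`` or ``chain A,B`` — chain id membership,
* ``resid 1-30`` or ``resid 5,9,20-40`` — author residue-number ranges
  (insertion-coded residues are excluded from ranges),
* an atom class: ``CA`` | ``backbone`` | ``heavy`` | ``all`` | ``protein``.

Examples: ``"chain A and heavy"``, ``"chain B and resid 1-113 and CA"``.
"""

from __future__ import annotations

import numpy as np

from .io import is_protein_residue
from .model import AtomSet, SelectionError, Structure

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OT1", "OT2", "OXT"}
_CLASS_KEYWORDS = {"ca", "backbone", "heavy", "all", "protein"}


def _parse_ranges(spec: str) -> list[tuple[int, int]]:
    ranges = []
    for part in spec.split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part[1:]:  # allow negative lower bounds like -5
            lo_s, hi_s = part.rsplit("-", 1)
            lo, hi = int(lo_s), int(hi_s)
        else:
            lo = hi = int(part)
        if hi < lo:
            raise SelectionError(f"empty residue range {part!r}")
        ranges.append((lo, hi))
    if not ranges:
        raise SelectionError("resid clause needs at least one range")
    return ranges


def _class_mask(structure: Structure, keyword: str) -> np.ndarray:
    kw = keyword.lower()
    if kw == "all":
        return np.ones(structure.n_atoms, dtype=bool)
    if kw == "ca":
        return structure.atom_names == "CA"
    if kw == "backbone":
        return np.isin(structure.atom_names.astype(str), list(_BACKBONE_NAMES))
    if kw == "heavy":
        return np.array([str(e).upper() not in ("H", "D") for e in structure.elements])
    if kw == "protein":
        return np.array([is_protein_residue(str(r)) for r in structure.residue_names])
    raise SelectionError(f"unknown atom class {keyword!r}")


def select(structure: Structure, spec: str, allow_empty: bool = False) -> AtomSet:
    """Evaluate a selection expression; returns atoms in structure order.

    Raises :class:`SelectionError` on an empty result unless ``allow_empty``.
    """
    if not spec or not spec.strip():
        raise SelectionError("empty selection expression")
    mask = np.ones(structure.n_atoms, dtype=bool)
    for clause in (c.strip() for c in spec.split(" and ")):
        if not clause:
            raise SelectionError(f"empty clause in {spec!r}")
        tokens = clause.split(None, 1)
        head = tokens[0].lower()
        if head == "chain":
            if len(tokens) != 2:
                raise SelectionError("chain clause needs an argument")
            chains = {c.strip() for c in tokens[1].split(",") if c.strip()}
            mask &= np.isin(structure.chain_ids.astype(str), list(chains))
        elif head == "resid":
            if len(tokens) != 2:
                raise SelectionError("resid clause needs an argument")
            in_range = np.zeros(structure.n_atoms, dtype=bool)
            for lo, hi in _parse_ranges(tokens[1]):
                in_range |= ((structure.residue_numbers >= lo)
                             & (structure.residue_numbers <= hi))
            # ranges never capture insertion-coded residues implicitly
            in_range &= structure.insertion_codes.astype(str) == ""
            mask &= in_range
        elif head in _CLASS_KEYWORDS and len(tokens) == 1:
            mask &= _class_mask(structure, head)
        else:
            raise SelectionError(f"cannot parse selection clause {clause!r}")
    indices = np.nonzero(mask)[0]
    if len(indices) == 0 and not allow_empty:
        raise SelectionError(f"selection {spec!r} matched no atoms")
    return AtomSet(indices, label=spec)


def union(*atomsets: AtomSet, label: str = "") -> AtomSet:
    """Order-preserving union of atom sets (structure order)."""
    merged = np.unique(np.concatenate([a.indices for a in atomsets]))
    return AtomSet(merged, label=label or "+".join(a.label for a in atomsets))
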