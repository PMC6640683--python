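"""Domain maps: named fragments, Fab/Fc region groups and anchor residues.

An IgG decomposes into two light chains (VL + CL) and two heavy chains
(VH + CH1 + hinge linker + CH2 + CH3): twelve structured domains joined by
linkers, grouped into two Fab arms and one Fc stem.  Large-scale Fab/Fc
motion is tracked through four anchor residues — one at the tip of each Fab,
one at the bottom of the Fc, and one in the central CH1–CH2 linker that acts
as the vertex of all measured angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .model import AbtrajError, AtomSet, Structure
from .selection import select, union

# anchor roles: three endpoints and the shared linker vertex
ROLE_FAB_LEFT = "fab_left"
ROLE_FAB_RIGHT = "fab_right"
ROLE_FC = "fc"
ROLE_HINGE = "hinge"
ANCHOR_ROLES = (ROLE_FAB_LEFT, ROLE_FAB_RIGHT, ROLE_FC, ROLE_HINGE)

#: angle label -> (endpoint_a role, vertex role, endpoint_b role)
ANGLE_TRIPLETS = {
    "left": (ROLE_FAB_LEFT, ROLE_HINGE, ROLE_FC),
    "right": (ROLE_FAB_RIGHT, ROLE_HINGE, ROLE_FC),
    "top": (ROLE_FAB_LEFT, ROLE_HINGE, ROLE_FAB_RIGHT),
}


@dataclass
class Fragment:
    """A named set of residue ranges on one chain (ranges inclusive)."""

    label: str
    chain_id: str
    ranges: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.ranges:
            raise AbtrajError(f"fragment {self.label!r} has no residue ranges")
        cleaned = []
        for lo, hi in self.ranges:
            lo, hi = int(lo), int(hi)
            if hi < lo:
                raise AbtrajError(f"fragment {self.label!r}: empty range {lo}-{hi}")
            cleaned.append((lo, hi))
        cleaned.sort()
        for (lo1, hi1), (lo2, _hi2) in zip(cleaned, cleaned[1:]):
            if lo2 <= hi1:
                raise AbtrajError(
                    f"fragment {self.label!r}: overlapping ranges "
                    f"{lo1}-{hi1} and starting at {lo2}"
                )
        self.ranges = cleaned

    def selection_spec(self, atom_class: str = "all") -> str:
        resid = ",".join(f"{lo}-{hi}" for lo, hi in self.ranges)
        spec = f"chain {self.chain_id} and resid {resid}"
        if atom_class != "all":
            spec += f" and {atom_class}"
        return spec


@dataclass
class Anchor:
    """A single residue used as an angle endpoint or vertex.

    ``atom_rule`` is ``"CA"`` (that residue's CA atom) or ``"centroid"``
    (the mean position of the residue's atoms).
    """

    label: str
    chain_id: str
    residue_number: int
    atom_rule: str = "CA"
    residue_name: str | None = None

    def resolve(self, structure: Structure) -> np.ndarray:
        """Indices of the atoms this anchor uses in ``structure``."""
        mask = ((structure.chain_ids.astype(str) == self.chain_id)
                & (structure.residue_numbers == self.residue_number)
                & (structure.insertion_codes.astype(str) == ""))
        if self.atom_rule.upper() == "CA":
            mask &= structure.atom_names == "CA"
            idx = np.nonzero(mask)[0]
            if len(idx) != 1:
                raise AbtrajError(
                    f"anchor {self.label!r} (chain {self.chain_id}, residue "
                    f"{self.residue_number}, CA) resolves to {len(idx)} atoms, "
                    "expected exactly 1"
                )
            return idx
        if self.atom_rule == "centroid":
            idx = np.nonzero(mask)[0]
            if len(idx) == 0:
                raise AbtrajError(
                    f"anchor {self.label!r}: residue {self.residue_number} "
                    f"absent from chain {self.chain_id}"
                )
            return idx
        raise AbtrajError(f"unknown anchor atom rule {self.atom_rule!r}")


@dataclass
class DomainMap:
    """Fragments, region groups and anchors for one molecule."""

    fragments: dict[str, Fragment]
    regions: dict[str, list[str]]
    anchors: dict[str, Anchor]

    def __post_init__(self) -> None:
        if not self.fragments:
            raise AbtrajError("domain map declares zero fragments")
        for region, members in self.regions.items():
            for m in members:
                if m not in self.fragments:
                    raise AbtrajError(
                        f"region {region!r} references undefined fragment {m!r}"
                    )

    def fragment_atomset(self, structure: Structure, label: str,
                         atom_class: str = "all") -> AtomSet:
        frag = self.fragments.get(label)
        if frag is None:
            raise AbtrajError(f"unknown fragment {label!r}")
        aset = select(structure, frag.selection_spec(atom_class))
        aset.label = label if atom_class == "all" else f"{label} ({atom_class})"
        return aset

    def region_atomset(self, structure: Structure, region: str,
                       atom_class: str = "all") -> AtomSet:
        members = self.regions.get(region)
        if not members:
            raise AbtrajError(f"unknown region {region!r}")
        sets = [self.fragment_atomset(structure, m, atom_class) for m in members]
        return union(*sets, label=region)

    def validate(self, structure: Structure) -> None:
        """Resolve every fragment and anchor against ``structure``; raise on failure."""
        for label in self.fragments:
            self.fragment_atomset(structure, label)
        for anchor in self.anchors.values():
            anchor.resolve(structure)
        missing = [r for r in ANCHOR_ROLES if r not in self.anchors]
        if missing:
            raise AbtrajError(f"domain map missing anchor roles: {missing}")

    # ---- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "fragments": [
                {"label": f.label, "chain": f.chain_id,
                 "ranges": [[lo, hi] for lo, hi in f.ranges]}
                for f in self.fragments.values()
            ],
            "regions": {k: list(v) for k, v in self.regions.items()},
            "anchors": {
                role: {"chain": a.chain_id, "resid": a.residue_number,
                       "atom_rule": a.atom_rule,
                       **({"resname": a.residue_name} if a.residue_name else {})}
                for role, a in self.anchors.items()
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "DomainMap":
        for key in ("fragments", "regions", "anchors"):
            if key not in data:
                raise AbtrajError(f"domain map config missing {key!r} section")
        fragments = {}
        for entry in data["fragments"]:
            frag = Fragment(entry["label"], str(entry["chain"]),
                            [tuple(r) for r in entry["ranges"]])
            if frag.label in fragments:
                raise AbtrajError(f"duplicate fragment label {frag.label!r}")
            fragments[frag.label] = frag
        anchors = {
            role: Anchor(role, str(a["chain"]), int(a["resid"]),
                         a.get("atom_rule", "CA"), a.get("resname"))
            for role, a in data["anchors"].items()
        }
        return cls(fragments, {k: list(v) for k, v in data["regions"].items()},
                   anchors)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_domain_map(path, structure: Structure | None = None) -> DomainMap:
    """Load a YAML domain map, optionally validating it against a structure."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise AbtrajError(f"domain map {path} is not a mapping")
    dm = DomainMap.from_dict(data)
    if structure is not None:
        dm.validate(structure)
    return dm
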