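"""Fab/Fc hinge kinematics: angles among anchor residues across the CH1-CH2 linker.

Three angles share the linker anchor (Cys-type vertex) and track large-scale
arm motion: *left* (left-Fab tip - linker - Fc tip), *right* (right-Fab tip -
linker - Fc tip) and *top* (left tip - linker - right tip).  Angles are
invariant under rigid motion of the whole molecule, so no alignment is applied
before measuring them; their sum is 360 deg only when the three arms happen to
be coplanar.
"""

from __future__ import annotations

import numpy as np

from .domains import ANGLE_TRIPLETS, Anchor, DomainMap
from .model import AbtrajError, Structure, TimeSeries, Trajectory

_MIN_SEPARATION = 1e-6  # Å


def anchor_point(frame_coords: np.ndarray, structure: Structure,
                 anchor: Anchor) -> np.ndarray:
    """The anchor's position in one coordinate frame (CA atom or residue centroid)."""
    frame_coords = np.asarray(frame_coords, dtype=float)
    if frame_coords.shape != (structure.n_atoms, 3):
        raise AbtrajError("frame coordinates must match the structure")
    idx = anchor.resolve(structure)
    return frame_coords[idx].mean(axis=0)


def triplet_angle(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    """Angle at ``vertex`` between rays to ``a`` and ``b``, in degrees [0, 180]."""
    a = np.asarray(a, dtype=float)
    vertex = np.asarray(vertex, dtype=float)
    b = np.asarray(b, dtype=float)
    va = a - vertex
    vb = b - vertex
    na = np.linalg.norm(va)
    nb = np.linalg.norm(vb)
    if na <= _MIN_SEPARATION or nb <= _MIN_SEPARATION:
        raise AbtrajError("degenerate angle: endpoint coincides with vertex")
    cosang = np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def angle_series(traj: Trajectory, domain_map: DomainMap) -> dict[str, TimeSeries]:
    """Per-frame left/right/top hinge angles (degrees), keyed by angle label."""
    structure = traj.structure
    anchor_idx = {}
    for label, (role_a, role_v, role_b) in ANGLE_TRIPLETS.items():
        for role in (role_a, role_v, role_b):
            if role not in domain_map.anchors:
                raise AbtrajError(f"domain map missing anchor role {role!r} "
                                  f"needed by the {label} angle")
            if role not in anchor_idx:
                anchor_idx[role] = domain_map.anchors[role].resolve(structure)

    points = {role: traj.coordinates[:, idx, :].mean(axis=1)
              for role, idx in anchor_idx.items()}
    out = {}
    for label, (role_a, role_v, role_b) in ANGLE_TRIPLETS.items():
        values = np.empty(traj.n_frames)
        for f in range(traj.n_frames):
            try:
                values[f] = triplet_angle(points[role_a][f], points[role_v][f],
                                          points[role_b][f])
            except AbtrajError as exc:
                raise AbtrajError(f"frame {f}, {label} angle: {exc}") from exc
        out[label] = TimeSeries(f"{label}_angle", traj.times.copy(), values,
                                "degrees")
    return out


def angle_table(series: dict[str, TimeSeries]):
    """The three angle series as a DataFrame (time_ns, left_deg, right_deg, top_deg)."""
    import pandas as pd

    data = {"time_ns": next(iter(series.values())).times}
    for label in ("left", "right", "top"):
        data[f"{label}_deg"] = series[label].values
    return pd.DataFrame(data)


def write_angle_csv(series: dict[str, TimeSeries], domain_map: DomainMap,
                    path) -> None:
    with open(path, "w") as fh:
        fh.write("# units: degrees\n")
        for role, a in domain_map.anchors.items():
            fh.write(f"# anchor {role}: chain {a.chain_id} resid "
                     f"{a.residue_number} ({a.atom_rule})\n")
        angle_table(series).to_csv(fh, index=False)
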