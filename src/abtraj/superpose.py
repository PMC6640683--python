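"""Optimal rigid-body superposition (Kabsch) and per-frame trajectory alignment.

Structures are treated as rigid bodies and overlapped using translations and
proper rotations only: ``best_fit`` returns the rotation/translation pair that
minimises the (optionally weighted) RMSD between index-matched point sets, via
the SVD form of the Kabsch algorithm with the determinant sign corrected on the
smallest singular value so that reflections are never returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import AbtrajError, AtomSet, DegenerateGeometryError, Trajectory


@dataclass
class SuperpositionResult:
    """A proper rigid transform mapping mobile onto reference coordinates.

    ``rotation`` is 3×3 orthonormal with det = +1; applying the transform is
    ``coords @ rotation.T + translation``.  ``fitted_rmsd`` is the minimised
    weighted RMSD in Å.
    """

    rotation: np.ndarray
    translation: np.ndarray
    fitted_rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def as_matrix(self) -> np.ndarray:
        """The transform as a 4×4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def save_matrix(self, path) -> None:
        np.savetxt(path, self.as_matrix(), fmt="%.10f",
                   header="rigid transform: rows of a 4x4 homogeneous matrix")


def _check_cloud(coords: np.ndarray, name: str) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise AbtrajError(f"{name} must be an (n, 3) array")
    if not np.all(np.isfinite(coords)):
        raise AbtrajError(f"non-finite coordinates in {name}")
    return coords


def _check_nondegenerate(centered: np.ndarray, weights: np.ndarray, name: str) -> None:
    if centered.shape[0] < 3:
        raise DegenerateGeometryError(
            f"{name}: at least 3 points are required for a rigid fit"
        )
    cov = (centered * weights[:, None]).T @ centered
    # rank < 2 <=> all (weighted) points collinear
    if np.linalg.matrix_rank(cov, tol=1e-10 * max(1.0, float(np.abs(cov).max()))) < 2:
        raise DegenerateGeometryError(f"{name}: points are collinear")


def best_fit(mobile: np.ndarray, reference: np.ndarray,
             weights: np.ndarray | None = None) -> SuperpositionResult:
    """Least-squares proper rigid superposition of ``mobile`` onto ``reference``.

    Parameters
    ----------
    mobile, reference : (n, 3) index-matched coordinates, Å.
    weights : optional nonnegative per-atom weights (e.g. masses); uniform if
        omitted.

    Returns
    -------
    SuperpositionResult with det(rotation) = +1 and the minimised RMSD.
    """
    mobile = _check_cloud(mobile, "mobile")
    reference = _check_cloud(reference, "reference")
    if mobile.shape != reference.shape:
        raise AbtrajError(
            f"point count mismatch: mobile {mobile.shape[0]} vs "
            f"reference {reference.shape[0]}"
        )
    n = mobile.shape[0]
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise AbtrajError("weights must be one per atom")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise AbtrajError("weights must be finite and nonnegative")
        total = w.sum()
        if total <= 0:
            raise AbtrajError("weights must not all be zero")
        w = w / total

    mob_centroid = w @ mobile
    ref_centroid = w @ reference
    mob_c = mobile - mob_centroid
    ref_c = reference - ref_centroid
    _check_nondegenerate(mob_c, w, "mobile")
    _check_nondegenerate(ref_c, w, "reference")

    cov = (w[:, None] * mob_c).T @ ref_c
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:  # pragma: no cover - excluded by the rank check
        d = 1.0
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ref_centroid - rotation @ mob_centroid
    fitted = mob_c @ rotation.T - ref_c
    rmsd = float(np.sqrt(max(0.0, np.sum(w * np.einsum("ij,ij->i", fitted, fitted)))))
    return SuperpositionResult(rotation, translation, rmsd)


def align_trajectory(traj: Trajectory, fit_set: AtomSet,
                     reference: int | np.ndarray = 0,
                     weights: np.ndarray | None = None) -> Trajectory:
    """Superpose every frame onto a reference using the fit-set atoms.

    ``reference`` is a frame index into ``traj`` or an (n_fit, 3) external
    coordinate array matching the fit set.  Each frame is transformed rigidly,
    so intra-frame geometry is preserved exactly.
    """
    fit_set.validate(traj.structure)
    idx = fit_set.indices
    if isinstance(reference, (int, np.integer)):
        ref_coords = traj.coordinates[int(reference)][idx]
    else:
        ref_coords = np.asarray(reference, dtype=float)
        if ref_coords.shape != (len(idx), 3):
            raise AbtrajError(
                f"external reference must match the fit set: expected "
                f"({len(idx)}, 3), got {ref_coords.shape}"
            )
    out = np.empty_like(traj.coordinates)
    for f in range(traj.n_frames):
        try:
            fit = best_fit(traj.coordinates[f][idx], ref_coords, weights)
        except DegenerateGeometryError as exc:
            raise DegenerateGeometryError(f"frame {f}: {exc}") from exc
        out[f] = fit.apply(traj.coordinates[f])
    return Trajectory(traj.structure, out, traj.times.copy())
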