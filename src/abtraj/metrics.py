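"""RMSD and RMSF engines and steady-state window statistics.

RMSD between two index-matched structures is

    RMSD = sqrt( (1/N) * sum_i |r_i(t1) - r_i(t2)|^2 )

computed either literally or after optimal rigid superposition.  The
per-residue fluctuation about the time-averaged structure is

    RMSF_k = sqrt( < (1/N_k) * sum_{i in k} |r_i(t) - <r_i>_T|^2 >_T )

where ``<.>_T`` is the time average over the aligned trajectory.  Because a
relative re-orientation of two domains inflates both quantities, the engines
support fragment-local alignment: fitting on the analysed fragment itself
removes inter-domain motion and leaves only internal flexibility.
"""

from __future__ import annotations

import warnings

import numpy as np

from .model import (AbtrajError, AtomSet, RmsfProfile, Structure, TimeSeries,
                    Trajectory, WindowStats)
from .superpose import best_fit


def rmsd_pair(coords_a: np.ndarray, coords_b: np.ndarray,
              superpose: bool = False) -> float:
    """Root-mean-square distance between two index-matched coordinate sets (Å).

    With ``superpose=True`` the mobile set (``coords_a``) is first rigidly
    fitted onto ``coords_b``.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise AbtrajError(f"coordinate shapes differ or are not (n, 3): "
                          f"{a.shape} vs {b.shape}")
    if a.shape[0] < 1:
        raise AbtrajError("RMSD needs at least one atom")
    if superpose:
        return best_fit(a, b).fitted_rmsd
    d = a - b
    return float(np.sqrt(np.mean(np.einsum("ij,ij->i", d, d))))


def _reference_coords(traj: Trajectory, reference, indices: np.ndarray,
                      what: str) -> np.ndarray:
    if isinstance(reference, (int, np.integer)):
        return traj.coordinates[int(reference)][indices]
    ref = np.asarray(reference, dtype=float)
    if ref.shape == (traj.n_atoms, 3):
        return ref[indices]
    if ref.shape == (len(indices), 3):
        return ref
    raise AbtrajError(
        f"{what} reference must be a frame index, full-structure coordinates "
        f"or coordinates matching the atom set; got shape {ref.shape}"
    )


def rmsd_series(traj: Trajectory, reference=0, calc_set: AtomSet | None = None,
                fit_set: AtomSet | None = None, label: str = "rmsd") -> TimeSeries:
    """Per-frame RMSD to a reference after per-frame rigid fitting.

    Each frame is superposed onto the reference via ``fit_set`` (defaults to
    ``calc_set``: whole-molecule fit when calc_set is the whole molecule,
    fragment-local fit when it is a fragment), then the RMSD is evaluated over
    ``calc_set``.
    """
    if calc_set is None:
        calc_set = AtomSet(np.arange(traj.n_atoms), label="all")
    calc_set.validate(traj.structure)
    if fit_set is None:
        fit_set = calc_set
    fit_set.validate(traj.structure)
    ref_fit = _reference_coords(traj, reference, fit_set.indices, "fit")
    ref_calc = _reference_coords(traj, reference, calc_set.indices, "calc")
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        try:
            sup = best_fit(traj.coordinates[f][fit_set.indices], ref_fit)
        except AbtrajError as exc:
            raise AbtrajError(f"frame {f}: {exc}") from exc
        values[f] = rmsd_pair(sup.apply(traj.coordinates[f][calc_set.indices]),
                              ref_calc)
    return TimeSeries(label, traj.times.copy(), values, "Å")


def mean_structure(traj: Trajectory, atomset: AtomSet | None = None,
                   fit_set: AtomSet | None = None, max_iter: int = 10,
                   tol: float = 1e-6) -> np.ndarray:
    """Iteratively aligned time-average coordinates of ``atomset``.

    The time average <r_i>_T depends on the alignment, which in turn depends
    on the average; starting from frame 0, frames are re-fitted (on
    ``fit_set``) to the running mean until it shifts by less than ``tol`` Å
    RMS or ``max_iter`` is reached (then a warning is issued and the last
    iterate returned).
    """
    if atomset is None:
        atomset = AtomSet(np.arange(traj.n_atoms), label="all")
    atomset.validate(traj.structure)
    if fit_set is None:
        fit_set = atomset
    fit_set.validate(traj.structure)
    work = np.union1d(atomset.indices, fit_set.indices)
    pos_in_work = np.searchsorted(work, atomset.indices)
    fit_in_work = np.searchsorted(work, fit_set.indices)

    coords = traj.coordinates[:, work, :]
    mean = coords[0].copy()
    for _ in range(max_iter):
        aligned = np.empty_like(coords)
        for f in range(coords.shape[0]):
            sup = best_fit(coords[f][fit_in_work], mean[fit_in_work])
            aligned[f] = sup.apply(coords[f])
        new_mean = aligned.mean(axis=0)
        shift = np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1)))
        mean = new_mean
        if shift < tol:
            break
    else:
        warnings.warn(
            f"mean structure not converged to {tol} Å after {max_iter} "
            "iterations; returning last iterate", stacklevel=2)
    return mean[pos_in_work]


def _aligned_fragment_coords(traj: Trajectory, fragment: AtomSet,
                             fit_set: AtomSet, max_iter: int,
                             tol: float) -> np.ndarray:
    """Fragment coordinates of every frame after fitting to the iterative mean."""
    ref_fit = mean_structure(traj, fit_set, fit_set, max_iter=max_iter, tol=tol)
    out = np.empty((traj.n_frames, len(fragment), 3))
    for f in range(traj.n_frames):
        sup = best_fit(traj.coordinates[f][fit_set.indices], ref_fit)
        out[f] = sup.apply(traj.coordinates[f][fragment.indices])
    return out


def rmsf_profile(traj: Trajectory, fragment: AtomSet,
                 fit_mode: str | AtomSet = "local", label: str | None = None,
                 max_iter: int = 10, tol: float = 1e-6) -> RmsfProfile:
    """Per-residue RMSF of a fragment about its time-averaged structure.

    ``fit_mode='local'`` aligns frames on the fragment itself (removing
    inter-domain motion before measuring fluctuations); passing an AtomSet
    aligns on that set instead, so the profile then includes any relative
    motion between the fragment and the fit set.
    """
    if traj.n_frames < 2:
        raise AbtrajError(
            "RMSF is undefined for a single-frame trajectory (fluctuations "
            "about a one-frame average are identically zero by construction)"
        )
    fragment.validate(traj.structure)
    if len(fragment) == 0:
        raise AbtrajError("empty fragment")
    if isinstance(fit_mode, AtomSet):
        fit_set = fit_mode
    elif fit_mode == "local":
        fit_set = fragment
    else:
        raise AbtrajError(f"fit_mode must be 'local' or an AtomSet, got {fit_mode!r}")

    coords = _aligned_fragment_coords(traj, fragment, fit_set, max_iter, tol)
    atom_mean = coords.mean(axis=0)                       # <r_i>_T
    dev2 = np.sum((coords - atom_mean) ** 2, axis=2)       # (frames, atoms)

    s = traj.structure
    keys = list(zip(s.chain_ids[fragment.indices],
                    s.residue_numbers[fragment.indices],
                    s.insertion_codes[fragment.indices]))
    order: dict[tuple, list[int]] = {}
    for col, key in enumerate(keys):
        order.setdefault(key, []).append(col)

    chains, resids, icodes, values = [], [], [], []
    for (chain, resid, icode), cols in order.items():
        per_frame = dev2[:, cols].mean(axis=1)             # residue mean, N_k atoms
        values.append(np.sqrt(per_frame.mean()))           # time average, then sqrt
        chains.append(chain)
        resids.append(resid)
        icodes.append(icode)
    return RmsfProfile(
        label or fragment.label or "fragment",
        np.asarray(chains, dtype=object), np.asarray(resids, dtype=int),
        np.asarray(values), traj.n_frames,
        insertion_codes=np.asarray(icodes, dtype=object),
    )


def window_stats(series: TimeSeries, t_start: float, t_end: float) -> WindowStats:
    """Mean and sample (n-1) standard deviation over ``t_start <= t <= t_end``."""
    if not t_start < t_end:
        raise AbtrajError("window requires t_start < t_end")
    mask = (series.times >= t_start) & (series.times <= t_end)
    n = int(mask.sum())
    if n == 0:
        raise AbtrajError(
            f"window [{t_start}, {t_end}] ns contains no points of "
            f"series {series.label!r}"
        )
    vals = series.values[mask]
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return WindowStats(t_start, t_end, float(vals.mean()), sd, n)
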