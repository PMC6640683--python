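"""Cross-trajectory comparison: conformation matching and time rescaling.

Implicit-solvent simulations explore conformational space faster than explicit
ones; the speedup is quantified by finding the implicit-trajectory time at
which the molecule best matches a reference conformation (e.g. the final
explicit-solvent frame) and taking the ratio of the two times.  Rescaled
series can then be overlaid on a common time grid for side-by-side plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AbtrajError, AtomSet, TimeSeries, Trajectory
from .metrics import rmsd_pair


@dataclass
class ScaleFit:
    """A matched-conformation time and the implied sampling scale factor.

    ``factor = reference_time / t_match``: how much faster the searched
    trajectory reaches the reference conformation than the trajectory that
    produced it.
    """

    t_match: float
    reference_time: float
    factor: float
    match_rmsd: float

    def __post_init__(self) -> None:
        if self.t_match <= 0:
            raise AbtrajError("t_match must be positive")
        if self.match_rmsd < 0:
            raise AbtrajError("match_rmsd must be nonnegative")

    @property
    def factor_rounded(self) -> int:
        """Convenience integer factor (nearest), as quoted in reports."""
        return int(round(self.factor))


def match_time(query_coords: np.ndarray, traj: Trajectory,
               calc_set: AtomSet | None = None) -> tuple[float, float]:
    """Earliest trajectory time whose frame best matches ``query_coords``.

    ``query_coords`` must hold the same atom selection (same count and order)
    as ``calc_set`` applied to the trajectory; each frame is compared by
    superposed RMSD and the earliest minimum returned as ``(t_match,
    match_rmsd)``.
    """
    if calc_set is None:
        calc_set = AtomSet(np.arange(traj.n_atoms), label="all")
    calc_set.validate(traj.structure)
    query = np.asarray(query_coords, dtype=float)
    if query.shape != (len(calc_set), 3):
        raise AbtrajError(
            f"query has {query.shape} coordinates but the comparison set has "
            f"{len(calc_set)} atoms; use the same selection on both systems"
        )
    rmsds = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        rmsds[f] = rmsd_pair(traj.coordinates[f][calc_set.indices], query,
                             superpose=True)
    best = int(np.argmin(rmsds))  # argmin returns the earliest minimum
    return float(traj.times[best]), float(rmsds[best])


def estimate_scale_factor(reference_time: float, t_match: float,
                          match_rmsd: float = 0.0) -> ScaleFit:
    """Sampling scale factor from a matched pair of times.

    Example: a conformation reached after 100 ns of one trajectory matched at
    16.88 ns of another gives factor 100/16.88 = 5.92 (~6).
    """
    if reference_time <= 0 or t_match <= 0:
        raise AbtrajError("both times must be positive")
    return ScaleFit(t_match=float(t_match), reference_time=float(reference_time),
                    factor=float(reference_time) / float(t_match),
                    match_rmsd=float(match_rmsd))


def match_and_estimate(query_coords: np.ndarray, reference_time: float,
                       traj: Trajectory,
                       calc_set: AtomSet | None = None) -> ScaleFit:
    """Convenience: :func:`match_time` followed by :func:`estimate_scale_factor`."""
    t, r = match_time(query_coords, traj, calc_set)
    return estimate_scale_factor(reference_time, t, r)


def rescale_time(series: TimeSeries, factor: float) -> TimeSeries:
    """Multiply the time axis by ``factor``; values are untouched."""
    if factor <= 0:
        raise AbtrajError("rescale factor must be positive")
    label = series.label if factor == 1 else f"{series.label} (time x{factor:g})"
    return TimeSeries(label, series.times * factor, series.values.copy(),
                      series.units)


def overlay_table(series_list: list[TimeSeries],
                  grid: np.ndarray) -> pd.DataFrame:
    """Linear-interpolation overlay of several series on a common time grid.

    One row per grid time, one column per series; cells outside a series'
    support are left empty (NaN) — no extrapolation.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise AbtrajError("empty time grid")
    out = {"time_ns": grid}
    for s in series_list:
        col = np.interp(grid, s.times, s.values)
        col = np.where((grid < s.times[0]) | (grid > s.times[-1]), np.nan, col)
        out[s.label or f"series_{len(out)}"] = col
    return pd.DataFrame(out)
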