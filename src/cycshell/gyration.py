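"""Radius of gyration and plateau (convergence) detection.

Structural convergence of a trajectory is declared when the radius of
gyration reaches a plateau: the earliest frame from which every
sliding-window least-squares slope stays below a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DomainError, System, as_trajectory
from .density import center_of_mass
from .selection import resolve_nonempty


def radius_of_gyration(system: System, selection="species=peptide",
                       weighting: str = "mass") -> float:
    """sqrt( sum w_i |r_i - r_com|^2 / sum w_i ) over the selection (Å).

    Peptide atoms only by default: the quantity tracks shell size, so
    counterions and water are excluded.
    """
    ids = resolve_nonempty(system.topology, selection, "Rg selection")
    coords = system.coords[ids]
    if weighting == "mass":
        w = system.topology.masses[ids]
    elif weighting == "geometric":
        w = np.ones(len(ids))
    else:
        raise DomainError(f"unknown weighting {weighting!r}")
    com = (w[:, None] * coords).sum(axis=0) / w.sum()
    return float(np.sqrt((w * ((coords - com) ** 2).sum(axis=1)).sum()
                         / w.sum()))


def rg_series(traj, selection="species=peptide",
              weighting: str = "mass") -> np.ndarray:
    """Per-frame radius of gyration."""
    traj = as_trajectory(traj)
    return np.array([radius_of_gyration(traj[i], selection, weighting)
                     for i in range(len(traj))])


@dataclass
class ConvergenceReport:
    series: np.ndarray
    plateau_start: int | None
    plateau_mean: float | None
    window: int
    slope_tol: float


def detect_plateau(series, window: int | None = None,
                   slope_tol: float = 0.01) -> ConvergenceReport:
    """Earliest frame t such that every least-squares slope over
    [t', t'+window), t' >= t, satisfies |slope| < slope_tol (Å/frame).

    ``window`` defaults to 20% of the series (at least 2 frames).
    ``plateau_start`` is None when no such frame exists; ``plateau_mean``
    averages the series from the plateau start on.
    """
    series = np.asarray(series, dtype=float)
    if window is None:
        window = max(2, len(series) // 5)
    if window < 2 or window > len(series):
        raise DomainError(
            f"window {window} outside 2..{len(series)} frames")
    x = np.arange(window) - (window - 1) / 2.0
    denom = (x ** 2).sum()
    n_starts = len(series) - window + 1
    slopes = np.array([
        (x * (series[t:t + window] - series[t:t + window].mean())).sum()
        / denom
        for t in range(n_starts)
    ])
    ok = np.abs(slopes) < slope_tol
    # plateau start: earliest t with all later windows flat (suffix scan)
    start = None
    for t in range(n_starts - 1, -1, -1):
        if not ok[t]:
            break
        start = t
    mean = float(series[start:].mean()) if start is not None else None
    return ConvergenceReport(series=series, plateau_start=start,
                             plateau_mean=mean, window=window,
                             slope_tol=slope_tol)
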