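"""Normalized radial number density profiles and hollow-shell classification.

``rho_norm(r)`` is the radial number density of a species about a reference
center of mass, divided by the species' particle count ``N``, so
``rho_norm(r) * N`` is the local average number density at distance ``r``.
Distances to the center of mass are computed on unwrapped coordinates: the
assembly may span the box, so minimum imaging against a COM is ill-defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (DomainError, System, as_trajectory,
                   resolve_frame_range)
from .selection import resolve_nonempty


def center_of_mass(system: System, selection=None,
                   weighting: str = "mass") -> np.ndarray:
    """Weighted mean position of the selected atoms (mass or geometric)."""
    ids = resolve_nonempty(system.topology, selection, "COM selection")
    coords = system.coords[ids]
    if weighting == "mass":
        w = system.topology.masses[ids]
    elif weighting == "geometric":
        w = np.ones(len(ids))
    else:
        raise DomainError(f"unknown weighting {weighting!r}")
    return (w[:, None] * coords).sum(axis=0) / w.sum()


@dataclass
class RadialProfile:
    """Binned rho_norm(r) for one species.

    Invariant: ``sum(rho_norm * shell_volumes) == 1`` whenever all particles
    of the species lie inside the binned range.
    """

    bin_edges: np.ndarray
    rho_norm: np.ndarray
    n_particles: int
    species: str
    frames_used: tuple

    @property
    def bin_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def shell_volumes(self) -> np.ndarray:
        e = self.bin_edges
        return 4.0 / 3.0 * np.pi * (e[1:] ** 3 - e[:-1] ** 3)

    @property
    def bin_fractions(self) -> np.ndarray:
        """Average fraction of particles per bin (rho_norm * shell volume)."""
        return self.rho_norm * self.shell_volumes


def radial_density(traj, selection, ref_selection=None, bin_width: float = 1.0,
                   frame_range=None, weighting: str = "mass",
                   r_max: float | None = None) -> RadialProfile:
    """rho_norm(r) of the selected atoms about the reference COM, frame by
    frame, averaged over ``frame_range``.

    ``ref_selection`` defaults to the selection itself (a species referenced
    to its own center of mass).  ``r_max`` defaults to the largest observed
    distance, rounded up to a whole bin.
    """
    if bin_width <= 0:
        raise DomainError("bin_width must be > 0")
    traj = as_trajectory(traj)
    frames = resolve_frame_range(traj, frame_range)
    topo = traj.topology
    ids = resolve_nonempty(topo, selection, "density selection")
    ref = ref_selection if ref_selection is not None else selection

    dists = []
    for i in frames:
        system = traj[i]
        com = center_of_mass(system, ref, weighting=weighting)
        dists.append(np.linalg.norm(system.coords[ids] - com, axis=1))
    dists = np.array(dists)

    if r_max is None:
        r_max = float(np.ceil(dists.max() / bin_width) * bin_width)
        r_max = max(r_max, bin_width)
    edges = np.arange(0.0, r_max + 0.5 * bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    for row in dists:
        counts += np.histogram(row, bins=edges)[0]
    counts /= len(frames)

    vols = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rho = counts / (len(ids) * vols)
    label = selection if isinstance(selection, str) else f"{len(ids)} atoms"
    return RadialProfile(bin_edges=edges, rho_norm=rho, n_particles=len(ids),
                         species=str(label),
                         frames_used=(frames.start, frames.stop))


def classify_hollow(profile: RadialProfile, zero_tol: float = 0.005,
                    inner_radius_min: float = 10.0):
    """(is_hollow, inner_radius): hollow iff the density vanishes between the
    center and a finite radius.

    The mean number density inside a candidate inner radius is compared with
    the species' mean density over its occupied radial extent: the structure
    is hollow when, for some radius >= ``inner_radius_min``, the inner
    density stays below ``zero_tol`` times that reference (a plain
    fraction-of-total rule would label any dilute gas in a large box hollow,
    because a small central sphere holds a small fraction of a *uniform*
    distribution too).  ``inner_radius`` is the largest radius meeting the
    tolerance (0 if the center is populated at reference density).
    """
    frac = profile.bin_fractions
    total = frac.sum()
    if total <= 0:
        raise DomainError("profile contains no particles")
    edges = profile.bin_edges
    populated = np.flatnonzero(frac > 0)
    r_extent = edges[populated[-1] + 1]
    rho_ref = total / (4.0 / 3.0 * np.pi * r_extent ** 3)
    cum = np.cumsum(frac)
    inner_vol = 4.0 / 3.0 * np.pi * edges[1:] ** 3
    below = np.flatnonzero(cum / inner_vol < zero_tol * rho_ref)
    # require contiguity from the center outward
    n_lead = 0
    for i, k in enumerate(below):
        if k != i:
            break
        n_lead += 1
    inner_radius = float(edges[n_lead]) if n_lead else 0.0
    return inner_radius >= inner_radius_min, inner_radius
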