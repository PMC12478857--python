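"""Contact censuses, condensation time series, and hydration statistics.

All counting operations use the minimum-image convention and heavy atoms
only (hydrogens would make a 3 Å contact rule trivially satisfiable); water
is identified by its oxygen atom throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import (AnalysisError, DomainError, SelectionError, System,
                   as_trajectory, resolve_frame_range)
from .pbc import wrap_coords
from .selection import resolve, resolve_nonempty

DEFAULT_CONTACT_CUT = 3.0


def _heavy_ids(topo, selection, what):
    ids = resolve_nonempty(topo, selection, what)
    return ids[topo.heavy_mask[ids]]


def _group_by_residue(topo, ids):
    """{residue_index: array of atom ids} preserving sorted order."""
    groups: dict = {}
    res = topo.residue_index
    for i in ids:
        groups.setdefault(int(res[i]), []).append(int(i))
    return {k: np.array(v) for k, v in groups.items()}


# ---------------------------------------------------------------------------
# condensation


@dataclass
class CondensationSeries:
    """Per-frame condensed-ion counts and tail-averaged per-residue rates."""

    counts: np.ndarray            # condensed ions per frame
    per_peptide: np.ndarray       # counts / n_peptides
    per_peptide_counts: list      # per frame: np.ndarray over peptide ids
    per_arg_mean: float           # tail-averaged ions condensed via Arg
    n_peptides: int
    tail_frames: tuple


def condensation_timeseries(traj, ions=None, cutoff: float =
                            DEFAULT_CONTACT_CUT, tail_frames: int | None =
                            None) -> CondensationSeries:
    """Ions with any heavy atom within ``cutoff`` of any peptide heavy atom.

    Each condensed ion is attributed to its nearest peptide (ties broken by
    lowest peptide id).  ``per_arg_mean`` is the tail-averaged number of ions
    condensed via an Arg side-chain heavy atom, divided by the total number
    of Arg residues.
    """
    traj = as_trajectory(traj)
    topo = traj.topology
    ion_ids = _heavy_ids(topo, ions if ions is not None else "species=anion",
                         "ion selection")
    ion_groups = _group_by_residue(topo, ion_ids)
    pep_heavy = np.flatnonzero((topo.species == "peptide") & topo.heavy_mask)
    if pep_heavy.size == 0:
        raise SelectionError("no peptide heavy atoms present")
    pep_of_atom = topo.peptide_id[pep_heavy]
    n_peptides = int(topo.peptide_id.max()) + 1
    arg_side = np.flatnonzero((topo.residue_name == "ARG")
                              & topo.role_mask("sidechain") & topo.heavy_mask)
    n_arg = len({int(topo.residue_index[i]) for i in arg_side})

    counts, per_pep_counts, arg_condensed = [], [], []
    for i in range(len(traj)):
        system = traj[i]
        tree = cKDTree(wrap_coords(system.coords[pep_heavy], system.box),
                       boxsize=system.box)
        arg_tree = cKDTree(wrap_coords(system.coords[arg_side], system.box),
                           boxsize=system.box) if arg_side.size else None
        frame_count = 0
        frame_arg = 0
        pp = np.zeros(n_peptides, dtype=int)
        for rid, aids in ion_groups.items():
            wrapped = wrap_coords(system.coords[aids], system.box)
            d, j = tree.query(wrapped, k=1)
            if np.min(d) <= cutoff:
                frame_count += 1
                # nearest peptide over all ion atoms; ties -> lowest id
                order = np.lexsort((pep_of_atom[j], d))
                pp[pep_of_atom[j[order[0]]]] += 1
                if arg_tree is not None:
                    d_arg, _ = arg_tree.query(wrapped, k=1)
                    if np.min(d_arg) <= cutoff:
                        frame_arg += 1
        counts.append(frame_count)
        per_pep_counts.append(pp)
        arg_condensed.append(frame_arg)

    counts = np.array(counts)
    n_tail = tail_frames if tail_frames is not None else len(traj)
    if not 1 <= n_tail <= len(traj):
        raise DomainError("tail_frames outside trajectory length")
    per_arg = float(np.mean(arg_condensed[-n_tail:]) / n_arg) if n_arg \
        else 0.0
    return CondensationSeries(
        counts=counts, per_peptide=counts / n_peptides,
        per_peptide_counts=per_pep_counts, per_arg_mean=per_arg,
        n_peptides=n_peptides,
        tail_frames=(len(traj) - n_tail, len(traj)),
    )


# ---------------------------------------------------------------------------
# side-chain censuses


@dataclass
class ContactCensus:
    """Which peptides have residue-type side chains in ion contact."""

    flags: dict          # residue type -> bool array over peptide ids
    counts: dict         # residue type -> number of peptides flagged
    residues_by_ion: dict  # ion residue index -> set of contacted types
    n_peptides: int


def sidechain_contact_census(system: System, ions=None, cutoff: float =
                             DEFAULT_CONTACT_CUT) -> ContactCensus:
    """Flag each peptide per residue type when any side-chain heavy atom of
    that type is within ``cutoff`` of any ion heavy atom."""
    topo = system.topology
    ion_ids = _heavy_ids(topo, ions if ions is not None else "species=anion",
                         "ion selection")
    n_peptides = int(topo.peptide_id.max()) + 1
    side = np.flatnonzero((topo.species == "peptide")
                          & topo.role_mask("sidechain") & topo.heavy_mask)
    if side.size == 0:
        raise SelectionError("no side-chain heavy atoms present")
    tree = cKDTree(wrap_coords(system.coords[ion_ids], system.box),
                   boxsize=system.box)
    hits = tree.query_ball_point(wrap_coords(system.coords[side], system.box),
                                 cutoff)
    types = sorted(set(topo.residue_name[side]))
    flags = {t: np.zeros(n_peptides, dtype=bool) for t in types}
    residues_by_ion: dict = {}
    res_of_ion = topo.residue_index
    for s, idxs in zip(side, hits):
        if not idxs:
            continue
        t = topo.residue_name[s]
        flags[t][topo.peptide_id[s]] = True
        for i in idxs:
            rid = int(res_of_ion[ion_ids[i]])
            residues_by_ion.setdefault(rid, set()).add(str(t))
    counts = {t: int(flags[t].sum()) for t in types}
    return ContactCensus(flags=flags, counts=counts,
                         residues_by_ion=residues_by_ion,
                         n_peptides=n_peptides)


def interpeptide_residue_contacts(system: System, residue_name: str,
                                  cutoff: float = DEFAULT_CONTACT_CUT):
    """Per side chain of ``residue_name``: how many same-type side chains on
    *other* peptides have any heavy-atom pair within ``cutoff``.

    Returns ``(per_chain, mean)`` with ``per_chain`` keyed by residue index.
    """
    topo = system.topology
    mask = ((topo.residue_name == residue_name)
            & topo.role_mask("sidechain") & topo.heavy_mask
            & (topo.species == "peptide"))
    ids = np.flatnonzero(mask)
    if ids.size == 0:
        raise SelectionError(
            f"no {residue_name} side-chain heavy atoms present")
    groups = _group_by_residue(topo, ids)
    tree = cKDTree(wrap_coords(system.coords[ids], system.box),
                   boxsize=system.box)
    hits = tree.query_ball_point(wrap_coords(system.coords[ids], system.box),
                                 cutoff)
    res = topo.residue_index
    pid = topo.peptide_id
    partners = {rid: set() for rid in groups}
    for local_i, idxs in enumerate(hits):
        a = ids[local_i]
        for local_j in idxs:
            b = ids[local_j]
            if pid[a] != pid[b]:
                partners[int(res[a])].add(int(res[b]))
    per_chain = {rid: len(p) for rid, p in partners.items()}
    return per_chain, float(np.mean(list(per_chain.values())))


# ---------------------------------------------------------------------------
# radial distribution functions / hydration


@dataclass
class RDFResult:
    """Pair correlation g(r) with the bulk density used for normalization."""

    bin_edges: np.ndarray
    g: np.ndarray
    pair_counts: np.ndarray     # mean pair count per center per bin
    bulk_density: float
    n_centers: int
    first_min: float | None = None
    coordination: float | None = None

    @property
    def bin_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def pair_rdf(traj, centers, targets, bin_width: float = 0.1,
             r_max: float = 10.0, frame_range=None) -> RDFResult:
    """Standard pair correlation between two selections under periodic
    boundaries; bulk density is N_targets / V_box."""
    traj = as_trajectory(traj)
    frames = resolve_frame_range(traj, frame_range)
    topo = traj.topology
    c_ids = resolve_nonempty(topo, centers, "RDF centers")
    t_ids = resolve_nonempty(topo, targets, "RDF targets")
    box = traj.frames[0].box
    if r_max >= min(box) / 2:
        raise DomainError(
            f"r_max {r_max} Å must be below half the smallest box length "
            f"({min(box) / 2} Å)"
        )
    if bin_width <= 0:
        raise DomainError("bin_width must be > 0")
    edges = np.arange(0.0, r_max + 0.5 * bin_width, bin_width)
    shared = len(np.intersect1d(c_ids, t_ids))

    counts = np.zeros(len(edges) - 1)
    for i in frames:
        system = traj[i]
        tree_c = cKDTree(wrap_coords(system.coords[c_ids], system.box),
                         boxsize=system.box)
        tree_t = cKDTree(wrap_coords(system.coords[t_ids], system.box),
                         boxsize=system.box)
        cum = tree_c.count_neighbors(tree_t, edges)
        cum = cum.astype(float) - shared   # remove zero-distance self pairs
        counts += np.diff(cum)
    counts /= len(frames)

    v_box = float(np.prod(box))
    rho_bulk = len(t_ids) / v_box
    vols = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (len(c_ids) * rho_bulk * vols)
    return RDFResult(bin_edges=edges, g=g, pair_counts=counts / len(c_ids),
                     bulk_density=rho_bulk, n_centers=len(c_ids))


def first_minimum(rdf: RDFResult, search_window=None,
                  smooth_bins: int = 3) -> float:
    """First local minimum of the smoothed g(r) after its first maximum.

    Smoothing (centered moving average over ``smooth_bins``) is used for
    detection only.  Raises :class:`AnalysisError` when no minimum exists
    (e.g. monotone g), rather than guessing.
    """
    g = rdf.g
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        sm = np.convolve(g, kernel, mode="same")
    else:
        sm = g.copy()
    mid = rdf.bin_mid
    lo, hi = search_window if search_window is not None else \
        (float(mid[0]), float(mid[-1]))
    # first maximum: largest smoothed value before the window end
    inside = (mid >= lo) & (mid <= hi)
    if not inside.any():
        raise AnalysisError("search window contains no bins")
    i_max = int(np.argmax(np.where(mid <= hi, sm, -np.inf)))
    if sm[i_max] <= 0:
        raise AnalysisError("g(r) has no maximum before the window end")
    for i in range(max(i_max + 1, 1), len(sm) - 1):
        if mid[i] > hi:
            break
        if mid[i] < lo:
            continue
        if sm[i] <= sm[i - 1] and sm[i] <= sm[i + 1]:
            return float(mid[i])
    raise AnalysisError(
        "no local minimum of g(r) found after its maximum within "
        f"[{lo}, {hi}] Å"
    )


def coordination_number(traj, centers, targets, r_min: float,
                        frame_range=None) -> float:
    """Mean count of target atoms within ``r_min`` of each center, by direct
    counting (not the integral approximation), averaged over frames."""
    if r_min <= 0:
        raise DomainError("r_min must be > 0")
    traj = as_trajectory(traj)
    frames = resolve_frame_range(traj, frame_range)
    topo = traj.topology
    c_ids = resolve_nonempty(topo, centers, "coordination centers")
    t_ids = resolve_nonempty(topo, targets, "coordination targets")
    shared = set(np.intersect1d(c_ids, t_ids).tolist())
    totals = []
    for i in frames:
        system = traj[i]
        tree = cKDTree(wrap_coords(system.coords[t_ids], system.box),
                       boxsize=system.box)
        hits = tree.query_ball_point(
            wrap_coords(system.coords[c_ids], system.box), r_min)
        n = sum(len(h) for h in hits)
        if shared:
            n -= sum(1 for c in c_ids if int(c) in shared)
        totals.append(n / len(c_ids))
    return float(np.mean(totals))


def waters_per_peptide(traj, cutoff: float = 3.5, frame_range=None) -> float:
    """Mean number of waters whose oxygen is within ``cutoff`` of any heavy
    atom of a peptide (each water may count toward several peptides)."""
    traj = as_trajectory(traj)
    frames = resolve_frame_range(traj, frame_range)
    topo = traj.topology
    w_ids = resolve(topo, "species=water and element=O")
    if w_ids.size == 0:
        raise SelectionError("no water oxygens present")
    pep_heavy = np.flatnonzero((topo.species == "peptide") & topo.heavy_mask)
    if pep_heavy.size == 0:
        raise SelectionError("no peptide heavy atoms present")
    n_peptides = int(topo.peptide_id.max()) + 1
    pid = topo.peptide_id[pep_heavy]
    means = []
    for i in frames:
        system = traj[i]
        tree = cKDTree(wrap_coords(system.coords[w_ids], system.box),
                       boxsize=system.box)
        hits = tree.query_ball_point(
            wrap_coords(system.coords[pep_heavy], system.box), cutoff)
        per_pep = [set() for _ in range(n_peptides)]
        for atom_pos, idxs in enumerate(hits):
            per_pep[pid[atom_pos]].update(idxs)
        means.append(np.mean([len(s) for s in per_pep]))
    return float(np.mean(means))
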