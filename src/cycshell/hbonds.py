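"""Hydrogen-bond detection and per-anion / bridging statistics.

A hydrogen bond is a donor-heavy / hydrogen / acceptor-heavy triple with
minimum-image heavy-heavy distance <= ``d_cut`` (default 3.0 Å) and
donor-hydrogen-acceptor angle (measured at the hydrogen) >= ``angle_cut``
(default 150 degrees), donor and acceptor in different residues.  Both
thresholds are inclusive.  Each hydrogen of a multi-hydrogen donor can form
its own bond (guanidinium multidentacity requires per-hydrogen accounting).

An anion is *condensed* when any of its heavy atoms lies within 3 Å of any
peptide heavy atom, and *bridging* when it forms hydrogen bonds with
side chains of Arg/Gln from two or more distinct peptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import (SelectionError, System, TopologyError, as_trajectory,
                   resolve_frame_range)
from .pbc import minimum_image_displacement, wrap_coords
from .selection import resolve, resolve_nonempty

DEFAULT_D_CUT = 3.0
DEFAULT_ANGLE_CUT = 150.0


@dataclass(frozen=True)
class HBondRecord:
    donor_heavy: int
    hydrogen: int
    acceptor_heavy: int
    distance: float
    angle: float
    donor_peptide: int
    acceptor_species: str


def find_hbonds(system: System, donors=None, acceptors=None,
                d_cut: float = DEFAULT_D_CUT,
                angle_cut: float = DEFAULT_ANGLE_CUT) -> list:
    """All hydrogen bonds between the donor and acceptor selections.

    ``donors``/``acceptors`` default to every donor-heavy / acceptor-heavy
    atom.  Output is sorted by (donor, acceptor, hydrogen).  Uses a periodic
    KD-tree neighbor search, so cost is near-linear in atom count.
    """
    topo = system.topology
    donor_ids = resolve(topo, donors)
    acceptor_ids = resolve(topo, acceptors)
    donor_mask = topo.role_mask("donor_heavy")
    acceptor_mask = topo.role_mask("acceptor_heavy")
    donor_ids = donor_ids[donor_mask[donor_ids]]
    for i in donor_ids:
        if not topo[int(i)].bonded_hydrogens:
            raise TopologyError(
                f"donor atom {i} ({topo[int(i)].residue_name}/"
                f"{topo[int(i)].name}) has no bonded hydrogen in the topology"
            )
    acceptor_ids = acceptor_ids[acceptor_mask[acceptor_ids]]
    if donor_ids.size == 0 or acceptor_ids.size == 0:
        return []

    box = system.box
    coords = system.coords
    tree_a = cKDTree(wrap_coords(coords[acceptor_ids], box), boxsize=box)
    tree_d = cKDTree(wrap_coords(coords[donor_ids], box), boxsize=box)
    pairs = tree_d.query_ball_tree(tree_a, d_cut)

    res_idx = topo.residue_index
    records = []
    for di, neighbors in enumerate(pairs):
        d_id = int(donor_ids[di])
        d_atom = topo[d_id]
        for ai in neighbors:
            a_id = int(acceptor_ids[ai])
            if res_idx[a_id] == res_idx[d_id]:
                continue
            disp = minimum_image_displacement(coords[d_id], coords[a_id], box)
            dist = float(np.linalg.norm(disp))
            if dist > d_cut:
                continue
            for h_id in d_atom.bonded_hydrogens:
                v_d = minimum_image_displacement(coords[h_id], coords[d_id],
                                                 box)
                v_a = minimum_image_displacement(coords[h_id], coords[a_id],
                                                 box)
                denom = np.linalg.norm(v_d) * np.linalg.norm(v_a)
                if denom == 0:
                    continue
                cosang = np.clip(np.dot(v_d, v_a) / denom, -1.0, 1.0)
                angle = float(np.degrees(np.arccos(cosang)))
                if angle >= angle_cut:
                    records.append(HBondRecord(
                        donor_heavy=d_id, hydrogen=int(h_id),
                        acceptor_heavy=a_id, distance=dist, angle=angle,
                        donor_peptide=int(topo.peptide_id[d_id]),
                        acceptor_species=topo[a_id].species,
                    ))
    records.sort(key=lambda r: (r.donor_heavy, r.acceptor_heavy, r.hydrogen))
    return records


@dataclass
class AnionHBStats:
    """Per-anion hydrogen-bond statistics (counts keyed by anion residue)."""

    counts_by_anion: dict
    pmf: dict                  # HB count -> probability (sums to 1 over anions)
    mean: float
    mean_rounded: int
    fraction_by_residue: dict  # donor residue name -> fraction of HBs

    @property
    def n_anions(self) -> int:
        return len(self.counts_by_anion)


def _anion_residues(topo, anions):
    ids = resolve_nonempty(topo, anions if anions is not None
                           else "species=anion", "anion selection")
    res = topo.residue_index[ids]
    return ids, sorted(set(int(r) for r in res))


def hbonds_per_anion(traj, anions=None, donors=None,
                     d_cut: float = DEFAULT_D_CUT,
                     angle_cut: float = DEFAULT_ANGLE_CUT,
                     frame_range=None) -> AnionHBStats:
    """Distribution of peptide-to-anion hydrogen bonds per anion.

    Donors default to all peptide donor-heavy atoms; acceptors are the anion
    atoms.  With a trajectory, counts are averaged per anion over the frame
    range (the probability mass function pools frames with equal weight).
    """
    traj = as_trajectory(traj)
    frames = resolve_frame_range(traj, frame_range)
    topo = traj.topology
    anion_ids, anion_res = _anion_residues(topo, anions)
    donor_sel = donors if donors is not None else \
        "species=peptide and role=donor_heavy"

    per_frame_counts = []
    residue_hits: dict = {}
    for i in frames:
        system = traj[i]
        records = find_hbonds(system, donors=donor_sel, acceptors=anion_ids,
                              d_cut=d_cut, angle_cut=angle_cut)
        counts = {r: 0 for r in anion_res}
        for rec in records:
            counts[int(topo.residue_index[rec.acceptor_heavy])] += 1
            dres = topo[rec.donor_heavy].residue_name
            residue_hits[dres] = residue_hits.get(dres, 0) + 1
        per_frame_counts.append(counts)

    mean_by_anion = {
        r: float(np.mean([c[r] for c in per_frame_counts])) for r in anion_res
    }
    all_counts = [c[r] for c in per_frame_counts for r in anion_res]
    values, freqs = np.unique(all_counts, return_counts=True)
    pmf = {int(v): float(f) / len(all_counts)
           for v, f in zip(values, freqs)}
    mean = float(np.mean(all_counts)) if all_counts else 0.0
    total_hits = sum(residue_hits.values())
    frac = {k: v / total_hits for k, v in sorted(residue_hits.items())} \
        if total_hits else {}
    return AnionHBStats(
        counts_by_anion=mean_by_anion, pmf=pmf, mean=mean,
        mean_rounded=int(np.floor(mean + 0.5)),
        fraction_by_residue=frac,
    )


@dataclass
class BridgeReport:
    """Per-anion peptide sets and condensed/bridging counts and ratios."""

    peptides_by_anion: dict    # anion residue index -> set of peptide ids
    condensed_ids: set
    bridging_ids: set
    n_total: int
    n_condensed: int
    n_bridging: int
    ratio_total: float
    ratio_condensed: float | None

    def __post_init__(self):
        assert self.n_bridging <= self.n_condensed <= self.n_total


def find_bridging_ions(system: System, restrict_residues=("ARG", "GLN"),
                       d_cut: float = DEFAULT_D_CUT,
                       angle_cut: float = DEFAULT_ANGLE_CUT,
                       condense_cut: float = 3.0,
                       anions=None) -> BridgeReport:
    """Bridging census: anions hydrogen-bonded to side chains of
    ``restrict_residues`` on two or more distinct peptides.

    Condensation uses the heavy-atom contact rule: an anion is condensed
    when any of its heavy atoms is within ``condense_cut`` of any peptide
    heavy atom (minimum image).  ``ratio_condensed`` is None when no anion
    is condensed.
    """
    topo = system.topology
    anion_ids, anion_res = _anion_residues(topo, anions)
    # side-chain donors of the named residues only
    donor_ids = resolve(topo, "species=peptide and role=donor_heavy")
    side = topo.role_mask("sidechain")
    keep = side[donor_ids] & np.isin(topo.residue_name[donor_ids],
                                     list(restrict_residues))
    donor_ids = donor_ids[keep]

    peptides_by_anion = {r: set() for r in anion_res}
    if donor_ids.size:
        for rec in find_hbonds(system, donors=donor_ids, acceptors=anion_ids,
                               d_cut=d_cut, angle_cut=angle_cut):
            rid = int(topo.residue_index[rec.acceptor_heavy])
            peptides_by_anion[rid].add(rec.donor_peptide)

    # heavy-atom condensation
    heavy = topo.heavy_mask
    pep_heavy = np.flatnonzero((topo.species == "peptide") & heavy)
    anion_heavy = anion_ids[heavy[anion_ids]]
    condensed = set()
    if pep_heavy.size and anion_heavy.size:
        tree = cKDTree(wrap_coords(system.coords[pep_heavy], system.box),
                       boxsize=system.box)
        d, _ = tree.query(wrap_coords(system.coords[anion_heavy], system.box),
                          k=1)
        for aid, dist in zip(anion_heavy, d):
            if dist <= condense_cut:
                condensed.add(int(topo.residue_index[aid]))

    bridging = {r for r, peps in peptides_by_anion.items() if len(peps) >= 2}
    n_total = len(anion_res)
    n_condensed = len(condensed)
    n_bridging = len(bridging)
    return BridgeReport(
        peptides_by_anion=peptides_by_anion,
        condensed_ids=condensed, bridging_ids=bridging,
        n_total=n_total, n_condensed=n_condensed, n_bridging=n_bridging,
        ratio_total=n_bridging / n_total if n_total else 0.0,
        ratio_condensed=(n_bridging / n_condensed) if n_condensed else None,
    )


def backbone_hb_census(system: System, d_cut_census: float = 3.85):
    """Mean number of backbone amide hydrogens within ``d_cut_census`` of
    each backbone carbonyl oxygen (other residues only).

    Returns ``(mean, per_oxygen)`` where ``per_oxygen`` maps carbonyl-O atom
    ids to counts.
    """
    topo = system.topology
    o_mask = (topo.role_mask("backbone") & topo.role_mask("acceptor_heavy")
              & (topo.element == "O"))
    h_mask = topo.role_mask("backbone") & topo.role_mask("hydrogen")
    o_ids = np.flatnonzero(o_mask)
    h_ids = np.flatnonzero(h_mask)
    if o_ids.size == 0:
        raise SelectionError("no backbone carbonyl oxygens in the topology")
    per_o = {int(o): 0 for o in o_ids}
    if h_ids.size:
        tree = cKDTree(wrap_coords(system.coords[h_ids], system.box),
                       boxsize=system.box)
        res = topo.residue_index
        hits = tree.query_ball_point(
            wrap_coords(system.coords[o_ids], system.box), d_cut_census)
        for o, idxs in zip(o_ids, hits):
            per_o[int(o)] = sum(
                1 for i in idxs if res[h_ids[i]] != res[o])
    mean = float(np.mean(list(per_o.values())))
    return mean, per_o
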