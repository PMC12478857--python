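"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (O(n^2) scans, 27-image searches) and
shares no code path with the package's cell-list / KD-tree implementations.
"""

import itertools

import numpy as np


def min_image_distance_27(a, b, box):
    """Minimum distance between a and b over the 27 neighbor images."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    box = np.asarray(box, float)
    best = np.inf
    for shift in itertools.product((-1, 0, 1), repeat=3):
        d = np.linalg.norm(b + np.array(shift) * box - a)
        best = min(best, d)
    return best


def _mi(a, b, box):
    d = np.asarray(b, float) - np.asarray(a, float)
    return d - box * np.round(d / box)


def brute_force_hbonds(system, d_cut=3.0, angle_cut=150.0,
                       donor_ids=None, acceptor_ids=None):
    """All-pairs hydrogen-bond scan; returns {(donor, hydrogen, acceptor)}."""
    topo = system.topology
    coords = system.coords
    box = system.box
    if donor_ids is None:
        donor_ids = [a.atom_id for a in topo if "donor_heavy" in a.roles]
    if acceptor_ids is None:
        acceptor_ids = [a.atom_id for a in topo if "acceptor_heavy" in a.roles]
    found = set()
    for d in donor_ids:
        for a in acceptor_ids:
            if topo[d].residue_index == topo[a].residue_index:
                continue
            if np.linalg.norm(_mi(coords[d], coords[a], box)) > d_cut:
                continue
            for h in topo[d].bonded_hydrogens:
                v1 = _mi(coords[h], coords[d], box)
                v2 = _mi(coords[h], coords[a], box)
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1)
                                           * np.linalg.norm(v2))
                angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if angle >= angle_cut:
                    found.add((d, h, a))
    return found


def brute_force_contacts(system, ids_a, ids_b, cutoff):
    """All pairs (i in ids_a, j in ids_b) within cutoff (minimum image)."""
    coords = system.coords
    box = system.box
    pairs = set()
    for i in ids_a:
        for j in ids_b:
            if i == j:
                continue
            if np.linalg.norm(_mi(coords[i], coords[j], box)) <= cutoff:
                pairs.add((int(i), int(j)))
    return pairs


def brute_force_pair_counts(system, c_ids, t_ids, edges):
    """Per-bin pair counts between selections (minimum image), excluding
    identical atoms."""
    coords = system.coords
    box = system.box
    dists = []
    for i in c_ids:
        for j in t_ids:
            if i == j:
                continue
            dists.append(np.linalg.norm(_mi(coords[i], coords[j], box)))
    return np.histogram(dists, bins=edges)[0]


def brute_force_radial_histogram(coords, center, edges):
    """One-pass histogram of distances from a fixed center (no imaging)."""
    d = np.linalg.norm(np.asarray(coords) - np.asarray(center), axis=1)
    return np.histogram(d, bins=edges)[0]


def weighted_com(coords, weights):
    w = np.asarray(weights, float)
    return (w[:, None] * np.asarray(coords)).sum(axis=0) / w.sum()


def direct_rg(coords, weights):
    com = weighted_com(coords, weights)
    w = np.asarray(weights, float)
    return np.sqrt((w * ((coords - com) ** 2).sum(axis=1)).sum() / w.sum())
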