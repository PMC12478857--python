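"""Synthetic fixtures with planted, exactly-known ground truth.

The trajectories behind the original study are not deposited, so every
statistic in the pipeline is validated against fixtures whose truth is known
by construction: hollow shells and dispersed gases for density profiles,
donor-H-acceptor triples with controlled distance/angle geometry for
hydrogen-bond detection, bridging anions spanning a chosen number of
peptides, hydration shells of known coordination number, and
Gaussian-jittered multi-frame trajectories for time-series statistics.

Planted geometry keeps a margin of at least 0.05 Å / 5 degrees from the
3 Å / 150 degree detection thresholds, so boundary-inclusiveness conventions
cannot flip a truth label.  Truth is emitted alongside each fixture and never
recomputed from it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import (DomainError, Frame, PackingError, System, Trajectory)
from .pbc import minimum_image_distance
from .residues import label_atoms

#: inter-site center separation guaranteeing >6 Å between atoms of different
#: planted groups (site extent is at most ~5 Å from its center)
_SITE_SEP = 17.0


@dataclass
class PlantedTruth:
    """Ground truth shipped next to a fixture (test oracle container)."""

    hbond_triples: list = field(default_factory=list)
    bridging_ion_ids: set = field(default_factory=set)
    condensed_ion_ids: set = field(default_factory=set)
    coordination_by_center: dict = field(default_factory=dict)
    profile_kind: str | None = None
    shell_radius: float | None = None

    def to_json(self, path) -> None:
        data = asdict(self)
        data["hbond_triples"] = [list(t) for t in self.hbond_triples]
        data["bridging_ion_ids"] = sorted(self.bridging_ion_ids)
        data["condensed_ion_ids"] = sorted(self.condensed_ion_ids)
        data["coordination_by_center"] = {
            str(k): v for k, v in self.coordination_by_center.items()
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            hbond_triples=[tuple(t) for t in data["hbond_triples"]],
            bridging_ion_ids=set(data["bridging_ion_ids"]),
            condensed_ion_ids=set(data["condensed_ion_ids"]),
            coordination_by_center={
                int(k): v for k, v in data["coordination_by_center"].items()
            },
            profile_kind=data.get("profile_kind"),
            shell_radius=data.get("shell_radius"),
        )


def _uniform_directions(n: int, rng) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _spread_sites(n: int, box, rng, min_sep: float = _SITE_SEP,
                  max_attempts: int = 200000) -> np.ndarray:
    """Random site centers with pairwise minimum-image separation."""
    box = np.asarray(box, float)
    sites = np.empty((0, 3))
    attempts = 0
    while len(sites) < n:
        if attempts >= max_attempts:
            raise PackingError(
                f"placed only {len(sites)} of {n} sites at separation "
                f"{min_sep} Å; enlarge the box"
            )
        attempts += 1
        cand = rng.uniform(0.0, 1.0, 3) * box
        if sites.size and np.min(
                minimum_image_distance(sites, cand, box)) < min_sep:
            continue
        sites = np.vstack([sites, cand])
    return sites


# ---------------------------------------------------------------------------
# density-profile fixtures


def make_shell_fixture(n_points: int, radius: float, thickness: float,
                       box, seed: int = 0):
    """Points uniform (in volume) on a spherical shell [radius, radius+thickness].

    Returns a single-frame Trajectory of shell pseudo-atoms centered in the
    box, plus truth recording ``profile_kind="hollow_shell"``.
    """
    box = np.asarray(box, float)
    if radius < 0 or thickness < 0:
        raise DomainError("radius and thickness must be >= 0")
    if radius + thickness >= min(box) / 2:
        raise DomainError(
            f"shell of outer radius {radius + thickness} Å does not fit in "
            f"half the box ({min(box) / 2} Å)"
        )
    rng = np.random.default_rng(seed)
    dirs = _uniform_directions(n_points, rng)
    r0, r1 = radius, radius + thickness
    if thickness == 0:
        radii = np.full(n_points, float(radius))
    else:
        u = rng.uniform(size=n_points)
        radii = np.cbrt(r0 ** 3 + u * (r1 ** 3 - r0 ** 3))
    coords = box / 2.0 + dirs * radii[:, None]
    raw = [{"name": "PS", "residue_name": "SHP", "residue_index": i,
            "peptide_id": i} for i in range(n_points)]
    traj = Trajectory(label_atoms(raw), [Frame(coords, box)])
    truth = PlantedTruth(profile_kind="hollow_shell", shell_radius=radius)
    return traj, truth


def make_gas_fixture(n_points: int, box, seed: int = 0):
    """Points uniform in the box (dispersed-gas reference for profiles)."""
    box = np.asarray(box, float)
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, 1.0, (n_points, 3)) * box
    raw = [{"name": "GS", "residue_name": "GAS", "residue_index": i,
            "peptide_id": i} for i in range(n_points)]
    traj = Trajectory(label_atoms(raw), [Frame(coords, box)])
    truth = PlantedTruth(profile_kind="uniform_gas")
    return traj, truth


# ---------------------------------------------------------------------------
# hydrogen-bond fixtures


def _triple_coords(site, d: float, theta_deg: float, rng):
    """Donor/hydrogen/acceptor positions with D-A distance ``d`` and
    D-H-A angle ``theta`` (degrees), D-H = 1.0 Å, at a random orientation."""
    w = _uniform_directions(1, rng)[0]          # D -> H direction
    donor = np.asarray(site, float)
    hydrogen = donor + w
    # perpendicular direction for the bend
    t = np.cross(w, _uniform_directions(1, rng)[0])
    while np.linalg.norm(t) < 1e-8:             # pragma: no cover - rare
        t = np.cross(w, _uniform_directions(1, rng)[0])
    t /= np.linalg.norm(t)
    theta = math.radians(theta_deg)
    # |HA| from the triangle with sides |HD|=1, |DA|=d, angle theta at H
    x = math.cos(theta) + math.sqrt(d * d - math.sin(theta) ** 2)
    ha_dir = math.cos(theta) * (-w) + math.sin(theta) * t
    acceptor = hydrogen + x * ha_dir
    return donor, hydrogen, acceptor


def plant_hbond_set(n_true: int, n_decoy_far: int, n_decoy_bent: int,
                    box, seed: int = 0):
    """Donor-H-acceptor triples with controlled geometry.

    True triples: heavy-atom distance in [2.6, 2.95] Å and angle in
    [155, 180] degrees.  Far decoys: distance in [3.1, 4.0] Å, good angle.
    Bent decoys: good distance, angle in [100, 145] degrees.  Triples are
    mutually separated by more than 6 Å; truth lists exactly the true
    triples as (donor_id, hydrogen_id, acceptor_id).
    """
    if min(n_true, n_decoy_far, n_decoy_bent) < 0:
        raise DomainError("counts must be >= 0")
    box = np.asarray(box, float)
    rng = np.random.default_rng(seed)
    n = n_true + n_decoy_far + n_decoy_bent
    sites = _spread_sites(n, box, rng)

    raw, coords, truth_triples = [], [], []
    pid = 0
    for i in range(n):
        if i < n_true:
            d = rng.uniform(2.6, 2.95)
            theta = rng.uniform(155.0, 180.0)
        elif i < n_true + n_decoy_far:
            d = rng.uniform(3.1, 4.0)
            theta = rng.uniform(155.0, 180.0)
        else:
            d = rng.uniform(2.6, 2.95)
            theta = rng.uniform(100.0, 145.0)
        donor, hydrogen, acceptor = _triple_coords(sites[i], d, theta, rng)
        base = len(raw)
        raw.append({"name": "D", "residue_name": "DON",
                    "residue_index": 2 * i, "peptide_id": pid})
        raw.append({"name": "HD", "residue_name": "DON",
                    "residue_index": 2 * i, "peptide_id": pid})
        raw.append({"name": "A", "residue_name": "ACC",
                    "residue_index": 2 * i + 1, "peptide_id": -1})
        coords.extend([donor, hydrogen, acceptor])
        if i < n_true:
            truth_triples.append((base, base + 1, base + 2))
        pid += 1
    system = System(label_atoms(raw), Frame(np.array(coords), box))
    return system, PlantedTruth(hbond_triples=truth_triples)


def plant_bridges(n_bridging: int, peptides_per_bridge: int, n_mono: int,
                  n_free: int, box, seed: int = 0):
    """Anions bridging a chosen number of mini-peptides via Arg-site HBs.

    Each bridging anion receives valid hydrogen-bond geometry to the Arg
    side-chain donor of ``peptides_per_bridge`` distinct mini-peptides;
    ``n_mono`` anions bond to exactly one peptide; ``n_free`` anions sit
    beyond 6 Å from every peptide.  Truth records the bridging set and the
    condensed set (bridging plus mono) as anion residue indices.
    """
    if peptides_per_bridge < 2 and n_bridging > 0:
        raise DomainError("peptides_per_bridge must be >= 2")
    if min(n_bridging, n_mono, n_free) < 0:
        raise DomainError("counts must be >= 0")
    box = np.asarray(box, float)
    rng = np.random.default_rng(seed)
    n_sites = n_bridging + n_mono + n_free
    sites = _spread_sites(n_sites, box, rng)

    raw, coords = [], []
    res_counter = 0
    pid = 0
    bridging_ids, condensed_ids = set(), set()

    def add_anion(pos):
        nonlocal res_counter
        raw.append({"name": "F", "residue_name": "F",
                    "residue_index": res_counter, "peptide_id": -1})
        coords.append(pos)
        rid = res_counter
        res_counter += 1
        return rid

    def add_arg_peptide(anion_pos, direction):
        """Mini ARG peptide whose CZ-H points its H straight at the anion."""
        nonlocal res_counter, pid
        cz = anion_pos + 2.8 * direction
        hs1 = cz - 1.0 * direction           # on the CZ->anion segment
        # remaining hydrogens point away from the anion
        perp = np.cross(direction, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(direction, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        ca = cz + 1.5 * direction
        for name, pos in (("CA", ca), ("CZ", cz), ("HS1", hs1),
                          ("HS2", cz + perp),
                          ("HS3", cz + 0.5 * direction +
                           math.sqrt(3) / 2 * perp),
                          ("HS4", cz + 0.5 * direction -
                           math.sqrt(3) / 2 * perp)):
            raw.append({"name": name, "residue_name": "ARG",
                        "residue_index": res_counter, "peptide_id": pid})
            coords.append(pos)
        res_counter += 1
        pid += 1

    for i in range(n_sites):
        site = sites[i]
        if i < n_bridging + n_mono:
            m = peptides_per_bridge if i < n_bridging else 1
            rid = add_anion(site)
            # well-separated donor directions around the anion
            from .builder import fibonacci_sphere_points
            dirs = fibonacci_sphere_points(max(m, 2))[:m]
            rand_rot = _random_rotation(rng)
            for d in dirs:
                add_arg_peptide(site, rand_rot @ d)
            condensed_ids.add(rid)
            if m >= 2:
                bridging_ids.add(rid)
        else:
            add_anion(site)

    system = System(label_atoms(raw), Frame(np.array(coords), box))
    truth = PlantedTruth(bridging_ion_ids=bridging_ids,
                         condensed_ion_ids=condensed_ids)
    return system, truth


def _random_rotation(rng) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    return Rotation.random(rng=rng).as_matrix()


# ---------------------------------------------------------------------------
# hydration fixture


def plant_hydration(k: int, r_shell: float, n_far: int, box, seed: int = 0):
    """One anion center with ``k`` first-shell waters at ``r_shell`` ± 0.1 Å
    and ``n_far`` waters in [r_shell+2, r_shell+4] Å.  Truth records the
    coordination number ``k`` for the center atom."""
    if k < 0 or n_far < 0:
        raise DomainError("counts must be >= 0")
    box = np.asarray(box, float)
    if r_shell + 4.0 >= min(box) / 2:
        raise DomainError("hydration bands do not fit in half the box")
    rng = np.random.default_rng(seed)
    center = box / 2.0

    raw = [{"name": "F", "residue_name": "F", "residue_index": 0,
            "peptide_id": -1}]
    coords = [center]

    def water_positions(n, r_lo, r_hi, existing, min_sep=2.0,
                        max_attempts=200000):
        placed = list(existing)
        out = []
        attempts = 0
        while len(out) < n:
            if attempts >= max_attempts:
                raise PackingError(
                    f"placed only {len(out)} of {n} waters in "
                    f"[{r_lo}, {r_hi}] Å"
                )
            attempts += 1
            pos = center + rng.uniform(r_lo, r_hi) * \
                _uniform_directions(1, rng)[0]
            if placed and np.min(minimum_image_distance(
                    np.array(placed), pos, box)) < min_sep:
                continue
            out.append(pos)
            placed.append(pos)
        return out

    shell_o = water_positions(k, r_shell - 0.1, r_shell + 0.1, [])
    far_o = water_positions(n_far, r_shell + 2.0, r_shell + 4.0, shell_o)
    res = 1
    for opos in shell_o + far_o:
        h1 = opos + np.array([0.96, 0.0, 0.0])
        h2 = opos + np.array([-0.24, 0.93, 0.0])
        for name, pos in (("O", opos), ("H1", h1), ("H2", h2)):
            raw.append({"name": name, "residue_name": "HOH",
                        "residue_index": res, "peptide_id": -1})
            coords.append(pos)
        res += 1
    system = System(label_atoms(raw), Frame(np.array(coords), box))
    truth = PlantedTruth(coordination_by_center={0: k})
    return system, truth


# ---------------------------------------------------------------------------
# trajectories


def make_jitter_trajectory(system: System, n_frames: int, sigma: float,
                           seed: int = 0) -> Trajectory:
    """Frames of i.i.d. Gaussian displacements about the input coordinates.

    Frame 0 is the input; frame t adds N(0, sigma^2) noise per atom to frame
    0 (not cumulative).  Deterministic under ``seed``.
    """
    if n_frames < 1:
        raise DomainError("n_frames must be >= 1")
    if sigma < 0:
        raise DomainError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    frames = [Frame(system.coords.copy(), system.box.copy())]
    for _ in range(1, n_frames):
        noise = rng.normal(0.0, sigma, system.coords.shape) if sigma > 0 \
            else 0.0
        frames.append(Frame(system.coords + noise, system.box.copy()))
    return Trajectory(system.topology, frames)
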