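"""Preassembled shell construction.

The shell is assembled from tessellation units of stacked cyclic
d,l-octapeptides: unit centers are distributed near-uniformly on a sphere
(Fibonacci lattice), ring normals point radially, and each unit stacks
``peptides_per_unit`` rings along its normal.  Neutralizing counterions are
then placed at random in the box, rejection-sampled against a minimum
separation.

The cyclopeptide template is idealized: a planar octagonal Calpha ring with
per-residue backbone sites (amide N-H and carbonyl O alternating up/down, as
in cyclic d,l-peptide stacks) and one side-chain pseudo-group per residue
placed radially outward in the ring plane.  Every statistic computed by this
package is a label/geometry census, so this reduced template carries all the
structure the analyses need; an all-atom template can be substituted by
extending the mapping table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .core import (BuildError, DomainError, Frame, PackingError, System,
                   Topology)
from .pbc import minimum_image_displacement, wrap_coords
from .residues import label_atoms, load_table, residue_spec

DEFAULT_SEQUENCE = ("GLN", "DLE", "ARG", "DLE", "ARG", "DLE", "ARG", "DLE")


@dataclass
class ShellSpec:
    """Parameters of the preassembled shell (defaults: the 432-peptide model)."""

    sequence: tuple = DEFAULT_SEQUENCE
    n_units: int = 144
    peptides_per_unit: int = 3
    shell_radius: float = 45.0
    stack_spacing: float = 4.85
    ring_radius: float = 4.1
    box: tuple = (175.0, 173.0, 172.0)
    seed: int = 0

    def __post_init__(self):
        if len(self.sequence) != 8:
            raise DomainError("sequence must list 8 residue names")
        if self.shell_radius <= self.ring_radius:
            raise DomainError("shell_radius must exceed ring_radius")
        if self.n_units < 1 or self.peptides_per_unit < 1:
            raise DomainError("n_units and peptides_per_unit must be >= 1")


@dataclass
class IonSpec:
    """A counterion species to place.

    ``count="auto"`` resolves to the exact number neutralizing the peptide
    charge.  Polyatomic geometries (tetrahedral phosphate, P-O 1.54 Å) are
    built in; any single-atom residue from the mapping table works directly.
    """

    name: str
    valence: int
    count: object = "auto"
    min_separation: float = 3.5

    def __post_init__(self):
        if self.valence == 0:
            raise DomainError("ion valence must be nonzero")


def fibonacci_sphere_points(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors on the sphere (golden-angle lattice)."""
    if n < 1:
        raise DomainError("n must be >= 1")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = i * math.pi * (3.0 - math.sqrt(5.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _template_geometry(sequence, ring_radius):
    """Raw atoms + local-frame coordinates for one cyclopeptide ring.

    Local frame: ring in the xy-plane centered at the origin, normal = +z.
    Amide H and carbonyl O alternate above/below the plane with residue
    parity, mimicking the hydrogen-bonding register of cyclic d,l-peptide
    stacks.
    """
    table = load_table()
    raw, xyz = [], []
    n_res = len(sequence)
    for i, resname in enumerate(sequence):
        rspec = residue_spec(resname, table)
        if rspec.species != "peptide":
            raise DomainError(f"residue {resname!r} is not a peptide residue")
        phi = 2.0 * math.pi * i / n_res
        rhat = np.array([math.cos(phi), math.sin(phi), 0.0])
        that = np.array([-math.sin(phi), math.cos(phi), 0.0])
        zhat = np.array([0.0, 0.0, 1.0])
        s = 1.0 if i % 2 == 0 else -1.0

        def add(name, pos):
            raw.append({"name": name, "residue_name": resname,
                        "residue_index": i, "peptide_id": 0})
            xyz.append(np.asarray(pos, float))

        add("N", (ring_radius - 0.4) * rhat + 0.35 * s * zhat)
        add("HN", (ring_radius - 0.4) * rhat + 1.35 * s * zhat)
        add("CA", ring_radius * rhat)
        add("O", ring_radius * rhat - 0.95 * s * zhat)

        # Side-chain pseudo-groups sit azimuthally between Calphas, barely
        # outside the ring, with donor hydrogens tilted mostly out of plane:
        # the 45 Å preassembly packs units ~10 Å apart, so the template's
        # in-plane radius must stay small for a clash-free initial shell.
        phi_s = phi + math.pi / n_res
        shat = np.array([math.cos(phi_s), math.sin(phi_s), 0.0])
        side_r = ring_radius + 0.2
        # donor hydrogen directions: in-plane component 0.2, rest axial
        h_dirs = [np.array([0.2 * math.cos(phi_s + a),
                            0.2 * math.sin(phi_s + a),
                            sz * math.sqrt(1.0 - 0.04)])
                  for a, sz in ((0.0, 1.0), (math.pi, 1.0),
                                (0.0, -1.0), (math.pi, -1.0))]
        if resname == "ARG":
            cz = side_r * shat
            add("CZ", cz)
            for name, d in zip(("HS1", "HS2", "HS3", "HS4"), h_dirs):
                add(name, cz + d)
        elif resname == "LYS":
            nz = side_r * shat
            add("NZ", nz)
            for name, d in zip(("HS1", "HS2", "HS3"), h_dirs):
                add(name, nz + d)
        elif resname == "GLN":
            ang = 0.10  # radians; amide O and N straddle the side-chain axis
            ro = np.array([math.cos(phi_s + ang), math.sin(phi_s + ang), 0.0])
            rn = np.array([math.cos(phi_s - ang), math.sin(phi_s - ang), 0.0])
            ne2 = side_r * rn
            add("OE1", side_r * ro)
            add("NE2", ne2)
            add("HE21", ne2 + h_dirs[0])
            add("HE22", ne2 + h_dirs[2])
        else:  # LEU / DLE: single nonpolar site
            add("CG", side_r * shat)
    return raw, np.array(xyz)


def build_cyclopeptide_template(sequence=DEFAULT_SEQUENCE, ring_radius=4.1,
                                box=(999.0, 999.0, 999.0)) -> System:
    """One idealized cyclopeptide ring centered at the origin (normal +z)."""
    raw, xyz = _template_geometry(tuple(sequence), ring_radius)
    topo = label_atoms(raw)
    return System(topo, Frame(xyz, np.asarray(box, float)))


def _align_z_to(u: np.ndarray) -> Rotation:
    """Rotation taking +z to the unit vector ``u``."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, u))
    if c > 1.0 - 1e-12:
        return Rotation.identity()
    if c < -1.0 + 1e-12:
        return Rotation.from_rotvec(math.pi * np.array([1.0, 0.0, 0.0]))
    axis = np.cross(z, u)
    axis /= np.linalg.norm(axis)
    return Rotation.from_rotvec(math.acos(c) * axis)


def build_shell(spec: ShellSpec = None, overlap_tol: float = 1.0) -> System:
    """Construct the preassembled shell.

    Each unit is a coaxial stack of ``peptides_per_unit`` template rings with
    normals along its sphere point; stack centers sit exactly at
    ``shell_radius``.  The azimuthal orientation of each unit is drawn from
    the seeded generator (the initial order relaxes in any real trajectory,
    so no particular register is preferred).  Raises :class:`BuildError` if
    atoms of different units approach closer than ``overlap_tol`` Å.
    """
    spec = spec or ShellSpec()
    rng = np.random.default_rng(spec.seed)
    units = fibonacci_sphere_points(spec.n_units)
    raw_tpl, xyz_tpl = _template_geometry(tuple(spec.sequence),
                                          spec.ring_radius)
    n_res = len(spec.sequence)
    p = spec.peptides_per_unit
    offset = 0.5 * (p - 1) * spec.stack_spacing  # center the stack radially

    raw, coords, unit_of_atom = [], [], []
    res_counter = 0
    pid = 0
    center = np.asarray(spec.box, float) / 2.0
    for j, u in enumerate(units):
        align = _align_z_to(u)
        azimuth = Rotation.from_rotvec(rng.uniform(0, 2 * math.pi) * u)
        rot = azimuth * align
        local = rot.apply(xyz_tpl)
        for k in range(p):
            ring_center = (spec.shell_radius + k * spec.stack_spacing
                           - offset) * u
            for ra, pos in zip(raw_tpl, local):
                raw.append({"name": ra["name"],
                            "residue_name": ra["residue_name"],
                            "residue_index": res_counter + ra["residue_index"],
                            "peptide_id": pid})
                coords.append(center + ring_center + pos)
                unit_of_atom.append(j)
            res_counter += n_res
            pid += 1

    coords = np.array(coords)
    box = np.asarray(spec.box, float)
    tree = cKDTree(wrap_coords(coords, box), boxsize=box)
    unit_of_atom = np.array(unit_of_atom)
    for a, b in tree.query_pairs(overlap_tol):
        if unit_of_atom[a] != unit_of_atom[b]:
            raise BuildError(
                f"atoms of units {unit_of_atom[a]} and {unit_of_atom[b]} "
                f"overlap below {overlap_tol} Å; increase shell_radius"
            )
    topo = label_atoms(raw)
    return System(topo, Frame(coords, box))


def shell_unit_centers(spec: ShellSpec = None) -> np.ndarray:
    """Stack-center positions (relative to the shell center) of each unit."""
    spec = spec or ShellSpec()
    return spec.shell_radius * fibonacci_sphere_points(spec.n_units)


def neutralizing_count(n_peptides: int, peptide_charge: int,
                       valence: int) -> int:
    """Ions of ``valence`` needed to exactly neutralize the peptide charge."""
    if valence == 0:
        raise DomainError("valence must be nonzero")
    product = abs(n_peptides * peptide_charge)
    if product % abs(valence):
        raise DomainError(
            f"{product} peptide charges are not divisible by |valence| "
            f"{abs(valence)}: no integer ion count neutralizes the system"
        )
    return product // abs(valence)


_TET = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                dtype=float) / math.sqrt(3.0)


def ion_template(name: str):
    """(atom names, local coordinates) for an ion residue.

    Phosphates are tetrahedral with P-O 1.54 Å; dihydrogen phosphate adds
    O-H hydrogens on two oxygens.  Any single-atom residue in the mapping
    table is a point ion.
    """
    if name == "PO4":
        names = ["P", "O1", "O2", "O3", "O4"]
        xyz = np.vstack([[0.0, 0.0, 0.0], 1.54 * _TET])
        return names, xyz
    if name == "H2P":
        names = ["P", "O1", "O2", "O3", "O4", "HO1", "HO2"]
        oxy = 1.54 * _TET
        h = [(1.54 + 0.96) * _TET[0], (1.54 + 0.96) * _TET[1]]
        return names, np.vstack([[0.0, 0.0, 0.0], oxy, h])
    rspec = residue_spec(name)
    if len(rspec.atoms) != 1:
        raise DomainError(
            f"no built-in geometry for polyatomic ion {name!r}"
        )
    return [next(iter(rspec.atoms))], np.zeros((1, 3))


def peptide_formal_charge(topology: Topology) -> int:
    """Total formal charge of the peptide species only."""
    table = load_table()
    seen, total = set(), 0
    for a in topology:
        if a.species != "peptide" or a.residue_index in seen:
            continue
        seen.add(a.residue_index)
        total += residue_spec(a.residue_name, table).charge
    return total


def place_counterions(system: System, ion: IonSpec, seed: int = 0,
                      max_attempts_per_ion: int = 2000) -> System:
    """Add randomly placed ions, rejection-sampled against ``min_separation``.

    Positions are uniform in the box and orientations uniform on SO(3); a
    candidate is rejected if any of its atoms falls within
    ``ion.min_separation`` (minimum image) of any existing atom, including
    previously placed ions.  Deterministic under ``seed``.
    """
    box = system.box
    if ion.count == "auto":
        q = peptide_formal_charge(system.topology)
        count = neutralizing_count(1, q, ion.valence)
    else:
        count = int(ion.count)
    if count < 0:
        raise DomainError("ion count must be >= 0")

    names, local = ion_template(ion.name)
    rng = np.random.default_rng(seed)
    existing_tree = None
    if system.n_atoms:
        existing_tree = cKDTree(wrap_coords(system.coords, box), boxsize=box)

    placed = []          # per-ion atom coordinate blocks
    placed_flat = np.empty((0, 3))
    attempts = 0
    budget = max_attempts_per_ion * max(count, 1)
    while len(placed) < count:
        if attempts >= budget:
            raise PackingError(
                f"placed only {len(placed)} of {count} {ion.name} ions in "
                f"{budget} attempts; enlarge the box or reduce min_separation"
            )
        attempts += 1
        pos = rng.uniform(0.0, 1.0, 3) * box
        if len(local) > 1:
            rot = Rotation.random(rng=rng)
            atoms = pos + rot.apply(local)
        else:
            atoms = pos + local
        if existing_tree is not None:
            d, _ = existing_tree.query(wrap_coords(atoms, box), k=1)
            if np.min(d) < ion.min_separation:
                continue
        if placed_flat.size:
            disp = minimum_image_displacement(placed_flat[None, :, :],
                                              atoms[:, None, :], box)
            if np.min(np.linalg.norm(disp, axis=-1)) < ion.min_separation:
                continue
        placed.append(atoms)
        placed_flat = np.vstack([placed_flat, atoms])

    res_base = (max(a.residue_index for a in system.topology) + 1
                if system.n_atoms else 0)
    raw = [{"name": a.name, "residue_name": a.residue_name,
            "residue_index": a.residue_index, "peptide_id": a.peptide_id}
           for a in system.topology]
    coords = [system.coords]
    for iion, atoms in enumerate(placed):
        for name in names:
            raw.append({"name": name, "residue_name": ion.name,
                        "residue_index": res_base + iion, "peptide_id": -1})
        coords.append(atoms)
    topo = label_atoms(raw)
    return System(topo, Frame(np.vstack(coords), box))
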