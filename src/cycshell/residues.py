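"""Residue-name -> species/role mapping.

The mapping ships as an editable YAML table (``data/residues.yaml``); analyses
consult labels only, so supporting a new file dialect means editing the table,
not the code.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .core import AtomRecord, LabelingError, Topology

_TABLE_CACHE: dict | None = None


@dataclass(frozen=True)
class ResidueSpec:
    name: str
    species: str
    charge: int
    atoms: dict  # atom name -> {"element", "roles", "hydrogens"}


def load_table(path=None) -> dict:
    """Load the residue mapping table (package default, or a user override)."""
    global _TABLE_CACHE
    if path is None:
        if _TABLE_CACHE is not None:
            return _TABLE_CACHE
        text = (resources.files("cycshell") / "data" / "residues.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    table = {}
    for rname, spec in raw.items():
        atoms = {}
        for aname, aspec in spec["atoms"].items():
            atoms[aname] = {
                "element": str(aspec["element"]),
                "roles": frozenset(aspec.get("roles", [])),
                "hydrogens": tuple(aspec.get("hydrogens", [])),
            }
        table[str(rname)] = ResidueSpec(
            name=str(rname),
            species=spec["species"],
            charge=int(spec.get("charge", 0)),
            atoms=atoms,
        )
    if path is None:
        _TABLE_CACHE = table
    return table


def residue_spec(residue_name: str, table: dict | None = None) -> ResidueSpec:
    table = table or load_table()
    try:
        return table[residue_name]
    except KeyError:
        raise LabelingError(
            f"residue name {residue_name!r} is not in the mapping table; "
            f"known names: {', '.join(sorted(table))}"
        ) from None


def residue_charge(residue_name: str, table: dict | None = None) -> int:
    return residue_spec(residue_name, table).charge


def label_atoms(raw_atoms, table: dict | None = None) -> Topology:
    """Build a labeled Topology from parsed file records.

    ``raw_atoms`` is a list of dicts with keys ``name``, ``residue_name``,
    ``residue_index`` (global 0-based residue instance), ``peptide_id``.
    Species, element, roles and donor-hydrogen bookkeeping all come from the
    mapping table; hydrogens are associated with their donor heavy atom by
    name within the same residue instance (no inference from distances).
    """
    table = table or load_table()
    # index atoms by (residue_index, atom name) to resolve hydrogen names
    by_res_name: dict[tuple, int] = {}
    for i, ra in enumerate(raw_atoms):
        by_res_name[(ra["residue_index"], ra["name"])] = i

    records = []
    for i, ra in enumerate(raw_atoms):
        rspec = residue_spec(ra["residue_name"], table)
        try:
            aspec = rspec.atoms[ra["name"]]
        except KeyError:
            raise LabelingError(
                f"atom name {ra['name']!r} not defined for residue "
                f"{ra['residue_name']!r} in the mapping table"
            ) from None
        hydrogens = tuple(
            by_res_name[(ra["residue_index"], h)]
            for h in aspec["hydrogens"]
            if (ra["residue_index"], h) in by_res_name
        )
        roles = aspec["roles"]
        if "donor_heavy" in roles and not hydrogens:
            # a donor site whose hydrogens are absent from the file is not a
            # usable donor; demote rather than invent hydrogens
            roles = roles - {"donor_heavy"}
        records.append(
            AtomRecord(
                atom_id=i,
                name=ra["name"],
                element=aspec["element"],
                residue_name=ra["residue_name"],
                residue_index=ra["residue_index"],
                peptide_id=ra["peptide_id"] if rspec.species == "peptide" else -1,
                species=rspec.species,
                roles=roles,
                bonded_hydrogens=hydrogens,
            )
        )
    topo = Topology(records)
    topo.validate()
    return topo


def formal_charge(topology: Topology, table: dict | None = None) -> int:
    """Total formal charge: sum of residue charges over residue instances."""
    table = table or load_table()
    seen = set()
    total = 0
    for a in topology:
        if a.residue_index in seen:
            continue
        seen.add(a.residue_index)
        total += residue_charge(a.residue_name, table)
    return total
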