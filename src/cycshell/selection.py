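"""Selection mini-language.

Grammar (documented in the README)::

    expr    := clause (" and " clause)*
    clause  := key "=" value ("," value)*
    key     := species | resname | residue_name | role | peptide_id
               | name | element | residue_index

Comma-separated values are alternatives (OR); clauses are conjoined (AND).
Resolving a selection always yields a sorted, deterministic atom-id array.
"""

from __future__ import annotations

import numpy as np

from .core import ROLES, SPECIES, SelectionError, Topology

_KEYS = {
    "species",
    "resname",
    "residue_name",
    "role",
    "peptide_id",
    "name",
    "element",
    "residue_index",
}


def parse(expr: str) -> list:
    """Parse an expression into [(key, (values...)), ...]."""
    clauses = []
    for part in expr.split(" and "):
        part = part.strip()
        if not part:
            raise SelectionError(f"empty clause in selection {expr!r}")
        if "=" not in part:
            raise SelectionError(f"clause {part!r} lacks '=' (selection {expr!r})")
        key, _, val = part.partition("=")
        key = key.strip()
        if key not in _KEYS:
            raise SelectionError(
                f"unknown selection key {key!r}; known: {', '.join(sorted(_KEYS))}"
            )
        values = tuple(v.strip() for v in val.split(",") if v.strip())
        if not values:
            raise SelectionError(f"clause {part!r} lists no values")
        clauses.append((key, values))
    return clauses


def _clause_mask(topology: Topology, key: str, values) -> np.ndarray:
    if key == "species":
        for v in values:
            if v not in SPECIES:
                raise SelectionError(f"unknown species {v!r}")
        return np.isin(topology.species, values)
    if key in ("resname", "residue_name"):
        return np.isin(topology.residue_name, values)
    if key == "role":
        mask = np.zeros(len(topology), dtype=bool)
        for v in values:
            if v not in ROLES:
                raise SelectionError(f"unknown role {v!r}")
            mask |= topology.role_mask(v)
        return mask
    if key == "name":
        return np.isin(topology.name, values)
    if key == "element":
        return np.isin(topology.element, values)
    try:
        ints = [int(v) for v in values]
    except ValueError:
        raise SelectionError(f"{key} values must be integers: {values}") from None
    arr = topology.peptide_id if key == "peptide_id" else topology.residue_index
    return np.isin(arr, ints)


def resolve(topology: Topology, selection) -> np.ndarray:
    """Resolve a selection to a sorted array of atom ids.

    Accepts an expression string, an iterable of atom ids, or None (all
    atoms).  Resolution is idempotent and order-independent.
    """
    if selection is None:
        return np.arange(len(topology))
    if isinstance(selection, str):
        mask = np.ones(len(topology), dtype=bool)
        for key, values in parse(selection):
            mask &= _clause_mask(topology, key, values)
        return np.flatnonzero(mask)
    ids = np.unique(np.asarray(list(selection), dtype=int))
    if ids.size and (ids[0] < 0 or ids[-1] >= len(topology)):
        raise SelectionError("atom id out of range")
    return ids


def resolve_nonempty(topology: Topology, selection, what: str = "selection"):
    ids = resolve(topology, selection)
    if ids.size == 0:
        raise SelectionError(f"{what} {selection!r} selects no atoms")
    return ids
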