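"""Domain types shared by every analysis stage.

A :class:`System` couples a topology (immutable per-atom labels) with one
coordinate :class:`Frame`; a :class:`Trajectory` is an ordered list of frames
sharing one topology.  Coordinates are always in Å and kept unwrapped;
periodic wrapping is applied only inside distance computations (see
:mod:`cycshell.pbc`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np

SPECIES = ("peptide", "anion", "cation", "water")

ROLES = (
    "backbone",
    "sidechain",
    "donor_heavy",
    "acceptor_heavy",
    "hydrogen",
    "reference_atom",
)

#: Standard atomic masses (u) for the elements that occur in this domain.
ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "NA": 22.990,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
}


class CycshellError(Exception):
    """Base class for all package errors."""


class FormatError(CycshellError):
    """A structure/trajectory file does not parse under the named standard."""


class LabelingError(CycshellError):
    """A residue or element name is not covered by the mapping table."""


class SelectionError(CycshellError):
    """A selection expression is malformed or resolves to nothing."""


class TopologyError(CycshellError):
    """Topology violates an invariant (e.g. donor without hydrogens)."""


class DomainError(CycshellError):
    """An argument is outside the operation's domain."""


class BuildError(CycshellError):
    """Shell construction failed (e.g. inter-unit overlap)."""


class PackingError(CycshellError):
    """Random placement exhausted its attempt budget."""


class AnalysisError(CycshellError):
    """An analysis could not produce a well-defined result."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom with its species/role labels.

    ``peptide_id`` is ``-1`` for non-peptide species.  ``bonded_hydrogens``
    lists the atom ids of hydrogens covalently bonded to a donor heavy atom;
    hydrogens must be explicit in the input — none are ever inferred.
    """

    atom_id: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    peptide_id: int
    species: str
    roles: frozenset = field(default_factory=frozenset)
    bonded_hydrogens: tuple = ()

    def __post_init__(self):
        if self.species not in SPECIES:
            raise LabelingError(f"unknown species {self.species!r}")
        bad = set(self.roles) - set(ROLES)
        if bad:
            raise LabelingError(f"unknown roles {sorted(bad)}")
        if self.species == "peptide" and self.peptide_id < 0:
            raise TopologyError(
                f"peptide atom {self.atom_id} ({self.name}) has peptide_id < 0"
            )


class Topology:
    """Immutable list of :class:`AtomRecord` with cached label arrays."""

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms = tuple(atoms)
        for i, a in enumerate(self.atoms):
            if a.atom_id != i:
                raise TopologyError(
                    f"atom_id {a.atom_id} at position {i}: ids must be 0-based "
                    "and contiguous"
                )

    def __len__(self):
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def __getitem__(self, i):
        return self.atoms[i]

    @cached_property
    def name(self) -> np.ndarray:
        return np.array([a.name for a in self.atoms])

    @cached_property
    def element(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    @cached_property
    def residue_name(self) -> np.ndarray:
        return np.array([a.residue_name for a in self.atoms])

    @cached_property
    def residue_index(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms], dtype=int)

    @cached_property
    def peptide_id(self) -> np.ndarray:
        return np.array([a.peptide_id for a in self.atoms], dtype=int)

    @cached_property
    def species(self) -> np.ndarray:
        return np.array([a.species for a in self.atoms])

    @cached_property
    def masses(self) -> np.ndarray:
        try:
            return np.array([ATOMIC_MASS[a.element.upper()] for a in self.atoms])
        except KeyError as exc:  # pragma: no cover - guarded by mapping table
            raise LabelingError(f"no atomic mass for element {exc}") from exc

    def role_mask(self, role: str) -> np.ndarray:
        if role not in ROLES:
            raise SelectionError(f"unknown role {role!r}")
        return np.array([role in a.roles for a in self.atoms], dtype=bool)

    @cached_property
    def heavy_mask(self) -> np.ndarray:
        return self.element != "H"

    def validate(self) -> None:
        """Check the cross-atom invariants the analyses rely on."""
        for a in self.atoms:
            if "donor_heavy" in a.roles and not a.bonded_hydrogens:
                raise TopologyError(
                    f"donor heavy atom {a.atom_id} ({a.residue_name}/{a.name}) "
                    "lists no bonded hydrogen"
                )
            for h in a.bonded_hydrogens:
                if not (0 <= h < len(self.atoms)):
                    raise TopologyError(f"bonded hydrogen id {h} out of range")


@dataclass
class Frame:
    """One coordinate set (Å) plus the orthorhombic box edge lengths (Å)."""

    coordinates: np.ndarray
    box: np.ndarray

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise DomainError("coordinates must have shape (n_atoms, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise DomainError("box must be three positive edge lengths")


@dataclass
class System:
    """Topology + one frame."""

    topology: Topology
    frame: Frame

    def __post_init__(self):
        if len(self.topology) != len(self.frame.coordinates):
            raise TopologyError(
                f"coordinate count {len(self.frame.coordinates)} != atom "
                f"count {len(self.topology)}"
            )

    @property
    def coords(self) -> np.ndarray:
        return self.frame.coordinates

    @property
    def box(self) -> np.ndarray:
        return self.frame.box

    @property
    def n_atoms(self) -> int:
        return len(self.topology)


@dataclass
class Trajectory:
    """Ordered frames sharing one topology.

    ``frame_spacing`` is the time per frame in ns; it is metadata and may be
    unknown (``None``).
    """

    topology: Topology
    frames: list
    frame_spacing: float | None = None

    def __post_init__(self):
        if not self.frames:
            raise DomainError("a trajectory needs at least one frame")
        n = len(self.topology)
        for i, f in enumerate(self.frames):
            if len(f.coordinates) != n:
                raise TopologyError(f"frame {i} has {len(f.coordinates)} atoms, "
                                    f"topology has {n}")

    def __len__(self):
        return len(self.frames)

    def __getitem__(self, i) -> System:
        return System(self.topology, self.frames[i])

    def tail(self, n_frames: int) -> "Trajectory":
        """The final ``n_frames`` frames (for tail-averaged statistics)."""
        if n_frames < 1:
            raise DomainError("tail length must be >= 1")
        return Trajectory(self.topology, self.frames[-n_frames:],
                          self.frame_spacing)


def as_trajectory(obj) -> Trajectory:
    """Promote a System to a single-frame Trajectory; pass Trajectory through."""
    if isinstance(obj, Trajectory):
        return obj
    if isinstance(obj, System):
        return Trajectory(obj.topology, [obj.frame])
    raise DomainError(f"expected System or Trajectory, got {type(obj).__name__}")


def resolve_frame_range(traj: Trajectory, frame_range) -> range:
    """Normalize a frame_range argument (None, slice-like tuple, or range)."""
    n = len(traj)
    if frame_range is None:
        return range(n)
    if isinstance(frame_range, range):
        r = frame_range
    else:
        start, stop = frame_range
        if start < 0:
            start += n
        if stop is None:
            stop = n
        elif stop < 0:
            stop += n
        r = range(start, stop)
    if len(r) == 0 or r.start < 0 or r.stop > n:
        raise DomainError(f"frame range {r} empty or outside 0..{n}")
    return r
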