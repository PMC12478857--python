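"""Structure and trajectory I/O.

Two plain-text formats are supported:

* **PDB** — ``ATOM``/``HETATM`` records with ``CRYST1`` for the box and
  ``MODEL``/``ENDMDL`` for multi-frame trajectories.  ``TER`` records delimit
  peptides: every peptide written by this package ends with ``TER``, and on
  reading, consecutive peptide-species residues between ``TER`` records are
  grouped into one peptide.  Species and roles are inferred from residue
  names via the mapping table (:mod:`cycshell.residues`).
* **XYZ** — point clouds with a ``box Lx Ly Lz`` comment line; each symbol
  must name a single-atom residue in the mapping table (e.g. ``CL``, ``F``,
  ``SHP``).

Binary trajectory formats are out of scope; established readers (MDAnalysis,
mdtraj) can be used upstream to convert them to multi-model PDB.
"""

from __future__ import annotations

import os

import numpy as np

from .core import DomainError, FormatError, Frame, System, Trajectory
from .residues import label_atoms, load_table, residue_spec

# ---------------------------------------------------------------------------
# PDB


def _parse_pdb(path, table):
    raw_atoms = []      # first-model atom dicts
    frames_xyz = []     # list of coordinate lists
    box = None
    cur_xyz = None
    in_model = False
    model_count = 0
    res_key_prev = None
    residue_counter = -1
    ter_segment = 0
    seg_of_residue = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                try:
                    box = np.array([float(line[6:15]), float(line[15:24]),
                                    float(line[24:33])])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: bad CRYST1 record")
            elif rec == "MODEL ":
                in_model = True
                model_count += 1
                cur_xyz = []
            elif rec == "ENDMDL":
                in_model = False
                frames_xyz.append(cur_xyz)
                cur_xyz = None
            elif rec in ("ATOM  ", "HETATM"):
                try:
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: unparsable coordinates in "
                        f"{rec.strip()} record"
                    )
                if cur_xyz is None:
                    cur_xyz = []
                cur_xyz.append((x, y, z))
                if model_count <= 1:
                    name = line[12:16].strip()
                    resname = line[17:21].strip()
                    resseq = line[22:26].strip()
                    icode = line[26:27]
                    chain = line[21:22]
                    if not name or not resname:
                        raise FormatError(
                            f"{path}:{lineno}: missing atom/residue name"
                        )
                    key = (chain, resseq, resname, icode)
                    if key != res_key_prev:
                        residue_counter += 1
                        res_key_prev = key
                        seg_of_residue[residue_counter] = ter_segment
                    raw_atoms.append(
                        {"name": name, "residue_name": resname,
                         "residue_index": residue_counter}
                    )
            elif rec == "TER   " or line.strip() == "TER":
                ter_segment += 1
                res_key_prev = None
    if cur_xyz is not None and not in_model:
        frames_xyz.append(cur_xyz)
    if not frames_xyz and cur_xyz:
        frames_xyz.append(cur_xyz)
    if not raw_atoms:
        raise FormatError(f"{path}: no ATOM/HETATM records found")

    # peptide_id: dense rank of the TER segment among segments that contain
    # peptide-species residues
    pep_segments = []
    for ra in raw_atoms:
        seg = seg_of_residue[ra["residue_index"]]
        species = residue_spec(ra["residue_name"], table).species
        if species == "peptide" and seg not in pep_segments:
            pep_segments.append(seg)
    seg_rank = {seg: i for i, seg in enumerate(pep_segments)}
    for ra in raw_atoms:
        seg = seg_of_residue[ra["residue_index"]]
        ra["peptide_id"] = seg_rank.get(seg, -1)
    return raw_atoms, frames_xyz, box


def load_trajectory(path, format=None, box=None, table=None,
                    frame_spacing=None) -> Trajectory:
    """Read a (possibly multi-model) structure file into a Trajectory."""
    fmt = format or _infer_format(path)
    table = table or load_table()
    if fmt == "pdb":
        raw_atoms, frames_xyz, file_box = _parse_pdb(path, table)
        the_box = file_box if file_box is not None else box
        if the_box is None:
            raise FormatError(
                f"{path}: no CRYST1 record; pass box lengths explicitly"
            )
        topo = label_atoms(raw_atoms, table)
        n = len(topo)
        frames = []
        for i, xyz in enumerate(frames_xyz):
            if len(xyz) != n:
                raise FormatError(
                    f"{path}: model {i + 1} has {len(xyz)} atoms, expected {n}"
                )
            frames.append(Frame(np.array(xyz), np.asarray(the_box, float)))
        return Trajectory(topo, frames, frame_spacing)
    if fmt == "xyz":
        return _load_xyz(path, box=box, table=table, frame_spacing=frame_spacing)
    raise DomainError(f"unknown format {fmt!r} (pdb or xyz)")


def load_structure(path, format=None, box=None, table=None) -> System:
    """Read a structure file; for multi-model files, the first frame."""
    traj = load_trajectory(path, format=format, box=box, table=table)
    return traj[0]


def write_structure(obj, path, format=None) -> None:
    """Write a System or Trajectory to PDB or XYZ (inferred from extension)."""
    fmt = format or _infer_format(path)
    if fmt == "pdb":
        _write_pdb(obj, path)
    elif fmt == "xyz":
        _write_xyz(obj, path)
    else:
        raise DomainError(f"unknown format {fmt!r} (pdb or xyz)")


def _infer_format(path) -> str:
    ext = os.path.splitext(str(path))[1].lower().lstrip(".")
    return {"pdb": "pdb", "xyz": "xyz"}.get(ext, ext)


def _pdb_atom_line(serial, atom, xyz):
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    elem = atom.element[:2].rjust(2)
    return (
        f"ATOM  {serial % 100000:5d} {name:<4s} {atom.residue_name:<4s}"
        f"{(atom.residue_index % 9999) + 1:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {elem}\n"
    )


def _write_pdb(obj, path):
    from .core import as_trajectory

    traj = as_trajectory(obj)
    topo = traj.topology
    box = traj.frames[0].box
    multi = len(traj.frames) > 1
    with open(path, "w") as fh:
        fh.write(
            f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
        )
        for imodel, frame in enumerate(traj.frames, start=1):
            if multi:
                fh.write(f"MODEL     {imodel:4d}\n")
            serial = 1
            prev_pid = None
            for atom, xyz in zip(topo, frame.coordinates):
                if (prev_pid is not None and prev_pid >= 0
                        and atom.peptide_id != prev_pid):
                    fh.write("TER\n")
                    serial += 1
                fh.write(_pdb_atom_line(serial, atom, xyz))
                serial += 1
                prev_pid = atom.peptide_id
            if prev_pid is not None and prev_pid >= 0:
                fh.write("TER\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# XYZ


def _load_xyz(path, box=None, table=None, frame_spacing=None) -> Trajectory:
    table = table or load_table()
    frames = []
    raw_atoms = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    lineno = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise FormatError(f"{path}:{i + 1}: expected atom count")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        frame_box = box
        parts = comment.split()
        if parts and parts[0].lower() == "box":
            try:
                frame_box = [float(v) for v in parts[1:4]]
            except (ValueError, IndexError):
                raise FormatError(f"{path}:{i + 2}: bad box comment record")
        if frame_box is None:
            raise FormatError(
                f"{path}:{i + 2}: no 'box Lx Ly Lz' comment; pass box lengths"
            )
        symbols, xyz = [], []
        for j in range(n):
            lineno = i + 2 + j
            try:
                tok = lines[lineno].split()
                symbols.append(tok[0])
                xyz.append([float(tok[1]), float(tok[2]), float(tok[3])])
            except (IndexError, ValueError):
                raise FormatError(f"{path}:{lineno + 1}: unparsable XYZ atom line")
        if raw_atoms is None:
            raw_atoms = []
            pid = 0
            for k, sym in enumerate(symbols):
                rspec = residue_spec(sym, table)
                if len(rspec.atoms) != 1:
                    raise FormatError(
                        f"{path}: XYZ symbol {sym!r} is not a single-atom "
                        "residue in the mapping table"
                    )
                aname = next(iter(rspec.atoms))
                raw_atoms.append(
                    {"name": aname, "residue_name": sym, "residue_index": k,
                     "peptide_id": pid if rspec.species == "peptide" else -1}
                )
                if rspec.species == "peptide":
                    pid += 1
        frames.append(Frame(np.array(xyz), np.asarray(frame_box, float)))
        i += 2 + n
    if raw_atoms is None:
        raise FormatError(f"{path}: empty XYZ file")
    topo = label_atoms(raw_atoms, table)
    return Trajectory(topo, frames, frame_spacing)


def _write_xyz(obj, path):
    from .core import as_trajectory

    traj = as_trajectory(obj)
    topo = traj.topology
    # symbol = residue name; valid only for single-atom residues on re-read
    res_sizes: dict[int, int] = {}
    for a in topo:
        res_sizes[a.residue_index] = res_sizes.get(a.residue_index, 0) + 1
    with open(path, "w") as fh:
        for frame in traj.frames:
            b = frame.box
            fh.write(f"{len(topo)}\n")
            fh.write(f"box {b[0]:.6f} {b[1]:.6f} {b[2]:.6f}\n")
            for a, xyz in zip(topo, frame.coordinates):
                sym = a.residue_name if res_sizes[a.residue_index] == 1 else a.name
                fh.write(f"{sym} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")
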