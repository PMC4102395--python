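"""PDB and multi-frame XYZ readers/writers.

Only the ATOM/HETATM/MODEL/ENDMDL records of the PDB format are
interpreted; author residue numbering and atom order are preserved
exactly, and write -> read is the identity on the fields used.
Coordinates round-trip at the format's 10^-3 Å precision.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .core import Atom, Structure, Trajectory, ValidationError


class PDBParseError(ValueError):
    """Malformed record; message carries the 1-based line number."""


def _parse_atom_line(line: str, lineno: int) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        res_name = line[17:21].strip()
        chain = line[21].strip() or "A"
        res_seq = int(line[22:26])
        pos = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from exc
    if not name:
        raise PDBParseError(f"line {lineno}: empty atom name")
    if not element:
        element = _guess_element(name)
    return Atom(serial, name, element, res_name, res_seq, chain, np.array(pos))


def _guess_element(name: str) -> str:
    stripped = name.strip()
    if stripped[:2].capitalize() in ("Fe", "Na", "Cl", "Mg", "Zn", "Ca"):
        return stripped[:2].capitalize()
    m = re.search(r"[A-Za-z]", stripped)
    return m.group(0).upper() if m else "X"


def read_pdb(path: str | Path) -> Structure:
    """Read the first (or only) model of a PDB file as a Structure."""
    models = _read_pdb_models(path)
    if not models:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    try:
        return Structure(models[0])
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def read_pdb_trajectory(path: str | Path, dt: float = 0.02) -> Trajectory:
    """Read a multi-model PDB as a Trajectory (frame spacing ``dt`` ns)."""
    models = _read_pdb_models(path)
    if not models:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    ref = Structure(models[0])
    n = len(ref)
    frames = []
    for k, atoms in enumerate(models):
        if len(atoms) != n:
            raise ValidationError(
                f"{path}: MODEL {k + 1} has {len(atoms)} atoms, expected {n}"
            )
        frames.append(np.array([a.pos for a in atoms]))
    return Trajectory(ref, np.stack(frames), dt=dt)


def _read_pdb_models(path: str | Path) -> list[list[Atom]]:
    models: list[list[Atom]] = []
    current: list[Atom] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if current:
                    models.append(current)
                current = []
                in_model = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                current.append(_parse_atom_line(line.rstrip("\n"), lineno))
    if current or not models:
        if current:
            models.append(current)
    return models


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure as single-model PDB (ATOM records, %8.3f coords)."""
    with open(path, "w") as fh:
        _write_model(fh, structure.atoms, structure.coords)
        fh.write("END\n")


def write_pdb_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as a multi-model PDB."""
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"MODEL {k + 1:8d}\n")
            _write_model(fh, traj.reference.atoms, traj.frames[k])
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _write_model(fh, atoms, coords, bfactors=None) -> None:
    for i, atom in enumerate(atoms):
        x, y, z = coords[i]
        name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
        b = 0.0 if bfactors is None else bfactors[i]
        fh.write(
            f"ATOM  {atom.serial:5d} {name}{'':1s}{atom.res_name:<4s}"
            f"{atom.chain:1s}{atom.res_seq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}"
            f"          {atom.element:>2s}\n"
        )


def write_pdb_flags(structure: Structure, flags, path: str | Path) -> None:
    """Write a PDB with per-atom integer flags in the B-factor column
    (2 = QM, 1 = mobile, 0 = fixed)."""
    with open(path, "w") as fh:
        _write_model(fh, structure.atoms, structure.coords, bfactors=list(flags))
        fh.write("END\n")


# ---------------------------------------------------------------------------
# multi-frame XYZ: comment line carries "t=<ns>"
# ---------------------------------------------------------------------------

_TIME_RE = re.compile(r"t\s*=\s*([-+0-9.eE]+)")


def read_xyz_trajectory(path: str | Path, reference: Structure) -> Trajectory:
    """Read a multi-frame XYZ file against a reference Structure.

    Each frame: atom count, a comment line with ``t=<ns>``, then
    ``element x y z`` lines in reference atom order.
    """
    frames: list[np.ndarray] = []
    times: list[float] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    lineno = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise PDBParseError(f"line {i + 1}: expected atom count: {exc}") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        m = _TIME_RE.search(comment)
        times.append(float(m.group(1)) if m else len(times) * 0.02)
        coords = np.empty((n, 3))
        for k in range(n):
            lineno = i + 2 + k
            try:
                parts = lines[lineno].split()
                coords[k] = [float(v) for v in parts[1:4]]
            except (IndexError, ValueError) as exc:
                raise PDBParseError(f"line {lineno + 1}: malformed XYZ row: {exc}") from exc
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise PDBParseError(f"{path}: no XYZ frames found")
    if frames[0].shape[0] != len(reference):
        raise ValidationError(
            f"{path}: {frames[0].shape[0]} atoms per frame, reference has {len(reference)}"
        )
    return Trajectory(reference, np.stack(frames), np.array(times))


def write_xyz_trajectory(traj: Trajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"t={traj.times[k]:.6f}\n")
            for a, (x, y, z) in zip(traj.reference.atoms, traj.frames[k]):
                fh.write(f"{a.element:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")
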