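"""Structure/trajectory data model and geometry primitives.

All coordinates are in angstroms (Å), residue numbering is the author
(PDB) numbering, and residue ranges are inclusive on both ends.
Trajectory times are in nanoseconds.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import ATOMIC_MASSES

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


class GeometryError(ValueError):
    """Degenerate geometry (collinear points, empty selection, ...)."""


class ValidationError(ValueError):
    """Structure-level consistency violation."""


@dataclasses.dataclass(frozen=True)
class Atom:
    """One atom with PDB-style identity and a position in Å."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain: str
    pos: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.pos, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValidationError(
                f"atom {self.serial} {self.name}: position must be a finite 3-vector"
            )
        object.__setattr__(self, "pos", pos)

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_NAMES

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.res_seq, self.name)


class Structure:
    """An ordered list of atoms plus a (chain, res_seq) -> atom-index map.

    Atom order is stable: it is the order atoms were supplied in, and it
    survives a write -> read round trip through the PDB writer.
    """

    def __init__(self, atoms: Iterable[Atom], validate: bool = True):
        self.atoms: list[Atom] = list(atoms)
        self._residue_index: dict[tuple[str, int], list[int]] = {}
        seen: set[tuple[str, int, str]] = set()
        for i, atom in enumerate(self.atoms):
            if validate:
                if atom.key in seen:
                    raise ValidationError(
                        f"duplicate atom (chain={atom.chain!r}, res_seq={atom.res_seq},"
                        f" name={atom.name!r})"
                    )
                seen.add(atom.key)
            self._residue_index.setdefault((atom.chain, atom.res_seq), []).append(i)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) array of positions in Å."""
        return np.array([a.pos for a in self.atoms], dtype=float)

    def residue_atoms(self, chain: str, res_seq: int) -> list[int]:
        """Atom indices of one residue, in atom order."""
        return list(self._residue_index.get((chain, res_seq), []))

    def residues(self) -> list[tuple[str, int]]:
        """All (chain, res_seq) keys in first-appearance order."""
        return list(self._residue_index)

    def find_atom(self, chain: str, res_seq: int, name: str) -> int | None:
        for i in self._residue_index.get((chain, res_seq), []):
            if self.atoms[i].name == name:
                return i
        return None

    def subset(self, indices: Sequence[int]) -> "Structure":
        return Structure([self.atoms[i] for i in indices])

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValidationError("coordinate array shape mismatch")
        atoms = [dataclasses.replace(a, pos=c) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, validate=False)


@dataclasses.dataclass(frozen=True)
class Selection:
    """Declarative atom predicate.

    Any field left as None matches everything; ``res_range`` is an
    inclusive (lo, hi) pair in author numbering.
    """

    chain: str | None = None
    res_range: tuple[int, int] | None = None
    names: frozenset[str] | None = None
    backbone_only: bool = False

    def __post_init__(self):
        if self.names is not None:
            object.__setattr__(self, "names", frozenset(self.names))
        if self.res_range is not None and self.res_range[0] > self.res_range[1]:
            raise ValidationError(f"empty residue range {self.res_range}")

    def matches(self, atom: Atom) -> bool:
        if self.chain is not None and atom.chain != self.chain:
            return False
        if self.res_range is not None and not (
            self.res_range[0] <= atom.res_seq <= self.res_range[1]
        ):
            return False
        if self.names is not None and atom.name not in self.names:
            return False
        if self.backbone_only and not atom.is_backbone:
            return False
        return True

    def resolve(self, structure: Structure) -> np.ndarray:
        """Matching atom indices in structure order (deterministic)."""
        idx = [i for i, a in enumerate(structure.atoms) if self.matches(a)]
        return np.array(idx, dtype=int)


def resolve_selection(
    structure: Structure, selection: Selection | Sequence[int] | None
) -> np.ndarray:
    """Normalise a Selection / index list / None (= all atoms) to indices."""
    if selection is None:
        return np.arange(len(structure))
    if isinstance(selection, Selection):
        return selection.resolve(structure)
    return np.asarray(selection, dtype=int)


class Trajectory:
    """Frames congruent with a reference Structure; times in ns."""

    def __init__(
        self,
        reference: Structure,
        frames: np.ndarray,
        times: Sequence[float] | None = None,
        dt: float = 0.02,
    ):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[1] != len(reference) or frames.shape[2] != 3:
            raise ValidationError(
                f"frames must be (n_frames, {len(reference)}, 3); got {frames.shape}"
            )
        if times is None:
            times = np.arange(frames.shape[0]) * dt
        times = np.asarray(times, dtype=float)
        if len(times) != frames.shape[0]:
            raise ValidationError("len(times) != number of frames")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValidationError("times must be strictly increasing")
        self.reference = reference
        self.frames = frames
        self.times = times

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def frame_structure(self, i: int) -> Structure:
        return self.reference.with_coords(self.frames[i])

    def slice_time(self, t_min: float, t_max: float = np.inf) -> "Trajectory":
        """Frames with t_min <= t <= t_max (both ns, inclusive)."""
        mask = (self.times >= t_min) & (self.times <= t_max)
        if not mask.any():
            raise ValidationError(f"no frames in time window [{t_min}, {t_max}] ns")
        return Trajectory(self.reference, self.frames[mask], self.times[mask])

    @classmethod
    def from_structures(
        cls, structures: Sequence[Structure], times: Sequence[float] | None = None,
        dt: float = 0.02,
    ) -> "Trajectory":
        ref = structures[0]
        frames = np.stack([s.coords for s in structures])
        return cls(ref, frames, times, dt=dt)


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def atom_masses(structure: Structure, indices: np.ndarray) -> np.ndarray:
    masses = []
    for i in indices:
        el = structure.atoms[i].element.capitalize()
        m = ATOMIC_MASSES.get(el, 0.0)
        masses.append(m)
    return np.array(masses, dtype=float)


def center_of_mass(
    structure: Structure,
    selection: Selection | Sequence[int] | None = None,
    mass_weighted: bool = False,
    coords: np.ndarray | None = None,
) -> np.ndarray:
    """Centroid (or mass-weighted centre) of a selection, in Å.

    ``coords`` optionally overrides the structure's own coordinates
    (e.g. one trajectory frame).
    """
    idx = resolve_selection(structure, selection)
    if idx.size == 0:
        raise GeometryError("center_of_mass: empty selection")
    xyz = (structure.coords if coords is None else np.asarray(coords, float))[idx]
    if not mass_weighted:
        return xyz.mean(axis=0)
    w = atom_masses(structure, idx)
    if np.any(w <= 0):
        bad = structure.atoms[idx[int(np.argmin(w))]]
        raise GeometryError(
            f"center_of_mass: unknown mass for element {bad.element!r} "
            f"(atom {bad.serial}); use mass_weighted=False"
        )
    return (xyz * w[:, None]).sum(axis=0) / w.sum()


def dihedral(p1, p2, p3, p4, collinear_tol: float = 1e-8) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, in (-180, 180].

    IUPAC sign convention: looking down p2 -> p3, a clockwise rotation of
    p4 relative to p1 is positive.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if np.linalg.norm(n1) < collinear_tol or np.linalg.norm(n2) < collinear_tol or b2n < collinear_tol:
        raise GeometryError("dihedral: three consecutive points are collinear")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / b2n)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:  # map -180 to +180 so the range is (-180, 180]
        ang += 360.0
    return float(ang)


def angle_between(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle between two vectors, degrees in [0, 180]."""
    v1 = np.asarray(v1, float)
    v2 = np.asarray(v2, float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise GeometryError("angle_between: zero-length vector")
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid-body fit of ``mobile`` onto ``target``.

    Returns (rotation matrix R, translation t, fitted coordinates) such
    that ``fitted = (mobile - mobile_centroid) @ R.T + target_centroid``.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - ct, mobile - cm)
    R = rot.as_matrix()
    fitted = (mobile - cm) @ R.T + ct
    t = ct - cm @ R.T
    return R, t, fitted


def _fit_frames(traj: Trajectory, fit_idx: np.ndarray, ref_coords: np.ndarray) -> np.ndarray:
    """Superpose every frame onto ref_coords using the fit selection."""
    out = np.empty_like(traj.frames)
    for f in range(traj.n_frames):
        R, t, _ = superpose(traj.frames[f][fit_idx], ref_coords)
        out[f] = traj.frames[f] @ R.T + t
    return out


def rmsd(
    traj: Trajectory,
    selection: Selection | Sequence[int] | None = None,
    reference: str | int = "average",
    fit_selection: Selection | Sequence[int] | None = None,
    mass_weighted: bool = False,
) -> np.ndarray:
    """Per-frame RMSD (Å) after rigid-body superposition.

    ``reference`` is either a frame index or "average": deviations from
    the mean coordinates of the superposed ensemble, the convention used
    for stability analyses of MD runs.
    """
    sel = resolve_selection(traj.reference, selection)
    if sel.size == 0:
        raise GeometryError("rmsd: empty selection")
    fit = resolve_selection(traj.reference, fit_selection) if fit_selection is not None else sel

    if isinstance(reference, int):
        ref = traj.frames[reference][fit]
        fitted = _fit_frames(traj, fit, ref)
        ref_sel = fitted[reference][sel]
    else:
        # two-pass: fit to frame 0, take the mean, refit to the mean
        fitted = _fit_frames(traj, fit, traj.frames[0][fit])
        mean = fitted.mean(axis=0)
        fitted = _fit_frames(Trajectory(traj.reference, fitted, traj.times), fit, mean[fit])
        ref_sel = fitted.mean(axis=0)[sel]

    if mass_weighted:
        w = atom_masses(traj.reference, sel)
        w = w / w.sum()
    else:
        w = np.full(sel.size, 1.0 / sel.size)
    d2 = ((fitted[:, sel, :] - ref_sel) ** 2).sum(axis=2)
    return np.sqrt((d2 * w).sum(axis=1))


def rmsf(
    traj: Trajectory,
    selection: Selection | Sequence[int] | None = None,
    fit_selection: Selection | Sequence[int] | None = None,
) -> np.ndarray:
    """Per-atom RMS fluctuation (Å) about the mean superposed coordinates."""
    sel = resolve_selection(traj.reference, selection)
    if sel.size == 0:
        raise GeometryError("rmsf: empty selection")
    fit = resolve_selection(traj.reference, fit_selection) if fit_selection is not None else sel
    fitted = _fit_frames(traj, fit, traj.frames[0][fit])
    mean = fitted.mean(axis=0)
    fitted = _fit_frames(Trajectory(traj.reference, fitted, traj.times), fit, mean[fit])
    mean_sel = fitted[:, sel, :].mean(axis=0)
    d2 = ((fitted[:, sel, :] - mean_sel) ** 2).sum(axis=2)
    return np.sqrt(d2.mean(axis=0))


def pair_distance(
    traj: Trajectory,
    sel_a: Selection | Sequence[int],
    sel_b: Selection | Sequence[int],
    mode: str = "com",
    mass_weighted: bool = False,
) -> np.ndarray:
    """Per-frame distance (Å) between two selections.

    mode="com": COM-COM distance; mode="min": minimum interatomic distance.
    """
    ia = resolve_selection(traj.reference, sel_a)
    ib = resolve_selection(traj.reference, sel_b)
    if ia.size == 0 or ib.size == 0:
        raise GeometryError("pair_distance: empty selection")
    if mode == "com":
        out = np.empty(traj.n_frames)
        for f in range(traj.n_frames):
            ca = center_of_mass(traj.reference, ia, mass_weighted, coords=traj.frames[f])
            cb = center_of_mass(traj.reference, ib, mass_weighted, coords=traj.frames[f])
            out[f] = np.linalg.norm(ca - cb)
        return out
    if mode == "min":
        out = np.empty(traj.n_frames)
        for f in range(traj.n_frames):
            diff = traj.frames[f][ia][:, None, :] - traj.frames[f][ib][None, :, :]
            out[f] = np.sqrt((diff ** 2).sum(axis=2)).min()
        return out
    raise ValueError(f"pair_distance: unknown mode {mode!r}")
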