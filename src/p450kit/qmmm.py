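"""Deterministic bookkeeping for QM/MM system preparation.

Covers the four preparation steps that precede any electronic-structure
work: truncating distant solvent (and the membrane), selecting the QM
region around Compound I (bare iron-oxo porphine plus the proximal
cysteine modelled as SCH2, plus the substrate), placing hydrogen link
atoms on every severed covalent bond, and partitioning the MM atoms
into mobile and fixed sets by proximity to the reactive centre.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .constants import (
    FERRYL_O_NAMES,
    HEME_RESNAMES,
    HEME_SUBSTITUENT_BONDS,
    ION_RESNAMES,
    LIPID_RESNAMES,
    PORPHINE_RING_ATOMS,
    WATER_RESNAMES,
)
from .core import GeometryError, Structure, ValidationError

LINK_ATOM_DISTANCE = 1.09  # Å, standard C-H bond length


@dataclasses.dataclass(frozen=True)
class LinkAtom:
    qm_index: int  # boundary atom kept in the QM region
    mm_index: int  # first atom on the MM side of the severed bond
    position: np.ndarray  # Å, on the qm -> mm bond vector


@dataclasses.dataclass
class QMRegionSpec:
    qm_indices: list[int]
    link_atoms: list[LinkAtom]
    qm_charge: int
    spin_multiplicity: int  # quartet Compound I = 4

    @property
    def n_qm(self) -> int:
        return len(self.qm_indices)


@dataclasses.dataclass
class MobilityMask:
    mobile: np.ndarray  # per-atom booleans; every atom is mobile xor fixed

    @property
    def n_mobile(self) -> int:
        return int(self.mobile.sum())


@dataclasses.dataclass(frozen=True)
class RestraintSpec:
    atom_a: str
    atom_b: str
    target: float  # Å
    force_constant: float  # kcal mol^-1 Å^-2
    context: str  # "md_prep" | "qmmm_scan"

    def __post_init__(self):
        if self.force_constant <= 0:
            raise ValidationError("restraint force constant must be positive")


def md_prep_restraint(
    atom_a: str = "O1", atom_b: str = "H5", target: float = 1.2,
    force_constant: float = 100.0,
) -> RestraintSpec:
    """Near-transition-state restraint used to prepare MD starting structures."""
    return RestraintSpec(atom_a, atom_b, target, force_constant, "md_prep")


def _residue_class(res_name: str, water, ions, lipids) -> str:
    rn = res_name.upper()
    if rn in water:
        return "water"
    if rn in ions:
        return "ion"
    if rn in lipids:
        return "lipid"
    return "core"


def truncate_solvent(
    structure: Structure,
    cutoff: float = 5.0,
    remove_membrane: bool = False,
    water_resnames=WATER_RESNAMES,
    ion_resnames=ION_RESNAMES,
    lipid_resnames=LIPID_RESNAMES,
) -> Structure:
    """Drop waters/ions farther than ``cutoff`` Å from any core atom.

    Core atoms (protein, heme, substrate — anything not named as water,
    ion or lipid) are never removed. Lipid residues are all dropped when
    ``remove_membrane`` is set. A water or ion residue survives iff any
    of its atoms lies within ``cutoff`` of any core atom. Idempotent.
    """
    classes = [
        _residue_class(a.res_name, water_resnames, ion_resnames, lipid_resnames)
        for a in structure.atoms
    ]
    core = [i for i, c in enumerate(classes) if c == "core"]
    if not core:
        raise GeometryError("truncate_solvent: no protein atoms found")
    tree = cKDTree(structure.coords[core])

    keep: list[int] = []
    for chain, res_seq in structure.residues():
        atoms = structure.residue_atoms(chain, res_seq)
        cls = classes[atoms[0]]
        if cls == "core":
            keep.extend(atoms)
        elif cls == "lipid":
            if not remove_membrane:
                keep.extend(atoms)
        else:  # water / ion: keep iff near the core
            d, _ = tree.query(structure.coords[atoms], k=1)
            if np.min(d) <= cutoff:
                keep.extend(atoms)
    keep.sort()
    return structure.subset(keep)


def _find_heme(structure: Structure, heme_resnames) -> tuple[str, int]:
    for chain, res_seq in structure.residues():
        atoms = structure.residue_atoms(chain, res_seq)
        if structure.atoms[atoms[0]].res_name.upper() in heme_resnames:
            return chain, res_seq
    raise GeometryError("no heme residue found")


def _find_proximal_cys(structure: Structure, fe_pos: np.ndarray) -> tuple[str, int]:
    best = None
    best_d = np.inf
    for chain, res_seq in structure.residues():
        atoms = structure.residue_atoms(chain, res_seq)
        if structure.atoms[atoms[0]].res_name.upper() != "CYS":
            continue
        sg = structure.find_atom(chain, res_seq, "SG")
        if sg is None:
            continue
        d = float(np.linalg.norm(structure.atoms[sg].pos - fe_pos))
        if d < best_d:
            best, best_d = (chain, res_seq), d
    if best is None:
        raise GeometryError("no cysteine with an SG atom found (proximal ligand missing)")
    return best


def select_qm_region(
    structure: Structure,
    include_substrate: bool = True,
    substrate_resnames: Sequence[str] = ("WAR", "SUB", "LIG"),
    qm_charge: int = 0,
    spin_multiplicity: int = 4,
    heme_resnames=HEME_RESNAMES,
    link_distance: float = LINK_ATOM_DISTANCE,
) -> QMRegionSpec:
    """Select the Compound-I QM region and generate its link atoms.

    QM atoms: Fe, the ferryl oxygen, the 24-atom porphine ring (heme
    substituents excluded), the proximal cysteine as SCH2 (Sγ, Cβ and
    Cβ hydrogens) and, when requested, every substrate atom. A hydrogen
    link atom is placed ``link_distance`` Å along each severed bond:
    the 8 ring-substituent bonds and the cysteine Cβ-Cα bond.
    """
    heme_chain, heme_seq = _find_heme(structure, heme_resnames)
    fe = structure.find_atom(heme_chain, heme_seq, "FE")
    if fe is None:
        raise GeometryError("heme residue has no FE atom")
    ferryl = None
    for name in FERRYL_O_NAMES:
        ferryl = structure.find_atom(heme_chain, heme_seq, name)
        if ferryl is not None:
            break
    if ferryl is None:
        raise GeometryError("Cpd I not present: ferryl oxygen missing from the heme")

    qm: list[int] = [fe, ferryl]
    for name in PORPHINE_RING_ATOMS:
        i = structure.find_atom(heme_chain, heme_seq, name)
        if i is None:
            raise GeometryError(f"porphine ring atom {name} missing from the heme")
        qm.append(i)

    links: list[LinkAtom] = []
    for ring_name, sub_name in HEME_SUBSTITUENT_BONDS:
        ri = structure.find_atom(heme_chain, heme_seq, ring_name)
        si = structure.find_atom(heme_chain, heme_seq, sub_name)
        if si is None:
            continue  # fixture without this substituent: nothing severed
        links.append(_place_link(structure, ri, si, link_distance))

    cys_chain, cys_seq = _find_proximal_cys(
        structure, structure.atoms[fe].pos
    )
    sg = structure.find_atom(cys_chain, cys_seq, "SG")
    cb = structure.find_atom(cys_chain, cys_seq, "CB")
    if cb is None:
        raise GeometryError("proximal cysteine has no CB atom")
    qm.extend([sg, cb])
    for i in structure.residue_atoms(cys_chain, cys_seq):
        a = structure.atoms[i]
        if a.element == "H" and a.name.startswith("HB"):
            qm.append(i)
    ca = structure.find_atom(cys_chain, cys_seq, "CA")
    if ca is not None:
        links.append(_place_link(structure, cb, ca, link_distance))

    if include_substrate:
        for chain, res_seq in structure.residues():
            atoms = structure.residue_atoms(chain, res_seq)
            if structure.atoms[atoms[0]].res_name.upper() in {
                s.upper() for s in substrate_resnames
            }:
                qm.extend(atoms)

    qm = sorted(set(qm))
    mm_side = {ln.mm_index for ln in links}
    if mm_side & set(qm):
        raise ValidationError("QM region overlaps the MM side of a link bond")
    return QMRegionSpec(qm, links, qm_charge, spin_multiplicity)


def _place_link(structure: Structure, qm_i: int, mm_i: int, dist: float) -> LinkAtom:
    p_qm = structure.atoms[qm_i].pos
    p_mm = structure.atoms[mm_i].pos
    v = p_mm - p_qm
    n = np.linalg.norm(v)
    if n == 0:
        raise GeometryError("coincident atoms at a QM/MM boundary bond")
    return LinkAtom(qm_i, mm_i, p_qm + v * (dist / n))


def mobility_mask(
    structure: Structure,
    qm_spec: QMRegionSpec,
    cutoff: float = 5.0,
) -> MobilityMask:
    """Residue-granular mobile/fixed partition for QM/MM minimisation.

    A residue (waters count as single residues) is mobile iff any of its
    atoms lies within ``cutoff`` Å of any atom of Compound I or the
    substrate — i.e. of any QM atom.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    tree = cKDTree(structure.coords[qm_spec.qm_indices])
    mobile = np.zeros(len(structure), dtype=bool)
    for chain, res_seq in structure.residues():
        atoms = structure.residue_atoms(chain, res_seq)
        d, _ = tree.query(structure.coords[atoms], k=1)
        if np.min(d) <= cutoff:
            mobile[atoms] = True
    return MobilityMask(mobile)


def scan_restraints(
    start: float = 1.8,
    lo: float = 0.9,
    hi: float = 3.1,
    step: float = 0.1,
    force_constant: float = 1000.0,
    atom_a: str = "O1",
    atom_b: str = "H5",
) -> tuple[list[RestraintSpec], list[RestraintSpec]]:
    """Restraint targets for an adiabatic reaction-coordinate scan.

    The scan starts at ``start`` and proceeds in increments of ``step``
    up to ``hi`` and down to ``lo``; each leg begins at ``start``, so
    with the defaults the ascending leg has 14 targets (1.8 → 3.1), the
    descending leg 10 (1.8 → 0.9), and there are 23 distinct targets.
    Bounds that are not whole multiples of ``step`` away from ``start``
    are rejected rather than silently rounded.
    """
    if not (lo < start < hi):
        raise ValueError(f"need lo < start < hi; got {lo} < {start} < {hi}")
    if step <= 0:
        raise ValueError("step must be positive")
    n_up = (hi - start) / step
    n_dn = (start - lo) / step
    if abs(n_up - round(n_up)) > 1e-9 or abs(n_dn - round(n_dn)) > 1e-9:
        raise ValueError(
            f"bounds ({lo}, {hi}) are not commensurate with step {step} from {start}"
        )

    def spec(r: float) -> RestraintSpec:
        return RestraintSpec(atom_a, atom_b, round(r, 10), force_constant, "qmmm_scan")

    up = [spec(start + k * step) for k in range(int(round(n_up)) + 1)]
    down = [spec(start - k * step) for k in range(int(round(n_dn)) + 1)]
    return up, down


def write_qm_region(
    structure: Structure, qm_spec: QMRegionSpec, mask: MobilityMask, outdir: str | Path
) -> None:
    """Export serial lists, link-atom TSV and a flagged PDB (beta column:
    2 = QM, 1 = mobile, 0 = fixed)."""
    from .pdbio import write_pdb_flags

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "qm_atoms.txt", "w") as fh:
        for i in qm_spec.qm_indices:
            fh.write(f"{structure.atoms[i].serial}\n")
    with open(outdir / "link_atoms.tsv", "w") as fh:
        fh.write("qm_serial\tmm_serial\tx_A\ty_A\tz_A\n")
        for ln in qm_spec.link_atoms:
            x, y, z = ln.position
            fh.write(
                f"{structure.atoms[ln.qm_index].serial}\t"
                f"{structure.atoms[ln.mm_index].serial}\t"
                f"{x:.4f}\t{y:.4f}\t{z:.4f}\n"
            )
    flags = np.where(mask.mobile, 1, 0)
    flags[qm_spec.qm_indices] = 2
    write_pdb_flags(structure, flags, outdir / "system_flags.pdb")
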