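"""Elastic-network construction for coarse-grained protein models.

An elastic network places harmonic restraints between backbone particles
within a distance cutoff, preserving tertiary structure during CG
simulation. For a membrane protein whose transmembrane (TM) helix
placement relative to the globular domain is unknown, the cross-domain
restraints are selectively removed ("relaxed") so the two domains can
reorient while the bilayer self-assembles.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

from scipy.spatial import cKDTree

from .core import Selection, Structure, resolve_selection


@dataclasses.dataclass(frozen=True, order=True)
class ElasticBond:
    i: int  # atom index into the source structure, i < j
    j: int
    r0: float  # equilibrium length, Å (the build-time distance)
    k: float  # force constant, model units (pass-through)

    def __post_init__(self):
        if self.i >= self.j:
            raise ValueError("ElasticBond requires i < j")
        if self.r0 <= 0:
            raise ValueError("ElasticBond requires r0 > 0")


@dataclasses.dataclass
class ElasticNetwork:
    bonds: frozenset[ElasticBond]
    removed: frozenset[ElasticBond]
    cutoff: float
    structure: Structure

    def __post_init__(self):
        if self.bonds & self.removed:
            raise ValueError("a bond cannot be both active and removed")

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)


def build_network(
    structure: Structure,
    backbone_selection: Selection | None = None,
    cutoff: float = 7.0,
    k: float = 500.0,
    exclusion_window: int = 2,
) -> ElasticNetwork:
    """Bond every backbone-particle pair within ``cutoff`` Å.

    Pairs closer than ``exclusion_window`` in sequence on the same chain
    are skipped — those contacts are maintained by the bonded terms of
    the CG force field, not the elastic network.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if backbone_selection is None:
        backbone_selection = Selection(backbone_only=True, names=frozenset({"CA", "BB"}))
    idx = resolve_selection(structure, backbone_selection)
    coords = structure.coords[idx]
    bonds = set()
    if len(idx) >= 2:
        tree = cKDTree(coords)
        for a, b in tree.query_pairs(cutoff):
            i, j = int(idx[a]), int(idx[b])
            if i > j:
                i, j = j, i
            ai, aj = structure.atoms[i], structure.atoms[j]
            if ai.chain == aj.chain and abs(ai.res_seq - aj.res_seq) <= exclusion_window:
                continue
            r0 = float(((ai.pos - aj.pos) ** 2).sum() ** 0.5)
            if r0 <= 0:
                continue
            bonds.add(ElasticBond(i, j, r0, k))
    return ElasticNetwork(frozenset(bonds), frozenset(), cutoff, structure)


def relax_cross_domain(
    network: ElasticNetwork,
    tm_residues: tuple[int, int],
    globular_residues: tuple[int, int],
) -> ElasticNetwork:
    """Move every TM-globular cross bond from ``bonds`` to ``removed``.

    ``tm_residues`` and ``globular_residues`` are inclusive author-numbered
    ranges and must not overlap. Intra-domain bonds are untouched; the
    operation is idempotent and conserves |bonds| + |removed|.
    """
    t_lo, t_hi = tm_residues
    g_lo, g_hi = globular_residues
    if max(t_lo, g_lo) <= min(t_hi, g_hi):
        raise ValueError(
            f"TM range {tm_residues} overlaps globular range {globular_residues}"
        )

    def domain(res_seq: int) -> str | None:
        if t_lo <= res_seq <= t_hi:
            return "tm"
        if g_lo <= res_seq <= g_hi:
            return "glob"
        return None

    keep, removed = set(), set(network.removed)
    for bond in network.bonds:
        di = domain(network.structure.atoms[bond.i].res_seq)
        dj = domain(network.structure.atoms[bond.j].res_seq)
        if {di, dj} == {"tm", "glob"}:
            removed.add(bond)
        else:
            keep.add(bond)
    return ElasticNetwork(frozenset(keep), frozenset(removed), network.cutoff, network.structure)


def write_network_tsv(network: ElasticNetwork, path: str | Path) -> None:
    """TSV export: i, j (atom serials), r0 in Å, force constant."""
    with open(path, "w") as fh:
        fh.write("i_serial\tj_serial\tr0_A\tk\n")
        for b in sorted(network.bonds):
            si = network.structure.atoms[b.i].serial
            sj = network.structure.atoms[b.j].serial
            fh.write(f"{si}\t{sj}\t{b.r0:.4f}\t{b.k:g}\n")


def format_itp_bonds(network: ElasticNetwork) -> str:
    """ITP-like [ bonds ] block (nm lengths) for downstream CG engines."""
    lines = ["[ bonds ]", "; i  j  func  length_nm  k"]
    for b in sorted(network.bonds):
        si = network.structure.atoms[b.i].serial
        sj = network.structure.atoms[b.j].serial
        lines.append(f"{si:6d} {sj:6d}  1  {b.r0 / 10.0:.5f}  {b.k:g}")
    return "\n".join(lines) + "\n"
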