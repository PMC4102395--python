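"""Substrate-channel gating and active-site analyses.

Access channels in P450s are controlled by pairs of gating side chains
(mostly phenylalanines). A gate is open in a frame when the distance
between the centres of mass of the two gating side chains falls below a
threshold (7 Å by default). This module also classifies the heme
propionate conformation (distal "up" vs proximal "down"), measures the
propionate salt bridges, tracks the Arg212 side-chain orientation,
correlates substrate mobility with gate opening, and ranks docking
poses by probe-to-site distance.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .constants import (
    CYP3A4_GATES,
    CYP3A4_PROPIONATE_PARTNERS,
    GATE_OPEN_THRESHOLD,
    PROPIONATE_O_NAMES,
    SALT_BRIDGE_N_NAMES,
)
from .core import (
    GeometryError,
    Structure,
    Trajectory,
    ValidationError,
    dihedral,
)

_BACKBONE_AND_H = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclasses.dataclass(frozen=True)
class GateDefinition:
    """A named channel gate: two residues and an open/closed threshold."""

    name: str
    residue_a: tuple[str, int, str]  # (chain, res_seq, res_name)
    residue_b: tuple[str, int, str]
    open_threshold: float = GATE_OPEN_THRESHOLD

    def __post_init__(self):
        if self.residue_a[:2] == self.residue_b[:2]:
            raise ValidationError(f"gate {self.name}: residues must be distinct")
        if self.open_threshold <= 0:
            raise ValidationError(f"gate {self.name}: threshold must be positive")


def default_gates(chain: str = "A", threshold: float = GATE_OPEN_THRESHOLD) -> list[GateDefinition]:
    """The six CYP3A4 channel gates (2a, 2b, 2c, 2e, 3, S)."""
    return [
        GateDefinition(name, (chain, ra[0], ra[1]), (chain, rb[0], rb[1]), threshold)
        for name, (ra, rb) in CYP3A4_GATES.items()
    ]


@dataclasses.dataclass
class GateTrace:
    gate: GateDefinition
    times: np.ndarray  # ns
    d: np.ndarray  # Å, per frame

    @property
    def open_flags(self) -> np.ndarray:
        return self.d < self.gate.open_threshold

    @property
    def fraction_open(self) -> float:
        return float(self.open_flags.mean())


def sidechain_heavy_atoms(structure: Structure, chain: str, res_seq: int) -> list[int]:
    """Heavy side-chain atom indices (Cβ onward; backbone and H excluded)."""
    out = []
    for i in structure.residue_atoms(chain, res_seq):
        a = structure.atoms[i]
        if a.name in _BACKBONE_AND_H or a.element == "H":
            continue
        out.append(i)
    return out


def gate_trace(traj: Trajectory, gate: GateDefinition) -> GateTrace:
    """Per-frame side-chain COM separation and open/closed flags."""
    idx = {}
    for label, (chain, res_seq, res_name) in (
        ("a", gate.residue_a), ("b", gate.residue_b)
    ):
        if not traj.reference.residue_atoms(chain, res_seq):
            raise GeometryError(
                f"gate {gate.name}: residue {res_name}{res_seq} (chain {chain}) missing"
            )
        atoms = sidechain_heavy_atoms(traj.reference, chain, res_seq)
        if not atoms:
            raise GeometryError(
                f"gate {gate.name}: residue {res_name}{res_seq} has no side-chain "
                "heavy atoms (glycine cannot gate)"
            )
        idx[label] = np.array(atoms)
    d = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        ca = traj.frames[f][idx["a"]].mean(axis=0)
        cb = traj.frames[f][idx["b"]].mean(axis=0)
        d[f] = np.linalg.norm(ca - cb)
    return GateTrace(gate, traj.times.copy(), d)


def fraction_open_report(
    traces: dict[str, dict[str, Sequence[GateTrace]]]
) -> pd.DataFrame:
    """Percent-open per gate and per model, pooled over replicas.

    ``traces[model][gate_name]`` is a list of replica GateTraces; pooling
    concatenates their frames. The returned frame has one row per gate
    plus an "overall" row, columns are models, values are percentages.
    """
    if not traces:
        raise ValueError("fraction_open_report: no traces supplied")
    gate_names: list[str] = []
    for model in traces.values():
        for g in model:
            if g not in gate_names:
                gate_names.append(g)
    data: dict[str, dict[str, float]] = {}
    for model, by_gate in traces.items():
        col = {}
        pooled_all = []
        for g in gate_names:
            reps = by_gate.get(g, [])
            if not reps:
                col[g] = np.nan
                continue
            flags = np.concatenate([t.open_flags for t in reps])
            pooled_all.append(flags)
            col[g] = 100.0 * flags.mean()
        col["overall"] = (
            100.0 * np.concatenate(pooled_all).mean() if pooled_all else np.nan
        )
        data[model] = col
    return pd.DataFrame(data).reindex(gate_names + ["overall"])


@dataclasses.dataclass
class PropionateState:
    times: np.ndarray
    dihedrals: np.ndarray  # degrees, C3A-C2A-CAA-CBA
    states: list[str]  # "distal" (up) / "proximal" (down)


def propionate_states(
    traj: Trajectory,
    heme_chain: str,
    heme_res_seq: int,
    atom_names: tuple[str, str, str, str] = ("C3A", "C2A", "CAA", "CBA"),
) -> PropionateState:
    """Classify the propionate-A conformation frame by frame.

    The dihedral over the ring-to-chain bond separates the two faces of
    the porphyrin: positive (around +100°) puts the propionate on the
    distal side ("up"), negative (around −100°) on the proximal side
    ("down"). The boundary rule is dihedral >= 0 -> distal.
    """
    idx = []
    for name in atom_names:
        i = traj.reference.find_atom(heme_chain, heme_res_seq, name)
        if i is None:
            raise GeometryError(
                f"propionate_states: atom {name} missing from heme residue "
                f"{heme_res_seq} (chain {heme_chain})"
            )
        idx.append(i)
    dihedrals = np.array([
        dihedral(*(traj.frames[f][i] for i in idx)) for f in range(traj.n_frames)
    ])
    states = ["distal" if v >= 0 else "proximal" for v in dihedrals]
    return PropionateState(traj.times.copy(), dihedrals, states)


def salt_bridge_distances(
    traj: Trajectory,
    heme_chain: str,
    heme_res_seq: int,
    propionate: str = "A",
    partners: Sequence[tuple[int, str]] = CYP3A4_PROPIONATE_PARTNERS,
    partner_chain: str | None = None,
) -> dict[str, np.ndarray]:
    """Minimum propionate-O to partner side-chain-N distance per frame.

    Partners missing from the structure are omitted with a warning.
    """
    chain = partner_chain if partner_chain is not None else heme_chain
    o_names = PROPIONATE_O_NAMES[propionate]
    o_idx = [
        traj.reference.find_atom(heme_chain, heme_res_seq, n)
        for n in o_names
    ]
    o_idx = [i for i in o_idx if i is not None]
    if not o_idx:
        raise GeometryError(
            f"salt_bridge_distances: propionate {propionate} carboxylate oxygens "
            f"{o_names} not found on heme residue {heme_res_seq}"
        )
    out: dict[str, np.ndarray] = {}
    for res_seq, res_name in partners:
        label = f"{res_name}{res_seq}"
        n_names = SALT_BRIDGE_N_NAMES.get(res_name.upper(), ())
        n_idx = [traj.reference.find_atom(chain, res_seq, n) for n in n_names]
        n_idx = [i for i in n_idx if i is not None]
        if not n_idx:
            warnings.warn(f"salt bridge partner {label} missing; omitted", stacklevel=2)
            continue
        d = np.empty(traj.n_frames)
        for f in range(traj.n_frames):
            diff = traj.frames[f][o_idx][:, None, :] - traj.frames[f][n_idx][None, :, :]
            d[f] = np.sqrt((diff ** 2).sum(axis=2)).min()
        out[label] = d
    return out


def arg212_orientation(
    traj: Trajectory,
    site_center: np.ndarray | None = None,
    arg_chain: str = "A",
    arg_res_seq: int = 212,
    fe_index: int | None = None,
) -> list[str]:
    """Per-frame "in"/"out" label for the Arg212 side chain.

    The side chain points "in" when its guanidinium carbon CZ sits
    closer to the active-site centre (heme Fe by default) than its own
    Cα does — a geometric proxy for the two conformations seen in the
    crystal structures.
    """
    cz = traj.reference.find_atom(arg_chain, arg_res_seq, "CZ")
    ca = traj.reference.find_atom(arg_chain, arg_res_seq, "CA")
    if cz is None:
        raise GeometryError(f"arg212_orientation: CZ missing from Arg{arg_res_seq}")
    if ca is None:
        raise GeometryError(f"arg212_orientation: CA missing from Arg{arg_res_seq}")
    if site_center is None and fe_index is None:
        fe = [i for i, a in enumerate(traj.reference.atoms) if a.name == "FE"]
        if not fe:
            raise GeometryError("arg212_orientation: no FE atom and no site_center given")
        fe_index = fe[0]
    labels = []
    for f in range(traj.n_frames):
        centre = (
            traj.frames[f][fe_index] if site_center is None
            else np.asarray(site_center, float)
        )
        d_cz = np.linalg.norm(traj.frames[f][cz] - centre)
        d_ca = np.linalg.norm(traj.frames[f][ca] - centre)
        labels.append("in" if d_cz < d_ca else "out")
    return labels


@dataclasses.dataclass
class MobilityCorrelation:
    window: int  # frames per window
    variances: np.ndarray  # per-window variance of the O(ferryl)-substrate distance
    fraction_open: np.ndarray  # per-window gate occupancy
    rho: float | None  # Spearman rank correlation; None when undefined
    p_value: float | None


def mobility_vs_gate(
    traj: Trajectory,
    gate: GateDefinition,
    substrate_selection,
    ferryl_o_index: int,
    window: int = 50,
) -> MobilityCorrelation:
    """Correlate substrate mobility with gate opening over time windows.

    Substrate mobility in each non-overlapping window is the variance of
    the ferryl-O to substrate-COM distance; it is paired with the gate's
    fraction-open in the same window and summarised by a Spearman rank
    correlation. With fewer than two windows, or constant series, the
    correlation is undefined and reported as None.
    """
    if window < 10:
        raise ValueError("window must be >= 10 frames")
    if traj.n_frames < window:
        raise ValueError(
            f"trajectory ({traj.n_frames} frames) shorter than one window ({window})"
        )
    from .core import resolve_selection

    s_idx = resolve_selection(traj.reference, substrate_selection)
    if s_idx.size == 0:
        raise GeometryError("mobility_vs_gate: empty substrate selection")
    d = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        com = traj.frames[f][s_idx].mean(axis=0)
        d[f] = np.linalg.norm(traj.frames[f][ferryl_o_index] - com)
    flags = gate_trace(traj, gate).open_flags

    n_windows = traj.n_frames // window
    variances = np.array([
        d[w * window:(w + 1) * window].var() for w in range(n_windows)
    ])
    occupancy = np.array([
        flags[w * window:(w + 1) * window].mean() for w in range(n_windows)
    ])
    rho = p = None
    if n_windows >= 2 and np.ptp(variances) > 0 and np.ptp(occupancy) > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r, pv = spearmanr(variances, occupancy)
        if np.isfinite(r):
            rho, p = float(r), float(pv)
    return MobilityCorrelation(window, variances, occupancy, rho, p)


def rank_poses_by_site_distance(
    poses: Sequence[Structure],
    probe_atom: tuple[str, int, str],
    site_atom: tuple[str, int, str],
) -> list[int]:
    """Order docking poses by probe-to-site distance, ascending.

    Mirrors selecting the pose whose reactive carbon sits closest to the
    heme iron. Returns 1-based pose indices; ties keep input order.
    """
    dists = []
    for k, pose in enumerate(poses):
        pi = pose.find_atom(*probe_atom)
        si = pose.find_atom(*site_atom)
        if pi is None or si is None:
            which = "probe" if pi is None else "site"
            raise GeometryError(f"pose {k + 1}: {which} atom missing")
        dists.append(float(np.linalg.norm(pose.atoms[pi].pos - pose.atoms[si].pos)))
    order = sorted(range(len(poses)), key=lambda k: (dists[k], k))
    return [k + 1 for k in order]


def write_gate_tsv(trace: GateTrace, path) -> None:
    """TSV export: time_ns, d_A, open (0/1)."""
    with open(path, "w") as fh:
        fh.write("time_ns\td_A\topen\n")
        for t, d, o in zip(trace.times, trace.d, trace.open_flags):
            fh.write(f"{t:.4f}\t{d:.4f}\t{int(o)}\n")
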