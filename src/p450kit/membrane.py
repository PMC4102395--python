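"""Bilayer shape and protein-orientation analyses.

The bilayer surface is described by the lipid phosphate positions; its
deformation around the protein is mapped on a 2-D grid in a
protein-fixed frame. Protein orientation in the membrane is quantified
by two helix-axis vectors (v_c across helices C and F, v_i along helix
I) against the membrane normal, by the tilt of the heme plane, and by
the insertion depth of anchoring segments below the phosphate plane.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .core import (
    GeometryError,
    Selection,
    Structure,
    Trajectory,
    angle_between,
    center_of_mass,
    resolve_selection,
    superpose,
)

# Cα ranges defining the orientation vectors for CYP3A4:
# v_c joins one helical turn in helix C to one in helix F;
# v_i joins the first and last turns of helix I.
VC_RANGES = ((137, 141), (207, 211))
VI_RANGES = ((292, 296), (321, 325))


@dataclasses.dataclass
class DeformationSurface:
    """Per-leaflet gridded mean phosphate height in a protein-fixed frame."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    mean_z: dict[str, np.ndarray]  # leaflet -> (nx, ny) grid, NaN where empty
    counts: dict[str, np.ndarray]
    grid_spacing: float

    def occupied(self, leaflet: str) -> np.ndarray:
        return self.counts[leaflet] > 0


@dataclasses.dataclass(frozen=True)
class OrientationVectors:
    v_c: np.ndarray
    v_i: np.ndarray
    alpha: float  # angle(normal, v_c), degrees
    beta: float  # angle(normal, v_i), degrees


def _unit_normal(normal) -> np.ndarray:
    n = np.asarray(normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise GeometryError("membrane normal must be non-zero")
    return n / norm


def fit_membrane_normal(phosphate_coords: np.ndarray) -> np.ndarray:
    """Normal as the smallest principal axis of phosphate covariance.

    Useful for tilted boxes; the default convention elsewhere is the
    simulation-frame z axis.
    """
    xyz = np.asarray(phosphate_coords, float)
    if xyz.shape[0] < 3:
        raise GeometryError("need >= 3 phosphate positions to fit a normal")
    centred = xyz - xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    n = vt[-1]
    return n if n[2] >= 0 else -n


def deformation_surface(
    traj: Trajectory,
    phosphate_selection: Selection | Sequence[int],
    protein_selection: Selection | Sequence[int] | None = None,
    grid_spacing: float = 2.0,
    split_leaflets: bool = True,
) -> DeformationSurface:
    """Grid the mean phosphate Z around the protein, per leaflet.

    Each frame is first superposed onto frame 0 via the protein
    selection (default: Cα atoms), so the surface is accumulated in a
    protein-fixed frame and is invariant under rigid-body motion of the
    whole system. Leaflets are split by the sign of z relative to the
    per-frame phosphate midplane (``split_leaflets=False`` keeps every
    phosphate in the "upper" surface — for single-sheet inputs). Cells
    never visited carry NaN and a zero count — they are reported
    missing, not interpolated.
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    p_idx = resolve_selection(traj.reference, phosphate_selection)
    if p_idx.size == 0:
        raise GeometryError("deformation_surface: no phosphate atoms matched")
    if protein_selection is None:
        protein_selection = Selection(names=frozenset({"CA", "BB"}))
    c_idx = resolve_selection(traj.reference, protein_selection)
    if c_idx.size == 0:
        raise GeometryError("deformation_surface: empty protein selection")

    ref = traj.frames[0][c_idx]
    all_xy = []
    all_z = []
    all_leaflet = []
    for f in range(traj.n_frames):
        R, t, _ = superpose(traj.frames[f][c_idx], ref)
        phos = traj.frames[f][p_idx] @ R.T + t
        all_xy.append(phos[:, :2])
        all_z.append(phos[:, 2])
        if split_leaflets:
            all_leaflet.append(phos[:, 2] >= phos[:, 2].mean())
        else:
            all_leaflet.append(np.ones(len(phos), dtype=bool))
    xy = np.concatenate(all_xy)
    z = np.concatenate(all_z)
    upper = np.concatenate(all_leaflet)

    pad = grid_spacing  # half-open binning; pad so extremes land inside
    x_edges = np.arange(xy[:, 0].min() - pad, xy[:, 0].max() + 2 * pad, grid_spacing)
    y_edges = np.arange(xy[:, 1].min() - pad, xy[:, 1].max() + 2 * pad, grid_spacing)
    shape = (len(x_edges) - 1, len(y_edges) - 1)

    mean_z, counts = {}, {}
    for leaflet, mask in (("upper", upper), ("lower", ~upper)):
        cnt, _, _ = np.histogram2d(xy[mask, 0], xy[mask, 1], bins=(x_edges, y_edges))
        total, _, _ = np.histogram2d(
            xy[mask, 0], xy[mask, 1], bins=(x_edges, y_edges), weights=z[mask]
        )
        with np.errstate(invalid="ignore"):
            mz = np.where(cnt > 0, total / np.maximum(cnt, 1), np.nan)
        mean_z[leaflet] = mz.reshape(shape)
        counts[leaflet] = cnt.astype(int)
    return DeformationSurface(x_edges, y_edges, mean_z, counts, grid_spacing)


def write_surface_tsv(surface: DeformationSurface, path: str | Path) -> None:
    """TSV export: x_A, y_A (cell centres), leaflet, meanZ_A, n."""
    xc = 0.5 * (surface.x_edges[:-1] + surface.x_edges[1:])
    yc = 0.5 * (surface.y_edges[:-1] + surface.y_edges[1:])
    with open(path, "w") as fh:
        fh.write("x_A\ty_A\tleaflet\tmeanZ_A\tn\n")
        for leaflet in ("upper", "lower"):
            mz = surface.mean_z[leaflet]
            cnt = surface.counts[leaflet]
            for i, x in enumerate(xc):
                for j, y in enumerate(yc):
                    if cnt[i, j] == 0:
                        continue
                    fh.write(f"{x:.2f}\t{y:.2f}\t{leaflet}\t{mz[i, j]:.4f}\t{cnt[i, j]}\n")


def flat_plane_report(surface: DeformationSurface, leaflet: str = "upper") -> dict:
    """Compare the gridded surface against a fitted flat plane.

    The flat plane is the planar-slab picture used by orientation
    databases such as OPM; the report quantifies how far the simulated,
    deformed surface departs from it (mean |deviation|, max thinning and
    thickening in Å).
    """
    mz = surface.mean_z[leaflet]
    occ = surface.occupied(leaflet)
    if not occ.any():
        raise GeometryError(f"no occupied cells in leaflet {leaflet!r}")
    z = mz[occ]
    plane_z = float(z.mean())
    dev = z - plane_z
    return {
        "leaflet": leaflet,
        "plane_z_A": plane_z,
        "mean_abs_deviation_A": float(np.abs(dev).mean()),
        "max_thickening_A": float(dev.max()),
        "max_thinning_A": float(-dev.min()),
        "n_cells": int(occ.sum()),
    }


def lipid_contact_fraction(
    traj: Trajectory,
    protein_residues: Sequence[tuple[str, int]],
    tail_selection: Selection | Sequence[int],
    contact_cutoff: float = 6.0,
) -> dict[tuple[str, int], float]:
    """Fraction of frames each residue contacts a lipid tail atom.

    A residue is "in contact" in a frame when any of its atoms lies
    within ``contact_cutoff`` Å of any tail atom.
    """
    if contact_cutoff <= 0:
        raise ValueError("contact_cutoff must be positive")
    t_idx = resolve_selection(traj.reference, tail_selection)
    res_atoms = {
        (chain, rs): traj.reference.residue_atoms(chain, rs)
        for chain, rs in protein_residues
    }
    hits = {key: 0 for key in res_atoms}
    for f in range(traj.n_frames):
        if t_idx.size == 0:
            break
        tree = cKDTree(traj.frames[f][t_idx])
        for key, atoms in res_atoms.items():
            if not atoms:
                continue
            d, _ = tree.query(traj.frames[f][atoms], k=1)
            if np.min(d) <= contact_cutoff:
                hits[key] += 1
    return {key: hits[key] / traj.n_frames for key in res_atoms}


def _ca_midpoint(structure: Structure, coords: np.ndarray, res_range: tuple[int, int],
                 chain: str | None) -> np.ndarray:
    sel = Selection(chain=chain, res_range=res_range, names=frozenset({"CA"}))
    idx = sel.resolve(structure)
    expected = res_range[1] - res_range[0] + 1
    if idx.size < expected:
        have = {structure.atoms[i].res_seq for i in idx}
        missing = sorted(set(range(res_range[0], res_range[1] + 1)) - have)
        raise GeometryError(f"missing Cα atom(s) for residue(s) {missing}")
    return coords[idx].mean(axis=0)


def orientation_angles(
    structure: Structure,
    normal=(0.0, 0.0, 1.0),
    coords: np.ndarray | None = None,
    chain: str | None = None,
    vc_ranges: tuple = VC_RANGES,
    vi_ranges: tuple = VI_RANGES,
) -> OrientationVectors:
    """Orientation of the globular domain relative to the membrane normal.

    alpha = angle(normal, v_c) and beta = angle(normal, v_i), degrees.
    """
    n = _unit_normal(normal)
    xyz = structure.coords if coords is None else np.asarray(coords, float)
    v_c = _ca_midpoint(structure, xyz, vc_ranges[1], chain) - _ca_midpoint(
        structure, xyz, vc_ranges[0], chain
    )
    v_i = _ca_midpoint(structure, xyz, vi_ranges[1], chain) - _ca_midpoint(
        structure, xyz, vi_ranges[0], chain
    )
    return OrientationVectors(v_c, v_i, angle_between(n, v_c), angle_between(n, v_i))


def heme_tilt(
    structure: Structure,
    porphyrin_selection: Selection | Sequence[int],
    normal=(0.0, 0.0, 1.0),
    coords: np.ndarray | None = None,
    complement: bool = False,
) -> float:
    """Tilt of the least-squares heme plane against the membrane plane.

    Default convention: the angle between the two planes, 0° when the
    heme lies parallel to the membrane, 90° when it contains the
    normal. ``complement=True`` returns 90° minus that (the
    plane-vs-normal convention used by some experimental reports).
    """
    n = _unit_normal(normal)
    idx = resolve_selection(structure, porphyrin_selection)
    if idx.size < 3:
        raise GeometryError("heme_tilt: need >= 3 porphyrin atoms")
    xyz = (structure.coords if coords is None else np.asarray(coords, float))[idx]
    centred = xyz - xyz.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] < 1e-8:
        raise GeometryError("heme_tilt: selected atoms are collinear")
    plane_normal = vt[-1]
    tilt = float(np.degrees(np.arccos(np.clip(abs(np.dot(plane_normal, n)), 0.0, 1.0))))
    return 90.0 - tilt if complement else tilt


def insertion_depth(
    traj: Trajectory,
    selection: Selection | Sequence[int],
    phosphate_selection: Selection | Sequence[int],
    leaflet: str = "upper",
) -> np.ndarray:
    """Signed depth (Å) of the selection COM below the phosphate plane.

    Positive values mean the selection is buried below the mean
    phosphate Z of the chosen leaflet (leaflets split at the per-frame
    phosphate midplane; ``leaflet="all"`` averages every phosphate,
    appropriate for single-sheet inputs).
    """
    s_idx = resolve_selection(traj.reference, selection)
    p_idx = resolve_selection(traj.reference, phosphate_selection)
    if s_idx.size == 0:
        raise GeometryError("insertion_depth: empty selection")
    if p_idx.size == 0:
        raise GeometryError("insertion_depth: empty bilayer selection")
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        com = center_of_mass(traj.reference, s_idx, coords=traj.frames[f])
        pz = traj.frames[f][p_idx][:, 2]
        if leaflet == "all":
            sel_z = pz
        else:
            mid = pz.mean()
            sel_z = pz[pz >= mid] if leaflet == "upper" else pz[pz < mid]
            if sel_z.size == 0:
                sel_z = pz
        out[f] = sel_z.mean() - com[2]
    return out
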