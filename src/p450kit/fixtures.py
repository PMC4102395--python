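"""Deterministic synthetic fixtures with embedded ground truth.

Every generator is a pure function of its parameters and seed and
returns (object, metadata): the metadata records the parameters the
generator imposed, so each analysis's expected output can be computed
without reading coordinates back. Fixtures ship as code — the
repository carries no coordinate files.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Atom, Structure, Trajectory


def _atom(serial, name, element, res_name, res_seq, chain, pos):
    return Atom(serial, name, element, res_name, res_seq, chain, np.asarray(pos, float))


# ---------------------------------------------------------------------------
# ideal alpha-helix
# ---------------------------------------------------------------------------

def make_helix(
    n_residues: int,
    rise: float = 1.5,
    twist: float = 100.0,
    chain: str = "A",
    first_res: int = 1,
    with_backbone: bool = True,
) -> tuple[Structure, dict]:
    """Ideal α-helix Cα trace along z (rise Å/residue, twist °/residue).

    The helix radius is chosen so consecutive Cα atoms sit ~3.8 Å
    apart. With ``with_backbone``, dummy N/C/O atoms are attached to
    each Cα so backbone selections resolve.
    """
    if n_residues < 4:
        raise ValueError("a helix needs at least 4 residues")
    chord = np.sqrt(max(3.8 ** 2 - rise ** 2, 0.0))
    radius = chord / (2.0 * np.sin(np.radians(twist) / 2.0))
    atoms = []
    serial = 1
    for k in range(n_residues):
        phi = np.radians(twist) * k
        ca = np.array([radius * np.cos(phi), radius * np.sin(phi), rise * k])
        res = first_res + k
        if with_backbone:
            u = np.array([np.cos(phi), np.sin(phi), 0.0])  # radial unit vector
            atoms.append(_atom(serial, "N", "N", "ALA", res, chain, ca + 1.2 * u + (0, 0, -0.8)))
            serial += 1
        atoms.append(_atom(serial, "CA", "C", "ALA", res, chain, ca))
        serial += 1
        if with_backbone:
            atoms.append(_atom(serial, "C", "C", "ALA", res, chain, ca + 1.2 * u + (0, 0, 0.8)))
            serial += 1
            atoms.append(_atom(serial, "O", "O", "ALA", res, chain, ca + 2.2 * u + (0, 0, 0.9)))
            serial += 1
    meta = {
        "kind": "helix",
        "n_residues": n_residues,
        "rise_A": rise,
        "twist_deg": twist,
        "radius_A": float(radius),
        "axis": [0.0, 0.0, 1.0],
    }
    return Structure(atoms), meta


def make_globular_blob(
    n_residues: int,
    radius: float = 15.0,
    seed: int = 0,
    chain: str = "A",
    first_res: int = 1,
) -> tuple[Structure, dict]:
    """Random Cα cloud inside a sphere — a stand-in globular domain."""
    rng = np.random.default_rng(seed)
    atoms = []
    for k in range(n_residues):
        while True:
            p = rng.uniform(-radius, radius, size=3)
            if np.linalg.norm(p) <= radius:
                break
        atoms.append(_atom(k + 1, "CA", "C", "GLY", first_res + k, chain, p))
    return Structure(atoms), {"kind": "globular_blob", "n_residues": n_residues,
                              "radius_A": radius, "seed": seed}


# ---------------------------------------------------------------------------
# deformable phosphate sheet
# ---------------------------------------------------------------------------

def gaussian_field(x, y, depth: float, sigma: float, center=(0.0, 0.0)):
    """Gaussian dimple depth field evaluated at (x, y)."""
    dx = np.asarray(x) - center[0]
    dy = np.asarray(y) - center[1]
    return depth * np.exp(-(dx ** 2 + dy ** 2) / (2.0 * sigma ** 2))


def make_lipid_sheet(
    nx: int,
    ny: int,
    spacing: float = 8.0,
    z0: float = 20.0,
    deformation: dict | None = None,
    two_leaflets: bool = False,
) -> tuple[Structure, dict]:
    """Phosphate pseudo-atom sheet(s) with an optional imposed dimple.

    The upper sheet sits at z = z0 - field(x, y); with ``two_leaflets``
    a mirrored sheet at z = -(z0 - field) is added, so the leaflet
    separation is 2*(z0 - field) everywhere. ``deformation`` is e.g.
    ``{"kind": "gaussian", "depth": 5, "sigma": 10, "center": (0, 0)}``.
    """
    if nx < 2 or ny < 2:
        raise ValueError("sheet needs nx, ny >= 2")
    xs = (np.arange(nx) - (nx - 1) / 2.0) * spacing
    ys = (np.arange(ny) - (ny - 1) / 2.0) * spacing
    atoms = []
    serial = 1
    res = 1
    for leaflet, sign, chain in (("upper", 1.0, "L"), ("lower", -1.0, "M")):
        if leaflet == "lower" and not two_leaflets:
            continue
        for x in xs:
            for y in ys:
                dz = 0.0
                if deformation is not None:
                    if deformation["kind"] != "gaussian":
                        raise ValueError(f"unknown field kind {deformation['kind']!r}")
                    dz = float(gaussian_field(
                        x, y, deformation["depth"], deformation["sigma"],
                        deformation.get("center", (0.0, 0.0)),
                    ))
                atoms.append(
                    _atom(serial, "P", "P", "POPC", res, chain,
                          (x, y, sign * (z0 - dz)))
                )
                serial += 1
                res += 1
    meta = {
        "kind": "lipid_sheet", "nx": nx, "ny": ny, "spacing_A": spacing,
        "z0_A": z0, "deformation": deformation, "two_leaflets": two_leaflets,
    }
    return Structure(atoms), meta


# ---------------------------------------------------------------------------
# Markov-switching gate trajectory
# ---------------------------------------------------------------------------

_PHE_SIDECHAIN = (  # local side-chain heavy-atom geometry (name, offset Å)
    ("CB", (0.0, 0.0, 0.0)),
    ("CG", (1.4, 0.4, 0.0)),
    ("CD1", (2.3, -0.4, 0.6)),
    ("CD2", (2.3, 1.2, -0.6)),
)


def _phe_residue(serial0, res_seq, chain, origin):
    origin = np.asarray(origin, float)
    atoms = [
        _atom(serial0, "N", "N", "PHE", res_seq, chain, origin + (-1.8, -1.0, 0.0)),
        _atom(serial0 + 1, "CA", "C", "PHE", res_seq, chain, origin + (-1.2, 0.0, 0.0)),
        _atom(serial0 + 2, "C", "C", "PHE", res_seq, chain, origin + (-1.8, 1.0, 0.0)),
        _atom(serial0 + 3, "O", "O", "PHE", res_seq, chain, origin + (-2.9, 1.2, 0.0)),
    ]
    for k, (name, off) in enumerate(_PHE_SIDECHAIN):
        atoms.append(_atom(serial0 + 4 + k, name, "C", "PHE", res_seq, chain,
                           origin + np.asarray(off)))
    return atoms


def markov_gate_states(
    n_frames: int, p_open: float, rate: float, seed: int
) -> np.ndarray:
    """Two-state chain with stationary open probability ``p_open``.

    Transition probabilities are a = rate * p_open (closed -> open) and
    b = rate * (1 - p_open) (open -> closed), so the stationary
    distribution is exactly p_open and ``rate`` sets the switching
    frequency. The initial state is drawn from the stationary law.
    """
    if not 0.0 < p_open < 1.0:
        raise ValueError("p_open must lie strictly between 0 and 1")
    if not 0.0 < rate <= 1.0:
        raise ValueError("rate must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    a = rate * p_open
    b = rate * (1.0 - p_open)
    states = np.empty(n_frames, dtype=bool)
    states[0] = rng.random() < p_open
    for t in range(1, n_frames):
        if states[t - 1]:
            states[t] = rng.random() >= b
        else:
            states[t] = rng.random() < a
    return states


def make_gate_trajectory(
    n_frames: int,
    d_open: float = 5.0,
    d_closed: float = 9.0,
    p_open: float = 0.4,
    rate: float = 0.2,
    seed: int = 0,
    dt: float = 0.02,
) -> tuple[Trajectory, dict]:
    """Two-phenylalanine system whose side-chain COM separation follows a
    Markov-switching open/closed schedule."""
    base_a = _phe_residue(1, 108, "A", (0.0, 0.0, 0.0))
    base_b = _phe_residue(9, 220, "A", (0.0, 0.0, 0.0))
    ref = Structure(base_a + base_b)
    states = markov_gate_states(n_frames, p_open, rate, seed)
    coords0 = ref.coords
    frames = np.empty((n_frames, len(ref), 3))
    # the two residues share identical local geometry, so their side-chain
    # COM offsets cancel and the COM-COM separation is exactly the shift
    for t in range(n_frames):
        d = d_open if states[t] else d_closed
        frames[t] = coords0
        frames[t, 8:, 0] = coords0[8:, 0] + d  # residue B shifted along x by d
    traj = Trajectory(ref, frames, dt=dt)
    meta = {
        "kind": "gate_trajectory", "n_frames": n_frames, "d_open_A": d_open,
        "d_closed_A": d_closed, "p_open": p_open, "rate": rate, "seed": seed,
        "states_open": states.tolist(),
    }
    return traj, meta


# ---------------------------------------------------------------------------
# toy Compound-I site
# ---------------------------------------------------------------------------

def place_atom_dihedral(p1, p2, p3, length: float, angle: float, torsion: float):
    """Place a fourth point with given bond length (Å), bond angle and
    torsion (degrees) relative to the chain p1-p2-p3."""
    p1, p2, p3 = (np.asarray(p, float) for p in (p1, p2, p3))
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    ab = p2 - p1
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    th = np.radians(angle)
    ph = np.radians(torsion)
    d = length * (-np.cos(th) * bc + np.sin(th) * (np.cos(ph) * m + np.sin(ph) * n))
    return p3 + d


def make_toy_heme(
    with_substrate: bool = True,
    propionate_dihedral: float = 100.0,
    chain: str = "A",
    heme_res: int = 508,
) -> tuple[Structure, dict]:
    """Toy Compound-I site with PDB heme atom naming.

    Contains the 24-atom planar porphine ring, Fe and ferryl O, all 8
    substituent stubs (propionates A/D, vinyls B/C, four methyls), a
    proximal-cysteine fragment (CA, CB, HB1, HB2, SG) and optionally a
    5-atom substrate carrying the reactive C10 and its abstractable H5.
    The propionate-A C3A-C2A-CAA-CBA torsion is constructed at the
    requested angle. Metadata records the atom inventory and the QM/link
    counts ``select_qm_region`` must reproduce.
    """
    atoms = []
    serial = [0]

    def add(name, element, pos, res_name="HEM", res_seq=heme_res):
        serial[0] += 1
        atoms.append(_atom(serial[0], name, element, res_name, res_seq, chain, pos))
        return np.asarray(pos, float)

    add("FE", "Fe", (0.0, 0.0, 0.0))
    add("O1", "O", (0.0, 0.0, 1.65))

    ring_pos = {}
    for k, letter in enumerate("ABCD"):
        phi = np.radians(90.0 * k)
        c, s = np.cos(phi), np.sin(phi)

        def rot(p):
            return np.array([c * p[0] - s * p[1], s * p[0] + c * p[1], 0.0])

        ring_pos[f"N{letter}"] = add(f"N{letter}", "N", rot((2.05, 0.0, 0.0)))
        ring_pos[f"C1{letter}"] = add(f"C1{letter}", "C", rot((2.9, -1.1, 0.0)))
        ring_pos[f"C2{letter}"] = add(f"C2{letter}", "C", rot((4.25, -0.7, 0.0)))
        ring_pos[f"C3{letter}"] = add(f"C3{letter}", "C", rot((4.25, 0.7, 0.0)))
        ring_pos[f"C4{letter}"] = add(f"C4{letter}", "C", rot((2.9, 1.1, 0.0)))
    for k, letter in enumerate("ABCD"):
        phi = np.radians(90.0 * k + 45.0)
        ring_pos[f"CH{letter}"] = add(
            f"CH{letter}", "C", (3.4 * np.cos(phi), 3.4 * np.sin(phi), 0.0)
        )

    # propionate A on C2A, torsion constructed at the requested angle
    caa = place_atom_dihedral(ring_pos["NA"], ring_pos["C3A"], ring_pos["C2A"],
                              1.54, 122.0, 150.0)
    add("CAA", "C", caa)
    cba = place_atom_dihedral(ring_pos["C3A"], ring_pos["C2A"], caa,
                              1.54, 111.0, propionate_dihedral)
    add("CBA", "C", cba)
    cga = place_atom_dihedral(ring_pos["C2A"], caa, cba, 1.52, 112.0, 180.0)
    add("CGA", "C", cga)
    add("O1A", "O", place_atom_dihedral(caa, cba, cga, 1.25, 118.0, 0.0))
    add("O2A", "O", place_atom_dihedral(caa, cba, cga, 1.25, 118.0, 180.0))
    # methyls, vinyls and propionate D as radial stubs
    stubs = {
        "CMA": ("C3A", None), "CMB": ("C2B", None), "CAB": ("C3B", "CBB"),
        "CMC": ("C2C", None), "CAC": ("C3C", "CBC"), "CMD": ("C2D", None),
        "CAD": ("C3D", ("CBD", "CGD", "O1D", "O2D")),
    }
    for name, (ring_name, extra) in stubs.items():
        base = ring_pos[ring_name]
        u = base / np.linalg.norm(base)
        pos = add(name, "C", base + 1.5 * u)
        if extra is None:
            continue
        tail = (extra,) if isinstance(extra, str) else extra
        prev = pos
        for j, t_name in enumerate(tail):
            el = "O" if t_name.startswith("O") else "C"
            prev = add(t_name, el, prev + 1.45 * u + np.array([0, 0, 0.4 * (j + 1)]))

    # proximal cysteine (modelled downstream as SCH2)
    cys_res = 442
    add("N", "N", (1.0, 2.2, -4.9), "CYS", cys_res)
    ca = add("CA", "C", (0.4, 1.9, -3.9), "CYS", cys_res)
    add("C", "C", (1.2, 2.6, -2.9), "CYS", cys_res)
    add("O", "O", (2.3, 3.0, -3.1), "CYS", cys_res)
    cb = add("CB", "C", (0.3, 0.5, -3.4), "CYS", cys_res)
    add("HB1", "H", (-0.5, 0.5, -2.7), "CYS", cys_res)
    add("HB2", "H", (1.2, 0.2, -2.9), "CYS", cys_res)
    add("SG", "S", (0.0, 0.0, -2.3), "CYS", cys_res)

    n_heme_and_cys = len(atoms)
    substrate_names = []
    if with_substrate:
        sub_res = 600
        add("C9", "C", (1.6, 0.8, 3.6), "WAR", sub_res)
        add("C10", "C", (0.6, 0.3, 2.9), "WAR", sub_res)
        add("H5", "H", (0.25, 0.12, 2.05), "WAR", sub_res)
        add("C11", "C", (-0.6, 1.0, 3.3), "WAR", sub_res)
        add("O2", "O", (2.6, 0.2, 4.1), "WAR", sub_res)
        substrate_names = ["C9", "C10", "H5", "C11", "O2"]

    meta = {
        "kind": "toy_heme",
        "with_substrate": with_substrate,
        "propionate_dihedral_deg": propionate_dihedral,
        "n_atoms": len(atoms),
        "n_ring_atoms": 24,
        # QM region: Fe + O1 + 24 ring + SG + CB + HB1 + HB2 (+ substrate)
        "n_qm_expected": 30 + (len(substrate_names) if with_substrate else 0),
        # links: 8 ring-substituent bonds + Cys CB-CA
        "n_links_expected": 9,
        "substrate_atoms": substrate_names,
        "heme_res_seq": heme_res,
        "cys_res_seq": cys_res,
        "n_heme_and_cys_atoms": n_heme_and_cys,
    }
    return Structure(atoms), meta


def rotated(structure: Structure, axis, angle_deg: float,
            center=(0.0, 0.0, 0.0)) -> Structure:
    """Rigid rotation of a structure about an axis through ``center``."""
    axis = np.asarray(axis, float)
    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis / np.linalg.norm(axis))
    center = np.asarray(center, float)
    coords = (structure.coords - center) @ rot.as_matrix().T + center
    return structure.with_coords(coords)
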