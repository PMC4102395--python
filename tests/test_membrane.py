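"""Bilayer deformation surfaces, contacts, orientation and heme tilt."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from p450kit.core import Selection, Structure, Trajectory, center_of_mass
from p450kit.fixtures import (
    gaussian_field,
    make_gate_trajectory,
    make_helix,
    make_lipid_sheet,
    make_toy_heme,
    markov_gate_states,
    rotated,
)
from p450kit.membrane import (
    deformation_surface,
    fit_membrane_normal,
    flat_plane_report,
    heme_tilt,
    insertion_depth,
    lipid_contact_fraction,
    orientation_angles,
)

P_SEL = Selection(names=frozenset({"P"}))


def _static_traj(structure, n=1):
    return Trajectory(structure, np.stack([structure.coords] * n))


class TestDeformationSurface:
    def test_flat_sheet_recovers_z0_everywhere(self, flat_sheet):
        sheet, meta = flat_sheet
        surf = deformation_surface(_static_traj(sheet), P_SEL, protein_selection=P_SEL)
        occ = surf.occupied("upper")
        assert occ.any()
        assert np.allclose(surf.mean_z["upper"][occ], meta["z0_A"], atol=1e-9)
        assert not surf.occupied("lower").any()  # single leaflet
        assert np.isnan(surf.mean_z["upper"][~occ]).all()  # empty cells flagged

    def test_gaussian_dimple_depth_recovered(self):
        depth, sigma = 5.0, 10.0
        sheet, meta = make_lipid_sheet(
            25, 25, spacing=2.0, z0=20.0,
            deformation={"kind": "gaussian", "depth": depth, "sigma": sigma},
        )
        spacing = 2.0
        surf = deformation_surface(
            _static_traj(sheet), P_SEL, protein_selection=P_SEL,
            grid_spacing=spacing, split_leaflets=False,
        )
        occ = surf.occupied("upper")
        zmin = np.nanmin(surf.mean_z["upper"][occ])
        # binning error bounded by the field's max gradient x grid spacing
        max_grad = depth / sigma * np.exp(-0.5)
        assert zmin == pytest.approx(20.0 - depth, abs=max_grad * spacing + 1e-9)

    def test_two_leaflet_thickness_constant_for_flat_sheet(self):
        sheet, meta = make_lipid_sheet(10, 10, spacing=4.0, z0=18.0, two_leaflets=True)
        surf = deformation_surface(_static_traj(sheet), P_SEL, protein_selection=P_SEL)
        both = surf.occupied("upper") & surf.occupied("lower")
        assert both.any()
        thickness = surf.mean_z["upper"][both] - surf.mean_z["lower"][both]
        assert np.allclose(thickness, 2 * 18.0, atol=1e-9)

    def test_invariant_under_rigid_motion_of_whole_system(self):
        sheet, _ = make_lipid_sheet(
            12, 12, spacing=3.0, z0=20.0,
            deformation={"kind": "gaussian", "depth": 4.0, "sigma": 8.0},
        )
        base = sheet.coords
        rot = Rotation.from_euler("xyz", [10, -7, 30], degrees=True).as_matrix()
        moved = base @ rot.T + np.array([5.0, -3.0, 12.0])
        traj = Trajectory(sheet, np.stack([base, moved]))
        surf2 = deformation_surface(traj, P_SEL, protein_selection=P_SEL,
                                    split_leaflets=False)
        surf1 = deformation_surface(_static_traj(sheet), P_SEL, protein_selection=P_SEL,
                                    split_leaflets=False)
        occ = surf1.occupied("upper")
        # the protein-fixed frame removes the transform: two frames of the
        # same (moved) sheet bin identically to one
        assert np.allclose(
            surf2.mean_z["upper"][occ], surf1.mean_z["upper"][occ], atol=1e-6
        )

    def test_no_phosphates_matched_raises(self, helix10):
        helix, _ = helix10
        with pytest.raises(Exception, match="phosphate"):
            deformation_surface(_static_traj(helix), P_SEL)


class TestFlatPlaneReport:
    def test_reports_imposed_deformation_amplitude(self):
        sheet, _ = make_lipid_sheet(
            25, 25, spacing=2.0, z0=20.0,
            deformation={"kind": "gaussian", "depth": 5.0, "sigma": 6.0},
        )
        surf = deformation_surface(_static_traj(sheet), P_SEL, protein_selection=P_SEL,
                                   split_leaflets=False)
        report = flat_plane_report(surf, "upper")
        # dimple is narrow: plane sits near 20, max thinning near the depth
        assert report["max_thinning_A"] == pytest.approx(5.0, abs=0.8)
        assert report["max_thickening_A"] < 0.8


class TestLipidContacts:
    def _contact_traj(self, states, d_contact=3.0, d_far=12.0):
        atoms = [
            # one-residue "protein" and one lipid tail bead
            _a(1, "CA", "C", "ALA", 1, "A", (0, 0, 0)),
            _a(2, "C2", "C", "POPC", 901, "L", (d_far, 0, 0)),
        ]
        s = Structure(atoms)
        frames = np.stack([s.coords] * len(states))
        frames[:, 1, 0] = np.where(states, d_contact, d_far)
        return Trajectory(s, frames)

    def test_always_in_contact(self):
        traj = self._contact_traj(np.ones(20, bool))
        frac = lipid_contact_fraction(traj, [("A", 1)], [1], contact_cutoff=6.0)
        assert frac[("A", 1)] == 1.0

    def test_never_in_contact(self):
        traj = self._contact_traj(np.zeros(20, bool))
        frac = lipid_contact_fraction(traj, [("A", 1)], [1], contact_cutoff=6.0)
        assert frac[("A", 1)] == 0.0

    def test_markov_contact_fraction_within_3_se(self):
        p, n = 0.25, 5000
        states = markov_gate_states(n, p_open=p, rate=0.3, seed=11)
        traj = self._contact_traj(states)
        frac = lipid_contact_fraction(traj, [("A", 1)], [1], contact_cutoff=6.0)
        # Markov correlation inflates the naive binomial SE; 3 SE on the
        # effective sample size n*rate/(2-rate) keeps the bound honest
        n_eff = n * 0.3 / (2 - 0.3)
        se_eff = np.sqrt(p * (1 - p) / n_eff)
        assert abs(frac[("A", 1)] - p) < 3 * se_eff
        assert frac[("A", 1)] == pytest.approx(states.mean())  # exact bookkeeping


def _a(serial, name, element, res_name, res_seq, chain, pos):
    from p450kit.core import Atom

    return Atom(serial, name, element, res_name, res_seq, chain, np.asarray(pos, float))


def _orientation_fixture():
    """Cα atoms for the four helix-turn ranges, v_c along +z, v_i along +x."""
    atoms = []
    serial = 1

    def turn(res_lo, center):
        nonlocal serial
        for k in range(5):
            off = np.array([0.3 * (k - 2), 0.2 * ((k % 2) - 0.5), 0.0])
            atoms.append(_a(serial, "CA", "C", "ALA", res_lo + k, "A",
                            np.asarray(center) + off))
            serial += 1

    turn(137, (0, 0, 0))
    turn(207, (0, 0, 30))  # v_c = +30 z
    turn(292, (10, 5, 15))
    turn(321, (40, 5, 15))  # v_i = +30 x
    return Structure(atoms)


class TestOrientationAngles:
    def test_aligned_and_orthogonal(self):
        s = _orientation_fixture()
        ov = orientation_angles(s, normal=(0, 0, 1))
        assert ov.alpha == pytest.approx(0.0, abs=1e-9)
        assert ov.beta == pytest.approx(90.0, abs=1e-9)

    def test_rotation_shifts_alpha_by_exactly_the_angle(self):
        s = _orientation_fixture()
        for angle in (25.0, 60.0):
            rs = rotated(s, (1, 0, 0), angle)  # axis perpendicular to normal and v_c
            ov = orientation_angles(rs, normal=(0, 0, 1))
            assert ov.alpha == pytest.approx(angle, abs=1e-8)

    def test_antiparallel_supplement(self):
        s = _orientation_fixture()
        up = orientation_angles(s, normal=(0, 0, 1))
        dn = orientation_angles(s, normal=(0, 0, -1))
        assert up.alpha + dn.alpha == pytest.approx(180.0)
        assert up.beta + dn.beta == pytest.approx(180.0)

    def test_missing_ca_names_residue(self):
        s = _orientation_fixture()
        keep = [i for i, a in enumerate(s.atoms) if a.res_seq != 139]
        with pytest.raises(Exception, match="139"):
            orientation_angles(s.subset(keep))


class TestHemeTilt:
    def _ring(self):
        ang = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pts = np.stack([3 * np.cos(ang), 3 * np.sin(ang), np.zeros(12)], axis=1)
        return Structure([
            _a(i + 1, f"C{i}", "C", "HEM", 508, "A", p) for i, p in enumerate(pts)
        ])

    def test_parallel_plane_is_zero(self):
        assert heme_tilt(self._ring(), None) == pytest.approx(0.0, abs=1e-9)

    def test_plane_containing_normal_is_90(self):
        s = rotated(self._ring(), (1, 0, 0), 90.0)
        assert heme_tilt(s, None) == pytest.approx(90.0, abs=1e-9)

    @pytest.mark.parametrize("angle", [37.0, 12.5, 81.0])
    def test_constructed_tilt_recovered(self, angle):
        s = rotated(self._ring(), (0, 1, 0), angle)
        assert heme_tilt(s, None) == pytest.approx(angle, abs=1e-6)

    def test_invariant_under_in_plane_rotation(self):
        s = rotated(self._ring(), (0, 1, 0), 37.0)
        for az in (45, 160, 300):
            assert heme_tilt(rotated(s, (0, 0, 1), az), None) == pytest.approx(
                37.0, abs=1e-6
            )

    def test_complement_convention(self):
        s = rotated(self._ring(), (0, 1, 0), 37.0)
        assert heme_tilt(s, None, complement=True) == pytest.approx(53.0, abs=1e-6)

    def test_collinear_selection_raises(self):
        s = Structure([
            _a(i + 1, f"C{i}", "C", "HEM", 1, "A", (float(i), 0, 0)) for i in range(5)
        ])
        with pytest.raises(Exception, match="collinear"):
            heme_tilt(s, None)

    def test_tilt_on_toy_heme_porphyrin(self, toy_heme):
        site, _ = toy_heme
        from p450kit.constants import PORPHINE_RING_ATOMS

        sel = Selection(names=frozenset(PORPHINE_RING_ATOMS))
        assert heme_tilt(site, sel) == pytest.approx(0.0, abs=1e-6)
        tilted = rotated(site, (1, 0, 0), 60.0)
        assert heme_tilt(tilted, sel) == pytest.approx(60.0, abs=1e-6)


class TestInsertionDepth:
    def test_com_at_plane_is_zero_and_below_is_positive(self, flat_sheet):
        sheet, meta = flat_sheet
        z0 = meta["z0_A"]
        probe_at = _a(999, "CA", "C", "ALA", 1, "A", (0, 0, z0))
        probe_below = _a(998, "CB", "C", "ALA", 1, "A", (0, 0, z0 - 5.0))
        s = Structure(list(sheet.atoms) + [probe_at, probe_below])
        traj = Trajectory(s, s.coords[None])
        p_idx = P_SEL.resolve(s)
        at = insertion_depth(traj, [len(s) - 2], p_idx, leaflet="all")
        below = insertion_depth(traj, [len(s) - 1], p_idx, leaflet="all")
        assert at[0] == pytest.approx(0.0, abs=1e-9)
        assert below[0] == pytest.approx(5.0, abs=1e-9)

    def test_deformed_sheet_matches_brute_force(self):
        sheet, _ = make_lipid_sheet(
            10, 10, spacing=4.0, z0=20.0,
            deformation={"kind": "gaussian", "depth": 6.0, "sigma": 9.0},
        )
        probe = _a(999, "CA", "C", "ALA", 1, "A", (1.0, -2.0, 13.0))
        s = Structure(list(sheet.atoms) + [probe])
        traj = Trajectory(s, s.coords[None])
        p_idx = P_SEL.resolve(s)
        got = insertion_depth(traj, [len(s) - 1], p_idx, leaflet="all")[0]
        brute = s.coords[p_idx][:, 2].mean() - 13.0
        assert got == pytest.approx(brute, abs=1e-12)


def test_fitted_normal_matches_construction():
    sheet, _ = make_lipid_sheet(10, 10, spacing=4.0, z0=0.0)
    tilted = rotated(sheet, (1, 0, 0), 20.0)
    n = fit_membrane_normal(tilted.coords)
    expected = Rotation.from_rotvec(np.radians(20.0) * np.array([1, 0, 0])).apply([0, 0, 1])
    assert abs(np.dot(n, expected)) == pytest.approx(1.0, abs=1e-9)
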