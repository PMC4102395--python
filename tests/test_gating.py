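"""Channel gating, propionates, salt bridges and substrate mobility."""

import numpy as np
import pytest

from p450kit.core import Atom, GeometryError, Structure, Trajectory, dihedral
from p450kit.fixtures import make_gate_trajectory, make_toy_heme
from p450kit.gating import (
    GateDefinition,
    arg212_orientation,
    default_gates,
    fraction_open_report,
    gate_trace,
    mobility_vs_gate,
    propionate_states,
    rank_poses_by_site_distance,
    salt_bridge_distances,
    sidechain_heavy_atoms,
    write_gate_tsv,
)

GATE_2B = GateDefinition("2b", ("A", 108, "PHE"), ("A", 220, "PHE"))


def _a(serial, name, element, res_name, res_seq, chain, pos):
    return Atom(serial, name, element, res_name, res_seq, chain, np.asarray(pos, float))


class TestGateTrace:
    def test_constant_open_distance(self):
        traj, _ = make_gate_trajectory(30, d_open=5.0, d_closed=5.0, p_open=0.5, seed=0)
        trace = gate_trace(traj, GATE_2B)
        assert np.allclose(trace.d, 5.0, atol=1e-9)
        assert trace.fraction_open == 1.0

    def test_always_closed(self):
        traj, _ = make_gate_trajectory(30, d_open=8.0, d_closed=8.0, p_open=0.5, seed=0)
        trace = gate_trace(traj, GATE_2B)
        assert trace.fraction_open == 0.0

    def test_flags_match_threshold_rule(self):
        traj, meta = make_gate_trajectory(200, p_open=0.3, seed=3)
        trace = gate_trace(traj, GATE_2B)
        assert np.array_equal(trace.open_flags, trace.d < trace.gate.open_threshold)
        assert np.array_equal(trace.open_flags, np.array(meta["states_open"]))

    def test_fraction_open_invariant_under_frame_reordering(self):
        traj, _ = make_gate_trajectory(100, p_open=0.5, seed=4)
        trace = gate_trace(traj, GATE_2B)
        rng = np.random.default_rng(0)
        perm = rng.permutation(traj.n_frames)
        shuffled = Trajectory(traj.reference, traj.frames[perm])
        assert gate_trace(shuffled, GATE_2B).fraction_open == trace.fraction_open

    def test_fraction_open_monotone_in_threshold(self):
        traj, _ = make_gate_trajectory(100, p_open=0.5, seed=5)
        fracs = [
            gate_trace(
                traj,
                GateDefinition("2b", ("A", 108, "PHE"), ("A", 220, "PHE"), thr),
            ).fraction_open
            for thr in (4.0, 6.0, 8.0, 10.0)
        ]
        assert fracs == sorted(fracs)

    @pytest.mark.parametrize("p_open", [0.1, 0.4, 0.6, 0.9])
    def test_markov_occupancy_recovered_within_3_se(self, p_open):
        n, rate = 10_000, 0.2
        n_eff = n * rate / (2 - rate)  # autocorrelation-corrected sample size
        se = np.sqrt(p_open * (1 - p_open) / n_eff)
        for seed in range(5):
            traj, _ = make_gate_trajectory(n, p_open=p_open, rate=rate, seed=seed)
            trace = gate_trace(traj, GATE_2B)
            assert abs(trace.fraction_open - p_open) < 3 * se

    def test_missing_residue_named_in_error(self):
        traj, _ = make_gate_trajectory(5, seed=0)
        bad = GateDefinition("x", ("A", 108, "PHE"), ("A", 999, "PHE"))
        with pytest.raises(GeometryError, match="999"):
            gate_trace(traj, bad)

    def test_glycine_gate_rejected(self):
        atoms = [
            _a(1, "N", "N", "GLY", 10, "A", (0, 0, 0)),
            _a(2, "CA", "C", "GLY", 10, "A", (1, 0, 0)),
            _a(3, "CB", "C", "PHE", 20, "A", (5, 0, 0)),
        ]
        s = Structure(atoms)
        traj = Trajectory(s, s.coords[None])
        with pytest.raises(GeometryError, match="side-chain"):
            gate_trace(traj, GateDefinition("g", ("A", 10, "GLY"), ("A", 20, "PHE")))

    def test_sidechain_excludes_backbone_and_hydrogen(self, toy_heme):
        site, _ = toy_heme
        names = {site.atoms[i].name for i in sidechain_heavy_atoms(site, "A", 442)}
        assert names == {"CB", "SG"}

    def test_default_gate_table(self):
        gates = default_gates()
        assert {g.name for g in gates} == {"2a", "2b", "2c", "2e", "3", "S"}
        by_name = {g.name: g for g in gates}
        assert by_name["2a"].residue_a[1:] == (57, "PHE")
        assert by_name["S"].residue_b[1:] == (482, "LEU")
        assert all(g.open_threshold == 7.0 for g in gates)


class TestFractionOpenReport:
    def _trace(self, flags):
        flags = np.asarray(flags, bool)
        d = np.where(flags, 5.0, 9.0)
        return type("T", (), {"open_flags": flags, "d": d})()

    def test_single_gate_always_open(self):
        report = fraction_open_report({"apo": {"2b": [self._trace([1, 1, 1, 1])]}})
        assert report.at["2b", "apo"] == 100.0
        assert report.at["overall", "apo"] == 100.0

    def test_half_open_across_gates(self):
        traces = {
            "apo": {
                name: [self._trace([1, 1])] if k < 3 else [self._trace([0, 0])]
                for k, name in enumerate(["2a", "2b", "2c", "2e", "3", "S"])
            }
        }
        report = fraction_open_report(traces)
        assert report.at["overall", "apo"] == 50.0

    def test_prescribed_occupancy_vector_reproduced(self):
        rng = np.random.default_rng(0)
        target = {"2a": 0.2, "2b": 0.6, "3": 0.9}
        traces = {"m": {}}
        for name, frac in target.items():
            flags = np.zeros(1000, bool)
            flags[: int(1000 * frac)] = True
            # split across two "replicas" to exercise pooling
            traces["m"][name] = [self._trace(flags[:400]), self._trace(flags[400:])]
        report = fraction_open_report(traces)
        for name, frac in target.items():
            assert report.at[name, "m"] == pytest.approx(100 * frac)


class TestPropionateStates:
    @pytest.mark.parametrize(
        "angle,expected", [(100.0, "distal"), (-100.0, "proximal")]
    )
    def test_sign_rule(self, angle, expected):
        site, _ = make_toy_heme(propionate_dihedral=angle)
        traj = Trajectory(site, site.coords[None])
        ps = propionate_states(traj, "A", 508)
        assert ps.dihedrals[0] == pytest.approx(angle, abs=1e-6)
        assert ps.states == [expected]

    def test_boundary_zero_is_distal(self):
        # exactly planar cis arrangement in z = 0: the torsion evaluates to
        # a signed zero and the >= 0 rule labels it distal
        atoms = [
            _a(1, "C3A", "C", "HEM", 508, "A", (0, 1, 0)),
            _a(2, "C2A", "C", "HEM", 508, "A", (0, 0, 0)),
            _a(3, "CAA", "C", "HEM", 508, "A", (1.5, 0, 0)),
            _a(4, "CBA", "C", "HEM", 508, "A", (1.5, 1.5, 0)),
        ]
        s = Structure(atoms)
        ps = propionate_states(Trajectory(s, s.coords[None]), "A", 508)
        assert ps.dihedrals[0] == 0.0
        assert ps.states == ["distal"]

    def test_labels_match_cross_product_oracle(self):
        angles = [-170.0, -45.0, 10.0, 120.0, 179.0]
        sites = [make_toy_heme(propionate_dihedral=a)[0] for a in angles]
        traj = Trajectory.from_structures(sites)
        ps = propionate_states(traj, "A", 508)
        for f, a in enumerate(angles):
            idx = [traj.reference.find_atom("A", 508, n) for n in
                   ("C3A", "C2A", "CAA", "CBA")]
            oracle = dihedral(*(traj.frames[f][i] for i in idx))
            assert ps.dihedrals[f] == pytest.approx(oracle)
            assert ps.states[f] == ("distal" if oracle >= 0 else "proximal")

    def test_missing_atom_raises(self, toy_heme):
        site, _ = toy_heme
        keep = [i for i, a in enumerate(site.atoms) if a.name != "CBA"]
        sub = site.subset(keep)
        traj = Trajectory(sub, sub.coords[None])
        with pytest.raises(GeometryError, match="CBA"):
            propionate_states(traj, "A", 508)


class TestSaltBridges:
    def _site_with_arg(self, d=2.8):
        site, _ = make_toy_heme()
        o1a = site.atoms[site.find_atom("A", 508, "O1A")].pos
        o2a = site.atoms[site.find_atom("A", 508, "O2A")].pos
        # place the guanidinium along the O2A -> O1A direction so O1A-NH1
        # is guaranteed to be the closest pair, at exactly d
        u = (o1a - o2a) / np.linalg.norm(o1a - o2a)
        arg_atoms = [
            _a(900, "CA", "C", "ARG", 375, "A", o1a + (d + 4) * u),
            _a(901, "NE", "N", "ARG", 375, "A", o1a + (d + 1.2) * u),
            _a(902, "NH1", "N", "ARG", 375, "A", o1a + d * u),
            _a(903, "NH2", "N", "ARG", 375, "A", o1a + (d + 0.8) * u),
        ]
        return Structure(list(site.atoms) + arg_atoms)

    def test_constructed_ion_pair_distance(self):
        s = self._site_with_arg(2.8)
        traj = Trajectory(s, s.coords[None])
        out = salt_bridge_distances(traj, "A", 508, partners=[(375, "ARG")])
        assert out["ARG375"][0] == pytest.approx(2.8, abs=1e-9)

    def test_missing_partner_warns_and_omits(self):
        s = self._site_with_arg()
        traj = Trajectory(s, s.coords[None])
        with pytest.warns(UserWarning, match="ARG105"):
            out = salt_bridge_distances(
                traj, "A", 508, partners=[(375, "ARG"), (105, "ARG")]
            )
        assert set(out) == {"ARG375"}

    def test_equals_brute_force_minimum(self):
        s = self._site_with_arg(3.3)
        traj = Trajectory(s, s.coords[None])
        out = salt_bridge_distances(traj, "A", 508, partners=[(375, "ARG")])
        o_idx = [s.find_atom("A", 508, n) for n in ("O1A", "O2A")]
        n_idx = [s.find_atom("A", 375, n) for n in ("NE", "NH1", "NH2")]
        brute = min(
            np.linalg.norm(s.atoms[i].pos - s.atoms[j].pos)
            for i in o_idx for j in n_idx
        )
        assert out["ARG375"][0] == pytest.approx(brute, abs=1e-12)


class TestArg212:
    def _traj(self, cz_dists, ca_dist=10.0):
        frames = []
        atoms = [
            _a(1, "FE", "Fe", "HEM", 508, "A", (0, 0, 0)),
            _a(2, "CA", "C", "ARG", 212, "A", (ca_dist, 0, 0)),
            _a(3, "CZ", "C", "ARG", 212, "A", (cz_dists[0], 0, 0)),
        ]
        s = Structure(atoms)
        for d in cz_dists:
            c = s.coords.copy()
            c[2, 0] = d
            frames.append(c)
        return Trajectory(s, np.stack(frames))

    def test_in_and_out_labels(self):
        traj = self._traj([4.0, 12.0])
        assert arg212_orientation(traj) == ["in", "out"]

    def test_flip_schedule_reproduced(self):
        sched = [4.0, 12.0, 4.0, 4.0, 12.0]
        labels = arg212_orientation(self._traj(sched))
        assert labels == ["in" if d < 10.0 else "out" for d in sched]

    def test_missing_cz_raises(self):
        atoms = [
            _a(1, "FE", "Fe", "HEM", 508, "A", (0, 0, 0)),
            _a(2, "CA", "C", "ARG", 212, "A", (10, 0, 0)),
        ]
        s = Structure(atoms)
        with pytest.raises(GeometryError, match="CZ"):
            arg212_orientation(Trajectory(s, s.coords[None]))


class TestMobilityVsGate:
    def _traj_with_substrate(self, n_frames, open_flags, jitter):
        """Gate fixture + ferryl O + one-atom substrate whose displacement
        amplitude is ``jitter[t]`` per frame."""
        traj, _ = make_gate_trajectory(n_frames, p_open=0.5, seed=0)
        flags = np.asarray(open_flags, bool)
        frames = traj.frames.copy()
        frames[:, 8:, 0] = frames[:, 8:, 0] * 0 + np.where(flags, 5.0, 9.0)[:, None] + (
            traj.frames[0, 8:, 0] - traj.frames[0, 8:, 0].mean()
        )
        extra = [
            _a(100, "O1", "O", "HEM", 508, "A", (0, 10, 0)),
            _a(101, "C1", "C", "WAR", 600, "A", (0, 13, 0)),
        ]
        s = Structure(list(traj.reference.atoms) + extra)
        full = np.concatenate(
            [frames, np.broadcast_to(s.coords[-2:], (n_frames, 2, 3)).copy()], axis=1
        )
        full[:, -1, 1] = 13.0 + jitter
        return Trajectory(s, full)

    def test_frozen_substrate_reports_undefined_correlation(self):
        n = 100
        flags = np.zeros(n, bool)
        flags[50:] = True
        traj = self._traj_with_substrate(n, flags, np.zeros(n))
        mc = mobility_vs_gate(traj, GATE_2B, [len(traj.reference) - 1],
                              len(traj.reference) - 2, window=25)
        assert np.allclose(mc.variances, 0)
        assert mc.rho is None

    def test_constructed_monotone_relation_gives_rho_1(self):
        n, w = 200, 50
        rng = np.random.default_rng(2)
        occupancy = np.repeat([0.0, 0.24, 0.72, 1.0], w)
        flags = np.zeros(n, bool)
        for k in range(4):
            block = slice(k * w, (k + 1) * w)
            n_open = int(occupancy[k * w] * w)
            flags[k * w: k * w + n_open] = True
        amp = np.repeat([0.0, 0.5, 1.5, 3.0], w)
        jitter = amp * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        traj = self._traj_with_substrate(n, flags, jitter)
        mc = mobility_vs_gate(traj, GATE_2B, [len(traj.reference) - 1],
                              len(traj.reference) - 2, window=w)
        assert mc.rho == pytest.approx(1.0)

    def test_window_longer_than_trajectory_rejected(self):
        traj = self._traj_with_substrate(40, np.zeros(40, bool), np.zeros(40))
        with pytest.raises(ValueError, match="shorter"):
            mobility_vs_gate(traj, GATE_2B, [len(traj.reference) - 1],
                             len(traj.reference) - 2, window=50)


class TestPoseRanking:
    def _pose(self, d):
        return Structure([
            _a(1, "FE", "Fe", "HEM", 508, "A", (0, 0, 0)),
            _a(2, "C10", "C", "WAR", 600, "A", (d, 0, 0)),
        ])

    def test_sorting_oracle(self):
        poses = [self._pose(d) for d in (4.0, 6.0, 5.0)]
        order = rank_poses_by_site_distance(
            poses, ("A", 600, "C10"), ("A", 508, "FE")
        )
        assert order == [1, 3, 2]

    def test_single_pose(self):
        assert rank_poses_by_site_distance(
            [self._pose(4.0)], ("A", 600, "C10"), ("A", 508, "FE")
        ) == [1]

    def test_ties_keep_input_order(self):
        poses = [self._pose(5.0), self._pose(5.0)]
        assert rank_poses_by_site_distance(
            poses, ("A", 600, "C10"), ("A", 508, "FE")
        ) == [1, 2]

    def test_missing_atom_names_pose(self):
        poses = [self._pose(5.0), Structure([self._pose(5.0).atoms[0]])]
        with pytest.raises(GeometryError, match="pose 2"):
            rank_poses_by_site_distance(poses, ("A", 600, "C10"), ("A", 508, "FE"))


def test_gate_tsv_layout(tmp_path):
    traj, _ = make_gate_trajectory(10, seed=0)
    trace = gate_trace(traj, GATE_2B)
    path = tmp_path / "gate.tsv"
    write_gate_tsv(trace, path)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "time_ns\td_A\topen"
    assert len(lines) == 11
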