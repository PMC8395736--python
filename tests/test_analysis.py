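"""Contact detection, class aggregation, segmentation, RMSF and R_g."""

import numpy as np
import pytest

from corona_lab.analysis import (
    ContactConfig,
    ContactProfile,
    ResidueClassification,
    average_profiles,
    classify_site,
    com_rmsd_trace,
    contact_probability,
    contact_residues,
    detect_three_steps,
    radius_of_gyration,
    rmsf,
)
from corona_lab.trajectory import Frame, Topology, Trajectory


def two_bead_system(separation):
    """One protein backbone bead and one ligand bead at a given distance."""
    top = Topology(
        molecule_id=[1, 2],
        residue_id=[1, 1],
        residue_type=["L", "MUS"],
        role=["backbone", "ligand"],
    )
    pos = np.array([[5.0, 5.0, 5.0], [5.0 + separation, 5.0, 5.0]])
    return top, Frame(0.0, pos, [20, 20, 20])


def random_mixed_system(rng, n_prot=30, n_np=40, box=6.0):
    roles = ["backbone" if i % 2 == 0 else "sidechain" for i in range(n_prot)]
    top = Topology(
        molecule_id=[1] * n_prot + [2] * n_np,
        residue_id=[i // 2 + 1 for i in range(n_prot)] + [1] * n_np,
        residue_type=["A"] * n_prot + ["MUS"] * n_np,
        role=roles + ["ligand"] * n_np,
    )
    pos = rng.uniform(0, box, (n_prot + n_np, 3))
    frame = Frame(0.0, pos, [box] * 3)
    np_sel = top.select(role="ligand")
    return top, frame, np_sel


class TestContactResidues:
    @pytest.mark.parametrize("sep,expected", [(0.44, {1}), (0.46, set())])
    def test_cutoff_boundary(self, sep, expected):
        top, frame = two_bead_system(sep)
        got = contact_residues(frame, top, top.select(role="ligand"))
        assert got == frozenset(expected)

    def test_matches_brute_force_on_random_frames(self, rng):
        """Exact equality with an all-pairs minimum-image scan, 50 frames."""
        from corona_lab.trajectory import minimum_image_distance

        for _ in range(50):
            top, frame, np_sel = random_mixed_system(rng)
            got = contact_residues(frame, top, np_sel)
            want = set()
            bb = np.where(top.select(role="backbone"))[0]
            nps = np.where(np_sel)[0]
            for i in bb:
                for j in nps:
                    d = minimum_image_distance(
                        frame.positions[i], frame.positions[j], frame.box
                    )
                    if d < 0.45:
                        want.add(int(top.residue_id[i]))
            assert got == frozenset(want)

    def test_invariant_under_rigid_transformation(self, rng):
        """Rotating and translating the whole system (far from the box
        boundary) leaves the contact set unchanged."""
        top = Topology(
            molecule_id=[1] * 6 + [2] * 6,
            residue_id=[1, 1, 2, 2, 3, 3] + [1] * 6,
            residue_type=["A"] * 6 + ["MUS"] * 6,
            role=["backbone", "sidechain"] * 3 + ["ligand"] * 6,
        )
        pos = rng.uniform(-0.8, 0.8, (12, 3))
        big_box = [100.0] * 3
        base = contact_residues(
            Frame(0.0, pos + 50.0, big_box), top, top.select(role="ligand")
        )
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        moved = pos @ R.T + np.array([1.3, -2.2, 0.4]) + 50.0
        assert contact_residues(
            Frame(0.0, moved, big_box), top, top.select(role="ligand")
        ) == base

    def test_empty_and_overlapping_selections_rejected(self):
        top, frame = two_bead_system(0.4)
        with pytest.raises(ValueError, match="empty"):
            contact_residues(frame, top, np.zeros(2, dtype=bool))
        with pytest.raises(ValueError, match="overlap"):
            contact_residues(
                frame, top, np.ones(2, dtype=bool), np.ones(2, dtype=bool)
            )


class TestContactProbability:
    def test_always_in_contact_gives_probability_one(self):
        top, frame = two_bead_system(0.3)
        traj = Trajectory(top, [Frame(float(t), frame.positions, frame.box) for t in range(4)])
        prof = contact_probability(traj, top.select(role="ligand"))
        assert prof.per_residue_probability[1] == 1.0
        assert prof.binding_site == frozenset({1})

    def test_per_type_percentages_count_binding_site(self):
        """Binding site {L, L, V, K} -> L 50%, V 25%, K 25%."""
        types = ["L", "L", "V", "K", "E"]
        n = len(types)
        top = Topology(
            molecule_id=[1] * n + [2],
            residue_id=list(range(1, n + 1)) + [1],
            residue_type=types + ["MUS"],
            role=["backbone"] * n + ["ligand"],
        )
        pos = np.full((n + 1, 3), 5.0)
        # residues 1-4 within cutoff, residue 5 far away
        for i in range(4):
            pos[i] = [5.0 + 0.2, 5.0, 5.0]
        pos[4] = [8.0, 8.0, 8.0]
        traj = Trajectory(top, [Frame(0.0, pos, [20] * 3)])
        prof = contact_probability(traj, top.select(role="ligand"))
        assert prof.binding_site == frozenset({1, 2, 3, 4})
        assert prof.per_type_percentage == {"L": 50.0, "V": 25.0, "K": 25.0}

    def test_replica_average_matches_hand_mean(self):
        mk = lambda p, site, types: ContactProfile(p, frozenset(site), types)
        replicas = [
            mk({1: 1.0, 2: 0.0}, {1}, {"L": 100.0}),
            mk({1: 0.5, 2: 0.5}, {1, 2}, {"L": 50.0, "K": 50.0}),
            mk({1: 0.0, 2: 1.0}, {2}, {"K": 100.0}),
        ]
        avg = average_profiles(replicas)
        assert avg.per_residue_probability == {1: 0.5, 2: 0.5}
        assert avg.per_type_percentage == {"K": 50.0, "L": 50.0}


class TestClassification:
    def test_classes_partition_the_twenty_residues(self):
        rc = ResidueClassification()
        assert sorted(rc.class_of) == sorted("ACDEFGHIKLMNPQRSTVWY")
        assert set(rc.class_of.values()) == {"hydrophobic", "charged", "polar", "others"}

    def test_class_percentages_conserve_type_total(self):
        prof = ContactProfile({}, frozenset(), {"L": 40.0, "K": 35.0, "S": 25.0})
        classes = classify_site(prof)
        assert sum(classes.values()) == pytest.approx(sum(prof.per_type_percentage.values()))
        assert classes == {
            "hydrophobic": 40.0, "charged": 35.0, "polar": 25.0, "others": 0.0
        }

    def test_all_zero_profile(self):
        classes = classify_site(ContactProfile({}, frozenset(), {}))
        assert set(classes.values()) == {0.0}

    def test_unknown_residue_code_rejected(self):
        prof = ContactProfile({}, frozenset(), {"X": 100.0})
        with pytest.raises(ValueError, match="unknown residue"):
            classify_site(prof)

    def test_incomplete_classification_rejected(self):
        with pytest.raises(ValueError, match="20 canonical"):
            ResidueClassification(class_of={"A": "hydrophobic"})


class TestComTrace:
    def test_static_protein_gives_constant_series(self):
        top = Topology([1, 1], [1, 2], ["A", "A"], ["backbone", "backbone"])
        pos = np.array([[3.0, 5, 5], [4.0, 5, 5]])
        traj = Trajectory(top, [Frame(float(t), pos, [10] * 3) for t in range(5)])
        trace = com_rmsd_trace(traj, np.ones(2, dtype=bool), reference=[5.0, 5.0, 5.0])
        assert len(trace) == 5
        assert np.allclose(trace, trace[0])

    def test_phase_means_match_scenario_standoffs(self, adsorption):
        # standoffs are defined from the particle's geometric center (the
        # box center), not its ligand-skewed center of mass
        res = adsorption
        trace = com_rmsd_trace(
            res.trajectory,
            res.protein_selection,
            reference=res.trajectory.frames[0].box / 2,
        )
        b1, b2 = res.breakpoints
        assert trace[b1:b2].mean() == pytest.approx(res.contact_standoff, abs=0.1)
        assert trace[b2:].mean() == pytest.approx(res.bound_standoff, abs=0.1)
        assert len(trace) == res.trajectory.n_frames


class TestThreeStepDetection:
    def test_noiseless_step_function(self):
        seg = detect_three_steps(np.array([5.0, 5, 3, 3, 1, 1, 1, 1, 1]))
        assert seg.breakpoints == (2, 4)
        assert seg.segment_means == (5.0, 3.0, 1.0)
        assert seg.sse == pytest.approx(0.0, abs=1e-12)
        assert not seg.degenerate

    def test_recovers_generator_breakpoints_within_tolerance(self, np_model):
        from corona_lab.synthetic import AdsorptionScenario, make_adsorption_trajectory, make_decoy_protein

        prot = make_decoy_protein(80, seed=2)
        hits = []
        for seed in range(5):
            res = make_adsorption_trajectory(
                prot, np_model, AdsorptionScenario(phase_durations=(40, 25, 60), seed=seed)
            )
            trace = com_rmsd_trace(
                res.trajectory, res.protein_selection, np_selection=res.np_selection
            )
            seg = detect_three_steps(trace)
            hits.append(
                abs(seg.breakpoints[0] - 40) <= 3 and abs(seg.breakpoints[1] - 65) <= 3
            )
        assert all(hits)

    def test_dp_beats_random_breakpoint_pairs(self, rng):
        y = np.concatenate(
            [rng.normal(8, 0.5, 40), rng.normal(5, 0.5, 30), rng.normal(2, 0.5, 50)]
        )
        seg = detect_three_steps(y)

        def sse_of(b1, b2):
            return sum(((s := y[a:b]) - s.mean()) @ (s - s.mean()) for a, b in ((0, b1), (b1, b2), (b2, len(y))))

        for _ in range(200):
            b1 = int(rng.integers(1, len(y) - 1))
            b2 = int(rng.integers(b1 + 1, len(y)))
            assert seg.sse <= sse_of(b1, b2) + 1e-9

    def test_two_level_trace_flagged_degenerate(self):
        seg = detect_three_steps(np.array([5.0] * 6 + [1.0] * 6))
        assert seg.degenerate

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="9 frames"):
            detect_three_steps(np.arange(8.0))


class TestRmsf:
    @staticmethod
    def _traj(coords_per_frame, types=None):
        n = coords_per_frame[0].shape[0]
        types = types or ["A"] * n
        top = Topology([1] * n, range(1, n + 1), types, ["backbone"] * n)
        return Trajectory(
            top,
            [Frame(float(t), c, [50] * 3) for t, c in enumerate(coords_per_frame)],
        )

    def test_rigid_translation_gives_zero_rmsf(self, rng):
        base = rng.normal(size=(10, 3))
        frames = [base + np.array([0.1 * t, -0.05 * t, 0.2 * t]) for t in range(20)]
        traj = self._traj(frames)
        fl = rmsf(traj, np.ones(10, dtype=bool), window=20)
        assert max(fl.values()) < 1e-10

    def test_rigid_rotation_gives_zero_rmsf(self, rng):
        base = rng.normal(size=(10, 3))
        frames = []
        for t in range(20):
            th = 0.05 * t
            R = np.array(
                [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
            )
            frames.append(base @ R.T + 3.0)
        fl = rmsf(self._traj(frames), np.ones(10, dtype=bool), window=20)
        assert max(fl.values()) < 1e-9

    def test_jittered_residue_matches_isotropic_expectation(self, rng):
        """One bead jittered with sigma s among many fixed anchors: its RMSF
        tends to s*sqrt(3) (the superposition absorbs a vanishing share of
        the motion as the anchor count grows)."""
        s = 0.05
        n_anchor = 40
        base = np.vstack([rng.normal(size=(n_anchor, 3)) * 2.0, [[0.5, 0.5, 0.5]]])
        frames = []
        for _ in range(10_000):
            c = base.copy()
            c[-1] += rng.normal(scale=s, size=3)
            frames.append(c)
        fl = rmsf(self._traj(frames), np.ones(n_anchor + 1, dtype=bool), window=10_000)
        assert fl[n_anchor + 1] == pytest.approx(s * np.sqrt(3), rel=0.1)
        assert max(fl[r] for r in range(1, n_anchor + 1)) < 0.2 * fl[n_anchor + 1]

    def test_bound_patch_less_mobile_than_free_tail(self, rng):
        """Two-domain decoy: rigid 'bound' half, strongly jittered free half."""
        base = rng.normal(size=(12, 3)) * 2.0
        frames = []
        for _ in range(200):
            c = base.copy()
            c[6:] += rng.normal(scale=0.15, size=(6, 3))
            frames.append(c)
        fl = rmsf(self._traj(frames), np.ones(12, dtype=bool), window=200)
        bound = np.mean([fl[r] for r in range(1, 7)])
        free = np.mean([fl[r] for r in range(7, 13)])
        assert bound < 0.5 * free

    def test_window_validation(self):
        traj = self._traj([np.zeros((3, 3)), np.ones((3, 3))])
        with pytest.raises(ValueError, match="at least 2"):
            rmsf(traj, np.ones(3, dtype=bool), window=1)
        with pytest.raises(ValueError, match="longer than"):
            rmsf(traj, np.ones(3, dtype=bool), window=5)


class TestRadiusOfGyration:
    def test_single_bead_is_zero(self):
        top = Topology([1], [1], ["A"], ["backbone"])
        assert radius_of_gyration(Frame(0.0, np.zeros((1, 3))), top) == 0.0

    def test_two_unit_masses_two_nm_apart(self):
        top = Topology([1, 1], [1, 2], ["A", "A"], ["backbone", "backbone"], mass=[1, 1])
        f = Frame(0.0, [[0, 0, 0], [2, 0, 0]])
        assert radius_of_gyration(f, top) == pytest.approx(1.0)

    def test_matches_direct_sum_on_random_cloud(self, rng):
        n = 40
        m = rng.uniform(10, 100, n)
        pos = rng.normal(size=(n, 3)) * 1.5
        top = Topology([1] * n, range(1, n + 1), ["A"] * n, ["backbone"] * n, mass=m)
        com = (m[:, None] * pos).sum(axis=0) / m.sum()
        want = np.sqrt((m * ((pos - com) ** 2).sum(axis=1)).sum() / m.sum())
        assert radius_of_gyration(Frame(0.0, pos), top) == pytest.approx(want)
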