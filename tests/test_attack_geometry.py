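import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import sitewater as sw
from sitewater.attack_geometry import (
    HBondPartner,
    PRE_R,
    PRE_S,
    UNDEFINED,
    coordination_label,
)
from sitewater.errors import DegenerateGeometryError
from sitewater.trajectory_io import Frame

from helpers import TRIGONAL_SUBS, toy_topology, toy_trajectory, trigonal_frame

TOY_CONVENTION = sw.FaceConvention(
    center="name C3",
    substituents=("name S1", "name S2", "name S3"),
    positive_face_label=PRE_S,
)


class TestFaceNormal:
    def test_planar_construction(self):
        top, frame = trigonal_frame([0, 0, 2.0])
        normal, dev = sw.face_normal(frame, 0, (1, 2, 3))
        np.testing.assert_allclose(normal, [0, 0, 1], atol=1e-12)
        assert dev == pytest.approx(0.0, abs=1e-12)

    def test_substituent_swap_flips_normal(self):
        top, frame = trigonal_frame([0, 0, 2.0])
        normal, _ = sw.face_normal(frame, 0, (2, 1, 3))
        np.testing.assert_allclose(normal, [0, 0, -1], atol=1e-12)

    def test_pyramidalised_centre_deviation(self):
        top, frame = trigonal_frame([0, 0, 2.0], center_lift=0.3)
        _, dev = sw.face_normal(frame, 0, (1, 2, 3))
        assert dev == pytest.approx(0.3, abs=1e-12)

    def test_collinear_substituents_degenerate(self):
        top = toy_topology(
            [("C3", "LIG", 1), ("S1", "LIG", 1), ("S2", "LIG", 1), ("S3", "LIG", 1)]
        )
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(DegenerateGeometryError):
            sw.face_normal(Frame(coordinates=coords), 0, (1, 2, 3))


class TestClassifyFace:
    def test_positive_side_gets_positive_label(self):
        top, frame = trigonal_frame([0, 0, 2.0])
        assert sw.classify_face(frame, top, TOY_CONVENTION, 4) == PRE_S

    def test_negative_side_gets_opposite_label(self):
        top, frame = trigonal_frame([0, 0, -2.0])
        assert sw.classify_face(frame, top, TOY_CONVENTION, 4) == PRE_R

    def test_rotation_invariance(self):
        top, frame = trigonal_frame([0.3, -0.2, 2.5])
        rots = Rotation.random(1000, random_state=42)
        for rot in rots:
            rotated = Frame(coordinates=rot.apply(frame.coordinates))
            assert sw.classify_face(rotated, top, TOY_CONVENTION, 4) == PRE_S

    def test_translation_invariance(self):
        top, frame = trigonal_frame([0.3, -0.2, 2.5])
        shifted = Frame(coordinates=frame.coordinates + np.array([10.0, -5.0, 3.0]))
        assert sw.classify_face(shifted, top, TOY_CONVENTION, 4) == PRE_S

    def test_mirror_reflection_flips_label(self):
        top, frame = trigonal_frame([0.3, -0.2, 2.5])
        mirrored = Frame(coordinates=frame.coordinates * np.array([1.0, 1.0, -1.0]))
        assert sw.classify_face(mirrored, top, TOY_CONVENTION, 4) == PRE_R

    def test_substituent_transposition_flips_label(self):
        top, frame = trigonal_frame([0, 0, 2.0])
        swapped = sw.FaceConvention(
            center="name C3",
            substituents=("name S2", "name S1", "name S3"),
            positive_face_label=PRE_S,
        )
        assert sw.classify_face(frame, top, swapped, 4) == PRE_R

    def test_grazing_approach_undefined(self):
        top, frame = trigonal_frame([2.5, 0.5, 0.05])  # essentially in-plane
        assert sw.classify_face(frame, top, TOY_CONVENTION, 4) == UNDEFINED

    def test_pyramidalised_centre_undefined(self):
        top, frame = trigonal_frame([0, 0, 2.0], center_lift=0.4)
        assert sw.classify_face(frame, top, TOY_CONVENTION, 4) == UNDEFINED


class TestHBondPartners:
    def _water_frame(self, acceptor_pos, h_toward=None):
        top = toy_topology(
            [("O", "HOH", 100, "W"), ("H1", "HOH", 100, "W"), ("OD1", "ASP", 5)]
        )
        o = np.zeros(3)
        acc = np.asarray(acceptor_pos, dtype=float)
        if h_toward is None:
            h = np.array([0.3, 0.9, 0.0])
        else:
            h = 0.97 * (np.asarray(h_toward) / np.linalg.norm(h_toward))
        return top, Frame(coordinates=np.vstack([o, h, acc]))

    def test_aligned_short_contact_is_partner(self):
        top, frame = self._water_frame([2.8, 0, 0], h_toward=[1, 0, 0])
        partners = sw.hbond_partners(frame, top, 0, [(2, "acid")])
        assert len(partners) == 1
        assert partners[0].kind == "acid"
        assert partners[0].angle == pytest.approx(180.0, abs=1.0)

    def test_long_contact_is_not_partner(self):
        top, frame = self._water_frame([4.0, 0, 0], h_toward=[1, 0, 0])
        assert sw.hbond_partners(frame, top, 0, [(2, "acid")]) == []

    def test_bent_geometry_fails_angle_criterion(self):
        # H points perpendicular to the O->acceptor direction: angle ~94 deg
        top, frame = self._water_frame([2.8, 0, 0], h_toward=[0, 1, 0])
        assert sw.hbond_partners(frame, top, 0, [(2, "acid")]) == []

    def test_without_hydrogens_distance_only_with_warning(self):
        top = toy_topology([("O", "HOH", 100, "W"), ("OD1", "ASP", 5)])
        frame = Frame(coordinates=np.array([[0, 0, 0], [2.8, 0, 0]], dtype=float))
        with pytest.warns(UserWarning, match="no hydrogens"):
            partners = sw.hbond_partners(frame, top, 0, [(1, "acid")])
        assert len(partners) == 1 and partners[0].angle is None


class TestCoordinationLabel:
    @pytest.mark.parametrize(
        "kinds,expected",
        [
            (["ppi"], "ppi_only"),
            (["ppi", "acid"], "ppi_plus_acid"),
            (["acid"], "acid_only"),
            ([], "uncoordinated"),
            (["ppi", "other"], "ppi_only"),
        ],
    )
    def test_labels(self, kinds, expected):
        partners = [HBondPartner(atom=f"X:{i}:A", kind=k, distance=3.0, angle=None)
                    for i, k in enumerate(kinds)]
        assert coordination_label(partners) == expected


class TestDeprotonationDistances:
    def _toy(self, o_positions, h_positions):
        assert len(o_positions) <= 3  # site selector names O1..O3
        entries = (
            [("C15", "FDP", 1)]
            + [(f"H15{chr(65 + i)}", "FDP", 1) for i in range(len(h_positions))]
            + [(f"O{i + 1}", "POP", 2) for i in range(len(o_positions))]
        )
        top = toy_topology(entries)
        coords = np.vstack(
            [np.zeros(3)] + [np.asarray(h) for h in h_positions]
            + [np.asarray(o) for o in o_positions]
        )
        return toy_trajectory(top, [coords])

    def test_single_pair(self, site):
        traj = self._toy([[2.5, 0, 0]], [[0, 0, 0]])
        s = sw.deprotonation_distances(traj, site)
        assert s.values[0] == pytest.approx(2.5)

    def test_min_over_oxygens(self, site):
        traj = self._toy([[3.0, 0, 0], [0, 2.0, 0]], [[0, 0, 0]])
        s = sw.deprotonation_distances(traj, site)
        assert s.values[0] == pytest.approx(2.0)

    def test_matches_brute_force_on_random_sets(self, site):
        rng = np.random.default_rng(11)
        o_pos = rng.uniform(-5, 5, (3, 3))
        h_pos = rng.uniform(-5, 5, (3, 3))
        traj = self._toy(list(o_pos), list(h_pos))
        s = sw.deprotonation_distances(traj, site)
        oracle = min(
            float(np.linalg.norm(o - h)) for o in o_pos for h in h_pos
        )
        assert s.values[0] == pytest.approx(oracle, abs=1e-9)

    def test_missing_roles_is_spec_error(self):
        top = toy_topology([("C3", "FDP", 1)])
        traj = toy_trajectory(top, [np.zeros((1, 3))])
        with pytest.raises(sw.SiteSpecError):
            sw.deprotonation_distances(traj, sw.synthetic_sitespec())


class TestSummarizeAttacks:
    def test_pure_preS_construction(self, site, convention):
        cfg = sw.SyntheticConfig(
            n_frames=150, n_replicas=1, seed=6,
            attack=sw.AttackParams(p_preS=1.0, approach_rate=0.5),
        )
        traj = sw.generate_carbocation_trajectory(cfg, 0)
        summary = sw.summarize_attacks(traj, site, convention)
        assert summary.n_events > 0
        assert summary.frac_preS == 1.0
        assert summary.face_counts[PRE_R] == 0

    def test_no_events_summary(self, site, convention):
        cfg = sw.SyntheticConfig(
            n_frames=60, n_replicas=1, seed=6,
            attack=sw.AttackParams(approach_rate=0.0),
        )
        traj = sw.generate_carbocation_trajectory(cfg, 0)
        summary = sw.summarize_attacks(traj, site, convention)
        assert summary.n_events == 0
        assert summary.frac_preS is None
        assert summary.events == []

    def test_coordination_by_face_structure(self, site, convention, small_config):
        traj = sw.generate_carbocation_trajectory(small_config, 0)
        summary = sw.summarize_attacks(traj, site, convention)
        # generator geometry: every pre-R approach H-bonds the PPi flank only
        assert set(summary.coordination_by_face.get(PRE_R, {})) <= {"ppi_only"}
        total = sum(
            c for t in summary.coordination_by_face.values() for c in t.values()
        )
        assert total == summary.n_events
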