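import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sitewater as sw
from sitewater.errors import ConsistencyError, FormatError, SelectionError
from sitewater.trajectory_io import Frame, infer_element, max_safe_cutoff

from helpers import (
    brute_force_min_image,
    random_triclinic_cell,
    toy_topology,
    toy_trajectory,
)

WATER_PDB = """\
ATOM      1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
ATOM      2  H1  HOH A   1       0.957   0.000   0.000  1.00  0.00           H
ATOM      3  H2  HOH A   1      -0.240   0.927   0.000  1.00  0.00           H
END
"""

# element columns left blank: elements must be inferred from names
BLANK_ELEMENT_PDB = """\
ATOM      1  C1  LIG A   1       0.000   0.000   0.000  1.00  0.00
ATOM      2  OW  HOH A   2       3.000   0.000   0.000  1.00  0.00
END
"""


class TestLoadTopology:
    def test_parses_handwritten_water(self, tmp_path):
        p = tmp_path / "water.pdb"
        p.write_text(WATER_PDB)
        top = sw.load_topology(p)
        assert top.n_atoms == 3
        assert [a.element for a in top.atoms] == ["O", "H", "H"]
        assert [a.serial for a in top.atoms] == [1, 2, 3]
        assert top.atoms[0].residue_name == "HOH"

    def test_infers_elements_from_names_when_column_blank(self, tmp_path):
        p = tmp_path / "blank.pdb"
        p.write_text(BLANK_ELEMENT_PDB)
        top = sw.load_topology(p)
        assert [a.element for a in top.atoms] == ["C", "O"]

    def test_empty_file_is_format_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises((FormatError, IOError)):
            sw.load_topology(p)

    def test_missing_file_is_io_error(self, tmp_path):
        with pytest.raises(IOError):
            sw.load_topology(tmp_path / "nope.pdb")

    @pytest.mark.parametrize(
        "name,element",
        [("C1", "C"), ("OW", "O"), ("H15A", "H"), ("1HB", "H"), ("MG", "Mg"),
         ("CL", "Cl"), ("OE1", "O")],
    )
    def test_element_inference_table(self, name, element):
        assert infer_element(name) == element


class TestRoundTrips:
    @pytest.fixture()
    def water_traj(self):
        top = toy_topology([("O", "HOH", 1), ("H1", "HOH", 1), ("H2", "HOH", 1)])
        c0 = [[0, 0, 0], [0.957, 0, 0], [-0.24, 0.927, 0]]
        c1 = [[1, 2, 3], [1.957, 2, 3], [0.76, 2.927, 3]]
        return toy_trajectory(top, [c0, c1])

    def test_two_model_pdb_loads_two_frames(self, tmp_path, water_traj):
        p = sw.write_trajectory(water_traj, tmp_path / "w.pdb", "multimodel-pdb")
        top = sw.load_topology(p)
        traj = sw.load_trajectory(p, top, "multimodel-pdb")
        assert traj.n_frames == 2
        for a, b in zip(traj.frames, water_traj.frames):
            np.testing.assert_allclose(a.coordinates, b.coordinates, atol=1e-3)

    def test_xyz_roundtrip_to_1e6(self, tmp_path, water_traj):
        p = sw.write_trajectory(water_traj, tmp_path / "w.xyz", "xyz-frames")
        traj = sw.load_trajectory(p, water_traj.topology, "xyz-frames")
        assert traj.n_frames == water_traj.n_frames
        for a, b in zip(traj.frames, water_traj.frames):
            np.testing.assert_allclose(a.coordinates, b.coordinates, atol=1e-6)

    def test_synthetic_suite_roundtrip_preserves_counts(self, tmp_path):
        cfg = sw.SyntheticConfig(n_frames=50, n_replicas=1, seed=5)
        traj = sw.generate_variant_trajectory(cfg, 0)
        p = sw.write_trajectory(traj, tmp_path / "s.pdb", "multimodel-pdb")
        top = sw.load_topology(p)
        back = sw.load_trajectory(p, top, "multimodel-pdb")
        assert back.n_frames == traj.n_frames
        assert back.topology.n_atoms == traj.topology.n_atoms
        err = max(
            np.abs(a.coordinates - b.coordinates).max()
            for a, b in zip(back.frames, traj.frames)
        )
        assert err < 1e-3

    def test_many_frame_file_has_one_model_per_frame(self, tmp_path):
        cfg = sw.SyntheticConfig(n_frames=1000, n_replicas=1, seed=5)
        traj = sw.generate_cyclization_trajectory(cfg, 0)
        p = sw.write_trajectory(traj, tmp_path / "big.pdb", "multimodel-pdb")
        n_models = sum(1 for line in open(p) if line.startswith("MODEL"))
        assert n_models == 1000

    def test_zero_frame_trajectory_rejected(self):
        top = toy_topology([("O", "HOH", 1)])
        with pytest.raises(ConsistencyError):
            sw.Trajectory(topology=top, frames=[])

    def test_atom_count_mismatch_is_consistency_error(self, tmp_path):
        top4 = toy_topology([("O", "HOH", i) for i in range(1, 5)])
        traj = toy_trajectory(top4, [np.zeros((4, 3))])
        p = sw.write_trajectory(traj, tmp_path / "four.xyz", "xyz-frames")
        top3 = toy_topology([("O", "HOH", i) for i in range(1, 4)])
        with pytest.raises(ConsistencyError):
            sw.load_trajectory(p, top3, "xyz-frames")

    def test_dcd_reader_and_mismatch(self, tmp_path):
        import warnings

        import MDAnalysis as mda

        top = toy_topology([("O", "HOH", i) for i in range(1, 5)])
        coords = np.arange(12, dtype=float).reshape(4, 3)
        u = mda.Universe.empty(4, trajectory=True)
        p = tmp_path / "t.dcd"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.Writer(str(p), 4) as w:
                u.atoms.positions = coords
                w.write(u.atoms)
        traj = sw.load_trajectory(p, top, "dcd")
        np.testing.assert_allclose(traj.frames[0].coordinates, coords, atol=1e-4)
        top3 = toy_topology([("O", "HOH", i) for i in range(1, 4)])
        with pytest.raises(ConsistencyError):
            sw.load_trajectory(p, top3, "dcd")

    def test_truncated_xyz_names_frame_index(self, tmp_path):
        p = tmp_path / "trunc.xyz"
        p.write_text("2 2\n# frame 0\nO 0 0 0\nO 1 1 1\n# frame 1\nO 0 0 0\n")
        top = toy_topology([("O", "HOH", 1), ("O", "HOH", 2)])
        with pytest.raises(FormatError, match="frame 1"):
            sw.load_trajectory(p, top, "xyz-frames")


class TestSelections:
    @pytest.fixture(scope="class")
    def toy(self):
        return toy_topology(
            [
                ("C11", "LIG", 1),
                ("C3", "LIG", 1),
                ("O", "HOH", 2, "W"),
                ("H1", "HOH", 2, "W"),
                ("O", "HOH", 3, "W"),
                ("H1", "HOH", 3, "W"),
            ]
        )

    def test_water_oxygens(self, toy):
        assert sw.resolve_selection(toy, "resname HOH and name O") == [2, 4]

    def test_single_name(self, toy):
        assert sw.resolve_selection(toy, "name C11") == [0]

    def test_resid_range_and_chain(self, toy):
        assert sw.resolve_selection(toy, "resid 2:3 and element O") == [2, 4]
        assert sw.resolve_selection(toy, "chain W and element H") == [3, 5]

    def test_empty_result_allowed(self, toy):
        assert sw.resolve_selection(toy, "resname XYZ") == []

    @pytest.mark.parametrize(
        "bad", ["name ((", "", "and name O", "name", "bogus C1", "name O and"]
    )
    def test_malformed_selector_raises(self, toy, bad):
        with pytest.raises(SelectionError):
            sw.resolve_selection(toy, bad)

    def test_deterministic_topology_order(self, toy):
        a = sw.resolve_selection(toy, "resname HOH and name O")
        b = sw.resolve_selection(toy, "name O and resname HOH")
        assert a == b == sorted(a)


class TestMinimumImage:
    def test_three_four_five_without_box(self):
        fr = Frame(coordinates=np.array([[0.0, 0, 0], [3, 4, 0]]))
        assert sw.minimum_image_distance(fr, 0, 1) == pytest.approx(5.0)

    def test_orthorhombic_wrap(self):
        fr = Frame(
            coordinates=np.array([[1.0, 0, 0], [9, 0, 0]]), box=np.eye(3) * 10
        )
        assert sw.minimum_image_distance(fr, 0, 1) == pytest.approx(2.0)

    def test_matches_brute_force_on_random_triclinic_cells(self):
        rng = np.random.default_rng(20240901)
        for _ in range(200):
            box = random_triclinic_cell(rng)
            pts = rng.uniform(0, 1, (2, 3)) @ box
            fr = Frame(coordinates=pts, box=box)
            impl = sw.minimum_image_distance(fr, 0, 1)
            oracle = brute_force_min_image(pts[1] - pts[0], box)
            assert impl == pytest.approx(oracle, abs=1e-9)
            assert impl == pytest.approx(
                sw.minimum_image_distance(fr, 1, 0), abs=1e-12
            )  # symmetry

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-20, 20), min_size=6, max_size=6))
    def test_huge_box_agrees_with_unboxed(self, flat):
        pts = np.array(flat).reshape(2, 3)
        boxed = Frame(coordinates=pts, box=np.eye(3) * 1e4)
        free = Frame(coordinates=pts)
        assert sw.minimum_image_distance(boxed, 0, 1) == pytest.approx(
            sw.minimum_image_distance(free, 0, 1), abs=1e-9
        )

    def test_index_out_of_range(self):
        fr = Frame(coordinates=np.zeros((2, 3)))
        with pytest.raises(IndexError):
            sw.minimum_image_distance(fr, 0, 5)

    def test_max_safe_cutoff_orthorhombic(self):
        assert max_safe_cutoff(np.diag([10.0, 12.0, 14.0])) == pytest.approx(5.0)
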