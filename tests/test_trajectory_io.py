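"""Coordinate I/O, periodic geometry and topology contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import kbsolv as kb
from kbsolv.trajectory_io import StructureError, TrajectoryParseError


def brute_force_min_image(a, b, lengths):
    """Shortest |a - b + n*L| over all 27 neighbour images."""
    best = np.inf
    for ix in (-1, 0, 1):
        for iy in (-1, 0, 1):
            for iz in (-1, 0, 1):
                shift = np.array([ix, iy, iz]) * lengths
                best = min(best, np.linalg.norm(a - b + shift))
    return best


class TestBoxAndMinimumImage:
    def test_box_requires_positive_lengths(self):
        with pytest.raises(ValueError):
            kb.Box([1.0, -1.0, 1.0])

    def test_axis_wraparound(self):
        box = kb.Box([10.0, 10.0, 10.0])
        d = kb.minimum_image_distance(np.array([1.0, 0, 0]), np.array([9.0, 0, 0]), box)
        assert d == pytest.approx(2.0, abs=1e-14)

    def test_identical_points(self):
        box = kb.Box([10.0, 10.0, 10.0])
        a = np.array([3.0, 4.0, 5.0])
        assert kb.minimum_image_distance(a, a, box) == 0.0

    def test_matches_27_image_brute_force(self, rng):
        box = kb.Box([3.0, 5.0, 7.0])
        for _ in range(100):
            a = rng.uniform(0, box.lengths)
            b = rng.uniform(0, box.lengths)
            assert kb.minimum_image_distance(a, b, box) == pytest.approx(
                brute_force_min_image(a, b, box.lengths), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_symmetry(self, seed):
        local = np.random.default_rng(seed)
        box = kb.Box([4.0, 4.0, 4.0])
        a, b = local.uniform(0, 4, size=(2, 3))
        assert kb.minimum_image_distance(a, b, box) == pytest.approx(
            kb.minimum_image_distance(b, a, box), abs=1e-14)


class TestCenterOfMass:
    def _frame_topo(self, coords, masses):
        rows = [("C", m, 0.15, 0, "mol", "none") for m in masses]
        topo = kb.Topology(pd.DataFrame(
            rows, columns=["element", "mass", "vdw_radius", "molecule_id",
                           "species_name", "hb_role"]))
        frame = kb.Frame(np.asarray(coords, dtype=float), 0.0, kb.Box([10.0] * 3))
        return frame, topo

    def test_equal_masses_midpoint(self):
        frame, topo = self._frame_topo([[0, 0, 0], [2, 0, 0]], [1.0, 1.0])
        assert kb.center_of_mass(frame, 0, topo) == pytest.approx([1, 0, 0])

    def test_weighted_mean(self):
        frame, topo = self._frame_topo([[0, 0, 0], [4, 0, 0]], [1.0, 3.0])
        assert kb.center_of_mass(frame, 0, topo)[0] == pytest.approx(3.0)

    def test_molecule_split_across_boundary(self):
        frame, topo = self._frame_topo([[9.9, 1, 1], [0.1, 1, 1]], [1.0, 1.0])
        com = kb.center_of_mass(frame, 0, topo)
        assert com[0] == pytest.approx(0.0, abs=1e-12) or com[0] == pytest.approx(10.0)

    def test_zero_total_mass_rejected(self):
        frame, topo = self._frame_topo([[1, 1, 1]], [0.0])
        with pytest.raises(ValueError, match="mass"):
            kb.center_of_mass(frame, 0, topo)

    def test_translation_equivariance_mod_box(self, rng):
        coords = rng.uniform(0, 10, size=(4, 3))
        frame, topo = self._frame_topo(coords, [1.0, 2.0, 3.0, 4.0])
        com = kb.center_of_mass(frame, 0, topo)
        shift = np.array([3.7, 8.1, 0.4])
        shifted = kb.Frame(np.mod(coords + shift, 10.0), 0.0, frame.box)
        com2 = kb.center_of_mass(shifted, 0, topo)
        delta = np.mod(com2 - com - shift, 10.0)
        delta = np.minimum(delta, 10.0 - delta)
        assert np.allclose(delta, 0.0, atol=1e-9)


class TestRoundTrips:
    @pytest.mark.parametrize("fmt,atol", [("gro", 6e-4), ("xyz", 1e-8),
                                          ("pdb", 6e-5)])
    def test_write_then_read(self, tmp_path, tiny_trajectory, fmt, atol):
        path = tmp_path / f"traj.{fmt}"
        kb.write_trajectory(tiny_trajectory, path)
        back = kb.read_trajectory(path, topology=tiny_trajectory.topology,
                                  box=tiny_trajectory.box)
        assert back.n_frames == tiny_trajectory.n_frames
        assert np.allclose(back.coords, tiny_trajectory.coords, atol=atol)

    def test_gro_box_line(self, tmp_path):
        path = tmp_path / "one.gro"
        path.write_text("title\n1\n    1MOL     X    1   1.000   2.000   3.000\n"
                        "  10.00000  10.00000  10.00000\n")
        traj = kb.read_trajectory(path)
        assert np.allclose(traj.box.lengths, [10.0, 10.0, 10.0])
        assert np.allclose(traj.coords[0, 0], [1.0, 2.0, 3.0])

    def test_xyz_requires_box(self, tmp_path, tiny_trajectory):
        path = tmp_path / "traj.xyz"
        kb.write_trajectory(tiny_trajectory, path)
        with pytest.raises(ValueError, match="box"):
            kb.read_trajectory(path)

    def test_atom_count_change_is_structural_error(self, tmp_path):
        frame1 = ("t\n3\n" + "    1MOL     X    1   1.000   1.000   1.000\n" * 3
                  + "  10.0 10.0 10.0\n")
        frame2 = ("t\n4\n" + "    1MOL     X    1   1.000   1.000   1.000\n" * 4
                  + "  10.0 10.0 10.0\n")
        path = tmp_path / "bad.gro"
        path.write_text(frame1 + frame2)
        with pytest.raises(StructureError, match="atoms"):
            kb.read_trajectory(path)

    def test_malformed_record_names_line(self, tmp_path):
        path = tmp_path / "bad.gro"
        path.write_text("t\n1\n    1MOL     X    1   x.000   1.000   1.000\n"
                        "  10.0 10.0 10.0\n")
        with pytest.raises(TrajectoryParseError, match=r":3"):
            kb.read_trajectory(path)

    def test_topology_atom_count_cross_check(self, tmp_path, tiny_trajectory):
        path = tmp_path / "traj.gro"
        kb.write_trajectory(tiny_trajectory, path)
        wrong = kb.monatomic_topology({"alpha": 2})
        with pytest.raises(StructureError):
            kb.read_trajectory(path, topology=wrong)


class TestTopology:
    def test_sidecar_round_trip(self, tmp_path, hb_scene_pair):
        _, topo = hb_scene_pair
        path = tmp_path / "topology.tsv"
        topo.write(path)
        back = kb.Topology.read(path)
        pd.testing.assert_frame_equal(back.table, topo.table, check_dtype=False)
        assert back.bonded_hydrogens == topo.bonded_hydrogens

    def test_hydrogen_under_two_donors_rejected(self):
        df = pd.DataFrame({
            "element": ["O", "O", "H"], "mass": [16.0, 16.0, 1.0],
            "vdw_radius": [0.15, 0.15, 0.11], "molecule_id": [0, 0, 0],
            "species_name": ["m", "m", "m"],
            "hb_role": ["donor-heavy", "donor-heavy", "hydrogen"]})
        with pytest.raises(ValueError, match="two donors"):
            kb.Topology(df, {0: [2], 1: [2]})

    def test_orphan_hydrogen_rejected(self):
        df = pd.DataFrame({
            "element": ["H"], "mass": [1.0], "vdw_radius": [0.11],
            "molecule_id": [0], "species_name": ["m"], "hb_role": ["hydrogen"]})
        with pytest.raises(ValueError, match="without a donor"):
            kb.Topology(df)

    def test_empty_species_rejected(self):
        df = pd.DataFrame({
            "element": ["C"], "mass": [12.0], "vdw_radius": [0.17],
            "molecule_id": [0], "species_name": [""], "hb_role": ["none"]})
        with pytest.raises(ValueError, match="species_name"):
            kb.Topology(df)


class TestSelection:
    def test_unknown_species_errors(self, tiny_trajectory):
        sel = kb.Selection("missing", granularity="atom")
        with pytest.raises(ValueError, match="no atoms"):
            sel.atom_indices(tiny_trajectory.topology)

    def test_atom_name_filter(self, hb_scene_pair):
        _, topo = hb_scene_pair
        sel = kb.Selection("donor_mol", granularity="atom", atom_names=("H",))
        assert len(sel.atom_indices(topo)) == 2  # one H per scene geometry

    def test_com_granularity_counts_molecules(self, tiny_trajectory):
        sel = kb.Selection("alpha", granularity="molecule-COM")
        assert sel.n_sites(tiny_trajectory.topology) == 3
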