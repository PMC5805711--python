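"""Structure parsing, Kabsch superposition, backbone RMSD and contacts.

All coordinate fixtures are synthetic, generated programmatically.
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from titrakit import (
    contact_distances,
    pair_rmsd,
    read_structure,
    select_backbone,
    superpose,
)
from _oracles import grid_superpose_rmsd
from conftest import synthetic_protein_coords, write_synthetic_pdb


@pytest.fixture()
def protein_pair(tmp_path, rng):
    """Two synthetic 76-residue single-chain models, B = perturbed copy of A."""
    residues = synthetic_protein_coords(76, rng)
    path_a = write_synthetic_pdb(tmp_path / "synthetic_a.pdb", {"A": residues})
    R = Rotation.from_euler("zyx", [40, -25, 70], degrees=True).as_matrix()
    shifted = []
    for resnum, resname, atoms in residues:
        new_atoms = []
        for name, x, y, z, occ, alt in atoms:
            pos = R @ np.array([x, y, z]) + np.array([5.0, -3.0, 8.0])
            # perturb the flexible tail more strongly than the core
            pos += rng.normal(0, 1.0 if resnum >= 74 else 0.2, 3)
            new_atoms.append((name, *pos, occ, alt))
        shifted.append((resnum, resname, new_atoms))
    path_b = write_synthetic_pdb(tmp_path / "synthetic_b.pdb", {"A": shifted})
    return read_structure(path_a), read_structure(path_b)


class TestReadStructure:
    def test_minimal_three_atom_fixture(self, tmp_path):
        path = write_synthetic_pdb(
            tmp_path / "mini.pdb",
            {"A": [(1, "GLY", [("N", 0.0, 0.0, 0.0, 1.0, " "),
                               ("CA", 1.5, 0.0, 0.0, 1.0, " "),
                               ("C", 2.2, 1.2, 0.0, 1.0, " ")])]},
        )
        model = read_structure(path)
        residues = model.polymer_residues("A")
        assert len(residues) == 1
        assert len(residues[0]) == 3

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        path = write_synthetic_pdb(
            tmp_path / "alt.pdb",
            {"A": [(1, "SER", [("N", 0.0, 0.0, 0.0, 1.0, " "),
                               ("CA", 1.5, 0.0, 0.0, 1.0, " "),
                               ("OG", 3.0, 0.0, 0.0, 0.4, "A"),
                               ("OG", 4.0, 0.0, 0.0, 0.6, "B")])]},
        )
        model = read_structure(path)
        pos = model.atom_pos("A", 1, "OG")
        assert pos[0] == pytest.approx(4.0)  # occupancy 0.6 wins

    def test_altloc_tie_prefers_a(self, tmp_path):
        path = write_synthetic_pdb(
            tmp_path / "tie.pdb",
            {"A": [(1, "SER", [("OG", 3.0, 0.0, 0.0, 0.5, "A"),
                               ("OG", 4.0, 0.0, 0.0, 0.5, "B")])]},
        )
        model = read_structure(path)
        assert model.atom_pos("A", 1, "OG")[0] == pytest.approx(3.0)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "nope.pdb")


class TestSelectBackbone:
    @pytest.mark.parametrize(
        "residue_range,atom_set,expected",
        [((1, 76), "N-CA-C-O", 304), ((1, 73), "N-CA-C-O", 292),
         ((74, 76), "N-CA-C-O", 12), ((1, 76), "N-CA-C", 228)],
    )
    def test_complete_chain_counts(self, protein_pair, residue_range, atom_set, expected):
        model, _ = protein_pair
        sel = select_backbone(model, "A", residue_range, atom_set)
        assert len(sel) == expected

    def test_empty_selection_rejected(self, protein_pair):
        model, _ = protein_pair
        with pytest.raises(ValueError, match="empty"):
            select_backbone(model, "A", (200, 300))


class TestSuperpose:
    def test_identity(self, rng):
        pts = rng.normal(0, 5, (10, 3))
        result = superpose(pts, pts)
        assert result.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(result.rotation, np.eye(3), atol=1e-12)

    def test_rigid_transform_invariance(self, rng):
        pts = rng.normal(0, 5, (15, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ R.T + np.array([1.0, 2.0, 3.0])
        result = superpose(pts, moved)
        assert result.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.linalg.det(result.rotation) == pytest.approx(1.0)

    def test_reflection_guard(self):
        # mirrored set must NOT be fit with a reflection: rmsd stays positive
        pts = np.array([[0, 0, 0], [2, 0, 0], [0, 1.5, 0], [0.3, 0.2, 1.0]])
        mirrored = pts * np.array([1, 1, -1])
        result = superpose(pts, mirrored)
        assert np.linalg.det(result.rotation) == pytest.approx(1.0)
        assert result.rmsd > 0.1

    def test_small_instance_matches_grid_oracle(self):
        A = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        B = np.array([[0, 0, 0], [1, 0, 0], [0, 1.2, 0]], float)
        assert superpose(A, B).rmsd == pytest.approx(grid_superpose_rmsd(A, B), abs=1e-4)

    def test_random_instances_match_grid_oracle(self, rng):
        for _ in range(5):
            A = rng.normal(0, 2, (5, 3))
            B = rng.normal(0, 2, (5, 3))
            assert superpose(A, B).rmsd == pytest.approx(
                grid_superpose_rmsd(A, B), abs=1e-4
            )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)


class TestPairRMSD:
    def test_self_rmsd_zero(self, protein_pair):
        model, _ = protein_pair
        assert pair_rmsd(model, model, "A", "A", (1, 76)).rmsd == pytest.approx(0.0, abs=1e-12)

    def test_symmetric(self, protein_pair):
        a, b = protein_pair
        fwd = pair_rmsd(a, b, "A", "A", (1, 73))
        rev = pair_rmsd(b, a, "A", "A", (1, 73))
        assert fwd.rmsd == pytest.approx(rev.rmsd, rel=1e-9)

    def test_tail_exclusion_lowers_rmsd(self, protein_pair):
        # the synthetic pair perturbs residues 74-76 more strongly
        a, b = protein_pair
        with_tail = pair_rmsd(a, b, "A", "A", (1, 76)).rmsd
        without = pair_rmsd(a, b, "A", "A", (1, 73)).rmsd
        assert without < with_tail

    def test_mismatched_chains_rejected(self, protein_pair, tmp_path, rng):
        a, _ = protein_pair
        # numbering offset by 49: only residues 50-76 can pair up (< 50%)
        offset = [(num + 49, name, atoms) for num, name, atoms
                  in synthetic_protein_coords(76, rng)]
        other = read_structure(write_synthetic_pdb(tmp_path / "off.pdb", {"A": offset}))
        with pytest.raises(ValueError, match="matched"):
            pair_rmsd(a, other, "A", "A", (1, 76))


class TestContactDistances:
    def test_simple_distance(self, tmp_path):
        path = write_synthetic_pdb(
            tmp_path / "two.pdb",
            {"A": [(62, "GLN", [("N", 0.0, 0.0, 0.0, 1.0, " ")]),
                   (65, "SER", [("OG", 3.0, 0.0, 0.0, 1.0, " ")])]},
        )
        model = read_structure(path)
        table = contact_distances(model, ("A", 62, "N"), ("A", 65, ("OG",)))
        assert table.attrs["min_distance_A"] == pytest.approx(3.0)
        assert bool(table["hbond_plausible"].iloc[0]) is True

    def test_minimum_over_candidates(self, tmp_path):
        path = write_synthetic_pdb(
            tmp_path / "cand.pdb",
            {"A": [(62, "GLN", [("N", 0.0, 0.0, 0.0, 1.0, " ")]),
                   (65, "ASP", [("OD1", 4.0, 0.0, 0.0, 1.0, " "),
                                ("OD2", 0.0, 2.5, 0.0, 1.0, " ")])]},
        )
        model = read_structure(path)
        table = contact_distances(model, ("A", 62, "N"), ("A", 65, ("OD1", "OD2")))
        assert table.attrs["min_distance_A"] == pytest.approx(2.5)
        assert table["acceptor_atom"].iloc[0] == "OD2"

    def test_rigid_transform_invariance(self, tmp_path, rng):
        residues = synthetic_protein_coords(5, rng, atoms=("N", "CA", "C", "O"))
        path = write_synthetic_pdb(tmp_path / "orig.pdb", {"A": residues})
        R = Rotation.random(random_state=3).as_matrix()
        moved = [
            (num, name, [(an, *(R @ np.array([x, y, z]) + 7.0), occ, al)
                         for an, x, y, z, occ, al in atoms])
            for num, name, atoms in residues
        ]
        path2 = write_synthetic_pdb(tmp_path / "moved.pdb", {"A": moved})
        d1 = contact_distances(read_structure(path), ("A", 1, "N"), ("A", 5, ("CA",)))
        d2 = contact_distances(read_structure(path2), ("A", 1, "N"), ("A", 5, ("CA",)))
        assert d1.attrs["min_distance_A"] == pytest.approx(d2.attrs["min_distance_A"], abs=1e-3)

    def test_missing_atom_named(self, tmp_path):
        path = write_synthetic_pdb(
            tmp_path / "m.pdb", {"A": [(62, "GLN", [("N", 0.0, 0.0, 0.0, 1.0, " ")])]}
        )
        model = read_structure(path)
        with pytest.raises(KeyError, match="OG"):
            contact_distances(model, ("A", 62, "N"), ("A", 65, ("OG",)))
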