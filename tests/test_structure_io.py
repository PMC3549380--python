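import numpy as np
import pytest

from aanet.structure_io import (
    radius_of_gyration,
    read_conformer_series,
    read_structure,
)
from aanet.synthetic import write_pdb

from oracles import radius_of_gyration_bruteforce


def _atom(serial, name, resname, chain, resseq, x, y, z, element, het=False,
          altloc=" ", occ=1.0):
    rec = "HETATM" if het else "ATOM  "
    return (
        f"{rec}{serial:5d}  {name:<3s}{altloc}{resname:>3s} {chain}"
        f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
        f"          {element:>2s}\n"
    )


@pytest.fixture
def tripeptide(tmp_path):
    """GLY-ALA-VAL with hand-placed coordinates, a water and a ligand."""
    lines = [
        _atom(1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0, "N"),
        _atom(2, "CA", "GLY", "A", 1, 1.5, 0.0, 0.0, "C"),
        _atom(3, "C", "GLY", "A", 1, 2.5, 1.0, 0.0, "C"),
        _atom(4, "O", "GLY", "A", 1, 2.5, 2.0, 0.0, "O"),
        _atom(5, "N", "ALA", "A", 2, 3.5, 0.5, 0.0, "N"),
        _atom(6, "CA", "ALA", "A", 2, 4.8, 0.0, 0.0, "C"),
        _atom(7, "CB", "ALA", "A", 2, 5.0, -1.0, 1.0, "C"),
        _atom(8, "C", "ALA", "A", 2, 6.0, 1.0, 0.0, "C"),
        _atom(9, "O", "ALA", "A", 2, 6.0, 2.2, 0.0, "O"),
        _atom(10, "N", "VAL", "A", 3, 7.0, 0.5, 0.0, "N"),
        _atom(11, "CA", "VAL", "A", 3, 8.3, 0.0, 0.0, "C"),
        _atom(12, "CB", "VAL", "A", 3, 0.0, 0.0, 0.0, "C"),
        _atom(13, "CG1", "VAL", "A", 3, 3.0, 0.0, 0.0, "C"),
        _atom(14, "CG2", "VAL", "A", 3, 0.0, 3.0, 0.0, "C"),
        _atom(15, "O", "HOH", "A", 101, 9.0, 9.0, 9.0, "O", het=True),
        _atom(16, "C1", "DRG", "A", 200, -3.0, 0.0, 0.0, "C", het=True),
        _atom(17, "O1", "DRG", "A", 200, -3.5, 1.0, 0.0, "O", het=True),
    ]
    p = tmp_path / "tri.pdb"
    p.write_text("".join(lines) + "END\n")
    return p


class TestReadStructure:
    def test_three_nodes_in_chain_order(self, tripeptide):
        s = read_structure(tripeptide)
        assert [n.res_type for n in s.nodes] == ["GLY", "ALA", "VAL"]
        assert [n.seq_index for n in s.nodes] == [0, 1, 2]

    def test_glycine_centroid_is_ca(self, tripeptide):
        s = read_structure(tripeptide)
        assert np.allclose(s.nodes[0].centroid, [1.5, 0.0, 0.0])
        assert s.nodes[0].n_sidechain_atoms == 1

    def test_alanine_centroid_is_cb(self, tripeptide):
        s = read_structure(tripeptide)
        assert np.allclose(s.nodes[1].centroid, [5.0, -1.0, 1.0])

    def test_valine_centroid_is_sidechain_mean(self, tripeptide):
        s = read_structure(tripeptide)
        assert np.allclose(s.nodes[2].centroid, [1.0, 1.0, 0.0])
        assert s.nodes[2].n_sidechain_atoms == 3

    def test_waters_excluded_ligand_kept(self, tripeptide):
        s = read_structure(tripeptide)
        assert list(s.ligands) == ["DRG:A:200"]
        assert len(s.ligands["DRG:A:200"]) == 2

    def test_empty_file_is_hard_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(ValueError):
            read_structure(p)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        lines = [
            _atom(1, "CA", "ALA", "A", 1, 0, 0, 0, "C"),
            _atom(2, "CB", "ALA", "A", 1, 1, 0, 0, "C", altloc="A", occ=0.4),
            _atom(3, "CB", "ALA", "A", 1, 2, 0, 0, "C", altloc="B", occ=0.6),
            _atom(4, "CA", "GLY", "A", 2, 3, 0, 0, "C"),
        ]
        p = tmp_path / "alt.pdb"
        p.write_text("".join(lines) + "END\n")
        s = read_structure(p)
        assert np.allclose(s.nodes[0].centroid, [2, 0, 0])

    def test_hydrogens_discarded(self, tmp_path):
        lines = [
            _atom(1, "CA", "ALA", "A", 1, 0, 0, 0, "C"),
            _atom(2, "CB", "ALA", "A", 1, 1, 0, 0, "C"),
            _atom(3, "HB1", "ALA", "A", 1, 9, 9, 9, "H"),
            _atom(4, "CA", "GLY", "A", 2, 3, 0, 0, "C"),
        ]
        p = tmp_path / "h.pdb"
        p.write_text("".join(lines) + "END\n")
        s = read_structure(p)
        assert np.allclose(s.nodes[0].centroid, [1, 0, 0])
        assert "H" not in s.atom_elements


class TestMultiModel:
    def _write(self, tmp_path, order=(1, 2, 3)):
        blocks = []
        for m in order:
            blocks.append(f"MODEL     {m:4d}\n")
            blocks.append(_atom(1, "CA", "GLY", "A", 1, float(m), 0, 0, "C"))
            blocks.append(_atom(2, "CA", "GLY", "A", 2, float(m) + 3.8, 0, 0, "C"))
            blocks.append("ENDMDL\n")
        p = tmp_path / "multi.pdb"
        p.write_text("".join(blocks) + "END\n")
        return p

    def test_model_selection(self, tmp_path):
        p = self._write(tmp_path)
        s = read_structure(p, model=2)
        assert np.allclose(s.nodes[0].centroid, [2, 0, 0])

    def test_missing_model_is_error(self, tmp_path):
        p = self._write(tmp_path)
        with pytest.raises(ValueError, match="model 9"):
            read_structure(p, model=9)

    def test_series_stride_and_order(self, tmp_path):
        p = self._write(tmp_path, order=(3, 1, 2))
        series = read_conformer_series(p)
        assert [f.model_id for f in series.frames] == [1, 2, 3]
        strided = read_conformer_series(p, stride=2)
        assert [f.model_id for f in strided.frames] == [1, 3]

    def test_single_model_series_has_length_one(self, tripeptide):
        series = read_conformer_series(tripeptide)
        assert len(series) == 1

    def test_roster_mismatch_names_divergence(self, tmp_path):
        blocks = [
            "MODEL        1\n",
            _atom(1, "CA", "GLY", "A", 1, 0, 0, 0, "C"),
            _atom(2, "CA", "ALA", "A", 2, 3.8, 0, 0, "C"),
            "ENDMDL\n",
            "MODEL        2\n",
            _atom(1, "CA", "GLY", "A", 1, 0, 0, 0, "C"),
            _atom(2, "CA", "SER", "A", 2, 3.8, 0, 0, "C"),
            "ENDMDL\n",
        ]
        p = tmp_path / "mismatch.pdb"
        p.write_text("".join(blocks) + "END\n")
        with pytest.raises(ValueError, match="node 1"):
            read_conformer_series(p)


class TestRadiusOfGyration:
    def test_single_point_is_zero(self, tmp_path):
        lines = [_atom(1, "CA", "GLY", "A", 1, 5, 5, 5, "C")]
        p = tmp_path / "one.pdb"
        p.write_text("".join(lines) + "END\n")
        s = read_structure(p)
        assert radius_of_gyration(s, "centroids") == 0.0

    def test_two_equal_masses_two_angstrom_apart(self, tmp_path):
        lines = [
            _atom(1, "CA", "GLY", "A", 1, 0, 0, 0, "C"),
            _atom(2, "CA", "GLY", "A", 2, 2, 0, 0, "C"),
        ]
        p = tmp_path / "two.pdb"
        p.write_text("".join(lines) + "END\n")
        s = read_structure(p)
        assert radius_of_gyration(s, "atoms") == pytest.approx(1.0)

    def test_matches_direct_sum(self, small_chain):
        expected = radius_of_gyration_bruteforce(
            small_chain.atom_coords, small_chain.atom_masses
        )
        assert radius_of_gyration(small_chain, "atoms") == pytest.approx(
            expected, rel=1e-12
        )

    def test_scales_linearly(self, small_chain):
        from aanet.synthetic import make_expansion_series

        series = make_expansion_series(small_chain, [1.0, 1.15])
        r0 = radius_of_gyration(series.frames[0], "centroids")
        r1 = radius_of_gyration(series.frames[1], "centroids")
        assert r1 == pytest.approx(1.15 * r0, rel=1e-9)


class TestRigidMotionInvariance:
    def test_distances_unchanged_under_rotation_translation(self, small_chain):
        from scipy.spatial.transform import Rotation

        pts = small_chain.centroids
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        moved = pts @ rot.T + np.array([11.0, -4.0, 2.5])
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d1 = np.linalg.norm(moved[:, None] - moved[None, :], axis=-1)
        assert np.allclose(d0, d1, atol=1e-9)

    def test_pdb_roundtrip_preserves_nodes(self, small_chain, tmp_path):
        p = tmp_path / "chain.pdb"
        write_pdb(small_chain, p)
        back = read_structure(p)
        assert back.n_nodes == small_chain.n_nodes
        assert [n.res_type for n in back.nodes] == [
            n.res_type for n in small_chain.nodes
        ]
        # PDB coordinates carry three decimals
        assert np.allclose(back.centroids, small_chain.centroids, atol=1e-3)
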