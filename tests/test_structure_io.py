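import numpy as np
import pytest

from confens.errors import (
    EmptyStructureError,
    PdbParseError,
    SelectionError,
    TopologyError,
)
from confens.structure_io import (
    FRAGMENT_PRESETS,
    FragmentSpec,
    Frame,
    read_pdb,
    select,
    select_ensemble,
    write_pdb,
)

from conftest import ca_frame, make_atom


class TestReadPdb:
    def test_minimal_single_atom(self, minimal_pdb):
        frames = read_pdb(minimal_pdb)
        assert len(frames) == 1
        (atom,) = frames[0].atoms
        assert atom.atom_name == "CA"
        assert atom.residue_number == 1
        np.testing.assert_allclose(atom.coordinates, [11.104, 6.134, -6.504])

    def test_two_models_three_atoms_each(self, two_model_pdb):
        frames = read_pdb(two_model_pdb)
        assert [f.model_index for f in frames] == [0, 1]
        assert [len(f.atoms) for f in frames] == [3, 3]

    def test_no_atoms_raises(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("HEADER    NOTHING\nEND\n")
        with pytest.raises(EmptyStructureError):
            read_pdb(p)

    def test_malformed_coordinate_names_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(
            "ATOM      1  CA  ALA A   1      xx.xxx   6.134  -6.504  1.00  0.00\n"
        )
        with pytest.raises(PdbParseError, match="line 1"):
            read_pdb(p)

    def test_insertion_code_rejected(self, tmp_path):
        p = tmp_path / "icode.pdb"
        p.write_text(
            "ATOM      1  CA  ALA A  52A     11.104   6.134  -6.504  1.00  0.00\n"
        )
        with pytest.raises(PdbParseError, match="insertion code"):
            read_pdb(p)

    def test_zinc_kept_waters_skipped(self, tmp_path):
        p = tmp_path / "het.pdb"
        p.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00\n"
            "HETATM    2 ZN    ZN A 101       1.000   1.000   1.000  1.00  0.00\n"
            "HETATM    3  O   HOH A 201       2.000   2.000   2.000  1.00  0.00\n"
        )
        (frame,) = read_pdb(p)
        names = [(a.atom_name, a.het) for a in frame.atoms]
        assert ("ZN", True) in names
        assert all(a.residue_name != "HOH" for a in frame.atoms)


class TestWritePdb:
    def test_round_trip_coordinates_to_3_decimals(self, rng, tmp_path):
        coords = rng.normal(scale=30.0, size=(10, 3))
        frame = ca_frame(coords)
        path = write_pdb([frame], tmp_path / "rt.pdb")
        (back,) = read_pdb(path)
        got = np.array([a.coordinates for a in back.atoms])
        np.testing.assert_allclose(got, coords, atol=5.1e-4)

    def test_two_frames_get_model_records(self, tmp_path, random_coords):
        frames = [ca_frame(random_coords(), model_index=i) for i in range(2)]
        path = write_pdb(frames, tmp_path / "mm.pdb")
        text = path.read_text()
        assert "MODEL " in text and "ENDMDL" in text
        assert len(read_pdb(path)) == 2

    def test_empty_list_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_pdb([], tmp_path / "x.pdb")

    def test_inconsistent_atom_counts_rejected(self, tmp_path, random_coords):
        frames = [ca_frame(random_coords(5)), ca_frame(random_coords(6))]
        with pytest.raises(TopologyError):
            write_pdb(frames, tmp_path / "x.pdb")

    def test_round_trip_multimodel_identity(self, tmp_path, random_coords):
        frames = [ca_frame(random_coords(), model_index=i) for i in range(3)]
        p1 = write_pdb(frames, tmp_path / "a.pdb")
        back = read_pdb(p1)
        p2 = write_pdb(back, tmp_path / "b.pdb")
        assert p1.read_text().splitlines()[1:] == p2.read_text().splitlines()[1:]

    def test_mdtraj_reads_our_output(self, tmp_path, random_coords):
        mdtraj = pytest.importorskip("mdtraj")
        coords = random_coords(8)
        path = write_pdb([ca_frame(coords)], tmp_path / "x.pdb")
        traj = mdtraj.load_pdb(str(path), standard_names=False)
        np.testing.assert_allclose(traj.xyz[0] * 10.0, coords, atol=5.1e-4)


class TestSelect:
    def _dbd_like_frame(self):
        # residues 440..470, one CA each
        return ca_frame(np.arange(31 * 3).reshape(31, 3) * 1.0, first_residue=440)

    def test_lever_arm_preset_selects_seven_ca(self):
        sel = select(self._dbd_like_frame(), FRAGMENT_PRESETS["lever_arm"])
        assert len(sel) == 7
        assert list(sel.residue_numbers) == list(range(450, 457))

    def test_empty_selection_names_the_spec(self):
        spec = FragmentSpec("nowhere", (900, 905))
        with pytest.raises(SelectionError, match="nowhere"):
            select(self._dbd_like_frame(), spec)

    def test_alt_loc_highest_occupancy_wins(self):
        frame = Frame(
            [
                make_atom("CA", 453, (0, 0, 0), alt="A", occ=0.6),
                make_atom("CA", 453, (9, 9, 9), alt="B", occ=0.4),
            ]
        )
        sel = select(frame, FragmentSpec("his", (453, 453)))
        assert len(sel) == 1
        np.testing.assert_array_equal(sel.coords[0], [0, 0, 0])

    def test_alt_loc_tie_goes_to_first_label(self):
        frame = Frame(
            [
                make_atom("CA", 453, (9, 9, 9), alt="B", occ=0.5),
                make_atom("CA", 453, (0, 0, 0), alt="A", occ=0.5),
            ]
        )
        sel = select(frame, FragmentSpec("his", (453, 453)))
        np.testing.assert_array_equal(sel.coords[0], [0, 0, 0])

    def test_backbone_canonical_order(self):
        frame = Frame(
            [
                make_atom("C", 1, (2, 0, 0)),
                make_atom("CB", 1, (4, 0, 0)),
                make_atom("N", 1, (0, 0, 0)),
                make_atom("O", 1, (3, 0, 0)),
                make_atom("CA", 1, (1, 0, 0)),
            ]
        )
        spec = FragmentSpec("bb", (1, 1), atom_names={"N", "CA", "C", "O", "CB"})
        sel = select(frame, spec)
        assert [a.atom_name for a in sel.atoms] == ["N", "CA", "C", "O", "CB"]

    def test_missing_atom_errors_by_default(self):
        frame = Frame(
            [make_atom("CA", 1), make_atom("N", 2, (1, 0, 0))]  # res 2 lacks CA
        )
        with pytest.raises(SelectionError, match="A2"):
            select(frame, FragmentSpec("x", (1, 2)))

    def test_zinc_never_selected(self):
        atoms = [make_atom("CA", 450 + i, (i, 0, i * i), serial=i) for i in range(7)]
        from dataclasses import replace

        zn = replace(make_atom("ZN", 460, (1, 1, 1), resname="ZN"), het=True)
        frame = Frame(atoms + [zn])
        sel = select(frame, FragmentSpec("za", (450, 460)))
        assert len(sel) == 7
        assert all(not a.het for a in sel.atoms)

    def test_selection_is_deterministic(self, random_coords):
        frame = ca_frame(random_coords(20), first_residue=450)
        spec = FRAGMENT_PRESETS["lever_arm"]
        a, b = select(frame, spec), select(frame, spec)
        np.testing.assert_array_equal(a.coords, b.coords)
        np.testing.assert_array_equal(a.index_map, b.index_map)


class TestSelectEnsemble:
    def test_mismatched_topology_raises_not_truncates(self, random_coords):
        f1 = ca_frame(random_coords(5), first_residue=1)
        f2 = ca_frame(random_coords(4), first_residue=1)  # residue 5 absent
        with pytest.raises(TopologyError):
            select_ensemble([f1, f2], FragmentSpec("x", (1, 5)))

    def test_allow_missing_drops_residue_from_all_frames(self, random_coords):
        f1 = ca_frame(random_coords(5), first_residue=1)
        f2 = ca_frame(random_coords(4), first_residue=1)
        sels = select_ensemble(
            [f1, f2], FragmentSpec("x", (1, 5)), allow_missing=True
        )
        assert [len(s) for s in sels] == [4, 4]
        assert list(sels[0].residue_numbers) == [1, 2, 3, 4]
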