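import numpy as np
import pytest

from hingeforge.structio import (
    AtomRecord,
    AtomSelector,
    CaTrace,
    SelectionError,
    StructureError,
    StructureModel,
    extract_ca_trace,
    read_structure,
    resolve_atom,
    write_structure,
)

from conftest import ca_model

ONE_ATOM_PDB = (
    "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
    "END\n"
)


def make_atom(**kw):
    defaults = dict(
        chain="A",
        resnum=1,
        icode="",
        resname="ALA",
        name="CA",
        element="C",
        coords=np.zeros(3),
    )
    defaults.update(kw)
    return AtomRecord(**defaults)


class TestReadWrite:
    def test_single_atom_pdb_text(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(ONE_ATOM_PDB)
        model = read_structure(p)
        assert len(model) == 1
        np.testing.assert_allclose(model.atoms[0].coords, [1.0, 2.0, 3.0])

    def test_roundtrip_preserves_coordinates(self, tmp_path):
        rng = np.random.default_rng(0)
        model = ca_model(rng.normal(0.0, 30.0, size=(100, 3)))
        p = tmp_path / "rt.pdb"
        write_structure(model, p)
        back = read_structure(p)
        assert len(back) == len(model)
        # PDB stores 3 decimals
        np.testing.assert_allclose(back.coords(), model.coords(), atol=5.1e-4)

    def test_empty_model_writes_end_record(self, tmp_path):
        p = tmp_path / "empty.pdb"
        write_structure(StructureModel([]), p)
        assert p.read_text().strip().splitlines()[-1].startswith("END")
        assert len(read_structure(p)) == 0

    def test_out_of_range_coordinate_rejected(self, tmp_path):
        model = StructureModel([make_atom(coords=np.array([1e6, 0.0, 0.0]))])
        with pytest.raises(StructureError):
            write_structure(model, tmp_path / "bad.pdb")

    def test_duplicate_atom_key_rejected(self):
        with pytest.raises(StructureError, match="duplicate"):
            StructureModel([make_atom(), make_atom()])

    def test_unknown_format_rejected(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(ONE_ATOM_PDB)
        with pytest.raises(Exception, match="format"):
            read_structure(p, format="xyz")

    def test_waters_dropped_heteroatoms_kept(self, tmp_path):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2  N5  FAD A 701       5.000   0.000   0.000  1.00  0.00           N\n"
            "HETATM    3  O   HOH A 801       9.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        p = tmp_path / "het.pdb"
        p.write_text(text)
        model = read_structure(p)
        names = {a.resname for a in model.atoms}
        assert names == {"ALA", "FAD"}
        model_all = read_structure(p, drop_waters=False)
        assert {a.resname for a in model_all.atoms} == {"ALA", "FAD", "HOH"}

    def test_altloc_pruned_to_highest_occupancy(self, tmp_path):
        text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.60  0.00           C\n"
            "END\n"
        )
        p = tmp_path / "alt.pdb"
        p.write_text(text)
        model = read_structure(p)
        assert len(model) == 1
        np.testing.assert_allclose(model.atoms[0].coords, [2.0, 0.0, 0.0])


class TestCaTrace:
    def test_extract_simple_chain(self):
        coords = [[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]]
        trace = extract_ca_trace(ca_model(coords), "A")
        assert len(trace) == 3
        assert not trace.has_breaks
        np.testing.assert_array_equal(trace.residue_numbers, [1, 2, 3])

    def test_residue_without_ca_skipped(self):
        atoms = [
            make_atom(resnum=1, coords=np.array([0.0, 0, 0])),
            make_atom(resnum=2, name="CB", coords=np.array([3.8, 0, 0])),
            make_atom(resnum=3, coords=np.array([3.8, 0, 0])),
        ]
        trace = extract_ca_trace(StructureModel(atoms), "A")
        assert len(trace) == 2
        assert list(trace.residue_numbers) == [1, 3]

    def test_trace_length_matches_generator(self, hinge_pair):
        assert len(hinge_pair.confA) == 60 + 60 + 12

    def test_order_stable_under_record_shuffle(self, tmp_path):
        rng = np.random.default_rng(4)
        coords = rng.normal(0.0, 10.0, size=(20, 3))
        model = ca_model(coords)
        lines_path = tmp_path / "a.pdb"
        write_structure(model, lines_path)
        trace1 = extract_ca_trace(read_structure(lines_path), "A")
        # shuffle ATOM records; author order within the file changes but
        # numbering does not — the trace must come back in residue order
        lines = [l for l in lines_path.read_text().splitlines() if l.startswith("ATOM")]
        rng.shuffle(lines)
        shuffled = tmp_path / "b.pdb"
        shuffled.write_text("\n".join(lines) + "\nEND\n")
        trace2 = extract_ca_trace(read_structure(shuffled), "A")
        order = np.argsort(trace2.residue_numbers)
        np.testing.assert_array_equal(
            trace2.residue_numbers[order], trace1.residue_numbers
        )
        np.testing.assert_allclose(
            trace2.coords[order], trace1.coords, atol=5.1e-4
        )

    def test_missing_chain_raises(self):
        with pytest.raises(SelectionError, match="chain"):
            extract_ca_trace(ca_model([[0, 0, 0], [3.8, 0, 0]]), "Z")

    def test_break_flagging(self):
        trace = CaTrace(
            "A",
            np.array([1, 2, 3]),
            np.array(["ALA"] * 3, dtype=object),
            np.array([[0, 0, 0], [3.8, 0, 0], [30.0, 0, 0]]),
        )
        assert trace.has_breaks


class TestResolveAtom:
    def test_unique_hit(self):
        model = StructureModel(
            [
                make_atom(chain="B", resnum=454, name="NZ", element="N"),
                make_atom(chain="B", resnum=454, name="CA"),
            ]
        )
        xyz = resolve_atom(model, AtomSelector("B", 454, "NZ"))
        np.testing.assert_allclose(xyz, [0, 0, 0])

    def test_zero_matches_raise(self):
        model = StructureModel([make_atom()])
        with pytest.raises(SelectionError, match="no atom"):
            resolve_atom(model, AtomSelector("A", 99, "CA"))

    def test_resname_filter_disambiguates_cofactor_copies(self):
        # one FAD per chain: without a chain-aware selector, two hits
        atoms = [
            make_atom(chain="C", resnum=701, resname="FAD", name="N5", element="N"),
            make_atom(
                chain="D",
                resnum=701,
                resname="FAD",
                name="N5",
                element="N",
                coords=np.array([50.0, 0, 0]),
            ),
        ]
        model = StructureModel(atoms)
        xyz = resolve_atom(model, AtomSelector("D", 701, "N5", resname="FAD"))
        np.testing.assert_allclose(xyz, [50.0, 0, 0])

    def test_ambiguous_altlocs_raise(self):
        atoms = [
            make_atom(altloc="A", occupancy=0.5),
            make_atom(altloc="B", occupancy=0.5, coords=np.array([1.0, 0, 0])),
        ]
        model = StructureModel(atoms)
        with pytest.raises(SelectionError, match="ambiguous"):
            resolve_atom(model, AtomSelector("A", 1, "CA"))
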