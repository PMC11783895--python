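"""PDB parsing, fragment harvesting and chemical completion."""

import numpy as np
import pytest

from flexfrag import chemistry as ch
from flexfrag.extraction import (complete_fragment, extract_dual_fragments,
                                 extract_single_fragments, parse_structure)

from conftest import fragment_as_pdb_residues, make_fragment, pdb_lines


def _pdb_text(residues, chain="A"):
    return "\n".join(pdb_lines(residues, chain=chain) + ["END"]) + "\n"


def _chain_of(codes, gap_after=None, gap=5.0):
    """Crude poly-residue chain: template conformers strung N-to-C.

    Residue i+1 is translated so its N continues from residue i's C at
    peptide-bond distance (or at ``gap`` A after ``gap_after`` to emulate a
    chain break).
    """
    residues = []
    offset = np.zeros(3)
    prev_c = None
    for num, code in enumerate(codes, start=1):
        frag = make_fragment(code)
        t = ch.get_template(code)
        coords = frag.coords.copy()
        if prev_c is not None:
            d = gap if (gap_after is not None and num - 1 == gap_after) else 1.33
            target_n = prev_c + np.array([d, 0.45, 0.0]) * (d / np.hypot(d, 0.45))
            coords = coords - coords[t.index_of("N")] + target_n
        prev_c = coords[t.index_of("C")]
        atoms = [(a.name, a.element, tuple(coords[i]))
                 for i, a in enumerate(t.atoms)
                 if a.element != "H" and a.name != "OXT"]
        residues.append((code, num, atoms))
    return residues


class TestParse:
    def test_minimal_single_residue(self, ala_fragment):
        text = _pdb_text(fragment_as_pdb_residues(ala_fragment,
                                                  drop=("OXT",)))
        model = parse_structure(text)
        assert len(model.chains) == 1
        chain_name, residues = model.chains[0]
        assert len(residues) == 1
        assert residues[0].name == "ALA"
        assert len(residues[0].atoms) == 5  # N CA C O CB

    def test_hydrogens_dropped(self, ala_fragment):
        text = _pdb_text(fragment_as_pdb_residues(ala_fragment,
                                                  heavy_only=False))
        model = parse_structure(text)
        atoms = model.chains[0][1][0].atoms
        assert all(not name.startswith("H") for name in atoms)

    def test_altloc_resolved_to_single_coordinate(self):
        frag = make_fragment("ALA")
        residues = fragment_as_pdb_residues(frag, drop=("OXT",))
        lines = pdb_lines(residues)
        # duplicate the CB line as altloc A/B with different x
        cb = [ln for ln in lines if " CB " in ln][0]
        lines.remove(cb)
        a_loc = cb[:16] + "A" + cb[17:]
        b_loc = cb[:16] + "B" + cb[17:30] + f"{99.0:8.3f}" + cb[38:]
        text = "\n".join(lines + [a_loc, b_loc, "END"]) + "\n"
        model = parse_structure(text)
        atoms = model.chains[0][1][0].atoms
        assert "CB" in atoms
        assert atoms["CB"][0] != pytest.approx(99.0)

    def test_no_atom_records_rejected(self):
        with pytest.raises(ValueError, match="empty|unreadable"):
            parse_structure("HEADER  NOTHING\nEND\n")


class TestExtractSingle:
    def test_three_residue_chain(self):
        text = _pdb_text(_chain_of(["ALA", "GLY", "SER"]))
        frags = extract_single_fragments(parse_structure(text))
        assert [f.label for f in frags] == ["ALA", "GLY", "SER"]
        for f in frags:
            assert f.n_atoms == ch.atom_count(f.label)

    def test_missing_side_chain_atom_skipped(self):
        residues = _chain_of(["ALA", "SER", "GLY"])
        name, num, atoms = residues[1]
        residues[1] = (name, num, [a for a in atoms if a[0] != "OG"])
        skip_log = []
        frags = extract_single_fragments(
            parse_structure(_pdb_text(residues)), skip_log)
        assert [f.label for f in frags] == ["ALA", "GLY"]
        assert len(skip_log) == 1

    def test_non_standard_residue_skipped(self):
        residues = _chain_of(["ALA", "GLY"])
        residues.append(("LIG", 3, [("C1", "C", (30.0, 0.0, 0.0))]))
        skip_log = []
        frags = extract_single_fragments(
            parse_structure(_pdb_text(residues)), skip_log)
        assert len(frags) == 2
        assert len(skip_log) == 1

    def test_heavy_atoms_bit_identical(self):
        residues = _chain_of(["MET"])
        text = _pdb_text(residues)
        model = parse_structure(text)
        frags = extract_single_fragments(model)
        # PDB text carries 3 decimals; the parsed values must pass through
        # completion bit-identically
        parsed = model.chains[0][1][0].atoms
        frag = frags[0]
        for name, xyz in parsed.items():
            i = frag.atom_names.index(name)
            assert np.array_equal(frag.coords[i], xyz)
        for a in residues[0][2]:
            assert np.allclose(parsed[a[0]], a[2], atol=1e-3)


class TestExtractDual:
    def test_consecutive_pairs(self):
        text = _pdb_text(_chain_of(["ALA", "GLY", "SER"]))
        frags = extract_dual_fragments(parse_structure(text))
        assert [f.label for f in frags] == ["ALAGLY", "GLYSER"]
        for f in frags:
            assert f.n_atoms == ch.atom_count(f.label)

    def test_chain_break_terminates_pairing(self):
        text = _pdb_text(_chain_of(["ALA", "GLY", "SER", "VAL"],
                                   gap_after=2))
        frags = extract_dual_fragments(parse_structure(text))
        assert [f.label for f in frags] == ["ALAGLY", "SERVAL"]

    def test_single_residue_chain_yields_nothing(self):
        text = _pdb_text(_chain_of(["TRP"]))
        assert extract_dual_fragments(parse_structure(text)) == []

    def test_chain_of_length_l_gives_l_minus_1(self):
        codes = ["ALA", "GLY", "SER", "VAL", "LEU", "THR"]
        text = _pdb_text(_chain_of(codes))
        frags = extract_dual_fragments(parse_structure(text))
        assert len(frags) == len(codes) - 1


class TestComplete:
    def test_proline_completion_count(self, pro_fragment):
        heavy = {(n, 0): xyz for n, e, xyz in
                 zip(pro_fragment.atom_names, pro_fragment.elements,
                     pro_fragment.coords) if e != "H" and n != "OXT"}
        frag = complete_fragment("PRO", heavy)
        assert frag.n_atoms == 17

    def test_idempotent_on_complete_input(self, met_ensemble):
        src = met_ensemble[0]
        heavy = {(n, 0): xyz for n, e, xyz in
                 zip(src.atom_names, src.elements, src.coords) if e != "H"}
        once = complete_fragment("MET", heavy)
        heavy2 = {(n, 0): xyz for n, e, xyz in
                  zip(once.atom_names, once.elements, once.coords)
                  if e != "H"}
        twice = complete_fragment("MET", heavy2)
        assert np.array_equal(once.coords[once.heavy_mask],
                              twice.coords[twice.heavy_mask])

    def test_heavy_coordinates_unchanged(self, met_ensemble):
        src = met_ensemble[1]
        heavy = {(n, 0): xyz for n, e, xyz in
                 zip(src.atom_names, src.elements, src.coords) if e != "H"}
        out = complete_fragment("MET", heavy)
        for (name, _), xyz in heavy.items():
            i = out.atom_names.index(name)
            assert np.array_equal(out.coords[i], xyz)

    def test_missing_heavy_atom_rejected(self, ala_fragment):
        heavy = {(n, 0): xyz for n, e, xyz in
                 zip(ala_fragment.atom_names, ala_fragment.elements,
                     ala_fragment.coords) if e != "H"}
        del heavy[("CB", 0)]
        with pytest.raises(ValueError, match="CB"):
            complete_fragment("ALA", heavy)

    def test_extra_heavy_atom_rejected(self, ala_fragment):
        heavy = {(n, 0): xyz for n, e, xyz in
                 zip(ala_fragment.atom_names, ala_fragment.elements,
                     ala_fragment.coords) if e != "H"}
        heavy[("XX", 0)] = np.zeros(3)
        with pytest.raises(ValueError, match="XX"):
            complete_fragment("ALA", heavy)

    def test_completed_fragment_validates(self, met_ensemble):
        src = met_ensemble[2]
        heavy = {(n, 0): xyz for n, e, xyz in
                 zip(src.atom_names, src.elements, src.coords) if e != "H"}
        complete_fragment("MET", heavy).validate()
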