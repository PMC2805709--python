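import numpy as np
import pytest

from cidkit.contacts import (
    ContactCriteria,
    EmptySelectionError,
    StructureModel,
    StructureParseError,
    contact_table,
    contacts_to_tsv,
    find_hbonds,
    find_hydrophobic_contacts,
    find_pi_cation,
    find_salt_bridges,
    find_water_mediated_hbonds,
    parse_structure,
    select_ligand,
)
from cidkit.synthetic import (
    ComplexSpec,
    SpecError,
    gen_complex,
    random_rigid_transform,
)

MINIMAL_PDB = """\
ATOM      1  CA  SER A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CB  SER A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  OG  SER A   1       2.900   0.000   0.000  1.00  0.00           O
END
"""

TWO_MODELS_PDB = """\
MODEL        1
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  GLY A   1       9.000   9.000   9.000  1.00  0.00           C
ATOM      2  CB  GLY A   1       8.000   9.000   9.000  1.00  0.00           C
ENDMDL
END
"""


@pytest.fixture
def complex_with_everything(tmp_path):
    cx = gen_complex(
        ComplexSpec(water_bridge=True, n_decoys=20, subsites=(-1, -2, -3))
    )
    path = tmp_path / "complex.pdb"
    cx.write(path)
    model = parse_structure(path)
    ligand = select_ligand(model, subsites=cx.subsites)
    return cx, model, ligand


class TestParse:
    def test_minimal_fixture(self, tmp_path):
        path = tmp_path / "min.pdb"
        path.write_text(MINIMAL_PDB)
        model = parse_structure(path)
        assert model.n_atoms == 3
        np.testing.assert_allclose(model.coords[2], [2.9, 0, 0])
        assert list(model.atoms.element) == ["C", "C", "O"]

    def test_first_model_only(self, tmp_path):
        path = tmp_path / "two.pdb"
        path.write_text(TWO_MODELS_PDB)
        model = parse_structure(path)
        assert model.n_atoms == 1
        np.testing.assert_allclose(model.coords[0], [0, 0, 0])

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(StructureParseError):
            parse_structure(path)


class TestSelectLigand:
    def test_sugars_in_sequence_order(self, complex_with_everything):
        _, model, ligand = complex_with_everything
        assert [k[1] for k in ligand.residues] == [1, 2, 3]
        assert all(k[2] == "NAG" for k in ligand.residues)

    def test_no_sugars(self, tmp_path):
        path = tmp_path / "min.pdb"
        path.write_text(MINIMAL_PDB)
        model = parse_structure(path)
        with pytest.raises(EmptySelectionError):
            select_ligand(model)

    def test_subsite_labels_attached(self, complex_with_everything):
        _, model, ligand = complex_with_everything
        assert ligand.subsite(ligand.residues[0]) == -1
        assert ligand.subsite(ligand.residues[2]) == -3

    def test_wrong_label_count(self, complex_with_everything):
        _, model, _ = complex_with_everything
        with pytest.raises(ValueError):
            select_ligand(model, subsites=[-1])


def as_pairs(records):
    return {
        (r.kind, r.protein_res, r.protein_atom, r.ligand_res, r.ligand_atom)
        for r in records
    }


class TestPlantedDetection:
    def test_exact_recovery_all_kinds(self, complex_with_everything):
        cx, model, ligand = complex_with_everything
        detected = (
            as_pairs(find_hbonds(model, ligand))
            | as_pairs(find_water_mediated_hbonds(model, ligand))
            | as_pairs(find_hydrophobic_contacts(model, ligand))
            | as_pairs(find_salt_bridges(model))
            | as_pairs(find_pi_cation(model))
        )
        expected = {
            (t.kind, t.protein_res, t.protein_atom, t.ligand_res,
             t.ligand_atom)
            for t in cx.truth
        }
        assert detected == expected

    def test_distances_match_plant(self, complex_with_everything):
        cx, model, ligand = complex_with_everything
        hbonds = [
            r for r in find_hbonds(model, ligand) if not r.water_mediated
        ]
        for rec in hbonds:
            assert rec.distance == pytest.approx(2.9, abs=1e-3)

    def test_subsites_attributed(self, complex_with_everything):
        _, model, ligand = complex_with_everything
        subsites = {r.ligand_res: r.subsite for r in find_hbonds(model, ligand)}
        assert subsites == {"NAG1": -1, "NAG2": -2}

    def test_water_bridge_flagged(self, complex_with_everything):
        _, model, ligand = complex_with_everything
        wm = find_water_mediated_hbonds(model, ligand)
        assert len(wm) == 1
        assert wm[0].water_mediated and wm[0].water_res == "HOH501"

    def test_rigid_transform_invariance(self, complex_with_everything):
        cx, model, ligand = complex_with_everything
        moved = StructureModel(atoms=random_rigid_transform(model.atoms, 7))
        for finder in (
            lambda m: find_hbonds(m, ligand),
            lambda m: find_water_mediated_hbonds(m, ligand),
            lambda m: find_hydrophobic_contacts(m, ligand),
            find_salt_bridges,
            find_pi_cation,
        ):
            assert as_pairs(finder(moved)) == as_pairs(finder(model))


def single_pair_model(res_name, atom_name, element, xyz, lig_atom="O3",
                      lig_element="O"):
    """One protein atom and one single-atom NAG at a chosen separation."""
    from cidkit.synthetic import _Builder

    b = _Builder()
    b.add("A", 1, res_name, atom_name, element, False, np.zeros(3))
    b.add("L", 1, "NAG", lig_atom, lig_element, True, np.asarray(xyz, float))
    model = StructureModel(atoms=b.build())
    from cidkit.contacts import LigandSelection

    ligand = LigandSelection(residues=(("L", 1, "NAG"),))
    return model, ligand


class TestCutoffs:
    def test_hbond_outside_cutoff(self):
        model, ligand = single_pair_model("GLU", "OE1", "O", [4.0, 0, 0])
        assert find_hbonds(model, ligand) == []

    def test_hbond_inside_cutoff(self):
        model, ligand = single_pair_model("GLU", "OE1", "O", [2.9, 0, 0])
        assert len(find_hbonds(model, ligand)) == 1

    def test_polar_pair_not_hydrophobic(self):
        model, ligand = single_pair_model("GLU", "OE1", "O", [3.0, 0, 0])
        assert find_hydrophobic_contacts(model, ligand) == []

    def test_cc_pair_boundaries(self):
        # vdW sum 3.4 + tolerance 0.5 = 3.9
        near, lig = single_pair_model("ALA", "CB", "C", [3.8, 0, 0],
                                      lig_atom="C1", lig_element="C")
        assert len(find_hydrophobic_contacts(near, lig)) == 1
        far, lig = single_pair_model("ALA", "CB", "C", [4.5, 0, 0],
                                     lig_atom="C1", lig_element="C")
        assert find_hydrophobic_contacts(far, lig) == []

    def test_asp_ser_is_not_a_salt_bridge(self):
        from cidkit.synthetic import _Builder

        b = _Builder()
        b.add("A", 1, "ASP", "OD1", "O", False, np.zeros(3))
        b.add("A", 2, "SER", "OG", "O", False, np.array([3.0, 0, 0]))
        assert find_salt_bridges(StructureModel(atoms=b.build())) == []

    def test_phe_lys_pi_cation(self):
        from cidkit.synthetic import _Builder
        import math

        b = _Builder()
        for m, name in enumerate(("CG", "CD1", "CE1", "CZ", "CE2", "CD2")):
            ang = math.radians(60 * m)
            b.add("A", 1, "PHE", name, "C", False,
                  1.39 * np.array([math.cos(ang), 0, math.sin(ang)]))
        b.add("A", 2, "LYS", "NZ", "N", False, np.array([0, 4.5, 0]))
        hits = find_pi_cation(StructureModel(atoms=b.build()))
        assert len(hits) == 1
        assert hits[0].distance == pytest.approx(4.5, abs=1e-6)

    def test_shrinking_cutoffs_never_add_contacts(
        self, complex_with_everything
    ):
        _, model, ligand = complex_with_everything
        loose = ContactCriteria()
        tight = ContactCriteria(
            hbond_max_da=2.5, hydrophobic_tolerance=0.1,
            salt_bridge_max=3.0, pi_cation_max=4.0, water_bridge_max=2.0,
        )
        assert as_pairs(find_hbonds(model, ligand, tight)) <= as_pairs(
            find_hbonds(model, ligand, loose)
        )
        assert as_pairs(
            find_hydrophobic_contacts(model, ligand, tight)
        ) <= as_pairs(find_hydrophobic_contacts(model, ligand, loose))
        assert as_pairs(find_salt_bridges(model, tight)) <= as_pairs(
            find_salt_bridges(model, loose)
        )
        assert as_pairs(find_pi_cation(model, tight)) <= as_pairs(
            find_pi_cation(model, loose)
        )


class TestBruteForceOracle:
    def test_all_pairs_scan_agrees(self, complex_with_everything):
        """O(n^2) distance scan agrees with the KD-tree detectors."""
        _, model, ligand = complex_with_everything
        a = model.atoms
        prot = model.protein_mask() & np.isin(a.element, ["N", "O", "S"])
        from cidkit.contacts import _ligand_atom_mask

        lig = _ligand_atom_mask(model, ligand) & np.isin(
            a.element, ["N", "O"]
        )
        brute = set()
        for i in np.flatnonzero(prot):
            for j in np.flatnonzero(lig):
                if np.linalg.norm(a.coord[i] - a.coord[j]) <= 3.5:
                    brute.add((str(a.atom_name[i]), int(a.res_id[i]),
                               str(a.atom_name[j]), int(a.res_id[j])))
        kd = {
            (r.protein_atom, int(r.protein_res[1:]), r.ligand_atom,
             int(r.ligand_res[3:]))
            for r in find_hbonds(model, ligand)
        }
        assert kd == brute


class TestReports:
    def test_contact_table_groups(self, complex_with_everything):
        _, model, ligand = complex_with_everything
        table = contact_table(
            model, ligand,
            residue_groups={"S101": "CID", "S102": "CID", "A201": "TIM"},
        )
        row = table[table.subsite == -1].iloc[0]
        assert row["CID_hbond"] == "S101"
        by_sub = {r.subsite: r for _, r in table.iterrows()}
        assert by_sub[-3]["TIM_hydrophobic"] == "A201"

    def test_tsv_output(self, complex_with_everything):
        _, model, ligand = complex_with_everything
        tsv = contacts_to_tsv(find_hbonds(model, ligand))
        assert tsv.startswith("kind\t")
        assert "hbond\tS101\tOG\tNAG1\tO3" in tsv


class TestSpecValidation:
    def test_infeasible_distance_rejected(self):
        with pytest.raises(SpecError):
            gen_complex(ComplexSpec(hbond_distance=4.0))

    def test_more_hbonds_than_sugars(self):
        with pytest.raises(SpecError):
            gen_complex(ComplexSpec(n_sugars=1, n_hbonds=2))
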