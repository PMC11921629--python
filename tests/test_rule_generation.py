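"""Atom mapping, SRR decomposition, reaction centers, and CSRR emission."""

import pytest
from rdkit import Chem

from xenomet.chem_core import canonical_key, sanitize_molecule
from xenomet.gem_io import read_reaction_table
from xenomet.rule_generation import (
    MappingError,
    ReactionSkipped,
    apply_rule_to_mol,
    decompose_to_srrs,
    generate_csrrs,
    generate_rules_for_reaction,
    identify_reaction_center,
    map_atoms,
    read_rule_db,
    write_rule_db,
)


def _tsv_record(tmp_path, reaction_smiles, reaction_id="R1", direction="forward"):
    p = tmp_path / f"{reaction_id}.tsv"
    p.write_text("reaction_id\treaction_smiles\tdirection\n"
                 f"{reaction_id}\t{reaction_smiles}\t{direction}\n")
    return read_reaction_table(str(p))[0]


def _by_id(records):
    return {r.reaction_id: r for r in records}


class TestMapAtoms:
    def test_premapped_input_passes_through(self, fixture_set):
        rec = _by_id(fixture_set.reactions)["RXN_DECARB"]
        mr = map_atoms(rec)
        assert mr.mapper_source == "input"
        maps = sorted(a.GetAtomMapNum() for a in mr.substrate_mols[0].GetAtoms())
        assert maps == list(range(1, 14))

    def test_fallback_mcs_partition_tyrosine(self, tmp_path):
        # unmapped decarboxylation: 13 tyrosine atoms must split 10 + 3
        rec = _tsv_record(tmp_path, "NC(Cc1ccc(O)cc1)C(=O)O>>NCCc1ccc(O)cc1.O=C=O")
        mr = map_atoms(rec)
        assert mr.mapper_source == "fallback_mcs"
        sub_maps = {a.GetAtomMapNum() for a in mr.substrate_mols[0].GetAtoms()}
        inherited = [
            sum(1 for a in p.GetAtoms() if a.GetAtomMapNum() in sub_maps)
            for p in mr.product_mols
        ]
        assert sorted(inherited) == [3, 10]

    def test_atom_budget_skips_large_reactions(self, tmp_path):
        chain = "C" * 650  # 650 heavy atoms per side -> 1300 total
        rec = _tsv_record(tmp_path, f"{chain}>>{chain}")
        with pytest.raises(ReactionSkipped) as err:
            map_atoms(rec)
        assert err.value.reason == "atom budget"

    def test_duplicate_map_indices_rejected(self, tmp_path):
        rec = _tsv_record(tmp_path, "[CH3:1][OH:1]>>[CH3:1][OH:2]")
        with pytest.raises(MappingError) as err:
            map_atoms(rec)
        assert "1" in str(err.value)

    def test_cross_side_mismatch_rejected(self, tmp_path):
        # map 2 exists only on the substrate side
        rec = _tsv_record(tmp_path, "[CH3:1][OH:2]>>[CH4:1].[OH2:3]")
        with pytest.raises(MappingError):
            map_atoms(rec)

    def test_fixture_maps_all_validate(self, retained):
        for rec in retained:
            assert map_atoms(rec).mapper_source == "input"


class TestDecomposeToSrrs:
    def test_srr_count_equals_distinct_substrates(self, retained):
        expected = {"RXN_DECARB": 1, "RXN_NITRO": 2, "RXN_ESTER": 2,
                    "RXN_ODEMETH": 2, "RXN_AZO": 2}
        for rec in retained:
            srrs = decompose_to_srrs(map_atoms(rec))
            distinct = len({p.record.key for p in rec.substrates if p.record})
            assert len(srrs) == distinct == expected[rec.reaction_id]

    def test_single_substrate_single_product_forced_main(self, tmp_path):
        rec = _tsv_record(tmp_path, "[CH3:1][OH:2]>>[CH2:1]=[O:2]")
        srrs = decompose_to_srrs(map_atoms(rec))
        assert len(srrs) == 1
        assert srrs[0].main_product.record.key == canonical_key("C=O")

    def test_aspirin_main_product_is_salicylic_acid(self, retained):
        rec = _by_id(retained)["RXN_ESTER"]
        srrs = decompose_to_srrs(map_atoms(rec))
        aspirin = next(s for s in srrs if s.substrate_record.heavy_atom_count == 13)
        # inherited-map-count oracle: salicylic 10 atoms vs acetic 3
        counts = sorted((p.inherited_atoms, p.record.key) for p in aspirin.products)
        assert [c for c, _ in counts] == [3, 10]
        assert aspirin.main_product.record.key == canonical_key("Oc1ccccc1C(=O)O")
        assert aspirin.main_product.inherited_atoms == 10

    def test_stoichiometric_duplicates_collapse(self, retained):
        rec = _by_id(retained)["RXN_NITRO"]  # formate appears three times
        srrs = decompose_to_srrs(map_atoms(rec))
        formate = [s for s in srrs if s.substrate_record.key == canonical_key("O=CO")]
        assert len(formate) == 1


class TestReactionCenter:
    def _srr(self, retained, reaction_id, n_substrate_atoms):
        rec = _by_id(retained)[reaction_id]
        return next(s for s in decompose_to_srrs(map_atoms(rec))
                    if s.substrate_record.heavy_atom_count == n_substrate_atoms)

    def test_decarboxylation_center_from_bond_diff(self, retained):
        srr = self._srr(retained, "RXN_DECARB", 13)
        center = identify_reaction_center(srr)
        symbols = sorted(srr.substrate_mol.GetAtomWithIdx(i).GetSymbol() for i in center)
        # bond-table diff: alpha-C loses the carboxyl bond, carboxyl C loses
        # the C-C bond and gains a C=O, the hydroxyl O loses its hydrogen
        assert symbols == ["C", "C", "O"]
        maps = {srr.substrate_mol.GetAtomWithIdx(i).GetAtomMapNum() for i in center}
        assert maps == {2, 11, 13}

    def test_nitro_reduction_center_includes_n_and_both_o(self, retained):
        srr = self._srr(retained, "RXN_NITRO", 9)
        center = identify_reaction_center(srr)
        symbols = sorted(srr.substrate_mol.GetAtomWithIdx(i).GetSymbol() for i in center)
        assert symbols == ["N", "O", "O"]

    def test_identity_transformation_is_an_error(self, tmp_path):
        rec = _tsv_record(tmp_path, "[CH3:1][OH:2]>>[CH3:1][OH:2]")
        srr = decompose_to_srrs(map_atoms(rec))[0]
        with pytest.raises(MappingError, match="no chemical change"):
            identify_reaction_center(srr)


class TestGenerateCsrrs:
    def test_rule_sets_are_nested_chains(self, retained):
        for rec in retained:
            for srr in decompose_to_srrs(map_atoms(rec)):
                rules = generate_csrrs(srr)
                sizes = [r.num_atoms for r in rules]
                assert sizes == sorted(sizes)
                # reconstruct matched atom sets by re-matching each query side
                mol = Chem.MolFromSmiles(srr.substrate_record.structure)
                prev: set[int] = set()
                for rule in rules:
                    matches = [set(m) for _, m in apply_rule_to_mol(rule.smarts, mol)]
                    containing = [m for m in matches if prev <= m]
                    assert containing, "larger rule must extend a smaller one"
                    prev = min(containing, key=len)

    def test_smallest_rule_is_the_reaction_center(self, retained):
        for rec in retained:
            for srr in decompose_to_srrs(map_atoms(rec)):
                center = identify_reaction_center(srr)
                rules = generate_csrrs(srr)
                assert rules[0].num_atoms == len(center)

    def test_largest_rule_saturates_substrate(self, retained):
        for rec in retained:
            for srr in decompose_to_srrs(map_atoms(rec)):
                rules = generate_csrrs(srr)
                assert rules[-1].num_atoms == min(40, srr.substrate_record.heavy_atom_count)

    def test_forty_atom_cap_on_large_substrate(self, tmp_path):
        # 60-carbon chain acid, decarboxylated: largest rule caps at exactly 40
        n = 58
        chain = "C" * n
        sub = "".join(f"[CH2:{i+1}]" if 0 < i < n - 1 else f"[CH3:{i+1}]"
                      for i in range(n))
        sub = sub.replace(f"[CH3:{n}]", f"[CH2:{n}]") + f"[C:{n+1}](=[O:{n+2}])[OH:{n+3}]"
        prod = "".join(f"[CH2:{i+1}]" if 0 < i < n - 1 else f"[CH3:{i+1}]"
                       for i in range(n))
        rec = _tsv_record(tmp_path, f"{sub}>>{prod}.[O:{n+2}]=[C:{n+1}]=[O:{n+3}]")
        rules = generate_rules_for_reaction(rec)
        assert max(r.num_atoms for r in rules) == 40
        assert all(r.num_atoms <= 40 for r in rules)

    def test_round_trip_for_every_fixture_rule(self, rule_db):
        assert rule_db, "fixture rule database must not be empty"
        for rule in rule_db:
            mol = Chem.MolFromSmiles(rule.substrate_smiles)
            target = canonical_key(rule.product_smiles)
            mains = []
            for prods, _ in apply_rule_to_mol(rule.smarts, mol):
                try:
                    Chem.SanitizeMol(prods[0])
                    mains.append(sanitize_molecule(Chem.MolToSmiles(prods[0])).key)
                except Exception:
                    continue
            assert target in mains, f"rule {rule.rule_id} does not round-trip"

    def test_element_conservation_in_srrs(self, retained):
        # mapped substrate atoms must reappear, element for element
        for rec in retained:
            mr = map_atoms(rec)
            for srr in decompose_to_srrs(mr):
                sub_elems = sorted(a.GetSymbol() for a in srr.substrate_mol.GetAtoms())
                own = {a.GetAtomMapNum() for a in srr.substrate_mol.GetAtoms()}
                prod_elems = sorted(
                    a.GetSymbol()
                    for p in srr.products for a in p.mol.GetAtoms()
                    if a.GetAtomMapNum() in own
                )
                assert sub_elems == prod_elems


class TestRuleDbIO:
    def test_tsv_round_trip_field_by_field(self, rule_db, tmp_path):
        # writing collapses duplicates (same pattern + source pair) across
        # reactions, so the round trip is checked on the loaded set
        path = tmp_path / "rules.tsv"
        write_rule_db(rule_db, str(path))
        loaded = read_rule_db(str(path))
        assert loaded == sorted(
            loaded, key=lambda r: (r.reaction_id, r.num_atoms, r.rule_id))
        again = tmp_path / "again.tsv"
        write_rule_db(loaded, str(again))
        assert read_rule_db(str(again)) == loaded
        assert {(r.smarts, r.substrate_smiles, r.product_smiles) for r in loaded} == \
               {(r.smarts, r.substrate_smiles, r.product_smiles) for r in rule_db}

    def test_json_round_trip(self, rule_db, tmp_path):
        tsv, js = tmp_path / "rules.tsv", tmp_path / "rules.json"
        write_rule_db(rule_db, str(tsv))
        write_rule_db(rule_db, str(js))
        assert read_rule_db(str(js)) == read_rule_db(str(tsv))

    def test_write_is_deterministic(self, rule_db, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_rule_db(rule_db, str(p1))
        write_rule_db(list(reversed(rule_db)), str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_duplicate_rules_merge_annotations(self, rule_db, tmp_path):
        from dataclasses import replace

        dup = replace(rule_db[0], rule_id="other", ec_numbers=("9.9.9.9",),
                      organism_refs=("FIX_ORG_EXTRA",))
        path = tmp_path / "rules.tsv"
        write_rule_db(list(rule_db) + [dup], str(path))
        loaded = read_rule_db(str(path))
        assert len(loaded) == len(read_rule_db(str(path)))
        merged = next(r for r in loaded if r.smarts == rule_db[0].smarts
                      and r.substrate_smiles == rule_db[0].substrate_smiles)
        assert "9.9.9.9" in merged.ec_numbers
        assert "FIX_ORG_EXTRA" in merged.organism_refs

    def test_empty_database_round_trips(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_rule_db([], str(path))
        assert read_rule_db(str(path)) == []

    def test_version_mismatch_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("# other-version\nrule_id\n")
        with pytest.raises(ValueError, match="version"):
            read_rule_db(str(path))

    def test_corrupted_row_names_rule_id(self, rule_db, tmp_path):
        path = tmp_path / "rules.tsv"
        write_rule_db(rule_db[:1], str(path))
        lines = path.read_text().splitlines()
        lines[-1] = "\t".join(lines[-1].split("\t")[:4])  # truncate the row
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="corrupted row"):
            read_rule_db(str(path))
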