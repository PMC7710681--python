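"""Matrix data model, polarity policies, and file round trips."""

import pytest

from morphoclad import (
    CharacterDefinition,
    CharacterMatrix,
    MatrixFormatError,
    StateCode,
    apply_polarity_policy,
    derived_taxon_set,
    laophontodes_matrix,
    load_matrix,
    write_matrix,
    write_nexus,
)


def small_matrix():
    chars = [
        CharacterDefinition(1, "seta lost", "seta present"),
        CharacterDefinition(2, "segment fused", "segment free"),
    ]
    cells = [
        [StateCode.APOMORPHIC, StateCode.PLESIOMORPHIC_VARIABLE, StateCode.MISSING],
        [StateCode.APOMORPHIC_UNCERTAIN, StateCode.PLESIOMORPHIC,
         StateCode.PLESIOMORPHIC_UNCERTAIN],
    ]
    return CharacterMatrix(["tax_a", "tax_b", "tax_c"], chars, cells)


class TestLoad:
    def test_minimal_csv(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("id,description,A,B\n1,some seta lost,0,1\n")
        m = load_matrix(path)
        assert m.taxa == ["A", "B"]
        assert m.cell(1, "B") is StateCode.APOMORPHIC
        assert m.cell(1, "A") is StateCode.PLESIOMORPHIC

    def test_unknown_token_reports_coordinates(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("id,description,A,B\n1,x,0,2\n")
        with pytest.raises(MatrixFormatError, match=r"line 2, column 4.*'2'"):
            load_matrix(path)

    def test_ragged_row_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("id,description,A,B\n1,x,0\n")
        with pytest.raises(MatrixFormatError, match="line 2"):
            load_matrix(path)

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("id,description\n")
        with pytest.raises(MatrixFormatError, match="line 1"):
            load_matrix(path)

    def test_taxa_as_rows_layout(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("taxon,1,2\nA,0,1\nB,1,0*\n")
        m = load_matrix(path, taxa_as_rows=True)
        assert m.taxa == ["A", "B"]
        assert m.cell(2, "B") is StateCode.PLESIOMORPHIC_VARIABLE


class TestRoundTrip:
    @pytest.mark.parametrize("dialect,suffix", [
        ("csv", ".csv"), ("tsv", ".tsv"), ("nexus", ".nex"),
    ])
    def test_all_codes_survive(self, tmp_path, dialect, suffix):
        m = small_matrix()
        path = tmp_path / f"m{suffix}"
        write_matrix(m, path, dialect)
        again = load_matrix(path)
        assert again.taxa == m.taxa
        assert again.cells == m.cells

    @pytest.mark.parametrize("dialect,suffix", [
        ("csv", ".csv"), ("tsv", ".tsv"), ("nexus", ".nex"),
    ])
    def test_packaged_matrix(self, tmp_path, matrix, dialect, suffix):
        path = tmp_path / f"fixture{suffix}"
        write_matrix(matrix, path, dialect)
        again = load_matrix(path)
        assert again.cells == matrix.cells
        if dialect == "nexus":
            assert again.convergence_annotations == matrix.convergence_annotations
            assert [c.description for c in again.characters] == [
                c.description for c in matrix.characters
            ]

    def test_nexus_sidecar_single_annotation(self, tmp_path):
        m = CharacterMatrix(
            ["A"], [CharacterDefinition(1, "x", "y")],
            [[StateCode.PLESIOMORPHIC_VARIABLE]],
        )
        path = tmp_path / "m.nex"
        write_nexus(m, path)
        codes = [l for l in path.read_text().splitlines() if l.strip().startswith("CODE")]
        assert len(codes) == 1
        assert "0*" in codes[0]

    def test_empty_taxa_rejected(self):
        with pytest.raises(ValueError, match="no taxa"):
            CharacterMatrix([], [CharacterDefinition(1, "x")], [[]])


class TestValidation:
    def test_duplicate_taxa_rejected(self):
        with pytest.raises(ValueError, match="duplicate taxon"):
            CharacterMatrix(
                ["A", "A"], [CharacterDefinition(1, "x")],
                [[StateCode.APOMORPHIC, StateCode.APOMORPHIC]],
            )

    def test_annotation_must_mark_apomorphic_cell(self):
        with pytest.raises(ValueError, match="apomorphic"):
            CharacterMatrix(
                ["A"], [CharacterDefinition(1, "x")],
                [[StateCode.PLESIOMORPHIC]],
                convergence_annotations={(1, "A")},
            )

    def test_empty_description_rejected(self):
        with pytest.raises(ValueError, match="empty description"):
            CharacterDefinition(1, "")


class TestPolarityPolicy:
    def test_as_argued_resolutions(self, matrix):
        r = apply_polarity_policy(matrix, "as-argued")
        assert r.cell(2, "L_spongiosus") is StateCode.APOMORPHIC
        assert r.cell(2, "L_macclintocki") is StateCode.PLESIOMORPHIC
        assert r.cell(3, "L_whitsoni") is StateCode.PLESIOMORPHIC
        assert r.cell(2, "L_sarsi") is StateCode.MISSING

    def test_conservative_discards_qualified_codes(self, matrix):
        r = apply_polarity_policy(matrix, "conservative")
        for char_id, taxon in [(2, "L_spongiosus"), (2, "L_macclintocki"),
                               (3, "L_whitsoni"), (26, "L_whitsoni")]:
            assert r.cell(char_id, taxon) is StateCode.MISSING

    def test_identity_on_clean_matrix(self, tmp_path):
        m = CharacterMatrix(
            ["A", "B"], [CharacterDefinition(1, "x")],
            [[StateCode.PLESIOMORPHIC, StateCode.APOMORPHIC]],
        )
        assert apply_polarity_policy(m).cells == m.cells

    def test_unknown_policy(self, matrix):
        with pytest.raises(ValueError, match="unknown polarity policy"):
            apply_polarity_policy(matrix, "optimistic")


class TestDerivedSets:
    def test_packaged_dimensions(self, matrix):
        assert matrix.n_characters == 39
        assert matrix.n_taxa == 12

    def test_char_1_derived_everywhere(self, resolved):
        assert derived_taxon_set(resolved, 1) == set(resolved.taxa)

    @pytest.mark.parametrize("char_id,size", [
        (3, 9), (6, 8), (7, 8), (8, 6), (9, 4), (10, 3), (12, 2),
    ])
    def test_group_sizes(self, resolved, char_id, size):
        assert len(derived_taxon_set(resolved, char_id)) == size

    def test_singleton_characters(self, resolved):
        assert derived_taxon_set(resolved, 15) == {"L_sarsi"}

    def test_all_but_char_1_are_proper_subsets(self, resolved):
        taxa = set(resolved.taxa)
        for c in resolved.characters:
            if c.id == 1:
                continue
            assert derived_taxon_set(resolved, c.id) < taxa

    def test_unknown_char_id(self, resolved):
        with pytest.raises(KeyError):
            derived_taxon_set(resolved, 99)
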