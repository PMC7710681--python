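"""Synapomorphy grouping, conflict arbitration, and cladogram assembly."""

import pytest

from morphoclad import (
    CharacterDefinition,
    ResolvedMatrix,
    SimulationConfig,
    StateCode,
    apply_polarity_policy,
    arbitrate,
    build_cladogram,
    characters_compatible,
    derived_taxon_set,
    group_by_synapomorphy,
    parsimony_length,
    rf_distance,
    simulate,
    tree_from_clades,
)


def resolved_from_rows(taxa, rows):
    chars = [CharacterDefinition(i + 1, f"char {i + 1}") for i in range(len(rows))]
    cells = [[StateCode.parse(tok) for tok in row.split()] for row in rows]
    return ResolvedMatrix(taxa, chars, cells)


def fixture_report(resolved):
    hyps, conflicts = group_by_synapomorphy(resolved)
    return arbitrate(hyps, conflicts, resolved)


class TestCompatibility:
    def test_nested_sets_compatible(self, resolved):
        assert characters_compatible(
            derived_taxon_set(resolved, 8), derived_taxon_set(resolved, 6)
        )

    def test_overlapping_sets_conflict(self, resolved):
        assert not characters_compatible(
            derived_taxon_set(resolved, 3), derived_taxon_set(resolved, 4)
        )

    def test_empty_set_compatible_with_anything(self):
        assert characters_compatible(frozenset(), frozenset({"A", "B"}))


class TestGrouping:
    def test_nine_species_group_supported_by_chars_2_and_3(self, resolved):
        hyps, _ = group_by_synapomorphy(resolved)
        nine = [h for h in hyps if len(h.taxa) == 9 and 3 in h.supporting_chars]
        assert len(nine) == 1
        # char 2 joins despite the unknown male of L. sarsi
        assert nine[0].supporting_chars == {2, 3}

    def test_sister_pair_supported_by_three_characters(self, resolved):
        hyps, _ = group_by_synapomorphy(resolved)
        pair = [h for h in hyps if h.taxa == frozenset({"L_sarsi", "L_scottorum"})]
        assert pair and pair[0].supporting_chars == {12, 13, 14}

    def test_char_30_forms_its_own_hypothesis(self, resolved):
        hyps, _ = group_by_synapomorphy(resolved)
        h30 = [h for h in hyps if 30 in h.supporting_chars]
        assert h30 and h30[0].taxa == frozenset({"L_typicus", "L_macclintocki"})

    def test_autapomorphies_only_gives_no_hypotheses(self):
        m = resolved_from_rows(["A", "B", "C"], ["1 0 0", "0 1 0", "0 0 1"])
        hyps, conflicts = group_by_synapomorphy(m)
        assert hyps == [] and conflicts == []

    def test_strict_missing_mode_demotes_char_2(self, resolved):
        hyps, _ = group_by_synapomorphy(resolved, missing_mode="strict")
        supported = set().union(*(h.supporting_chars for h in hyps))
        assert 2 not in supported and 30 not in supported
        assert 3 in supported


class TestArbitration:
    def test_fixture_convergences(self, resolved):
        report = fixture_report(resolved)
        assert report.convergent_ids == {4, 5, 17, 30}

    def test_fixture_accepted_clade_sizes(self, resolved):
        report = fixture_report(resolved)
        sizes = sorted(
            (len(h.taxa) for h in report.accepted_clades if len(h.taxa) < 12),
            reverse=True,
        )
        assert sizes == [9, 8, 6, 4, 3, 2, 2]

    def test_fixture_autapomorphies(self, resolved):
        report = fixture_report(resolved)
        expected = {
            "L_sarsi": {15},
            "L_scottorum": {16},
            "L_volkerlehmanskii": {18, 19, 20, 21, 22, 23},
            "L_georgei": {24, 25},
            "L_gertraudae": {26},
            "L_spongiosus": {27},
            "L_mourois": {29},
            "L_monsmaris": {31, 32},
            "L_sabinegeorgeae": {33, 34, 35, 36, 37},
            "L_whitsoni": {38, 39},
        }
        assert report.autapomorphies == expected

    def test_convergence_origins_enumerated(self, resolved):
        report = fixture_report(resolved)
        assert report.convergences[17] == [
            frozenset({"L_scottorum"}), frozenset({"L_spongiosus"}),
        ]
        assert frozenset({"L_macclintocki"}) in report.convergences[4]

    def test_character_accounting_partitions_all_39(self, resolved):
        report = fixture_report(resolved)
        buckets = report.character_accounting()
        assert not buckets["uninformative"]
        ids = [i for bucket in buckets.values() for i in bucket]
        assert sorted(ids) == list(range(1, 40))

    def test_accepted_clades_pairwise_compatible(self, resolved):
        report = fixture_report(resolved)
        accepted = [h.taxa for h in report.accepted_clades]
        for i, a in enumerate(accepted):
            for b in accepted[i + 1 :]:
                assert characters_compatible(a, b)

    def test_unconflicted_hypotheses_never_discarded(self):
        for seed in range(5):
            cfg = SimulationConfig(
                n_taxa=9, n_chars=14, homoplasy_fraction=0.4,
                missing_rate=0.0, uncertainty_rate=0.0, seed=seed,
            )
            matrix, _ = simulate(cfg)
            resolved = apply_polarity_policy(matrix)
            hyps, conflicts = group_by_synapomorphy(resolved)
            in_conflict = {id(h) for pair in conflicts for h in pair}
            report = arbitrate(hyps, conflicts, resolved)
            accepted_ids = {id(h) for h in report.accepted_clades}
            for h in hyps:
                if id(h) not in in_conflict:
                    assert id(h) in accepted_ids

    def test_fully_compatible_matrix_has_no_convergences(self):
        cfg = SimulationConfig(
            n_taxa=8, n_chars=12, homoplasy_fraction=0.0,
            missing_rate=0.0, uncertainty_rate=0.0, seed=4,
        )
        matrix, _ = simulate(cfg)
        resolved = apply_polarity_policy(matrix)
        hyps, conflicts = group_by_synapomorphy(resolved)
        assert conflicts == []
        report = arbitrate(hyps, conflicts, resolved)
        assert report.convergences == {}


class TestCladogram:
    def test_fixture_reproduces_reference_topology(self, resolved, reference):
        report = fixture_report(resolved)
        tree = build_cladogram(report)
        assert rf_distance(tree, reference) == 0

    def test_empty_report_gives_star(self):
        m = resolved_from_rows(["A", "B", "C"], ["1 0 0"])
        hyps, conflicts = group_by_synapomorphy(m)
        report = arbitrate(hyps, conflicts, m)
        tree = build_cladogram(report)
        assert len(tree.root.children) == 3

    def test_recovers_true_tree_without_homoplasy(self):
        for seed in range(3):
            cfg = SimulationConfig(
                n_taxa=9, n_chars=20, homoplasy_fraction=0.0,
                missing_rate=0.0, uncertainty_rate=0.0, seed=seed,
                cover_all_clades=True,
            )
            matrix, truth = simulate(cfg)
            resolved = apply_polarity_policy(matrix)
            hyps, conflicts = group_by_synapomorphy(resolved)
            tree = build_cladogram(arbitrate(hyps, conflicts, resolved))
            assert rf_distance(tree, truth.true_tree) == 0
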