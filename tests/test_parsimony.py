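"""Parsimony lengths, reconstructions and homoplasy indices, checked
against a brute-force state-assignment oracle."""

import math

import numpy as np
import pytest

from morphoclad import (
    CharacterDefinition,
    CharacterMatrix,
    ResolvedMatrix,
    SimulationConfig,
    StateCode,
    apply_polarity_policy,
    consistency_index,
    convergent_characters,
    parsimony_length,
    per_character_lengths,
    parse_tree,
    reconstruct,
    retention_index,
    sample_tree,
    simulate,
    tree_from_clades,
)
from morphoclad.tree import Cladogram, Node

from oracle import brute_force_length, fitch_length


def resolved_from_rows(taxa, rows):
    chars = [CharacterDefinition(i + 1, f"char {i + 1}") for i in range(len(rows))]
    cells = [[StateCode.parse(tok) for tok in row.split()] for row in rows]
    return ResolvedMatrix(taxa, chars, cells)


def random_instance(seed, n_taxa=6, n_chars=8, homoplasy=0.3, missing=0.05):
    cfg = SimulationConfig(
        n_taxa=n_taxa, n_chars=n_chars, homoplasy_fraction=homoplasy,
        missing_rate=missing, uncertainty_rate=0.0, seed=seed,
    )
    matrix, truth = simulate(cfg)
    return apply_polarity_policy(matrix), truth


class TestLength:
    def test_all_plesiomorphic_costs_nothing(self):
        m = resolved_from_rows(["A", "B", "C"], ["0 0 0", "0 0 0"])
        assert parsimony_length(parse_tree("(A,(B,C));"), m) == 0

    def test_all_derived_costs_one_root_edge_origin(self):
        m = resolved_from_rows(["A", "B", "C"], ["1 1 1"])
        assert parsimony_length(parse_tree("(A,(B,C));"), m) == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_assignment_oracle_on_random_instances(self, seed):
        resolved, truth = random_instance(seed)
        assert parsimony_length(truth.true_tree, resolved) == brute_force_length(
            truth.true_tree, resolved
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_oracle_on_polytomy_trees(self, seed):
        # collapse random internal edges, then recompute both ways
        resolved, truth = random_instance(seed, n_taxa=7)
        clades = sorted(truth.true_tree.clades(), key=sorted)
        kept = clades[:: 2]
        poly = tree_from_clades(kept, sorted(truth.true_tree.taxa))
        assert parsimony_length(poly, resolved) == brute_force_length(poly, resolved)

    def test_reference_length_is_35_plus_two_convergent_pairs(
        self, reference, resolved
    ):
        # 35 single-origin characters + 4 characters with two origins
        assert parsimony_length(reference, resolved) == 43
        assert brute_force_length(reference, resolved) == 43

    def test_star_tree_length_matches_oracle(self, reference, resolved):
        star = tree_from_clades([], sorted(reference.taxa))
        assert parsimony_length(star, resolved) == brute_force_length(star, resolved)
        assert parsimony_length(star, resolved) >= parsimony_length(
            reference, resolved
        )

    def test_fitch_oracle_agrees_with_assignment_oracle(self):
        for seed in range(4):
            resolved, truth = random_instance(seed, n_taxa=6)
            assert fitch_length(truth.true_tree, resolved) == brute_force_length(
                truth.true_tree, resolved
            )

    def test_leaf_mismatch_lists_difference(self, resolved):
        tree = parse_tree("(L_sarsi,L_scottorum);")
        with pytest.raises(ValueError, match="L_typicus"):
            parsimony_length(tree, resolved)


class TestInvariance:
    def test_child_reordering(self, reference, resolved):
        shuffled = parse_tree(
            "((L_monsmaris,((L_spongiosus,(L_georgei,(L_volkerlehmanskii,"
            "(L_scottorum,L_sarsi))),L_gertraudae),(L_typicus,L_mourois))),"
            "L_sabinegeorgeae,L_macclintocki,L_whitsoni);"
        )
        assert shuffled == reference
        assert parsimony_length(shuffled, resolved) == parsimony_length(
            reference, resolved
        )

    def test_leaf_relabeling_bijection(self):
        resolved, truth = random_instance(11)
        mapping = {t: f"x_{t}" for t in resolved.taxa}

        def relabel(node):
            if node.is_leaf:
                return Node(label=mapping[node.label])
            return Node(children=[relabel(c) for c in node.children])

        renamed_tree = Cladogram(relabel(truth.true_tree.root))
        renamed_matrix = ResolvedMatrix(
            [mapping[t] for t in resolved.taxa], resolved.characters, resolved.cells
        )
        assert parsimony_length(renamed_tree, renamed_matrix) == parsimony_length(
            truth.true_tree, resolved
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_refining_a_polytomy_never_increases_length(self, seed):
        resolved, truth = random_instance(seed, n_taxa=8, n_chars=10)
        full = truth.true_tree
        clades = sorted(full.clades(), key=sorted)
        rng = np.random.default_rng(seed)
        kept = [c for c in clades if rng.random() < 0.5]
        collapsed = tree_from_clades(kept, sorted(full.taxa))
        assert parsimony_length(full, resolved) <= parsimony_length(
            collapsed, resolved
        )


class TestReconstruct:
    def test_autapomorphy_on_terminal_edge(self, reference, resolved):
        rec = {r.char_id: r for r in reconstruct(reference, resolved)}
        assert rec[18].origin_edges == {frozenset({"L_volkerlehmanskii"})}

    def test_convergent_character_on_two_terminal_edges(self, reference, resolved):
        rec = {r.char_id: r for r in reconstruct(reference, resolved)}
        assert rec[17].origin_edges == {
            frozenset({"L_scottorum"}), frozenset({"L_spongiosus"}),
        }
        assert rec[30].origin_edges == {
            frozenset({"L_typicus"}), frozenset({"L_macclintocki"}),
        }

    def test_group_autapomorphy_on_root_edge(self, reference, resolved):
        rec = {r.char_id: r for r in reconstruct(reference, resolved)}
        assert rec[1].origin_edges == {frozenset(resolved.taxa)}
        assert rec[1].origin_count == 1

    def test_character_with_missing_cell_keeps_single_origin(
        self, reference, resolved
    ):
        nine = frozenset(resolved.taxa) - {
            "L_macclintocki", "L_sabinegeorgeae", "L_whitsoni",
        }
        rec = {r.char_id: r for r in reconstruct(reference, resolved)}
        assert rec[2].origin_edges == {nine}

    def test_steps_sum_to_length(self, reference, resolved):
        for placement in ("delay-changes", "accelerate-changes"):
            recs = reconstruct(reference, resolved, placement)
            assert sum(r.steps for r in recs) == parsimony_length(
                reference, resolved
            )
            for r in recs:
                assert r.origin_count >= 1

    def test_delay_prefers_parallel_origins_over_reversal(self):
        # two distant derived leaves: delay must give two origins, no reversal
        m = resolved_from_rows(["A", "B", "C", "D"], ["1 0 0 1"])
        tree = parse_tree("((A,B),(C,D));")
        (rec,) = reconstruct(tree, m, "delay-changes")
        assert rec.origin_count == 2 and not rec.reversal_edges

    def test_unknown_placement_rejected(self, reference, resolved):
        with pytest.raises(ValueError, match="placement"):
            reconstruct(reference, resolved, "random")

    def test_convergent_characters_on_fixture(self, reference, resolved):
        assert convergent_characters(reference, resolved) == {4, 5, 17, 30}

    def test_compatible_matrix_has_no_convergence(self):
        cfg = SimulationConfig(
            n_taxa=8, n_chars=12, homoplasy_fraction=0.0,
            missing_rate=0.0, uncertainty_rate=0.0, seed=5,
        )
        matrix, truth = simulate(cfg)
        resolved = apply_polarity_policy(matrix)
        assert convergent_characters(truth.true_tree, resolved) == set()


class TestIndices:
    def test_ci_is_one_without_homoplasy(self):
        cfg = SimulationConfig(
            n_taxa=8, n_chars=12, homoplasy_fraction=0.0,
            missing_rate=0.0, uncertainty_rate=0.0, seed=2,
        )
        matrix, truth = simulate(cfg)
        resolved = apply_polarity_policy(matrix)
        assert consistency_index(truth.true_tree, resolved) == 1.0

    def test_fixture_ci(self, reference, resolved):
        assert consistency_index(reference, resolved) == pytest.approx(39 / 43)

    def test_star_tree_ci_not_higher(self, reference, resolved):
        star = tree_from_clades([], sorted(reference.taxa))
        assert consistency_index(star, resolved) <= consistency_index(
            reference, resolved
        )

    def test_ri_bounds(self, reference, resolved):
        ri = retention_index(reference, resolved)
        assert 0.0 <= ri <= 1.0

    def test_zero_step_matrix_flagged_undefined(self):
        m = resolved_from_rows(["A", "B"], ["0 0"])
        assert math.isnan(consistency_index(parse_tree("(A,B);"), m))
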