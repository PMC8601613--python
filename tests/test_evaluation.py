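"""Tests for rule benchmarking and FBA gene-deletion validation."""

from __future__ import annotations

import pytest

from gprules.gpr_algebra import GeneRef, RuleClass
from gprules.evaluation import (
    InfeasibleWildTypeError,
    Viability,
    ViabilityOutcome,
    confusion_matrix,
    evaluate_rules_table,
    evaluation_category,
    gene_deletion_viability,
    global_jaccard,
    single_gene_deletions,
)
from gprules.snapshot_io import RuleRow, RulesTable


def table(*rows):
    return RulesTable(tuple(RuleRow(*row) for row in rows))


class TestEvaluateRulesTable:
    def test_perfect_matches_counted(self):
        summary = evaluate_rules_table(
            table(
                ("r1", "g1", "g1", ""),
                ("r2", "g2 and g3", "g3 and g2", ""),
                ("r3", "g4", "g5", ""),
                ("r4", "", "", ""),
            )
        )
        assert summary.n_perfect == 3  # r1, r2 and the doubly-empty r4
        assert summary.counts[RuleClass.ONE_GENE].perfect == 1
        assert summary.counts[RuleClass.AND].perfect == 1
        assert summary.counts[RuleClass.NO_GENE].perfect == 1
        assert summary.counts[RuleClass.ONE_GENE].not_automatic == 1

    def test_operator_mismatch_scored_with_hamming(self):
        summary = evaluate_rules_table(table(("r1", "g1 and g2", "g1 or g2", "")))
        result = summary.per_reaction["r1"]
        assert result.jaccard == 1.0
        assert result.hamming_similarity == pytest.approx(0.5)

    def test_corrected_label_counts_as_automatic(self):
        summary = evaluate_rules_table(
            table(
                ("r1", "g1", "g1", "Perfect match"),
                ("r2", "g2", "g3", "Corrected"),
                ("r3", "g4", "g5", "Not automatically reconstructed"),
            )
        )
        counts = summary.counts[RuleClass.ONE_GENE]
        assert (counts.perfect, counts.corrected, counts.not_automatic) == (1, 1, 1)
        assert summary.automatic_fraction == pytest.approx(2 / 3)
        assert summary.automatic_fraction + summary.not_automatic_fraction == pytest.approx(1.0)

    def test_unparseable_rows_excluded_and_reported(self):
        summary = evaluate_rules_table(table(("r1", "g1 and", "g1", ""), ("r2", "g1", "g1", "")))
        assert summary.n_rows == 1
        assert summary.excluded[0][0] == "r1"

    def test_permutation_invariant_counts(self):
        rows = [
            ("r1", "g1", "g1", ""),
            ("r2", "g2 and g3", "g2 or g3", ""),
            ("r3", "", "g9", ""),
        ]
        a = evaluate_rules_table(table(*rows))
        b = evaluate_rules_table(table(*reversed(rows)))
        assert a.counts == b.counts
        assert a.global_jaccard == b.global_jaccard

    def test_class_taken_from_original_rule(self):
        summary = evaluate_rules_table(table(("r1", "(g1 and g2) or g3", "g1", "")))
        assert summary.counts[RuleClass.MIXED].total == 1


class TestGlobalJaccard:
    def test_identical_tables_score_one(self):
        t = table(("r1", "g1 and g2", "g1 and g2", ""))
        assert global_jaccard(t) == 1.0

    def test_disjoint_universes_score_zero(self):
        t = table(("r1", "g1", "g2", ""))
        assert global_jaccard(t) == 0.0

    def test_pooled_one_shared_of_three(self):
        t = table(("r1", "g1 or g2", "g1", ""), ("r2", "", "g3", ""))
        assert global_jaccard(t) == pytest.approx(1 / 3)

    def test_mean_method_averages_per_reaction(self):
        t = table(("r1", "g1", "g1", ""), ("r2", "g2", "g3", ""))
        assert global_jaccard(t, method="mean") == pytest.approx(0.5)


class TestGeneDeletions:
    def test_hand_solved_viability_calls(self, toy_fba):
        """Deletion calls match the hand-solved linear programs.

        In the toy chain the only A->B step needs g1 (essential); the
        two B->P routes back each other up, so g2..g5 are all viable.
        """
        model, rules = toy_fba
        expected = {
            "g1": Viability.NOT_VIABLE,
            "g2": Viability.VIABLE,
            "g3": Viability.VIABLE,
            "g4": Viability.VIABLE,
            "g5": Viability.VIABLE,
        }
        for name, want in expected.items():
            got = gene_deletion_viability(model, rules, "BIO", GeneRef(name))
            assert got == want, name

    def test_gene_absent_from_all_rules_is_viable(self, toy_fba):
        model, rules = toy_fba
        assert gene_deletion_viability(model, rules, "BIO", GeneRef("zz")) == Viability.VIABLE

    def test_empty_rules_never_constrained(self, toy_fba):
        model, rules = toy_fba
        # EX_A and BIO carry empty rules; deleting every named gene must
        # close the pathway through rules, not through the empty ones
        genes = [GeneRef(f"g{i}") for i in range(1, 6)]
        assert gene_deletion_viability(model, rules, "BIO", genes) == Viability.NOT_VIABLE

    def test_deletion_monotonicity(self, toy_fba):
        """Deleting a superset never rescues a lethal deletion."""
        from itertools import combinations

        model, rules = toy_fba
        names = ["g1", "g2", "g3", "g4", "g5"]
        calls = {}
        for r in (1, 2):
            for combo in combinations(names, r):
                calls[combo] = gene_deletion_viability(
                    model, rules, "BIO", [GeneRef(n) for n in combo]
                )
        for small, verdict in calls.items():
            if verdict == Viability.NOT_VIABLE:
                for big, big_verdict in calls.items():
                    if set(small) <= set(big):
                        assert big_verdict == Viability.NOT_VIABLE

    def test_crosscheck_against_cobra_knockouts(self, toy_fba):
        """Independent route: COBRApy's own GPR evaluation and knockout."""
        import cobra

        model, rules = toy_fba
        reference = cobra.Model("ref")
        for rxn in model.reactions:
            clone = cobra.Reaction(rxn.id)
            clone.lower_bound, clone.upper_bound = rxn.bounds
            reference.add_reactions([clone])
            clone.add_metabolites(
                {cobra.Metabolite(m.id, compartment=m.compartment): c
                 for m, c in rxn.metabolites.items()}
            )
        from gprules.gpr_algebra import serialize_rule

        for rxn in reference.reactions:
            rxn.gene_reaction_rule = serialize_rule(rules[rxn.id])
        reference.objective = "BIO"
        for name in ("g1", "g2", "g3", "g4", "g5"):
            with reference:
                reference.genes.get_by_id(name).knock_out()
                cobra_viable = reference.slim_optimize() > 1e-9
            ours = gene_deletion_viability(model, rules, "BIO", GeneRef(name))
            assert (ours == Viability.VIABLE) == cobra_viable, name

    def test_infeasible_wild_type_rejected(self, toy_fba):
        model, rules = toy_fba
        with model:
            model.reactions.EX_A.upper_bound = 0.0
            with pytest.raises(InfeasibleWildTypeError):
                gene_deletion_viability(model, rules, "BIO", GeneRef("g1"))

    def test_single_gene_deletions_pairs_with_annotations(self, toy_fba):
        model, rules = toy_fba
        annotations = {
            GeneRef("g1"): Viability.NOT_VIABLE,
            GeneRef("g2"): Viability.VIABLE,
            GeneRef("g3"): Viability.NOT_VIABLE,  # deliberately wrong annotation
        }
        outcomes = single_gene_deletions(model, rules, "BIO", annotations)
        matrix = confusion_matrix(outcomes)
        assert matrix.total == 3
        assert matrix.accuracy == pytest.approx(2 / 3)


class TestConfusionMatrix:
    def outcome(self, predicted, annotated, name="g1"):
        return ViabilityOutcome(GeneRef(name), predicted, annotated)

    def test_all_correct(self):
        outcomes = [
            self.outcome(Viability.VIABLE, Viability.VIABLE, "a"),
            self.outcome(Viability.NOT_VIABLE, Viability.NOT_VIABLE, "b"),
        ]
        assert confusion_matrix(outcomes).accuracy == 1.0

    def test_half_correct_and_frequencies(self):
        outcomes = [
            self.outcome(Viability.VIABLE, Viability.VIABLE, "a"),
            self.outcome(Viability.VIABLE, Viability.NOT_VIABLE, "b"),
            self.outcome(Viability.NOT_VIABLE, Viability.VIABLE, "c"),
            self.outcome(Viability.NOT_VIABLE, Viability.NOT_VIABLE, "d"),
        ]
        matrix = confusion_matrix(outcomes)
        assert matrix.accuracy == 0.5
        assert sum(matrix.frequencies().values()) == pytest.approx(1.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([])


class TestEvaluationCategory:
    @pytest.mark.parametrize(
        "label, expected",
        [
            ("Perfect match", "perfect"),
            ("Corrected", "corrected"),
            ("corrected by some tool", "corrected"),
            ("Not automatically reconstructed", "not_automatic"),
            ("", None),
            ("mystery", None),
        ],
    )
    def test_prefix_normalization(self, label, expected):
        assert evaluation_category(label) == expected
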