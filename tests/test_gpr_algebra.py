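"""Unit and property tests for the GPR Boolean algebra."""

from __future__ import annotations

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gprules.gpr_algebra import (
    EMPTY,
    Equivalence,
    GeneRef,
    GPRExpression,
    GPRParseError,
    MatchStatus,
    MissingGeneError,
    RuleClass,
    TruthTableCapacityError,
    canonical_form,
    classify_rule,
    compare_rules,
    evaluate,
    hamming_similarity,
    jaccard_index,
    parse_rule,
    rules_equivalent,
    serialize_rule,
    truth_table,
)


def genes(*names):
    return frozenset(GeneRef(n) for n in names)


class TestGeneRef:
    @pytest.mark.parametrize("bad", ["", "a b", "g(1", "and", "OR"])
    def test_invalid_identifiers_rejected(self, bad):
        with pytest.raises(ValueError):
            GeneRef(bad)

    def test_case_preserving_comparison(self):
        assert GeneRef("YAL054C") != GeneRef("yal054c")


class TestParse:
    def test_empty_text_is_empty_rule(self):
        assert parse_rule("") is EMPTY
        assert parse_rule("   ") is EMPTY

    def test_parenthesized_and_inside_or(self):
        expr = parse_rule("(g1 and g2) or g3")
        assert expr.kind.value == "or"
        kinds = sorted(c.kind.value for c in expr.children)
        assert kinds == ["and", "gene"]
        assert expr.genes() == genes("g1", "g2", "g3")

    def test_precedence_and_binds_tighter_than_or(self):
        assert parse_rule("g1 and g2 or g3") == parse_rule("(g1 and g2) or g3")

    def test_keyword_case_and_whitespace_tolerance(self):
        assert parse_rule("g1 AND  g2   Or g3") == parse_rule("(g1 and g2) or g3")

    def test_flattening_and_dedup(self):
        expr = parse_rule("g1 or (g2 or g3) or g1")
        assert len(expr.children) == 3
        assert all(c.kind.value == "gene" for c in expr.children)

    @pytest.mark.parametrize(
        "text", ["(g1 and g2", "g1 and", "and g1", "g1 or or g2", "()", "g1)"]
    )
    def test_malformed_rules_report_offset(self, text):
        with pytest.raises(GPRParseError) as err:
            parse_rule(text)
        assert err.value.offset >= 0


class TestSerialize:
    def test_empty_serializes_to_empty_string(self):
        assert serialize_rule(EMPTY) == ""

    def test_single_gene(self):
        assert serialize_rule(parse_rule("g5")) == "g5"

    def test_canonical_child_order(self):
        # children ordered by gene-set signature regardless of input order
        assert serialize_rule(parse_rule("g3 or (g2 and g1)")) == "(g1 and g2) or g3"
        assert serialize_rule(parse_rule("(g2 and g1) or g3")) == "(g1 and g2) or g3"

    @given(st.integers(0, 10**6))
    @settings(max_examples=50, deadline=None)
    def test_serialize_parse_fixed_point(self, seed):
        from conftest import random_expr, render

        rng = random.Random(seed)
        text = render(random_expr(rng, [f"g{i}" for i in range(6)]))
        once = serialize_rule(parse_rule(text))
        assert serialize_rule(parse_rule(once)) == once


class TestEvaluate:
    @pytest.mark.parametrize(
        "rule, assignment, expected",
        [
            ("g1 and g2", {"g1": True, "g2": False}, False),
            ("g1 or g2", {"g1": True, "g2": False}, True),
            ("(g1 and g2) or g3", {"g1": False, "g2": True, "g3": True}, True),
            ("(g1 and g2) or g3", {"g1": True, "g2": True, "g3": False}, True),
            ("(g1 and g2) or g3", {"g1": False, "g2": True, "g3": False}, False),
        ],
    )
    def test_boolean_semantics(self, rule, assignment, expected):
        refs = {GeneRef(k): v for k, v in assignment.items()}
        assert evaluate(parse_rule(rule), refs) is expected

    def test_empty_rule_is_false(self):
        assert evaluate(EMPTY, {}) is False

    def test_missing_gene_named_in_error(self):
        with pytest.raises(MissingGeneError, match="g2"):
            evaluate(parse_rule("g1 and g2"), {GeneRef("g1"): True})


class TestTruthTable:
    def test_and_bit_encoding(self):
        table = truth_table(parse_rule("g1 and g2"), [GeneRef("g1"), GeneRef("g2")])
        # rows 00, 10, 01, 11 (variable j true iff bit j of the row is set)
        assert table.outputs.tolist() == [False, False, False, True]

    def test_single_gene(self):
        table = truth_table(parse_rule("g1"), [GeneRef("g1")])
        assert table.outputs.tolist() == [False, True]

    def test_empty_rule_single_false_row(self):
        table = truth_table(EMPTY, [])
        assert table.outputs.tolist() == [False]

    def test_cap_enforced(self):
        order = [GeneRef(f"g{i}") for i in range(21)]
        with pytest.raises(TruthTableCapacityError):
            truth_table(parse_rule("g0"), order)


class TestClassify:
    @pytest.mark.parametrize(
        "rule, expected",
        [
            ("", RuleClass.NO_GENE),
            ("g1", RuleClass.ONE_GENE),
            ("g1 or g2 or g3", RuleClass.OR),
            ("g1 and g2", RuleClass.AND),
            ("(g1 and g2) or g3", RuleClass.MIXED),
        ],
    )
    def test_five_classes(self, rule, expected):
        assert classify_rule(parse_rule(rule)) is expected

    def test_invariant_under_gene_renaming(self):
        a = parse_rule("(g1 and g2) or g3")
        b = parse_rule("(x9 and x8) or x7")
        assert classify_rule(a) is classify_rule(b)


class TestEquivalence:
    def test_commutativity(self):
        assert (
            rules_equivalent(parse_rule("g1 and g2"), parse_rule("g2 and g1"))
            is Equivalence.EQUIVALENT
        )

    def test_and_vs_or_not_equivalent(self):
        assert (
            rules_equivalent(parse_rule("g1 and g2"), parse_rule("g1 or g2"))
            is Equivalence.NOT_EQUIVALENT
        )

    def test_above_cap_or_rules_by_set_equality(self):
        names = [f"g{i}" for i in range(25)]
        a = " or ".join(names)
        b = " or ".join(reversed(names))
        assert rules_equivalent(parse_rule(a), parse_rule(b)) is Equivalence.EQUIVALENT
        c = " or ".join(names[:-1] + ["other"])
        assert rules_equivalent(parse_rule(a), parse_rule(c)) is Equivalence.NOT_EQUIVALENT

    def test_above_cap_mixed_mismatch_is_indeterminate(self):
        names = [f"g{i}" for i in range(25)]
        a = "(a1 and a2) or " + " or ".join(names)
        b = "(a1 and a2 and a3) or " + " or ".join(names)
        assert rules_equivalent(parse_rule(a), parse_rule(b)) is Equivalence.INDETERMINATE

    def test_absorption_in_canonical_form(self):
        expr = canonical_form(parse_rule("g1 or (g1 and g2)"))
        assert serialize_rule(expr) == "g1"

    def test_oracle_agreement_small_sample(self, expr_oracle):
        """rules_equivalent must agree with brute-force enumeration."""
        from itertools import product

        random_expr, render, node_genes, eval_node = expr_oracle
        rng = random.Random(42)
        pool = [f"g{i}" for i in range(8)]
        for _ in range(100):
            na, nb = random_expr(rng, pool), random_expr(rng, pool)
            union = sorted(node_genes(na) | node_genes(nb))
            brute = all(
                eval_node(na, dict(zip(union, bits)))
                == eval_node(nb, dict(zip(union, bits)))
                for bits in product([False, True], repeat=len(union))
            )
            verdict = rules_equivalent(parse_rule(render(na)), parse_rule(render(nb)))
            assert verdict is (
                Equivalence.EQUIVALENT if brute else Equivalence.NOT_EQUIVALENT
            )


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (("g1", "g2"), ("g2", "g3"), 1 / 3),
            ((), (), 1.0),
            (("g1",), ("g2",), 0.0),
        ],
    )
    def test_formula_and_conventions(self, a, b, expected):
        assert jaccard_index(genes(*a), genes(*b)) == pytest.approx(expected)

    @given(
        st.sets(st.sampled_from([f"g{i}" for i in range(6)])),
        st.sets(st.sampled_from([f"g{i}" for i in range(6)])),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_identity(self, a, b):
        assert jaccard_index(a, b) == jaccard_index(b, a)
        assert (jaccard_index(a, b) == 1.0) == (set(a) == set(b))


class TestHamming:
    def test_identical_tables_score_one(self):
        order = [GeneRef("g1"), GeneRef("g2")]
        t = truth_table(parse_rule("g1 and g2"), order)
        assert hamming_similarity(t, t) == 1.0

    def test_complementary_tables_score_zero(self):
        order = [GeneRef("g1")]
        a = truth_table(parse_rule("g1"), order)
        b = a.__class__(a.variables, ~a.outputs)
        assert hamming_similarity(a, b) == 0.0

    def test_and_vs_or_half(self):
        order = [GeneRef("g1"), GeneRef("g2")]
        a = truth_table(parse_rule("g1 and g2"), order)
        b = truth_table(parse_rule("g1 or g2"), order)
        assert hamming_similarity(a, b) == 0.5
        assert hamming_similarity(b, a) == 0.5

    def test_mismatched_orders_rejected(self):
        a = truth_table(parse_rule("g1"), [GeneRef("g1")])
        b = truth_table(parse_rule("g2"), [GeneRef("g2")])
        with pytest.raises(ValueError):
            hamming_similarity(a, b)


class TestCompareRules:
    def test_identical_single_gene_is_perfect(self):
        result = compare_rules(parse_rule("g1"), parse_rule("g1"))
        assert result.status is MatchStatus.PERFECT
        assert result.jaccard == 1.0

    def test_same_genes_different_operator(self):
        result = compare_rules(parse_rule("g1 and g2"), parse_rule("g1 or g2"))
        assert result.status is MatchStatus.NEGATIVE
        assert result.jaccard == 1.0
        assert result.hamming_similarity == pytest.approx(0.5)
        assert result.rule_class_original is RuleClass.AND
        assert result.rule_class_generated is RuleClass.OR

    def test_different_genes_no_hamming(self):
        result = compare_rules(parse_rule("g1 or g2"), parse_rule("g1 or g3"))
        assert result.status is MatchStatus.NEGATIVE
        assert result.jaccard == pytest.approx(1 / 3)
        assert result.hamming_similarity is None
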