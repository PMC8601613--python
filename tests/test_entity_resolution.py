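"""Tests for metabolite/reaction/organism matching and the macro database."""

from __future__ import annotations

from fractions import Fraction

import pytest

from gprules.gpr_algebra import GeneRef
from gprules.entity_resolution import (
    AmbiguousOrganismError,
    CompoundIndex,
    CompoundRecord,
    DEFAULT_ALIASES,
    NotTransportReactionError,
    OrganismNotFoundError,
    ReactionRecord,
    TransporterRecord,
    build_macro_database,
    filter_genes_by_localization,
    match_internal_reaction,
    match_metabolite,
    match_transport_reaction,
    metabolic_reactions_for_organism,
    resolve_organism,
)
from gprules.relationship_mining import ProteinRecord


@pytest.fixture
def compound_index():
    return CompoundIndex(
        [
            CompoundRecord("C1", "chebi", ("ATP", "adenosine triphosphate")),
            CompoundRecord("C2", "chebi", ("ADP",)),
            CompoundRecord("C3", "chebi", ("citric acid", "citrate"), inchi="InChI=1S/C6H8O7"),
            CompoundRecord("C4", "chebi", ("isocitric acid",)),
            CompoundRecord("C5", "chebi", ("ACP", "acyl carrier protein")),
        ]
    )


class TestMatchMetabolite:
    def test_exact_synonym_accepted_at_100(self, compound_index):
        result = match_metabolite("Adenosine Triphosphate", compound_index)
        assert result.accepted == "C1"
        assert result.shortlist[0].score == 100

    def test_below_threshold_returns_shortlist(self, compound_index):
        # 'citrid acid' is closest to 'citric acid' but ambiguity with
        # 'isocitric acid' keeps the best score shy of certainty at
        # a high threshold
        result = match_metabolite("citrus acid", compound_index, threshold=95)
        assert result.accepted is None
        assert result.shortlist
        assert result.shortlist[0].score < 95
        assert result.shortlist == tuple(
            sorted(result.shortlist, key=lambda c: -c.score)
        )

    def test_unique_best_at_or_above_threshold_accepted(self, compound_index):
        result = match_metabolite("citric acids", compound_index, threshold=91)
        assert result.accepted == "C3"
        assert result.shortlist[0].method == "fuzzy"

    def test_word_order_insensitive(self, compound_index):
        result = match_metabolite("acid citric", compound_index)
        assert result.accepted == "C3"

    def test_alias_table_resolution(self, compound_index):
        result = match_metabolite("ACP1", compound_index, aliases=DEFAULT_ALIASES)
        assert result.accepted == "C5"
        assert result.shortlist[0].method == "alias"

    def test_inchi_hit(self, compound_index):
        result = match_metabolite(
            "unknown-name-entirely", compound_index, inchi="InChI=1S/C6H8O7"
        )
        assert result.accepted == "C3"
        assert result.shortlist[0].method == "inchi"

    def test_empty_name_rejected(self, compound_index):
        with pytest.raises(ValueError):
            match_metabolite("  ", compound_index)

    def test_raising_threshold_never_accepts_a_rejected_name(self, compound_index):
        low = match_metabolite("citrus acid", compound_index, threshold=50)
        high = match_metabolite("citrus acid", compound_index, threshold=95)
        if high.accepted is None and low.accepted is not None:
            assert low.accepted == low.shortlist[0].compound_id


def rec(rid, source, subs, prods, genes=(), **kw):
    return ReactionRecord(
        reaction_id=rid,
        sources=frozenset({source}),
        substrates=tuple(subs),
        products=tuple(prods),
        genes=frozenset(GeneRef(g) for g in genes),
        **kw,
    )


class TestMacroDatabase:
    def test_cross_source_duplicates_merge_with_union(self):
        a = rec("K1", "kegg", [("C1", 1), ("C2", 1)], [("C3", 1)], genes=["g1"])
        b = rec("M1", "metacyc", [("C1", 1), ("C2", 1)], [("C3", 1)], genes=["g2"])
        db = build_macro_database([a, b])
        assert len(db.entries) == 1
        entry = db.entries[0]
        assert entry.sources == {"kegg", "metacyc"}
        assert entry.genes == frozenset({GeneRef("g1"), GeneRef("g2")})

    def test_different_stoichiometry_stays_separate(self):
        a = rec("K1", "kegg", [("C1", 1)], [("C3", 1)])
        b = rec("K2", "kegg", [("C1", 2)], [("C3", 1)])
        assert len(build_macro_database([a, b]).entries) == 2

    def test_orientation_insensitive_merge(self):
        a = rec("K1", "kegg", [("A", 1), ("B", 1)], [("C", 1)])
        b = rec("M9", "metacyc", [("C", 1)], [("A", 1), ("B", 1)])
        assert len(build_macro_database([a, b]).entries) == 1

    def test_idempotent_and_order_independent(self):
        records = [
            rec("K1", "kegg", [("C1", 1), ("C2", 1)], [("C3", 1)], genes=["g1"]),
            rec("M1", "metacyc", [("C1", 1), ("C2", 1)], [("C3", 1)], genes=["g2"]),
            rec("R9", "rhea", [("C4", 1)], [("C5", 2)]),
        ]
        db1 = build_macro_database(records)
        db2 = build_macro_database(list(reversed(records)))
        assert db1.entries == db2.entries
        remerged = build_macro_database(db1.entries)
        assert remerged.entries == db1.entries

    def test_entry_count_bounded_by_record_count(self):
        records = [
            rec("K1", "kegg", [("C1", 1)], [("C2", 1)]),
            rec("K2", "kegg", [("C3", 1)], [("C4", 1)]),
        ]
        assert len(build_macro_database(records).entries) == len(records)

    def test_internal_lookup_including_swapped_sides(self):
        entry = rec("K1", "kegg", [("A", 1), ("B", 1)], [("C", 1)])
        db = build_macro_database([entry])
        assert match_internal_reaction([("A", 1), ("B", 1)], [("C", 1)], db) is not None
        assert match_internal_reaction([("C", 1)], [("B", 1), ("A", 1)], db) is not None
        assert match_internal_reaction([("A", 1)], [("C", 1)], db) is None

    def test_ignored_compounds_excluded_from_signature(self):
        a = rec("K1", "kegg", [("A", 1), ("h2o", 1)], [("C", 1)])
        b = rec("M1", "metacyc", [("A", 1)], [("C", 1)])
        assert len(build_macro_database([a, b], ignore=frozenset({"h2o"})).entries) == 1
        assert len(build_macro_database([a, b]).entries) == 2


class TestTransport:
    @pytest.fixture
    def tcdb(self):
        return [
            TransporterRecord("2.A.1.1", frozenset({"glc"}), frozenset({GeneRef("t1")})),
            TransporterRecord("2.A.1.2", frozenset({"glc", "fru"}), frozenset({GeneRef("t2")})),
        ]

    def test_cross_compartment_substrate_lookup(self, tcdb):
        genes = match_transport_reaction([("glc", "e")], [("glc", "c")], tcdb)
        assert genes == frozenset({GeneRef("t1"), GeneRef("t2")})

    def test_internal_reaction_raises(self, tcdb):
        with pytest.raises(NotTransportReactionError):
            match_transport_reaction(
                [("a", "c"), ("b", "c")], [("c", "c")], tcdb
            )

    def test_unlisted_substrate_matches_no_genes(self, tcdb):
        assert match_transport_reaction([("xyl", "e")], [("xyl", "c")], tcdb) == frozenset()

    def test_bad_tc_code_rejected(self):
        with pytest.raises(ValueError):
            TransporterRecord("not-a-code", frozenset(), frozenset())


class TestLocalizationFilter:
    def make_proteins(self, locs):
        gene = GeneRef("g1")
        return gene, {gene: ProteinRecord(gene=gene, localizations=locs)}

    def test_manual_annotation_has_priority(self):
        gene, proteins = self.make_proteins(
            (("mitochondrion", "manual"), ("nucleus", "automatic"))
        )
        assert filter_genes_by_localization({gene}, "m", proteins) == {gene}
        # manual says mitochondrion only, so cytosol drops it despite
        # no automatic claim either way
        assert filter_genes_by_localization({gene}, "c", proteins) == frozenset()

    def test_automatic_used_when_no_manual(self):
        gene, proteins = self.make_proteins((("cytosol", "automatic"),))
        assert filter_genes_by_localization({gene}, "c", proteins) == {gene}

    def test_unknown_localization_keeps_gene(self):
        gene, proteins = self.make_proteins(())
        assert filter_genes_by_localization({gene}, "c", proteins) == {gene}
        stranger = GeneRef("g2")
        assert filter_genes_by_localization({stranger}, "c", {}) == {stranger}

    def test_output_subset_of_input(self):
        gene, proteins = self.make_proteins((("nucleus", "manual"),))
        out = filter_genes_by_localization({gene}, "c", proteins)
        assert out <= {gene}


class TestOrganismResolution:
    INDEX = {
        "sce": "Saccharomyces cerevisiae S288C",
        "scb": "Saccharomyces cerevisiae YJM789",
        "hsa": "Homo sapiens",
    }

    def test_unique_substring_match(self):
        assert resolve_organism("homo", self.INDEX) == "hsa"

    def test_ambiguity_interactive_raises_with_candidates(self):
        with pytest.raises(AmbiguousOrganismError) as err:
            resolve_organism("cerevisiae", self.INDEX, interactive=True)
        assert len(err.value.candidates) == 2

    def test_ambiguity_noninteractive_best_lexicographic(self):
        assert resolve_organism("cerevisiae", self.INDEX) == "sce"

    def test_unknown_name_errors(self):
        with pytest.raises(OrganismNotFoundError):
            resolve_organism("martian yeast", self.INDEX)


class TestOrganismReactions:
    def test_metabolic_filter_and_macro_union(self):
        g1, g2, g3 = GeneRef("g1"), GeneRef("g2"), GeneRef("g3")
        genome = {"org": frozenset({g1, g2, g3})}
        hierarchy = {
            g1: ("Metabolism", "Carbohydrate metabolism"),
            g2: ("Genetic Information Processing",),  # non-metabolic only
            g3: ("Metabolism",),
        }
        reactions = {g1: frozenset({"RX1"}), g2: frozenset({"RX1"}), g3: frozenset({"RX2"})}
        db = build_macro_database(
            [rec("RX1", "kegg", [("A", 1)], [("B", 1)], genes=["g9"])]
        )
        out = metabolic_reactions_for_organism("org", genome, hierarchy, reactions, db)
        # g2 excluded everywhere; RX1 unions the macro entry's g9
        assert out["RX1"] == frozenset({g1, GeneRef("g9")})
        assert out["RX2"] == frozenset({g3})

    def test_missing_organism_errors(self):
        db = build_macro_database([])
        with pytest.raises(OrganismNotFoundError):
            metabolic_reactions_for_organism("nope", {}, {}, {}, db)

    def test_no_metabolic_genes_gives_empty_map(self):
        g1 = GeneRef("g1")
        db = build_macro_database([])
        out = metabolic_reactions_for_organism(
            "org", {"org": frozenset({g1})}, {g1: ("Drug Development",)},
            {g1: frozenset({"R1"})}, db,
        )
        assert out == {}
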