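"""Assembly of final GPR expressions from pairwise gene relations.

Genes connected by SUBUNIT edges form enzyme complexes: each connected
component of the SUBUNIT subgraph becomes an AND group, parenthesized
when it has two or more members.  The groups (and SUBUNIT-isolated
genes, which are single-gene alternatives) are then joined by OR, i.e.
AND groups are built first and isoform information is layered on top.

Pairwise labels alone cannot express a gene shared between two
alternative complexes (isoenzymes sharing a common subunit): the shared
gene would merge both complexes into one AND component.  When explicit
complex membership sets are available and a gene belongs to more than
one complete complex within the reaction's gene set, each complex
becomes its own AND group and the shared gene is duplicated across
groups; without complex sets the merged-component interpretation is
used and the situation is logged.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .gpr_algebra import EMPTY, GeneRef, GPRExpression
from .relationship_mining import (
    ComplexRecord,
    DEFAULT_SOURCE_PRIORITY,
    EvidenceSource,
    Relation,
    RelationEvidence,
    RelationGraph,
    gene_pair,
    resolve_relations,
)

__all__ = ["assemble_gpr", "assemble_all"]

logger = logging.getLogger(__name__)


def _group_expression(group: Iterable[GeneRef]) -> GPRExpression:
    members = sorted(group)
    if len(members) == 1:
        return GPRExpression.from_gene(members[0])
    return GPRExpression.conjunction(GPRExpression.from_gene(g) for g in members)


def assemble_gpr(
    genes: Iterable[GeneRef],
    graph: RelationGraph,
    complexes: Optional[Sequence[ComplexRecord]] = None,
) -> GPRExpression:
    """Build the GPR expression for one reaction.

    Parameters
    ----------
    genes:
        The reaction's gene set.
    graph:
        Resolved pairwise relations; pairs not present are ISOFORM.
    complexes:
        Optional complex membership sets.  When a gene belongs to
        several complete complexes inside ``genes``, each complex
        becomes its own AND group (the gene appears in several groups);
        genes not covered by any such complex fall back to the
        connected-component interpretation.
    """
    gene_set = frozenset(genes)
    if not gene_set:
        return EMPTY
    if len(gene_set) == 1:
        return GPRExpression.from_gene(next(iter(gene_set)))

    groups: list[frozenset[GeneRef]] = []
    covered: set[GeneRef] = set()
    if complexes:
        complete = sorted(
            {
                frozenset(c.components)
                for c in complexes
                if len(c.components) >= 2 and c.components <= gene_set
            },
            key=lambda s: sorted(s),
        )
        membership: dict[GeneRef, int] = {}
        for members in complete:
            for g in members:
                membership[g] = membership.get(g, 0) + 1
        if any(count >= 2 for count in membership.values()):
            # shared-subunit isoenzymes: keep each complex as its own
            # AND group, duplicating the shared genes across groups.
            groups.extend(complete)
            covered = set().union(*complete)

    sub = nx.Graph()
    sub.add_nodes_from(g for g in gene_set if g not in covered)
    inconsistencies = 0
    for a, b in combinations(sorted(gene_set), 2):
        if graph.relation(a, b) is Relation.SUBUNIT:
            if a in covered or b in covered:
                continue
            sub.add_edge(a, b)
    for component in nx.connected_components(sub):
        groups.append(frozenset(component))
        # ISOFORM-labelled pairs inside an AND-connected component are
        # tolerated (component membership wins) but worth flagging.
        if len(component) > 2:
            for a, b in combinations(sorted(component), 2):
                if graph.relation(a, b) is Relation.ISOFORM and gene_pair(a, b) in graph.resolved:
                    inconsistencies += 1
    if inconsistencies:
        logger.warning(
            "%d isoform-labelled pair(s) inside AND-connected components; "
            "component membership wins",
            inconsistencies,
        )

    if len(groups) == 1:
        return _group_expression(groups[0])
    return GPRExpression.disjunction(_group_expression(g) for g in groups)


def assemble_all(
    reaction_to_genes: Mapping[str, Iterable[GeneRef]],
    per_gene_evidence: Mapping[GeneRef, Sequence[RelationEvidence]],
    priority: Sequence[EvidenceSource] = DEFAULT_SOURCE_PRIORITY,
    complexes: Optional[Sequence[ComplexRecord]] = None,
) -> dict[str, GPRExpression]:
    """Assemble one GPR expression per reaction.

    For each reaction, the evidence of its genes is pooled (restricted
    to pairs inside the reaction's gene set by ``resolve_relations``),
    resolved into a relation graph and assembled.  Reactions with empty
    gene sets map to the empty rule.  The result is deterministic for
    identical inputs.
    """
    out: dict[str, GPRExpression] = {}
    for rid in sorted(reaction_to_genes):
        gene_set = frozenset(reaction_to_genes[rid])
        evidence: list[RelationEvidence] = []
        for gene in sorted(gene_set):
            evidence.extend(per_gene_evidence.get(gene, ()))
        graph = resolve_relations(gene_set, evidence, priority)
        out[rid] = assemble_gpr(gene_set, graph, complexes)
    return out
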