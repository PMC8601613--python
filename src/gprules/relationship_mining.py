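"""Mining of subunit (AND) and isoform (OR) gene relationships.

For every metabolic gene of a reaction, pairwise relationships to the
other genes are collected from five evidence channels:

* free-text protein annotation, "Interaction" and "Function" sections
  (keyword-guided sentence mining; genes named in a sentence containing
  a complex/interaction keyword are taken as co-subunits),
* curated macromolecular-complex records (all components of a complex
  containing the gene are its co-subunits),
* an interaction network with functional-term annotations (network
  neighbours sharing a protein-complex term are co-subunits),
* orthology groups (genes sharing a functional-ortholog identifier are
  isoforms).

The default keyword list is the one that a frequency analysis of
curated annotation text surfaces: the monograms *complex*, *component*,
*interact* (stem-tolerant) and the qualifier *by similarity*, plus the
n-grams *interact with*, *part of a complex with*, *consist of*,
*associate with* and *heteromerization with*.

Conflicting evidence for a pair (both SUBUNIT and ISOFORM) is settled by
a configurable source-priority order; pairs with no evidence at all
default to ISOFORM, matching the observation that absence of complex
evidence yields OR-joined rules.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .gpr_algebra import GeneRef
from .textutils import STOP_WORDS, ngrams, split_sentences, tokenize

__all__ = [
    "Relation",
    "EvidenceSource",
    "Qualifier",
    "ProteinRecord",
    "ComplexRecord",
    "FunctionalTerm",
    "InteractionNetwork",
    "OrthologyGroup",
    "RelationEvidence",
    "RelationGraph",
    "DEFAULT_KEYWORDS",
    "DEFAULT_SOURCE_PRIORITY",
    "gene_pair",
    "frequency_profile",
    "keyword_sentences",
    "extract_partners",
    "complex_partners",
    "string_partners",
    "isoform_partners",
    "resolve_relations",
]

logger = logging.getLogger(__name__)


class Relation(Enum):
    SUBUNIT = "subunit"
    ISOFORM = "isoform"


class EvidenceSource(Enum):
    UNIPROT_INTERACTION = "uniprot_interaction"
    UNIPROT_FUNCTION = "uniprot_function"
    COMPLEX_PORTAL = "complex_portal"
    STRING = "string"
    KEGG_ORTHOLOGY = "kegg_orthology"


class Qualifier(Enum):
    BY_SIMILARITY = "by_similarity"
    NONE = "none"


#: Conflict-resolution order: manually curated structured data over
#: curated text over predictions.
DEFAULT_SOURCE_PRIORITY: tuple[EvidenceSource, ...] = (
    EvidenceSource.COMPLEX_PORTAL,
    EvidenceSource.UNIPROT_INTERACTION,
    EvidenceSource.UNIPROT_FUNCTION,
    EvidenceSource.STRING,
    EvidenceSource.KEGG_ORTHOLOGY,
)

#: Keyword list guiding sentence extraction from annotation text.
DEFAULT_KEYWORDS: tuple[str, ...] = (
    "complex",
    "component",
    "interact",
    "by similarity",
    "interact with",
    "part of a complex with",
    "consist of",
    "associate with",
    "heteromerization with",
)


def gene_pair(a: GeneRef, b: GeneRef) -> tuple[GeneRef, GeneRef]:
    """Canonical (sorted) representation of an unordered gene pair."""
    if a == b:
        raise ValueError(f"pair members must be distinct (got {a.identifier!r} twice)")
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ProteinRecord:
    """Annotation record for one gene product.

    ``localizations`` pairs each subcellular-location term with its
    evidence label: ``manual`` (curator-assigned) or ``automatic``
    (computationally predicted).  ``organism`` and ``branches``
    (functional-hierarchy branch labels) support the organism-name
    pipeline mode.
    """

    gene: GeneRef
    synonyms: tuple[str, ...] = ()
    interaction_text: str = ""
    function_text: str = ""
    complex_xrefs: tuple[str, ...] = ()
    localizations: tuple[tuple[str, str], ...] = ()
    organism: str = ""
    branches: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for term, evidence in self.localizations:
            if evidence not in ("manual", "automatic"):
                raise ValueError(
                    f"localization evidence must be manual/automatic, got {evidence!r}"
                )


@dataclass(frozen=True)
class ComplexRecord:
    complex_id: str
    components: frozenset[GeneRef]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("a complex must have at least one component")


@dataclass(frozen=True)
class FunctionalTerm:
    """A functional-enrichment term; ``is_complex`` marks complex terms."""

    term: str
    is_complex: bool = False


@dataclass(frozen=True)
class InteractionNetwork:
    edges: frozenset[tuple[GeneRef, GeneRef]] = frozenset()
    node_annotations: Mapping[GeneRef, frozenset[FunctionalTerm]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a not in self.node_annotations or b not in self.node_annotations:
                raise ValueError("network edges must reference annotated nodes")

    def neighbours(self, gene: GeneRef) -> set[GeneRef]:
        out = set()
        for a, b in self.edges:
            if a == gene:
                out.add(b)
            elif b == gene:
                out.add(a)
        return out


@dataclass(frozen=True)
class OrthologyGroup:
    group_id: str
    members: frozenset[GeneRef]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("an orthology group must have at least one member")


@dataclass(frozen=True)
class RelationEvidence:
    """One piece of pairwise evidence; the pair is stored canonically."""

    pair: tuple[GeneRef, GeneRef]
    relation: Relation
    source: EvidenceSource
    qualifier: Qualifier = Qualifier.NONE

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair", gene_pair(*self.pair))


@dataclass
class RelationGraph:
    """Resolved pairwise relation labels for one reaction's gene set.

    ``resolved`` holds one label per evidenced pair; unevidenced pairs
    are ISOFORM by default, queried through :meth:`relation`.
    ``conflicts`` lists pairs that carried both labels.
    """

    genes: frozenset[GeneRef]
    evidence: tuple[RelationEvidence, ...]
    resolved: dict[tuple[GeneRef, GeneRef], Relation]
    conflicts: tuple[tuple[GeneRef, GeneRef], ...] = ()

    def relation(self, a: GeneRef, b: GeneRef) -> Relation:
        return self.resolved.get(gene_pair(a, b), Relation.ISOFORM)

    def subunit_pairs(self) -> list[tuple[GeneRef, GeneRef]]:
        return [p for p, rel in self.resolved.items() if rel is Relation.SUBUNIT]


# ---------------------------------------------------------------------------
# Text mining
# ---------------------------------------------------------------------------


def frequency_profile(
    texts: Iterable[str],
    stop_words: frozenset[str] = STOP_WORDS,
    ngram_max: int = 1,
) -> list[tuple[str, int]]:
    """Rank lowercased tokens and n-grams of a text corpus by count.

    Stop words are excluded from the monogram ranking (n-grams are kept
    whole even when they contain stop words).  Ties are broken
    alphabetically so the ranking is deterministic.
    """
    if ngram_max < 1:
        raise ValueError("ngram_max must be >= 1")
    counts: Counter[str] = Counter()
    for text in texts:
        tokens = tokenize(text)
        counts.update(t for t in tokens if t not in stop_words)
        for n in range(2, ngram_max + 1):
            counts.update(ngrams(tokens, n))
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def _sentence_matches(sentence_lower: str, tokens: list[str], keyword: str) -> bool:
    if " " in keyword:
        return keyword in sentence_lower
    # monogram: prefix-tolerant token match, so the stem "interact" also
    # matches "interacts" and "interaction", "component" matches
    # "components", etc.
    return any(t.startswith(keyword) for t in tokens)


def keyword_sentences(
    text: str, keywords: Sequence[str] = DEFAULT_KEYWORDS
) -> list[str]:
    """Sentences of ``text`` containing at least one keyword, in order."""
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    lowered = [k.lower() for k in keywords]
    hits = []
    for sentence in split_sentences(text):
        low = sentence.lower()
        tokens = tokenize(sentence)
        if any(_sentence_matches(low, tokens, k) for k in lowered):
            hits.append(sentence)
    return hits


def extract_partners(
    record: ProteinRecord,
    universe: Mapping[str, GeneRef],
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
) -> list[RelationEvidence]:
    """Mine a protein record's annotation text for co-subunit genes.

    Every gene token of a keyword-bearing sentence that resolves through
    ``universe`` (case-insensitive symbol/synonym map) and differs from
    the record's own gene yields one SUBUNIT evidence; sentences
    mentioning "by similarity" mark their evidence with that qualifier.
    Tokens outside the universe are ignored, so unknown names can never
    produce partners.
    """
    uni = {k.lower(): v for k, v in universe.items()}
    evidence: list[RelationEvidence] = []
    seen: set[tuple[tuple[GeneRef, GeneRef], EvidenceSource]] = set()
    sections = (
        (record.interaction_text, EvidenceSource.UNIPROT_INTERACTION),
        (record.function_text, EvidenceSource.UNIPROT_FUNCTION),
    )
    for text, source in sections:
        if not text:
            continue
        for sentence in keyword_sentences(text, keywords):
            qualifier = (
                Qualifier.BY_SIMILARITY
                if "by similarity" in sentence.lower()
                else Qualifier.NONE
            )
            for token in tokenize(sentence):
                partner = uni.get(token)
                if partner is None or partner == record.gene:
                    continue
                pair = gene_pair(record.gene, partner)
                if (pair, source) in seen:
                    continue
                seen.add((pair, source))
                evidence.append(
                    RelationEvidence(pair, Relation.SUBUNIT, source, qualifier)
                )
    return evidence


# ---------------------------------------------------------------------------
# Structured evidence
# ---------------------------------------------------------------------------


def complex_partners(
    gene: GeneRef, complexes: Iterable[ComplexRecord]
) -> list[RelationEvidence]:
    """SUBUNIT evidence pairing ``gene`` with its complex co-components."""
    evidence = []
    for record in complexes:
        if gene not in record.components:
            continue
        for other in sorted(record.components):
            if other != gene:
                evidence.append(
                    RelationEvidence(
                        gene_pair(gene, other),
                        Relation.SUBUNIT,
                        EvidenceSource.COMPLEX_PORTAL,
                    )
                )
    return evidence


def string_partners(
    gene: GeneRef, network: InteractionNetwork
) -> list[RelationEvidence]:
    """SUBUNIT evidence from network neighbours sharing a complex term."""
    annotations = network.node_annotations
    if gene not in annotations:
        logger.info("gene %s absent from interaction network", gene.identifier)
        return []
    own_terms = {t.term for t in annotations[gene] if t.is_complex}
    evidence = []
    for neighbour in sorted(network.neighbours(gene)):
        shared = own_terms & {
            t.term for t in annotations.get(neighbour, frozenset()) if t.is_complex
        }
        if shared:
            evidence.append(
                RelationEvidence(
                    gene_pair(gene, neighbour),
                    Relation.SUBUNIT,
                    EvidenceSource.STRING,
                )
            )
    return evidence


def isoform_partners(
    gene: GeneRef, groups: Iterable[OrthologyGroup]
) -> list[RelationEvidence]:
    """ISOFORM evidence pairing ``gene`` with its orthology-group peers."""
    evidence = []
    for group in groups:
        if gene not in group.members:
            continue
        for other in sorted(group.members):
            if other != gene:
                evidence.append(
                    RelationEvidence(
                        gene_pair(gene, other),
                        Relation.ISOFORM,
                        EvidenceSource.KEGG_ORTHOLOGY,
                    )
                )
    return evidence


# ---------------------------------------------------------------------------
# Resolution
# ---------------------------------------------------------------------------


def resolve_relations(
    genes: Iterable[GeneRef],
    evidence: Iterable[RelationEvidence],
    priority: Sequence[EvidenceSource] = DEFAULT_SOURCE_PRIORITY,
) -> RelationGraph:
    """Assign one relation label per evidenced gene pair.

    On conflicting labels for a pair, the label supported by the
    highest-priority source wins and the conflict is logged.  Pairs with
    no evidence are not stored; :meth:`RelationGraph.relation` returns
    ISOFORM for them.
    """
    priority = tuple(priority)
    missing = set(EvidenceSource) - set(priority)
    if missing:
        names = ", ".join(sorted(s.value for s in missing))
        raise ValueError(f"priority order must cover all sources; missing: {names}")
    gene_set = frozenset(genes)
    per_pair: dict[tuple[GeneRef, GeneRef], list[RelationEvidence]] = {}
    kept: list[RelationEvidence] = []
    for ev in evidence:
        if not set(ev.pair) <= gene_set:
            continue
        per_pair.setdefault(ev.pair, []).append(ev)
        kept.append(ev)
    resolved: dict[tuple[GeneRef, GeneRef], Relation] = {}
    conflicts: list[tuple[GeneRef, GeneRef]] = []
    rank = {source: i for i, source in enumerate(priority)}
    for pair, items in per_pair.items():
        labels = {ev.relation for ev in items}
        if len(labels) == 1:
            resolved[pair] = next(iter(labels))
            continue
        best = min(items, key=lambda ev: rank[ev.source])
        resolved[pair] = best.relation
        conflicts.append(pair)
        logger.warning(
            "conflicting relation evidence for (%s, %s); keeping %s from %s",
            pair[0].identifier,
            pair[1].identifier,
            best.relation.value,
            best.source.value,
        )
    return RelationGraph(gene_set, tuple(kept), resolved, tuple(conflicts))
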