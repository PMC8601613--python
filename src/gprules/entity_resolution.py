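"""Entity resolution: metabolites, reactions, transporters, organisms.

Metabolite names coming from a draft model are resolved against a merged
compound dictionary (names + synonyms, InChI strings, cross-references)
by a cascade: configured alias -> exact name -> InChI -> fuzzy
token-sort similarity, with automatic acceptance only for a unique best
fuzzy candidate scoring at or above the acceptance threshold
(default 91, calibrated to exclude clearly wrong matches).

Reactions from several source databases are merged into a single
"macro database" keyed by a canonical participant signature (sorted
participant multisets with stoichiometry, orientation-insensitive), so
one merged entry accumulates the sources, cross-references, EC numbers
and catalyzing genes of all its duplicates.  Internal reactions are
matched by signature lookup; transport reactions (same compound on both
sides in different compartments) are matched through transporter
records by transported substrate.

A localization filter keeps only genes whose subcellular-location
annotation is compatible with the reaction compartment, giving priority
to manual annotations over automatic predictions and keeping genes with
no localization data at all.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

from .gpr_algebra import GeneRef
from .relationship_mining import ProteinRecord
from .textutils import token_sort_ratio

__all__ = [
    "CompoundRecord",
    "CompoundIndex",
    "ReactionRecord",
    "MacroDatabase",
    "TransporterRecord",
    "MatchCandidate",
    "MatchResult",
    "DEFAULT_MATCH_THRESHOLD",
    "DEFAULT_ALIASES",
    "DEFAULT_COMPARTMENT_VOCABULARY",
    "NotTransportReactionError",
    "OrganismNotFoundError",
    "AmbiguousOrganismError",
    "match_metabolite",
    "build_macro_database",
    "match_internal_reaction",
    "match_transport_reaction",
    "filter_genes_by_localization",
    "resolve_organism",
    "metabolic_reactions_for_organism",
]

logger = logging.getLogger(__name__)

#: Fuzzy-match acceptance threshold on the 0-100 similarity scale.
DEFAULT_MATCH_THRESHOLD = 91

#: Manual alias table for model metabolite names that cannot be traced to
#: a database compound under their written form.  Each entry maps a
#: lowercased model name to candidate database names tried in order by
#: exact lookup: the acyl-carrier protein written with a numeric suffix,
#: the NADPH <-> adrenal-ferredoxin dependency, the electron-transfer
#: flavoproteins resolved through their FAD/FADH2 cofactors, and the
#: generic diglyceride standing for 1,2-diacyl-sn-glycerol.
DEFAULT_ALIASES: Mapping[str, tuple[str, ...]] = {
    "acp1": ("acp", "acyl-carrier protein"),
    "nadph": ("nadph", "ferredoxin"),
    "ferredoxin": ("ferredoxin", "nadph"),
    "electron-transferring flavoprotein": ("fad", "fadh2"),
    "electron transfer flavoprotein": ("fad", "fadh2"),
    "diglyceride": ("1,2-diacyl-sn-glycerol",),
}

#: Model compartment tag -> admissible subcellular-location terms.
DEFAULT_COMPARTMENT_VOCABULARY: Mapping[str, frozenset[str]] = {
    "c": frozenset({"cytosol", "cytoplasm"}),
    "e": frozenset({"extracellular", "secreted", "cell membrane"}),
    "m": frozenset({"mitochondrion", "mitochondria"}),
    "n": frozenset({"nucleus"}),
    "x": frozenset({"peroxisome"}),
    "r": frozenset({"endoplasmic reticulum"}),
    "g": frozenset({"golgi apparatus"}),
    "v": frozenset({"vacuole"}),
    "l": frozenset({"lysosome"}),
}


class NotTransportReactionError(ValueError):
    """Raised when transport matching is applied to an internal reaction."""


class OrganismNotFoundError(KeyError):
    pass


class AmbiguousOrganismError(ValueError):
    def __init__(self, name: str, candidates: Sequence[tuple[str, str]]):
        self.candidates = list(candidates)
        listing = "; ".join(f"{code}: {oname}" for code, oname in self.candidates)
        super().__init__(f"organism name {name!r} is ambiguous among: {listing}")


@dataclass(frozen=True)
class CompoundRecord:
    """One compound entry from a source database."""

    compound_id: str
    source: str
    names: tuple[str, ...]
    inchi: Optional[str] = None
    xrefs: Mapping[str, str] = field(default_factory=dict)
    ontology_parents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError(f"compound {self.compound_id!r} must have at least one name")


@dataclass(frozen=True)
class MatchCandidate:
    compound_id: str
    score: int
    method: str  # exact_name | inchi | fuzzy | alias

    def __post_init__(self) -> None:
        if not 0 <= self.score <= 100:
            raise ValueError("score must lie in [0, 100]")


@dataclass(frozen=True)
class MatchResult:
    accepted: Optional[str]
    shortlist: tuple[MatchCandidate, ...]


class CompoundIndex:
    """Name, synonym and InChI lookup over a compound collection."""

    def __init__(self, compounds: Iterable[CompoundRecord]):
        self.by_id: dict[str, CompoundRecord] = {}
        self._by_name: dict[str, set[str]] = {}
        self._by_inchi: dict[str, set[str]] = {}
        for record in compounds:
            self.by_id[record.compound_id] = record
            for name in record.names:
                self._by_name.setdefault(name.lower(), set()).add(record.compound_id)
            if record.inchi:
                self._by_inchi.setdefault(record.inchi, set()).add(record.compound_id)

    def exact(self, name: str) -> set[str]:
        return set(self._by_name.get(name.lower(), ()))

    def by_inchi(self, inchi: str) -> set[str]:
        return set(self._by_inchi.get(inchi, ()))

    def fuzzy_scores(self, name: str) -> dict[str, int]:
        """Best token-sort score per compound over all of its names."""
        scores: dict[str, int] = {}
        for record in self.by_id.values():
            best = max(token_sort_ratio(name, n) for n in record.names)
            scores[record.compound_id] = best
        return scores


def match_metabolite(
    name: str,
    index: CompoundIndex,
    threshold: int = DEFAULT_MATCH_THRESHOLD,
    aliases: Optional[Mapping[str, tuple[str, ...]]] = None,
    inchi: Optional[str] = None,
    shortlist_size: int = 5,
) -> MatchResult:
    """Resolve a metabolite name to a compound identifier.

    Resolution order: alias-table hit (exact lookup of the alias
    targets), exact case-insensitive name/synonym hit, InChI hit when
    the query carries one, then fuzzy similarity over all names.  A
    fuzzy match is accepted automatically only when a unique best
    candidate scores at least ``threshold``; otherwise the descending
    shortlist is returned for confirmation.
    """
    if not name or not name.strip():
        raise ValueError("metabolite name must be non-empty")
    if not 0 <= threshold <= 100:
        raise ValueError("threshold must lie in [0, 100]")
    if aliases:
        targets = aliases.get(name.lower())
        if targets:
            for target in targets:
                hit = index.exact(target)
                if len(hit) == 1:
                    return MatchResult(
                        next(iter(hit)), (MatchCandidate(next(iter(hit)), 100, "alias"),)
                    )
    exact = index.exact(name)
    if len(exact) == 1:
        cid = next(iter(exact))
        return MatchResult(cid, (MatchCandidate(cid, 100, "exact_name"),))
    if len(exact) > 1:
        shortlist = tuple(
            MatchCandidate(cid, 100, "exact_name") for cid in sorted(exact)
        )
        return MatchResult(None, shortlist)
    if inchi:
        hit = index.by_inchi(inchi)
        if len(hit) == 1:
            cid = next(iter(hit))
            return MatchResult(cid, (MatchCandidate(cid, 100, "inchi"),))
    scores = index.fuzzy_scores(name)
    if not scores:
        return MatchResult(None, ())
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    best_score = ranked[0][1]
    best = [cid for cid, s in ranked if s == best_score]
    if len(best) == 1 and best_score >= threshold:
        return MatchResult(best[0], (MatchCandidate(best[0], best_score, "fuzzy"),))
    shortlist = tuple(
        MatchCandidate(cid, s, "fuzzy") for cid, s in ranked[:shortlist_size]
    )
    return MatchResult(None, shortlist)


# ---------------------------------------------------------------------------
# Reactions and the macro database
# ---------------------------------------------------------------------------

Participants = tuple[tuple[str, Fraction], ...]


def _side(participants: Iterable[tuple[str, object]]) -> Participants:
    out = []
    for cid, coeff in participants:
        frac = Fraction(coeff).limit_denominator(10**6) if not isinstance(coeff, Fraction) else coeff
        if frac <= 0:
            raise ValueError(f"stoichiometric coefficient for {cid!r} must be positive")
        out.append((cid, frac))
    return tuple(sorted(out))


def reaction_signature(
    substrates: Iterable[tuple[str, object]],
    products: Iterable[tuple[str, object]],
    ignore: frozenset[str] = frozenset(),
) -> tuple[Participants, Participants]:
    """Canonical, orientation-insensitive participant signature.

    The two sides are sorted participant multisets (with coefficients);
    the signature is the lexicographically smaller of the two possible
    orderings of the sides, so a reaction written in either direction
    hashes identically.  ``ignore`` lists compound ids (e.g. protons,
    water) excluded from matching when so configured.
    """
    sub = _side((c, k) for c, k in substrates if c not in ignore)
    prod = _side((c, k) for c, k in products if c not in ignore)
    return min((sub, prod), (prod, sub))


@dataclass(frozen=True)
class ReactionRecord:
    """A reaction entry, possibly merged from several source databases."""

    reaction_id: str
    sources: frozenset[str]
    substrates: Participants
    products: Participants
    ec_numbers: tuple[str, ...] = ()
    genes: frozenset[GeneRef] = frozenset()
    xrefs: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise ValueError(f"reaction {self.reaction_id!r} must have both sides non-empty")
        object.__setattr__(self, "substrates", _side(self.substrates))
        object.__setattr__(self, "products", _side(self.products))

    def signature(self, ignore: frozenset[str] = frozenset()):
        return reaction_signature(self.substrates, self.products, ignore)


@dataclass
class MacroDatabase:
    """Merged reaction store: one entry per unique participant signature."""

    entries: list[ReactionRecord]
    signature_index: dict[tuple[Participants, Participants], ReactionRecord]
    reference_index: dict[str, ReactionRecord]

    def find(self, reference: str) -> Optional[ReactionRecord]:
        """Look an entry up by reaction id or any cross-reference id."""
        return self.reference_index.get(reference)


def _merge(a: ReactionRecord, b: ReactionRecord) -> ReactionRecord:
    xrefs = dict(a.xrefs)
    for key, value in b.xrefs.items():
        if key in xrefs and xrefs[key] != value:
            xrefs[key] = f"{xrefs[key]}|{value}"
        else:
            xrefs[key] = value
    for source, rid in ((next(iter(b.sources)), b.reaction_id),):
        xrefs.setdefault(source, rid)
    ec = tuple(dict.fromkeys(a.ec_numbers + b.ec_numbers))
    return ReactionRecord(
        reaction_id=a.reaction_id,
        sources=a.sources | b.sources,
        substrates=a.substrates,
        products=a.products,
        ec_numbers=ec,
        genes=a.genes | b.genes,
        xrefs=xrefs,
    )


def build_macro_database(
    records: Iterable[ReactionRecord],
    ignore: frozenset[str] = frozenset(),
) -> MacroDatabase:
    """Merge reaction records into a macro database.

    Records with equal canonical signatures (same participants and
    stoichiometry, either orientation) merge into a single entry holding
    the union of sources, cross-references, EC numbers and genes.  The
    merge is order-independent: entries are combined in a deterministic
    order regardless of input permutation.
    """
    buckets: dict[tuple[Participants, Participants], list[ReactionRecord]] = {}
    for record in records:
        buckets.setdefault(record.signature(ignore), []).append(record)
    entries = []
    signature_index = {}
    for sig, group in buckets.items():
        group = sorted(group, key=lambda r: (r.reaction_id, sorted(r.sources)))
        merged = group[0]
        for other in group[1:]:
            merged = _merge(merged, other)
        entries.append(merged)
        signature_index[sig] = merged
    entries.sort(key=lambda r: r.reaction_id)
    reference_index: dict[str, ReactionRecord] = {}
    for entry in entries:
        reference_index.setdefault(entry.reaction_id, entry)
        for value in entry.xrefs.values():
            for ref in value.split("|"):
                reference_index.setdefault(ref, entry)
    return MacroDatabase(entries, signature_index, reference_index)


def match_internal_reaction(
    substrates: Iterable[tuple[str, object]],
    products: Iterable[tuple[str, object]],
    db: MacroDatabase,
    ignore: frozenset[str] = frozenset(),
) -> Optional[ReactionRecord]:
    """Signature lookup of an internal reaction in the macro database."""
    sig = reaction_signature(substrates, products, ignore)
    return db.signature_index.get(sig)


# ---------------------------------------------------------------------------
# Transport reactions
# ---------------------------------------------------------------------------

_TC_RE = re.compile(r"^\d+(\.[A-Za-z0-9]+)+$")


@dataclass(frozen=True)
class TransporterRecord:
    """A transport system: TC code, transported substrates, genes."""

    tc_code: str
    substrates: frozenset[str]
    genes: frozenset[GeneRef]

    def __post_init__(self) -> None:
        if not _TC_RE.match(self.tc_code):
            raise ValueError(f"{self.tc_code!r} is not a valid TC number")


def transported_compounds(
    substrates: Iterable[tuple[str, str]],
    products: Iterable[tuple[str, str]],
) -> set[str]:
    """Compounds moved across compartments: same id on both sides, different tag."""
    sub_comps: dict[str, set[str]] = {}
    for cid, compartment in substrates:
        sub_comps.setdefault(cid, set()).add(compartment)
    moved = set()
    for cid, compartment in products:
        if cid in sub_comps and compartment not in sub_comps[cid]:
            moved.add(cid)
    return moved


def match_transport_reaction(
    substrates: Iterable[tuple[str, str]],
    products: Iterable[tuple[str, str]],
    tcdb: Iterable[TransporterRecord],
) -> frozenset[GeneRef]:
    """Genes of every transporter record carrying a transported compound.

    ``substrates``/``products`` are (compound_id, compartment) pairs.
    Raises :class:`NotTransportReactionError` when no compound crosses a
    compartment boundary.
    """
    moved = transported_compounds(substrates, products)
    if not moved:
        raise NotTransportReactionError(
            "no compound crosses a compartment boundary: not a transport reaction"
        )
    genes: set[GeneRef] = set()
    for record in tcdb:
        if record.substrates & moved:
            genes |= record.genes
    return frozenset(genes)


# ---------------------------------------------------------------------------
# Localization filter
# ---------------------------------------------------------------------------


def filter_genes_by_localization(
    genes: Iterable[GeneRef],
    compartment: str,
    proteins: Mapping[GeneRef, ProteinRecord],
    vocabulary: Mapping[str, frozenset[str]] = DEFAULT_COMPARTMENT_VOCABULARY,
) -> frozenset[GeneRef]:
    """Keep genes whose localization is compatible with the compartment.

    Manual annotations take priority: when a gene has any manual
    localization terms, only those count; otherwise automatic terms are
    used; genes with no localization data at all are kept (the filter is
    a refinement, not a hard gate).
    """
    wanted = {t.lower() for t in vocabulary.get(compartment, frozenset({compartment}))}
    wanted.add(compartment.lower())
    kept = set()
    for gene in genes:
        record = proteins.get(gene)
        if record is None or not record.localizations:
            kept.add(gene)
            continue
        manual = {t.lower() for t, ev in record.localizations if ev == "manual"}
        effective = manual or {t.lower() for t, _ in record.localizations}
        if effective & wanted:
            kept.add(gene)
    return frozenset(kept)


# ---------------------------------------------------------------------------
# Organism mode
# ---------------------------------------------------------------------------


def resolve_organism(
    name: str,
    index: Mapping[str, str],
    interactive: bool = False,
) -> str:
    """Resolve an organism name to its code by substring match.

    A unique case-insensitive substring match wins.  On multiple
    matches, interactive mode raises :class:`AmbiguousOrganismError`
    carrying the candidate list for disambiguation; non-interactive mode
    logs a warning and returns the lexicographically best match (sorted
    by organism name, then code).
    """
    query = name.strip().lower()
    if not query:
        raise OrganismNotFoundError("organism name must be non-empty")
    matches = [
        (code, oname)
        for code, oname in index.items()
        if query in oname.lower() or query == code.lower()
    ]
    if not matches:
        raise OrganismNotFoundError(f"no organism matches {name!r}")
    if len(matches) == 1:
        return matches[0][0]
    matches.sort(key=lambda co: (co[1].lower(), co[0]))
    if interactive:
        raise AmbiguousOrganismError(name, matches)
    logger.warning(
        "organism name %r matches %d entries; choosing %s (%s)",
        name,
        len(matches),
        matches[0][0],
        matches[0][1],
    )
    return matches[0][0]


def metabolic_reactions_for_organism(
    code: str,
    genome: Mapping[str, frozenset[GeneRef]],
    hierarchy: Mapping[GeneRef, tuple[str, ...]],
    reactions: Mapping[GeneRef, frozenset[str]],
    db: MacroDatabase,
    metabolic_branches: Optional[frozenset[str]] = None,
) -> dict[str, frozenset[GeneRef]]:
    """Reaction -> gene map for one organism, restricted to metabolism.

    Genes are first filtered to those annotated under a metabolic branch
    of the functional hierarchy (by default, any branch label containing
    "metabol"); each reaction's gene set is the union of the genes
    mapped to it and the genes of the corresponding macro-database entry
    when one exists.
    """
    if code not in genome:
        raise OrganismNotFoundError(f"organism {code!r} missing from snapshot")

    def is_metabolic(branch: str) -> bool:
        if metabolic_branches is not None:
            return branch in metabolic_branches
        return "metabol" in branch.lower()

    metabolic = {
        gene
        for gene in genome[code]
        if any(is_metabolic(b) for b in hierarchy.get(gene, ()))
    }
    out: dict[str, set[GeneRef]] = {}
    for gene in sorted(metabolic):
        for rid in reactions.get(gene, frozenset()):
            out.setdefault(rid, set()).add(gene)
    result: dict[str, frozenset[GeneRef]] = {}
    for rid, genes in out.items():
        entry = db.find(rid)
        if entry is not None:
            genes = genes | entry.genes
        result[rid] = frozenset(genes)
    return result
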