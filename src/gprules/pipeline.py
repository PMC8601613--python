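"""End-to-end reconstruction pipelines.

Two entry points mirror the two input modes: :func:`reconstruct_model`
starts from a draft model (SBML or reaction list) and
:func:`reconstruct_organism` starts from an organism name resolved
against the snapshot's organism index.  Both converge on the shared
core: per-reaction gene sets -> pairwise relationship mining ->
relation resolution -> rule assembly.

Interactive disambiguation (metabolite shortlists, organism candidates)
has a scriptable alternative: ``RunConfig.answers`` maps a metabolite
label to the compound id to use.  In non-interactive mode every
would-be prompt is resolved by the documented default — the top
shortlist candidate — and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .entity_resolution import (
    CompoundIndex,
    DEFAULT_ALIASES,
    DEFAULT_COMPARTMENT_VOCABULARY,
    DEFAULT_MATCH_THRESHOLD,
    MacroDatabase,
    build_macro_database,
    filter_genes_by_localization,
    match_internal_reaction,
    match_transport_reaction,
    resolve_organism,
    transported_compounds,
)
from .gpr_algebra import DEFAULT_GENE_CAP, GeneRef, GPRExpression, serialize_rule
from .relationship_mining import (
    DEFAULT_KEYWORDS,
    DEFAULT_SOURCE_PRIORITY,
    EvidenceSource,
    RelationEvidence,
    complex_partners,
    extract_partners,
    isoform_partners,
    string_partners,
)
from .rule_assembly import assemble_all
from .snapshot_io import ModelInput, RuleRow, RulesTable, SnapshotBundle

__all__ = ["RunConfig", "ReconstructionResult", "reconstruct_model", "reconstruct_organism"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Tunable knobs of a reconstruction run."""

    threshold: int = DEFAULT_MATCH_THRESHOLD
    cap: int = DEFAULT_GENE_CAP
    priority: Sequence[EvidenceSource] = DEFAULT_SOURCE_PRIORITY
    keywords: Sequence[str] = DEFAULT_KEYWORDS
    aliases: Mapping[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_ALIASES))
    vocabulary: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_COMPARTMENT_VOCABULARY)
    )
    interactive: bool = False
    answers: Mapping[str, str] = field(default_factory=dict)
    ignore_compounds: frozenset[str] = frozenset()
    apply_localization_filter: bool = True


@dataclass
class ReconstructionResult:
    rules: dict[str, GPRExpression]
    table: RulesTable
    reaction_genes: dict[str, frozenset[GeneRef]]
    log: list[dict]

    def log_events(self, event: str) -> list[dict]:
        return [entry for entry in self.log if entry["event"] == event]


def _note(log: list[dict], stage: str, entity: str, event: str, detail: str) -> None:
    log.append({"stage": stage, "entity": entity, "event": event, "detail": detail})
    logger.info("[%s] %s: %s (%s)", stage, entity, event, detail)


def build_universe(bundle: SnapshotBundle) -> dict[str, GeneRef]:
    """Token -> gene map over symbols and synonyms (case-insensitive)."""
    universe: dict[str, GeneRef] = {}
    for gene, record in bundle.proteins.items():
        universe.setdefault(gene.identifier.lower(), gene)
        for synonym in record.synonyms:
            universe.setdefault(synonym.lower(), gene)
    return universe


def mine_evidence(
    bundle: SnapshotBundle,
    genes: Sequence[GeneRef],
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
) -> dict[GeneRef, list[RelationEvidence]]:
    """All five evidence channels for each gene, deterministically."""
    universe = build_universe(bundle)
    store: dict[GeneRef, list[RelationEvidence]] = {}
    for gene in sorted(set(genes)):
        evidence: list[RelationEvidence] = []
        record = bundle.proteins.get(gene)
        if record is not None:
            evidence.extend(extract_partners(record, universe, keywords))
        evidence.extend(complex_partners(gene, bundle.complexes))
        evidence.extend(string_partners(gene, bundle.network))
        evidence.extend(isoform_partners(gene, bundle.orthology))
        store[gene] = evidence
    return store


def _resolve_metabolites(
    model: ModelInput,
    index: CompoundIndex,
    config: RunConfig,
    log: list[dict],
) -> dict[str, Optional[str]]:
    from .entity_resolution import match_metabolite

    labels = sorted(
        {
            p.compound_id
            for reaction in model.reactions
            for p in reaction.substrates + reaction.products
        }
    )
    resolved: dict[str, Optional[str]] = {}
    for label in labels:
        if label in config.answers:
            resolved[label] = config.answers[label]
            _note(log, "metabolites", label, "answered", config.answers[label])
            continue
        result = match_metabolite(
            label, index, threshold=config.threshold, aliases=config.aliases
        )
        if result.accepted is not None:
            resolved[label] = result.accepted
            method = result.shortlist[0].method if result.shortlist else "exact_name"
            _note(log, "metabolites", label, "accepted", f"{result.accepted} ({method})")
        elif result.shortlist:
            top = result.shortlist[0]
            resolved[label] = top.compound_id
            _note(
                log,
                "metabolites",
                label,
                "shortlist_default",
                f"auto-accepted top candidate {top.compound_id} (score {top.score})",
            )
        else:
            resolved[label] = None
            _note(log, "metabolites", label, "unresolved", "no candidate found")
    return resolved


def _reaction_gene_sets(
    model: ModelInput,
    bundle: SnapshotBundle,
    macro: MacroDatabase,
    resolved: Mapping[str, Optional[str]],
    config: RunConfig,
    log: list[dict],
) -> dict[str, frozenset[GeneRef]]:
    reaction_genes: dict[str, frozenset[GeneRef]] = {}
    for reaction in model.reactions:
        rid = reaction.reaction_id
        participants = list(reaction.substrates) + list(reaction.products)
        if any(resolved.get(p.compound_id) is None for p in participants):
            _note(log, "genes", rid, "skipped", "unresolved metabolite(s)")
            reaction_genes[rid] = frozenset()
            continue
        substrates = [(resolved[p.compound_id], p.coefficient) for p in reaction.substrates]
        products = [(resolved[p.compound_id], p.coefficient) for p in reaction.products]
        sub_comp = [(resolved[p.compound_id], p.compartment) for p in reaction.substrates]
        prod_comp = [(resolved[p.compound_id], p.compartment) for p in reaction.products]
        moved = transported_compounds(sub_comp, prod_comp)
        genes: set[GeneRef] = set()
        if moved:
            entry = match_internal_reaction(
                substrates, products, macro, config.ignore_compounds
            )
            if entry is not None:
                genes |= entry.genes
            genes |= match_transport_reaction(sub_comp, prod_comp, bundle.transporters)
            if not genes:
                _note(log, "genes", rid, "no_match", "transport reaction matched no genes")
        else:
            entry = match_internal_reaction(
                substrates, products, macro, config.ignore_compounds
            )
            if entry is None:
                _note(log, "genes", rid, "no_match", "no macro-database entry")
            else:
                genes |= entry.genes
        if genes and config.apply_localization_filter:
            compartments = {p.compartment for p in participants}
            kept: set[GeneRef] = set()
            for compartment in compartments:
                kept |= filter_genes_by_localization(
                    genes, compartment, bundle.proteins, config.vocabulary
                )
            dropped = genes - kept
            if dropped:
                names = ",".join(sorted(g.identifier for g in dropped))
                _note(log, "localization", rid, "filtered", names)
            genes = kept
        reaction_genes[rid] = frozenset(genes)
    return reaction_genes


def _assemble(
    reaction_genes: Mapping[str, frozenset[GeneRef]],
    bundle: SnapshotBundle,
    config: RunConfig,
) -> dict[str, GPRExpression]:
    all_genes = sorted({g for genes in reaction_genes.values() for g in genes})
    evidence = mine_evidence(bundle, all_genes, config.keywords)
    return assemble_all(
        reaction_genes, evidence, config.priority, complexes=bundle.complexes
    )


def reconstruct_model(
    model: ModelInput,
    bundle: SnapshotBundle,
    config: Optional[RunConfig] = None,
) -> ReconstructionResult:
    """Reconstruct GPR rules for a draft model against a snapshot bundle.

    Stages: metabolite identification (alias/exact/InChI/fuzzy cascade),
    macro-database reaction matching (internal by signature, transport
    via transporter substrates), localization filtering, relationship
    mining and rule assembly.
    """
    config = config or RunConfig()
    log: list[dict] = []
    index = CompoundIndex(bundle.compounds)
    resolved = _resolve_metabolites(model, index, config, log)
    macro = build_macro_database(bundle.reactions, config.ignore_compounds)
    reaction_genes = _reaction_gene_sets(model, bundle, macro, resolved, config, log)
    rules = _assemble(reaction_genes, bundle, config)
    rows = tuple(
        RuleRow(
            rxn=reaction.reaction_id,
            rule_original=reaction.rule or "",
            rule_generated=serialize_rule(rules[reaction.reaction_id]),
        )
        for reaction in model.reactions
    )
    return ReconstructionResult(rules, RulesTable(rows), reaction_genes, log)


def reconstruct_organism(
    name: str,
    bundle: SnapshotBundle,
    config: Optional[RunConfig] = None,
) -> ReconstructionResult:
    """Reconstruct GPR rules for an organism resolved by name.

    The organism's genes are filtered to metabolic branches of the
    functional hierarchy; each harvested reaction's gene set is the
    union of the genes annotated to it and the macro-database entry's
    genes; mining and assembly then proceed as in the model mode.
    """
    from .entity_resolution import metabolic_reactions_for_organism

    config = config or RunConfig()
    log: list[dict] = []
    code = resolve_organism(name, bundle.organisms, interactive=config.interactive)
    _note(log, "organism", name, "resolved", code)
    genome = {
        code: frozenset(
            gene
            for gene, record in bundle.proteins.items()
            if record.organism in ("", code)
        )
    }
    hierarchy = {gene: record.branches for gene, record in bundle.proteins.items()}
    macro = build_macro_database(bundle.reactions, config.ignore_compounds)
    gene_reactions: dict[GeneRef, set[str]] = {}
    for entry in macro.entries:
        for gene in entry.genes:
            gene_reactions.setdefault(gene, set()).add(entry.reaction_id)
    reaction_genes = metabolic_reactions_for_organism(
        code,
        genome,
        hierarchy,
        {g: frozenset(rids) for g, rids in gene_reactions.items()},
        macro,
    )
    rules = _assemble(reaction_genes, bundle, config)
    rows = tuple(
        RuleRow(rxn=rid, rule_original="", rule_generated=serialize_rule(rules[rid]))
        for rid in sorted(rules)
    )
    return ReconstructionResult(
        rules, RulesTable(rows), dict(reaction_genes), log
    )
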