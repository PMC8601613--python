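"""Synthetic organism snapshots with known ground-truth GPR rules.

The generator plants a rule of a drawn structural class for every
reaction of a small metabolic model and then fabricates exactly the
evidence the mining stages consume:

* each AND group becomes a complex record, keyword-bearing annotation
  sentences on its members' protein records ("Component of a complex
  composed of ...", "Interacts with ... (By similarity)", ...), and a
  clique of interaction-network edges sharing a complex-flagged term —
  each channel independently included with probability
  ``evidence_completeness``;
* each OR group becomes an orthology group;
* distractor sentences reuse gene-like tokens absent from the gene
  universe, probing the universe gate of the text miner;
* compound synonyms are perturbed at a configurable edit rate, probing
  the fuzzy metabolite matcher.

Every reaction carries a unique pair of marker compounds, so reaction
signatures never collide and the macro database keeps reactions apart.
Generation is fully deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

import numpy as np

from .gpr_algebra import (
    EMPTY,
    Equivalence,
    GeneRef,
    GPRExpression,
    RuleClass,
    classify_rule,
    rules_equivalent,
)
from .entity_resolution import CompoundRecord, ReactionRecord
from .relationship_mining import (
    ComplexRecord,
    FunctionalTerm,
    InteractionNetwork,
    OrthologyGroup,
    ProteinRecord,
    Relation,
    RelationGraph,
    gene_pair,
)
from .snapshot_io import ModelInput, ModelReaction, Participant, SnapshotBundle

__all__ = ["FixtureSpec", "GroundTruth", "RecoveryReport", "generate_fixture", "recovery_report"]

#: Gross rule-class composition of well-curated metabolic models:
#: roughly 30% no-gene, 45% one-gene, the rest multi-gene dominated by OR.
DEFAULT_CLASS_MIX: Mapping[RuleClass, float] = {
    RuleClass.NO_GENE: 0.30,
    RuleClass.ONE_GENE: 0.45,
    RuleClass.OR: 0.12,
    RuleClass.AND: 0.08,
    RuleClass.MIXED: 0.05,
}

_SENTENCE_TEMPLATES = (
    "Component of a complex composed of {partners}.",
    "Part of a complex with {partners}.",
    "Interacts with {partners} (By similarity).",
    "Heteromerization with {partners}.",
    "The holoenzyme consists of {partners}.",
    "Associates with {partners}.",
)

_FILLER = "Catalyzes a step of central carbon metabolism."


@dataclass(frozen=True)
class FixtureSpec:
    """Statistical recipe for one synthetic snapshot."""

    seed: int = 0
    n_genes: int = 400
    n_reactions: int = 60
    class_mix: Mapping[RuleClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    complex_size_law: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.6, 3: 0.3, 4: 0.1}
    )
    isoform_group_law: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.6, 3: 0.4}
    )
    evidence_completeness: float = 1.0
    text_noise: int = 0
    name_perturbation: float = 0.0

    def __post_init__(self) -> None:
        for law, name in (
            (self.class_mix, "class_mix"),
            (self.complex_size_law, "complex_size_law"),
            (self.isoform_group_law, "isoform_group_law"),
        ):
            total = sum(law.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1 (got {total})")
            if any(p < 0 for p in law.values()):
                raise ValueError(f"{name} proportions must be non-negative")
        if not 0.0 <= self.evidence_completeness <= 1.0:
            raise ValueError("evidence_completeness must lie in [0, 1]")
        if not 0.0 <= self.name_perturbation <= 1.0:
            raise ValueError("name_perturbation must lie in [0, 1]")
        if self.text_noise < 0:
            raise ValueError("text_noise must be non-negative")
        if any(k < 2 for k in self.complex_size_law) or any(
            k < 2 for k in self.isoform_group_law
        ):
            raise ValueError("group sizes must be at least 2")


@dataclass
class GroundTruth:
    rules: dict[str, GPRExpression]
    relations: dict[str, RelationGraph]


@dataclass
class RecoveryReport:
    """Per-class fractions of reactions recovered equivalent to truth."""

    per_class: dict[RuleClass, float]
    counts: dict[RuleClass, tuple[int, int]]  # (recovered, total)
    overall: float


class _GenePool:
    def __init__(self, limit: int):
        self.limit = limit
        self.used = 0

    def take(self, n: int) -> list[GeneRef]:
        if self.used + n > self.limit:
            raise ValueError(
                f"spec infeasible: needs more than n_genes={self.limit} genes"
            )
        out = [GeneRef(f"G{self.used + i:04d}") for i in range(n)]
        self.used += n
        return out


def _draw(rng: np.random.Generator, law: Mapping[int, float]) -> int:
    keys = sorted(law)
    return int(rng.choice(keys, p=[law[k] for k in keys]))


def _partner_list(partners) -> str:
    return ", ".join(g.identifier for g in partners)


def _perturb(rng: np.random.Generator, name: str) -> str:
    # duplicate one letter: keeps digits (the discriminating part) intact
    letters = [i for i, ch in enumerate(name) if ch.isalpha()]
    if not letters:
        return name + "x"
    i = int(rng.integers(0, len(letters)))
    j = letters[i]
    return name[: j + 1] + name[j] + name[j + 1 :]


def generate_fixture(spec: FixtureSpec) -> tuple[SnapshotBundle, ModelInput, GroundTruth]:
    """Generate a snapshot bundle, draft model and ground truth for a spec."""
    rng = np.random.default_rng(spec.seed)
    pool = _GenePool(spec.n_genes)
    ec = spec.evidence_completeness

    classes = sorted(spec.class_mix, key=lambda c: c.name)
    probs = [spec.class_mix[c] for c in classes]

    interaction_texts: dict[GeneRef, list[str]] = {}
    complexes: list[ComplexRecord] = []
    orthology: list[OrthologyGroup] = []
    edges: set[tuple[GeneRef, GeneRef]] = set()
    extra_terms: dict[GeneRef, set[FunctionalTerm]] = {}
    rules: dict[str, GPRExpression] = {}
    relations: dict[str, RelationGraph] = {}
    reaction_genes: dict[str, list[GeneRef]] = {}

    def enabled() -> bool:
        # one Bernoulli draw per evidence channel
        return bool(rng.random() < ec)

    def plant_complex(rid: str, index: int, members: list[GeneRef]) -> None:
        cid = f"CPX-{rid}-{index}"
        if enabled():
            complexes.append(ComplexRecord(cid, frozenset(members)))
        if enabled():
            template = _SENTENCE_TEMPLATES[int(rng.integers(0, len(_SENTENCE_TEMPLATES)))]
            for gene in members:
                partners = [g for g in members if g != gene]
                sentence = template.format(partners=_partner_list(partners))
                interaction_texts.setdefault(gene, []).append(sentence)
        if enabled():
            term = FunctionalTerm(f"{cid} complex", is_complex=True)
            for gene in members:
                extra_terms.setdefault(gene, set()).add(term)
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    edges.add(gene_pair(a, b))

    def plant_isoforms(rid: str, index: int, members: list[GeneRef]) -> None:
        if enabled():
            orthology.append(OrthologyGroup(f"KO-{rid}-{index}", frozenset(members)))

    for i in range(spec.n_reactions):
        rid = f"R{i:04d}"
        cls = classes[int(rng.choice(len(classes), p=probs))]
        groups: list[list[GeneRef]] = []
        if cls is RuleClass.NO_GENE:
            pass
        elif cls is RuleClass.ONE_GENE:
            groups = [pool.take(1)]
        elif cls is RuleClass.OR:
            k = _draw(rng, spec.isoform_group_law)
            groups = [[g] for g in pool.take(k)]
        elif cls is RuleClass.AND:
            groups = [pool.take(_draw(rng, spec.complex_size_law))]
        else:  # MIXED: one complex plus at least one alternative branch
            groups = [pool.take(_draw(rng, spec.complex_size_law))]
            if rng.random() < 0.5:
                groups.append(pool.take(_draw(rng, spec.complex_size_law)))
            else:
                groups.append(pool.take(1))

        genes = [g for group in groups for g in group]
        reaction_genes[rid] = genes

        complex_index = 0
        isoform_index = 0
        resolved: dict[tuple[GeneRef, GeneRef], Relation] = {}
        for group in groups:
            if len(group) >= 2:
                if cls is RuleClass.OR:
                    continue  # OR singletons handled below as one group
                plant_complex(rid, complex_index, group)
                complex_index += 1
                for a_i, a in enumerate(group):
                    for b in group[a_i + 1 :]:
                        resolved[gene_pair(a, b)] = Relation.SUBUNIT
        if cls is RuleClass.OR:
            members = genes
            plant_isoforms(rid, isoform_index, members)
            isoform_index += 1
            for a_i, a in enumerate(members):
                for b in members[a_i + 1 :]:
                    resolved[gene_pair(a, b)] = Relation.ISOFORM
        else:
            for g_i, group_a in enumerate(groups):
                for group_b in groups[g_i + 1 :]:
                    for a in group_a:
                        for b in group_b:
                            resolved[gene_pair(a, b)] = Relation.ISOFORM

        if not groups:
            rules[rid] = EMPTY
        else:
            branches = [
                GPRExpression.from_gene(group[0])
                if len(group) == 1
                else GPRExpression.conjunction(
                    GPRExpression.from_gene(g) for g in group
                )
                for group in groups
            ]
            rules[rid] = (
                branches[0] if len(branches) == 1 else GPRExpression.disjunction(branches)
            )
        relations[rid] = RelationGraph(frozenset(genes), (), resolved)

    # distractor sentences: keyword-bearing text naming tokens outside the
    # gene universe, to probe the miner's universe gate
    all_genes = [GeneRef(f"G{i:04d}") for i in range(pool.used)]
    for gene in all_genes:
        for _ in range(spec.text_noise):
            fake = f"ZX{int(rng.integers(0, 10**6)):06d}"
            interaction_texts.setdefault(gene, []).append(
                f"Interacts with {fake} (By similarity)."
            )

    proteins = {
        gene: ProteinRecord(
            gene=gene,
            interaction_text=" ".join(interaction_texts.get(gene, [])),
            function_text=_FILLER,
            localizations=(("cytosol", "manual"),),
            organism="syn",
            branches=("Metabolism",),
        )
        for gene in all_genes
    }

    base_term = FunctionalTerm("metabolic pathways", is_complex=False)
    annotations = {
        gene: frozenset({base_term} | extra_terms.get(gene, set()))
        for gene in all_genes
    }
    network = InteractionNetwork(frozenset(edges), annotations)

    # compounds: two shared cofactors plus a unique substrate/product
    # marker pair per reaction, so reaction signatures never collide
    compounds: list[CompoundRecord] = []
    labels: dict[str, str] = {}

    def add_compound(cid: str, name: str) -> None:
        synonyms = [f"{name} (syn)"]
        label = name
        if rng.random() < spec.name_perturbation:
            label = _perturb(rng, name)
            synonyms.append(label)
        compounds.append(
            CompoundRecord(
                compound_id=cid,
                source="chebi",
                names=(name, *synonyms),
                inchi=f"InChI=1S/FX{cid}",
            )
        )
        labels[cid] = label

    add_compound("C_ATP", "synthon-triphosphate")
    add_compound("C_ADP", "synthon-diphosphate")
    snapshot_reactions: list[ReactionRecord] = []
    model_reactions: list[ModelReaction] = []
    one = Fraction(1)
    for i in range(spec.n_reactions):
        rid = f"R{i:04d}"
        sub_id, prod_id = f"C{2 * i:05d}", f"C{2 * i + 1:05d}"
        add_compound(sub_id, f"metabolite-{2 * i}")
        add_compound(prod_id, f"metabolite-{2 * i + 1}")
        snapshot_reactions.append(
            ReactionRecord(
                reaction_id=f"RX{i:04d}",
                sources=frozenset({"kegg"}),
                substrates=((sub_id, one), ("C_ATP", one)),
                products=((prod_id, one), ("C_ADP", one)),
                genes=frozenset(reaction_genes[rid]),
                xrefs={"kegg": f"RX{i:04d}"},
            )
        )
        model_reactions.append(
            ModelReaction(
                rid,
                substrates=(
                    Participant(labels[sub_id], "c", one),
                    Participant(labels["C_ATP"], "c", one),
                ),
                products=(
                    Participant(labels[prod_id], "c", one),
                    Participant(labels["C_ADP"], "c", one),
                ),
            )
        )

    # tables sorted by primary key, matching writer order, so a bundle
    # written and re-read compares equal
    bundle = SnapshotBundle(
        compounds=tuple(sorted(compounds, key=lambda c: c.compound_id)),
        reactions=tuple(sorted(snapshot_reactions, key=lambda r: r.reaction_id)),
        transporters=(),
        proteins=proteins,
        complexes=tuple(sorted(complexes, key=lambda c: c.complex_id)),
        network=network,
        orthology=tuple(sorted(orthology, key=lambda g: g.group_id)),
        organisms={"syn": "Synthetica exempli"},
        manifest={
            "organism": "syn",
            "gene_namespace": "model",
            "synthetic": True,
            "seed": spec.seed,
            "sources": {"reactions": "generated", "proteins": "generated"},
        },
    )
    model = ModelInput(tuple(model_reactions))
    return bundle, model, GroundTruth(rules, relations)


def recovery_report(
    truth: GroundTruth,
    produced: Mapping[str, GPRExpression],
    cap: int = 20,
) -> RecoveryReport:
    """Fraction of reactions per rule class recovered equivalent to truth."""
    if set(truth.rules) != set(produced):
        missing = sorted(set(truth.rules) ^ set(produced))
        raise ValueError(f"reaction id sets differ: {missing[:10]}")
    recovered: dict[RuleClass, int] = {}
    totals: dict[RuleClass, int] = {}
    for rid, expected in truth.rules.items():
        cls = classify_rule(expected)
        totals[cls] = totals.get(cls, 0) + 1
        verdict = rules_equivalent(expected, produced[rid], cap=cap)
        if verdict is Equivalence.EQUIVALENT:
            recovered[cls] = recovered.get(cls, 0) + 1
    per_class = {
        cls: recovered.get(cls, 0) / totals[cls] for cls in sorted(totals, key=lambda c: c.name)
    }
    counts = {
        cls: (recovered.get(cls, 0), totals[cls])
        for cls in sorted(totals, key=lambda c: c.name)
    }
    total = sum(totals.values())
    overall = sum(recovered.values()) / total if total else 1.0
    return RecoveryReport(per_class, counts, overall)
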