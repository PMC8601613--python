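"""Readers and writers for every file the pipeline touches.

* **Snapshot bundles** — the offline representation of the data sources
  (compounds, reactions, transporters, proteins, complexes, interaction
  network, orthology groups, organisms) as a directory of tab-separated
  UTF-8 tables with a one-line header plus a JSON manifest.  List-valued
  fields are pipe-separated; key-value fields use ``key=value`` items.
  The format is deliberately plain text: hand-editable and diffable.
* **Models** — SBML (read any level; gene associations from the fbc
  package or legacy notes; written fbc-style) through COBRApy, or a
  documented TSV reaction-list dialect.
* **Rules tables** — the four-column comparison schema
  (``Rxn``, ``rule_original``, a generated-rule column, ``Evaluation``)
  with comma/semicolon delimiter autodetection.

Readers reject nothing silently: skipped or unparseable rows are
collected into a structured report.  Writers order rows and format
coefficients deterministically, so identical inputs give byte-identical
files.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .gpr_algebra import GeneRef, GPRExpression, parse_rule, serialize_rule
from .entity_resolution import CompoundRecord, ReactionRecord, TransporterRecord
from .relationship_mining import (
    ComplexRecord,
    FunctionalTerm,
    InteractionNetwork,
    OrthologyGroup,
    ProteinRecord,
)

__all__ = [
    "SnapshotBundle",
    "Participant",
    "ModelReaction",
    "ModelInput",
    "RuleRow",
    "RulesTable",
    "ModelFormatError",
    "SnapshotFormatError",
    "SnapshotIntegrityError",
    "read_snapshot",
    "write_snapshot",
    "read_model",
    "write_model",
    "write_annotated_model",
    "read_rules_table",
    "write_rules_table",
    "GENERATED_RULE_COLUMN",
]

logger = logging.getLogger(__name__)

LIST_SEP = "|"
KV_SEP = "="
GENERATED_RULE_COLUMN = "rule_generated"

_EVALUATION_LABELS_HINT = (
    "labels are free text; rows whose label does not start with "
    "'Perfect'/'Corrected'/'Not auto' are retained verbatim with a warning"
)


class ModelFormatError(ValueError):
    pass


class SnapshotFormatError(ValueError):
    pass


class SnapshotIntegrityError(ValueError):
    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "snapshot referential-integrity violations:\n  " + "\n  ".join(self.problems)
        )


# ---------------------------------------------------------------------------
# Snapshot bundle
# ---------------------------------------------------------------------------


@dataclass
class SnapshotBundle:
    """In-memory image of one organism's snapshot directory."""

    compounds: tuple[CompoundRecord, ...] = ()
    reactions: tuple[ReactionRecord, ...] = ()
    transporters: tuple[TransporterRecord, ...] = ()
    proteins: dict[GeneRef, ProteinRecord] = field(default_factory=dict)
    complexes: tuple[ComplexRecord, ...] = ()
    network: InteractionNetwork = field(default_factory=InteractionNetwork)
    orthology: tuple[OrthologyGroup, ...] = ()
    organisms: dict[str, str] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    @property
    def gene_namespace(self) -> str:
        return self.manifest.get("gene_namespace", "model")

    def validate(self) -> list[str]:
        """Referential-integrity report (empty when the bundle is sound)."""
        problems: list[str] = []
        compound_ids = {c.compound_id for c in self.compounds}
        genes = set(self.proteins)

        def check_genes(refs: Iterable[GeneRef], where: str) -> None:
            for g in refs:
                if g not in genes:
                    problems.append(f"{where}: unknown gene {g.identifier!r}")

        for r in self.reactions:
            for cid, _ in r.substrates + r.products:
                if cid not in compound_ids:
                    problems.append(
                        f"reaction {r.reaction_id!r}: unknown compound {cid!r}"
                    )
            check_genes(r.genes, f"reaction {r.reaction_id!r}")
        for t in self.transporters:
            for cid in t.substrates:
                if cid not in compound_ids:
                    problems.append(f"transporter {t.tc_code!r}: unknown compound {cid!r}")
            check_genes(t.genes, f"transporter {t.tc_code!r}")
        for c in self.complexes:
            check_genes(c.components, f"complex {c.complex_id!r}")
        for group in self.orthology:
            check_genes(group.members, f"orthology group {group.group_id!r}")
        check_genes(self.network.node_annotations, "network")
        return problems


# -- low-level table helpers -------------------------------------------------


def _write_table(path: Path, header: Sequence[str], rows: Iterable[Sequence[str]]) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def _read_table(path: Path, required: Sequence[str]) -> list[dict[str, str]]:
    if not path.exists():
        raise SnapshotFormatError(f"missing table {path.name}")
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        for column in required:
            if column not in reader.fieldnames:
                raise SnapshotFormatError(f"{path.name}: missing column {column!r}")
        return [dict(row) for row in reader]


def _join(items: Iterable[str]) -> str:
    items = list(items)
    for item in items:
        if LIST_SEP in item:
            raise SnapshotFormatError(f"list item {item!r} contains the separator {LIST_SEP!r}")
    return LIST_SEP.join(items)


def _split(text: str) -> list[str]:
    return [t for t in text.split(LIST_SEP) if t] if text else []


def _join_kv(mapping: Mapping[str, str]) -> str:
    return _join(f"{k}{KV_SEP}{v}" for k, v in sorted(mapping.items()))


def _split_kv(text: str, where: str) -> dict[str, str]:
    out = {}
    for item in _split(text):
        if KV_SEP not in item:
            raise SnapshotFormatError(f"{where}: malformed key-value item {item!r}")
        k, v = item.split(KV_SEP, 1)
        out[k] = v
    return out


def _frac(text: str, where: str) -> Fraction:
    try:
        return Fraction(text)
    except (ValueError, ZeroDivisionError) as exc:
        raise SnapshotFormatError(f"{where}: bad coefficient {text!r}") from exc


def _participants_str(side) -> str:
    return _join(f"{cid}:{coeff}" for cid, coeff in side)


def _participants_parse(text: str, where: str):
    out = []
    for item in _split(text):
        if ":" not in item:
            raise SnapshotFormatError(f"{where}: malformed participant {item!r}")
        cid, coeff = item.rsplit(":", 1)
        out.append((cid, _frac(coeff, where)))
    return tuple(out)


# -- writers -----------------------------------------------------------------

_TABLES = (
    "compounds",
    "reactions",
    "transporters",
    "proteins",
    "complexes",
    "network_edges",
    "network_annotations",
    "orthology",
    "organisms",
)


def write_snapshot(bundle: SnapshotBundle, directory) -> None:
    """Write a bundle as a snapshot directory (tables + manifest.json)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    _write_table(
        directory / "compounds.tsv",
        ["compound_id", "source", "names", "inchi", "xrefs", "ontology_parents"],
        [
            [
                c.compound_id,
                c.source,
                _join(c.names),
                c.inchi or "",
                _join_kv(c.xrefs),
                _join(c.ontology_parents),
            ]
            for c in sorted(bundle.compounds, key=lambda c: c.compound_id)
        ],
    )
    _write_table(
        directory / "reactions.tsv",
        ["reaction_id", "sources", "substrates", "products", "ec_numbers", "genes", "xrefs"],
        [
            [
                r.reaction_id,
                _join(sorted(r.sources)),
                _participants_str(r.substrates),
                _participants_str(r.products),
                _join(r.ec_numbers),
                _join(sorted(g.identifier for g in r.genes)),
                _join_kv(r.xrefs),
            ]
            for r in sorted(bundle.reactions, key=lambda r: r.reaction_id)
        ],
    )
    _write_table(
        directory / "transporters.tsv",
        ["tc_code", "substrates", "genes"],
        [
            [t.tc_code, _join(sorted(t.substrates)), _join(sorted(g.identifier for g in t.genes))]
            for t in sorted(bundle.transporters, key=lambda t: t.tc_code)
        ],
    )
    _write_table(
        directory / "proteins.tsv",
        [
            "gene",
            "synonyms",
            "interaction_text",
            "function_text",
            "complex_xrefs",
            "localizations",
            "organism",
            "branches",
        ],
        [
            [
                p.gene.identifier,
                _join(p.synonyms),
                p.interaction_text,
                p.function_text,
                _join(p.complex_xrefs),
                _join(f"{term}{KV_SEP}{ev}" for term, ev in p.localizations),
                p.organism,
                _join(p.branches),
            ]
            for p in sorted(bundle.proteins.values(), key=lambda p: p.gene)
        ],
    )
    _write_table(
        directory / "complexes.tsv",
        ["complex_id", "components"],
        [
            [c.complex_id, _join(sorted(g.identifier for g in c.components))]
            for c in sorted(bundle.complexes, key=lambda c: c.complex_id)
        ],
    )
    _write_table(
        directory / "network_edges.tsv",
        ["gene_a", "gene_b"],
        sorted(
            [sorted([a.identifier, b.identifier]) for a, b in bundle.network.edges]
        ),
    )
    _write_table(
        directory / "network_annotations.tsv",
        ["gene", "terms"],
        [
            [
                gene.identifier,
                _join(
                    f"{t.term}{KV_SEP}{'complex' if t.is_complex else 'other'}"
                    for t in sorted(terms, key=lambda t: t.term)
                ),
            ]
            for gene, terms in sorted(
                bundle.network.node_annotations.items(), key=lambda kv: kv[0]
            )
        ],
    )
    _write_table(
        directory / "orthology.tsv",
        ["group_id", "members"],
        [
            [g.group_id, _join(sorted(m.identifier for m in g.members))]
            for g in sorted(bundle.orthology, key=lambda g: g.group_id)
        ],
    )
    _write_table(
        directory / "organisms.tsv",
        ["code", "name"],
        [[code, name] for code, name in sorted(bundle.organisms.items())],
    )

    manifest = dict(bundle.manifest)
    manifest.setdefault("gene_namespace", "model")
    manifest["tables"] = list(_TABLES)
    with (directory / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


# -- readers -----------------------------------------------------------------


def read_snapshot(directory, validate: bool = True) -> SnapshotBundle:
    """Load a snapshot directory; validates referential integrity."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise SnapshotFormatError(f"missing manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    namespace = manifest.get("gene_namespace", "model")

    def gene(identifier: str) -> GeneRef:
        return GeneRef(identifier, namespace)

    compounds = tuple(
        CompoundRecord(
            compound_id=row["compound_id"],
            source=row["source"],
            names=tuple(_split(row["names"])),
            inchi=row["inchi"] or None,
            xrefs=_split_kv(row["xrefs"], f"compound {row['compound_id']}"),
            ontology_parents=tuple(_split(row["ontology_parents"])),
        )
        for row in _read_table(
            directory / "compounds.tsv",
            ["compound_id", "source", "names", "inchi", "xrefs", "ontology_parents"],
        )
    )
    reactions = tuple(
        ReactionRecord(
            reaction_id=row["reaction_id"],
            sources=frozenset(_split(row["sources"])),
            substrates=_participants_parse(
                row["substrates"], f"reaction {row['reaction_id']}"
            ),
            products=_participants_parse(
                row["products"], f"reaction {row['reaction_id']}"
            ),
            ec_numbers=tuple(_split(row["ec_numbers"])),
            genes=frozenset(gene(g) for g in _split(row["genes"])),
            xrefs=_split_kv(row["xrefs"], f"reaction {row['reaction_id']}"),
        )
        for row in _read_table(
            directory / "reactions.tsv",
            ["reaction_id", "sources", "substrates", "products", "ec_numbers", "genes", "xrefs"],
        )
    )
    transporters = tuple(
        TransporterRecord(
            tc_code=row["tc_code"],
            substrates=frozenset(_split(row["substrates"])),
            genes=frozenset(gene(g) for g in _split(row["genes"])),
        )
        for row in _read_table(directory / "transporters.tsv", ["tc_code", "substrates", "genes"])
    )
    proteins: dict[GeneRef, ProteinRecord] = {}
    for row in _read_table(
        directory / "proteins.tsv",
        ["gene", "synonyms", "interaction_text", "function_text", "complex_xrefs", "localizations"],
    ):
        locs = []
        for item in _split(row["localizations"]):
            if KV_SEP not in item:
                raise SnapshotFormatError(
                    f"protein {row['gene']}: malformed localization {item!r}"
                )
            term, ev = item.rsplit(KV_SEP, 1)
            locs.append((term, ev))
        record = ProteinRecord(
            gene=gene(row["gene"]),
            synonyms=tuple(_split(row["synonyms"])),
            interaction_text=row["interaction_text"],
            function_text=row["function_text"],
            complex_xrefs=tuple(_split(row["complex_xrefs"])),
            localizations=tuple(locs),
            organism=row.get("organism", ""),
            branches=tuple(_split(row.get("branches", ""))),
        )
        proteins[record.gene] = record
    complexes = tuple(
        ComplexRecord(row["complex_id"], frozenset(gene(g) for g in _split(row["components"])))
        for row in _read_table(directory / "complexes.tsv", ["complex_id", "components"])
    )
    edges = frozenset(
        (gene(row["gene_a"]), gene(row["gene_b"]))
        for row in _read_table(directory / "network_edges.tsv", ["gene_a", "gene_b"])
    )
    annotations: dict[GeneRef, frozenset[FunctionalTerm]] = {}
    for row in _read_table(directory / "network_annotations.tsv", ["gene", "terms"]):
        terms = []
        for item in _split(row["terms"]):
            term, _, flag = item.rpartition(KV_SEP)
            terms.append(FunctionalTerm(term, flag == "complex"))
        annotations[gene(row["gene"])] = frozenset(terms)
    network = InteractionNetwork(edges, annotations)
    orthology = tuple(
        OrthologyGroup(row["group_id"], frozenset(gene(g) for g in _split(row["members"])))
        for row in _read_table(directory / "orthology.tsv", ["group_id", "members"])
    )
    organisms = {
        row["code"]: row["name"]
        for row in _read_table(directory / "organisms.tsv", ["code", "name"])
    }

    bundle = SnapshotBundle(
        compounds=compounds,
        reactions=reactions,
        transporters=transporters,
        proteins=proteins,
        complexes=complexes,
        network=network,
        orthology=orthology,
        organisms=organisms,
        manifest=manifest,
    )
    if validate:
        problems = bundle.validate()
        if problems:
            raise SnapshotIntegrityError(problems)
    return bundle


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Participant:
    compound_id: str
    compartment: str
    coefficient: Fraction = Fraction(1)


@dataclass(frozen=True)
class ModelReaction:
    reaction_id: str
    substrates: tuple[Participant, ...]
    products: tuple[Participant, ...]
    rule: Optional[str] = None  # existing gene-association string, verbatim


@dataclass
class ModelInput:
    reactions: tuple[ModelReaction, ...]
    gene_namespace: str = "model"

    def __post_init__(self) -> None:
        ids = [r.reaction_id for r in self.reactions]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ModelFormatError(f"duplicate reaction ids: {dup}")


_PARTICIPANT_RE = re.compile(
    r"^\s*(?:(?P<coeff>\d+(?:\.\d+)?|\d+/\d+)\s*\*\s*)?(?P<cid>[^\[\]]+?)\s*\[(?P<comp>[^\]]+)\]\s*$"
)


def _parse_participant(token: str, where: str) -> Participant:
    m = _PARTICIPANT_RE.match(token)
    if m is None:
        raise ModelFormatError(
            f"{where}: malformed participant {token!r} "
            "(expected 'coeff*compound[compartment]')"
        )
    coeff = Fraction(m.group("coeff")) if m.group("coeff") else Fraction(1)
    return Participant(m.group("cid"), m.group("comp"), coeff)


def _format_participant(p: Participant) -> str:
    prefix = "" if p.coefficient == 1 else f"{p.coefficient}*"
    return f"{prefix}{p.compound_id}[{p.compartment}]"


def _read_model_tsv(path: Path) -> ModelInput:
    """TSV dialect: columns ``reaction_id``, ``substrates``, ``products``
    and optional ``rule``; participant lists are pipe-separated tokens
    ``coeff*compound[compartment]`` (coefficient omitted when 1)."""
    rows = _read_table(path, [])
    with path.open(newline="", encoding="utf-8") as fh:
        fieldnames = csv.DictReader(fh, delimiter="\t").fieldnames or []
    for column in ("reaction_id", "substrates", "products"):
        if column not in fieldnames:
            raise ModelFormatError(f"{path.name}: missing required column {column!r}")
    reactions = []
    for row in rows:
        rid = row["reaction_id"]
        subs = tuple(
            _parse_participant(t, f"reaction {rid}") for t in _split(row["substrates"])
        )
        prods = tuple(
            _parse_participant(t, f"reaction {rid}") for t in _split(row["products"])
        )
        rule = row.get("rule")
        reactions.append(ModelReaction(rid, subs, prods, rule if rule else None))
    return ModelInput(tuple(reactions))


def _strip_compartment(met_id: str, compartment: str) -> str:
    for pattern in (f"_{compartment}", f"[{compartment}]"):
        if met_id.endswith(pattern):
            return met_id[: -len(pattern)]
    return met_id


def _read_model_sbml(path: Path) -> ModelInput:
    import cobra.io

    try:
        model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises various types for bad files
        raise ModelFormatError(f"cannot parse SBML model {path}: {exc}") from exc
    reactions = []
    for rxn in model.reactions:
        subs, prods = [], []
        for met, coeff in rxn.metabolites.items():
            compartment = met.compartment or ""
            participant = Participant(
                _strip_compartment(met.id, compartment),
                compartment,
                abs(Fraction(coeff).limit_denominator(10**6)),
            )
            (subs if coeff < 0 else prods).append(participant)
        rule = rxn.gene_reaction_rule or None
        reactions.append(
            ModelReaction(rxn.id, tuple(sorted(subs, key=lambda p: p.compound_id)),
                          tuple(sorted(prods, key=lambda p: p.compound_id)), rule)
        )
    return ModelInput(tuple(reactions))


def read_model(path, dialect: str = "sbml") -> ModelInput:
    """Read a metabolic model as a reaction list.

    ``dialect`` is ``sbml`` (any level; gene associations captured
    verbatim from the fbc slot or legacy notes) or ``tsv`` (see
    :func:`_read_model_tsv` for the column contract).
    """
    path = Path(path)
    if not path.exists():
        raise ModelFormatError(f"model file {path} does not exist")
    if dialect == "sbml":
        return _read_model_sbml(path)
    if dialect == "tsv":
        return _read_model_tsv(path)
    raise ValueError(f"unknown model dialect {dialect!r}")


def write_model(model: ModelInput, path, dialect: str = "tsv") -> None:
    """Write a model in the TSV dialect (or SBML via the annotated writer)."""
    path = Path(path)
    if dialect == "tsv":
        _write_table(
            path,
            ["reaction_id", "substrates", "products", "rule"],
            [
                [
                    r.reaction_id,
                    _join(_format_participant(p) for p in r.substrates),
                    _join(_format_participant(p) for p in r.products),
                    r.rule or "",
                ]
                for r in model.reactions
            ],
        )
        return
    if dialect == "sbml":
        rules = {
            r.reaction_id: parse_rule(r.rule) for r in model.reactions if r.rule
        }
        write_annotated_model(model, rules, path)
        return
    raise ValueError(f"unknown model dialect {dialect!r}")


def _sanitize(identifier: str) -> str:
    clean = re.sub(r"[^A-Za-z0-9_]", "_", identifier)
    return clean if clean and not clean[0].isdigit() else f"x{clean}"


def write_annotated_model(
    model: ModelInput,
    rules: Mapping[str, GPRExpression],
    path,
    bounds: tuple[float, float] = (-1000.0, 1000.0),
) -> None:
    """Write an SBML model carrying the assembled GPR rules.

    Serialized rules go into the standard gene-association slot (fbc);
    reactions without a rule (or with the empty rule) carry an empty
    association.  Rule keys must be reaction ids of the model.
    """
    import cobra
    import cobra.io

    model_ids = {r.reaction_id for r in model.reactions}
    unknown = sorted(set(rules) - model_ids)
    if unknown:
        raise ValueError(f"rules refer to unknown reaction ids: {unknown}")

    out = cobra.Model("gprules_model")
    mets: dict[tuple[str, str], "cobra.Metabolite"] = {}

    def metabolite(p: Participant) -> "cobra.Metabolite":
        key = (p.compound_id, p.compartment)
        if key not in mets:
            met = cobra.Metabolite(
                _sanitize(f"{p.compound_id}_{p.compartment}"), compartment=p.compartment
            )
            mets[key] = met
        return mets[key]

    cobra_reactions = []
    for reaction in model.reactions:
        rxn = cobra.Reaction(_sanitize(reaction.reaction_id))
        rxn.lower_bound, rxn.upper_bound = bounds
        stoich: dict = {}
        for p in reaction.substrates:
            met = metabolite(p)
            stoich[met] = stoich.get(met, 0) - float(p.coefficient)
        for p in reaction.products:
            met = metabolite(p)
            stoich[met] = stoich.get(met, 0) + float(p.coefficient)
        rxn.add_metabolites(stoich)
        cobra_reactions.append((rxn, reaction.reaction_id))
    out.add_reactions([r for r, _ in cobra_reactions])
    for rxn, rid in cobra_reactions:
        expr = rules.get(rid)
        rxn.gene_reaction_rule = serialize_rule(expr) if expr is not None else ""
    cobra.io.write_sbml_model(out, str(path))


# ---------------------------------------------------------------------------
# Rules tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RuleRow:
    rxn: str
    rule_original: str
    rule_generated: str
    evaluation: str = ""


@dataclass
class RulesTable:
    """The four-column rule-comparison schema."""

    rows: tuple[RuleRow, ...]

    def __post_init__(self) -> None:
        ids = [r.rxn for r in self.rows]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate Rxn ids in rules table: {dup}")

    def parse_report(self) -> list[tuple[str, str, str]]:
        """(rxn, column, message) for every rule string that fails to parse."""
        failures = []
        for row in self.rows:
            for column, text in (
                ("rule_original", row.rule_original),
                (GENERATED_RULE_COLUMN, row.rule_generated),
            ):
                try:
                    parse_rule(text)
                except Exception as exc:
                    failures.append((row.rxn, column, str(exc)))
        return failures


_KNOWN_EVALUATION_PREFIXES = ("perfect", "corrected", "not auto")


def read_rules_table(path) -> RulesTable:
    """Read a rules table; comma and semicolon delimiters are autodetected.

    The generated-rule column is any ``rule_*`` column other than
    ``rule_original`` (the supplementary-file schema names it after the
    generating tool).  Unknown ``Evaluation`` labels trigger a warning
    and are retained verbatim.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    header = text.splitlines()[0] if text else ""
    delimiter = ";" if header.count(";") > header.count(",") else ","
    reader = csv.DictReader(text.splitlines(), delimiter=delimiter)
    fields = reader.fieldnames or []
    if "Rxn" not in fields or "rule_original" not in fields:
        raise ValueError(f"{path.name}: expected columns 'Rxn' and 'rule_original'")
    generated_columns = [
        f for f in fields if f.lower().startswith("rule_") and f != "rule_original"
    ]
    if not generated_columns:
        raise ValueError(f"{path.name}: no generated-rule column (rule_*) found")
    generated = generated_columns[0]
    rows = []
    for row in reader:
        evaluation = (row.get("Evaluation") or "").strip()
        if evaluation and not evaluation.lower().startswith(_KNOWN_EVALUATION_PREFIXES):
            logger.warning(
                "unknown Evaluation label %r for %s (%s)",
                evaluation,
                row["Rxn"],
                _EVALUATION_LABELS_HINT,
            )
        rows.append(
            RuleRow(
                rxn=row["Rxn"],
                rule_original=(row.get("rule_original") or "").strip(),
                rule_generated=(row.get(generated) or "").strip(),
                evaluation=evaluation,
            )
        )
    return RulesTable(tuple(rows))


def write_rules_table(table: RulesTable, path) -> None:
    """Write the exact four-column schema as comma-separated text."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["Rxn", "rule_original", GENERATED_RULE_COLUMN, "Evaluation"])
        for row in table.rows:
            writer.writerow([row.rxn, row.rule_original, row.rule_generated, row.evaluation])
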