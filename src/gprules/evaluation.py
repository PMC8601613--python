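"""Benchmarking of reconstructed GPR rules against ground truth.

Two complementary evaluations are provided:

* **Rule comparison** — every row of a rules table is compared by truth
  -table equivalence (perfect match vs negative match), with the Jaccard
  index over gene sets localizing gene-level disagreement and, for
  negative matches with identical gene sets, the normalized Hamming
  similarity of the truth tables quantifying operator-level
  disagreement.  Rows are tallied per rule class; a rule counts as
  *automatically reconstructed* when it is a perfect match or labelled
  as corrected (i.e. manual curation found the generated rule, not the
  ground truth, to be right).
* **Gene-deletion validation** — single-gene deletions on a
  constraint-based model: every reaction whose rule evaluates false
  under the deletion has its flux bounds closed, the biomass optimum is
  recomputed, and the gene is called viable iff the optimum stays
  positive.  Predicted calls against phenotype annotations give a 2x2
  confusion matrix and its accuracy.

The linear programs are solved through COBRApy's optimizer; the GPR
evaluation driving the knockouts is this package's own rule algebra, so
the Boolean semantics under test is the one documented in
:mod:`gprules.gpr_algebra`.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isnan
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .gpr_algebra import (
    DEFAULT_GENE_CAP,
    GeneRef,
    GPRExpression,
    Kind,
    MatchStatus,
    ComparisonResult,
    RuleClass,
    compare_rules,
    evaluate,
    jaccard_index,
    parse_rule,
)
from .snapshot_io import RulesTable

__all__ = [
    "ClassCounts",
    "EvaluationSummary",
    "Viability",
    "ViabilityOutcome",
    "ConfusionMatrix",
    "InfeasibleWildTypeError",
    "DEFAULT_FLUX_TOLERANCE",
    "evaluation_category",
    "evaluate_rules_table",
    "global_jaccard",
    "gene_deletion_viability",
    "single_gene_deletions",
    "confusion_matrix",
]

#: A biomass optimum above this value counts as positive (viable).
DEFAULT_FLUX_TOLERANCE = 1e-9

HISTOGRAM_BINS = 10


class InfeasibleWildTypeError(RuntimeError):
    """The unperturbed model has no positive biomass optimum."""


def evaluation_category(label: str) -> Optional[str]:
    """Normalize an Evaluation label: perfect / corrected / not_automatic.

    Matching is prefix-based and case-insensitive so the verbose labels
    of published comparison tables map without naming their tool.
    Unknown or empty labels yield ``None``.
    """
    low = label.strip().lower()
    if not low:
        return None
    if low.startswith("perfect"):
        return "perfect"
    if low.startswith("corrected"):
        return "corrected"
    if low.startswith("not auto"):
        return "not_automatic"
    return None


@dataclass
class ClassCounts:
    total: int = 0
    perfect: int = 0
    corrected: int = 0
    not_automatic: int = 0

    @property
    def automatic(self) -> int:
        return self.perfect + self.corrected


@dataclass
class EvaluationSummary:
    """Aggregate outcome of comparing a whole rules table."""

    per_reaction: dict[str, ComparisonResult]
    counts: dict[RuleClass, ClassCounts]
    global_jaccard: float
    jaccard_histogram: tuple[int, ...]
    hamming_histogram: tuple[int, ...]
    excluded: tuple[tuple[str, str, str], ...]  # unparseable rows: (rxn, column, error)

    @property
    def n_rows(self) -> int:
        return len(self.per_reaction)

    @property
    def n_perfect(self) -> int:
        return sum(c.perfect for c in self.counts.values())

    @property
    def automatic_fraction(self) -> float:
        total = sum(c.total for c in self.counts.values())
        if total == 0:
            return float("nan")
        return sum(c.automatic for c in self.counts.values()) / total

    @property
    def not_automatic_fraction(self) -> float:
        return 1.0 - self.automatic_fraction


def _histogram(values: Sequence[float]) -> tuple[int, ...]:
    counts, _ = np.histogram(values, bins=HISTOGRAM_BINS, range=(0.0, 1.0))
    return tuple(int(c) for c in counts)


def evaluate_rules_table(
    table: RulesTable, cap: int = DEFAULT_GENE_CAP
) -> EvaluationSummary:
    """Compare every row of a rules table against its ground truth.

    Rows whose rule strings do not parse are excluded and reported.
    Classes are taken from the original (ground-truth) rule.  The
    ``corrected``/``not_automatic`` tallies come from the Evaluation
    labels when present; rows that are neither perfect nor labelled
    corrected count as not automatic.
    """
    per_reaction: dict[str, ComparisonResult] = {}
    counts: dict[RuleClass, ClassCounts] = {cls: ClassCounts() for cls in RuleClass}
    excluded: list[tuple[str, str, str]] = []
    negatives_jaccard: list[float] = []
    hammings: list[float] = []
    originals: dict[str, GPRExpression] = {}
    generated: dict[str, GPRExpression] = {}

    for row in table.rows:
        try:
            original = parse_rule(row.rule_original)
        except Exception as exc:
            excluded.append((row.rxn, "rule_original", str(exc)))
            continue
        try:
            produced = parse_rule(row.rule_generated)
        except Exception as exc:
            excluded.append((row.rxn, "rule_generated", str(exc)))
            continue
        result = compare_rules(original, produced, cap=cap)
        per_reaction[row.rxn] = result
        originals[row.rxn] = original
        generated[row.rxn] = produced
        bucket = counts[result.rule_class_original]
        bucket.total += 1
        category = evaluation_category(row.evaluation)
        if result.status is MatchStatus.PERFECT:
            bucket.perfect += 1
        elif category == "corrected":
            bucket.corrected += 1
        else:
            bucket.not_automatic += 1
        if result.status is MatchStatus.NEGATIVE:
            negatives_jaccard.append(result.jaccard)
            if result.hamming_similarity is not None:
                hammings.append(result.hamming_similarity)

    pooled_original = set().union(*(e.genes() for e in originals.values())) if originals else set()
    pooled_generated = set().union(*(e.genes() for e in generated.values())) if generated else set()
    return EvaluationSummary(
        per_reaction=per_reaction,
        counts=counts,
        global_jaccard=jaccard_index(pooled_original, pooled_generated),
        jaccard_histogram=_histogram(negatives_jaccard),
        hamming_histogram=_histogram(hammings),
        excluded=tuple(excluded),
    )


def global_jaccard(table: RulesTable, method: str = "pooled") -> float:
    """Global Jaccard index between original and generated gene content.

    ``pooled`` (default): one Jaccard index between the unions of all
    genes appearing in the original rules and in the generated rules.
    ``mean``: the average of the per-reaction Jaccard indices.
    """
    originals, generated, per_rxn = set(), set(), []
    for row in table.rows:
        try:
            o = parse_rule(row.rule_original)
            g = parse_rule(row.rule_generated)
        except Exception:
            continue
        originals |= o.genes()
        generated |= g.genes()
        per_rxn.append(jaccard_index(o.genes(), g.genes()))
    if method == "pooled":
        return jaccard_index(originals, generated)
    if method == "mean":
        return float(np.mean(per_rxn)) if per_rxn else float("nan")
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Gene-deletion validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Viability:
    VIABLE = "viable"
    NOT_VIABLE = "not_viable"


@dataclass(frozen=True)
class ViabilityOutcome:
    gene: GeneRef
    predicted: str
    annotated: str

    def __post_init__(self) -> None:
        for value in (self.predicted, self.annotated):
            if value not in (Viability.VIABLE, Viability.NOT_VIABLE):
                raise ValueError(f"viability must be viable/not_viable, got {value!r}")


def _knockouts(
    rules: Mapping[str, GPRExpression], deleted: frozenset[GeneRef]
) -> list[str]:
    """Reactions whose rule evaluates false once ``deleted`` genes are off.

    Empty rules are never constrained: a no-gene reaction cannot be
    knocked out by gene deletion.
    """
    closed = []
    for rid, expr in rules.items():
        if expr.kind is Kind.EMPTY:
            continue
        assignment = {g: g not in deleted for g in expr.genes()}
        if not evaluate(expr, assignment):
            closed.append(rid)
    return closed


def gene_deletion_viability(
    model,
    rules: Mapping[str, GPRExpression],
    biomass_reaction: str,
    genes: Union[GeneRef, Iterable[GeneRef]],
    tolerance: float = DEFAULT_FLUX_TOLERANCE,
) -> str:
    """Viability call for deleting one gene (or a gene set) in an FBA model.

    ``model`` is a COBRApy model; ``rules`` maps its reaction ids to GPR
    expressions.  Deleted genes are set false in every rule; reactions
    whose rule evaluates false get zero flux bounds; the biomass optimum
    is then recomputed and compared to ``tolerance``.

    Raises
    ------
    InfeasibleWildTypeError
        If the wild-type model has no positive biomass optimum.
    """
    deleted = frozenset([genes]) if isinstance(genes, GeneRef) else frozenset(genes)
    model.objective = biomass_reaction
    wild_type = model.slim_optimize()
    if isnan(wild_type) or wild_type <= tolerance:
        raise InfeasibleWildTypeError(
            f"wild-type biomass optimum is not positive (got {wild_type!r})"
        )
    with model:
        for rid in _knockouts(rules, deleted):
            if model.reactions.has_id(rid):
                model.reactions.get_by_id(rid).bounds = (0.0, 0.0)
        optimum = model.slim_optimize()
    if isnan(optimum) or optimum <= tolerance:
        return Viability.NOT_VIABLE
    return Viability.VIABLE


def single_gene_deletions(
    model,
    rules: Mapping[str, GPRExpression],
    biomass_reaction: str,
    annotations: Mapping[GeneRef, str],
    tolerance: float = DEFAULT_FLUX_TOLERANCE,
) -> list[ViabilityOutcome]:
    """Run one deletion per annotated gene and pair calls with phenotype."""
    outcomes = []
    for gene in sorted(annotations):
        predicted = gene_deletion_viability(
            model, rules, biomass_reaction, gene, tolerance
        )
        outcomes.append(ViabilityOutcome(gene, predicted, annotations[gene]))
    return outcomes


@dataclass
class ConfusionMatrix:
    """2x2 counts over (predicted, annotated) viability calls."""

    counts: dict[tuple[str, str], int]
    total: int

    @property
    def accuracy(self) -> float:
        correct = (
            self.counts[(Viability.VIABLE, Viability.VIABLE)]
            + self.counts[(Viability.NOT_VIABLE, Viability.NOT_VIABLE)]
        )
        return correct / self.total

    def frequencies(self) -> dict[tuple[str, str], float]:
        """Relative frequency of each cell (cells sum to one)."""
        return {key: value / self.total for key, value in self.counts.items()}


def confusion_matrix(outcomes: Sequence[ViabilityOutcome]) -> ConfusionMatrix:
    """Tally viability outcomes into a confusion matrix with accuracy."""
    if not outcomes:
        raise ValueError("cannot build a confusion matrix from zero outcomes")
    cells = {
        (p, a): 0
        for p in (Viability.VIABLE, Viability.NOT_VIABLE)
        for a in (Viability.VIABLE, Viability.NOT_VIABLE)
    }
    for outcome in outcomes:
        cells[(outcome.predicted, outcome.annotated)] += 1
    return ConfusionMatrix(cells, len(outcomes))
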