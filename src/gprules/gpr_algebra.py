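"""Boolean algebra for gene-protein-reaction (GPR) rules.

A GPR rule is a Boolean expression over gene identifiers in which the AND
operator joins genes encoding distinct subunits of one enzyme complex
(all jointly required) and the OR operator joins alternative isoforms
(any one sufficient).  This module provides parsing, canonical
serialization, evaluation, truth-table construction, structural
classification and semantic comparison of such expressions.

Expressions are immutable trees normalized on construction: associative
nesting is flattened, duplicate children are removed, and children are
kept in a deterministic canonical order, so structural equality of two
normalized trees is a meaningful (conservative) equivalence test.

Semantic equivalence is decided by truth-table enumeration up to a
configurable gene cap (default 20, above which enumeration of 2^N rows
becomes impractical); beyond the cap a canonical-form comparison is used
which is exact for AND-only and OR-only rules and conservative
(``INDETERMINATE``) otherwise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "GeneRef",
    "Kind",
    "GPRExpression",
    "EMPTY",
    "TruthTable",
    "RuleClass",
    "Equivalence",
    "MatchStatus",
    "ComparisonResult",
    "GPRParseError",
    "MissingGeneError",
    "TruthTableCapacityError",
    "DEFAULT_GENE_CAP",
    "parse_rule",
    "serialize_rule",
    "evaluate",
    "truth_table",
    "classify_rule",
    "canonical_form",
    "rules_equivalent",
    "jaccard_index",
    "hamming_similarity",
    "compare_rules",
]

#: Above this many distinct genes, truth tables are not enumerated and
#: rule comparison falls back to canonical-form comparison.
DEFAULT_GENE_CAP = 20

_FORBIDDEN_WORDS = {"and", "or"}


class GPRParseError(ValueError):
    """Raised for malformed rule strings; carries the character offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class MissingGeneError(KeyError):
    """Raised when an assignment does not cover a gene of the expression."""


class TruthTableCapacityError(ValueError):
    """Raised when a truth table over more than ``cap`` genes is requested."""


@dataclass(frozen=True, order=True)
class GeneRef:
    """A reference to a gene in a named identifier scheme.

    Parameters
    ----------
    identifier:
        Non-empty token; must contain no whitespace or parentheses and
        must not be the bare keyword ``and``/``or``.  Comparison is
        case-preserving.
    namespace:
        Label of the identifier scheme (e.g. ``model``, ``kegg-gene``,
        ``gene-symbol``).
    """

    identifier: str
    namespace: str = "model"

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("gene identifier must be non-empty")
        if re.search(r"[\s()]", self.identifier):
            raise ValueError(
                f"gene identifier {self.identifier!r} contains whitespace or parentheses"
            )
        if self.identifier.lower() in _FORBIDDEN_WORDS:
            raise ValueError(f"gene identifier may not be the keyword {self.identifier!r}")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.identifier


class Kind(Enum):
    """Node kind of a :class:`GPRExpression`."""

    EMPTY = "empty"
    GENE = "gene"
    AND = "and"
    OR = "or"


@dataclass(frozen=True)
class GPRExpression:
    """Immutable, normalized Boolean expression tree over genes.

    Use the constructors :meth:`from_gene`, :meth:`conjunction`,
    :meth:`disjunction` and the module constant :data:`EMPTY`; the raw
    dataclass constructor performs no normalization.
    """

    kind: Kind
    gene: Optional[GeneRef] = None
    children: tuple["GPRExpression", ...] = ()

    # -- constructors ---------------------------------------------------
    @staticmethod
    def from_gene(gene: GeneRef) -> "GPRExpression":
        return GPRExpression(Kind.GENE, gene=gene)

    @staticmethod
    def conjunction(children: Iterable["GPRExpression"]) -> "GPRExpression":
        return _combine(Kind.AND, children)

    @staticmethod
    def disjunction(children: Iterable["GPRExpression"]) -> "GPRExpression":
        return _combine(Kind.OR, children)

    # -- queries --------------------------------------------------------
    def genes(self) -> frozenset[GeneRef]:
        """The set of genes appearing in the expression."""
        if self.kind is Kind.EMPTY:
            return frozenset()
        if self.kind is Kind.GENE:
            return frozenset((self.gene,))
        out: set[GeneRef] = set()
        for c in self.children:
            out.update(c.genes())
        return frozenset(out)

    def __str__(self) -> str:
        return serialize_rule(self)


EMPTY = GPRExpression(Kind.EMPTY)
"""The empty rule: no gene is required for catalysis."""


def _sort_key(expr: GPRExpression):
    ids = tuple(sorted((g.identifier, g.namespace) for g in expr.genes()))
    return (ids, serialize_rule(expr))


def _combine(kind: Kind, children: Iterable[GPRExpression]) -> GPRExpression:
    flat: list[GPRExpression] = []
    for child in children:
        if child.kind is Kind.EMPTY:
            raise ValueError("EMPTY may not appear as an operand")
        if child.kind is kind:
            flat.extend(child.children)
        else:
            flat.append(child)
    deduped: list[GPRExpression] = []
    for child in flat:
        if child not in deduped:
            deduped.append(child)
    if not deduped:
        raise ValueError("operator node requires at least one operand")
    if len(deduped) == 1:
        return deduped[0]
    deduped.sort(key=_sort_key)
    return GPRExpression(kind, children=tuple(deduped))


# ---------------------------------------------------------------------------
# Parsing and serialization
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<word>[^\s()]+))")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:  # only trailing whitespace remains
            break
        pos = m.end()
        offset = m.start("lpar") if m.group("lpar") else (
            m.start("rpar") if m.group("rpar") else m.start("word")
        )
        if m.group("lpar"):
            tokens.append(("(", "(", offset))
        elif m.group("rpar"):
            tokens.append((")", ")", offset))
        else:
            word = m.group("word")
            low = word.lower()
            if low in _FORBIDDEN_WORDS:
                tokens.append((low, word, offset))
            else:
                tokens.append(("gene", word, offset))
    return tokens


class _Parser:
    """Recursive-descent parser; precedence AND > OR, keywords any case."""

    def __init__(self, text: str, namespace: str):
        self.text = text
        self.namespace = namespace
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        if tok is not None:
            self.pos += 1
        return tok

    def fail(self, message: str) -> GPRParseError:
        tok = self.peek()
        offset = tok[2] if tok is not None else len(self.text)
        return GPRParseError(message, offset)

    def parse(self) -> GPRExpression:
        if not self.tokens:
            return EMPTY
        expr = self.expression()
        if self.peek() is not None:
            raise self.fail(f"unexpected token {self.peek()[1]!r}")
        return expr

    def expression(self) -> GPRExpression:
        operands = [self.term()]
        while self.peek() is not None and self.peek()[0] == "or":
            self.take()
            operands.append(self.term())
        return operands[0] if len(operands) == 1 else GPRExpression.disjunction(operands)

    def term(self) -> GPRExpression:
        operands = [self.factor()]
        while self.peek() is not None and self.peek()[0] == "and":
            self.take()
            operands.append(self.factor())
        return operands[0] if len(operands) == 1 else GPRExpression.conjunction(operands)

    def factor(self) -> GPRExpression:
        tok = self.peek()
        if tok is None:
            raise self.fail("dangling operator: expected gene or '('")
        kind, value, offset = tok
        if kind == "(":
            self.take()
            if self.peek() is not None and self.peek()[0] == ")":
                raise self.fail("empty parentheses")
            inner = self.expression()
            closing = self.peek()
            if closing is None or closing[0] != ")":
                raise GPRParseError("unbalanced parentheses: missing ')'", offset)
            self.take()
            return inner
        if kind == "gene":
            self.take()
            return GPRExpression.from_gene(GeneRef(value, self.namespace))
        raise self.fail(f"empty operand before {value!r}")


def parse_rule(text: str, namespace: str = "model") -> GPRExpression:
    """Parse a rule string into a normalized :class:`GPRExpression`.

    Keywords ``and``/``or`` are accepted in any letter case; whitespace
    is arbitrary; empty or whitespace-only text yields :data:`EMPTY`.
    Operator precedence is AND over OR, so ``g1 and g2 or g3`` equals
    ``(g1 and g2) or g3``.

    Raises
    ------
    GPRParseError
        On unbalanced parentheses, dangling operators or empty operands,
        naming the character offset of the problem.
    """
    return _Parser(text, namespace).parse()


def serialize_rule(expr: GPRExpression) -> str:
    """Serialize an expression to its canonical rule string.

    Children of an operator are emitted in the canonical order fixed at
    construction (lexicographic on their gene-set signature); nested
    operators are parenthesized; keywords are lowercase.  ``EMPTY``
    serializes to the empty string.  ``parse_rule(serialize_rule(e))``
    reproduces ``e`` exactly.
    """
    if expr.kind is Kind.EMPTY:
        return ""
    if expr.kind is Kind.GENE:
        return expr.gene.identifier
    keyword = " and " if expr.kind is Kind.AND else " or "
    parts = []
    for child in expr.children:
        text = serialize_rule(child)
        if child.kind in (Kind.AND, Kind.OR):
            text = f"({text})"
        parts.append(text)
    return keyword.join(parts)


# ---------------------------------------------------------------------------
# Evaluation, truth tables
# ---------------------------------------------------------------------------


def evaluate(expr: GPRExpression, assignment: Mapping[GeneRef, bool]) -> bool:
    """Evaluate an expression under a truth assignment of its genes.

    ``EMPTY`` evaluates to ``False`` by convention (a no-gene reaction is
    handled specially by deletion analysis and never constrained).

    Raises
    ------
    MissingGeneError
        If the assignment does not cover some gene of the expression.
    """
    if expr.kind is Kind.EMPTY:
        return False
    if expr.kind is Kind.GENE:
        try:
            return bool(assignment[expr.gene])
        except KeyError:
            raise MissingGeneError(
                f"assignment missing gene {expr.gene.identifier!r}"
            ) from None
    if expr.kind is Kind.AND:
        return all(evaluate(c, assignment) for c in expr.children)
    return any(evaluate(c, assignment) for c in expr.children)


@dataclass(frozen=True)
class TruthTable:
    """Truth table of an expression over an ordered gene list.

    Row ``i`` holds the expression value under the assignment in which
    variable ``j`` is true iff bit ``j`` of ``i`` is set; ``outputs`` has
    length ``2**len(variables)`` exactly.
    """

    variables: tuple[GeneRef, ...]
    outputs: np.ndarray = field(compare=False)

    def __post_init__(self) -> None:
        if len(self.outputs) != 2 ** len(self.variables):
            raise ValueError("outputs length must be 2**len(variables)")


def _columns(order: Sequence[GeneRef]) -> dict[GeneRef, np.ndarray]:
    n = len(order)
    rows = np.arange(2**n, dtype=np.uint32)
    return {g: ((rows >> j) & 1).astype(bool) for j, g in enumerate(order)}


def _eval_vec(expr: GPRExpression, cols: Mapping[GeneRef, np.ndarray], rows: int) -> np.ndarray:
    if expr.kind is Kind.EMPTY:
        return np.zeros(rows, dtype=bool)
    if expr.kind is Kind.GENE:
        return cols[expr.gene]
    out = _eval_vec(expr.children[0], cols, rows)
    for child in expr.children[1:]:
        if expr.kind is Kind.AND:
            out = out & _eval_vec(child, cols, rows)
        else:
            out = out | _eval_vec(child, cols, rows)
    return out


def truth_table(
    expr: GPRExpression,
    order: Sequence[GeneRef],
    cap: int = DEFAULT_GENE_CAP,
) -> TruthTable:
    """Enumerate the truth table of ``expr`` over the gene order ``order``.

    ``order`` must cover the genes of ``expr`` (it may include extra
    genes) and contain at most ``cap`` entries.  The empty rule over the
    empty order yields the single-row table ``(False,)``.
    """
    order = tuple(order)
    if len(order) > cap:
        raise TruthTableCapacityError(
            f"{len(order)} genes exceed the truth-table cap of {cap}; "
            "use canonical comparison instead"
        )
    missing = expr.genes() - set(order)
    if missing:
        names = ", ".join(sorted(g.identifier for g in missing))
        raise MissingGeneError(f"order does not cover genes: {names}")
    if len(set(order)) != len(order):
        raise ValueError("gene order contains duplicates")
    rows = 2 ** len(order)
    return TruthTable(order, _eval_vec(expr, _columns(order), rows))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


class RuleClass(Enum):
    """Structural class of a GPR rule.

    ``NO_GENE`` (empty rule), ``ONE_GENE`` (a single gene), and the three
    multi-gene classes: ``OR`` (only OR operators), ``AND`` (only AND
    operators), ``MIXED`` (both).
    """

    NO_GENE = "No gene"
    ONE_GENE = "One gene"
    OR = "OR"
    AND = "AND"
    MIXED = "Mixed"


def _operators(expr: GPRExpression) -> set[Kind]:
    if expr.kind in (Kind.EMPTY, Kind.GENE):
        return set()
    ops = {expr.kind}
    for child in expr.children:
        ops |= _operators(child)
    return ops


def classify_rule(expr: GPRExpression) -> RuleClass:
    """Classify a normalized expression into one of the five rule classes."""
    if expr.kind is Kind.EMPTY:
        return RuleClass.NO_GENE
    if expr.kind is Kind.GENE:
        return RuleClass.ONE_GENE
    ops = _operators(expr)
    if ops == {Kind.OR}:
        return RuleClass.OR
    if ops == {Kind.AND}:
        return RuleClass.AND
    return RuleClass.MIXED


# ---------------------------------------------------------------------------
# Comparison
# ---------------------------------------------------------------------------


class Equivalence(Enum):
    EQUIVALENT = "equivalent"
    NOT_EQUIVALENT = "not_equivalent"
    INDETERMINATE = "indeterminate"


def canonical_form(expr: GPRExpression) -> GPRExpression:
    """Canonicalize: flatten, dedupe, absorb (``x or (x and y) -> x``), sort.

    Exact (i.e. two rules are equivalent iff their canonical forms are
    structurally equal) for AND-only and OR-only rules; a conservative
    normal form otherwise.
    """
    if expr.kind in (Kind.EMPTY, Kind.GENE):
        return expr
    children = [canonical_form(c) for c in expr.children]
    rebuilt = _combine(expr.kind, children)
    if rebuilt.kind in (Kind.EMPTY, Kind.GENE):
        return rebuilt
    # absorption among term-like children (genes or pure opposite-operator
    # groups of genes): a child whose gene set strictly contains another
    # term's gene set is redundant.
    opposite = Kind.AND if rebuilt.kind is Kind.OR else Kind.OR
    kept: list[GPRExpression] = []
    sets: list[Optional[frozenset[GeneRef]]] = []
    for child in rebuilt.children:
        if child.kind is Kind.GENE or (
            child.kind is opposite and all(g.kind is Kind.GENE for g in child.children)
        ):
            sets.append(child.genes())
        else:
            sets.append(None)  # nested structure: do not absorb
    for i, child in enumerate(rebuilt.children):
        absorbed = False
        if sets[i] is not None:
            for j, other in enumerate(sets):
                if j == i or other is None:
                    continue
                if other < sets[i] or (other == sets[i] and j < i):
                    absorbed = True
                    break
        if not absorbed:
            kept.append(child)
    return _combine(rebuilt.kind, kept) if kept else rebuilt


def rules_equivalent(
    a: GPRExpression, b: GPRExpression, cap: int = DEFAULT_GENE_CAP
) -> Equivalence:
    """Decide semantic equivalence of two rules.

    When the union gene set has at most ``cap`` members, the decision is
    exact, by comparing truth tables over the union variable set.  Above
    the cap, canonical forms are compared: equal forms are equivalent,
    differing forms are not equivalent whenever neither rule is MIXED
    (set comparison is exact for AND-only/OR-only rules), and
    ``INDETERMINATE`` otherwise.
    """
    union = sorted(a.genes() | b.genes())
    if len(union) <= cap:
        ta = truth_table(a, union, cap=cap)
        tb = truth_table(b, union, cap=cap)
        equal = bool(np.array_equal(ta.outputs, tb.outputs))
        return Equivalence.EQUIVALENT if equal else Equivalence.NOT_EQUIVALENT
    if canonical_form(a) == canonical_form(b):
        return Equivalence.EQUIVALENT
    if classify_rule(a) is not RuleClass.MIXED and classify_rule(b) is not RuleClass.MIXED:
        return Equivalence.NOT_EQUIVALENT
    return Equivalence.INDETERMINATE


def jaccard_index(a: Iterable, b: Iterable) -> float:
    """Jaccard index |a∩b| / |a∪b| between two gene sets.

    Two empty sets score 1.0: equal sets must count as full overlap.
    """
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


def hamming_similarity(a: TruthTable, b: TruthTable) -> float:
    """Fraction of rows on which two truth tables agree.

    Oriented as a similarity: 1.0 for identical tables, 0.0 for
    complementary ones.  Both tables must be built over the same
    variable order.
    """
    if a.variables != b.variables:
        raise ValueError("truth tables must share the same variable order")
    return float(np.mean(a.outputs == b.outputs))


class MatchStatus(Enum):
    PERFECT = "perfect"
    NEGATIVE = "negative"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of comparing a generated rule against its ground truth.

    ``hamming_similarity`` is present only for negative matches whose
    gene sets coincide (Jaccard 1) and fit under the truth-table cap;
    it quantifies operator-level disagreement once gene-set differences
    are excluded.
    """

    status: MatchStatus
    jaccard: float
    hamming_similarity: Optional[float]
    rule_class_original: RuleClass
    rule_class_generated: RuleClass


def compare_rules(
    original: GPRExpression,
    generated: GPRExpression,
    cap: int = DEFAULT_GENE_CAP,
) -> ComparisonResult:
    """Compare two rules: equivalence, then Jaccard, then Hamming.

    Equivalent rules are a PERFECT match (Jaccard reported as 1.0: the
    rules are logically identical).  Otherwise the Jaccard index over
    the two gene sets localizes the mismatch; only when the gene sets
    coincide is the normalized Hamming similarity of the two truth
    tables (shared variable order) attached.
    """
    verdict = rules_equivalent(original, generated, cap=cap)
    cls_o, cls_g = classify_rule(original), classify_rule(generated)
    if verdict is Equivalence.EQUIVALENT:
        return ComparisonResult(MatchStatus.PERFECT, 1.0, None, cls_o, cls_g)
    jac = jaccard_index(original.genes(), generated.genes())
    status = (
        MatchStatus.NEGATIVE
        if verdict is Equivalence.NOT_EQUIVALENT
        else MatchStatus.INDETERMINATE
    )
    hamming: Optional[float] = None
    if status is MatchStatus.NEGATIVE and jac == 1.0:
        order = sorted(original.genes())
        if len(order) <= cap:
            hamming = hamming_similarity(
                truth_table(original, order, cap=cap),
                truth_table(generated, order, cap=cap),
            )
    return ComparisonResult(status, jac, hamming, cls_o, cls_g)
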