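"""Shared fixtures: gene shorthands, a toy FBA model, a tiny snapshot."""

from __future__ import annotations

import random

import pytest

from gprules.gpr_algebra import GeneRef, parse_rule


@pytest.fixture
def g():
    """Shorthand factory for model-namespace gene references."""
    return lambda name: GeneRef(name)


# ---------------------------------------------------------------------------
# Independent random-expression machinery (test-side oracle; kept free of
# the package's expression type so it can check it)
# ---------------------------------------------------------------------------


def random_expr(rng: random.Random, genes: list[str], depth: int = 0):
    """A random expression as nested tuples: 'gX' | ('and'|'or', [subs])."""
    if depth >= 3 or rng.random() < 0.35:
        return rng.choice(genes)
    op = rng.choice(["and", "or"])
    n = rng.randint(2, 3)
    return (op, [random_expr(rng, genes, depth + 1) for _ in range(n)])


def render(node) -> str:
    if isinstance(node, str):
        return node
    op, subs = node
    return "(" + f" {op} ".join(render(s) for s in subs) + ")"


def node_genes(node) -> set[str]:
    if isinstance(node, str):
        return {node}
    return set().union(*(node_genes(s) for s in node[1]))


def eval_node(node, assignment: dict[str, bool]) -> bool:
    """Brute-force evaluator over the tuple structure (oracle)."""
    if isinstance(node, str):
        return assignment[node]
    op, subs = node
    values = [eval_node(s, assignment) for s in subs]
    return all(values) if op == "and" else any(values)


@pytest.fixture
def expr_oracle():
    return random_expr, render, node_genes, eval_node


# ---------------------------------------------------------------------------
# Toy FBA model: linear chain with an isoform bypass, hand-solvable
# ---------------------------------------------------------------------------

TOY_RULES = {
    "EX_A": "",
    "T1": "g1",  # A -> B: sole gene, essential
    "T2": "g3 and g4",  # B -> P: complex, bypassed by ALT
    "ALT": "g2 or g5",  # B -> P: isoforms
    "BIO": "",  # P -> (objective)
}


def build_toy_model():
    """5-reaction chain: uptake -> A -T1-> B -(T2|ALT)-> P -> biomass.

    Wild-type optimum is 10 (the uptake bound).  By hand: deleting g1
    closes the only A->B step (not viable); every other single deletion
    leaves a B->P route open (viable).
    """
    import cobra

    model = cobra.Model("toy")
    a = cobra.Metabolite("A", compartment="c")
    b = cobra.Metabolite("B", compartment="c")
    p = cobra.Metabolite("P", compartment="c")

    def rxn(rid, stoich, lb=0.0, ub=1000.0):
        reaction = cobra.Reaction(rid)
        reaction.lower_bound, reaction.upper_bound = lb, ub
        reaction.add_metabolites(stoich)
        return reaction

    reactions = [
        rxn("EX_A", {a: 1}, ub=10.0),
        rxn("T1", {a: -1, b: 1}),
        rxn("T2", {b: -1, p: 1}),
        rxn("ALT", {b: -1, p: 1}),
        rxn("BIO", {p: -1}),
    ]
    model.add_reactions(reactions)
    model.objective = "BIO"
    return model


@pytest.fixture
def toy_fba():
    rules = {rid: parse_rule(text) for rid, text in TOY_RULES.items()}
    return build_toy_model(), rules
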