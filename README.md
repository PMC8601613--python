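# gprules

Automatic reconstruction and evaluation of **gene–protein–reaction (GPR)
rules** for genome-scale metabolic models.

A GPR rule is the Boolean expression attached to a metabolic reaction that
states which gene products enable its catalysis: the `and` operator joins
genes encoding distinct **subunits** of one enzyme complex (all jointly
required), the `or` operator joins **isoforms** (alternative enzymes, any one
sufficient). Reactions catalysed non-enzymatically carry the empty rule.
Correct GPRs are what make gene-knockout simulation and expression-data
integration in constraint-based models meaningful, yet in practice they are
still largely hand-curated.

`gprules` reconstructs these rules fully offline from *snapshot bundles* —
plain-text tables emulating the content of compound dictionaries (names,
synonyms, InChI), reaction databases (participants, stoichiometry, EC
numbers, catalysing genes), transporter classifications (TC codes and
substrates), protein annotation text, curated macromolecular complexes,
interaction networks with functional-term enrichment, and orthology groups.
It also ships the full evaluation machinery used to benchmark reconstructed
rules against a curated ground truth.

## Method at a glance

Starting from a draft model (SBML or a TSV reaction list) or from an
organism name:

1. **Metabolite identification** — each model metabolite label is resolved
   against the compound dictionary by a cascade: configurable alias table →
   exact name/synonym → InChI → fuzzy token-sort Levenshtein score, with
   automatic acceptance only for a unique best candidate scoring ≥ 91 on the
   0–100 scale; otherwise a shortlist is returned for confirmation.
2. **Reaction and gene identification** — reaction records from all sources
   are merged into a *macro database* keyed by a canonical
   participant-and-stoichiometry signature (orientation-insensitive).
   Internal reactions are matched by signature lookup; transport reactions
   (a compound changing compartment) additionally query transporter records
   by transported substrate. A localization filter then keeps only genes
   whose subcellular annotation is compatible with the reaction compartment,
   preferring manually curated terms over automatic predictions.
3. **Relationship mining** — for every gene pair of a reaction, SUBUNIT vs
   ISOFORM labels are collected from five channels: keyword-guided mining of
   protein "Interaction" and "Function" annotation text (keywords *complex*,
   *component*, *interact*, *by similarity*, plus phrases such as
   *part of a complex with*), complex-membership records, interaction-network
   neighbours sharing a complex term, and orthology groups (isoforms).
   Conflicts are settled by source priority; unevidenced pairs default to
   ISOFORM.
4. **Rule assembly** — connected components of the SUBUNIT graph become
   parenthesized `and` groups, joined by `or` (complexes first, isoforms
   layered on top). Explicit complex sets let a shared subunit appear in
   several alternative complexes.

**Evaluation**: two rules count as identical only if their truth tables over
the 2^N assignments agree exactly (N ≤ 20 by default; above the cap a
canonical-form comparison is used, exact for pure-`and`/pure-`or` rules).
Negative matches are decomposed with the Jaccard index |A∩B|/|A∪B| over gene
sets and, when the gene sets coincide, the normalized Hamming similarity
between truth tables (1 = identical, 0 = complementary). Flux-balance
single-gene deletions (via COBRApy) compare predicted viability — positive
biomass optimum after closing all reactions whose rule evaluates false —
against phenotype annotations in a 2×2 confusion matrix.

## Worked example

Generate a 15-reaction synthetic organism (snapshot + draft model + planted
ground-truth rules), reconstruct the rules, and evaluate them:

```bash
gprules make-fixture --out-dir fx --seed 3 --n-reactions 15 --n-genes 150
gprules reconstruct-list --model fx/model.tsv --snapshot fx/snapshot --out-dir run
head -4 run/rules.csv
```

```
Rxn,rule_original,rule_generated,Evaluation
R0000,,(G0000 and G0001) or G0002,
R0001,,,
R0002,,G0003,
```

`R0000` was planted as a two-subunit complex with a single-gene isoform
alternative and is reconstructed as `(G0000 and G0001) or G0002`; `R0001` is
a no-gene reaction (empty rule); `R0002` is a one-gene rule. Splicing the
generated column into the ground-truth table and evaluating:

```bash
gprules evaluate --rules merged.csv --out-dir eval
```

```
15 rules compared: 15 perfect matches, global Jaccard 1.000, automatic 100.0%
```

i.e. every reconstructed rule is truth-table-identical to its planted truth,
and the pooled gene content of the reconstructed rules coincides with the
ground truth (global Jaccard 1.0). Per-class counts land in
`eval/summary.tsv`, per-reaction comparison statistics in
`eval/per_reaction.tsv`, and the Jaccard/Hamming histograms in
`eval/histograms.tsv`.

Other subcommands: `reconstruct-model` (SBML input), `reconstruct-organism`
(name resolved against the snapshot's organism index), and `deletions`
(single-gene-deletion confusion matrix from an SBML model and a phenotype
table).

## Layout

- `src/gprules/gpr_algebra.py` — expression trees, parsing, truth tables,
  classification, equivalence, Jaccard/Hamming comparison
- `src/gprules/relationship_mining.py` — the five evidence channels and
  relation resolution
- `src/gprules/entity_resolution.py` — metabolite matching, macro database,
  transport matching, localization filter, organism mode
- `src/gprules/rule_assembly.py` — relations → Boolean expression
- `src/gprules/snapshot_io.py` — snapshot bundles, SBML/TSV models, rules
  tables
- `src/gprules/evaluation.py` — rule benchmarking and FBA gene deletions
- `src/gprules/synthetic_fixtures.py` — seeded snapshot generator with known
  ground truth
- `src/gprules/pipeline.py`, `src/gprules/cli.py` — orchestration and CLI

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
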